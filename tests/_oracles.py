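"""Independent brute-force oracles used only by the tests.

These deliberately avoid the package's vectorised code paths: catchment
sums use exact rational arithmetic (``fractions.Fraction``) rounded once at
the end, shortest paths are exhaustive simple-path enumeration, and the
rank-sum null is enumerated over all group assignments.
"""

from __future__ import annotations

import itertools
import math
from fractions import Fraction


def oracle_step_weight(minutes: float, bounds, weights) -> float:
    """Piecewise-constant decay weight via an explicit if-chain."""
    if minutes < 0:
        raise ValueError("negative travel time")
    lower = 0.0
    for b, w in zip(bounds, weights):
        if (lower == 0.0 and 0 <= minutes <= b) or (lower < minutes <= b):
            return w
        lower = b
    return 0.0


def oracle_e2sfca(providers, areas, time_of, bounds, weights, scale=100000.0):
    """Double-loop two-step floating catchment with exactly rounded sums.

    ``time_of(area_id, site_id)`` supplies minutes.  Returns
    (ratios by site_id, access by area_id).
    """
    ratios = {}
    for s in providers:
        total = Fraction(0)
        for a in areas:
            w = oracle_step_weight(time_of(a.area_id, s.site_id), bounds, weights)
            total += Fraction(a.population * w)  # the float product, exactly
        demand = float(total)  # correctly rounded sum
        ratios[s.site_id] = s.capacity / demand if demand > 0 else 0.0
    access = {}
    for a in areas:
        total = Fraction(0)
        for s in providers:
            w = oracle_step_weight(time_of(a.area_id, s.site_id), bounds, weights)
            total += Fraction(ratios[s.site_id] * w)
        access[a.area_id] = scale * float(total)
    return ratios, access


def oracle_all_simple_path_time(graph_edges, origin, destination, directed=False):
    """Shortest travel time by exhaustive simple-path enumeration.

    ``graph_edges`` is {(u, v): minutes}; undirected edges are symmetrised.
    """
    adj: dict[str, list[tuple[str, float]]] = {}
    for (u, v), m in graph_edges.items():
        adj.setdefault(u, []).append((v, m))
        if not directed:
            adj.setdefault(v, []).append((u, m))
    best = math.inf

    def walk(node, seen, cost):
        nonlocal best
        if node == destination:
            best = min(best, cost)
            return
        for nxt, m in adj.get(node, []):
            if nxt not in seen:
                walk(nxt, seen | {nxt}, cost + m)

    walk(origin, {origin}, 0.0)
    return best


def oracle_transit_time(stops, lines, walk_time, origin, destination,
                        max_access_walk):
    """Exhaustive enumeration over (line, boarding stop, alighting stop).

    ``lines`` are (stop sequence, segment minutes, headway, bidirectional);
    ``walk_time(a, b)`` gives walking minutes between two points.
    """
    best = walk_time(origin, destination)
    for stop_seq, seg_min, headway, bidirectional in lines:
        for i, j in itertools.permutations(range(len(stop_seq)), 2):
            if i < j:
                ride = sum(seg_min[i:j])
            elif bidirectional:
                ride = sum(seg_min[j:i])
            else:
                continue
            access = walk_time(origin, stops[stop_seq[i]])
            egress = walk_time(stops[stop_seq[j]], destination)
            if access > max_access_walk or egress > max_access_walk:
                continue
            best = min(best, access + headway / 2.0 + ride + egress)
    return best


def oracle_rank_sum_exact_p(x, y) -> float:
    """Two-sided exact rank-sum p by enumerating all group assignments."""
    x, y = list(x), list(y)
    pooled = sorted(x + y)
    assert len(set(pooled)) == len(pooled), "oracle assumes no ties"
    n1 = len(x)
    ranks = {v: i + 1 for i, v in enumerate(pooled)}
    u_obs = sum(ranks[v] for v in x) - n1 * (n1 + 1) / 2
    us = []
    for combo in itertools.combinations(range(len(pooled)), n1):
        r = sum(c + 1 for c in combo)
        us.append(r - n1 * (n1 + 1) / 2)
    total = len(us)
    p_le = sum(u <= u_obs for u in us) / total
    p_ge = sum(u >= u_obs for u in us) / total
    return min(1.0, 2.0 * min(p_le, p_ge))


def oracle_permutation_p(x, y, stat, n_perm, rng) -> float:
    """Monte-Carlo permutation two-sided p for an arbitrary statistic."""
    import numpy as np

    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    obs = abs(stat(x, y))
    pooled = np.concatenate([x, y])
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(pooled)
        if abs(stat(perm[: x.size], perm[x.size:])) >= obs:
            hits += 1
    return (hits + 1) / (n_perm + 1)
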