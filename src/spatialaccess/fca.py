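"""Enhanced two-step floating catchment area (E2SFCA) computation.

Step 1 computes, for every provider site j, the capacity-to-population ratio

    R_j = S_j / sum_k P_k * W(d_kj)

where the sum runs over areas k whose travel time d_kj to the site lies
within the catchment, and W is the step-decay weight.  Step 2 sums the
decay-weighted ratios reachable from each area i,

    A_i = scale * sum_j R_j * W(d_ij),

yielding providers per ``scale`` (default 100,000) population.  The same
area-to-site matrix serves both steps, consistent with patient-travel
semantics.  A site whose catchment holds no population contributes R_j = 0;
an area with no site in catchment gets A_i = 0 exactly.
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import IntegrityError
from .types import AccessSurface, AreaUnit, DecaySchedule, ProviderSite, TravelTimeMatrix

__all__ = ["step_weight", "provider_ratios", "accessibility", "e2sfca", "PER_100K"]

PER_100K = 100_000.0


def step_weight(minutes: float, schedule: DecaySchedule) -> float:
    """Decay weight of a travel time under the zone schedule.

    Zones are half-open ``(lower, upper]`` with 0 in the first zone; times
    beyond the catchment bound (including ``+inf``) weigh 0.  Negative times
    raise a :class:`~spatialaccess.errors.ConfigurationError`.
    """
    return schedule.weight(minutes)


def _aligned_weights(
    areas: Sequence[AreaUnit],
    sites: Sequence[ProviderSite],
    matrix: TravelTimeMatrix,
    schedule: DecaySchedule,
) -> np.ndarray:
    """Decay-weight matrix W(d_kj) aligned to the area/site orders."""
    area_ids = [a.area_id for a in areas]
    site_ids = [s.site_id for s in sites]
    sub = matrix.submatrix(area_ids, site_ids)
    return schedule.weight_array(sub.minutes)


def provider_ratios(
    providers: Sequence[ProviderSite],
    areas: Sequence[AreaUnit],
    matrix: TravelTimeMatrix,
    schedule: DecaySchedule | None = None,
) -> pd.Series:
    """Step 1: per-site ratio R_j of capacity to decay-weighted population.

    Returns a float Series indexed by ``site_id`` in the input site order.
    Sites with no population inside their catchment get R_j = 0.  Missing
    (area, site) pairs in the matrix raise :class:`IntegrityError` listing
    the offending IDs.
    """
    schedule = schedule or DecaySchedule()
    site_ids = [s.site_id for s in providers]
    if len(set(site_ids)) != len(site_ids):
        raise IntegrityError("duplicate site IDs in provider list")
    if not providers:
        return pd.Series(dtype=float, name="ratio").rename_axis("site_id")
    weights = _aligned_weights(areas, providers, matrix, schedule)
    pop = np.asarray([a.population for a in areas], dtype=float)
    products = pop[:, None] * weights  # P_k W(d_kj)
    # correctly-rounded sums make results independent of accumulation order
    demand = np.asarray([math.fsum(products[:, j]) for j in range(products.shape[1])])
    cap = np.asarray([s.capacity for s in providers], dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratios = np.where(demand > 0, cap / demand, 0.0)
    return pd.Series(ratios, index=pd.Index(site_ids, name="site_id"), name="ratio")


def accessibility(
    areas: Sequence[AreaUnit],
    ratios: pd.Series,
    matrix: TravelTimeMatrix,
    schedule: DecaySchedule | None = None,
    scale: float = PER_100K,
    mode: str | None = None,
    classification: str = "",
    period: str = "",
) -> AccessSurface:
    """Step 2: per-area access A_i = scale * sum_j R_j W(d_ij).

    ``ratios`` must come from :func:`provider_ratios` on the same matrix.
    Areas with no site within the catchment get exactly 0.
    """
    schedule = schedule or DecaySchedule()
    area_ids = [a.area_id for a in areas]
    site_ids = [str(s) for s in ratios.index]
    sub = matrix.submatrix(area_ids, site_ids)
    weights = schedule.weight_array(sub.minutes)
    products = weights * ratios.to_numpy(dtype=float)[None, :]  # R_j W(d_ij)
    values = scale * np.asarray([math.fsum(row) for row in products])
    return AccessSurface(
        mode=mode or matrix.mode,
        classification=classification,
        period=period,
        values=pd.Series(values, index=area_ids),
    )


def e2sfca(
    providers: Sequence[ProviderSite],
    areas: Sequence[AreaUnit],
    matrix: TravelTimeMatrix,
    schedule: DecaySchedule | None = None,
    *,
    classification: str | None = None,
    period: str | None = None,
    scale: float = PER_100K,
) -> AccessSurface:
    """Both E2SFCA steps for one provider classification and period.

    Providers are filtered to ``classification`` and ``period`` when given
    (sites already restricted upstream may pass ``None``).  An empty provider
    set yields a valid all-zero surface.
    """
    schedule = schedule or DecaySchedule()
    sites = [
        s
        for s in providers
        if (classification is None or s.classification == classification)
        and (period is None or s.period == period)
    ]
    label_class = classification if classification is not None else (
        sites[0].classification if sites else ""
    )
    label_period = period if period is not None else (sites[0].period if sites else "")
    if not sites:
        values = pd.Series(0.0, index=[a.area_id for a in areas])
        return AccessSurface(matrix.mode, label_class, label_period, values)
    ratios = provider_ratios(sites, areas, matrix, schedule)
    return accessibility(
        areas, ratios, matrix, schedule, scale=scale,
        mode=matrix.mode, classification=label_class, period=label_period,
    )
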