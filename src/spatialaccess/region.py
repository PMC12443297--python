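"""Synthetic toy regions with the statistical structure of U.S. access data.

The generator lays areas on a planar disk whose radial coordinate is measured
in car-travel minutes from a single metro core.  It reproduces, at desk
scale, the qualitative features the downstream measure must be sensitive to:

* providers cluster in the urban core (Pareto-like radial concentration);
* population density declines away from the core;
* transit exists only within a core radius, and every finite transit time is
  the sum of walk access, half-headway wait, in-vehicle time and walk egress;
* rural/urban strata follow distance-from-core quantiles (standing in for
  rural-urban commuting-area codes, whose construction is out of scope);
* deprivation quartiles are pure noise by default, deliberately uncorrelated
  with access;
* later periods add providers, preferentially to specialist classes and near
  the core, creating urban-favouring growth over time;
* specialist access exhibits excess zeros in non-metro areas, which
  :func:`inject_zero_inflation` can force exactly.

All randomness flows from a single integer seed via ``numpy``'s Generator;
identical configurations yield field-identical regions.
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .errors import ConfigurationError
from .types import AreaUnit, ProviderSite, TravelTimeMatrix

__all__ = ["RegionConfig", "SyntheticRegion", "generate_region", "inject_zero_inflation"]

RURAL_URBAN_CLASSES = ("metropolitan", "micropolitan", "small town", "rural")

#: Speed/level-of-service constants, in minutes per planar distance unit.
#: Distance units are calibrated so car speed is 1 (coordinates are in
#: car-minutes); walking is 12x slower (~5 vs ~60 km/h) and transit
#: in-vehicle 2x slower (~30 km/h).
WALK_FACTOR = 12.0
TRANSIT_VEHICLE_FACTOR = 2.0

DEFAULT_MODE_SHARES: dict[str, tuple[float, float, float]] = {
    "metropolitan": (0.80, 0.12, 0.08),
    "micropolitan": (0.90, 0.04, 0.06),
    "small town": (0.93, 0.02, 0.05),
    "rural": (0.96, 0.01, 0.03),
}

#: Per-period fractional provider growth; specialists grow faster than
#: generalists, mirroring the observed urban-favouring divergence.
DEFAULT_GROWTH: dict[str, float] = {"primary_care": 0.15, "specialty_care": 0.50}


@dataclass(frozen=True)
class RegionConfig:
    """Study conditions for one synthetic region.

    ``region_radius_min`` is the car-travel time from the core to the edge of
    the disk; with the default 30-minute catchment, peripheral areas lie well
    outside the reach of core-clustered providers.
    """

    n_areas: int = 400
    n_providers_by_class: Mapping[str, int] = field(
        default_factory=lambda: {"primary_care": 120, "specialty_care": 60}
    )
    metro_fraction: float = 0.35
    provider_urban_concentration: float = 3.0
    transit_coverage_radius_min: float = 20.0
    mode_share_profiles: Mapping[str, tuple[float, float, float]] = field(
        default_factory=lambda: dict(DEFAULT_MODE_SHARES)
    )
    periods: tuple[str, ...] = ("2016Q4", "2019Q4")
    period_growth: Mapping[str, float] | None = None
    region_radius_min: float = 60.0
    transit_headway_min: float = 12.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_areas < 0:
            raise ConfigurationError("n_areas must be >= 0")
        if not 0 <= self.metro_fraction <= 1:
            raise ConfigurationError("metro_fraction must lie in [0, 1]")
        if not self.provider_urban_concentration > 0:
            raise ConfigurationError("provider_urban_concentration must be > 0")
        if any(n < 0 for n in self.n_providers_by_class.values()):
            raise ConfigurationError("n_providers_by_class counts must be >= 0")
        if self.transit_coverage_radius_min < 0:
            raise ConfigurationError("transit_coverage_radius_min must be >= 0")
        if not self.region_radius_min > 0:
            raise ConfigurationError("region_radius_min must be > 0")
        if not self.transit_headway_min > 0:
            raise ConfigurationError("transit_headway_min must be > 0")
        if not self.periods:
            raise ConfigurationError("periods must be a nonempty ordered list")
        for label, triple in self.mode_share_profiles.items():
            if len(triple) != 3 or any(p < 0 for p in triple) or not any(p > 0 for p in triple):
                raise ConfigurationError(
                    f"mode_share_profiles[{label!r}] needs three nonnegative entries, one positive"
                )

    def growth_for(self, classification: str) -> float:
        if self.period_growth is not None:
            return float(self.period_growth.get(classification, 0.0))
        return DEFAULT_GROWTH.get(classification, 0.30)


@dataclass
class SyntheticRegion:
    """Areas, per-period provider sites and per-mode travel-time matrices."""

    config: RegionConfig
    areas: list[AreaUnit]
    providers: dict[str, list[ProviderSite]]  # period -> sites active that period
    matrices: dict[str, TravelTimeMatrix]  # mode -> areas x all-sites minutes

    @property
    def periods(self) -> tuple[str, ...]:
        return self.config.periods

    def sites(self, period: str | None = None, classification: str | None = None) -> list[ProviderSite]:
        pool = self.providers[period] if period else [s for p in self.periods for s in self.providers[p]]
        if classification is not None:
            pool = [s for s in pool if s.classification == classification]
        return pool

    def areas_in(self, rural_urban_class: str) -> list[AreaUnit]:
        return [a for a in self.areas if a.rural_urban_class == rural_urban_class]


def _assign_strata(order: np.ndarray, metro_fraction: float) -> list[str]:
    """Rural/urban labels by distance-from-core rank."""
    n = len(order)
    labels = [""] * n
    n_metro = int(math.ceil(metro_fraction * n)) if metro_fraction > 0 else 0
    n_metro = min(n_metro, n)
    rest = n - n_metro
    # split the remainder into three equal-as-possible distance bands
    cuts = [n_metro + round(rest * k / 3) for k in (1, 2, 3)]
    for rank, idx in enumerate(order):
        if rank < n_metro:
            labels[idx] = "metropolitan"
        elif rank < cuts[0]:
            labels[idx] = "micropolitan"
        elif rank < cuts[1]:
            labels[idx] = "small town"
        else:
            labels[idx] = "rural"
    return labels


def generate_region(config: RegionConfig) -> SyntheticRegion:
    """Build a deterministic synthetic region from its configuration.

    Raises :class:`~spatialaccess.errors.ConfigurationError` naming the
    offending field for invalid configurations.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    R = config.region_radius_min
    n = config.n_areas

    # --- areas: mildly core-densified scatter on the disk -----------------
    r = R * rng.uniform(0, 1, size=n) ** 0.7
    theta = rng.uniform(0, 2 * math.pi, size=n)
    ax, ay = r * np.cos(theta), r * np.sin(theta)
    order = np.argsort(r, kind="stable")
    strata = _assign_strata(order, config.metro_fraction) if n else []

    expected_pop = 900.0 + 4200.0 * np.exp(-1.5 * r / R)
    population = rng.poisson(expected_pop) if n else np.array([], dtype=int)

    # deprivation: noise-only score, quartiles by rank (uncorrelated with access)
    dep_score = rng.uniform(0, 1, size=n)
    dep_rank = np.empty(n, dtype=int)
    dep_rank[np.argsort(dep_score, kind="stable")] = np.arange(n)
    dep_labels = [f"Q{1 + min(3, int(4 * rk / n))}" for rk in dep_rank] if n else []

    areas: list[AreaUnit] = []
    for i in range(n):
        profile = np.asarray(config.mode_share_profiles.get(
            strata[i], DEFAULT_MODE_SHARES["rural"]), dtype=float)
        commuters_total = rng.binomial(int(population[i]), 0.45)
        counts = rng.multinomial(commuters_total, profile / profile.sum())
        areas.append(AreaUnit(
            area_id=f"{i + 1:011d}",  # FIPS-style fixed-width string, leading zeros
            x=float(ax[i]), y=float(ay[i]),
            population=float(population[i]),
            commuters_car=float(counts[0]),
            commuters_transit=float(counts[1]),
            commuters_walk=float(counts[2]),
            rural_urban_class=strata[i],
            deprivation_quartile=dep_labels[i],
        ))

    # --- providers: core-concentrated placement, growth across periods ---
    conc = config.provider_urban_concentration
    providers: dict[str, list[ProviderSite]] = {p: [] for p in config.periods}
    all_sites: list[ProviderSite] = []
    pid_counter = 0

    def place(count: int, classification: str, period_idx: int, concentration: float) -> list[tuple]:
        nonlocal pid_counter
        placed = []
        for _ in range(count):
            pid_counter += 1
            pr = R * rng.uniform() ** concentration
            pth = rng.uniform(0, 2 * math.pi)
            placed.append((f"P{pid_counter:06d}", classification,
                           pr * math.cos(pth), pr * math.sin(pth)))
        return placed

    base_records: dict[str, list[tuple]] = {}
    for classification, count in config.n_providers_by_class.items():
        base_records[classification] = place(count, classification, 0, conc)
        # ~8% of providers practise at a second site (duplicates retained)
        extra = []
        for rec in base_records[classification]:
            if rng.uniform() < 0.08:
                pr = R * rng.uniform() ** conc
                pth = rng.uniform(0, 2 * math.pi)
                extra.append((rec[0], classification, pr * math.cos(pth), pr * math.sin(pth)))
        base_records[classification].extend(extra)

    cumulative: dict[str, list[tuple]] = {c: list(recs) for c, recs in base_records.items()}
    site_counter = 0
    for k, period in enumerate(config.periods):
        if k > 0:
            for classification in list(cumulative):
                growth = config.growth_for(classification)
                added = int(round(growth * len(cumulative[classification])))
                # growth is twice as core-concentrated as the base placement
                cumulative[classification].extend(
                    place(added, classification, k, 2.0 * conc))
        for classification, recs in cumulative.items():
            for provider_id, cls, px, py in recs:
                site_counter += 1
                site = ProviderSite(
                    site_id=f"S{site_counter:06d}", provider_id=provider_id,
                    classification=cls, x=px, y=py, period=period, capacity=1.0,
                )
                providers[period].append(site)
                all_sites.append(site)

    matrices = _build_matrices(config, areas, all_sites, rng)
    return SyntheticRegion(config=config, areas=areas, providers=providers, matrices=matrices)


def _build_matrices(
    config: RegionConfig,
    areas: Sequence[AreaUnit],
    sites: Sequence[ProviderSite],
    rng: np.random.Generator,
) -> dict[str, TravelTimeMatrix]:
    """Per-mode minutes from every area to every site.

    Car time equals planar distance (coordinates are car-minutes); walking is
    ``WALK_FACTOR`` slower.  Transit time is walk-to-stop + half headway +
    in-vehicle + walk-from-stop, finite only when both endpoints lie within
    the transit coverage radius of the core (otherwise the access or egress
    stop is absent and the time is ``+inf``).
    """
    area_ids = [a.area_id for a in areas]
    site_ids = [s.site_id for s in sites]
    a_xy = np.array([[a.x, a.y] for a in areas], dtype=float).reshape(len(areas), 2)
    s_xy = np.array([[s.x, s.y] for s in sites], dtype=float).reshape(len(sites), 2)
    dist = np.hypot(a_xy[:, None, 0] - s_xy[None, :, 0], a_xy[:, None, 1] - s_xy[None, :, 1])

    car = dist.copy()
    walk = WALK_FACTOR * dist

    a_core = np.hypot(a_xy[:, 0], a_xy[:, 1])
    s_core = np.hypot(s_xy[:, 0], s_xy[:, 1])
    covered_a = a_core <= config.transit_coverage_radius_min
    covered_s = s_core <= config.transit_coverage_radius_min
    access_walk = rng.uniform(2.0, 8.0, size=len(areas))
    egress_walk = rng.uniform(2.0, 8.0, size=len(sites))
    transit = (
        access_walk[:, None]
        + config.transit_headway_min / 2.0
        + TRANSIT_VEHICLE_FACTOR * dist
        + egress_walk[None, :]
    )
    # within coverage a trip never takes transit when walking is quicker;
    # outside coverage the access or egress stop is absent and the mode is
    # unavailable (infinite), regardless of walkability
    transit = np.where(covered_a[:, None] & covered_s[None, :],
                       np.minimum(transit, walk), math.inf)

    return {
        "car": TravelTimeMatrix("car", area_ids, site_ids, car),
        "transit": TravelTimeMatrix("transit", area_ids, site_ids, transit),
        "walk": TravelTimeMatrix("walk", area_ids, site_ids, walk),
    }


def inject_zero_inflation(
    region: SyntheticRegion,
    class_label: str,
    zero_fraction: float,
    target_classes: tuple[str, ...] = ("rural",),
) -> SyntheticRegion:
    """Force exact zero access to one provider class for a fraction of areas.

    Selects ``round(zero_fraction * n_target)`` areas among the
    ``target_classes`` strata (rural by default; pass all non-metro labels to
    widen) and makes every site of ``class_label`` unreachable from them in
    every mode, so downstream access is exactly 0 there.  Selection is
    deterministic given the region's seed.  ``zero_fraction`` of 0 returns an
    unchanged copy; an unknown class label raises ``KeyError``.
    """
    if not 0 <= zero_fraction <= 1:
        raise ConfigurationError("zero_fraction must lie in [0, 1]")
    known = {s.classification for sites in region.providers.values() for s in sites}
    if class_label not in known:
        raise KeyError(f"unknown provider classification {class_label!r}")

    out = SyntheticRegion(
        config=region.config,
        areas=list(region.areas),
        providers={p: list(sites) for p, sites in region.providers.items()},
        matrices={m: copy.deepcopy(mat) for m, mat in region.matrices.items()},
    )
    targets = [a.area_id for a in region.areas if a.rural_urban_class in target_classes]
    k = int(math.floor(zero_fraction * len(targets) + 0.5))
    if k == 0:
        return out
    rng = np.random.default_rng(region.config.seed + 1)
    chosen = set(rng.choice(targets, size=k, replace=False).tolist())
    class_sites = {s.site_id for sites in out.providers.values() for s in sites
                   if s.classification == class_label}
    for mat in out.matrices.values():
        rows = [i for i, o in enumerate(mat.origin_ids) if o in chosen]
        cols = [j for j, d in enumerate(mat.dest_ids) if d in class_sites]
        if rows and cols:
            mat.minutes[np.ix_(rows, cols)] = math.inf
    return out
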