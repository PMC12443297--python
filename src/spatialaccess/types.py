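"""Core domain containers.

The measure operates on four kinds of objects: demand points (census-tract-like
areas with population and commuter counts), supply points (provider sites with
a service capacity), per-mode origin-destination travel-time matrices, and the
piecewise-constant distance-decay schedule that turns travel times into
catchment weights.  Access surfaces hold the resulting per-area
providers-per-100,000 values for one mode, provider classification and period.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, IntegrityError

__all__ = [
    "AreaUnit",
    "ProviderSite",
    "DecaySchedule",
    "TravelTimeMatrix",
    "AccessSurface",
    "MODES",
]

#: Travel modes with their own networks/matrices ("composite" is derived).
MODES = ("car", "transit", "walk")


@dataclass(frozen=True)
class AreaUnit:
    """A small-area demand point (census tract / block group analogue).

    Population is the demand weight in the catchment denominator; the three
    commuter counts drive the composite's mode-share weights.  Stratum labels
    (rural/urban class, deprivation quartile) are consumed as given — their
    construction is upstream of this package.
    """

    area_id: str
    x: float
    y: float
    population: float
    commuters_car: float = 0.0
    commuters_transit: float = 0.0
    commuters_walk: float = 0.0
    rural_urban_class: str = ""
    deprivation_quartile: str = ""

    def __post_init__(self) -> None:
        if self.population < 0:
            raise ConfigurationError(f"population must be >= 0 for area {self.area_id!r}")
        for name in ("commuters_car", "commuters_transit", "commuters_walk"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0 for area {self.area_id!r}")


@dataclass(frozen=True)
class ProviderSite:
    """A supply point: one provider-location record with capacity S_j.

    A provider practising at two locations appears as two sites sharing
    ``provider_id``; duplicates are retained by design, each with its own
    capacity (default 1 per record).
    """

    site_id: str
    provider_id: str
    classification: str
    x: float
    y: float
    period: str
    capacity: float = 1.0

    def __post_init__(self) -> None:
        if not self.capacity > 0:
            raise ConfigurationError(f"capacity must be > 0 for site {self.site_id!r}")


@dataclass(frozen=True)
class DecaySchedule:
    """Step-weighted distance decay over travel-time zones.

    ``zone_bounds`` are ascending minute cut points; the last bound is the
    catchment limit beyond which the weight is 0.  Zone ``i`` covers the
    half-open interval ``(bounds[i-1], bounds[i]]`` with the first zone
    including 0, so a travel time lying exactly on a cut point maps to exactly
    one weight.  Defaults: 30-minute catchment with the canonical
    Gaussian-derived step weights 1.00 / 0.68 / 0.22 on 0-10 / 10-20 /
    20-30 minutes.
    """

    zone_bounds: tuple[float, ...] = (10.0, 20.0, 30.0)
    zone_weights: tuple[float, ...] = (1.00, 0.68, 0.22)

    def __post_init__(self) -> None:
        bounds = tuple(float(b) for b in self.zone_bounds)
        weights = tuple(float(w) for w in self.zone_weights)
        object.__setattr__(self, "zone_bounds", bounds)
        object.__setattr__(self, "zone_weights", weights)
        if len(bounds) != len(weights) or not bounds:
            raise ConfigurationError("zone_bounds and zone_weights must be nonempty and equal length")
        if any(b2 <= b1 for b1, b2 in zip(bounds, bounds[1:])) or bounds[0] <= 0:
            raise ConfigurationError("zone_bounds must be strictly ascending and positive")
        if any(not (0 < w <= 1) for w in weights):
            raise ConfigurationError("zone_weights must lie in (0, 1]")
        if any(w2 > w1 for w1, w2 in zip(weights, weights[1:])):
            raise ConfigurationError("zone_weights must be nonincreasing")

    @property
    def catchment(self) -> float:
        """Maximum catchment travel time D0 in minutes."""
        return self.zone_bounds[-1]

    def weight(self, minutes: float) -> float:
        """Decay weight of a single travel time; 0 beyond the catchment."""
        if minutes < 0:
            raise ConfigurationError("travel time must be >= 0")
        return float(self.weight_array(np.asarray([minutes]))[0])

    def weight_array(self, minutes: np.ndarray) -> np.ndarray:
        """Vectorised decay weights; +inf and anything beyond D0 map to 0."""
        m = np.asarray(minutes, dtype=float)
        if np.any(m < 0):
            raise ConfigurationError("travel times must be >= 0")
        out = np.zeros(m.shape, dtype=float)
        lower = 0.0
        for bound, w in zip(self.zone_bounds, self.zone_weights):
            if lower == 0.0:
                mask = m <= bound  # first zone includes 0
            else:
                mask = (m > lower) & (m <= bound)
            out[mask] = w
            lower = bound
        return out


class TravelTimeMatrix:
    """Origin (area) x destination (provider site) travel times in minutes.

    Unreachable pairs are ``+inf``; finite entries are >= 0.  Rows follow the
    origin ID order and columns the destination ID order given at
    construction.
    """

    def __init__(
        self,
        mode: str,
        origin_ids: Sequence[str],
        dest_ids: Sequence[str],
        minutes: np.ndarray,
    ) -> None:
        self.mode = str(mode)
        self.origin_ids = [str(o) for o in origin_ids]
        self.dest_ids = [str(d) for d in dest_ids]
        minutes = np.asarray(minutes, dtype=float).reshape(len(self.origin_ids), len(self.dest_ids))
        if len(set(self.origin_ids)) != len(self.origin_ids):
            raise IntegrityError("origin IDs must be unique")
        if len(set(self.dest_ids)) != len(self.dest_ids):
            raise IntegrityError("destination IDs must be unique")
        finite = minutes[np.isfinite(minutes)]
        if finite.size and finite.min() < 0:
            raise IntegrityError("finite travel times must be >= 0")
        if np.isnan(minutes).any():
            raise IntegrityError("travel times must not be NaN")
        self.minutes = minutes
        self._orow = {o: i for i, o in enumerate(self.origin_ids)}
        self._dcol = {d: j for j, d in enumerate(self.dest_ids)}

    @property
    def shape(self) -> tuple[int, int]:
        return self.minutes.shape

    def time(self, origin_id: str, dest_id: str) -> float:
        return float(self.minutes[self._orow[origin_id], self._dcol[dest_id]])

    def submatrix(
        self,
        origin_ids: Iterable[str] | None = None,
        dest_ids: Iterable[str] | None = None,
    ) -> "TravelTimeMatrix":
        """Reindexed copy; raises :class:`IntegrityError` naming missing IDs."""
        o_ids = list(origin_ids) if origin_ids is not None else self.origin_ids
        d_ids = list(dest_ids) if dest_ids is not None else self.dest_ids
        missing_o = [o for o in o_ids if o not in self._orow]
        missing_d = [d for d in d_ids if d not in self._dcol]
        if missing_o or missing_d:
            raise IntegrityError(
                f"matrix {self.mode!r} missing origins {missing_o} and destinations {missing_d}"
            )
        rows = [self._orow[o] for o in o_ids]
        cols = [self._dcol[d] for d in d_ids]
        return TravelTimeMatrix(self.mode, o_ids, d_ids, self.minutes[np.ix_(rows, cols)])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.minutes, index=pd.Index(self.origin_ids, name="area_id"),
                            columns=self.dest_ids)

    @classmethod
    def from_frame(cls, mode: str, frame: pd.DataFrame) -> "TravelTimeMatrix":
        return cls(mode, [str(i) for i in frame.index], [str(c) for c in frame.columns],
                   frame.to_numpy(dtype=float))

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, TravelTimeMatrix)
            and self.mode == other.mode
            and self.origin_ids == other.origin_ids
            and self.dest_ids == other.dest_ids
            and np.array_equal(self.minutes, other.minutes)
        )

    def __repr__(self) -> str:
        return f"TravelTimeMatrix(mode={self.mode!r}, shape={self.shape})"


@dataclass
class AccessSurface:
    """Per-area access values in providers per 100,000 population (A_i)."""

    mode: str
    classification: str
    period: str
    values: pd.Series = field(repr=False)

    def __post_init__(self) -> None:
        s = pd.Series(self.values, dtype=float)
        s.index = s.index.astype(str)
        s.index.name = "area_id"
        s.name = "access_per_100k"
        if s.index.has_duplicates:
            raise IntegrityError("surface has duplicate area IDs")
        if (s < 0).any() or s.isna().any():
            raise IntegrityError("access values must be >= 0 and non-missing")
        self.values = s

    @property
    def area_ids(self) -> list[str]:
        return list(self.values.index)

    def to_frame(self) -> pd.DataFrame:
        out = self.values.reset_index()
        out.insert(1, "mode", self.mode)
        out.insert(2, "classification", self.classification)
        out.insert(3, "period", self.period)
        return out

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, AccessSurface)
            and (self.mode, self.classification, self.period)
            == (other.mode, other.classification, other.period)
            and self.values.index.equals(other.values.index)
            and np.array_equal(self.values.to_numpy(), other.values.to_numpy())
        )
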