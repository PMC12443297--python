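"""Commuting-share-weighted car-transit-walk composite access.

Each area's composite is the convex combination of its car, transit and walk
access values, weighted by the area's commuting mode shares.  Shares use the
three-mode commuter total as denominator: an area with counts 850/100/50 has
shares 0.85/0.10/0.05 and its composite is 85% of the car value, 10% of the
transit value and 5% of the walk value.  Areas with zero three-mode
commuters fall back to car-only weighting (1, 0, 0) — car is the dominant
national mode — and carry a flag so the fallback is auditable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, IntegrityError
from .types import AccessSurface, AreaUnit

__all__ = ["ModeShares", "mode_shares", "composite_access", "composite_surface", "mode_share_table"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ModeShares:
    """Commuting mode shares of one area; sums to 1 (car fallback when flagged)."""

    area_id: str
    p_car: float
    p_transit: float
    p_walk: float
    fallback: bool = False

    def __post_init__(self) -> None:
        for name in ("p_car", "p_transit", "p_walk"):
            if not 0 <= getattr(self, name) <= 1:
                raise ConfigurationError(f"{name} must lie in [0, 1]")
        if abs(self.p_car + self.p_transit + self.p_walk - 1.0) > 1e-9:
            raise ConfigurationError("mode shares must sum to 1")


def mode_shares(area: AreaUnit) -> ModeShares:
    """Shares of car/transit/walk commuters with the car-only zero fallback."""
    counts = (area.commuters_car, area.commuters_transit, area.commuters_walk)
    if any(c < 0 for c in counts):
        raise ConfigurationError(f"commuter counts must be >= 0 for area {area.area_id!r}")
    total = sum(counts)
    if total == 0:
        logger.info("area %s has no three-mode commuters; car-only fallback", area.area_id)
        return ModeShares(area.area_id, 1.0, 0.0, 0.0, fallback=True)
    return ModeShares(area.area_id, counts[0] / total, counts[1] / total, counts[2] / total)


def composite_access(shares: ModeShares, a_car: float, a_transit: float, a_walk: float) -> float:
    """p_car*a_car + p_transit*a_transit + p_walk*a_walk (per-100k scale)."""
    return shares.p_car * a_car + shares.p_transit * a_transit + shares.p_walk * a_walk


def mode_share_table(areas: Sequence[AreaUnit]) -> pd.DataFrame:
    """Per-area share table with the zero-commuter fallback flag column."""
    rows = [mode_shares(a) for a in areas]
    return pd.DataFrame(
        {
            "area_id": [s.area_id for s in rows],
            "p_car": [s.p_car for s in rows],
            "p_transit": [s.p_transit for s in rows],
            "p_walk": [s.p_walk for s in rows],
            "fallback_car_only": [s.fallback for s in rows],
        }
    )


def composite_surface(
    car: AccessSurface,
    transit: AccessSurface,
    walk: AccessSurface,
    areas: Sequence[AreaUnit],
) -> AccessSurface:
    """Elementwise composite of the three per-mode surfaces.

    The three surfaces must share classification, period and area set; the
    share weights come from each area's commuter counts.  Raises
    :class:`IntegrityError` on any mismatch.
    """
    surfaces = {"car": car, "transit": transit, "walk": walk}
    for label, surf in surfaces.items():
        if surf.mode != label:
            raise IntegrityError(f"surface passed as {label!r} has mode {surf.mode!r}")
    meta = {(s.classification, s.period) for s in surfaces.values()}
    if len(meta) != 1:
        raise IntegrityError(f"surfaces disagree on classification/period: {sorted(meta)}")
    area_ids = [a.area_id for a in areas]
    for label, surf in surfaces.items():
        if set(surf.area_ids) != set(area_ids) or len(surf.area_ids) != len(area_ids):
            raise IntegrityError(f"{label} surface area set differs from the area table")

    shares = [mode_shares(a) for a in areas]
    w = np.array([[s.p_car, s.p_transit, s.p_walk] for s in shares], dtype=float)
    vals = np.column_stack([
        car.values.reindex(area_ids).to_numpy(),
        transit.values.reindex(area_ids).to_numpy(),
        walk.values.reindex(area_ids).to_numpy(),
    ])
    combined = (w * vals).sum(axis=1)
    # bit-exact degeneracy: a pure single-mode share reproduces that surface
    pure = w == 1.0
    for col in range(3):
        mask = pure[:, col]
        if mask.any():
            combined[mask] = vals[mask, col]
    classification, period = next(iter(meta))
    return AccessSurface("composite", classification, period,
                         pd.Series(combined, index=area_ids))
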