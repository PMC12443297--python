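"""Tests for the synthetic-region generator."""

import dataclasses
import math

import numpy as np
import pytest

from spatialaccess import (
    ConfigurationError,
    RegionConfig,
    e2sfca,
    generate_region,
    inject_zero_inflation,
)
from spatialaccess.io import write_area_table, write_provider_table


def small_config(**kw):
    defaults = dict(n_areas=80, seed=42)
    defaults.update(kw)
    return RegionConfig(**defaults)


class TestGenerateRegion:
    def test_empty_region(self):
        region = generate_region(small_config(n_areas=0))
        assert region.areas == []

    def test_deterministic_given_seed(self, tmp_path):
        r1 = generate_region(small_config())
        r2 = generate_region(small_config())
        assert r1.areas == r2.areas
        assert r1.providers == r2.providers
        for mode in r1.matrices:
            assert r1.matrices[mode] == r2.matrices[mode]
        # byte-identical serialization
        for r, tag in ((r1, "a"), (r2, "b")):
            write_area_table(r.areas, tmp_path / f"areas_{tag}.csv")
            write_provider_table(r.sites(), tmp_path / f"prov_{tag}.csv")
        assert (tmp_path / "areas_a.csv").read_bytes() == (tmp_path / "areas_b.csv").read_bytes()
        assert (tmp_path / "prov_a.csv").read_bytes() == (tmp_path / "prov_b.csv").read_bytes()

    def test_different_seeds_differ(self):
        assert generate_region(small_config(seed=1)).areas != \
            generate_region(small_config(seed=2)).areas

    def test_metro_fraction_one_labels_everything_metropolitan(self):
        region = generate_region(small_config(metro_fraction=1.0))
        assert {a.rural_urban_class for a in region.areas} == {"metropolitan"}

    def test_all_four_strata_present_by_default(self):
        region = generate_region(small_config())
        assert {a.rural_urban_class for a in region.areas} == \
            {"metropolitan", "micropolitan", "small town", "rural"}

    def test_metro_areas_are_nearer_the_core(self):
        region = generate_region(small_config())
        r_of = {a.area_id: math.hypot(a.x, a.y) for a in region.areas}
        metro = [r_of[a.area_id] for a in region.areas_in("metropolitan")]
        rural = [r_of[a.area_id] for a in region.areas_in("rural")]
        assert max(metro) <= min(rural)

    @pytest.mark.parametrize("field, value", [
        ("n_areas", -1),
        ("metro_fraction", 1.5),
        ("provider_urban_concentration", 0.0),
        ("transit_coverage_radius_min", -2.0),
        ("periods", ()),
    ])
    def test_invalid_config_names_field(self, field, value):
        cfg = small_config(**{field: value})
        with pytest.raises(ConfigurationError, match=field.split("_")[0]):
            generate_region(cfg)

    def test_sites_inside_region_and_populations_nonnegative(self):
        region = generate_region(small_config())
        R = region.config.region_radius_min
        for s in region.sites():
            assert math.hypot(s.x, s.y) <= R + 1e-9
        assert all(a.population >= 0 for a in region.areas)

    def test_later_periods_only_add_sites(self):
        region = generate_region(small_config())
        p1, p2 = region.periods
        assert len(region.providers[p2]) > len(region.providers[p1])
        # specialists grow faster than generalists by default
        def count(period, cls):
            return sum(1 for s in region.providers[period] if s.classification == cls)
        growth_primary = count(p2, "primary_care") / count(p1, "primary_care")
        growth_special = count(p2, "specialty_care") / count(p1, "specialty_care")
        assert growth_special > growth_primary > 1.0

    def test_commuter_counts_respect_profiles(self):
        region = generate_region(small_config(n_areas=200))
        # car dominates everywhere; transit share higher in metro than rural
        metro = region.areas_in("metropolitan")
        rural = region.areas_in("rural")
        def share(areas, attr):
            tot = sum(a.commuters_car + a.commuters_transit + a.commuters_walk for a in areas)
            return sum(getattr(a, attr) for a in areas) / tot
        assert share(metro, "commuters_car") > 0.5
        assert share(metro, "commuters_transit") > share(rural, "commuters_transit")

    def test_deprivation_quartiles_are_balanced(self):
        region = generate_region(small_config(n_areas=200))
        counts = {}
        for a in region.areas:
            counts[a.deprivation_quartile] = counts.get(a.deprivation_quartile, 0) + 1
        assert set(counts) == {"Q1", "Q2", "Q3", "Q4"}
        assert max(counts.values()) - min(counts.values()) <= 1


class TestMatrices:
    def test_transit_infinite_outside_coverage(self):
        region = generate_region(small_config())
        cover = region.config.transit_coverage_radius_min
        t = region.matrices["transit"]
        r_area = {a.area_id: math.hypot(a.x, a.y) for a in region.areas}
        r_site = {s.site_id: math.hypot(s.x, s.y) for s in region.sites()}
        for i, aid in enumerate(t.origin_ids):
            for j, sid in enumerate(t.dest_ids):
                if r_area[aid] > cover or r_site[sid] > cover:
                    assert t.minutes[i, j] == math.inf

    def test_transit_never_slower_than_walk_within_coverage(self):
        region = generate_region(small_config())
        t, w = region.matrices["transit"].minutes, region.matrices["walk"].minutes
        finite = np.isfinite(t)
        assert (t[finite] <= w[finite] + 1e-9).all()

    def test_transit_leg_includes_walk_and_wait(self):
        # where the transit leg (not the walk fallback) wins, it must carry at
        # least both stop walks (>=2 min each) plus half the headway
        region = generate_region(small_config())
        t, w = region.matrices["transit"].minutes, region.matrices["walk"].minutes
        uses_leg = np.isfinite(t) & (t < w)
        floor = 2.0 + 2.0 + region.config.transit_headway_min / 2.0
        assert (t[uses_leg] >= floor).all()

    def test_car_no_slower_than_walk(self):
        region = generate_region(small_config())
        assert (region.matrices["car"].minutes <= region.matrices["walk"].minutes).all()

    def test_structure_recovery_metro_access_exceeds_rural(self, metro_region):
        region = metro_region
        p1 = region.periods[0]
        surf = e2sfca(region.sites(p1), region.areas, region.matrices["car"],
                      classification="primary_care", period=p1)
        med = lambda cls: float(np.median(
            [surf.values[a.area_id] for a in region.areas_in(cls)]))
        assert med("metropolitan") > med("rural")


def spread_config(**kw):
    """Compact, provider-rich region where every area has baseline access."""
    defaults = dict(n_areas=60, region_radius_min=25.0,
                    provider_urban_concentration=1.0,
                    n_providers_by_class={"primary_care": 60, "specialty_care": 40},
                    seed=9)
    defaults.update(kw)
    return RegionConfig(**defaults)


class TestInjectZeroInflation:
    def test_zero_fraction_zero_is_identity(self):
        region = generate_region(spread_config())
        out = inject_zero_inflation(region, "specialty_care", 0.0)
        for mode in region.matrices:
            assert out.matrices[mode] == region.matrices[mode]

    def test_unknown_class_is_lookup_error(self):
        region = generate_region(spread_config())
        with pytest.raises(KeyError):
            inject_zero_inflation(region, "podiatry", 0.5)

    def test_full_injection_zeroes_all_rural_access(self):
        region = generate_region(spread_config())
        out = inject_zero_inflation(region, "specialty_care", 1.0)
        p1 = region.periods[0]
        surf = e2sfca(out.sites(p1), out.areas, out.matrices["car"],
                      classification="specialty_care", period=p1)
        for a in out.areas_in("rural"):
            assert surf.values[a.area_id] == 0.0

    def test_half_injection_zeroes_exact_count(self):
        region = generate_region(spread_config())
        p1 = region.periods[0]
        before = e2sfca(region.sites(p1), region.areas, region.matrices["car"],
                        classification="specialty_care", period=p1)
        rural = [a.area_id for a in region.areas_in("rural")]
        assert all(before.values[aid] > 0 for aid in rural)  # fixture precondition
        out = inject_zero_inflation(region, "specialty_care", 0.5)
        after = e2sfca(out.sites(p1), out.areas, out.matrices["car"],
                       classification="specialty_care", period=p1)
        n_zero = sum(after.values[aid] == 0.0 for aid in rural)
        assert n_zero == int(math.floor(0.5 * len(rural) + 0.5))

    def test_other_strata_keep_or_gain_access(self):
        # removing rural demand from the sites' catchments can only shrink
        # step-1 denominators, so remaining areas never lose access
        region = generate_region(spread_config())
        out = inject_zero_inflation(region, "specialty_care", 1.0)
        p1 = region.periods[0]
        before = e2sfca(region.sites(p1), region.areas, region.matrices["car"],
                        classification="specialty_care", period=p1)
        after = e2sfca(out.sites(p1), out.areas, out.matrices["car"],
                       classification="specialty_care", period=p1)
        for a in region.areas:
            if a.rural_urban_class != "rural":
                assert after.values[a.area_id] >= before.values[a.area_id] - 1e-12
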