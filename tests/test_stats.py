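"""Richness, accumulation, nearest-stem distances, equivalent areas."""

import math

import numpy as np
import pytest

from rootkern import (CoreDataset, RootFragment, SoilCore, Species, Stem,
                      StemMap, equivalent_sampling_area, nearest_any_stem,
                      nearest_confamilial, nearest_conspecific,
                      richness_summary, species_accumulation)
from rootkern.errors import ResolutionError
from rootkern.stats import mean_quadrat_richness, total_cross_sectional_area


class TestRichnessSummary:
    def test_fixture_reproduces_printed_statistics(self, table1):
        rs = richness_summary(table1)
        assert round(rs.mean, 2) == 4.67
        assert round(rs.sd, 2) == 2.06
        assert rs.max == 9 and rs.min == 1
        # the richest core is the one sampled to 1 m depth
        richest = max(rs.per_core, key=rs.per_core.get)
        assert table1.core(richest).max_depth == 100

    def test_single_core_sd_absent(self):
        ds = CoreDataset([SoilCore("c1", 0, 0)],
                         [RootFragment("f1", "c1", 0, 10, "A")])
        rs = richness_summary(ds)
        assert rs.mean == rs.max == 1
        assert rs.sd is None

    def test_duplicate_taxa_do_not_inflate(self):
        ds = CoreDataset([SoilCore("c1", 0, 0)],
                         [RootFragment(f"f{i}", "c1", 0, 10, "A")
                          for i in range(5)])
        assert richness_summary(ds).per_core["c1"] == 1


class TestNearestStem:
    def test_three_four_five(self):
        sm = StemMap([Stem("a", "sp1", 3, 4, 2)], (-1, -1, 10, 10))
        rec = nearest_conspecific(sm, (0, 0), "sp1")
        assert rec.distance == pytest.approx(5.0)
        assert rec.target_stem_id == "a"

    def test_tie_breaks_to_smaller_stem_id(self):
        sm = StemMap([Stem("b", "sp1", 4, 0, 2), Stem("a", "sp1", -4, 0, 2)],
                     (-10, -10, 10, 10))
        assert nearest_conspecific(sm, (0, 0), "sp1").target_stem_id == "a"

    def test_min_dbh_filter_and_absent_record(self):
        sm = StemMap([Stem("a", "sp1", 1, 0, 0.5)], (-1, -1, 10, 10))
        rec = nearest_conspecific(sm, (0, 0), "sp1", min_dbh=1.0)
        assert not rec.found and "dbh" in rec.reason

    def test_coincident_point(self):
        sm = StemMap([Stem("a", "sp1", 5, 5, 2)], (0, 0, 10, 10))
        assert nearest_any_stem(sm, (5, 5)).distance == 0.0

    def test_conspecific_only_neighborhood(self):
        sm = StemMap([Stem("a", "sp1", 2, 2, 2)], (0, 0, 10, 10))
        assert (nearest_any_stem(sm, (0, 0)).distance
                == nearest_conspecific(sm, (0, 0), "sp1").distance)

    def test_matches_exhaustive_scan(self):
        rng = np.random.default_rng(99)
        stems = [Stem(f"s{i:04d}", f"sp{i % 7}", float(rng.uniform(0, 500)),
                      float(rng.uniform(0, 500)), float(rng.uniform(0.5, 60)))
                 for i in range(1000)]
        sm = StemMap(stems, (0, 0, 500, 500))
        for point in [(250, 250), (12.3, 400.0), (499, 1)]:
            for species in (None, "sp3"):
                if species is None:
                    rec = nearest_any_stem(sm, point)
                    pool = [s for s in stems if s.dbh >= 1.0]
                else:
                    rec = nearest_conspecific(sm, point, species)
                    pool = [s for s in stems
                            if s.species_code == species and s.dbh >= 1.0]
                best = min(pool, key=lambda s: (math.hypot(
                    point[0] - s.x, point[1] - s.y), s.stem_id))
                assert rec.target_stem_id == best.stem_id
                assert rec.distance == pytest.approx(
                    math.hypot(point[0] - best.x, point[1] - best.y),
                    abs=1e-9)


class TestNearestConfamilial:
    def _map(self):
        species = {
            "lia1": Species("lia1", "Liana one", family="Bignoniaceae",
                            guild="liana"),
            "tre1": Species("tre1", "Tree one", family="Bignoniaceae",
                            guild="tree"),
            "oth1": Species("oth1", "Other", family="Moraceae",
                            guild="tree"),
        }
        stems = [Stem("L", "lia1", 7, 0, 2), Stem("T", "tre1", 3, 0, 2),
                 Stem("O", "oth1", 1, 0, 2)]
        return StemMap(stems, (-1, -1, 10, 10), species=species)

    def test_family_match_with_guild(self):
        rec = nearest_confamilial(self._map(), (0, 0), "Bignoniaceae",
                                  guild_filter="liana")
        assert rec.distance == pytest.approx(7.0)
        assert rec.rank_used == "family"

    def test_guild_filter_can_empty_the_pool(self):
        sm = self._map().subset(lambda s: s.stem_id != "L")
        rec = nearest_confamilial(sm, (0, 0), "Bignoniaceae",
                                  guild_filter="liana")
        assert not rec.found

    def test_unknown_family_raises(self):
        with pytest.raises(ResolutionError):
            nearest_confamilial(self._map(), (0, 0), "Ategidae")


class TestSpeciesAccumulation:
    def test_shared_single_taxon_is_flat(self):
        cores = [SoilCore(f"c{i}", i, 0) for i in range(4)]
        frags = [RootFragment(f"f{i}", f"c{i}", 0, 10, "A") for i in range(4)]
        curve = species_accumulation(CoreDataset(cores, frags),
                                     n_permutations=20, seed=1)
        assert np.allclose(curve["mean_richness"], 1.0)

    def test_endpoint_is_total_richness_any_seed(self, table1):
        for seed in (1, 2, 3):
            curve = species_accumulation(table1, n_permutations=5, seed=seed)
            assert curve["mean_richness"].iloc[-1] == 32

    def test_monotone_nondecreasing(self, table1):
        curve = species_accumulation(table1, n_permutations=50, seed=0)
        assert (curve["mean_richness"].diff().dropna() >= -1e-12).all()


class TestTotalCoreArea:
    def test_twelve_standard_augers(self, table1):
        assert total_cross_sectional_area(table1) == pytest.approx(
            12 * math.pi * 0.03125 ** 2)


class TestEquivalentSamplingArea:
    def _grid_community(self, n=30):
        """One point per species on a unit grid: mean quadrat richness of a
        square of area A is A (per unit cell), so the area matching
        richness 1 is ~1 m^2."""
        pts = [(i + 0.5, j + 0.5, f"sp{i}_{j}")
               for i in range(n) for j in range(n)]
        return pts, (0.0, 0.0, float(n), float(n))

    def test_uniform_grid_analytic(self):
        pts, window = self._grid_community()
        res = equivalent_sampling_area(pts, 1.0, window, n_mc=400, seed=3,
                                       area_bounds=(0.05, 100.0))
        assert res.status == "converged"
        assert res.area == pytest.approx(1.0, rel=0.35)

    def test_unreachable_target_reports_boundary(self):
        pts, window = self._grid_community(10)
        res = equivalent_sampling_area(pts, 100.0, window, n_mc=50, seed=0,
                                       area_bounds=(0.1, 4.0))
        assert res.area is None
        assert res.status == "upper-bound"

    def test_mean_richness_monotone_in_area(self):
        rng = np.random.default_rng(8)
        pts = np.column_stack([rng.uniform(0, 50, 400),
                               rng.uniform(0, 50, 400)])
        species = np.array([f"sp{i % 40}" for i in range(400)], dtype=object)
        means = [mean_quadrat_richness(pts, species, a, (0, 0, 50, 50),
                                       n_mc=300,
                                       rng=np.random.default_rng(4))
                 for a in (1.0, 10.0, 100.0, 400.0)]
        assert all(b >= a for a, b in zip(means, means[1:]))
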