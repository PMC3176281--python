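"""Likelihood, optimization, model selection and goodness of fit."""

import math

import numpy as np
import pytest

from rootkern import (CoreDataset, FitConfig, KernelFamily, KernelParams,
                      RootFragment, RootModelParams, SoilCore, Stem, StemMap,
                      expected_proportions, fit_family,
                      negative_log_likelihood, observed_proportions,
                      select_model, variation_explained)
from rootkern.errors import ConfigurationError, UndefinedValueError
from rootkern.fit import FitResult, proportion_r_squared, read_fit_result, \
    write_fit_result


def make_dataset(core_specs):
    """core_specs: list of (core_id, (x, y), {taxon: n_fragments})."""
    cores, frags = [], []
    for cid, (x, y), counts in core_specs:
        cores.append(SoilCore(cid, x, y))
        k = 0
        for taxon, n in counts.items():
            for _ in range(n):
                k += 1
                frags.append(RootFragment(f"{cid}-f{k}", cid, 0, 10, taxon))
    return CoreDataset(cores, frags)


@pytest.fixture
def tiny_world(exp_params):
    rng = np.random.default_rng(5)
    stems = [Stem(f"s{i}", f"sp{i % 4 + 1}", float(rng.uniform(20, 80)),
                  float(rng.uniform(20, 80)), float(rng.uniform(2, 30)))
             for i in range(24)]
    sm = StemMap(stems, (0, 0, 100, 100))
    ds = make_dataset([
        ("c1", (40, 40), {"sp1": 3, "sp2": 1}),
        ("c2", (60, 55), {"sp2": 2, "sp3": 2, "sp4": 1}),
        ("c3", (33, 66), {"sp1": 1, "sp4": 2}),
    ])
    return sm, ds


class TestObservedProportions:
    def test_counts_mode(self):
        ds = make_dataset([("c1", (0, 0), {"A": 2, "B": 2})])
        p = observed_proportions(ds, "c1", ["A", "B"])
        assert p == pytest.approx([0.5, 0.5])

    def test_mass_mode(self):
        core = SoilCore("c1", 0, 0)
        frags = [RootFragment("f1", "c1", 0, 10, "A", mass=0.3),
                 RootFragment("f2", "c1", 0, 10, "B", mass=0.1)]
        ds = CoreDataset([core], frags)
        p = observed_proportions(ds, "c1", ["A", "B"], mode="mass")
        assert p == pytest.approx([0.75, 0.25])

    def test_missing_mass_falls_back_to_counts(self):
        core = SoilCore("c1", 0, 0)
        frags = [RootFragment("f1", "c1", 0, 10, "A", mass=0.3),
                 RootFragment("f2", "c1", 0, 10, "B")]
        ds = CoreDataset([core], frags)
        with pytest.warns(UserWarning, match="falling back"):
            p = observed_proportions(ds, "c1", ["A", "B"], mode="mass")
        assert p == pytest.approx([0.5, 0.5])

    def test_fixture_monodominant_core(self, table1):
        p = observed_proportions(table1, "E", table1.taxa())
        assert p[table1.taxa().index("quaras")] == pytest.approx(1.0)


class TestNegativeLogLikelihood:
    def test_certain_prediction_is_zero_nats(self, exp_params):
        sm = StemMap([Stem("a", "sp1", 50, 50, 10)], (0, 0, 100, 100))
        ds = make_dataset([("c1", (52, 50), {"sp1": 1})])
        cfg = FitConfig(ignore_edge=True)
        assert negative_log_likelihood(ds, sm, exp_params, cfg) == \
            pytest.approx(0.0, abs=1e-12)

    def test_even_split_hand_value(self, exp_params):
        sm = StemMap([Stem("a", "sp1", 40, 50, 10),
                      Stem("b", "sp2", 60, 50, 10)], (0, 0, 100, 100))
        ds = make_dataset([("c1", (50, 50), {"sp1": 1, "sp2": 1})])
        cfg = FitConfig(ignore_edge=True)
        assert negative_log_likelihood(ds, sm, exp_params, cfg) == \
            pytest.approx(2 * math.log(2), abs=1e-10)

    def test_matches_naive_oracle(self, tiny_world, exp_params):
        sm, ds = tiny_world
        cfg = FitConfig(ignore_edge=True)
        got = negative_log_likelihood(ds, sm, exp_params, cfg)
        taxa = sm.species_codes()
        want = 0.0
        for f in ds.fragments:
            core = ds.core(f.core_id)
            p = expected_proportions(sm, (core.x, core.y), exp_params, taxa,
                                     ignore_edge=True)
            want -= math.log(p[taxa.index(f.taxon_code)])
        assert got == pytest.approx(want, abs=1e-10)

    def test_zero_probability_reports_pairs(self):
        params = RootModelParams(1.0, KernelFamily.CONSTANT_THRESHOLD,
                                 KernelParams(r_max=5.0))
        sm = StemMap([Stem("a", "sp1", 50, 50, 10),
                      Stem("b", "sp2", 20, 20, 10)], (0, 0, 100, 100))
        ds = make_dataset([("c1", (50, 52), {"sp1": 1, "sp2": 1})])
        cfg = FitConfig(ignore_edge=True)
        with pytest.warns(UserWarning, match="sp2"):
            val = negative_log_likelihood(ds, sm, params, cfg)
        assert val == math.inf

    def test_irrelevant_taxon_leaves_likelihood_unchanged(self, tiny_world,
                                                          exp_params):
        sm, ds = tiny_world
        cfg = FitConfig(ignore_edge=True)
        base = negative_log_likelihood(ds, sm, exp_params, cfg)
        # a species with zero stems and zero observations
        sm2 = StemMap(sm.stems, sm.bounds, species={})
        assert negative_log_likelihood(ds, sm2, exp_params, cfg) == \
            pytest.approx(base, abs=1e-12)


class TestVariationExplained:
    def test_perfect_and_grand_mean_predictions(self):
        obs = np.array([[0.8, 0.2], [0.4, 0.6]])
        assert proportion_r_squared(obs, obs) == pytest.approx(1.0)
        grand = np.full_like(obs, obs.mean())
        assert proportion_r_squared(obs, grand) == pytest.approx(0.0)

    def test_undefined_for_constant_observations(self):
        obs = np.full((3, 2), 0.5)
        with pytest.raises(UndefinedValueError):
            proportion_r_squared(obs, obs * 0.9)

    def test_matches_two_pass_formula(self, tiny_world, exp_params):
        sm, ds = tiny_world
        cfg = FitConfig(ignore_edge=True)
        got = variation_explained(ds, sm, exp_params, cfg)
        taxa = sorted(ds.taxa())
        obs, pred = [], []
        for cid in ("c1", "c2", "c3"):
            core = ds.core(cid)
            obs.append(observed_proportions(ds, cid, taxa))
            pred.append(expected_proportions(sm, (core.x, core.y),
                                             exp_params, taxa,
                                             ignore_edge=True))
        obs, pred = np.array(obs), np.array(pred)
        ss_res = ((obs - pred) ** 2).sum()
        ss_tot = ((obs - obs.mean()) ** 2).sum()
        assert got == pytest.approx(1 - ss_res / ss_tot, abs=1e-12)


class TestFitFamily:
    def test_deterministic_given_seed(self, tiny_world):
        sm, ds = tiny_world
        cfg = FitConfig(ignore_edge=True, n_starts=2, max_evals=200, seed=11)
        r1 = fit_family(ds, sm, KernelFamily.EXPONENTIAL, "constant", cfg)
        r2 = fit_family(ds, sm, KernelFamily.EXPONENTIAL, "constant", cfg)
        assert r1.params == r2.params
        assert r1.log_likelihood == r2.log_likelihood
        assert r1.n_function_evals == r2.n_function_evals

    def test_aic_identity(self, tiny_world):
        sm, ds = tiny_world
        cfg = FitConfig(ignore_edge=True, n_starts=2, max_evals=200)
        r = fit_family(ds, sm, KernelFamily.GAUSSIAN, "constant", cfg)
        assert r.aic == pytest.approx(
            2 * r.n_params - 2 * r.log_likelihood, abs=1e-12)
        assert r.n_params == 2

    def test_diameter_power_mode_adds_parameter(self, tiny_world):
        sm, ds = tiny_world
        cfg = FitConfig(ignore_edge=True, n_starts=1, max_evals=100)
        r = fit_family(ds, sm, KernelFamily.EXPONENTIAL, "diameter_power",
                       cfg)
        assert r.n_params == 3
        assert 0 <= r.params.kernel.theta <= 2

    def test_monodominant_cores_push_beta_to_bound(self):
        # every core contains only the largest-dbh species: more mass on
        # big stems always helps, so beta runs to its upper bound
        stems = [Stem("big", "spB", 50, 50, 50.0),
                 Stem("small1", "spS", 45, 50, 1.0),
                 Stem("small2", "spS", 55, 50, 1.0)]
        sm = StemMap(stems, (0, 0, 100, 100))
        ds = make_dataset([("c1", (48, 50), {"spB": 5}),
                           ("c2", (52, 50), {"spB": 5})])
        cfg = FitConfig(ignore_edge=True, n_starts=3, max_evals=400)
        r = fit_family(ds, sm, KernelFamily.EXPONENTIAL, "constant", cfg)
        assert r.params.beta > 3.9

    def test_serialization_round_trip(self, tiny_world, tmp_path):
        sm, ds = tiny_world
        cfg = FitConfig(ignore_edge=True, n_starts=1, max_evals=150)
        r = fit_family(ds, sm, KernelFamily.INVERSE_POWER, "constant", cfg)
        path = tmp_path / "fit.yaml"
        write_fit_result(r, path)
        back = read_fit_result(path)
        assert back.params == r.params
        assert back.aic == pytest.approx(r.aic)
        assert back.per_species_residuals == pytest.approx(
            r.per_species_residuals)


class TestSelectModel:
    def _result(self, family, aic, n_params, key="d1"):
        params = RootModelParams(1.0, family, KernelParams(alpha=5.0)
                                 if family not in (
                                     KernelFamily.HYPERBOLIC,)
                                 else KernelParams(r_max=50.0))
        return FitResult(params=params, scale_mode="constant",
                         log_likelihood=(2 * n_params - aic) / 2,
                         n_params=n_params, aic=aic, r_squared=0.1,
                         per_species_residuals={}, converged=True,
                         n_function_evals=10, dataset_key=key)

    def test_min_aic_wins(self):
        a = self._result(KernelFamily.EXPONENTIAL, 100, 2)
        b = self._result(KernelFamily.GAUSSIAN, 105, 2)
        assert select_model([b, a]) is a

    def test_tie_prefers_fewer_parameters(self):
        a = self._result(KernelFamily.INVERSE_POWER, 100, 3)
        b = self._result(KernelFamily.GAUSSIAN, 100, 2)
        assert select_model([a, b]) is b

    def test_tie_then_family_order(self):
        a = self._result(KernelFamily.GAUSSIAN, 100, 2)
        b = self._result(KernelFamily.EXPONENTIAL, 100, 2)
        # exponential precedes gaussian in the enumeration
        assert select_model([a, b]) is b

    def test_mixed_datasets_rejected(self):
        a = self._result(KernelFamily.EXPONENTIAL, 100, 2, key="d1")
        b = self._result(KernelFamily.GAUSSIAN, 105, 2, key="d2")
        with pytest.raises(ConfigurationError):
            select_model([a, b])
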