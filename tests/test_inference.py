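"""Permutation, bootstrap, PERMANOVA, Mantel and taxa-removal machinery."""

from itertools import permutations as all_perms

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.spatial.distance import pdist, squareform

from mfstab import (EffectSelector, PathModel, PathModelSpec,
                    SimilarityMatrix, attach_similarities, bootstrap_effects,
                    extract_pairs, generate_random_tree, mantel_test,
                    multifunctional_similarity, permanova,
                    permutation_test_effects, simulate_path_matrices,
                    taxa_removal_contribution)
from mfstab.inference import permutation_pvalue
from mfstab.simulate import null_coefficients


@pytest.fixture(scope="module")
def calibrated():
    """Reference-design matrices with known injected path coefficients."""
    return simulate_path_matrices(aspect="invariability", seed=42)


class TestPermutationTest:
    def test_pvalue_formula_add_one_convention(self):
        null = np.array([0.5, -0.2, 0.1, 0.9])
        p, p1, side = permutation_pvalue(0.4, null)
        assert side == "greater"
        assert p1 == pytest.approx((1 + 2) / 5)
        assert p == 1.0  # doubled tail caps at 1
        p, p1, side = permutation_pvalue(-0.15, null)
        assert side == "less"
        assert p1 == pytest.approx((1 + 1) / 5)
        assert p == pytest.approx(2 * (1 + 1) / 5)
        p, _, _ = permutation_pvalue(0.0, np.zeros(4))
        assert p == 1.0  # capped

    def test_observed_effect_matches_direct_fit(self, calibrated):
        """The unpermuted statistic inside the test equals the effect from a
        plain model fit (identity permutation consistency)."""
        pairs = attach_similarities(
            extract_pairs(calibrated.design, "invariability"),
            calibrated.matrices)
        fit = PathModel.from_pairs(pairs, calibrated.spec).fit()
        res = permutation_test_effects(
            calibrated.matrices, calibrated.design, "invariability",
            EffectSelector("richness", kind="total"), spec=calibrated.spec,
            n_perm=5, seed=0)
        assert res.observed_effect == pytest.approx(
            fit.effect("richness", kind="total"), abs=1e-12)

    def test_injected_strong_effect_detected(self, calibrated):
        res = permutation_test_effects(
            calibrated.matrices, calibrated.design, "invariability",
            EffectSelector("richness", kind="total"), n_perm=999, seed=1)
        assert res.observed_effect > 0.3
        assert res.p_value <= 0.01

    def test_null_effect_not_detected(self):
        spec = PathModelSpec.default("invariability")
        exp = simulate_path_matrices(
            aspect="invariability", coefficients=null_coefficients(spec),
            seed=5)
        res = permutation_test_effects(
            exp.matrices, exp.design, "invariability",
            EffectSelector("richness", kind="total"), n_perm=199, seed=2)
        assert res.p_value > 0.05

    def test_permute_all_mode_runs(self, calibrated):
        res = permutation_test_effects(
            calibrated.matrices, calibrated.design, "invariability",
            EffectSelector("drought", kind="direct"), n_perm=49, seed=3,
            permute="all")
        assert res.n_permutations == 49

    def test_seeded_reproducibility(self, calibrated):
        kw = dict(effect=EffectSelector("invasion", kind="total"),
                  n_perm=29, seed=77)
        r1 = permutation_test_effects(calibrated.matrices, calibrated.design,
                                      "invariability", **kw)
        r2 = permutation_test_effects(calibrated.matrices, calibrated.design,
                                      "invariability", **kw)
        assert r1.p_value == r2.p_value
        assert np.array_equal(r1.null_effects, r2.null_effects)

    def test_invalid_arguments_rejected(self, calibrated):
        with pytest.raises(ValueError, match="n_perm"):
            permutation_test_effects(calibrated.matrices, calibrated.design,
                                     "invariability",
                                     EffectSelector("richness"), n_perm=0)
        with pytest.raises(ValueError, match="kind"):
            EffectSelector("richness", kind="sideways")


class TestBootstrap:
    def test_identity_resampler_reproduces_point_estimate(self, calibrated):
        out = bootstrap_effects(calibrated.matrices, calibrated.design,
                                "invariability", n_boot=2, seed=0,
                                resampler=lambda rng, pots: pots)
        for res in out.values():
            assert res.bootstrap_mean == pytest.approx(res.point_effect,
                                                       abs=1e-12)
            assert res.bootstrap_sd == pytest.approx(0.0, abs=1e-12)

    def test_bootstrap_mean_close_to_point(self, calibrated):
        out = bootstrap_effects(calibrated.matrices, calibrated.design,
                                "invariability", n_boot=60, seed=4)
        res = out["richness:total"]
        assert res.n_bootstrap == 60
        assert res.bootstrap_sd > 0
        tol = 4 * res.bootstrap_sd / np.sqrt(res.n_bootstrap) + 1e-3
        assert abs(res.bootstrap_mean - res.point_effect) < tol
        assert res.bias_corrected_mean == pytest.approx(
            2 * res.point_effect - res.bootstrap_mean)


class TestPermanova:
    def _design_frame(self, groups):
        return pd.DataFrame({
            "pot_id": [f"p{i}" for i in range(len(groups))],
            "assemblage_id": [f"A{i}" for i in range(len(groups))],
            "set_id": "S1",
            "richness": 1,
            "drought": groups,
            "invasion": 0,
        })

    def test_perfect_separation_gives_r2_one(self):
        groups = [0, 0, 0, 1, 1, 1]
        ids = [f"p{i}" for i in range(6)]
        d = np.ones((6, 6)) - np.eye(6)
        d[np.ix_(range(3), range(3))] = 0.0
        d[np.ix_(range(3, 6), range(3, 6))] = 0.0
        np.fill_diagonal(d, 0.0)
        dm = pd.DataFrame(d, index=ids, columns=ids)
        tab = permanova(dm, self._design_frame(groups), ["drought"],
                        n_perm=99, seed=0)
        assert tab.loc["drought", "R2"] == pytest.approx(1.0, abs=1e-10)

    def test_r_squared_partition_sums_to_one(self, small_design, rng):
        pts = rng.normal(size=(small_design.n_pots, 3))
        d = pd.DataFrame(squareform(pdist(pts)), index=small_design.pot_ids,
                         columns=small_design.pot_ids)
        tab = permanova(d, small_design, ["richness", "drought", "invasion"],
                        n_perm=49, seed=0)
        parts = tab.loc[["richness", "drought", "invasion", "Residual"], "R2"]
        assert parts.sum() == pytest.approx(1.0, abs=1e-10)

    def test_single_factor_euclidean_matches_anova_f_exactly(self, rng):
        values = rng.normal(size=12)
        groups = np.repeat([0, 1, 2], 4)
        ids = [f"p{i}" for i in range(12)]
        d = pd.DataFrame(squareform(pdist(values[:, None])), index=ids,
                         columns=ids)
        tab = permanova(d, self._design_frame(list(groups)), ["drought"],
                        n_perm=9, seed=0, categorical=("drought",))
        f_ref = stats.f_oneway(*(values[groups == g] for g in (0, 1, 2)))
        assert tab.loc["drought", "F"] == pytest.approx(f_ref.statistic,
                                                        abs=1e-10)

    def test_exhaustive_p_matches_independent_enumeration(self, rng):
        """n = 5 exhaustive permutation p equals an oracle built from the
        classical within/between group sum-of-squares formulation."""
        values = rng.normal(size=5)
        groups = np.array([0, 0, 1, 1, 1])
        ids = [f"p{i}" for i in range(5)]
        D = squareform(pdist(values[:, None]))
        dm = pd.DataFrame(D, index=ids, columns=ids)

        def pseudo_f(d2, g):
            n = len(g)
            sst = d2[np.triu_indices(n, 1)].sum() / n
            ssw = 0.0
            for lvl in np.unique(g):
                idx = np.flatnonzero(g == lvl)
                sub = d2[np.ix_(idx, idx)]
                ssw += sub[np.triu_indices(len(idx), 1)].sum() / len(idx)
            a = len(np.unique(g))
            return ((sst - ssw) / (a - 1)) / (ssw / (n - a))

        d2 = D ** 2
        f_obs = pseudo_f(d2, groups)
        count = sum(pseudo_f(d2, groups[list(perm)]) >= f_obs - 1e-12
                    for perm in all_perms(range(5)))
        p_oracle = count / 120
        tab = permanova(dm, self._design_frame(list(groups)), ["drought"],
                        categorical=("drought",), exhaustive=True)
        assert tab.loc["drought", "p"] == pytest.approx(p_oracle, abs=1e-12)
        assert tab.loc["drought", "F"] == pytest.approx(f_obs, abs=1e-10)

    def test_single_level_factor_rejected(self, rng):
        ids = ["p0", "p1", "p2"]
        d = pd.DataFrame(1 - np.eye(3), index=ids, columns=ids)
        frame = self._design_frame([0, 0, 0])[:3]
        with pytest.raises(ValueError, match="single level"):
            permanova(d, frame, ["drought"], n_perm=9)


class TestMantel:
    def _random_similarity(self, rng, n=12, kind="plant"):
        raw = rng.uniform(0.1, 0.9, size=(n, n))
        v = (raw + raw.T) / 2
        np.fill_diagonal(v, 1.0)
        return SimilarityMatrix([f"p{i}" for i in range(n)], v, kind=kind)

    def test_self_correlation_is_one(self, rng):
        m = self._random_similarity(rng)
        r, _ = mantel_test(m, m, n_perm=99, seed=0)
        assert r == pytest.approx(1.0)

    def test_anti_monotone_transform_gives_minus_one(self, rng):
        m = self._random_similarity(rng)
        v = 1.0 - 0.9 * m.values  # strictly decreasing in the entries of m
        np.fill_diagonal(v, 1.0)
        flipped = SimilarityMatrix(m.ids, v, kind="plant")
        r, _ = mantel_test(m, flipped, n_perm=99, seed=0)
        assert r == pytest.approx(-1.0)

    def test_invariant_under_simultaneous_relabeling(self, rng):
        a = self._random_similarity(rng)
        b = self._random_similarity(rng, kind="multifunctional")
        perm = rng.permutation(a.n)
        ids_shuffled = [a.ids[i] for i in perm]
        r1, _ = mantel_test(a, b, n_perm=49, seed=1)
        r2, _ = mantel_test(a.reorder(ids_shuffled), b.reorder(ids_shuffled),
                            n_perm=49, seed=1)
        assert r1 == pytest.approx(r2, abs=1e-12)

    def test_label_mismatch_rejected(self, rng):
        a = self._random_similarity(rng)
        b = self._random_similarity(rng)
        b.ids[0] = "other"
        b._index = {p: k for k, p in enumerate(b.ids)}
        with pytest.raises(ValueError, match="label"):
            mantel_test(a, b, n_perm=9)

    def test_null_p_values_roughly_uniform(self, rng):
        ps = []
        for _ in range(40):
            a = self._random_similarity(rng)
            b = self._random_similarity(rng)
            _, p = mantel_test(a, b, n_perm=99,
                               seed=int(rng.integers(2**31 - 1)))
            ps.append(p)
        assert 0.3 < np.mean(ps) < 0.7


class TestTaxaRemovalContribution:
    def _setup(self, rng, driver_strength=5.0):
        """Small experiment where taxon t0 drives every function."""
        from mfstab import build_design
        design = build_design(
            assemblages_per_richness={1: 2, 2: 2},
            set_treatments={"S1": (0, 0), "S2": (1, 0), "S3": (0, 1),
                            "S4": (1, 1)})
        taxa = [f"t{i}" for i in range(4)]
        tree = generate_random_tree(taxa, rng=rng)
        n = design.n_pots
        ab = pd.DataFrame(rng.uniform(0.5, 2.0, size=(n, 4)),
                          index=design.pot_ids, columns=taxa)
        ab["t0"] = rng.uniform(0.1, 10.0, size=n)
        funcs = pd.DataFrame(
            {f"f{k}": driver_strength * ab["t0"] / ab.sum(axis=1)
             + rng.normal(0, 0.05, size=n) for k in range(3)},
            index=design.pot_ids)
        mf = multifunctional_similarity(
            funcs - funcs.min() + 0.1)
        return design, ab, tree, mf

    def test_empty_set_and_absent_taxon_contribute_zero(self, rng):
        design, ab, tree, mf = self._setup(rng)
        ab["ghost"] = 0.0
        tree = generate_random_tree(list(ab.columns), rng=rng)
        contrib = taxa_removal_contribution(
            ab, tree, mf, design, "invariability",
            {"none": [], "ghost": ["ghost"]})
        assert contrib["none"] == 0.0
        assert contrib["ghost"] == 0.0

    def test_function_driving_taxon_has_maximal_contribution(self, rng):
        design, ab, tree, mf = self._setup(rng)
        sets = {t: [t] for t in ab.columns}
        contrib = taxa_removal_contribution(ab, tree, mf, design,
                                            "invariability", sets)
        assert contrib.idxmax() == "t0"
        assert contrib["t0"] > 0

    def test_emptying_a_pot_rejected(self, rng):
        design, ab, tree, mf = self._setup(rng)
        with pytest.raises(ValueError, match="empties"):
            taxa_removal_contribution(ab, tree, mf, design, "invariability",
                                      {"all": list(ab.columns)})

    def test_unknown_taxon_rejected(self, rng):
        design, ab, tree, mf = self._setup(rng)
        with pytest.raises(KeyError, match="unknown"):
            taxa_removal_contribution(ab, tree, mf, design, "invariability",
                                      {"x": ["nope"]})
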