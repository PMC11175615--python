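"""Co-expression network construction, module detection on planted
structure, module-trait statistics and the hub/SDM rules."""

import warnings

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from placentome.coexpr import (
    _tom_matrix,
    detect_modules,
    effective_trait_number,
    flag_sdm_and_key,
    hub_genes,
    module_eigengene,
    module_trait_association,
    pick_soft_power,
    vst_like_transform,
)
from placentome.de import size_factors

from conftest import planted_expression


class TestVST:
    def test_zero_count_maps_to_zero_at_unit_size_factor(self):
        counts = pd.DataFrame({"s1": [0, 7], "s2": [0, 7], "s3": [0, 7]})
        out = vst_like_transform(counts)
        assert out.iloc[:, 0].eq(0).all()

    def test_invariant_to_sample_scaling_with_matching_factors(self):
        # a sample sequenced c-fold deeper with a c-fold larger size factor
        # transforms to exactly the same values
        rng = np.random.default_rng(0)
        counts = pd.DataFrame(
            rng.poisson(40, size=(100, 6)), columns=[f"s{i}" for i in range(6)]
        )
        sf = size_factors(counts)
        c = pd.Series([1.0, 2.0, 0.5, 3.0, 1.0, 4.0], index=counts.columns)
        base = vst_like_transform(counts, sf=sf)
        out = vst_like_transform(counts * c, sf=sf * c)
        assert np.allclose(out.to_numpy(), base.to_numpy())

    def test_flattens_mean_variance_slope_of_nb_counts(self):
        rng = np.random.default_rng(1)
        mu = 2.0 ** rng.uniform(2, 10, 300)
        disp = 0.2
        y = rng.negative_binomial(1 / disp, 1 / (1 + disp * mu[:, None]), size=(300, 40))
        counts = pd.DataFrame(y, columns=[f"s{i}" for i in range(40)])

        def slope(mat):
            m = mat.mean(axis=1)
            v = mat.var(axis=1)
            ok = (m > 0) & (v > 0)
            return stats.linregress(np.log10(m[ok]), np.log10(v[ok])).slope

        raw_slope = slope(counts.to_numpy())
        vst_slope = slope(vst_like_transform(counts).to_numpy().T)
        assert vst_slope < raw_slope


class TestSoftPower:
    def test_planted_structure_reaches_fit_target(self):
        expr, _ = planted_expression(np.random.default_rng(7))
        power = pick_soft_power(expr)
        assert power >= 1  # selection implies R^2 >= 0.8 at that power

    def test_iid_noise_falls_back_with_warning(self):
        rng = np.random.default_rng(8)
        expr = pd.DataFrame(rng.standard_normal((37, 300)))
        with pytest.warns(UserWarning, match="no power reached"):
            pick_soft_power(expr)

    def test_deterministic_without_seed(self):
        expr, _ = planted_expression(np.random.default_rng(9))
        assert pick_soft_power(expr) == pick_soft_power(expr)

    def test_all_constant_matrix_errors(self):
        expr = pd.DataFrame(np.ones((30, 50)))
        with pytest.raises(ValueError, match="constant"):
            pick_soft_power(expr)


class TestDetectModules:
    def test_tom_is_symmetric_unit_diagonal_in_unit_interval(self):
        expr, _ = planted_expression(np.random.default_rng(10), n_noise=40)
        mset = detect_modules(expr, power=6)
        tom = mset.tom.to_numpy()
        assert np.allclose(tom, tom.T)
        assert np.allclose(np.diag(tom), 1.0)
        assert tom.min() >= 0 and tom.max() <= 1 + 1e-12

    def test_planted_blocks_recovered(self):
        from sklearn.metrics import adjusted_rand_score

        rng = np.random.default_rng(11)
        expr, truth = planted_expression(rng)
        power = pick_soft_power(expr)
        mset = detect_modules(expr, power, min_size=30)
        ari = adjusted_rand_score(truth, mset.assignments.to_numpy())
        assert ari >= 0.9

    def test_iid_noise_mostly_unassigned(self):
        rng = np.random.default_rng(12)
        expr = pd.DataFrame(
            rng.standard_normal((37, 300)), columns=[f"g{i}" for i in range(300)]
        )
        mset = detect_modules(expr, power=12, min_size=30)
        assert (mset.assignments == 0).mean() >= 0.95

    def test_min_size_larger_than_blocks_unassigns_everything(self):
        expr, _ = planted_expression(
            np.random.default_rng(13), block_sizes=(20, 20), n_noise=20
        )
        mset = detect_modules(expr, power=6, min_size=50)
        assert (mset.assignments == 0).all()

    def test_eigengenes_unit_variance_and_size_floor(self):
        expr, _ = planted_expression(np.random.default_rng(14))
        mset = detect_modules(expr, power=6, min_size=30)
        for mod in mset.module_ids:
            assert len(mset.members(mod)) >= 30
            assert mset.eigengenes[mod].std(ddof=0) == pytest.approx(1.0)


class TestEigengene:
    def test_identical_profiles_give_perfect_correlation(self):
        rng = np.random.default_rng(15)
        profile = rng.standard_normal(30)
        expr = pd.DataFrame({f"g{i}": profile for i in range(5)})
        e = module_eigengene(expr)
        assert abs(np.corrcoef(e, profile)[0, 1]) == pytest.approx(1.0)

    def test_orientation_tracks_member_sign_consistently(self):
        # the eigengene is oriented to correlate positively with its members,
        # so negating every member negates the summary in lockstep — the
        # relative orientation (mean member correlation >= 0) is what is
        # invariant, and SVD sign ambiguity never leaks through
        rng = np.random.default_rng(16)
        expr = pd.DataFrame(rng.standard_normal((25, 8)) + rng.standard_normal((25, 1)))
        a = module_eigengene(expr)
        b = module_eigengene(-expr)
        assert np.allclose(a, -b)
        mean_cor = np.mean([np.corrcoef(a, expr[c])[0, 1] for c in expr])
        assert mean_cor >= 0

    def test_orientation_stable_under_sample_reordering(self):
        rng = np.random.default_rng(17)
        expr = pd.DataFrame(
            rng.standard_normal((25, 8)) + rng.standard_normal((25, 1)),
            index=[f"s{i}" for i in range(25)],
        )
        perm = rng.permutation(25)
        a = module_eigengene(expr)
        b = module_eigengene(expr.iloc[perm])
        assert np.allclose(a.loc[b.index], b)

    def test_explains_more_variance_than_random_projections(self):
        rng = np.random.default_rng(18)
        expr = pd.DataFrame(rng.standard_normal((30, 12)))
        z = (expr - expr.mean()) / expr.std(ddof=0)
        e = module_eigengene(expr).to_numpy()
        var_pc = np.mean((z.to_numpy().T @ e / len(e)) ** 2)
        for _ in range(1000):
            w = rng.standard_normal(30)
            w = (w - w.mean()) / w.std(ddof=0)
            assert var_pc >= np.mean((z.to_numpy().T @ w / len(w)) ** 2) - 1e-12

    def test_requires_two_members(self):
        with pytest.raises(ValueError, match="at least 2"):
            module_eigengene(pd.DataFrame({"g": np.arange(5.0)}))


class TestModuleTraitAssociation:
    def _frame(self, n=27, seed=19):
        rng = np.random.default_rng(seed)
        idx = [f"s{i}" for i in range(n)]
        eig = pd.DataFrame({1: rng.standard_normal(n)}, index=idx)
        pop = pd.Series(["Tibetan"] * (n // 2) + ["Han"] * (n - n // 2), index=idx)
        return eig, pop, idx

    def test_self_correlation_is_perfect(self):
        eig, pop, idx = self._frame()
        traits = pd.DataFrame({"BW": eig[1]}, index=idx)
        out = module_trait_association(eig, traits, pop)
        assert out.loc[1, "r_BW"] == pytest.approx(1.0)
        assert out.loc[1, "p_BW"] == pytest.approx(0.0, abs=1e-30)

    def test_closed_form_t_p_value(self):
        # r = 0.5 at n = 27: t = 0.5*sqrt(25/0.75) ~ 2.887, p ~ 0.0078
        n = 27
        r_target = 0.5
        x = np.linspace(-1, 1, n)
        resid = np.sin(np.arange(n) * 2.1)
        resid -= np.polyval(np.polyfit(x, resid, 1), x)
        y = r_target * x / x.std() + np.sqrt(1 - r_target**2) * resid / resid.std()
        idx = [f"s{i}" for i in range(n)]
        eig = pd.DataFrame({1: x}, index=idx)
        traits = pd.DataFrame({"BW": y}, index=idx)
        pop = pd.Series(["Tibetan"] * 13 + ["Han"] * 14, index=idx)
        out = module_trait_association(eig, traits, pop)
        assert out.loc[1, "r_BW"] == pytest.approx(0.5, abs=1e-10)
        assert out.loc[1, "p_BW"] == pytest.approx(0.00776, abs=2e-4)

    def test_independent_trait_p_uniform(self):
        # KS check over replicates that the null p-distribution is uniform
        rng = np.random.default_rng(20)
        n = 40
        ps = []
        idx = [f"s{i}" for i in range(n)]
        pop = pd.Series(["Tibetan"] * 20 + ["Han"] * 20, index=idx)
        for _ in range(500):
            eig = pd.DataFrame({1: rng.standard_normal(n)}, index=idx)
            traits = pd.DataFrame({"BW": rng.standard_normal(n)}, index=idx)
            ps.append(module_trait_association(eig, traits, pop).loc[1, "p_BW"])
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_zero_variance_trait_gives_na_with_warning(self):
        eig, pop, idx = self._frame()
        traits = pd.DataFrame({"BW": np.ones(len(idx))}, index=idx)
        with pytest.warns(UserWarning, match="undefined correlation"):
            out = module_trait_association(eig, traits, pop)
        assert np.isnan(out.loc[1, "r_BW"])


class TestEffectiveTraitNumber:
    def test_identity_gives_full_count(self):
        meff, alpha = effective_trait_number(np.eye(12))
        assert meff == pytest.approx(12.0)
        assert alpha == pytest.approx(0.05 / 12)

    def test_rank_one_gives_single_trait(self):
        meff, alpha = effective_trait_number(np.ones((12, 12)))
        assert meff == pytest.approx(1.0)
        assert alpha == pytest.approx(0.05)

    def test_four_independent_blocks_give_bonferroni_00125(self):
        # 12 traits in 4 perfectly correlated triplets: Meff = 4, 0.05/4
        c = np.kron(np.eye(4), np.ones((3, 3)))
        meff, alpha = effective_trait_number(c)
        assert meff == pytest.approx(4.0)
        assert alpha == pytest.approx(0.0125)

    @pytest.mark.parametrize("n_traits,seed", [(5, 0), (11, 1), (12, 2)])
    def test_bounded_between_one_and_n(self, n_traits, seed):
        rng = np.random.default_rng(seed)
        x = rng.standard_normal((50, n_traits)) + 0.5 * rng.standard_normal((50, 1))
        meff, _ = effective_trait_number(np.corrcoef(x, rowvar=False))
        assert 1.0 - 1e-9 <= meff <= n_traits + 1e-9

    def test_rejects_invalid_matrices(self):
        with pytest.raises(ValueError, match="square"):
            effective_trait_number(np.ones((2, 3)))
        bad = np.eye(3)
        bad[0, 1] = 0.5  # asymmetric
        with pytest.raises(ValueError, match="symmetric"):
            effective_trait_number(bad)
        bad = np.eye(3) * 2.0
        with pytest.raises(ValueError, match="unit diagonal"):
            effective_trait_number(bad)


def _stats_table(p_pop, min_trait_p):
    return pd.DataFrame(
        {
            "p_pop": p_pop,
            "min_trait_p": min_trait_p,
            "best_trait": ["BW"] * len(p_pop),
        },
        index=pd.Index(range(1, len(p_pop) + 1), name="module"),
    )


class TestSDMAndHubs:
    def _module_set(self, rng, block_sizes=(40, 40), n_noise=40):
        expr, truth = planted_expression(rng, n_samples=40, block_sizes=block_sizes, n_noise=n_noise)
        mset = detect_modules(expr, power=6, min_size=20)
        return expr, mset

    def test_population_nonsignificance_blocks_sdm(self):
        rng = np.random.default_rng(21)
        expr, mset = self._module_set(rng)
        tab = _stats_table([0.2, 0.01], [0.001, 0.002])
        tab = tab.loc[[m for m in tab.index if m in mset.module_ids]]
        out = flag_sdm_and_key(tab, mset, set(), 1000, meff=4.0)
        assert not out.loc[1, "is_sdm"]

    def test_trait_p_below_00125_is_sdm_under_both_rules(self):
        rng = np.random.default_rng(22)
        expr, mset = self._module_set(rng)
        tab = _stats_table([0.01, 0.5], [0.002, 0.9])
        out = flag_sdm_and_key(tab, mset, set(), 1000, meff=4.0)
        assert bool(out.loc[1, "is_sdm_05"]) and bool(out.loc[1, "is_sdm_meff"])
        assert out.loc[1, "trait_alpha"] == pytest.approx(0.0125)

    def test_module_equal_to_deg_set_minimizes_overlap_p(self):
        rng = np.random.default_rng(23)
        expr, mset = self._module_set(rng)
        deg = set(mset.members(1))
        tab = _stats_table([0.01, 0.01], [0.01, 0.01])
        out = flag_sdm_and_key(
            tab, mset, deg, universe_size=expr.shape[1], meff=4.0, trait_threshold="0.05"
        )
        assert out["overlap_p"].idxmin() == 1
        assert out.loc[1, "deg_overlap"] == len(deg)

    def test_empty_deg_set_gives_overlap_p_one(self):
        rng = np.random.default_rng(24)
        expr, mset = self._module_set(rng)
        tab = _stats_table([0.01, 0.01], [0.01, 0.01])
        out = flag_sdm_and_key(tab, mset, set(), 1000, meff=4.0, trait_threshold="0.05")
        assert (out["overlap_p"] == 1.0).all()
        assert out["is_key"].sum() == 1  # lexicographic rule still picks one

    def test_no_gene_passes_trait_criterion_means_no_hubs(self):
        rng = np.random.default_rng(25)
        expr, mset = self._module_set(rng)
        traits = pd.DataFrame(
            {"BW": rng.standard_normal(expr.shape[0])}, index=expr.index
        )
        out = hub_genes(mset, expr, traits, trait_r_min=0.8)
        assert out.empty

    def test_planted_hub_gene_is_reported(self):
        # one gene IS the latent driving both its block and the trait
        rng = np.random.default_rng(26)
        n = 40
        latent = rng.standard_normal(n)
        cols = {"hub": latent}
        for i in range(19):
            cols[f"m{i}"] = 0.8 * latent + 0.6 * rng.standard_normal(n)
        for i in range(30):
            cols[f"n{i}"] = rng.standard_normal(n)
        expr = pd.DataFrame(cols, index=[f"s{i}" for i in range(n)])
        mset = detect_modules(expr, power=6, min_size=10)
        hub_module = mset.assignments["hub"]
        assert hub_module != 0
        traits = pd.DataFrame({"BW": latent + 0.3 * rng.standard_normal(n)}, index=expr.index)
        out = hub_genes(mset, expr, traits)
        assert "hub" in set(out["gene_id"])

    def test_degree_ties_at_cutoff_all_reported_and_flagged(self):
        # identical profiles: every member ties in intra-module connectivity
        rng = np.random.default_rng(27)
        profile = rng.standard_normal(30)
        cols = {f"g{i}": profile for i in range(6)}
        for i in range(20):
            cols[f"n{i}"] = rng.standard_normal(30)
        expr = pd.DataFrame(cols, index=[f"s{i}" for i in range(30)])
        mset = detect_modules(expr, power=6, min_size=5)
        traits = pd.DataFrame({"BW": profile}, index=expr.index)
        out = hub_genes(mset, expr, traits)
        mod = mset.assignments["g0"]
        got = out[out["module"] == mod]
        assert len(got) == 6  # all tied members included
        assert got["tied_at_cutoff"].all()


def test_trait_loaded_module_attains_smallest_trait_p(small_cohort):
    """On generator output with a BW loading on module 1 only, module 1's
    best trait p should be the smallest among modules."""
    from placentome._utils import TRAITS

    truth = small_cohort.truth
    meta = small_cohort.metadata
    sub = meta[meta["layer"] == "UC"].set_index("sample_id")
    expr = vst_like_transform(small_cohort.counts["UC"])
    eig = {}
    for mod in sorted(set(truth.module_assignment.values())):
        members = [g for g, m in truth.module_assignment.items() if m == mod]
        eig[mod] = module_eigengene(expr[members])
    eigengenes = pd.DataFrame(eig, index=expr.index)
    out = module_trait_association(
        eigengenes, sub[list(TRAITS)], sub["population"]
    )
    assert out["min_trait_p"].idxmin() == 1
    assert out.loc[1, "best_trait"] == "BW"
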