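"""Differential expression: normalization, the NB Wald test against an
independent GLM oracle, BH correction, and the DEG-set summaries."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from placentome._utils import bh_adjust
from placentome.de import (
    DEGSetCollection,
    classify_layer_sharing,
    direction_discordance,
    nb_glm_wald,
    size_factors,
    _design_matrix,
    _irls,
)

from conftest import nb_counts, one_layer_metadata


class TestSizeFactors:
    def test_identical_columns_get_unit_factors(self):
        col = np.array([5, 80, 0, 13, 200])
        counts = pd.DataFrame({f"s{i}": col for i in range(4)})
        assert np.allclose(size_factors(counts), 1.0)

    def test_scale_equivariance_for_doubled_column(self):
        rng = np.random.default_rng(0)
        base = rng.poisson(50, size=200)
        counts = pd.DataFrame({"a": base, "b": base, "c": 2 * base})
        sf = size_factors(counts)
        assert sf["c"] == pytest.approx(2 * sf["a"])

    def test_matches_hand_computed_median_of_ratios(self):
        counts = pd.DataFrame(
            {
                "s1": [10, 20, 30, 40, 55],
                "s2": [20, 40, 66, 80, 100],
                "s3": [5, 10, 15, 22, 25],
            }
        )
        # independent oracle: explicit median-of-ratios arithmetic
        y = counts.to_numpy(float)
        ref = np.exp(np.log(y).mean(axis=1))
        expected = np.median(y / ref[:, None], axis=0)
        assert np.allclose(size_factors(counts).to_numpy(), expected)

    def test_fallback_when_no_gene_covers_all_samples(self):
        counts = pd.DataFrame({"a": [10, 0], "b": [0, 30]})
        with pytest.warns(UserWarning, match="total-count"):
            sf = size_factors(counts)
        assert np.allclose(np.exp(np.mean(np.log(sf))), 1.0)


class TestBHAdjust:
    def test_hand_computed_step_up(self):
        # sorted p*m/i = {.04,.04,.04,.04}: every gene lands on 0.04
        adj = bh_adjust(np.array([0.01, 0.02, 0.03, 0.04]))
        assert np.allclose(adj, 0.04)

    @pytest.mark.parametrize("c", [0.2, 1.0])
    def test_equal_ps_unchanged(self, c):
        assert np.allclose(bh_adjust(np.full(7, c)), c)

    def test_single_test_identity_and_nan_passthrough(self):
        assert bh_adjust(np.array([0.03]))[0] == pytest.approx(0.03)
        adj = bh_adjust(np.array([0.01, np.nan, 0.04]))
        assert np.isnan(adj[1])
        # NaN not counted in m: equivalent to adjusting [0.01, 0.04] (m=2)
        assert adj[0] == pytest.approx(0.02)
        assert adj[2] == pytest.approx(0.04)

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            bh_adjust(np.array([0.5, 1.5]))

    def test_agrees_with_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(1)
        p = rng.uniform(size=200)
        expected = multipletests(p, method="fdr_bh")[1]
        assert np.allclose(bh_adjust(p), expected)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=60))
    def test_monotone_and_bounded(self, ps):
        p = np.array(ps)
        adj = bh_adjust(p)
        assert (adj <= 1 + 1e-12).all() and (adj >= p - 1e-12).all()
        order = np.argsort(p, kind="mergesort")
        assert (np.diff(adj[order]) >= -1e-12).all()


class TestNBGLM:
    def test_matches_statsmodels_fixed_dispersion(self):
        # dual-route check: the batched IRLS against statsmodels' NB GLM
        import statsmodels.api as sm

        rng = np.random.default_rng(2)
        meta = one_layer_metadata(seed=2)
        counts = nb_counts(rng, meta, n_genes=40, lfc={0: 1.0, 1: -1.5})
        X, _ = _design_matrix(meta, ["maternal_age"], ("Tibetan", "Han"))
        sf = size_factors(counts).to_numpy()
        alpha = np.full(40, 0.08)
        beta, cov = _irls(counts.to_numpy(float), X, np.log(sf), alpha)
        for g in [0, 1, 7, 23]:
            fit = sm.GLM(
                counts.to_numpy(float)[g],
                X,
                family=sm.families.NegativeBinomial(alpha=0.08),
                offset=np.log(sf),
            ).fit()
            assert np.allclose(beta[g], fit.params, atol=1e-4)
            assert np.allclose(np.sqrt(np.diag(cov[g])), fit.bse, rtol=1e-3)

    def test_all_zero_gene_excluded_as_na(self):
        rng = np.random.default_rng(3)
        meta = one_layer_metadata(seed=3)
        counts = nb_counts(rng, meta, n_genes=30)
        counts.iloc[5] = 0
        res = nb_glm_wald(counts, meta, covariates=["maternal_age"])
        assert np.isnan(res["p"].iloc[5]) and np.isnan(res["p_adj"].iloc[5])
        assert not bool(res["is_deg"].iloc[5])

    def test_label_swap_negates_lfc_keeps_p(self):
        rng = np.random.default_rng(4)
        meta = one_layer_metadata(seed=4)
        counts = nb_counts(rng, meta, n_genes=60, lfc={i: 1.0 for i in range(5)})
        a = nb_glm_wald(counts, meta, covariates=["maternal_age"],
                        population_levels=("Tibetan", "Han"))
        b = nb_glm_wald(counts, meta, covariates=["maternal_age"],
                        population_levels=("Han", "Tibetan"))
        mask = a["p"].notna()
        assert np.allclose(a["log2FC"][mask], -b["log2FC"][mask], atol=1e-6)
        assert np.allclose(a["p"][mask], b["p"][mask], atol=1e-8)

    def test_too_few_samples_per_population_errors(self):
        meta = one_layer_metadata(n_pop1=1, n_pop2=5, seed=5)
        counts = nb_counts(np.random.default_rng(5), meta, n_genes=10)
        with pytest.raises(ValueError, match="fewer than 2"):
            nb_glm_wald(counts, meta)

    def test_global_null_false_discovery_proportion(self):
        # under the global null every BH discovery is false; the realized
        # FDP averaged over replicates should stay near the nominal level
        fdps = []
        for rep in range(20):
            rng = np.random.default_rng(100 + rep)
            meta = one_layer_metadata(seed=100 + rep)
            counts = nb_counts(rng, meta, n_genes=400)
            res = nb_glm_wald(counts, meta, covariates=["maternal_age"])
            n_deg = int(res["is_deg"].sum())
            fdps.append(1.0 if n_deg > 0 else 0.0)
        assert np.mean(fdps) <= 0.07


def _collection(sets, universe=1000):
    return DEGSetCollection(
        stratum="combined",
        sets={l: {g: "up" for g in gs} for l, gs in sets.items()},
        universe_size=universe,
    )


class TestSharingAndDiscordance:
    def test_two_layer_shared_class_label(self):
        coll = _collection({"VF": {"g1", "g2"}, "VI": {"g1"}, "UC": set()})
        per_gene, summary = classify_layer_sharing(coll)
        row = per_gene.set_index("gene_id").loc["g1"]
        assert row["sharing_class"] == "2-layer-shared (VF,VI)"
        assert summary["per_k"] == {1: 1, 2: 1}

    def test_matches_brute_force_on_random_collections(self):
        rng = np.random.default_rng(6)
        genes = [f"g{i}" for i in range(40)]
        layers = ["UC", "AN", "VF", "VI"]
        sets = {
            l: set(rng.choice(genes, size=rng.integers(0, 20), replace=False))
            for l in layers
        }
        _, summary = classify_layer_sharing(_collection(sets))
        # oracle: plain set algebra per gene
        counts = {}
        for g in genes:
            k = sum(g in sets[l] for l in layers)
            if k:
                counts[k] = counts.get(k, 0) + 1
        assert summary["per_k"] == counts
        assert summary["n_distinct"] == sum(counts.values())

    def test_one_layer_share_uses_half_up_percent(self):
        sets = {"UC": {f"g{i}" for i in range(399)}}
        shared = {f"h{i}" for i in range(180)}
        sets["VF"] = shared
        sets["VI"] = shared
        _, summary = classify_layer_sharing(_collection(sets))
        assert summary["n_distinct"] == 579
        assert summary["one_layer_pct"] == 68.91

    def _results(self, lfc, deg):
        return pd.DataFrame(
            {"log2FC": lfc, "is_deg": deg},
            index=[f"g{i}" for i in range(len(lfc))],
        )

    def test_identical_strata_have_zero_discordance(self):
        male = self._results([1.0, -2.0, 0.5], [True, True, False])
        out = direction_discordance(male, male)
        assert out["n_opposite"] == 0 and out["discordance_pct"] == 0.0

    def test_fully_mirrored_strata_are_fully_discordant(self):
        male = self._results([1.0, -2.0], [True, True])
        female = self._results([-1.0, 2.0], [False, False])
        out = direction_discordance(male, female)
        assert out["discordance_pct"] == 100.0

    def test_zero_female_effect_counts_as_concordant(self):
        male = self._results([1.0], [True])
        female = self._results([0.0], [False])
        assert direction_discordance(male, female)["n_opposite"] == 0

    def test_missing_female_gene_excluded_from_denominator(self):
        male = self._results([1.0, -1.0], [True, True])
        female = self._results([-1.0], [False])  # only g0 present
        out = direction_discordance(male, female)
        assert out["n_used"] == 1 and out["n_excluded"] == 1
        assert out["discordance_pct"] == 100.0
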