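"""Normalization, dispersion, NB species tests, contrasts, QC, PCA, BH."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.metrics import silhouette_score

from primatlas import diffacc, synthdata
from primatlas.synthdata import SimConfig, sample_table

from conftest import make_truth


def meta_frame(species_per_sample):
    rows = [
        (f"s{i}", sp, 1, i) for i, sp in enumerate(species_per_sample)
    ]
    return pd.DataFrame(
        rows, columns=["sample_id", "species", "bio_rep", "tech_rep"]
    ).set_index("sample_id", drop=False)


def sim_counts(n_ocrs, alpha, fold=1.0, seed=0, baseline=200.0, state="common",
               frac_planted=0.1):
    """Counts with a planted-state fraction (the rest common), so that
    normalization cannot absorb the planted fold."""
    cfg = SimConfig(n_ocrs=n_ocrs, dispersion_alpha=alpha, seed=seed)
    truth = make_truth(n_ocrs, baseline=baseline, fold=fold)
    n_planted = int(frac_planted * n_ocrs) if state != "common" else 0
    planted_idx = truth.table.index[:n_planted]
    truth.table.loc[planted_idx, "state"] = state
    meta = sample_table(cfg)
    truth.size_factors = pd.Series(1.0, index=meta.index)
    counts = synthdata.simulate_counts(truth, cfg, np.random.default_rng(seed))
    return counts.clip(lower=1), meta, planted_idx


class TestSizeFactors:
    def test_identical_columns_give_unity(self):
        counts = pd.DataFrame({"a": [10, 20, 30], "b": [10, 20, 30]})
        s = diffacc.size_factors(counts).size_factors
        assert np.allclose(s, 1.0)

    def test_hand_computed_median_of_ratios(self):
        counts = pd.DataFrame([[10, 20], [30, 60]], columns=["a", "b"])
        s = diffacc.size_factors(counts).size_factors
        assert s["a"] == pytest.approx(1 / np.sqrt(2))
        assert s["b"] == pytest.approx(np.sqrt(2))

    def test_column_scaling_equivariance_and_row_permutation(self, rng):
        counts = pd.DataFrame(
            rng.integers(1, 500, (50, 4)), columns=list("abcd")
        )
        s = diffacc.size_factors(counts).size_factors
        scaled = counts.copy()
        scaled["c"] = counts["c"] * 3
        s2 = diffacc.size_factors(scaled).size_factors
        # scaling one column by 3 scales its factor by 3 relative to the
        # others (the geometric-mean reference shifts by a global constant)
        assert s2["c"] / s2["a"] == pytest.approx(3 * s["c"] / s["a"])
        assert np.allclose(s2["b"] / s2["a"], s["b"] / s["a"])
        perm = counts.sample(frac=1, random_state=0)
        s3 = diffacc.size_factors(perm).size_factors
        assert np.allclose(s3, s)

    def test_zero_counts_rejected(self):
        counts = pd.DataFrame({"a": [0, 5], "b": [2, 3]})
        with pytest.raises(ValueError, match="filter_zero_count"):
            diffacc.size_factors(counts)


class TestReplicateQc:
    def test_duplicate_columns_retained(self, rng):
        col = rng.integers(1, 1000, 100)
        meta = meta_frame(["human", "human", "human"])
        counts = pd.DataFrame({"s0": col, "s1": col, "s2": col})
        retained, corr = diffacc.replicate_qc(counts, meta)
        assert retained == ["s0", "s1", "s2"]
        assert corr.loc["s0", "s1"] == pytest.approx(1.0)

    def test_corrupted_replicate_excluded(self, small_sim):
        corrupted = synthdata.corrupt_replicate(
            small_sim.counts.clip(lower=1), "chimp_b1t2", 1.0, seed=2
        )
        retained, corr = diffacc.replicate_qc(corrupted, small_sim.meta)
        assert "chimp_b1t2" not in retained
        assert set(retained) == set(small_sim.counts.columns) - {"chimp_b1t2"}

    def test_single_outlier_alone_excluded(self, rng):
        base = rng.integers(50, 2000, 200).astype(float)
        a = rng.poisson(base)
        b = rng.poisson(base)
        c = rng.permutation(rng.poisson(base))  # unrelated to the others
        meta = meta_frame(["human", "human", "human"])
        counts = pd.DataFrame({"s0": a, "s1": b, "s2": c}).clip(lower=1)
        retained, corr = diffacc.replicate_qc(counts, meta)
        assert corr.loc["s0", "s1"] > 0.85 > corr.loc["s2", "s0"]
        assert retained == ["s0", "s1"]


class TestEstimateDispersion:
    def test_poisson_data_near_floor(self):
        counts, meta, planted = sim_counts(2000, alpha=0.0, seed=1)
        norm = diffacc.size_factors(counts)
        a = diffacc.estimate_dispersion(counts, norm, meta)
        assert np.median(a) < 0.02

    def test_recovery_at_half(self):
        cfg = SimConfig(
            n_ocrs=500,
            dispersion_alpha=0.5,
            n_bio_reps={"human": 10, "chimp": 10, "rhesus": 10},
            n_tech_reps=2,
            seed=2,
        )
        truth = make_truth(500, baseline=100.0)
        meta = sample_table(cfg)
        truth.size_factors = pd.Series(1.0, index=meta.index)
        counts = synthdata.simulate_counts(
            truth, cfg, np.random.default_rng(2)
        ).clip(lower=1)
        norm = diffacc.size_factors(counts)
        a = diffacc.estimate_dispersion(counts, norm, meta)
        assert a.mean() == pytest.approx(0.5, abs=0.1)

    def test_constant_rows_floored(self):
        counts = pd.DataFrame(np.full((10, 4), 7))
        meta = meta_frame(["human", "human", "chimp", "chimp"])
        counts.columns = meta.index
        norm = diffacc.size_factors(counts)
        a = diffacc.estimate_dispersion(counts, norm, meta)
        assert (a == diffacc.ALPHA_FLOOR).all()


class TestNbModelAgainstStatsmodels:
    """The vectorized per-group NB fit must agree with an independently
    fitted statsmodels NB GLM (species factor, log size-factor offset)."""

    def test_loglik_and_means_match(self):
        counts, meta, planted = sim_counts(20, alpha=0.2, seed=3)
        norm = diffacc.size_factors(counts)
        alpha = pd.Series(0.2, index=counts.index)
        fit = diffacc.fit_species_model(counts, norm, alpha, meta)
        X = pd.get_dummies(meta["species"], drop_first=False).astype(float)
        offset = np.log(norm.size_factors.to_numpy())
        for i, ocr in enumerate(counts.index[:10]):
            y = counts.loc[ocr].to_numpy()
            glm = sm.GLM(
                y, X.to_numpy(), family=sm.families.NegativeBinomial(alpha=0.2),
                offset=offset,
            ).fit()
            ll_sm = glm.llf
            ll_ours = None
            # our species log-likelihood for this OCR
            sub = counts.loc[[ocr]]
            f1 = diffacc.fit_species_model(sub, norm, alpha.loc[[ocr]], meta)
            ll_ours = f1["ll_species"][0]
            assert ll_ours == pytest.approx(ll_sm, abs=1e-4)
            for j, sp in enumerate(X.columns):
                assert np.log(f1["means"][sp][0]) == pytest.approx(
                    glm.params[j], abs=1e-4
                )


class TestSpeciesEffect:
    def test_null_type_one_error_controlled(self):
        counts, meta, planted = sim_counts(2000, alpha=0.1, fold=1.0, seed=4)
        norm = diffacc.size_factors(counts)
        alpha = diffacc.estimate_dispersion(counts, norm, meta)
        res = diffacc.test_species_effect(counts, norm, alpha, meta)
        assert (res["lrt_stat"] >= 0).all()
        assert (res["p"] < 0.05).mean() <= 1.5 * 0.05

    def test_planted_fold_detected(self):
        counts, meta, planted = sim_counts(
            400, alpha=0.05, fold=4.0, seed=5, state="human_increased"
        )
        norm = diffacc.size_factors(counts)
        alpha = diffacc.estimate_dispersion(counts, norm, meta)
        res = diffacc.test_species_effect(counts, norm, alpha, meta)
        assert (res.loc[planted, "q"] < 0.05).mean() > 0.8


class TestPairwiseContrast:
    def test_identical_group_means_zero_fc(self):
        col = np.arange(1, 21)
        counts = pd.DataFrame({f"s{i}": col for i in range(4)})
        meta = meta_frame(["human", "human", "chimp", "chimp"])
        counts.columns = meta.index
        norm = diffacc.size_factors(counts)
        alpha = pd.Series(0.1, index=counts.index)
        res = diffacc.pairwise_contrast(counts, norm, alpha, meta, "human", "chimp")
        assert np.allclose(res["log2fc"], 0.0)

    def test_swap_negates_fc_keeps_p(self):
        counts, meta, planted = sim_counts(50, alpha=0.1, fold=4.0, seed=6, state="human_increased")
        norm = diffacc.size_factors(counts)
        alpha = diffacc.estimate_dispersion(counts, norm, meta)
        ab = diffacc.pairwise_contrast(counts, norm, alpha, meta, "human", "chimp")
        ba = diffacc.pairwise_contrast(counts, norm, alpha, meta, "chimp", "human")
        assert np.allclose(ab["log2fc"], -ba["log2fc"], atol=1e-4)
        assert np.allclose(ab["p"], ba["p"], atol=1e-10)

    def test_planted_fold_recovered(self):
        counts, meta, planted = sim_counts(
            300, alpha=0.05, fold=4.0, seed=7, state="human_increased"
        )
        norm = diffacc.size_factors(counts)
        alpha = diffacc.estimate_dispersion(counts, norm, meta)
        res = diffacc.pairwise_contrast(counts, norm, alpha, meta, "human", "chimp")
        assert res.loc[planted, "log2fc"].mean() == pytest.approx(2.0, abs=0.25)


class TestPcaQc:
    def test_variance_fractions_and_species_separation(self):
        cfg = SimConfig(n_ocrs=500, seed=8)
        sim = synthdata.simulate_dataset(cfg)
        counts = sim.counts.clip(lower=1)
        norm = diffacc.size_factors(counts)
        coords, var = diffacc.pca_qc(norm, sim.meta)
        assert var.sum() == pytest.approx(1.0, abs=1e-6)
        sil = silhouette_score(
            coords[["PC1", "PC2"]].to_numpy(), coords["species"].to_numpy()
        )
        assert sil > 0

    def test_duplicate_samples_identical_coordinates(self, rng):
        col = rng.integers(1, 500, 100)
        counts = pd.DataFrame({"a": col, "b": col, "c": col * 2})
        meta = meta_frame(["human", "human", "chimp"])
        counts.columns = meta.index
        norm = diffacc.size_factors(counts)
        coords, _ = diffacc.pca_qc(norm, meta)
        pcs = [c for c in coords.columns if c.startswith("PC")]
        a, b = coords[pcs].astype(float).iloc[0], coords[pcs].astype(float).iloc[1]
        assert np.allclose(a, b, atol=1e-8)


class TestBhAdjust:
    def test_hand_computed_step_up(self):
        assert np.allclose(diffacc.bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_single_and_boundary(self):
        assert diffacc.bh_adjust([0.2])[0] == pytest.approx(0.2)
        assert np.allclose(diffacc.bh_adjust([1.0, 1.0]), 1.0)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            diffacc.bh_adjust([0.5, 1.5])

    @settings(deadline=None, max_examples=50)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=40))
    def test_monotone_in_p_and_bounded(self, ps):
        q = diffacc.bh_adjust(ps)
        assert ((q >= np.asarray(ps) - 1e-12) & (q <= 1 + 1e-12)).all()
        order = np.argsort(ps)
        assert (np.diff(q[order]) >= -1e-12).all()
        # q <= a must coincide with the classical step-up rejection set
        m = len(ps)
        p_sorted = np.sort(ps)
        for a in (0.01, 0.05, 0.25):
            below = np.flatnonzero(p_sorted <= (np.arange(1, m + 1) / m) * a)
            cutoff = p_sorted[below.max()] if below.size else -1.0
            rejected = np.asarray(ps) <= cutoff
            assert ((q <= a + 1e-12) == rejected).all()
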