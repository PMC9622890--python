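"""Unit and property tests of the NB differential-count engine."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from damtarget.countmodel import (
    CountMatrix,
    bh_adjust,
    call_de,
    estimate_dispersion,
    nb_wald_test,
    size_factors,
)
from damtarget.synthetic import SimulationConfig, simulate_depletion_experiment


def _cm(counts: dict, groups: dict, **kw) -> CountMatrix:
    return CountMatrix(pd.DataFrame(counts), pd.Series(groups), **kw)


class TestSizeFactors:
    def test_identical_samples_get_unit_factors(self):
        cm = _cm({"a": [10, 20, 5], "b": [10, 20, 5]}, {"a": "x", "b": "y"})
        sf = size_factors(cm)
        assert np.allclose(sf, [1.0, 1.0])

    def test_doubled_sample_splits_geometrically(self):
        # B = 2A: geometric-mean reference puts A at 1/sqrt(2), B at sqrt(2)
        cm = _cm({"a": [10, 20, 5], "b": [20, 40, 10]}, {"a": "x", "b": "y"})
        sf = size_factors(cm)
        assert np.allclose(sf, [1 / np.sqrt(2), np.sqrt(2)], atol=1e-9)

    def test_all_zero_feature_is_ignored(self):
        base = _cm({"a": [10, 20, 5], "b": [20, 40, 10]}, {"a": "x", "b": "y"})
        with_zero = _cm(
            {"a": [10, 20, 5, 0], "b": [20, 40, 10, 0]}, {"a": "x", "b": "y"}
        )
        assert np.allclose(size_factors(base), size_factors(with_zero))

    def test_scale_equivariance(self):
        rng = np.random.default_rng(0)
        counts = pd.DataFrame(rng.poisson(50, (100, 4)), columns=list("abcd"))
        groups = pd.Series({"a": "x", "b": "x", "c": "y", "d": "y"})
        sf1 = size_factors(CountMatrix(counts, groups))
        scaled = counts.copy()
        scaled["b"] *= 3
        sf2 = size_factors(CountMatrix(scaled, groups))
        assert np.isclose(sf2["b"] / sf1["b"], 3 * sf2["a"] / sf1["a"], rtol=1e-9)

    def test_no_common_nonzero_feature_raises(self):
        cm = _cm({"a": [1, 0], "b": [0, 1]}, {"a": "x", "b": "y"})
        with pytest.raises(ValueError, match="size factors"):
            size_factors(cm)


class TestDispersion:
    def test_constant_counts_give_zero_raw_dispersion(self):
        cm = _cm(
            {"a": [10, 7], "b": [10, 7], "c": [10, 7]},
            {"a": "g1", "b": "g1", "c": "g1"},
        )
        alpha = estimate_dispersion(cm, moderate=False)
        assert (alpha == 0).all()

    def test_poisson_counts_estimate_near_zero(self):
        rng = np.random.default_rng(1)
        counts = pd.DataFrame(
            rng.poisson(rng.lognormal(4, 1, 2000)[:, None], (2000, 6)),
            columns=[f"s{i}" for i in range(6)],
        )
        groups = pd.Series({f"s{i}": "c" if i < 3 else "t" for i in range(6)})
        alpha = estimate_dispersion(CountMatrix(counts, groups))
        assert alpha.median() <= 0.01

    def test_nb_dispersion_recovered_in_band(self):
        rng = np.random.default_rng(2)
        mu = rng.lognormal(5, 1, 2000)
        n = 1 / 0.1
        counts = pd.DataFrame(
            rng.negative_binomial(n, n / (n + mu[:, None]), (2000, 6)),
            columns=[f"s{i}" for i in range(6)],
        )
        groups = pd.Series({f"s{i}": "c" if i < 3 else "t" for i in range(6)})
        alpha = estimate_dispersion(CountMatrix(counts, groups))
        assert 0.05 <= alpha.median() <= 0.2

    def test_no_replicated_group_raises(self):
        cm = _cm({"a": [5, 8], "b": [6, 9]}, {"a": "x", "b": "y"})
        with pytest.raises(ValueError, match="replicates"):
            estimate_dispersion(cm)


class TestWaldTest:
    def test_label_swap_negates_log2fc_exactly(self, depletion_sim):
        cm, _ = depletion_sim
        fwd = nb_wald_test(cm, "control", "knockdown")
        rev = nb_wald_test(cm, "knockdown", "control")
        assert np.allclose(fwd["log2fc"], -rev["log2fc"], atol=0)

    def test_null_type_i_error_calibrated(self):
        cfg = SimulationConfig(
            n_genes=2000, seed=7, depletion_fraction=0.0, up_fraction=0.0
        )
        cm, _ = simulate_depletion_experiment(None, cfg)
        de = nb_wald_test(cm, "control", "knockdown")
        frac = (de["pvalue"].dropna() < 0.05).mean()
        assert 0.025 <= frac <= 0.075

    def test_planted_log2fc_recovered(self):
        cfg = SimulationConfig(n_genes=2000, seed=3, depletion_fold=4, up_fold=4)
        cm, truth = simulate_depletion_experiment(None, cfg)
        de = nb_wald_test(cm, "control", "knockdown")
        down = de.loc[sorted(truth.planted_down)]
        down = down[down["base_mean"] >= 100]
        assert abs(down["log2fc"].mean() - (-2.0)) <= 0.3

    def test_all_zero_feature_has_undefined_p(self):
        cm = _cm(
            {"a": [10, 0], "b": [12, 0], "c": [9, 0], "d": [11, 0]},
            {"a": "c", "b": "c", "c": "t", "d": "t"},
        )
        de = nb_wald_test(cm, "c", "t")
        assert np.isnan(de["pvalue"].iloc[1]) and np.isnan(de["padj"].iloc[1])
        assert np.isfinite(de["pvalue"].iloc[0])


class TestBH:
    def test_stepup_hand_example(self):
        # p = (.01,.02,.03,.04), m=4: every adjusted value collapses to 0.04
        padj = bh_adjust(np.array([0.01, 0.02, 0.03, 0.04]))
        assert np.allclose(padj, 0.04)

    def test_single_p_unchanged_and_zero_stays_zero(self):
        assert bh_adjust(np.array([0.2]))[0] == 0.2
        assert bh_adjust(np.array([0.0, 0.5]))[0] == 0.0

    def test_padj_at_least_pvalue(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(size=500)
        assert (bh_adjust(p) >= p).all()

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=50))
    @settings(deadline=None, max_examples=50)
    def test_permutation_invariance(self, ps):
        p = np.array(ps)
        perm = np.random.default_rng(0).permutation(len(p))
        direct = bh_adjust(p)[perm]
        permuted = bh_adjust(p[perm])
        assert np.allclose(direct, permuted)

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(5)
        p = rng.uniform(size=200)
        ours = bh_adjust(p)
        theirs = multipletests(p, method="fdr_bh")[1]
        assert np.allclose(ours, theirs)


class TestCallDe:
    def test_thresholds_are_strict(self):
        de = pd.DataFrame(
            {
                "log2fc": [0.5, 0.51, -1.2, -0.5],
                "padj": [0.005, 0.005, 0.005, 0.009],
            },
            index=["boundary_fc", "up", "down", "boundary_neg"],
        )
        up, down = call_de(de)
        assert up == {"up"}
        assert down == {"down"}

    def test_depletion_recovery_sensitivity_and_fdr(self, depletion_sim):
        cm, truth = depletion_sim
        de = nb_wald_test(cm, "control", "knockdown")
        up, down = call_de(de)
        t_down, t_up = set(truth.planted_down), set(truth.planted_up)
        sens = (len(down & t_down) + len(up & t_up)) / (len(t_down) + len(t_up))
        fdr = (len(down - t_down) + len(up - t_up)) / max(1, len(down) + len(up))
        assert sens >= 0.9
        assert fdr <= 0.05


def test_concordance_with_deseq2_reference():
    """The simplified engine agrees with the GLM-based reference
    implementation (pyDESeq2) on well-expressed genes: near-identical
    fold changes, same planted-effect magnitudes."""
    import warnings

    from pydeseq2.dds import DeseqDataSet
    from pydeseq2.ds import DeseqStats

    cfg = SimulationConfig(
        n_genes=300, markers_per_type=30, seed=4,
        depletion_fold=4, up_fold=4, up_fraction=0.05,
    )
    cm, truth = simulate_depletion_experiment(None, cfg)
    ours = nb_wald_test(cm, "control", "knockdown")

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        dds = DeseqDataSet(
            counts=cm.counts.T, metadata=pd.DataFrame({"condition": cm.groups}),
            design="~condition", quiet=True,
        )
        dds.deseq2()
        stats = DeseqStats(
            dds, contrast=["condition", "knockdown", "control"], quiet=True
        )
        stats.summary()
    ref = stats.results_df

    both = ours.join(ref[["log2FoldChange"]])
    hi = both[both["base_mean"] >= 100]
    assert np.corrcoef(hi["log2fc"], hi["log2FoldChange"])[0, 1] >= 0.999
    assert (hi["log2fc"] - hi["log2FoldChange"]).abs().max() <= 0.05
    down = sorted(truth.planted_down)
    assert ours.loc[down, "log2fc"].mean() == pytest.approx(
        ref.loc[down, "log2FoldChange"].mean(), abs=0.05
    )


def test_log2fc_invariant_under_sample_scaling(depletion_sim):
    """Scaling one sample's counts is absorbed by its size factor.

    The recomputed factors shift relative to the others by exactly the
    scale (the geometric-mean reference drifts by c**(1/m), which
    cancels in the ratio); with the scaled factor supplied, every
    log2fc is reproduced exactly.
    """
    cm, _ = depletion_sim
    sf = size_factors(cm)
    disp = estimate_dispersion(cm, sf)
    base = nb_wald_test(cm, "control", "knockdown", sf, disp)

    scaled_counts = cm.counts.copy()
    scaled_counts.iloc[:, 0] = scaled_counts.iloc[:, 0] * 2
    cm2 = CountMatrix(scaled_counts, cm.groups, cm.lengths)
    sf2 = size_factors(cm2)
    assert np.isclose(sf2.iloc[0] / sf.iloc[0], 2 * sf2.iloc[1] / sf.iloc[1], rtol=1e-9)

    sf_manual = sf.copy()
    sf_manual.iloc[0] *= 2
    scaled = nb_wald_test(cm2, "control", "knockdown", sf_manual, disp)
    assert np.allclose(base["log2fc"], scaled["log2fc"], atol=1e-6)
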