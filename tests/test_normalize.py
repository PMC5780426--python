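import warnings

import numpy as np
import pandas as pd
import pytest

from exocargo import nanostring as nm
from exocargo.errors import FormatError, ValidationError
from exocargo.nanostring import CountMatrix

from conftest import make_count_matrix, random_count_matrix


# ---------------------------------------------------------------- IO

class TestReadCounts:
    def test_round_trip(self, tmp_path, tiny_cm):
        path = tmp_path / "counts.csv"
        nm.write_counts(tiny_cm, path)
        cm = nm.read_counts(path, replicate_groups=tiny_cm.replicate_groups)
        pd.testing.assert_frame_equal(cm.counts, tiny_cm.counts.astype(float),
                                      check_names=False)
        assert list(cm.probe_class) == list(tiny_cm.probe_class)

    def test_synthetic_output_round_trips_record_by_record(self, tmp_path):
        from exocargo.simulate import SimConfig, simulate_counts
        cm, _ = simulate_counts(SimConfig(seed=3))
        path = tmp_path / "sim.csv"
        nm.write_counts(cm, path)
        back = nm.read_counts(path)
        assert back.counts.shape[0] == 171 + 6 + 6
        np.testing.assert_array_equal(back.counts.to_numpy(), cm.counts.to_numpy())

    def test_duplicate_probe_id_rejected(self, tmp_path):
        path = tmp_path / "dup.csv"
        path.write_text("probe_id,probe_class,expected_conc,s1\n"
                        "mir-a,endogenous,,5\nmir-a,endogenous,,6\n"
                        "POS_A,positive,32,100\nNEG_1,negative,,2\n")
        with pytest.raises(ValidationError, match="duplicate"):
            nm.read_counts(path)

    def test_missing_class_column_is_format_error(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("probe_id,expected_conc,s1\nmir-a,,5\n")
        with pytest.raises(FormatError, match="probe_class"):
            nm.read_counts(path)

    def test_unknown_class_and_negative_count_rejected(self, tmp_path):
        bad_class = tmp_path / "cls.csv"
        bad_class.write_text("probe_id,probe_class,expected_conc,s1\n"
                             "mir-a,mystery,,5\nPOS_A,positive,32,100\n"
                             "NEG_1,negative,,2\n")
        with pytest.raises(ValidationError, match="unknown probe class"):
            nm.read_counts(bad_class)
        neg = tmp_path / "neg.csv"
        neg.write_text("probe_id,probe_class,expected_conc,s1\n"
                       "mir-a,endogenous,,-5\nPOS_A,positive,32,100\n"
                       "NEG_1,negative,,2\n")
        with pytest.raises(ValidationError, match="negative"):
            nm.read_counts(neg)


# ------------------------------------------------------ geometric mean

@pytest.mark.parametrize("values, expected", [
    ((7.0, 7.0, 7.0), 7.0),
    ((2.0, 8.0), 4.0),
    ((1.0, 2.0, 4.0, 8.0), 2.8284271247461903),
])
def test_geometric_mean(values, expected):
    assert nm.geometric_mean(values) == pytest.approx(expected, rel=1e-12)


def test_geometric_mean_rejects_empty_and_nonpositive():
    with pytest.raises(ValidationError):
        nm.geometric_mean([])
    with pytest.raises(ValidationError):
        nm.geometric_mean([1.0, 0.0])


# ----------------------------------------------- positive-control step

class TestPositiveControlNormalize:
    def test_single_sample_factor_is_one(self):
        cm = make_count_matrix(endo={"mir-a": [5]}, pos={"POS_A": [40]},
                               neg={"NEG_1": [1]})
        factors, scaled = nm.positive_control_normalize(cm)
        assert factors["s1"] == pytest.approx(1.0)
        np.testing.assert_allclose(scaled.to_numpy(), cm.counts.to_numpy())

    def test_geomeans_10_and_20_give_factors(self):
        # geomean(s1 controls)=10, geomean(s2)=20 -> mean 15 -> 1.5, 0.75
        cm = make_count_matrix(endo={"mir-a": [5, 5]},
                               pos={"POS_A": [5, 10], "POS_B": [20, 40]},
                               neg={"NEG_1": [1, 1]})
        factors, _ = nm.positive_control_normalize(cm)
        assert factors["s1"] == pytest.approx(1.5)
        assert factors["s2"] == pytest.approx(0.75)

    def test_doubling_a_sample_halves_its_factor_up_to_recentering(self):
        base = make_count_matrix(endo={"mir-a": [8, 8], "mir-b": [2, 2]},
                                 pos={"POS_A": [50, 50]}, neg={"NEG_1": [1, 1]})
        doubled = make_count_matrix(endo={"mir-a": [8, 16], "mir-b": [2, 4]},
                                    pos={"POS_A": [50, 100]}, neg={"NEG_1": [1, 2]})
        fb, sb = nm.positive_control_normalize(base)
        fd, sd = nm.positive_control_normalize(doubled)
        # normalized tables differ only by one global recentering constant
        ratio = (sd / sb).to_numpy()
        np.testing.assert_allclose(ratio, ratio.flat[0])
        # within that recentering, the doubled sample's factor is halved
        c = ratio.flat[0]
        assert fd["s2"] == pytest.approx(c * fb["s2"] / 2)

    def test_all_zero_positive_controls_error_names_sample(self):
        cm = make_count_matrix(endo={"mir-a": [5, 5]}, pos={"POS_A": [100, 0]},
                               neg={"NEG_1": [1, 1]})
        with pytest.raises(ValidationError, match="s2"):
            nm.positive_control_normalize(cm)


# --------------------------------------------------------- background

class TestBackgroundThreshold:
    def test_sample_sd_formula(self):
        # negatives (2, 4, 6): mean 4, sample sd 2 -> threshold 8 at k=2
        cm = make_count_matrix(endo={"mir-a": [9], "mir-b": [8], "mir-c": [7]},
                               pos={"POS_A": [100]},
                               neg={"NEG_1": [2], "NEG_2": [4], "NEG_3": [6]})
        thr, out = nm.background_threshold(cm.counts, cm, k_sd=2.0)
        assert thr["s1"] == pytest.approx(8.0)
        assert out.loc["mir-a", "s1"] == 9            # above threshold
        assert out.loc["mir-b", "s1"] == 0            # boundary is inclusive
        assert out.loc["mir-c", "s1"] == 0

    def test_all_zero_negatives_leave_counts_unchanged(self, tiny_cm):
        thr, out = nm.background_threshold(tiny_cm.counts, tiny_cm)
        assert (thr == 0).all()
        np.testing.assert_array_equal(out.to_numpy(), tiny_cm.counts.to_numpy())

    def test_subtract_mode_clamps_at_zero(self):
        cm = make_count_matrix(endo={"mir-a": [10], "mir-b": [3]},
                               pos={"POS_A": [100]}, neg={"NEG_1": [4]})
        thr, out = nm.background_threshold(cm.counts, cm, k_sd=0.0, mode="subtract")
        assert out.loc["mir-a", "s1"] == pytest.approx(6.0)
        assert out.loc["mir-b", "s1"] == 0.0

    def test_negative_k_sd_rejected(self, tiny_cm):
        with pytest.raises(ValidationError):
            nm.background_threshold(tiny_cm.counts, tiny_cm, k_sd=-1)


# ------------------------------------------------------- content step

class TestContentNormalize:
    def test_identical_samples_all_factors_one(self):
        cm = make_count_matrix(endo={"mir-a": [40, 40], "mir-b": [10, 10]},
                               neg={"NEG_1": [0, 0]})
        factors, out, _ = nm.content_normalize(cm.counts, cm, top_n=2)
        np.testing.assert_allclose(factors.to_numpy(), [1.0, 1.0])

    def test_uniform_scale_invariance(self):
        cm = make_count_matrix(endo={"mir-a": [40, 120], "mir-b": [10, 30]},
                               neg={"NEG_1": [0, 0]})
        _, out, _ = nm.content_normalize(cm.counts, cm, top_n=2)
        endo = ["mir-a", "mir-b"]
        np.testing.assert_allclose(out.loc[endo, "s1"], out.loc[endo, "s2"])

    def test_top_set_chosen_by_cross_sample_mean(self):
        # probes a, b dominate the mean; factors depend on a, b only
        endo = {"mir-a": [80, 160], "mir-b": [20, 40],
                "mir-c": [1, 500], "mir-d": [2, 2], "mir-e": [3, 3]}
        cm = make_count_matrix(endo=endo, neg={"NEG_1": [0, 0]})
        means = {p: np.mean(v) for p, v in endo.items()}
        top2 = sorted(means, key=lambda p: (-means[p], p))[:2]
        factors, _, chosen = nm.content_normalize(cm.counts, cm, top_n=2)
        assert chosen == top2
        t = pd.Series({
            s: nm.geometric_mean([endo[p][i] for p in top2])
            for i, s in enumerate(["s1", "s2"])})
        expected = t.mean() / t
        np.testing.assert_allclose(factors.to_numpy(), expected.to_numpy())

    def test_fewer_probes_than_top_n_warns_and_uses_all(self, tiny_cm):
        with pytest.warns(UserWarning, match="top_n"):
            factors, _, chosen = nm.content_normalize(tiny_cm.counts, tiny_cm, top_n=50)
        assert len(chosen) == 2

    def test_all_zero_sample_is_error(self):
        cm = make_count_matrix(endo={"mir-a": [5, 0], "mir-b": [3, 0]},
                               neg={"NEG_1": [0, 0]})
        with pytest.raises(ValidationError, match="s2"):
            nm.content_normalize(cm.counts, cm, top_n=2)


# ----------------------------------------------------------------- QC

class TestReplicateQC:
    def test_duplicate_sample_r_is_one(self):
        cm = make_count_matrix(endo={"mir-a": [5, 5], "mir-b": [9, 9], "mir-c": [1, 1]},
                               groups={"s1": "g", "s2": "g"})
        qc = nm.replicate_qc(cm.counts, cm)
        assert qc["pearson_r"].iloc[0] == pytest.approx(1.0)

    def test_anti_correlated_pair(self):
        cm = make_count_matrix(endo={"mir-a": [1, 9], "mir-b": [5, 5], "mir-c": [9, 1]},
                               groups={"s1": "g", "s2": "g"})
        qc = nm.replicate_qc(cm.counts, cm)
        assert qc["pearson_r"].iloc[0] == pytest.approx(-1.0)

    def test_zero_variance_sample_reported_missing(self):
        cm = make_count_matrix(endo={"mir-a": [5, 1], "mir-b": [5, 9]},
                               groups={"s1": "g", "s2": "g"})
        with pytest.warns(UserWarning, match="zero-variance"):
            qc = nm.replicate_qc(cm.counts, cm)
        assert np.isnan(qc["pearson_r"].iloc[0])

    def test_synthetic_replicates_exceed_analytic_band(self):
        from exocargo.simulate import SimConfig, simulate_counts
        for seed in range(5):
            cm, _ = simulate_counts(SimConfig(seed=seed))
            prof = nm.normalize(cm)
            assert prof.qc["pearson_r"].iloc[0] > 0.8


def test_merge_replicates_averages_per_probe():
    cm = make_count_matrix(endo={"mir-a": [2, 4], "mir-b": [6, 6]},
                           groups={"s1": "g", "s2": "g"})
    merged = nm.merge_replicates(cm.counts, cm)
    assert merged.loc["mir-a", "g"] == pytest.approx(3.0)
    assert merged.loc["mir-b", "g"] == pytest.approx(6.0)


# -------------------------------------------------- pipeline invariants

@pytest.mark.parametrize("seed", range(5))
def test_normalization_invariants(seed):
    """Uniform per-sample rescale invariance, unit share sums, rank
    preservation and determinism of the full normalization."""
    rng = np.random.default_rng(seed)
    cm = random_count_matrix(rng)
    prof = nm.normalize(cm)

    sums = prof.shares.sum(axis=0)
    np.testing.assert_allclose(sums.to_numpy(), 1.0, atol=1e-9)

    # rescale one sample's raw counts (controls included) by 3
    counts2 = cm.counts.copy()
    counts2["s1"] = counts2["s1"] * 3
    cm2 = CountMatrix(counts=counts2, probe_class=cm.probe_class,
                      expected_conc=cm.expected_conc,
                      replicate_groups=cm.replicate_groups)
    prof2 = nm.normalize(cm2)
    np.testing.assert_allclose(prof2.shares.to_numpy(), prof.shares.to_numpy(),
                               atol=1e-9)

    # rank order within each sample is preserved (non-strictly: floored
    # probes collapse to 0, which only ever happens at the bottom)
    endo = cm.probes_of_class("endogenous")
    for s in cm.samples:
        raw = cm.counts.loc[endo, s].to_numpy()
        out = prof.values.loc[endo, s].to_numpy()
        order = np.argsort(-raw, kind="stable")
        assert (np.diff(out[order]) <= 1e-9).all()

    # determinism
    prof3 = nm.normalize(cm)
    pd.testing.assert_frame_equal(prof.values, prof3.values)
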