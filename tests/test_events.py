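import numpy as np
import pandas as pd
import pytest

from haplocn import (
    call_dosage,
    call_loh,
    classify_clonality,
    compute_thresholds,
    detect_msai,
    genome_fractions,
    subgroup_summary,
    summarize_patient,
)


def test_thresholds_pure_diploid():
    thr = compute_thresholds(1.0, 2.0)
    assert thr.gain_logr == pytest.approx(np.log2(1.25))
    assert thr.loss_logr == pytest.approx(np.log2(0.75))
    assert thr.amp_logr == pytest.approx(1.0)


def test_thresholds_ploidy_cancels_at_full_purity():
    for psi in (1.5, 2.0, 3.7, 6.0):
        thr = compute_thresholds(1.0, psi)
        assert thr.gain_logr == pytest.approx(np.log2(1.25))


def test_thresholds_mixed_sample():
    thr = compute_thresholds(0.5, 4.0)
    assert thr.gain_logr == pytest.approx(np.log2(3.5 / 3), abs=1e-6)
    assert thr.loss_logr == pytest.approx(np.log2(2.5 / 3), abs=1e-6)
    assert thr.amp_logr == pytest.approx(np.log2(5 / 3), abs=1e-6)


def test_threshold_ordering_over_grid():
    for rho in np.linspace(0.05, 1.0, 20):
        for psi in np.linspace(1.0, 8.0, 15):
            thr = compute_thresholds(rho, psi)
            assert thr.loss_logr < thr.gain_logr < thr.amp_logr


@pytest.mark.parametrize(
    "mean_logr, expected",
    [(0.5, "gain"), (0.0, "neutral"), (1.1, "amplification"), (-0.6, "loss")],
)
def test_dosage_mean_mode(mean_logr, expected):
    thr = compute_thresholds(1.0, 2.0)
    assert call_dosage([mean_logr], thr) == expected


def test_dosage_ttest_mode():
    thr = compute_thresholds(1.0, 2.0)
    rng = np.random.default_rng(0)
    gained = rng.normal(0.58, 0.1, 60)
    assert call_dosage(gained, thr, mode="ttest") == "gain"
    neutral = rng.normal(0.0, 0.1, 60)
    assert call_dosage(neutral, thr, mode="ttest") == "neutral"


def test_dosage_empty_bin_rejected():
    with pytest.raises(ValueError):
        call_dosage([], compute_thresholds(1.0, 2.0))


@pytest.mark.parametrize(
    "n_a, n_b, psi, expected",
    [
        (2, 0, 2.0, "cnloh"),
        (1, 1, 2.0, "none"),
        (4, 0, 3.8, "cnloh"),  # round(3.8) = 4
        (0, 0, 2.0, "homdel"),
        (3, 0, 2.0, "loh"),
        (0, 1, 2.0, "loh"),
    ],
)
def test_call_loh(n_a, n_b, psi, expected):
    assert call_loh(n_a, n_b, psi) == expected


@pytest.mark.parametrize(
    "states, expected",
    [
        ([(2, 1), (2, 1), (1, 2)], True),
        ([(2, 1), (2, 1), (2, 1)], False),
        ([(1, 1), (2, 2)], False),
    ],
)
def test_detect_msai(states, expected):
    assert detect_msai(states) is expected


def test_clonality_mirrored_gain_is_subclonal_parallel():
    """Present in every sample, but mirrored 4|2 / 4|2 / 2|3."""
    present = [True, True, True]
    states = [(4, 2), (4, 2), (2, 3)]
    assert classify_clonality(present, states) == ("subclonal", True)


def test_clonality_same_haplotype_is_clonal():
    present = [True, True, True]
    states = [(2, 1), (3, 1), (2, 1)]
    assert classify_clonality(present, states) == ("clonal", False)


def test_parallel_among_harbouring_samples_only():
    """Mirroring between the two gained samples decides, regardless of S3."""
    present = [True, True, False]
    states = [(2, 1), (1, 2), (1, 1)]
    assert classify_clonality(present, states) == ("subclonal", True)
    # same major haplotype in the harbouring pair: subclonal, not parallel
    states = [(2, 1), (2, 1), (1, 1)]
    assert classify_clonality(present, states) == ("subclonal", False)


def test_clonality_absent():
    assert classify_clonality([False, False], [(1, 1), (1, 1)]) == ("absent", False)


def _calls(rows):
    return pd.DataFrame(
        rows, columns=["bin_id", "sample_id", "n_a", "n_b", "dosage", "loh",
                       "imbalanced"]
    )


def _bins(widths):
    return pd.DataFrame(
        {
            "bin_id": range(len(widths)),
            "chrom": "chr1",
            "start": 1,
            "end": widths,
            "width": widths,
        }
    )


def test_genome_fractions_all_clonal_gain():
    calls = _calls(
        [(0, s, 2, 1, "gain", "none", True) for s in ("S1", "S2")]
    )
    summary = summarize_patient(calls, _bins([100]), ["S1", "S2"])
    f = genome_fractions(summary).set_index("metric")["fraction"]
    assert f["clonal_gain"] == pytest.approx(1.0)
    assert f["subclonal_gain"] == 0.0


def test_genome_fractions_msai_weighting():
    calls = _calls(
        [(0, "S1", 2, 1, "gain", "none", True), (0, "S2", 1, 2, "gain", "none", True),
         (1, "S1", 1, 1, "neutral", "none", False), (1, "S2", 1, 1, "neutral", "none", False)]
    )
    summary = summarize_patient(calls, _bins([30, 70]), ["S1", "S2"])
    f = genome_fractions(summary).set_index("metric")["fraction"]
    assert f["msai"] == pytest.approx(0.3)
    assert f["parallel_gain"] == pytest.approx(0.3)
    assert f["clonal_gain"] == 0.0


def test_genome_fractions_invariant_under_bin_split():
    whole = _calls([(0, "S1", 2, 1, "gain", "none", True),
                    (0, "S2", 2, 1, "gain", "none", True)])
    split = _calls([(0, "S1", 2, 1, "gain", "none", True),
                    (0, "S2", 2, 1, "gain", "none", True),
                    (1, "S1", 2, 1, "gain", "none", True),
                    (1, "S2", 2, 1, "gain", "none", True)])
    f1 = genome_fractions(
        summarize_patient(whole, _bins([100]), ["S1", "S2"])
    ).set_index("metric")["fraction"]
    f2 = genome_fractions(
        summarize_patient(split, _bins([50, 50]), ["S1", "S2"])
    ).set_index("metric")["fraction"]
    pd.testing.assert_series_equal(f1, f2)


def test_subgroup_clonal_within_group_subclonal_overall():
    """A gain mirrored between groups: group-clonal, patient-subclonal."""
    calls = _calls(
        [(0, "P1", 2, 1, "gain", "none", True), (0, "P2", 2, 1, "gain", "none", True),
         (0, "M1", 1, 2, "gain", "none", True)]
    )
    bins = _bins([100])
    patient_summary = summarize_patient(calls, bins, ["P1", "P2", "M1"])
    assert patient_summary.loc[0, "gain_clonality"] == "subclonal"
    assert patient_summary.loc[0, "gain_parallel"]
    groups = subgroup_summary(calls, bins, {"primary": ["P1", "P2"], "met": ["M1"]})
    assert groups["primary"]["summary"].loc[0, "gain_clonality"] == "clonal"
    assert groups["met"]["summary"].loc[0, "gain_clonality"] == "clonal"


def test_subgroup_unknown_sample_rejected():
    calls = _calls([(0, "S1", 1, 1, "neutral", "none", False),
                    (0, "S2", 1, 1, "neutral", "none", False)])
    with pytest.raises(ValueError, match="unknown samples"):
        subgroup_summary(calls, _bins([10]), {"g": ["S1", "SX"]})


def test_subgroup_overlapping_groups_rejected():
    calls = _calls([(0, "S1", 1, 1, "neutral", "none", False),
                    (0, "S2", 1, 1, "neutral", "none", False)])
    with pytest.raises(ValueError, match="more than one group"):
        subgroup_summary(calls, _bins([10]), {"a": ["S1"], "b": ["S1", "S2"]})
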