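import numpy as np
import pandas as pd
import pytest

from haplocn import (
    EventSpec,
    PatientData,
    SimulationParams,
    detection_limit,
    expected_baf,
    expected_logr,
    make_artificial_normal,
    msai_null,
    run_pipeline,
    score_recovery,
    simulate_cnloh_sweep,
    simulate_patient,
)
from haplocn.simulate import msai_fraction, randomize_events, replay_events


@pytest.mark.parametrize(
    "n_a, n_b, rho, expected",
    [
        (2, 1, 0.5, 0.4),
        (3, 2, 0.0, 0.5),  # pure normal
        (2, 0, 0.04, 0.48),  # low-CCF copy-neutral LOH
    ],
)
def test_expected_baf(n_a, n_b, rho, expected):
    assert expected_baf(n_a, n_b, rho) == pytest.approx(expected, abs=1e-9)


def test_expected_baf_haplotype_mirroring():
    assert expected_baf(2, 1, 0.5, b_on_hap_b=False) == pytest.approx(0.6)


@pytest.mark.parametrize(
    "n_total, rho, psi, expected",
    [
        (2, 0.7, 2.0, 0.0),  # at ploidy
        (3, 0.5, 2.0, np.log2(1.25)),
        (5, 0.0, 2.0, 0.0),  # pure normal
    ],
)
def test_expected_logr(n_total, rho, psi, expected):
    assert expected_logr(n_total, rho, psi) == pytest.approx(expected, abs=1e-9)


def test_simulation_is_deterministic():
    t1, p1 = simulate_patient(3, seed=42)
    t2, p2 = simulate_patient(3, seed=42)
    for a, b in zip(p1.samples, p2.samples):
        pd.testing.assert_frame_equal(a.snps, b.snps)
        pd.testing.assert_frame_equal(a.segments, b.segments)
    assert t1.purities == t2.purities


def test_noiseless_limit_recovers_truth_exactly():
    params = SimulationParams(coverage=None, logr_sd=0.0)
    truth, patient = simulate_patient(3, seed=7, params=params)
    result = run_pipeline(patient)
    score = score_recovery(truth, result)
    assert score["fraction_correct"] == 1.0
    # recomputed ploidy equals the generating ploidy exactly
    for _, row in result.ploidies.iterrows():
        assert row["psi_t"] == pytest.approx(truth.ploidies[row["sample_id"]], abs=1e-9)


def test_planted_msai_recovered():
    truth, patient = simulate_patient(3, seed=13)
    result = run_pipeline(patient)
    score = score_recovery(truth, result)
    assert set(truth.msai_chromosomes) <= score["msai_called_chromosomes"]
    spurious = score["msai_called_chromosomes"] - score["msai_true_chromosomes"]
    assert not (spurious & set(truth.balanced_chromosomes))


def test_cnloh_sweep_shape_and_extremes():
    sweep = simulate_cnloh_sweep(
        n_events=8, ccf_grid=[1, 15, 30], coverage=200, seed=0, baseline=False
    )
    assert list(sweep["ccf_percent"]) == [1, 15, 30]
    assert sweep["detected_phased"].iloc[0] <= 0.25  # near-null CCF
    assert sweep["detected_phased"].iloc[-1] == 1.0  # large-effect regime
    assert detection_limit(sweep) in (15.0, 30.0)


def test_cnloh_detection_monotone_in_ccf():
    sweep = simulate_cnloh_sweep(
        n_events=15, ccf_grid=[2, 5, 10, 20], seed=3, baseline=False
    )
    d = sweep["detected_phased"].to_numpy()
    assert np.all(np.diff(d) >= -0.15)  # non-decreasing within MC tolerance


def test_msai_null_zero_events():
    tree = {"S1": ("a",), "S2": ("b",)}
    lengths = {"chr1": 1000}
    res = msai_null([], tree, lengths, n_sims=20, seed=0)
    assert res.observed_fraction == 0.0
    assert res.p_value == 1.0
    assert res.null_fractions.max() == 0.0


def test_msai_null_p_value_formula():
    tree = {"S1": ("a",), "S2": ("b",)}
    lengths = {"chr1": 10_000_000, "chr2": 10_000_000}
    events = [
        EventSpec("a", "segmental_gain", "chr1", 1, 8_000_000, 0),
        EventSpec("b", "segmental_gain", "chr1", 1, 8_000_000, 1),
    ]
    res = msai_null(events, tree, lengths, n_sims=99, seed=5)
    expect = (1 + int(np.sum(res.null_fractions >= res.observed_fraction))) / 100
    assert res.p_value == pytest.approx(expect)
    assert res.p_value >= 1 / 100


def test_replay_wgd_and_events():
    tree = {"S1": ("root", "tip")}
    lengths = {"chr1": 100}
    events = [
        EventSpec("root", "wgd"),
        EventSpec("root", "chromosomal_gain", "chr1", haplotype=0),
        EventSpec("tip", "segmental_loss", "chr1", start=41, length=20, haplotype=1),
    ]
    k = replay_events(events, tree, lengths)
    segs = {(s, e): (na, nb) for s, e, na, nb in k["S1"]["chr1"]}
    assert segs[(1, 40)] == (3, 2)  # WGD then +1 on haplotype A
    assert segs[(41, 60)] == (3, 1)
    assert segs[(61, 100)] == (3, 2)


def test_randomize_preserves_event_lengths():
    rng = np.random.default_rng(0)
    lengths = {"chr1": 100, "chr2": 200}
    events = [EventSpec("a", "segmental_gain", "chr1", 10, 50, 0)]
    for _ in range(20):
        (new,) = randomize_events(events, lengths, rng)
        assert new.length == 50
        assert 1 <= new.start <= lengths[new.chrom] - 49


def test_msai_fraction_fully_mirrored():
    tree = {"S1": ("a",), "S2": ("b",)}
    lengths = {"chr1": 500}
    events = [
        EventSpec("a", "chromosomal_gain", "chr1", haplotype=0),
        EventSpec("b", "chromosomal_gain", "chr1", haplotype=1),
    ]
    k = replay_events(events, tree, lengths)
    assert msai_fraction(k, lengths) == 1.0


def test_artificial_normal_is_balanced(sim_patient):
    _, patient = sim_patient
    normal = make_artificial_normal(patient, seed=0, coverage=None, logr_sd=0.0)
    het = normal.snps["is_het"]
    assert (normal.snps.loc[het, "baf"] == 0.5).all()
    assert (normal.snps["logr"] == 0.0).all()
    assert (normal.segments[["cn_major", "cn_minor"]] == 1).all().all()


def test_noiseless_artificial_normal_never_imbalanced(sim_patient):
    _, patient = sim_patient
    normal = make_artificial_normal(patient, seed=1, coverage=None, logr_sd=0.0)
    augmented = PatientData(
        patient_id=patient.patient_id,
        samples=patient.samples + [normal],
        normal_baf=patient.normal_baf,
    )
    result = run_pipeline(augmented)
    flags = result.imbalance
    mine = flags[flags["sample_id"] == normal.sample_id]
    assert not mine["imbalanced"].any()
    # a balanced sample can never participate in mirroring
    cn = result.calls[result.calls["sample_id"] == normal.sample_id]
    assert (cn["n_a"] == cn["n_b"]).all()
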