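import numpy as np
import pytest

from haplocn import (
    estimate_nonparametric,
    estimate_parametric,
    recompute_ploidy,
    reestimate_bin,
    phased_haplotype_baf,
)
from haplocn.copynumber import round_half_up
from haplocn.simulate import expected_baf, expected_logr


@pytest.mark.parametrize(
    "b, logr, rho, psi, expected",
    [
        (0.5, 0.0, 1.0, 2.0, (1.0, 1.0)),  # diploid identity
        (0.4, np.log2(1.25), 0.5, 2.0, (2.0, 1.0)),  # forward-model inversion
        (0.0, 0.0, 1.0, 2.0, (2.0, 0.0)),  # copy-neutral LOH 2|0
    ],
)
def test_parametric_examples(b, logr, rho, psi, expected):
    n_a, n_b = estimate_parametric(b, logr, rho, psi)
    assert n_a == pytest.approx(expected[0], abs=1e-9)
    assert n_b == pytest.approx(expected[1], abs=1e-9)


def test_parametric_rejects_zero_purity():
    with pytest.raises(ValueError):
        estimate_parametric(0.5, 0.0, 0.0, 2.0)


def test_exact_inversion_small_grid():
    """Noiseless forward model round-trips through the estimator."""
    for n_a in range(5):
        for n_b in range(n_a + 1):
            for rho in (0.2, 0.5, 1.0):
                psi = 2.0
                b = expected_baf(n_a, n_b, rho)
                L = expected_logr(n_a + n_b, rho, psi)
                got = estimate_parametric(b, L, rho, psi)
                assert got[0] == pytest.approx(n_a, abs=1e-9)
                assert got[1] == pytest.approx(n_b, abs=1e-9)


def test_monotonicity_in_b():
    bs = np.linspace(0.05, 0.95, 10)
    out = [estimate_parametric(b, 0.1, 0.6, 2.0) for b in bs]
    n_a = [o[0] for o in out]
    n_b = [o[1] for o in out]
    assert all(np.diff(n_b) > 0)
    assert all(np.diff(n_a) < 0)


def test_round_half_up():
    assert list(round_half_up([-0.4, 0.5, 1.49, 1.5, 2.51])) == [0, 1, 1, 2, 3]


def test_phased_haplotype_baf_pools_mirrored():
    bafs = [0.7, 0.25, 0.72]
    is_b = [True, False, True]
    # A-haplotype SNP contributes 1 - 0.25 = 0.75
    assert phased_haplotype_baf(bafs, is_b) == pytest.approx((0.7 + 0.75 + 0.72) / 3)


def test_nonparametric_nearest_class():
    X = [[0.66, 0.32], [0.5, 0.0], [0.34, 0.32]]
    y = [(2, 1), (1, 1), (1, 2)]
    assert estimate_nonparametric([0.655, 0.33], X, y) == (2, 1)


def test_nonparametric_single_class_rejected():
    with pytest.raises(ValueError):
        estimate_nonparametric([0.5, 0.0], [[0.5, 0.0], [0.51, 0.01]], [(1, 1), (1, 1)])


def test_nonparametric_matches_parametric_on_recurring_states():
    """With every state recurring elsewhere in the training set (as in a
    multi-sample patient), both models agree on the integer states."""
    rng = np.random.default_rng(0)
    rho, psi = 0.7, 2.0
    base_states = [(1, 1), (2, 1), (2, 0), (3, 1), (1, 0), (2, 2)]
    states = base_states * 3  # same bin seen in other samples / other bins
    feats = [
        [
            expected_baf(a, b, rho) + rng.normal(0, 0.005),
            expected_logr(a + b, rho, psi) + rng.normal(0, 0.02),
        ]
        for a, b in states
    ]
    agree = 0
    for i, (a, b) in enumerate(states):
        X = feats[:i] + feats[i + 1 :]
        y = states[:i] + states[i + 1 :]
        got = estimate_nonparametric(feats[i], X, y)
        par = round_half_up(estimate_parametric(feats[i][0], feats[i][1], rho, psi))
        agree += got == tuple(par)
    assert agree >= 0.95 * len(states)


@pytest.mark.parametrize(
    "policy, imbalanced, expected_method",
    [
        ("on_new_imbalance", True, "parametric"),
        ("never", True, "input"),
        ("on_new_imbalance", False, "input"),
    ],
)
def test_reestimation_trigger(policy, imbalanced, expected_method):
    # input-balanced bin with newly detected imbalance
    res = reestimate_bin(
        0, "S1", b_hap=expected_baf(2, 1, 1.0), mean_logr=expected_logr(3, 1.0, 2.0),
        rho=1.0, psi=2.0, input_major=1, input_minor=1,
        imbalanced=imbalanced, policy=policy,
    )
    assert res.method == expected_method
    if expected_method == "parametric":
        assert (res.n_a, res.n_b) in {(2, 1), (1, 2)}


def test_carried_input_oriented_by_haplotype_baf():
    res = reestimate_bin(
        0, "S1", b_hap=0.65, mean_logr=0.3, rho=1.0, psi=2.0,
        input_major=2, input_minor=1, imbalanced=True, policy="on_new_imbalance",
    )
    # input already imbalanced: carried forward, major on haplotype B
    assert res.method == "input"
    assert (res.n_a, res.n_b) == (1, 2)


@pytest.mark.parametrize(
    "totals, widths, expected",
    [
        ([2, 4], [1, 1], 3.0),
        ([2, 4], [3, 1], 2.5),
        ([2], [10], 2.0),
    ],
)
def test_recompute_ploidy(totals, widths, expected):
    assert recompute_ploidy(totals, widths).psi_t == pytest.approx(expected)


def test_recompute_ploidy_empty_rejected():
    with pytest.raises(ValueError):
        recompute_ploidy([], [])
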