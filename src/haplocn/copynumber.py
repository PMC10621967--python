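"""Haplotype-specific copy-number re-estimation and ploidy recomputation.

The parametric model inverts the standard ASCAT-style forward model of
BAF and LogR for a tumour/normal mixture of purity rho and tumour
ploidy psi_t: for a bin with consolidated haplotype-B BAF b and mean
LogR L,

    n_A = (rho - 1 + (1 - b) * 2**L * (2(1 - rho) + rho*psi_t)) / rho
    n_B = (rho - 1 +      b  * 2**L * (2(1 - rho) + rho*psi_t)) / rho

Fractional values may be negative and are clamped only at
integerisation (round half up). A nonparametric alternative classifies
a bin into an integer state with a Gaussian naive-Bayes model trained
on the (haplotype BAF, LogR) features of other bins. After all bins are
re-estimated, sample ploidy is recomputed once as the width-weighted
mean total copy number.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.naive_bayes import GaussianNB

REESTIMATION_POLICIES = ("on_new_imbalance", "always", "never")


@dataclass
class HaplotypeCN:
    bin_id: int
    sample_id: str
    n_a_frac: float
    n_b_frac: float
    n_a: int
    n_b: int
    method: str  # "parametric" | "nonparametric" | "input"


@dataclass
class PloidyEstimate:
    sample_id: str
    psi_t: float


def round_half_up(x) -> np.ndarray:
    """Integerise copy numbers: clamp negatives to 0, then round half up."""
    return np.floor(np.maximum(np.asarray(x, float), 0.0) + 0.5).astype(int)


def estimate_parametric(b: float, logr: float, rho: float, psi: float):
    """Fractional haplotype copy numbers (n_a_frac, n_b_frac) from (b, L)."""
    if not 0 < rho <= 1:
        raise ValueError(f"purity must be in (0, 1], got {rho}")
    if psi <= 0:
        raise ValueError(f"ploidy must be positive, got {psi}")
    scale = 2.0**logr * (2 * (1 - rho) + rho * psi)
    n_a = (rho - 1 + (1 - b) * scale) / rho
    n_b = (rho - 1 + b * scale) / rho
    return float(n_a), float(n_b)


def estimate_nonparametric(
    query_features,
    training_features,
    training_labels,
) -> tuple[int, int]:
    """Maximum-posterior integer state from a Gaussian naive-Bayes model.

    Features are (mean haplotype-B BAF, mean LogR); training rows are
    the other bins of the same sample plus the same bin in the other
    samples, labelled with their integer (n_a, n_b) states. Raises
    ValueError with fewer than two distinct training classes (callers
    fall back to the parametric model).
    """
    X = np.asarray(training_features, float)
    labels = [tuple(map(int, lab)) for lab in training_labels]
    classes = sorted(set(labels))
    if len(classes) < 2:
        raise ValueError("need at least two distinct training classes")
    y = np.array([classes.index(lab) for lab in labels])
    # generous variance floor: class variances are estimated from very few
    # bins and would otherwise collapse, making queries outliers of their
    # own class
    clf = GaussianNB(var_smoothing=1e-2)
    clf.fit(X, y)
    pred = clf.predict(np.asarray(query_features, float).reshape(1, -1))[0]
    return classes[int(pred)]


def phased_haplotype_baf(bafs, is_hap_b) -> float:
    """Consolidated haplotype-B BAF for a bin.

    Pools the BAF of haplotype-B SNPs with the mirrored BAF (1 - b) of
    haplotype-A SNPs into a single segment-level value.
    """
    bafs = np.asarray(bafs, float)
    is_hap_b = np.asarray(is_hap_b, bool)
    vals = np.where(is_hap_b, bafs, 1.0 - bafs)
    vals = vals[~np.isnan(vals)]
    if vals.size == 0:
        raise ValueError("no BAF values to consolidate")
    return float(np.mean(vals))


def reestimate_bin(
    bin_id: int,
    sample_id: str,
    b_hap: float | None,
    mean_logr: float,
    rho: float,
    psi: float,
    input_major: int,
    input_minor: int,
    imbalanced: bool,
    policy: str = "on_new_imbalance",
) -> HaplotypeCN:
    """Re-estimate or carry forward one bin's phased copy numbers.

    Re-estimation (parametric) is triggered when ``policy`` is "always",
    or when it is "on_new_imbalance" and imbalance was detected in a bin
    whose input state was balanced. Otherwise the input major/minor
    values are carried forward, orienting the major copy number onto the
    haplotype with the higher consolidated BAF. Unphased bins
    (``b_hap`` is None) always carry the input state in A-major
    orientation.
    """
    if policy not in REESTIMATION_POLICIES:
        raise ValueError(f"unknown policy {policy!r}")
    if b_hap is None:
        n_a_frac, n_b_frac = float(input_major), float(input_minor)
        method = "input"
    else:
        new_imbalance = imbalanced and input_major == input_minor
        trigger = policy == "always" or (
            policy == "on_new_imbalance" and new_imbalance
        )
        if trigger:
            n_a_frac, n_b_frac = estimate_parametric(b_hap, mean_logr, rho, psi)
            method = "parametric"
        else:
            if b_hap > 0.5:  # haplotype B carries the major copy number
                n_a_frac, n_b_frac = float(input_minor), float(input_major)
            else:
                n_a_frac, n_b_frac = float(input_major), float(input_minor)
            method = "input"
    n_a, n_b = round_half_up([n_a_frac, n_b_frac])
    return HaplotypeCN(bin_id, sample_id, n_a_frac, n_b_frac, int(n_a), int(n_b), method)


def recompute_ploidy(totals, widths, sample_id: str = "") -> PloidyEstimate:
    """Width-weighted mean total copy number over the MCS bins."""
    totals = np.asarray(totals, float)
    widths = np.asarray(widths, float)
    if totals.size == 0 or widths.sum() <= 0:
        raise ValueError("ploidy recomputation needs bins with positive total width")
    return PloidyEstimate(sample_id, float(np.sum(totals * widths) / np.sum(widths)))
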