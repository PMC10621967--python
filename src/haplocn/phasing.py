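"""Reference sample selection, SNP phasing and allelic-imbalance testing.

Within each MCS bin, the sample with the strongest allelic imbalance
(highest mirrored mean BAF among samples whose input copy numbers are
imbalanced) serves as the phasing reference: SNPs with BAF above the
reference segment mean are assigned to haplotype B, the rest to
haplotype A, and this assignment is shared by all samples. Every sample
is then tested for allelic imbalance by comparing the BAF values of the
two haplotypes with a Wilcoxon rank-sum test gated on a Cohen's d effect
size.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.mixture import GaussianMixture
from statsmodels.stats.multitest import multipletests

DEFAULT_ALPHA = 0.05
DEFAULT_D_MIN = 1.0
DEFAULT_MIN_SNPS = 3
DEFAULT_MIN_BAF_VAR = 1e-5


@dataclass
class ReferenceChoice:
    bin_id: int
    reference_sample_id: str | None
    mirrored_baf: dict
    method: dict  # sample_id -> "direct" | "mixture"


@dataclass
class ImbalanceTest:
    bin_id: int
    sample_id: str
    p_value: float
    cohens_d: float
    testable: bool
    imbalanced: bool


def mirrored_mean_baf(bafs) -> float:
    """Mean absolute deviation of BAF from 0.5; 0 for balanced segments."""
    bafs = np.asarray(bafs, float)
    if bafs.size == 0:
        raise ValueError("mirrored mean BAF undefined for empty input")
    return float(np.mean(np.abs(bafs - 0.5)))


def mixture_mirrored_baf(bafs, random_state: int = 0) -> float:
    """Mirrored-imbalance estimate from a two-band Gaussian mixture.

    Fits a two-component equal-variance mixture to the BAF values and
    returns half the separation of the component means, an estimate of
    the mirrored mean BAF that is robust to unequal haplotype SNP
    counts. Falls back to the direct mirrored mean (with a warning) if
    EM does not converge.
    """
    bafs = np.asarray(bafs, float)
    if bafs.size < DEFAULT_MIN_SNPS:
        raise ValueError("mixture estimate requires at least 3 BAF values")
    if np.var(bafs) < DEFAULT_MIN_BAF_VAR:
        raise ValueError("BAF variance below threshold; use mirrored_mean_baf")
    gm = GaussianMixture(
        n_components=2,
        covariance_type="tied",
        n_init=10,
        random_state=random_state,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        gm.fit(bafs.reshape(-1, 1))
    if not gm.converged_:
        warnings.warn("mixture did not converge; falling back to direct estimate")
        return mirrored_mean_baf(bafs)
    mu = np.sort(gm.means_.ravel())
    return float((mu[1] - mu[0]) / 2)


def _mirrored_estimate(
    bafs: np.ndarray,
    min_snps: int,
    min_baf_var: float,
    random_state: int,
) -> tuple[float, str]:
    if bafs.size < min_snps or np.var(bafs) < min_baf_var:
        return mirrored_mean_baf(bafs), "direct"
    return mixture_mirrored_baf(bafs, random_state=random_state), "mixture"


def select_reference(
    bin_id: int,
    sample_bafs: dict,
    input_states: dict,
    min_snps: int = DEFAULT_MIN_SNPS,
    min_baf_var: float = DEFAULT_MIN_BAF_VAR,
    random_state: int = 0,
) -> ReferenceChoice:
    """Pick the phasing reference sample for one bin.

    Candidates are samples whose input major copy number differs from
    half the total (i.e. major != minor); among them the sample with the
    highest mirrored BAF wins. Ties go to the sample with more SNPs in
    the bin, then to the lexicographically smallest sample id. Bins with
    no input-imbalanced sample are not phased.

    Parameters
    ----------
    sample_bafs : dict sample_id -> array of het-SNP BAFs in the bin
    input_states : dict sample_id -> (cn_major, cn_minor) input state
    """
    mirrored: dict[str, float] = {}
    method: dict[str, str] = {}
    for sid, (major, minor) in input_states.items():
        if major == minor:
            continue  # input-balanced: not a candidate
        bafs = np.asarray(sample_bafs[sid], float)
        bafs = bafs[~np.isnan(bafs)]
        if bafs.size == 0:
            continue
        mirrored[sid], method[sid] = _mirrored_estimate(
            bafs, min_snps, min_baf_var, random_state
        )
    if not mirrored:
        return ReferenceChoice(bin_id, None, mirrored, method)
    best = min(
        mirrored,
        key=lambda sid: (
            -mirrored[sid],
            -int(np.sum(~np.isnan(np.asarray(sample_bafs[sid], float)))),
            sid,  # lexicographically smallest id wins the final tie
        ),
    )
    return ReferenceChoice(bin_id, best, mirrored, method)


def phase_bin(reference_bafs) -> np.ndarray:
    """Per-SNP haplotype assignment from the reference sample.

    Returns a boolean array: True where the SNP's B allele lies on
    haplotype B, i.e. its BAF strictly exceeds the segment mean BAF in
    the reference sample. The assignment is shared across all samples.
    """
    bafs = np.asarray(reference_bafs, float)
    if bafs.size == 0:
        raise ValueError("cannot phase a bin with no heterozygous SNPs")
    return bafs > np.mean(bafs)


def cohens_d(a, b) -> float:
    """Standardised mean difference (b minus a) with pooled, Bessel-corrected SD."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    n1, n2 = a.size, b.size
    if n1 + n2 < 3 or n1 == 0 or n2 == 0:
        return float("nan")
    var1 = np.var(a, ddof=1) if n1 > 1 else 0.0
    var2 = np.var(b, ddof=1) if n2 > 1 else 0.0
    pooled = np.sqrt(((n1 - 1) * var1 + (n2 - 1) * var2) / (n1 + n2 - 2))
    diff = np.mean(b) - np.mean(a)
    if pooled == 0:
        return 0.0 if diff == 0 else float(np.sign(diff)) * float("inf")
    return float(diff / pooled)


def test_allelic_imbalance(
    hap_a_bafs,
    hap_b_bafs,
    alpha: float = DEFAULT_ALPHA,
    d_min: float = DEFAULT_D_MIN,
    bin_id: int = -1,
    sample_id: str = "",
) -> ImbalanceTest:
    """Wilcoxon rank-sum test between the two haplotypes' BAF values.

    A sample is flagged imbalanced in a bin when the two-sided rank-sum
    p-value is <= alpha and |Cohen's d| >= d_min. Here the raw p is
    used (correct for a single test); in the patient pipeline the same
    raw p-values are Holm-adjusted across all bin x sample tests before
    flags are set. Fewer than two SNPs in total, or an empty haplotype,
    makes the bin untestable.
    """
    a = np.asarray(hap_a_bafs, float)
    b = np.asarray(hap_b_bafs, float)
    a = a[~np.isnan(a)]
    b = b[~np.isnan(b)]
    if a.size == 0 or b.size == 0 or a.size + b.size < 3:
        return ImbalanceTest(bin_id, sample_id, float("nan"), float("nan"), False, False)
    stat, p = stats.ranksums(b, a)
    d = cohens_d(a, b)
    imbalanced = bool(p <= alpha and abs(d) >= d_min)
    return ImbalanceTest(bin_id, sample_id, float(p), d, True, imbalanced)


def holm_adjust(p_values) -> np.ndarray:
    """Holm step-down adjusted p-values (family-wise error control)."""
    p = np.asarray(p_values, float)
    out = np.full(p.shape, np.nan)
    mask = ~np.isnan(p)
    if mask.any():
        out[mask] = multipletests(p[mask], method="holm")[1]
    return out
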