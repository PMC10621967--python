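"""Synthetic multi-sample patients and the built-in simulation experiments.

The forward model mirrors the quantities the estimation side inverts:
for a cell population in which a fraction ``rho`` of cells carry
haplotype copy numbers (n_a, n_b) and the rest are diploid 1|1, a
heterozygous SNP whose B allele lies on haplotype B has expected BAF

    (n_b * rho + (1 - rho)) / ((n_a + n_b) * rho + 2 * (1 - rho))

(1 minus that for a B allele on haplotype A), and the expected LogR of
a region with total copy number n against a sample of ploidy psi is

    log2[(2(1 - rho) + rho * n) / (2(1 - rho) + rho * psi)].

Observed BAFs are binomial draws at the sequencing coverage; LogR gets
additive Gaussian noise. Three experiments are provided: a purity sweep
measuring the detection limit for copy-neutral LOH, a permutation null
for mirrored subclonal allelic imbalance (MSAI) genome fractions, and
artificial balanced "normal" samples for specificity runs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from sklearn.mixture import GaussianMixture
from statsmodels.stats.multitest import multipletests

from .model import PatientData, SampleData
from .io import identify_heterozygous
from .phasing import (
    DEFAULT_ALPHA,
    DEFAULT_D_MIN,
    phase_bin,
    test_allelic_imbalance,
)

# ---------------------------------------------------------------------------
# forward model


def expected_baf(n_a: int, n_b: int, rho: float, b_on_hap_b: bool = True) -> float:
    """Expected BAF at a het SNP in a (n_a, n_b) region of purity rho."""
    if not 0 <= rho <= 1:
        raise ValueError(f"purity must be in [0, 1], got {rho}")
    den = (n_a + n_b) * rho + 2 * (1 - rho)
    if den == 0:  # homozygous deletion in a 100% pure sample: no reads
        warnings.warn("zero expected depth (homdel at purity 1); BAF set to 0.5")
        p = 0.5
    else:
        p = (n_b * rho + (1 - rho)) / den
    return float(p if b_on_hap_b else 1.0 - p)


def expected_logr(n_total: int, rho: float, psi: float) -> float:
    """Expected LogR of a region with total copy number ``n_total``."""
    if not 0 <= rho <= 1:
        raise ValueError(f"purity must be in [0, 1], got {rho}")
    if psi <= 0:
        raise ValueError(f"ploidy must be positive, got {psi}")
    return float(
        np.log2((2 * (1 - rho) + rho * n_total) / (2 * (1 - rho) + rho * psi))
    )


# ---------------------------------------------------------------------------
# synthetic patients


@dataclass
class SimulationParams:
    """Knobs of the synthetic patient generator.

    Defaults emulate a multi-region exome-like study: a handful of
    chromosomes with megabase-scale segments, ~100x coverage, LogR
    dispersion 0.15, purities between 0.3 and 0.9, one event-free
    (balanced) chromosome and one chromosome with planted MSAI per
    patient, and a whole-chromosome backbone event on the remaining
    chromosomes so that within-chromosome phase is identifiable.
    """

    n_chromosomes: int = 6
    segments_per_chromosome: tuple = (2, 4)  # inclusive range
    segment_length: tuple = (5_000_000, 20_000_000)
    snps_per_segment: tuple = (60, 120)
    coverage: int | None = 100
    logr_sd: float = 0.15
    purity_range: tuple = (0.3, 0.9)
    hom_fraction: float = 0.05
    p_clonal_backbone: float = 0.5
    p_segmental: float = 0.5
    n_balanced_chromosomes: int = 1
    n_msai_chromosomes: int = 1
    breakpoint_jitter: int = 0


@dataclass
class TruthProfile:
    """Planted ground truth behind a synthetic patient."""

    segments: pd.DataFrame  # seg_id, chrom, start, end, width
    states: dict  # sample_id -> (n_segments, 2) int array of (n_a, n_b)
    purities: dict
    ploidies: dict  # width-weighted mean total CN per sample
    snps: pd.DataFrame  # chrom, pos, seg_id, b_on_hap_b, is_het
    msai_chromosomes: list = field(default_factory=list)
    balanced_chromosomes: list = field(default_factory=list)


def _truth_ploidy(states: np.ndarray, widths: np.ndarray) -> float:
    totals = states.sum(axis=1)
    return float(np.sum(totals * widths) / np.sum(widths))


def simulate_patient(
    n_samples: int = 3,
    seed: int = 0,
    params: SimulationParams | None = None,
) -> tuple[TruthProfile, PatientData]:
    """Draw a synthetic patient from known haplotype-specific truth.

    Returns the truth profile and a PatientData shaped exactly like the
    parsed output of single-sample callers: per-sample major/minor
    segment tables (adjacent truth segments with equal configuration
    merged, optionally jittered), SNP BAF/LogR tracks, purity/ploidy,
    and a matched-normal BAF track. Fully reproducible from ``seed``.
    """
    if n_samples < 2:
        raise ValueError("at least two samples required")
    p = params or SimulationParams()
    rng = np.random.default_rng(seed)
    sample_ids = [f"S{i + 1}" for i in range(n_samples)]

    # --- truth segment grid
    seg_rows, snp_rows = [], []
    seg_id = 0
    chrom_segments: dict[str, list[int]] = {}
    for c in range(p.n_chromosomes):
        chrom = f"chr{c + 1}"
        chrom_segments[chrom] = []
        pos = 1
        for _ in range(rng.integers(p.segments_per_chromosome[0],
                                    p.segments_per_chromosome[1] + 1)):
            length = int(rng.integers(p.segment_length[0], p.segment_length[1] + 1))
            start, end = pos, pos + length - 1
            n_snps = int(rng.integers(p.snps_per_segment[0], p.snps_per_segment[1] + 1))
            snp_pos = np.sort(rng.choice(np.arange(start, end + 1), n_snps, replace=False))
            for sp in snp_pos:
                snp_rows.append(
                    {
                        "chrom": chrom,
                        "pos": int(sp),
                        "seg_id": seg_id,
                        "b_on_hap_b": bool(rng.random() < 0.5),
                        "is_het": bool(rng.random() >= p.hom_fraction),
                    }
                )
            seg_rows.append(
                {"seg_id": seg_id, "chrom": chrom, "start": start, "end": end,
                 "width": end - start + 1}
            )
            chrom_segments[chrom].append(seg_id)
            pos = end + 1
            seg_id += 1
    segments = pd.DataFrame(seg_rows)
    snps = pd.DataFrame(snp_rows)

    # --- plant events
    n_segs = len(segments)
    states = {sid: np.ones((n_segs, 2), int) for sid in sample_ids}
    chroms = [f"chr{c + 1}" for c in range(p.n_chromosomes)]
    balanced = chroms[: p.n_balanced_chromosomes]
    msai = chroms[p.n_balanced_chromosomes:
                  p.n_balanced_chromosomes + p.n_msai_chromosomes]
    for chrom in chroms:
        segs = np.array(chrom_segments[chrom])
        if chrom in balanced:
            continue
        if chrom in msai:
            # whole-chromosome gains of opposite haplotypes in two samples
            s1, s2 = rng.choice(n_samples, 2, replace=False)
            states[sample_ids[s1]][segs, 0] += 1
            states[sample_ids[s2]][segs, 1] += 1
            continue
        # backbone whole-chromosome event, clonal or in a random subset
        hap = int(rng.random() < 0.5)
        delta = 1 if rng.random() < 0.5 else -1
        if rng.random() < p.p_clonal_backbone:
            carriers = list(range(n_samples))
        else:
            k = int(rng.integers(1, n_samples))
            carriers = list(rng.choice(n_samples, k, replace=False))
        for ci in carriers:
            col = states[sample_ids[ci]][segs, hap]
            states[sample_ids[ci]][segs, hap] = np.maximum(col + delta, 0)
        # at most one segmental event per sample and chromosome, so each
        # sample's input major/minor segmentation preserves truth breakpoints
        for ci in range(n_samples):
            if rng.random() >= p.p_segmental or len(segs) < 2:
                continue
            i0 = int(rng.integers(0, len(segs)))
            i1 = int(rng.integers(i0, len(segs)))
            run = segs[i0 : i1 + 1]
            hap2 = int(rng.random() < 0.5)
            delta2 = 1 if rng.random() < 0.5 else -1
            st = states[sample_ids[ci]]
            new_col = np.maximum(st[run, hap2] + delta2, 0)
            # skip events that would create homozygous deletions: they are
            # rare/focal in real tumours and would sever the allelic-imbalance
            # continuity that makes within-chromosome phase identifiable
            if delta2 < 0 and np.any((new_col == 0) & (st[run, 1 - hap2] == 0)):
                continue
            st[run, hap2] = new_col

    widths = segments["width"].to_numpy(float)
    purities = {
        sid: float(rng.uniform(*p.purity_range)) for sid in sample_ids
    }
    ploidies = {sid: _truth_ploidy(states[sid], widths) for sid in sample_ids}

    # --- normal BAF track and het flags (as the input pipeline would see them)
    n_snp = len(snps)
    het_true = snps["is_het"].to_numpy(bool)
    hom_is_alt = rng.random(n_snp) < 0.5
    p_normal = np.where(het_true, 0.5, np.where(hom_is_alt, 0.99, 0.01))
    if p.coverage is None:
        normal_baf_vals = p_normal.copy()
    else:
        normal_baf_vals = rng.binomial(p.coverage, p_normal) / p.coverage
    normal_baf = pd.DataFrame(
        {"chrom": snps["chrom"], "pos": snps["pos"], "baf": normal_baf_vals}
    )
    is_het_flag = identify_heterozygous(normal_baf_vals)

    # --- per-sample observed tracks and input segmentations
    samples = []
    seg_of_snp = snps["seg_id"].to_numpy(int)
    b_on_b = snps["b_on_hap_b"].to_numpy(bool)
    for sid in sample_ids:
        rho = purities[sid]
        st = states[sid]
        p_baf = np.empty(n_snp)
        for i in range(n_snp):
            if het_true[i]:
                na, nb = st[seg_of_snp[i]]
                p_baf[i] = expected_baf(int(na), int(nb), rho, b_on_b[i])
            else:
                p_baf[i] = 0.99 if hom_is_alt[i] else 0.01
        mu_logr = np.array(
            [
                expected_logr(int(st[s].sum()), rho, ploidies[sid])
                for s in seg_of_snp
            ]
        )
        if p.coverage is None:
            baf = p_baf
        else:
            baf = rng.binomial(p.coverage, p_baf) / p.coverage
        logr = mu_logr + (rng.normal(0, p.logr_sd, n_snp) if p.logr_sd > 0 else 0)
        snp_df = pd.DataFrame(
            {
                "chrom": snps["chrom"],
                "pos": snps["pos"],
                "baf": baf,
                "logr": logr,
                "is_het": is_het_flag,
            }
        )
        seg_df = _input_segmentation(segments, st, p.breakpoint_jitter, rng)
        samples.append(
            SampleData(
                sample_id=sid,
                purity=rho,
                ploidy=ploidies[sid],
                snps=snp_df,
                segments=seg_df,
            )
        )
    truth = TruthProfile(
        segments=segments,
        states=states,
        purities=purities,
        ploidies=ploidies,
        snps=snps.assign(is_het=is_het_flag),
        msai_chromosomes=msai,
        balanced_chromosomes=balanced,
    )
    patient = PatientData(
        patient_id=f"SIM{seed}", samples=samples, normal_baf=normal_baf
    )
    return truth, patient


def _input_segmentation(
    segments: pd.DataFrame, states: np.ndarray, jitter: int, rng
) -> pd.DataFrame:
    """Major/minor input segments: merge equal-configuration neighbours."""
    rows = []
    for chrom, grp in segments.groupby("chrom", sort=False):
        grp = grp.sort_values("start")
        cur = None
        for _, r in grp.iterrows():
            na, nb = states[int(r["seg_id"])]
            major, minor = max(na, nb), min(na, nb)
            if cur is not None and (cur["cn_major"], cur["cn_minor"]) == (major, minor):
                cur["end"] = int(r["end"])
            else:
                if cur is not None:
                    rows.append(cur)
                cur = {
                    "chrom": chrom,
                    "start": int(r["start"]),
                    "end": int(r["end"]),
                    "cn_major": int(major),
                    "cn_minor": int(minor),
                }
        rows.append(cur)
    df = pd.DataFrame(rows)
    if jitter > 0:
        for chrom, grp in df.groupby("chrom", sort=False):
            idx = grp.index.to_list()
            for a, b in zip(idx[:-1], idx[1:]):
                shift = int(rng.integers(-jitter, jitter + 1))
                boundary = df.at[a, "end"] + shift
                boundary = max(df.at[a, "start"], min(boundary, df.at[b, "end"] - 1))
                df.at[a, "end"] = boundary
                df.at[b, "start"] = boundary + 1
    return df


def score_recovery(truth: TruthProfile, result) -> dict:
    """Compare pipeline output with planted truth.

    Integer states are compared per MCS bin (matched by midpoint) and
    scored width-weighted, allowing one global A/B swap per chromosome
    (between-chromosome haplotype labels are arbitrary). Also reports
    which chromosomes were truly vs. called MSAI.
    """
    bins = result.bins
    cn = result.copy_numbers.set_index(["bin_id", "sample_id"])
    seg_lookup = truth.segments
    sample_ids = list(truth.states)
    correct_width = 0.0
    total_width = 0.0
    for chrom, grp in bins.groupby("chrom", sort=False):
        w_id = 0.0
        w_flip = 0.0
        w_tot = 0.0
        for _, b in grp.iterrows():
            mid = (b["start"] + b["end"]) / 2
            hit = seg_lookup[
                (seg_lookup["chrom"] == chrom)
                & (seg_lookup["start"] <= mid)
                & (seg_lookup["end"] >= mid)
            ]
            if hit.empty:
                continue
            seg = int(hit.iloc[0]["seg_id"])
            w = float(b["width"])
            w_tot += w
            ok_id = ok_flip = True
            for sid in sample_ids:
                na_t, nb_t = truth.states[sid][seg]
                row = cn.loc[(b["bin_id"], sid)]
                na, nb = int(row["n_a"]), int(row["n_b"])
                ok_id &= (na, nb) == (na_t, nb_t)
                ok_flip &= (nb, na) == (na_t, nb_t)
            w_id += w * ok_id
            w_flip += w * ok_flip
        correct_width += max(w_id, w_flip)
        total_width += w_tot
    msai_true = set()
    for chrom, grp in seg_lookup.groupby("chrom", sort=False):
        for seg in grp["seg_id"]:
            diffs = [truth.states[sid][seg][0] - truth.states[sid][seg][1]
                     for sid in sample_ids]
            if any(d > 0 for d in diffs) and any(d < 0 for d in diffs):
                msai_true.add(chrom)
                break
    summary = result.summary
    msai_called = set(summary.loc[summary["msai"], "chrom"])
    return {
        "fraction_correct": correct_width / total_width if total_width else float("nan"),
        "msai_true_chromosomes": msai_true,
        "msai_called_chromosomes": msai_called,
    }


# ---------------------------------------------------------------------------
# CNLOH detection-limit sweep


def simulate_cnloh_sweep(
    n_events: int = 125,
    ccf_grid=None,
    coverage: int = 200,
    seed: int = 0,
    alpha: float = DEFAULT_ALPHA,
    d_min: float = DEFAULT_D_MIN,
    snp_range: tuple = (200, 2000),
    baseline: bool = True,
    baseline_max_snps: int = 300,
) -> pd.DataFrame:
    """Detection of simulated copy-neutral LOH across a CCF grid.

    For each candidate event a reference sample with clear allelic
    imbalance (purity * |n_a - n_b| >= 0.5) phases the SNPs; the test
    sample carries a 2|0 copy-neutral LOH at each cancer cell fraction
    of the grid (default 1-30% in 1% steps), with per-SNP BAF drawn
    Binomial(coverage, expected BAF) / coverage. Detection applies the
    rank-sum + Cohen's d imbalance test between the phased haplotypes.
    An unphased baseline detector (BIC selection between one- and
    two-component Gaussian mixtures of the raw BAFs) is also reported.

    Returns a table with one row per CCF grid point (in percent) and
    the detected fractions per detector.
    """
    if ccf_grid is None:
        ccf_grid = np.arange(1, 31)
    ccf_grid = np.asarray(ccf_grid, float)
    rng = np.random.default_rng(seed)
    ref_states = [(2, 0), (2, 1), (3, 1)]
    detected = np.zeros(len(ccf_grid), int)
    detected_base = np.zeros(len(ccf_grid), int)
    for _ in range(n_events):
        n_snps = int(rng.integers(snp_range[0], snp_range[1] + 1))
        na_r, nb_r = ref_states[rng.integers(0, len(ref_states))]
        rho_min = 0.5 / abs(na_r - nb_r)
        rho_ref = float(rng.uniform(rho_min, 1.0))
        b_on_b = rng.random(n_snps) < 0.5
        p_ref = np.where(
            b_on_b,
            expected_baf(na_r, nb_r, rho_ref, True),
            expected_baf(na_r, nb_r, rho_ref, False),
        )
        ref_baf = rng.binomial(coverage, p_ref) / coverage
        is_b_hat = phase_bin(ref_baf)
        for k, ccf in enumerate(ccf_grid):
            rho_t = ccf / 100.0
            p_test = np.where(
                b_on_b,
                expected_baf(2, 0, rho_t, True),
                expected_baf(2, 0, rho_t, False),
            )
            test_baf = rng.binomial(coverage, p_test) / coverage
            res = test_allelic_imbalance(
                test_baf[~is_b_hat], test_baf[is_b_hat], alpha=alpha, d_min=d_min
            )
            detected[k] += int(res.imbalanced)
            if baseline:
                sub = test_baf
                if sub.size > baseline_max_snps:
                    sub = rng.choice(sub, baseline_max_snps, replace=False)
                detected_base[k] += int(_mixture_detects(sub))
    out = pd.DataFrame(
        {
            "ccf_percent": ccf_grid,
            "detected_phased": detected / n_events,
        }
    )
    if baseline:
        out["detected_unphased"] = detected_base / n_events
    return out


def _mixture_detects(bafs: np.ndarray) -> bool:
    """Unphased detector: does a 2-band mixture beat 1 band by BIC?"""
    X = bafs.reshape(-1, 1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        bic1 = GaussianMixture(1, random_state=0).fit(X).bic(X)
        bic2 = GaussianMixture(
            2, covariance_type="tied", random_state=0, n_init=1
        ).fit(X).bic(X)
    return bool(bic2 < bic1)


def detection_limit(sweep: pd.DataFrame, column: str = "detected_phased") -> float:
    """Smallest CCF (percent) at which every event was flagged; NaN if never."""
    hit = sweep.loc[sweep[column] >= 1.0, "ccf_percent"]
    return float(hit.iloc[0]) if len(hit) else float("nan")


# ---------------------------------------------------------------------------
# MSAI permutation null


CHROMOSOMAL_KINDS = ("chromosomal_gain", "chromosomal_loss")
SEGMENTAL_KINDS = ("segmental_gain", "segmental_loss")


@dataclass(frozen=True)
class EventSpec:
    """One copy-number event on one branch of the sample tree."""

    branch: str
    kind: str  # chromosomal_gain/loss, segmental_gain/loss, wgd
    chrom: str | None = None
    start: int | None = None
    length: int | None = None
    haplotype: int | None = None  # 0 = A, 1 = B

    def __post_init__(self):
        if self.kind not in CHROMOSOMAL_KINDS + SEGMENTAL_KINDS + ("wgd",):
            raise ValueError(f"unknown event kind {self.kind!r}")


@dataclass
class MsaiNullResult:
    observed_fraction: float
    null_fractions: np.ndarray
    p_value: float
    n_sims: int


def _apply_event(karyotype: dict, ev: EventSpec, chrom_lengths: dict) -> None:
    """Apply one event in place; karyotype: chrom -> list of [s, e, na, nb]."""
    if ev.kind == "wgd":
        for segs in karyotype.values():
            for seg in segs:
                seg[2] *= 2
                seg[3] *= 2
        return
    chrom = ev.chrom
    if ev.kind in CHROMOSOMAL_KINDS:
        start, end = 1, chrom_lengths[chrom]
    else:
        start, end = ev.start, ev.start + ev.length - 1
    delta = 1 if ev.kind.endswith("gain") else -1
    col = 2 + ev.haplotype
    segs = karyotype[chrom]
    new = []
    for s, e, na, nb in segs:
        pieces = []
        lo, hi = max(s, start), min(e, end)
        if lo > hi:
            new.append([s, e, na, nb])
            continue
        if s < lo:
            pieces.append([s, lo - 1, na, nb])
        mid = [lo, hi, na, nb]
        mid[col] = max(mid[col] + delta, 0)
        pieces.append(mid)
        if hi < e:
            pieces.append([hi + 1, e, na, nb])
        new.extend(pieces)
    karyotype[chrom] = new


def replay_events(events, tree: dict, chrom_lengths: dict) -> dict:
    """Karyotypes per sample from branch events.

    ``tree`` maps sample_id -> ordered tuple of branch ids from root to
    tip; each sample receives the events of every branch on its path,
    in path order (WGD events of a branch are applied before that
    branch's other events).
    """
    by_branch: dict[str, list[EventSpec]] = {}
    for ev in events:
        by_branch.setdefault(ev.branch, []).append(ev)
    out = {}
    for sample, path in tree.items():
        karyotype = {
            c: [[1, length, 1, 1]] for c, length in chrom_lengths.items()
        }
        for branch in path:
            branch_events = by_branch.get(branch, [])
            for ev in branch_events:
                if ev.kind == "wgd":
                    _apply_event(karyotype, ev, chrom_lengths)
            for ev in branch_events:
                if ev.kind != "wgd":
                    _apply_event(karyotype, ev, chrom_lengths)
        out[sample] = karyotype
    return out


def msai_fraction(karyotypes: dict, chrom_lengths: dict) -> float:
    """Genome fraction where samples disagree on the major haplotype."""
    total = float(sum(chrom_lengths.values()))
    msai_len = 0.0
    samples = list(karyotypes)
    for chrom, length in chrom_lengths.items():
        cuts = {1, length + 1}
        for sid in samples:
            for s, e, _, _ in karyotypes[sid][chrom]:
                cuts.add(s)
                cuts.add(e + 1)
        cuts = sorted(cuts)
        for lo, hi in zip(cuts[:-1], cuts[1:]):
            up = down = False
            for sid in samples:
                for s, e, na, nb in karyotypes[sid][chrom]:
                    if s <= lo <= e:
                        up |= na > nb
                        down |= na < nb
                        break
            if up and down:
                msai_len += hi - lo
    return msai_len / total


def randomize_events(events, chrom_lengths: dict, rng) -> list:
    """Redraw event locations under the null, keeping number/kind/length."""
    chroms = list(chrom_lengths)
    out = []
    for ev in events:
        if ev.kind == "wgd":
            out.append(ev)
            continue
        hap = int(rng.integers(0, 2))
        if ev.kind in CHROMOSOMAL_KINDS:
            chrom = chroms[rng.integers(0, len(chroms))]
            out.append(replace(ev, chrom=chrom, start=1,
                               length=chrom_lengths[chrom], haplotype=hap))
        else:
            fitting = [c for c in chroms if chrom_lengths[c] >= ev.length]
            if not fitting:
                raise ValueError(
                    f"segmental event of length {ev.length} fits no chromosome"
                )
            chrom = fitting[rng.integers(0, len(fitting))]
            start = int(rng.integers(1, chrom_lengths[chrom] - ev.length + 2))
            out.append(replace(ev, chrom=chrom, start=start, haplotype=hap))
    return out


def msai_null(
    events,
    tree: dict,
    chrom_lengths: dict,
    n_sims: int = 350,
    seed: int = 0,
) -> MsaiNullResult:
    """Permutation test of the observed MSAI genome fraction.

    Each replicate keeps the number and kind of events on every branch
    but reassigns chromosomes uniformly (and segmental start positions
    uniformly, lengths fixed), replays the events to karyotypes, and
    measures the MSAI fraction. The right-tailed p-value uses the
    add-one estimator (1 + #{null >= observed}) / (n_sims + 1).
    """
    rng = np.random.default_rng(seed)
    events = list(events)
    observed = msai_fraction(replay_events(events, tree, chrom_lengths), chrom_lengths)
    null = np.empty(n_sims)
    for i in range(n_sims):
        sim_events = randomize_events(events, chrom_lengths, rng)
        null[i] = msai_fraction(
            replay_events(sim_events, tree, chrom_lengths), chrom_lengths
        )
    p = (1 + int(np.sum(null >= observed))) / (n_sims + 1)
    return MsaiNullResult(observed, null, float(p), n_sims)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values for cross-patient summaries."""
    return multipletests(np.asarray(p_values, float), method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# artificial normal samples


def make_artificial_normal(
    patient: PatientData,
    seed: int = 0,
    coverage: int | None = 100,
    logr_sd: float = 0.15,
    sample_id: str = "artificial_normal",
) -> SampleData:
    """A balanced pseudo-sample on the patient's SNP panel.

    BAF at het SNPs is binomial noise around 0.5, LogR is Gaussian
    noise around 0 (a normal-vs-normal depth ratio), and the input
    segmentation is one balanced 1/1 segment per chromosome. Appending
    it to a patient provides a specificity control: no allelic
    imbalance should be called in it. ``coverage=None`` with
    ``logr_sd=0`` gives the noiseless limit.
    """
    rng = np.random.default_rng(seed)
    base = patient.samples[0].snps
    n = len(base)
    het = base["is_het"].to_numpy(bool)
    hom_high = rng.random(n) < 0.5
    p_baf = np.where(het, 0.5, np.where(hom_high, 0.99, 0.01))
    baf = p_baf if coverage is None else rng.binomial(coverage, p_baf) / coverage
    logr = rng.normal(0, logr_sd, n) if logr_sd > 0 else np.zeros(n)
    snps = pd.DataFrame(
        {
            "chrom": base["chrom"],
            "pos": base["pos"],
            "baf": baf,
            "logr": logr,
            "is_het": het,
        }
    )
    # span the union of the tumour samples' covered extents per chromosome
    all_segs = pd.concat([s.segments for s in patient.samples])
    seg_rows = [
        {
            "chrom": chrom,
            "start": int(grp["start"].min()),
            "end": int(grp["end"].max()),
            "cn_major": 1,
            "cn_minor": 1,
        }
        for chrom, grp in all_segs.groupby("chrom", sort=False)
    ]
    return SampleData(
        sample_id=sample_id,
        purity=0.5,
        ploidy=2.0,
        snps=snps,
        segments=pd.DataFrame(seg_rows),
    )
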