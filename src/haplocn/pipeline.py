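"""End-to-end patient analysis: MCS -> phasing -> copy number -> events.

The pipeline builds the shared bin set, selects a phasing reference per
bin, transfers the reference's SNP phasing to every sample, tests each
(bin, sample) for allelic imbalance (Holm-adjusted family-wise across
the patient), re-estimates haplotype-specific copy numbers, recomputes
sample ploidies, resolves the along-chromosome segment orientation by
parsimony, and finally calls sample-level events and patient-level
clonality, MSAI and genome fractions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import copynumber, events, horizontal, mcs, phasing
from .model import PatientData

logger = logging.getLogger("haplocn")


@dataclass
class PipelineConfig:
    max_gap: int = mcs.DEFAULT_MAX_GAP
    alpha: float = phasing.DEFAULT_ALPHA
    d_min: float = phasing.DEFAULT_D_MIN
    min_snps: int = phasing.DEFAULT_MIN_SNPS
    min_baf_var: float = phasing.DEFAULT_MIN_BAF_VAR
    policy: str = "on_new_imbalance"  # CN re-estimation trigger
    model: str = "parametric"  # or "nonparametric"
    mode: str = "mean"  # dosage calling: "mean" | "ttest"
    reference: str = "ploidy"  # dosage thresholds: "ploidy" | "diploid"
    seed: int = 0
    groups: dict | None = None  # group label -> [sample ids]

    def __post_init__(self):
        if self.policy not in copynumber.REESTIMATION_POLICIES:
            raise ValueError(f"unknown policy {self.policy!r}")
        if self.model not in ("parametric", "nonparametric"):
            raise ValueError(f"unknown model {self.model!r}")
        if self.mode not in ("mean", "ttest"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.reference not in ("ploidy", "diploid"):
            raise ValueError(f"unknown reference {self.reference!r}")
        for name in ("max_gap", "alpha", "d_min"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


@dataclass
class PatientResult:
    patient_id: str
    config: PipelineConfig
    bins: pd.DataFrame  # bin_id, chrom, start, end, width, reference, flipped
    phasing: pd.DataFrame  # chrom, pos, haplotype, reference_sample
    imbalance: pd.DataFrame  # bin_id, sample_id, p, p_adj, cohens_d, imbalanced
    copy_numbers: pd.DataFrame  # bin_id, sample_id, n_*_frac, n_a, n_b, method
    ploidies: pd.DataFrame  # sample_id, input_ploidy, psi_t
    calls: pd.DataFrame  # bin_id, sample_id, dosage, loh, ...
    summary: pd.DataFrame  # per-bin clonality table
    fractions: pd.DataFrame  # genome-fraction metrics
    group_results: dict | None = None


def run_pipeline(patient: PatientData, config: PipelineConfig | None = None) -> PatientResult:
    cfg = config or PipelineConfig()
    seg = mcs.build_mcs(patient, cfg.max_gap)
    bins = seg.bins.copy()
    logger.info("patient %s: %d MCS bins over %d bp",
                patient.patient_id, seg.n_bins, seg.total_width)

    sample_ids = patient.sample_ids
    snps = {s.sample_id: s.snps for s in patient.samples}
    input_states = seg.input_states.set_index(["bin_id", "sample_id"])

    # --- per-bin reference selection and phasing
    reference: dict[int, str | None] = {}
    is_b: dict[int, np.ndarray] = {}
    for bin_id in bins["bin_id"]:
        idx = seg.snp_indices[bin_id]
        if idx.size == 0:
            reference[bin_id] = None
            continue
        sample_bafs = {sid: snps[sid]["baf"].to_numpy()[idx] for sid in sample_ids}
        states = {
            sid: (
                int(input_states.loc[(bin_id, sid), "cn_major"]),
                int(input_states.loc[(bin_id, sid), "cn_minor"]),
            )
            for sid in sample_ids
        }
        choice = phasing.select_reference(
            bin_id, sample_bafs, states,
            min_snps=cfg.min_snps, min_baf_var=cfg.min_baf_var,
            random_state=cfg.seed,
        )
        reference[bin_id] = choice.reference_sample_id
        if choice.reference_sample_id is not None:
            is_b[bin_id] = phasing.phase_bin(sample_bafs[choice.reference_sample_id])
    bins["reference"] = bins["bin_id"].map(lambda b: reference.get(b))
    logger.info("phased %d/%d bins", len(is_b), len(bins))

    # --- allelic imbalance tests, Holm-adjusted patient-wide
    tests = []
    for bin_id, mask in is_b.items():
        idx = seg.snp_indices[bin_id]
        for sid in sample_ids:
            baf = snps[sid]["baf"].to_numpy()[idx]
            t = phasing.test_allelic_imbalance(
                baf[~mask], baf[mask], alpha=cfg.alpha, d_min=cfg.d_min,
                bin_id=bin_id, sample_id=sid,
            )
            tests.append(t)
    imbalance = pd.DataFrame(
        [
            {"bin_id": t.bin_id, "sample_id": t.sample_id, "p": t.p_value,
             "cohens_d": t.cohens_d, "testable": t.testable}
            for t in tests
        ],
        columns=["bin_id", "sample_id", "p", "cohens_d", "testable"],
    )
    if len(imbalance):
        imbalance["p_adj"] = phasing.holm_adjust(imbalance["p"])
        imbalance["imbalanced"] = (
            imbalance["testable"]
            & (imbalance["p_adj"] <= cfg.alpha)
            & (imbalance["cohens_d"].abs() >= cfg.d_min)
        )
    else:
        imbalance["p_adj"] = pd.Series(dtype=float)
        imbalance["imbalanced"] = pd.Series(dtype=bool)
    flagged = imbalance.set_index(["bin_id", "sample_id"])["imbalanced"]

    # --- haplotype-specific copy numbers (first pass)
    cn_rows = []
    feature_rows = {}
    for bin_id in bins["bin_id"]:
        idx = seg.snp_indices[bin_id]
        mask = is_b.get(bin_id)
        for sid in sample_ids:
            major = int(input_states.loc[(bin_id, sid), "cn_major"])
            minor = int(input_states.loc[(bin_id, sid), "cn_minor"])
            sample = patient.get_sample(sid)
            logr_vals = snps[sid]["logr"].to_numpy()[idx] if idx.size else np.array([])
            mean_logr = float(np.nanmean(logr_vals)) if idx.size else 0.0
            if mask is None:
                b_hap = None
                imb = False
            else:
                baf = snps[sid]["baf"].to_numpy()[idx]
                b_hap = copynumber.phased_haplotype_baf(baf, mask)
                imb = bool(flagged.get((bin_id, sid), False))
            hap_cn = copynumber.reestimate_bin(
                bin_id, sid, b_hap, mean_logr, sample.purity, sample.ploidy,
                major, minor, imb, policy=cfg.policy,
            )
            cn_rows.append(hap_cn)
            feature_rows[(bin_id, sid)] = (b_hap, mean_logr)
    cn = pd.DataFrame([vars(c) for c in cn_rows])

    # --- optional nonparametric relabelling of re-estimated bins
    if cfg.model == "nonparametric":
        cn = _nonparametric_pass(cn, feature_rows, sample_ids)

    # --- ploidy recomputation (single pass, Eq-style width weighting)
    widths = bins.set_index("bin_id")["width"]
    ploidy_rows = []
    for s in patient.samples:
        sub = cn[cn["sample_id"] == s.sample_id]
        totals = np.maximum(sub["n_a_frac"], 0) + np.maximum(sub["n_b_frac"], 0)
        est = copynumber.recompute_ploidy(
            totals, widths.loc[sub["bin_id"]].to_numpy(), s.sample_id
        )
        ploidy_rows.append(
            {"sample_id": s.sample_id, "input_ploidy": s.ploidy, "psi_t": est.psi_t}
        )
        logger.info("sample %s: ploidy %.3f -> %.3f", s.sample_id, s.ploidy, est.psi_t)
    ploidies = pd.DataFrame(ploidy_rows).set_index("sample_id")

    # --- horizontal phasing per chromosome, bridging unphased bins
    cn = cn.set_index(["bin_id", "sample_id"])
    bins["flipped"] = False
    phased_ids = sorted(is_b)
    for chrom, grp in bins.groupby("chrom", sort=False):
        chrom_bins = [b for b in grp["bin_id"] if b in is_b]
        if not chrom_bins:
            continue
        states = [
            np.array([
                [cn.loc[(b, sid), "n_a"], cn.loc[(b, sid), "n_b"]]
                for sid in sample_ids
            ])
            for b in chrom_bins
        ]
        solution = horizontal.phase_chromosome(states, chrom=chrom)
        oriented = [
            st[:, ::-1] if fl else st for st, fl in zip(states, solution.flipped)
        ]
        w = widths.loc[chrom_bins].to_numpy(float)
        swap_all = horizontal.chromosome_orientation(w, np.array(oriented))
        for b, fl in zip(chrom_bins, solution.flipped):
            final_flip = bool(fl) ^ swap_all
            bins.loc[bins["bin_id"] == b, "flipped"] = final_flip
        if swap_all:
            # relabel every bin of the chromosome, phased or not
            for b in grp["bin_id"]:
                if b not in chrom_bins:
                    bins.loc[bins["bin_id"] == b, "flipped"] = True
    for b in bins.loc[bins["flipped"], "bin_id"]:
        for sid in sample_ids:
            key = (b, sid)
            cn.loc[key, ["n_a_frac", "n_b_frac"]] = cn.loc[
                key, ["n_b_frac", "n_a_frac"]
            ].to_numpy()
            cn.loc[key, ["n_a", "n_b"]] = cn.loc[key, ["n_b", "n_a"]].to_numpy()
        if b in is_b:
            is_b[b] = ~is_b[b]
    cn = cn.reset_index()

    # --- phasing table
    phase_rows = []
    pos_table = patient.snp_positions
    for bin_id in phased_ids:
        idx = seg.snp_indices[bin_id]
        mask = is_b[bin_id]
        for i, snp_i in enumerate(idx):
            phase_rows.append(
                {
                    "chrom": pos_table["chrom"].iloc[snp_i],
                    "pos": int(pos_table["pos"].iloc[snp_i]),
                    "haplotype": "B" if mask[i] else "A",
                    "reference_sample": reference[bin_id],
                }
            )
    phasing_df = pd.DataFrame(
        phase_rows, columns=["chrom", "pos", "haplotype", "reference_sample"]
    )

    # --- sample-level event calls
    call_rows = []
    cn_idx = cn.set_index(["bin_id", "sample_id"])
    for s in patient.samples:
        psi = float(ploidies.loc[s.sample_id, "psi_t"])
        psi_thr = 2.0 if cfg.reference == "diploid" else psi
        thr = events.compute_thresholds(s.purity, psi_thr, s.sample_id)
        for bin_id in bins["bin_id"]:
            idx = seg.snp_indices[bin_id]
            logr_vals = snps[s.sample_id]["logr"].to_numpy()[idx]
            row = cn_idx.loc[(bin_id, s.sample_id)]
            if idx.size:
                dosage = events.call_dosage(logr_vals, thr, mode=cfg.mode,
                                            alpha=cfg.alpha)
            else:
                dosage = "neutral"
            call_rows.append(
                {
                    "bin_id": bin_id,
                    "sample_id": s.sample_id,
                    "n_a": int(row["n_a"]),
                    "n_b": int(row["n_b"]),
                    "dosage": dosage,
                    "loh": events.call_loh(int(row["n_a"]), int(row["n_b"]), psi),
                    "imbalanced": bool(flagged.get((bin_id, s.sample_id), False)),
                    "reference": reference[bin_id],
                    "method": row["method"],
                }
            )
    calls = pd.DataFrame(call_rows)

    # --- patient-level summary
    summary = events.summarize_patient(calls, bins, sample_ids)
    fractions = events.genome_fractions(summary)
    group_results = None
    groups = cfg.groups or _groups_from_labels(patient)
    if groups:
        group_results = events.subgroup_summary(calls, bins, groups)
    return PatientResult(
        patient_id=patient.patient_id,
        config=cfg,
        bins=bins,
        phasing=phasing_df,
        imbalance=imbalance,
        copy_numbers=cn,
        ploidies=ploidies.reset_index(),
        calls=calls,
        summary=summary,
        fractions=fractions,
        group_results=group_results,
    )


def _groups_from_labels(patient: PatientData) -> dict | None:
    groups: dict[str, list[str]] = {}
    for s in patient.samples:
        if s.group_label:
            groups.setdefault(s.group_label, []).append(s.sample_id)
    return groups or None


def _nonparametric_pass(cn: pd.DataFrame, features: dict, sample_ids) -> pd.DataFrame:
    """Relabel re-estimated bins with the naive-Bayes model.

    Training rows for a query (bin, sample) are all other bins of the
    same sample plus the same bin in the other samples, labelled with
    their first-pass integer states; a single-class training set falls
    back to the parametric result (method flagged).
    """
    cn = cn.copy()
    labelled = {
        (r["bin_id"], r["sample_id"]): (int(r["n_a"]), int(r["n_b"]))
        for _, r in cn.iterrows()
    }
    for i, r in cn.iterrows():
        if r["method"] != "parametric":
            continue
        key = (r["bin_id"], r["sample_id"])
        b_hap, mean_logr = features[key]
        if b_hap is None:
            continue
        X, y = [], []
        for (bin_id, sid), lab in labelled.items():
            if (bin_id, sid) == key:
                continue
            if sid == r["sample_id"] or bin_id == r["bin_id"]:
                fb, fl = features[(bin_id, sid)]
                if fb is None:
                    continue
                X.append([fb, fl])
                y.append(lab)
        try:
            n_a, n_b = copynumber.estimate_nonparametric([b_hap, mean_logr], X, y)
            cn.loc[i, ["n_a", "n_b"]] = [n_a, n_b]
            cn.loc[i, ["n_a_frac", "n_b_frac"]] = [float(n_a), float(n_b)]
            cn.loc[i, "method"] = "nonparametric"
        except ValueError:
            cn.loc[i, "method"] = "parametric_fallback"
    return cn
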