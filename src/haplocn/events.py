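"""Sample-level SCNA event calling and patient-level clonality summaries.

Dosage events (amplification / gain / loss) are called per sample and
bin by comparing LogR against purity-ploidy derived thresholds

    amp  : LogR > log2[(2(1-rho) + 2.00*rho*psi) / (2(1-rho) + rho*psi)]
    gain : LogR > log2[(2(1-rho) + 1.25*rho*psi) / (2(1-rho) + rho*psi)]
    loss : LogR < log2[(2(1-rho) + 0.75*rho*psi) / (2(1-rho) + rho*psi)]

LOH classes come from the phased integer states. Patient-level
clonality compares the presence of each event class across samples and
reassigns present-in-all events to subclonal/parallel when mirrored
allelic states show they arose on different haplotypes (MSAI).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

EVENT_CLASSES = ("gain", "loss", "amplification", "loh", "cnloh", "homdel")


@dataclass
class EventThresholds:
    sample_id: str
    amp_logr: float
    gain_logr: float
    loss_logr: float


def compute_thresholds(rho: float, psi: float, sample_id: str = "") -> EventThresholds:
    """Purity-ploidy derived LogR cutoffs; loss < gain < amp always."""
    if not 0 < rho <= 1:
        raise ValueError(f"purity must be in (0, 1], got {rho}")
    if psi <= 0:
        raise ValueError(f"ploidy must be positive, got {psi}")
    den = 2 * (1 - rho) + rho * psi

    def cut(factor):
        return float(np.log2((2 * (1 - rho) + factor * rho * psi) / den))

    return EventThresholds(sample_id, cut(2.0), cut(1.25), cut(0.75))


def call_dosage(
    logr_values,
    thresholds: EventThresholds,
    mode: str = "mean",
    alpha: float = 0.05,
) -> str:
    """Classify a bin's dosage relative to ploidy for one sample.

    mode="mean" compares the mean bin LogR to the cutoffs; mode="ttest"
    runs a one-tailed one-sample Student's t-test of the within-bin LogR
    values against each cutoff (greater for amp/gain, less for loss).
    The neutral band includes the cutoffs themselves.
    """
    vals = np.asarray(logr_values, float)
    vals = vals[~np.isnan(vals)]
    if vals.size == 0:
        raise ValueError("cannot call dosage on an empty bin")
    if mode == "mean":
        m = float(np.mean(vals))
        if m > thresholds.amp_logr:
            return "amplification"
        if m > thresholds.gain_logr:
            return "gain"
        if m < thresholds.loss_logr:
            return "loss"
        return "neutral"
    if mode == "ttest":
        if vals.size < 2 or np.ptp(vals) == 0:
            # t-test degenerate; fall back to the mean rule
            return call_dosage(vals, thresholds, mode="mean")
        for thr, side, label in (
            (thresholds.amp_logr, "greater", "amplification"),
            (thresholds.gain_logr, "greater", "gain"),
            (thresholds.loss_logr, "less", "loss"),
        ):
            p = stats.ttest_1samp(vals, thr, alternative=side).pvalue
            if p <= alpha:
                return label
        return "neutral"
    raise ValueError(f"unknown dosage mode {mode!r}")


def call_loh(n_a: int, n_b: int, psi: float) -> str:
    """LOH class from phased integers: homdel, cnloh, loh or none."""
    if n_a == 0 and n_b == 0:
        return "homdel"
    if n_a == 0 or n_b == 0:
        major = max(n_a, n_b)
        if major == int(np.floor(psi + 0.5)):
            return "cnloh"
        return "loh"
    return "none"


def detect_msai(states) -> bool:
    """Mirrored subclonal allelic imbalance at one bin.

    True iff some sample has n_a > n_b while another has n_a < n_b,
    i.e. different haplotypes are the major allele in different samples.
    """
    states = np.asarray(states, int)
    diff = states[:, 0] - states[:, 1]
    return bool((diff > 0).any() and (diff < 0).any())


def classify_clonality(present, states) -> tuple[str, bool]:
    """(clonality, parallel) for one event class at one bin.

    ``present`` is a boolean per sample; ``states`` the phased (n_a,
    n_b) integers per sample. Clonal requires presence in every sample
    with no mirroring among them; presence in all samples but with
    mirrored major haplotypes is reassigned subclonal and parallel.
    Parallel requires mirroring among the specific samples harbouring
    the event, regardless of the other samples.
    """
    present = np.asarray(present, bool)
    states = np.asarray(states, int)
    if not present.any():
        return "absent", False
    harbouring = states[present]
    diff = harbouring[:, 0] - harbouring[:, 1]
    parallel = bool((diff > 0).any() and (diff < 0).any())
    if present.all() and not parallel:
        return "clonal", False
    return "subclonal", parallel


def summarize_patient(
    calls: pd.DataFrame,
    bins: pd.DataFrame,
    sample_ids: list[str],
) -> pd.DataFrame:
    """Per-bin patient-level clonality table.

    ``calls`` holds one row per (bin_id, sample_id) with columns n_a,
    n_b, dosage, loh, imbalanced. Returns one row per bin with an MSAI
    flag and, for every event class, its clonality and parallel flag.
    """
    rows = []
    for bin_id, grp in calls.groupby("bin_id"):
        grp = grp.set_index("sample_id").loc[sample_ids]
        states = grp[["n_a", "n_b"]].to_numpy(int)
        presence = {
            "gain": grp["dosage"].isin(["gain", "amplification"]).to_numpy(),
            "loss": (grp["dosage"] == "loss").to_numpy(),
            "amplification": (grp["dosage"] == "amplification").to_numpy(),
            "loh": grp["loh"].isin(["loh", "cnloh"]).to_numpy(),
            "cnloh": (grp["loh"] == "cnloh").to_numpy(),
            "homdel": (grp["loh"] == "homdel").to_numpy(),
        }
        row = {
            "bin_id": bin_id,
            "msai": detect_msai(states),
            "any_imbalance": bool(grp["imbalanced"].to_numpy(bool).any()),
        }
        for cls in EVENT_CLASSES:
            clon, par = classify_clonality(presence[cls], states)
            row[f"{cls}_clonality"] = clon
            row[f"{cls}_parallel"] = par
        rows.append(row)
    summary = pd.DataFrame(rows).merge(
        bins[["bin_id", "chrom", "start", "end", "width"]], on="bin_id"
    )
    cols = ["bin_id", "chrom", "start", "end", "width"]
    return summary[cols + [c for c in summary.columns if c not in cols]]


def genome_fractions(summary: pd.DataFrame) -> pd.DataFrame:
    """Width-weighted proportion-of-genome metrics over the MCS bins."""
    total = float(summary["width"].sum())
    rows = []

    def add(metric, mask):
        rows.append(
            {
                "metric": metric,
                "fraction": float(summary.loc[mask, "width"].sum()) / total,
            }
        )

    for cls in EVENT_CLASSES:
        add(f"clonal_{cls}", summary[f"{cls}_clonality"] == "clonal")
        add(f"subclonal_{cls}", summary[f"{cls}_clonality"] == "subclonal")
        add(f"parallel_{cls}", summary[f"{cls}_parallel"])
    add("msai", summary["msai"])
    add("allelic_imbalance", summary["any_imbalance"])
    return pd.DataFrame(rows)


def subgroup_summary(
    calls: pd.DataFrame,
    bins: pd.DataFrame,
    groups: dict,
) -> dict:
    """Group-level clonality and fractions using the shared patient phasing.

    ``groups`` maps group label -> list of sample ids (each sample in at
    most one group). Clonality is re-evaluated within each group's
    samples; the per-sample calls (and hence the phasing) are unchanged.
    """
    seen: set[str] = set()
    for label, sids in groups.items():
        dup = seen & set(sids)
        if dup:
            raise ValueError(f"samples assigned to more than one group: {sorted(dup)}")
        seen |= set(sids)
    known = set(calls["sample_id"])
    unknown = seen - known
    if unknown:
        raise ValueError(f"unknown samples in group spec: {sorted(unknown)}")
    out = {}
    for label, sids in groups.items():
        sub = calls[calls["sample_id"].isin(sids)]
        summary = summarize_patient(sub, bins, list(sids))
        out[label] = {
            "summary": summary,
            "fractions": genome_fractions(summary),
        }
    return out
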