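"""Minimum consistent segmentation (MCS) across the samples of a patient.

The MCS is the common genome binning obtained by taking the union of all
per-sample segment breakpoints, merging nearby breakpoints that come from
different samples (segmentation jitter), and keeping only the bins that
are covered by an input segment in every sample. Each surviving bin gets
the per-sample input major/minor copy numbers and the indices of the
heterozygous SNPs it contains.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import PatientData, SampleData, chromosome_sort_key

DEFAULT_MAX_GAP = 100_000  # bp


@dataclass(frozen=True)
class Breakpoint:
    chrom: str
    pos: int  # 1-based; position where a new bin starts
    origin_samples: frozenset

    def __post_init__(self):
        if not self.origin_samples:
            raise ValueError("breakpoint must have at least one origin sample")


@dataclass
class MinimumConsistentSegmentation:
    """Bins shared by all samples plus per-sample input states.

    bins: DataFrame(bin_id, chrom, start, end, width), genome-sorted.
    input_states: DataFrame(bin_id, sample_id, cn_major, cn_minor).
    snp_indices: bin_id -> integer row indices (into the patient SNP table)
        of the heterozygous SNPs contained in the bin.
    """

    bins: pd.DataFrame
    input_states: pd.DataFrame
    snp_indices: dict = field(default_factory=dict)

    @property
    def n_bins(self) -> int:
        return len(self.bins)

    @property
    def total_width(self) -> int:
        return int(self.bins["width"].sum())

    def input_state(self, bin_id: int, sample_id: str) -> tuple[int, int]:
        df = self.input_states
        row = df[(df["bin_id"] == bin_id) & (df["sample_id"] == sample_id)]
        r = row.iloc[0]
        return int(r["cn_major"]), int(r["cn_minor"])


def union_breakpoints(samples: list[SampleData]) -> list[Breakpoint]:
    """Union of segment boundaries over samples, tracking samples of origin.

    Each segment contributes its start and its end + 1 (the position where
    the following bin would begin).
    """
    origins: dict[tuple[str, int], set] = {}
    for s in samples:
        for chrom, grp in s.segments.groupby("chrom", sort=False):
            for pos in np.concatenate(
                [grp["start"].to_numpy(int), grp["end"].to_numpy(int) + 1]
            ):
                origins.setdefault((str(chrom), int(pos)), set()).add(s.sample_id)
    keys = sorted(origins, key=lambda k: (chromosome_sort_key(k[0]), k[1]))
    return [Breakpoint(c, p, frozenset(origins[(c, p)])) for c, p in keys]


def merge_close_breakpoints(
    breakpoints: list[Breakpoint], max_gap: int
) -> list[Breakpoint]:
    """Left-to-right merge of breakpoints closer than ``max_gap``.

    Two adjacent breakpoints are merged only if their origin sets are
    disjoint (jitter of the same underlying boundary estimated in
    different samples); breakpoints sharing a sample of origin are focal
    structure within that sample and are kept. The merged breakpoint
    keeps the leftmost position and the union of origins, and merging
    cascades left to right.
    """
    if max_gap < 0:
        raise ValueError("max_gap must be >= 0")
    if max_gap == 0 or len(breakpoints) < 2:
        return list(breakpoints)
    merged: list[Breakpoint] = []
    for bp in breakpoints:
        if (
            merged
            and merged[-1].chrom == bp.chrom
            and bp.pos - merged[-1].pos < max_gap
            and not (merged[-1].origin_samples & bp.origin_samples)
        ):
            prev = merged[-1]
            merged[-1] = Breakpoint(
                prev.chrom, prev.pos, prev.origin_samples | bp.origin_samples
            )
        else:
            merged.append(bp)
    return merged


def _covering_segment(segments: pd.DataFrame, chrom: str, point: float):
    """Return the (cn_major, cn_minor) of the segment containing ``point``."""
    grp = segments[segments["chrom"] == chrom]
    hit = grp[(grp["start"] <= point) & (grp["end"] >= point)]
    if hit.empty:
        return None
    r = hit.iloc[0]
    return int(r["cn_major"]), int(r["cn_minor"])


def build_mcs(
    patient: PatientData, max_gap: int = DEFAULT_MAX_GAP
) -> MinimumConsistentSegmentation:
    """Build the minimum consistent segmentation for a patient.

    Bins are formed between consecutive merged breakpoints of each
    chromosome; a bin is retained only if an input segment of every
    sample covers its midpoint. Raises if no bin survives.
    """
    breakpoints = merge_close_breakpoints(
        union_breakpoints(patient.samples), max_gap
    )
    snps = patient.snp_positions
    het = patient.het_mask
    bin_rows = []
    state_rows = []
    snp_indices: dict[int, np.ndarray] = {}
    bin_id = 0
    chroms = sorted({bp.chrom for bp in breakpoints}, key=chromosome_sort_key)
    for chrom in chroms:
        pos = [bp.pos for bp in breakpoints if bp.chrom == chrom]
        chrom_snps = snps.index[(snps["chrom"] == chrom) & het]
        chrom_pos = snps.loc[chrom_snps, "pos"].to_numpy(int)
        for start, nxt in zip(pos[:-1], pos[1:]):
            end = nxt - 1
            mid = (start + end) / 2
            states = [
                _covering_segment(s.segments, chrom, mid) for s in patient.samples
            ]
            if any(st is None for st in states):
                continue  # not covered in every sample
            for s, st in zip(patient.samples, states):
                state_rows.append(
                    {
                        "bin_id": bin_id,
                        "sample_id": s.sample_id,
                        "cn_major": st[0],
                        "cn_minor": st[1],
                    }
                )
            inside = (chrom_pos >= start) & (chrom_pos <= end)
            snp_indices[bin_id] = chrom_snps.to_numpy()[inside]
            bin_rows.append(
                {
                    "bin_id": bin_id,
                    "chrom": chrom,
                    "start": int(start),
                    "end": int(end),
                    "width": int(end - start + 1),
                }
            )
            bin_id += 1
    if not bin_rows:
        raise ValueError("no consistent segments shared by all samples")
    return MinimumConsistentSegmentation(
        bins=pd.DataFrame(bin_rows),
        input_states=pd.DataFrame(state_rows),
        snp_indices=snp_indices,
    )


def write_bed(mcs: MinimumConsistentSegmentation, path) -> None:
    """Export MCS bins as BED (0-based half-open, converted on write)."""
    with open(path, "w") as fh:
        fh.write("# MCS bins; coordinates converted to 0-based half-open\n")
        for _, r in mcs.bins.iterrows():
            fh.write(f"{r['chrom']}\t{r['start'] - 1}\t{r['end']}\tbin_{r['bin_id']}\n")
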