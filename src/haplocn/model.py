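"""Core in-memory containers for multi-sample tumour copy-number data.

A patient is a set of >=2 tumour samples sharing one ordered panel of
germline SNP positions. Each sample carries a SNP track (B-allele
frequency ``baf`` and log2 read-depth ratio ``logr``), an allele-specific
input segmentation in major/minor configuration, and purity/ploidy
estimates from a single-sample caller. All genomic coordinates are
1-based inclusive.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

SNP_COLUMNS = ["chrom", "pos", "baf", "logr", "is_het"]
SEGMENT_COLUMNS = ["chrom", "start", "end", "cn_major", "cn_minor"]


def chromosome_sort_key(chrom: str):
    """Natural ordering for chromosome names: chr1 < chr2 < chr10 < chrX."""
    name = re.sub(r"^chr", "", str(chrom))
    if name.isdigit():
        return (0, int(name), "")
    return (1, 0, name)


def sort_genomic(df: pd.DataFrame, pos_col: str = "pos") -> pd.DataFrame:
    key = df["chrom"].map(chromosome_sort_key)
    order = sorted(range(len(df)), key=lambda i: (key.iloc[i], df[pos_col].iloc[i]))
    return df.iloc[order].reset_index(drop=True)


class ValidationError(ValueError):
    """Raised when input data violates the container contracts."""


@dataclass
class SampleData:
    """One tumour sample: SNP track, input segmentation, purity and ploidy."""

    sample_id: str
    purity: float
    ploidy: float
    snps: pd.DataFrame
    segments: pd.DataFrame
    group_label: str | None = None

    def __post_init__(self):
        if not (0 < self.purity <= 1):
            raise ValidationError(
                f"sample {self.sample_id}: purity must be in (0, 1], got {self.purity}"
            )
        if not self.ploidy > 0:
            raise ValidationError(
                f"sample {self.sample_id}: ploidy must be positive, got {self.ploidy}"
            )
        missing = [c for c in SNP_COLUMNS if c not in self.snps.columns]
        if missing:
            raise ValidationError(f"sample {self.sample_id}: SNP table missing {missing}")
        missing = [c for c in SEGMENT_COLUMNS if c not in self.segments.columns]
        if missing:
            raise ValidationError(
                f"sample {self.sample_id}: segment table missing {missing}"
            )
        baf = self.snps["baf"].to_numpy(float)
        ok = np.isnan(baf) | ((baf >= 0) & (baf <= 1))
        if not ok.all():
            raise ValidationError(f"sample {self.sample_id}: BAF outside [0, 1]")
        if (self.snps["pos"].to_numpy() < 1).any():
            raise ValidationError(f"sample {self.sample_id}: SNP positions must be >= 1")
        seg = self.segments
        if (seg["start"] > seg["end"]).any():
            raise ValidationError(f"sample {self.sample_id}: segment start > end")
        if (seg["cn_minor"] < 0).any() or (seg["cn_major"] < seg["cn_minor"]).any():
            raise ValidationError(
                f"sample {self.sample_id}: require cn_major >= cn_minor >= 0"
            )
        for chrom, grp in seg.groupby("chrom", sort=False):
            g = grp.sort_values("start")
            if (g["start"].to_numpy()[1:] <= g["end"].to_numpy()[:-1]).any():
                raise ValidationError(
                    f"sample {self.sample_id}: overlapping segments on {chrom}"
                )

    @property
    def het_mask(self) -> np.ndarray:
        return self.snps["is_het"].to_numpy(bool)


@dataclass
class PatientData:
    """>=2 samples of one patient sharing an identical ordered SNP panel."""

    patient_id: str
    samples: list[SampleData]
    normal_baf: pd.DataFrame | None = None  # columns chrom, pos, baf

    def __post_init__(self):
        if len(self.samples) < 2:
            raise ValidationError("at least two tumour samples required")
        ids = [s.sample_id for s in self.samples]
        if len(set(ids)) != len(ids):
            raise ValidationError(f"duplicate sample ids: {ids}")
        ref = self.samples[0].snps[["chrom", "pos"]]
        for s in self.samples[1:]:
            other = s.snps[["chrom", "pos"]]
            if len(other) != len(ref) or not (
                (other["chrom"].to_numpy() == ref["chrom"].to_numpy()).all()
                and (other["pos"].to_numpy() == ref["pos"].to_numpy()).all()
            ):
                raise ValidationError(
                    f"sample {s.sample_id}: SNP positions differ from {ids[0]}"
                )

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    def get_sample(self, sample_id: str) -> SampleData:
        for s in self.samples:
            if s.sample_id == sample_id:
                return s
        raise KeyError(sample_id)

    @property
    def n_snps(self) -> int:
        return len(self.samples[0].snps)

    @property
    def snp_positions(self) -> pd.DataFrame:
        return self.samples[0].snps[["chrom", "pos"]].copy()

    @property
    def het_mask(self) -> np.ndarray:
        return self.samples[0].het_mask
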