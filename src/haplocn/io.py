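"""Reading and writing the tool's tabular formats.

Inputs are plain TSV tables in the shape produced by single-sample
allele-specific callers (ASCAT-style segment tables, SNP BAF/LogR
tracks, a matched-normal BAF track), tied together by a small YAML
config. All coordinates are 1-based inclusive; missing values are
written as "."; no quoting.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .model import (
    PatientData,
    SampleData,
    SEGMENT_COLUMNS,
    ValidationError,
    sort_genomic,
)

logger = logging.getLogger("haplocn")

NA_REP = "."

DEFAULT_HET_RANGE = (0.3, 0.7)

# accepted column aliases for ASCAT / Sequenza style tables
_SEGMENT_ALIASES = {
    "chr": "chrom",
    "chromosome": "chrom",
    "startpos": "start",
    "start.pos": "start",
    "endpos": "end",
    "end.pos": "end",
    "nmajor": "cn_major",
    "cnt_major": "cn_major",
    "nminor": "cn_minor",
    "cnt_minor": "cn_minor",
    "sample": "sample_id",
}
_SNP_ALIASES = {
    "chr": "chrom",
    "chromosome": "chrom",
    "position": "pos",
    "baf": "baf",
    "logr": "logr",
}


def _read_tsv(path, aliases: dict, extra_map: dict | None = None) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", na_values=[NA_REP], comment="#")
    rename = {}
    for col in df.columns:
        key = col.strip().lower()
        if extra_map and col in extra_map:
            rename[col] = extra_map[col]
        elif key in aliases:
            rename[col] = aliases[key]
        else:
            rename[col] = key
    df = df.rename(columns=rename)
    df["chrom"] = df["chrom"].astype(str)
    return df


def identify_heterozygous(
    normal_baf,
    lo: float = DEFAULT_HET_RANGE[0],
    hi: float = DEFAULT_HET_RANGE[1],
) -> np.ndarray:
    """Heterozygosity flags from matched-normal BAF: lo <= baf <= hi."""
    if lo >= hi:
        raise ValueError(f"require lo < hi, got [{lo}, {hi}]")
    baf = np.asarray(normal_baf, float)
    if np.nanmin(baf) < 0 or np.nanmax(baf) > 1:
        raise ValueError("normal BAF values must lie in [0, 1]")
    return (baf >= lo) & (baf <= hi)


def read_patient(config_path) -> PatientData:
    """Load a patient from a YAML config listing per-sample input files.

    The config names, per tumour sample, a segment TSV (chrom, start,
    end, cn_major, cn_minor or ASCAT/Sequenza aliases), a SNP TSV
    (chrom, pos, baf, logr), and purity/ploidy estimates; plus an
    optional matched-normal SNP TSV (chrom, pos, baf) used to flag
    heterozygous SNPs. SNP tracks are aligned on the intersection of
    (chrom, pos) across samples; SNPs missing anywhere (position absent
    or BAF/LogR missing) are dropped patient-wide and the count logged.
    """
    config_path = Path(config_path)
    with open(config_path) as fh:
        cfg = yaml.safe_load(fh)
    base = config_path.parent
    entries = cfg.get("samples", [])
    if len(entries) < 2:
        raise ValidationError("at least two tumour samples required")
    colmap = cfg.get("column_map") or None
    lo, hi = cfg.get("het_baf_range", DEFAULT_HET_RANGE)

    snp_tables = {}
    for e in entries:
        sid = str(e["sample_id"])
        try:
            purity = float(e["purity"])
            ploidy = float(e["ploidy"])
        except (TypeError, ValueError) as exc:
            raise ValidationError(f"sample {sid}: non-numeric purity/ploidy") from exc
        snp = _read_tsv(base / e["snps"], _SNP_ALIASES, colmap)
        snp_tables[sid] = (e, purity, ploidy, sort_genomic(snp))

    # intersection of SNP positions over samples, dropping incomplete records
    keys = None
    for sid, (_, _, _, snp) in snp_tables.items():
        complete = snp.dropna(subset=["baf", "logr"])
        k = set(zip(complete["chrom"], complete["pos"]))
        keys = k if keys is None else keys & k
    chrom_sets = [set(t[3]["chrom"]) for t in snp_tables.values()]
    if not set.intersection(*chrom_sets):
        raise ValidationError("samples share no chromosomes")

    normal = None
    if cfg.get("normal_snps"):
        normal = _read_tsv(base / cfg["normal_snps"], _SNP_ALIASES, colmap)
        normal = sort_genomic(normal.dropna(subset=["baf"]))
        keys &= set(zip(normal["chrom"], normal["pos"]))

    samples = []
    for sid, (e, purity, ploidy, snp) in snp_tables.items():
        n_before = len(snp)
        mask = [(c, p) in keys for c, p in zip(snp["chrom"], snp["pos"])]
        snp = snp[mask].reset_index(drop=True)
        dropped = n_before - len(snp)
        if dropped:
            logger.info("sample %s: dropped %d SNPs absent or incomplete in "
                        "some sample", sid, dropped)
        seg = _read_tsv(base / e["segments"], _SEGMENT_ALIASES, colmap)
        seg = seg[[c for c in seg.columns if c in SEGMENT_COLUMNS]]
        samples.append((sid, e, purity, ploidy, snp, seg))

    if normal is not None:
        mask = [(c, p) in keys for c, p in zip(normal["chrom"], normal["pos"])]
        normal = normal[mask].reset_index(drop=True)
        het = identify_heterozygous(normal["baf"].to_numpy(), lo, hi)

    out = []
    for sid, e, purity, ploidy, snp, seg in samples:
        if normal is not None:
            snp = snp.assign(is_het=het)
        elif "is_het" not in snp.columns:
            raise ValidationError(
                f"sample {sid}: no normal BAF track and no is_het column"
            )
        else:
            snp["is_het"] = snp["is_het"].astype(bool)
        out.append(
            SampleData(
                sample_id=sid,
                purity=purity,
                ploidy=ploidy,
                snps=snp[["chrom", "pos", "baf", "logr", "is_het"]],
                segments=seg.reset_index(drop=True),
                group_label=e.get("group"),
            )
        )
    normal_df = normal[["chrom", "pos", "baf"]] if normal is not None else None
    return PatientData(
        patient_id=str(cfg.get("patient_id", config_path.stem)),
        samples=out,
        normal_baf=normal_df,
    )


def _write_tsv(df: pd.DataFrame, path, header_comment: str | None = None) -> None:
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        df.to_csv(fh, sep="\t", index=False, na_rep=NA_REP)


def write_patient(patient: PatientData, out_dir) -> Path:
    """Emit a patient in the input TSV dialect plus a loader config.

    Returns the path of the written YAML config (round-trips through
    read_patient).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cfg = {"patient_id": patient.patient_id, "samples": []}
    coord_note = "coordinates are 1-based inclusive"
    for s in patient.samples:
        seg_path = out_dir / f"{s.sample_id}_segments.tsv"
        snp_path = out_dir / f"{s.sample_id}_snps.tsv"
        _write_tsv(s.segments[SEGMENT_COLUMNS], seg_path, coord_note)
        _write_tsv(s.snps[["chrom", "pos", "baf", "logr", "is_het"]], snp_path,
                   coord_note)
        entry = {
            "sample_id": s.sample_id,
            "segments": seg_path.name,
            "snps": snp_path.name,
            "purity": float(s.purity),
            "ploidy": float(s.ploidy),
        }
        if s.group_label:
            entry["group"] = s.group_label
        cfg["samples"].append(entry)
    if patient.normal_baf is not None:
        normal_path = out_dir / "normal_snps.tsv"
        _write_tsv(patient.normal_baf, normal_path, coord_note)
        cfg["normal_snps"] = normal_path.name
    cfg_path = out_dir / "patient.yaml"
    with open(cfg_path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)
    return cfg_path


def write_medicc2_input(result, path) -> None:
    """Phased integer copy numbers as a MEDICC2-compatible TSV.

    One row per (sample, bin), columns sample_id, chrom, start, end,
    cn_a, cn_b, preserving each sample's phased A|B orientation; rows
    sorted by sample then genome order.
    """
    cn = result.copy_numbers
    if cn.empty:
        raise ValueError("no copy numbers to write")
    if cn[["n_a", "n_b"]].isna().any().any():
        raise ValueError("missing integer copy number for some bin")
    merged = cn.merge(result.bins[["bin_id", "chrom", "start", "end"]], on="bin_id")
    merged = merged.sort_values(["sample_id", "bin_id"])
    out = merged[["sample_id", "chrom", "start", "end", "n_a", "n_b"]].rename(
        columns={"n_a": "cn_a", "n_b": "cn_b"}
    )
    out.to_csv(path, sep="\t", index=False, na_rep=NA_REP)


def write_summary_tables(result, out_dir) -> dict:
    """Write the per-bin per-sample call table and genome-fraction table."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    per_bin = result.calls.merge(
        result.bins[["bin_id", "chrom", "start", "end", "width"]], on="bin_id"
    )
    cols = ["sample_id", "bin_id", "chrom", "start", "end", "width"]
    per_bin = per_bin[cols + [c for c in per_bin.columns if c not in cols]]
    paths = {
        "per_bin": out_dir / "bin_calls.tsv",
        "summary": out_dir / "patient_summary.tsv",
        "fractions": out_dir / "genome_fractions.tsv",
    }
    _write_tsv(per_bin, paths["per_bin"], "coordinates are 1-based inclusive")
    _write_tsv(result.summary, paths["summary"], "coordinates are 1-based inclusive")
    _write_tsv(result.fractions, paths["fractions"])
    for label, tables in (result.group_results or {}).items():
        p = out_dir / f"genome_fractions_{label}.tsv"
        _write_tsv(tables["fractions"], p)
        paths[f"fractions_{label}"] = p
    return paths


def write_phasing(result, path) -> None:
    """Per-SNP phasing TSV: chrom, pos, haplotype (A/B), reference sample."""
    _write_tsv(result.phasing, path, "coordinates are 1-based inclusive")


def write_copy_numbers(result, path) -> None:
    """Per-bin copy-number TSV with fractional and integer states."""
    merged = result.copy_numbers.merge(
        result.bins[["bin_id", "chrom", "start", "end", "flipped"]], on="bin_id"
    )
    cols = ["sample_id", "chrom", "start", "end", "n_a_frac", "n_b_frac",
            "n_a", "n_b", "method", "flipped"]
    _write_tsv(merged[cols], path, "coordinates are 1-based inclusive")
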