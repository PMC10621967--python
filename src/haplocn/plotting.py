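"""Minimal summary plot: phased copy-number tracks and event flags."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt


def plot_summary(result, path) -> None:
    """Per-sample phased copy-number step tracks plus an MSAI strip.

    One panel per sample showing n_a (orange) and n_b (blue) along the
    concatenated genome, with bins flagged MSAI shaded in the bottom
    strip.
    """
    bins = result.bins.sort_values("bin_id")
    # concatenated genome coordinate
    offsets = {}
    offset = 0
    for chrom, grp in bins.groupby("chrom", sort=False):
        offsets[chrom] = offset - grp["start"].min()
        offset += grp["end"].max() - grp["start"].min() + 1
    x0 = bins.apply(lambda r: r["start"] + offsets[r["chrom"]], axis=1)
    x1 = bins.apply(lambda r: r["end"] + offsets[r["chrom"]], axis=1)

    cn = result.copy_numbers
    sample_ids = sorted(cn["sample_id"].unique())
    fig, axes = plt.subplots(
        len(sample_ids) + 1, 1, figsize=(10, 1.6 * len(sample_ids) + 1.2),
        sharex=True, gridspec_kw={"height_ratios": [3] * len(sample_ids) + [1]},
    )
    for ax, sid in zip(axes[:-1], sample_ids):
        sub = cn[cn["sample_id"] == sid].set_index("bin_id")
        for b, lo, hi in zip(bins["bin_id"], x0, x1):
            row = sub.loc[b]
            ax.hlines(row["n_a"] + 0.05, lo, hi, color="tab:orange", lw=2)
            ax.hlines(row["n_b"] - 0.05, lo, hi, color="tab:blue", lw=2)
        ax.set_ylabel(sid, fontsize=8)
        ax.set_ylim(-0.5, max(4, cn[["n_a", "n_b"]].to_numpy().max()) + 0.5)
    strip = axes[-1]
    summary = result.summary.set_index("bin_id")
    for b, lo, hi in zip(bins["bin_id"], x0, x1):
        if summary.loc[b, "msai"]:
            strip.axvspan(lo, hi, color="tab:red", alpha=0.6)
    strip.set_yticks([])
    strip.set_ylabel("MSAI", fontsize=8)
    strip.set_xlabel("concatenated genome position (bp)")
    fig.suptitle(f"{result.patient_id}: phased copy number (A orange, B blue)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
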