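"""Horizontal phasing: orient segments along a chromosome by parsimony.

Cross-sample phasing fixes the A/B assignment within each segment but
not between neighbouring segments. Horizontal phasing chooses a flip
state per segment (exchanging n_a and n_b for all samples of that
segment) minimising the total number of copy-number breakpoints,
measured as the summed Hamming distance between the integer states of
neighbouring segments over all samples and both haplotypes. Because the
total distance decomposes over boundaries and each boundary's relative
orientation is free, a greedy per-boundary choice is globally optimal;
ties are resolved against earlier predecessors and finally default to
unflipped.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class FlipSolution:
    chrom: str
    flipped: list  # per segment, in input order
    total_distance: int


def hamming_boundary(seg_prev, seg_next) -> int:
    """Number of allele-level copy-number changes across one boundary.

    Both arguments are (n_samples, 2) integer arrays of phased (n_a,
    n_b) states with identical sample order.
    """
    prev = np.asarray(seg_prev, int)
    nxt = np.asarray(seg_next, int)
    if prev.shape != nxt.shape:
        raise ValueError("segments cover different sample sets")
    return int((prev != nxt).sum())


def phase_chromosome(segment_states, chrom: str = "") -> FlipSolution:
    """Choose per-segment flips minimising total boundary Hamming distance.

    ``segment_states`` is an ordered list of (n_samples, 2) arrays, one
    per segment along the chromosome (unphased segments are simply
    omitted by the caller, which bridges across them). The first segment
    is kept fixed. At each boundary the flipped and unflipped distances
    to the (already oriented) predecessor are compared; on a tie the
    comparison walks back to earlier predecessors, and an unresolved tie
    chain defaults to unflipped.
    """
    states = [np.asarray(s, int) for s in segment_states]
    if not states:
        return FlipSolution(chrom, [], 0)
    flipped = [False]
    oriented = [states[0]]
    for cur in states[1:]:
        cur_f = cur[:, ::-1]
        decision = False
        for prev in reversed(oriented):
            d_u = hamming_boundary(prev, cur)
            d_f = hamming_boundary(prev, cur_f)
            if d_u != d_f:
                decision = d_f < d_u
                break
        flipped.append(decision)
        oriented.append(cur_f if decision else cur)
    total = sum(
        hamming_boundary(a, b) for a, b in zip(oriented[:-1], oriented[1:])
    )
    return FlipSolution(chrom, flipped, int(total))


def chromosome_orientation(widths, oriented_states) -> bool:
    """True if the whole chromosome's A/B labels should be swapped.

    Swaps when the width-weighted mean copy number of haplotype A over
    all samples is strictly below that of haplotype B, so that on
    average haplotype A is the larger one; ties leave the labels
    unchanged. Relative phasing is unaffected by the swap.
    """
    widths = np.asarray(widths, float)
    states = np.asarray(oriented_states, float)  # (n_segments, n_samples, 2)
    if states.size == 0:
        return False
    mean_a = float(np.sum(states[:, :, 0] * widths[:, None]))
    mean_b = float(np.sum(states[:, :, 1] * widths[:, None]))
    return mean_a < mean_b
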