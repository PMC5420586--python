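"""Sliding-window genotype calling and recombination-bin construction.

Low-coverage F2 genotype matrices are too noisy for direct breakpoint
detection, so each SNP is re-called from a 15-SNP window centred on it
(step 1): per window the P1/P2 allele ratio is computed (AA adds 1 to the P1
score, BB adds 1 to the P2 score, AB adds 0.5 to each, missing excluded) and
the window is homozygous for a parent when that parent's score reaches 11/15
of the non-missing total, heterozygous otherwise.  Runs of identical per-SNP
consensus calls merge into blocks; the breakpoint between two adjacent blocks
is placed at the midpoint between the last SNP of one and the first SNP of
the next.

The chromosome is then partitioned on a fixed 100-kb grid (anchored at
coordinate 0, half-open intervals): an interval is "hot" when any
individual's breakpoint falls in it, and every maximal run of intervals
starting at a hot interval (the hot interval is assigned to the downstream
bin) becomes one bin marker, trimmed to its first/last constituent SNP.
Within a bin no recombination occurs anywhere in the population, so all SNPs
in it segregate identically and the bin acts as a single marker.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import AA, AB, BB, NA, BinMatrix, SnpMatrix

DEFAULT_WINDOW = 15
DEFAULT_HOM_MIN = 11
DEFAULT_INTERVAL = 100_000


def window_genotype(calls, hom_min: int = DEFAULT_HOM_MIN,
                    window: int = DEFAULT_WINDOW, het_mode: str = "allele") -> int:
    """Consensus genotype of one window of SNP calls.

    ``het_mode="allele"`` (default) scores AB as 0.5 to each parent;
    ``"call"`` counts AB toward neither (sensitivity-analysis variant).
    Returns NA when the window has no usable call.
    """
    g = np.asarray(calls, dtype=np.int8).reshape(-1, 1)
    if g.shape[0] == 0:
        raise ValueError("window_genotype needs at least one call")
    out = _consensus_one_chrom(g, window, hom_min, het_mode, single_window=True)
    return int(out[0, 0])


def _consensus_one_chrom(g: np.ndarray, window: int, hom_min: int,
                         het_mode: str = "allele",
                         single_window: bool = False) -> np.ndarray:
    """Per-SNP consensus calls for one chromosome (vectorized).

    ``g`` is (n_snps, n_ind).  Each SNP is governed by the window centred on
    it (offset ceil(window/2)); near chromosome ends the nearest complete
    window applies, and chromosomes shorter than one window use a single
    truncated window with the proportional threshold.
    """
    n = g.shape[0]
    if n == 0:
        return g.copy()
    valid = (g >= AA) & (g <= BB)
    s1 = np.where(g == AA, 1.0, 0.0) + np.where(g == AB, 0.5, 0.0)
    s2 = np.where(g == BB, 1.0, 0.0) + np.where(g == AB, 0.5, 0.0)
    if het_mode == "call":
        s1 = (g == AA).astype(float)
        s2 = (g == BB).astype(float)
    elif het_mode != "allele":
        raise ValueError("het_mode must be 'allele' or 'call'")
    base = valid.astype(float)

    zero = np.zeros((1, g.shape[1]))
    c1 = np.vstack([zero, np.cumsum(s1, axis=0)])
    c2 = np.vstack([zero, np.cumsum(s2, axis=0)])
    cb = np.vstack([zero, np.cumsum(base, axis=0)])

    if single_window or n <= window:
        starts = np.zeros(n, dtype=np.intp)
        ends = np.full(n, n, dtype=np.intp)
    else:
        half = window - (window + 1) // 2  # SNPs before the centre element
        starts = np.clip(np.arange(n) - half, 0, n - window)
        ends = starts + window

    w1 = c1[ends] - c1[starts]
    w2 = c2[ends] - c2[starts]
    wb = cb[ends] - cb[starts]
    thr = (hom_min / window) * wb

    out = np.full_like(g, AB)
    with np.errstate(invalid="ignore"):
        out[(wb > 0) & (w1 >= thr)] = AA
        out[(wb > 0) & (w2 >= thr)] = BB
    out[wb == 0] = NA
    return out


def _fill_deferred(cons: np.ndarray) -> np.ndarray:
    """Fill all-missing-window calls by block inheritance: forward fill along
    the chromosome, then backward fill any leading gap."""
    if not (cons == NA).any():
        return cons
    df = pd.DataFrame(np.where(cons == NA, np.nan, cons))
    df = df.ffill(axis=0).bfill(axis=0)
    return np.where(np.isnan(df.to_numpy()), NA, df.to_numpy()).astype(np.int8)


@dataclass
class BlockSet:
    """Per-individual genotype blocks and breakpoints for every chromosome.

    ``blocks[chrom][j]`` is a list of ``(start_bp, end_bp, genotype)`` for
    individual ``j`` (block bounds are the first/last SNP of the run);
    ``breakpoints[chrom][j]`` holds the midpoints between adjacent blocks.
    ``consensus`` keeps the per-SNP consensus matrix for bin genotyping.
    """

    blocks: dict
    breakpoints: dict
    consensus: np.ndarray
    snps: SnpMatrix
    samples: list


def call_blocks(snps: SnpMatrix, window: int = DEFAULT_WINDOW,
                hom_min: int = DEFAULT_HOM_MIN,
                het_mode: str = "allele") -> BlockSet:
    """Scan the genotype matrix with the sliding window and merge runs of
    identical consensus calls into blocks per individual."""
    if snps.n_snps == 0:
        raise ValueError("cannot call blocks on an empty marker set")
    cons = np.empty_like(snps.geno)
    blocks: dict = {}
    breakpoints: dict = {}
    for c in snps.chromosomes:
        sl = snps.chrom_slice(c)
        cc = _consensus_one_chrom(snps.geno[sl], window, hom_min, het_mode)
        cc = _fill_deferred(cc)
        cons[sl] = cc
        pos = snps.pos[sl]
        blist, bplist = [], []
        for j in range(snps.n_samples):
            col = cc[:, j]
            change = np.flatnonzero(col[1:] != col[:-1])  # last index of each run
            starts = np.concatenate([[0], change + 1])
            ends = np.concatenate([change, [col.size - 1]])
            blist.append([(int(pos[s]), int(pos[e]), int(col[s]))
                          for s, e in zip(starts, ends)])
            bplist.append((pos[ends[:-1]] + pos[starts[1:]]) / 2.0)
        blocks[c] = blist
        breakpoints[c] = bplist
    return BlockSet(blocks=blocks, breakpoints=breakpoints, consensus=cons,
                    snps=snps, samples=list(snps.samples))


def _grid_index(bp, interval: int) -> np.ndarray:
    """0-based half-open grid interval [k*interval, (k+1)*interval) holding a
    1-based coordinate."""
    return np.floor((np.asarray(bp, dtype=float) - 1.0) / interval).astype(np.int64)


def build_bins(blockset: BlockSet, interval: int = DEFAULT_INTERVAL) -> BinMatrix:
    """Partition each chromosome into bin markers at breakpoint-bearing
    100-kb grid intervals and genotype every individual at every bin.

    The per-individual bin genotype is the majority consensus call over the
    bin's constituent SNPs (ties broken by the last SNP); disagreement is
    only possible inside the single hot interval opening a bin, so the
    majority is the block covering the bin body.
    """
    snps = blockset.snps
    chroms, starts, ends, nsnp, genos = [], [], [], [], []
    gstarts, gends = [], []
    for c in snps.chromosomes:
        sl = snps.chrom_slice(c)
        pos = snps.pos[sl]
        cons = blockset.consensus[sl]
        bps = np.concatenate([b for b in blockset.breakpoints[c]]) \
            if blockset.breakpoints[c] else np.empty(0)
        hot = np.unique(_grid_index(bps, interval)) if bps.size else np.empty(0, np.int64)
        snp_iv = _grid_index(pos, interval)
        # SNP in a hot interval belongs to the bin that interval opens
        bin_id = np.searchsorted(hot, snp_iv, side="right")
        for b in np.unique(bin_id):
            rows = np.flatnonzero(bin_id == b)
            sub = cons[rows]
            counts = np.stack([(sub == g).sum(axis=0) for g in (AA, AB, BB)])
            call = counts.argmax(axis=0).astype(np.int8)
            tie = (counts == counts.max(axis=0)).sum(axis=0) > 1
            call[tie] = sub[-1][tie]
            call[counts.sum(axis=0) == 0] = NA
            chroms.append(c)
            starts.append(int(pos[rows[0]]))
            ends.append(int(pos[rows[-1]]))
            nsnp.append(rows.size)
            genos.append(call)
            gstarts.append(int(hot[b - 1]) if b > 0 else int(snp_iv[rows[0]]))
            gends.append(int(snp_iv[rows[-1]]))
    return BinMatrix(np.array(chroms, dtype=object), np.array(starts),
                     np.array(ends), np.array(nsnp), np.vstack(genos),
                     blockset.samples, grid_start=np.array(gstarts),
                     grid_end=np.array(gends), interval=interval)


def bin_summary(bins: BinMatrix, short_threshold: int = 600_000) -> dict:
    """Physical-length statistics of the bin markers.

    Returns per-chromosome counts and the min/mean/median/max bin length in
    bp, plus the fraction of bins shorter than ``short_threshold``.
    """
    lengths = bins.lengths().astype(float)
    per_chrom = pd.Series(bins.chrom).value_counts(sort=False)
    return {
        "n_bins": int(bins.n_bins),
        "per_chromosome": per_chrom.to_dict(),
        "min_bp": float(lengths.min()),
        "mean_bp": float(lengths.mean()),
        "median_bp": float(np.median(lengths)),
        "max_bp": float(lengths.max()),
        "frac_below_threshold": float((lengths < short_threshold).mean()),
    }
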