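"""Recombination-fraction estimation and Kosambi genetic-map construction.

Adjacent bin markers are spaced by the maximum-likelihood recombination
fraction under the standard F2 two-locus model.  With gamete classes at
frequencies (1-r)/2 (parental) and r/2 (recombinant), the nine two-locus
genotype classes have probabilities

    P(AA,AA) = P(BB,BB) = (1-r)^2 / 4        P(AA,BB) = P(BB,AA) = r^2 / 4
    P(AA,AB) = P(AB,AA) = P(AB,BB) = P(BB,AB) = r(1-r) / 2
    P(AB,AB) = ((1-r)^2 + r^2) / 2

(the double-heterozygote mixes coupling and repulsion phases, which is what
makes the MLE non-trivial).  The likelihood is maximized either by bounded
1-D optimization (default) or by the classical EM recombinant-counting
iteration; both converge to the same maximizer.

Map distances are Kosambi centimorgans, d = 25 ln((1+2r)/(1-2r)), with exact
inverse r = tanh(d/50) / 2.  Marker order is taken from the physical
(reference-genome) order and never re-estimated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from .containers import AA, AB, BB, BinMatrix, GeneticMap

#: r at/above which an adjacent pair is flagged as a map gap
GAP_RF = 0.49
#: hard cap applied before the Kosambi transform (d(0.4999) ~ 115 cM)
MAX_RF = 0.4999


def kosambi(r) -> float:
    """Kosambi map distance (cM) for recombination fraction ``r`` in [0, 0.5).

    Raises for r >= 0.5 (infinite distance): cap r below 0.5 (e.g. MAX_RF)
    before converting.
    """
    r = np.asarray(r, dtype=float)
    if np.any((r < 0) | (r >= 0.5)):
        raise ValueError("kosambi requires 0 <= r < 0.5; cap r (e.g. at "
                         f"{MAX_RF}) before converting")
    d = 25.0 * np.log((1.0 + 2.0 * r) / (1.0 - 2.0 * r))
    return float(d) if d.ndim == 0 else d


def kosambi_inv(d):
    """Inverse Kosambi: cM back to recombination fraction (exact)."""
    d = np.asarray(d, dtype=float)
    if np.any(d < 0):
        raise ValueError("map distance must be >= 0")
    r = 0.5 * np.tanh(d / 50.0)
    return float(r) if r.ndim == 0 else r


def haldane(r):
    """Haldane map distance (cM); used as a cross-check (Kosambi <= Haldane)."""
    r = np.asarray(r, dtype=float)
    return -50.0 * np.log(1.0 - 2.0 * r)


@dataclass
class RfEstimate:
    """MLE of the recombination fraction between two markers.

    ``counts`` is the 3x3 joint genotype table (rows = first marker AA/AB/BB,
    columns = second marker); ``n`` its total.  ``gap_flag`` marks estimates
    at or above GAP_RF.
    """

    r: float
    loglik: float
    counts: np.ndarray
    n: int

    @property
    def gap_flag(self) -> bool:
        return bool(self.r >= GAP_RF)


def joint_counts(gi: np.ndarray, gj: np.ndarray) -> np.ndarray:
    """3x3 joint genotype count table over individuals with both calls."""
    gi = np.asarray(gi)
    gj = np.asarray(gj)
    ok = (gi >= AA) & (gi <= BB) & (gj >= AA) & (gj <= BB)
    idx = 3 * gi[ok].astype(np.int64) + gj[ok].astype(np.int64)
    return np.bincount(idx, minlength=9).reshape(3, 3)


def _cell_probs(r: float) -> np.ndarray:
    p = np.empty((3, 3))
    p[0, 0] = p[2, 2] = (1 - r) ** 2 / 4
    p[0, 2] = p[2, 0] = r ** 2 / 4
    p[0, 1] = p[1, 0] = p[1, 2] = p[2, 1] = r * (1 - r) / 2
    p[1, 1] = ((1 - r) ** 2 + r ** 2) / 2
    return p


def f2_loglik(r: float, counts: np.ndarray) -> float:
    """Multinomial log-likelihood of the 9-cell table at recombination
    fraction ``r``."""
    p = np.clip(_cell_probs(r), 1e-300, None)
    return float(np.sum(counts * np.log(p)))


# expected recombinant gametes per individual in each cell (EM E-step);
# the double-het entry depends on r and is filled in per iteration
_REC = np.array([[0.0, 1.0, 2.0],
                 [1.0, np.nan, 1.0],
                 [2.0, 1.0, 0.0]])


def estimate_rf(gi, gj, method: str = "bounded", tol: float = 1e-8,
                max_iter: int = 200) -> RfEstimate:
    """Maximum-likelihood recombination fraction between two genotype vectors.

    ``method="bounded"`` uses 1-D bounded likelihood maximization on
    [0, 0.5]; ``method="em"`` runs the classical recombinant-counting EM
    (monotone in likelihood).  Individuals missing either call are dropped;
    fewer than 2 informative individuals is undefined and raises.
    """
    counts = joint_counts(gi, gj)
    n = int(counts.sum())
    if n < 2:
        raise ValueError("recombination fraction undefined with fewer than 2 "
                         "informative individuals (gap)")
    off_diag = counts.sum() - np.trace(counts)
    if off_diag == 0:
        # no recombinant-bearing cell observed: the MLE is exactly 0
        return RfEstimate(0.0, f2_loglik(0.0, counts), counts, n)

    if method == "bounded":
        res = minimize_scalar(lambda r: -f2_loglik(r, counts),
                              bounds=(0.0, 0.5), method="bounded",
                              options={"xatol": 1e-10})
        r = float(np.clip(res.x, 0.0, 0.5))
    elif method == "em":
        r = 0.25
        last = -np.inf
        for _ in range(max_iter):
            rec = _REC.copy()
            rec[1, 1] = 2 * r * r / ((1 - r) ** 2 + r * r)
            r_new = float((counts * rec).sum() / (2 * n))
            ll = f2_loglik(r_new, counts)
            if ll < last - 1e-9:
                raise AssertionError("EM likelihood decreased")
            r = r_new
            if ll - last < tol:
                break
            last = ll
    else:
        raise ValueError("method must be 'bounded' or 'em'")
    return RfEstimate(r, f2_loglik(r, counts), counts, n)


def build_map(bins: BinMatrix, method: str = "bounded") -> GeneticMap:
    """Cumulative Kosambi cM positions for physically ordered bins.

    The cM position of bin k is the sum of Kosambi distances over adjacent
    pairs before it on its chromosome; a chromosome with one bin has length
    0.  Pairs estimated at r >= GAP_RF are kept (chromosome assignment is
    physical) but flagged as gaps; r is capped at MAX_RF before the
    transform.
    """
    names = bins.names
    rows = []
    for c in bins.chromosomes:
        idx = bins.chrom_index(c)
        cm = 0.0
        for k, i in enumerate(idx):
            rows.append({"marker": names[i], "chrom": c,
                         "start": int(bins.start[i]), "end": int(bins.end[i]),
                         "cm": cm, "rf_next": np.nan, "gap_flag": False})
            if k + 1 < idx.size:
                est = estimate_rf(bins.geno[i], bins.geno[idx[k + 1]],
                                  method=method)
                r = min(est.r, MAX_RF)
                rows[-1]["rf_next"] = est.r
                rows[-1]["gap_flag"] = est.gap_flag
                cm += kosambi(r)
    return GeneticMap(pd.DataFrame(rows))


def summary_from_counts(n_bins, sizes_cm, max_gaps=None) -> pd.DataFrame:
    """Map summary arithmetic from per-chromosome bin counts and sizes.

    Per chromosome: average gap = size / (bins - 1).  The Total row sums
    bins and sizes, takes overall average gap = sum(sizes) / sum(bins - 1)
    and the global maximum gap.  ``attrs["mean_bins_per_group"]`` carries the
    average marker count per linkage group.
    """
    n_bins = np.asarray(n_bins, dtype=float)
    sizes = np.asarray(sizes_cm, dtype=float)
    gaps = (None if max_gaps is None else np.asarray(max_gaps, dtype=float))
    with np.errstate(divide="ignore", invalid="ignore"):
        ave = np.where(n_bins > 1, sizes / (n_bins - 1), 0.0)
    df = pd.DataFrame({
        "chromosome": [str(i + 1) for i in range(n_bins.size)],
        "n_bins": n_bins.astype(int),
        "size_cm": sizes,
        "ave_gap_cm": ave,
        "max_gap_cm": gaps if gaps is not None else np.full(n_bins.size, np.nan),
    })
    total = pd.DataFrame({
        "chromosome": ["Total"],
        "n_bins": [int(n_bins.sum())],
        "size_cm": [float(sizes.sum())],
        "ave_gap_cm": [float(sizes.sum() / np.maximum((n_bins - 1).sum(), 1))],
        "max_gap_cm": [np.nan if gaps is None else float(np.nanmax(gaps))],
    })
    out = pd.concat([df, total], ignore_index=True)
    out.attrs["mean_bins_per_group"] = float(n_bins.mean())
    return out


def map_summary(gmap: GeneticMap) -> pd.DataFrame:
    """Per-chromosome map summary (bin count, size, average and max gap)
    with a Total row, computed from a GeneticMap."""
    counts, sizes, maxg, chroms = [], [], [], []
    for c in gmap.chromosomes:
        t = gmap.chrom_table(c)
        cm = t["cm"].to_numpy()
        chroms.append(c)
        counts.append(cm.size)
        sizes.append(float(cm.max() - cm.min()) if cm.size else 0.0)
        maxg.append(float(np.diff(cm).max()) if cm.size > 1 else 0.0)
    out = summary_from_counts(counts, sizes, maxg)
    out.loc[out.index[:-1], "chromosome"] = chroms
    return out
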