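"""Segregation-pattern classification and SNP-level marker filtering.

In a biparental F2 derived from two inbred lines, only SNPs where the parents
carry different homozygous genotypes (the ``aa x bb`` pattern) segregate
informatively in a 1:2:1 ratio; the remaining CP-style patterns (ab x cd,
ef x eg, hk x hk, lm x ll, nn x np, ab x cc, cc x ab) arise from residual
parental heterozygosity or calling artefacts and are discarded for this
design.  Retained SNPs are then screened for abnormal call tokens, excess
missingness (> 25% of individuals) and segregation distortion (chi-square
test against 1:2:1, df = 2, p < 0.001), in that fixed order so each removed
SNP carries exactly one primary reason code.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .containers import AA, AB, BB, NA, ABNORMAL, SnpMatrix

# pattern labels (parent1 x parent2)
AAXBB = "aaxbb"
PATTERNS = ("abxcd", "efxeg", "hkxhk", "lmxll", "nnxnp", AAXBB, "abxcc", "ccxab")

#: filter reason codes, in priority order
REASONS = ("pattern", "abnormal", "missing", "distortion")

_MISSING_ALLELES = {".", "N", "", "?", None}


def _alleles(genotype) -> tuple | None:
    """Normalize a parental genotype ('A/A', 'AT', ('A','T'), ...) to a
    2-tuple of allele strings, or None if uncallable."""
    if genotype is None:
        return None
    if isinstance(genotype, str):
        g = genotype.replace("|", "/")
        parts = g.split("/") if "/" in g else list(g)
    else:
        parts = list(genotype)
    if len(parts) != 2:
        return None
    a, b = (str(p).upper() for p in parts)
    if a in _MISSING_ALLELES or b in _MISSING_ALLELES:
        return None
    return a, b


def classify_segregation(parent1, parent2) -> str:
    """Classify the parental genotype pair into one of the eight segregation
    patterns, ``"monomorphic"`` or ``"uninformative"`` (missing parent).

    Only ``"aaxbb"`` (both parents homozygous for different alleles) is
    retained downstream for an F2 of inbred parents.
    """
    p1, p2 = _alleles(parent1), _alleles(parent2)
    if p1 is None or p2 is None:
        return "uninformative"
    h1, h2 = p1[0] == p1[1], p2[0] == p2[1]
    s1, s2 = set(p1), set(p2)
    if h1 and h2:
        return "monomorphic" if s1 == s2 else AAXBB
    if not h1 and h2:
        return "lmxll" if s2 <= s1 else "abxcc"
    if h1 and not h2:
        return "nnxnp" if s1 <= s2 else "ccxab"
    if s1 == s2:
        return "hkxhk"
    return "efxeg" if s1 & s2 else "abxcd"


def chi2_segregation(n_aa: int, n_ab: int, n_bb: int):
    """Chi-square test of the observed genotype counts against the Mendelian
    1:2:1 F2 expectation (df = 2; missing calls excluded from the total).

    Returns ``(chi2, p)``; raises if all counts are zero.
    """
    n = n_aa + n_ab + n_bb
    if n <= 0:
        raise ValueError("chi-square test needs at least one non-missing call")
    exp = np.array([0.25, 0.5, 0.25]) * n
    obs = np.array([n_aa, n_ab, n_bb], dtype=float)
    chi2 = float(np.sum((obs - exp) ** 2 / exp))
    return chi2, float(stats.chi2.sf(chi2, df=2))


def marker_stats(snps: SnpMatrix) -> pd.DataFrame:
    """Per-SNP genotype counts, missing fraction and distortion test."""
    g = snps.geno
    n = snps.n_samples
    n_aa = (g == AA).sum(axis=1)
    n_ab = (g == AB).sum(axis=1)
    n_bb = (g == BB).sum(axis=1)
    n_abn = (g == ABNORMAL).sum(axis=1)
    n_na = n - n_aa - n_ab - n_bb - n_abn
    tot = (n_aa + n_ab + n_bb).astype(float)
    exp = np.stack([0.25 * tot, 0.5 * tot, 0.25 * tot])
    obs = np.stack([n_aa, n_ab, n_bb]).astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        chi2 = np.where(tot > 0,
                        np.nansum((obs - exp) ** 2 / np.where(exp > 0, exp, np.nan),
                                  axis=0),
                        np.nan)
    p = np.where(np.isnan(chi2), np.nan, stats.chi2.sf(np.nan_to_num(chi2), df=2))
    return pd.DataFrame({
        "chrom": snps.chrom, "pos": snps.pos,
        "n_AA": n_aa, "n_AB": n_ab, "n_BB": n_bb, "n_NA": n_na,
        "n_abnormal": n_abn,
        "missing_frac": (n_na + n_abn) / n,
        "chi2": chi2, "p": p,
    })


def filter_markers(snps: SnpMatrix, p_threshold: float = 1e-3,
                   max_missing: float = 0.25):
    """Apply the F2 marker filters; returns ``(filtered SnpMatrix, stats)``.

    A SNP is retained iff its segregation pattern is ``aaxbb`` (when pattern
    labels are present), it has no abnormal call token, its missing fraction
    is <= ``max_missing`` and its 1:2:1 distortion p-value is
    >= ``p_threshold``.  ``stats`` carries one row per input SNP with a
    ``retained`` flag and the single highest-priority removal ``reason``
    (pattern > abnormal > missing > distortion).
    """
    stats_df = marker_stats(snps)
    n_in = snps.n_snps

    bad_pattern = (np.zeros(n_in, dtype=bool) if snps.pattern is None
                   else snps.pattern != AAXBB)
    bad_abnormal = stats_df["n_abnormal"].to_numpy() > 0
    bad_missing = stats_df["missing_frac"].to_numpy() > max_missing
    with np.errstate(invalid="ignore"):
        bad_distortion = stats_df["p"].to_numpy() < p_threshold

    reason = np.full(n_in, "", dtype=object)
    for name, bad in (("distortion", bad_distortion), ("missing", bad_missing),
                      ("abnormal", bad_abnormal), ("pattern", bad_pattern)):
        reason[bad] = name  # later assignments have higher priority
    retained = reason == ""
    stats_df["retained"] = retained
    stats_df["reason"] = reason

    if not retained.any():
        warnings.warn("no SNP passed the marker filters; downstream stages "
                      "will refuse to run on an empty marker set")
    return snps.subset(retained), stats_df
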