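"""Phenotype descriptives, trait correlations and QTL-interval gene lookup.

All outputs are pure functions of their inputs: identical inputs give
byte-identical tables.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

#: canonical trait order and units for the eight yield components
TRAIT_UNITS = {
    "EAL": "cm", "EAD": "cm", "CD": "cm", "KRN": "count",
    "CGR": "count", "EW": "g", "GWP": "g", "KW": "g",
}

SUMMARY_COLUMNS = ["Trait", "P1", "P2", "Min", "Max", "Mean", "Std. Dev."]


def trait_summary(phenotypes: pd.DataFrame,
                  parent_values: dict | None = None) -> pd.DataFrame:
    """Descriptive statistics per trait, in the publication column order
    (parent values, min, max, mean, sample standard deviation).

    ``parent_values`` maps trait -> (P1, P2); traits with fewer than one
    non-missing value yield an all-NA row with a warning.
    """
    rows = []
    for trait in phenotypes.columns:
        v = pd.to_numeric(phenotypes[trait], errors="coerce").dropna()
        p1, p2 = (parent_values or {}).get(trait, (np.nan, np.nan))
        if v.empty:
            warnings.warn(f"trait {trait!r} has no non-missing values")
            rows.append([trait, p1, p2, np.nan, np.nan, np.nan, np.nan])
            continue
        sd = float(v.std(ddof=1)) if v.size > 1 else 0.0
        rows.append([trait, p1, p2, float(v.min()), float(v.max()),
                     float(v.mean()), sd])
    return pd.DataFrame(rows, columns=SUMMARY_COLUMNS)


def pearson_matrix(phenotypes: pd.DataFrame, alpha: float = 0.05):
    """Pairwise-complete Pearson correlations with two-sided t-test flags.

    Returns ``(r, significant)``: symmetric DataFrames with unit diagonal;
    pairs with fewer than 3 complete observations or zero variance are NaN
    and unflagged.
    """
    cols = list(phenotypes.columns)
    k = len(cols)
    r = np.full((k, k), np.nan)
    sig = np.zeros((k, k), dtype=bool)
    for i in range(k):
        r[i, i] = 1.0
        for j in range(i + 1, k):
            pair = phenotypes[[cols[i], cols[j]]].apply(
                pd.to_numeric, errors="coerce").dropna()
            if len(pair) < 3 or pair.iloc[:, 0].std() == 0 or pair.iloc[:, 1].std() == 0:
                continue
            rr, p = stats.pearsonr(pair.iloc[:, 0], pair.iloc[:, 1])
            r[i, j] = r[j, i] = rr
            sig[i, j] = sig[j, i] = bool(p < alpha)
    return (pd.DataFrame(r, index=cols, columns=cols),
            pd.DataFrame(sig, index=cols, columns=cols))


def load_gene_index(gff3_path, feature_type: str = "gene") -> pd.DataFrame:
    """Read gene spans from a GFF3 file into a lookup table
    (seqid, start, end, gene_id, biotype)."""
    import gffutils

    db = gffutils.create_db(str(gff3_path), ":memory:",
                            merge_strategy="create_unique", keep_order=True)
    rows = []
    for f in db.features_of_type(feature_type):
        biotype = (f.attributes.get("biotype")
                   or f.attributes.get("gene_biotype") or [""])[0]
        gene_id = (f.attributes.get("ID") or f.attributes.get("gene_id")
                   or [f.id])[0]
        rows.append({"seqid": f.seqid, "start": f.start, "end": f.end,
                     "gene_id": gene_id, "biotype": biotype})
    return pd.DataFrame(rows, columns=["seqid", "start", "end", "gene_id",
                                       "biotype"])


def annotate_interval(chrom, start: int, end: int, genes: pd.DataFrame,
                      biotype: str | None = None) -> list[str]:
    """Gene ids whose span overlaps [start, end] on ``chrom``.

    Overlap is closed on both sides (a gene abutting the interval end is
    included), strand-agnostic, returned in positional order.  A contig name
    absent from the gene table triggers a warning and an empty result.
    ``biotype`` optionally restricts to one biotype (e.g.
    ``"protein_coding"``).
    """
    if genes.empty:
        return []
    if str(chrom) not in set(genes["seqid"].astype(str)):
        warnings.warn(f"contig {chrom!r} not present in the gene annotation; "
                      f"known contigs: {sorted(set(genes['seqid'].astype(str)))}")
        return []
    g = genes[genes["seqid"].astype(str) == str(chrom)]
    if biotype is not None:
        g = g[g["biotype"] == biotype]
    hit = g[(g["start"] <= end) & (g["end"] >= start)]
    return list(hit.sort_values("start")["gene_id"])


def correlation_tsv(r: pd.DataFrame, sig: pd.DataFrame) -> pd.DataFrame:
    """Lower-triangular rendition of the correlation matrix with ``*`` flags,
    as printed in trait-correlation tables."""
    out = pd.DataFrame("", index=r.index, columns=r.columns, dtype=object)
    for i, a in enumerate(r.index):
        for j, b in enumerate(r.columns):
            if j > i:
                continue
            if i == j:
                out.iloc[i, j] = "1"
            elif np.isnan(r.iloc[i, j]):
                out.iloc[i, j] = "NA"
            else:
                star = "*" if sig.iloc[i, j] else ""
                out.iloc[i, j] = f"{r.iloc[i, j]:.3f}{star}"
    return out
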