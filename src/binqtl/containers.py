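"""Shared genotype containers for the F2 bin-map pipeline.

Genotypes are stored as small integers throughout the package:

====  =====  =============================================
code  token  meaning
====  =====  =============================================
0     AA     homozygous for the P1 allele
1     AB     heterozygous
2     BB     homozygous for the P2 allele
-1    NA     missing call
3     XX     abnormal call (token outside the four classes)
====  =====  =============================================

Matrices are SNP-major (or bin-major): ``geno[i, j]`` is the call of
individual ``j`` at marker ``i``.  Physical positions are 1-based bp.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

AA, AB, BB = 0, 1, 2
NA = -1
ABNORMAL = 3

GENO_STR = {AA: "AA", AB: "AB", BB: "BB", NA: "NA", ABNORMAL: "XX"}
STR_GENO = {"AA": AA, "AB": AB, "BA": AB, "BB": BB, "NA": NA, "": NA,
            "./.": NA, "--": NA, "NN": NA}

VALID_CODES = frozenset({AA, AB, BB, NA})


def _as_codes(values) -> np.ndarray:
    """Map an array of string tokens to genotype codes (unknown -> ABNORMAL)."""
    flat = np.asarray(values, dtype=object).ravel()
    out = np.fromiter((STR_GENO.get(v, ABNORMAL) for v in flat),
                      dtype=np.int8, count=flat.size)
    return out.reshape(np.shape(values))


def _check_positions(chrom: np.ndarray, pos: np.ndarray) -> None:
    """Positions must be strictly increasing within each chromosome and
    chromosomes must form contiguous blocks."""
    seen = {}
    last_c = None
    for c in chrom:
        if c != last_c:
            if c in seen:
                raise ValueError(f"chromosome {c!r} appears in two separate blocks")
            seen[c] = True
            last_c = c
    for c in dict.fromkeys(chrom):
        p = pos[chrom == c]
        if p.size and not np.all(np.diff(p) > 0):
            raise ValueError(f"positions not strictly increasing on chromosome {c!r}")


@dataclass
class SnpMatrix:
    """Per-SNP calls for a mapping population.

    Parameters
    ----------
    chrom, pos
        Chromosome label and 1-based physical position per SNP.
    geno
        int8 array of shape (n_snps, n_samples).
    samples
        Individual identifiers, one per genotype column.
    pattern
        Optional parental segregation-pattern label per SNP (e.g. ``"aaxbb"``).
    """

    chrom: np.ndarray
    pos: np.ndarray
    geno: np.ndarray
    samples: list[str]
    pattern: np.ndarray | None = None

    def __post_init__(self):
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.geno = np.asarray(self.geno, dtype=np.int8)
        self.samples = list(self.samples)
        if self.geno.shape != (self.pos.size, len(self.samples)):
            raise ValueError("geno shape does not match (n_snps, n_samples)")
        if self.pattern is not None:
            self.pattern = np.asarray(self.pattern, dtype=object)
            if self.pattern.size != self.pos.size:
                raise ValueError("pattern length does not match SNP count")
        _check_positions(self.chrom, self.pos)

    @property
    def n_snps(self) -> int:
        return self.pos.size

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def chromosomes(self) -> list:
        return list(dict.fromkeys(self.chrom))

    def chrom_slice(self, c) -> slice:
        idx = np.flatnonzero(self.chrom == c)
        if idx.size == 0:
            raise KeyError(c)
        return slice(int(idx[0]), int(idx[-1]) + 1)

    def subset(self, mask) -> "SnpMatrix":
        mask = np.asarray(mask)
        return SnpMatrix(
            self.chrom[mask], self.pos[mask], self.geno[mask],
            self.samples,
            None if self.pattern is None else self.pattern[mask],
        )

    # ---- I/O ------------------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        tokens = np.vectorize(GENO_STR.get)(self.geno)
        df = pd.DataFrame(tokens, columns=self.samples)
        df.insert(0, "pos", self.pos)
        df.insert(0, "chrom", self.chrom)
        return df

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "SnpMatrix":
        df = pd.read_csv(path, sep="\t", dtype={"chrom": str},
                         keep_default_na=False)
        samples = [c for c in df.columns if c not in ("chrom", "pos")]
        geno = _as_codes(df[samples].astype(str).to_numpy())
        return cls(df["chrom"].to_numpy(), df["pos"].to_numpy(), geno, samples)

    def to_vcf(self, path, contig_lengths: dict | None = None) -> None:
        """Write calls as a minimal VCF (REF=A is the P1 allele, ALT=T the P2)."""
        gt = {AA: "0/0", AB: "0/1", BB: "1/1", NA: "./.", ABNORMAL: "./."}
        with open(path, "w") as fh:
            fh.write("##fileformat=VCFv4.2\n")
            fh.write('##source=binqtl\n')
            for c in self.chromosomes:
                ln = (contig_lengths or {}).get(c, int(self.pos[self.chrom == c].max()))
                fh.write(f"##contig=<ID={c},length={ln}>\n")
            fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
            fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                     + "\t".join(self.samples) + "\n")
            for i in range(self.n_snps):
                row = "\t".join(gt[int(g)] for g in self.geno[i])
                fh.write(f"{self.chrom[i]}\t{self.pos[i]}\t.\tA\tT\t.\tPASS\t.\tGT\t{row}\n")

    @classmethod
    def from_vcf(cls, path, p1_allele: str = "ref") -> "SnpMatrix":
        """Read a VCF; by convention P1 carries the reference allele
        (``p1_allele="alt"`` swaps AA and BB)."""
        from cyvcf2 import VCF

        vcf = VCF(str(path))
        samples = list(vcf.samples)
        chroms, pos, rows = [], [], []
        # cyvcf2 gt_types: 0=hom-ref, 1=het, 2=unknown, 3=hom-alt
        lut = np.array([AA, AB, NA, BB], dtype=np.int8)
        for v in vcf:
            chroms.append(v.CHROM)
            pos.append(v.POS)
            rows.append(lut[np.asarray(v.gt_types)])
        geno = np.vstack(rows) if rows else np.empty((0, len(samples)), np.int8)
        if p1_allele == "alt":
            swapped = geno.copy()
            swapped[geno == AA] = BB
            swapped[geno == BB] = AA
            geno = swapped
        elif p1_allele != "ref":
            raise ValueError("p1_allele must be 'ref' or 'alt'")
        return cls(np.array(chroms, dtype=object), np.array(pos), geno, samples)


@dataclass
class BinMatrix:
    """Recombination-bin markers with complete per-individual genotypes.

    ``start``/``end`` are the physical positions of the first and last SNP in
    the bin (1-based, inclusive); ``grid_start``/``grid_end`` are the indices
    of the constituent 100-kb grid intervals.
    """

    chrom: np.ndarray
    start: np.ndarray
    end: np.ndarray
    n_snps: np.ndarray
    geno: np.ndarray
    samples: list[str]
    grid_start: np.ndarray | None = None
    grid_end: np.ndarray | None = None
    interval: int = 100_000

    def __post_init__(self):
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.start = np.asarray(self.start, dtype=np.int64)
        self.end = np.asarray(self.end, dtype=np.int64)
        self.n_snps = np.asarray(self.n_snps, dtype=np.int64)
        self.geno = np.asarray(self.geno, dtype=np.int8)
        self.samples = list(self.samples)
        if self.geno.shape != (self.start.size, len(self.samples)):
            raise ValueError("geno shape does not match (n_bins, n_samples)")

    @property
    def n_bins(self) -> int:
        return self.start.size

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def names(self) -> list[str]:
        return [f"mk{i + 1}" for i in range(self.n_bins)]

    @property
    def chromosomes(self) -> list:
        return list(dict.fromkeys(self.chrom))

    def chrom_index(self, c) -> np.ndarray:
        return np.flatnonzero(self.chrom == c)

    def lengths(self) -> np.ndarray:
        """Physical bin lengths in bp (span of constituent SNPs)."""
        return self.end - self.start

    def to_frame(self) -> pd.DataFrame:
        tokens = np.vectorize(GENO_STR.get)(self.geno)
        df = pd.DataFrame(tokens, columns=self.samples)
        df.insert(0, "n_snps", self.n_snps)
        df.insert(0, "end", self.end)
        df.insert(0, "start", self.start)
        df.insert(0, "chrom", self.chrom)
        df.insert(0, "marker", self.names)
        return df

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "BinMatrix":
        df = pd.read_csv(path, sep="\t", dtype={"chrom": str},
                         keep_default_na=False)
        samples = [c for c in df.columns
                   if c not in ("marker", "chrom", "start", "end", "n_snps")]
        geno = _as_codes(df[samples].astype(str).to_numpy())
        return cls(df["chrom"].to_numpy(), df["start"].to_numpy(),
                   df["end"].to_numpy(), df["n_snps"].to_numpy(), geno, samples)

    def to_bed(self, path) -> None:
        """0-based half-open BED of bin spans."""
        with open(path, "w") as fh:
            for c, s, e, name in zip(self.chrom, self.start, self.end, self.names):
                fh.write(f"{c}\t{s - 1}\t{e}\t{name}\n")


@dataclass
class GeneticMap:
    """cM coordinates for an ordered set of bin markers.

    ``table`` columns: marker, chrom, start, end, cm, rf_next, gap_flag.
    ``rf_next`` is the recombination fraction to the next bin on the same
    chromosome (NaN on the last bin); ``gap_flag`` marks pairs estimated at
    r >= 0.49 (retained, not split, since chromosome assignment is physical).
    """

    table: pd.DataFrame

    def __post_init__(self):
        needed = {"marker", "chrom", "cm"}
        if not needed.issubset(self.table.columns):
            raise ValueError(f"map table must contain columns {sorted(needed)}")

    @property
    def chromosomes(self) -> list:
        return list(dict.fromkeys(self.table["chrom"]))

    def chrom_table(self, c) -> pd.DataFrame:
        return self.table[self.table["chrom"] == c]

    def chrom_length(self, c) -> float:
        return float(self.chrom_table(c)["cm"].max())

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "GeneticMap":
        return cls(pd.read_csv(path, sep="\t", dtype={"chrom": str}))
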