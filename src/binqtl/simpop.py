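"""Synthetic F2 populations with GBS-like observation noise.

The generator emulates the data structure of a biparental maize F2 mapping
study: two inbred parents (P1, P2) are crossed, the F1 is selfed, and each F2
individual inherits two independent recombinant gametes per chromosome.
Meiosis is modelled as a Poisson (no-interference, Haldane) crossover process:
the number of crossovers per gamete per chromosome is Poisson with mean equal
to the genetic length in Morgans, and crossover positions are uniform on the
physical span, so the cM/bp rate is constant within a chromosome.

Low-coverage genotyping-by-sequencing is emulated at the call level by three
sequential perturbations of the true genotype matrix: heterozygote
undercalling (a true AB observed as AA or BB with equal probability, the
dominant artefact of sampling one allele at well under 1x depth), random
genotype errors, and missing data.  Read-level simulation is out of scope.

Phenotypes follow the standard F2 single-locus decomposition
``y = mu + sum_k (a_k * x_k + d_k * z_k) + e`` with ``x in {+1, 0, -1}`` for
{AA, AB, BB} and ``z = 1`` for AB, so a positive additive effect means the
P1 allele increases the trait.  At exact F2 frequencies one QTL contributes
genetic variance ``a^2/2 + d^2/4``; the residual variance is set so that the
summed genetic variance is the requested fraction h^2 of the total.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import AA, AB, BB, NA, GENO_STR, SnpMatrix

#: Trait short names, in the conventional yield-component order:
#: ear length, ear diameter, cob diameter, kernel row number, grains per row,
#: ear weight, grain weight per plant, 100-kernel weight.
DEFAULT_TRAITS = ("EAL", "EAD", "CD", "KRN", "CGR", "EW", "GWP", "KW")

# Approximate maize physical chromosome lengths (bp, AGPv3-scale) and the
# per-chromosome genetic lengths (cM) of a published F2 bin map; used to
# build desk-scale genomes with realistic cM/bp and SNP density.
_MAIZE_PHYS_MB = (301.4, 237.1, 232.1, 241.5, 217.9, 169.2, 176.8, 175.8, 156.8, 150.2)
_MAIZE_GEN_CM = (309.26, 382.80, 228.78, 279.34, 189.79, 153.86, 185.30, 167.92, 200.09, 139.51)


@dataclass
class GenomeSpec:
    """Physical and genetic dimensions of the simulated genome.

    Parameters
    ----------
    chrom_names
        Chromosome labels.
    phys_len
        Physical length per chromosome, bp.
    gen_len
        Genetic length per chromosome, cM (crossovers per gamete are Poisson
        with mean ``gen_len / 100``).
    snp_density
        SNPs per Mb, used when ``snp_pos`` is not given.
    snp_pos
        Optional explicit SNP positions per chromosome (1-based, strictly
        increasing, <= phys_len).
    """

    chrom_names: tuple
    phys_len: tuple
    gen_len: tuple
    snp_density: float = 15.0
    snp_pos: dict | None = None

    def __post_init__(self):
        self.chrom_names = tuple(str(c) for c in self.chrom_names)
        self.phys_len = tuple(int(x) for x in self.phys_len)
        self.gen_len = tuple(float(x) for x in self.gen_len)
        if not (len(self.chrom_names) == len(self.phys_len) == len(self.gen_len)):
            raise ValueError("chrom_names, phys_len and gen_len must have equal length")
        if any(x <= 0 for x in self.phys_len):
            raise ValueError("physical lengths must be > 0")
        if any(x < 0 for x in self.gen_len):
            raise ValueError("genetic lengths must be >= 0")
        if self.snp_pos is not None:
            self.snp_pos = {str(c): np.asarray(p, dtype=np.int64)
                            for c, p in self.snp_pos.items()}
            for c, p in self.snp_pos.items():
                L = self.phys_len[self.chrom_names.index(c)]
                if p.size and (not np.all(np.diff(p) > 0) or p[0] < 1 or p[-1] > L):
                    raise ValueError(f"invalid SNP positions on chromosome {c}")

    @classmethod
    def maize(cls, scale: float = 1.0, n_chrom: int = 10,
              snp_density: float = 15.0) -> "GenomeSpec":
        """A maize-like 10-chromosome genome, optionally scaled down.

        ``scale`` multiplies both physical and genetic lengths, preserving the
        cM/bp rate and (with fixed ``snp_density``) the SNPs-per-cM density of
        the emulated study.  ``scale=0.1`` is the desk-scale default used in
        the test suite.
        """
        n = int(n_chrom)
        return cls(
            chrom_names=tuple(str(i + 1) for i in range(n)),
            phys_len=tuple(int(m * 1e6 * scale) for m in _MAIZE_PHYS_MB[:n]),
            gen_len=tuple(g * scale for g in _MAIZE_GEN_CM[:n]),
            snp_density=snp_density,
        )

    def chrom_index(self, chrom) -> int:
        return self.chrom_names.index(str(chrom))

    def draw_snp_positions(self, chrom, rng: np.random.Generator) -> np.ndarray:
        """SNP positions for one chromosome: explicit if given, otherwise
        uniform draws at ``snp_density`` per Mb (sorted, unique)."""
        c = str(chrom)
        if self.snp_pos is not None and c in self.snp_pos:
            return self.snp_pos[c]
        L = self.phys_len[self.chrom_index(c)]
        n = max(1, int(round(self.snp_density * L / 1e6)))
        pos = np.unique(rng.integers(1, L + 1, size=int(n * 1.3) + 8))
        while pos.size < n:  # top up in the unlikely event of many collisions
            pos = np.unique(np.concatenate([pos, rng.integers(1, L + 1, size=n)]))
        take = np.sort(rng.choice(pos.size, size=n, replace=False))
        return pos[take]


@dataclass
class Qtl:
    """One simulated QTL: additive effect ``a`` (P1 allele increases the
    trait when positive), dominance effect ``d``, attached to one trait."""

    chrom: str
    pos: int
    a: float
    d: float = 0.0
    trait: str = "KW"

    def __post_init__(self):
        self.chrom = str(self.chrom)
        self.pos = int(self.pos)


@dataclass
class SimConfig:
    """Study-condition parameters for one simulated F2 experiment.

    Defaults encode the emulated study design: 199 individuals, and a
    low-coverage noise regime (10% missing calls, 1% random genotype errors,
    30% heterozygote undercalling) of the kind the sliding-window bin caller
    is designed to absorb.
    """

    n_individuals: int = 199
    missing_rate: float = 0.10
    error_rate: float = 0.01
    het_undercall_rate: float = 0.30
    qtl: tuple = ()
    h2: float | dict = 0.5
    mu: float | dict = 0.0
    traits: tuple = DEFAULT_TRAITS
    seed: int = 0

    def __post_init__(self):
        for name in ("missing_rate", "error_rate", "het_undercall_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        self.qtl = tuple(self.qtl)
        self.traits = tuple(self.traits)
        for q in self.qtl:
            if q.trait not in self.traits:
                raise ValueError(f"QTL trait {q.trait!r} not in traits")

    def h2_for(self, trait: str) -> float:
        return self.h2[trait] if isinstance(self.h2, dict) else float(self.h2)

    def mu_for(self, trait: str) -> float:
        return self.mu[trait] if isinstance(self.mu, dict) else float(self.mu)


@dataclass
class SimTruth:
    """Ground truth of one simulated population.

    ``crossovers[chrom]`` is a list over individuals of
    ``(co_pos_gamete1, start_origin1, co_pos_gamete2, start_origin2)`` where
    origins are 0 for P1 and 1 for P2 and crossover positions are strictly
    increasing bp.  ``snps`` holds the true (noise-free) genotype matrix.
    """

    genome: GenomeSpec
    snps: SnpMatrix
    crossovers: dict
    qtl: tuple = ()
    qtl_snp_index: tuple = ()

    def qtl_genotypes(self) -> np.ndarray:
        """True genotype codes at each QTL's nearest SNP, (n_qtl, n_ind)."""
        if not self.qtl_snp_index:
            return np.empty((0, self.snps.n_samples), dtype=np.int8)
        return self.snps.geno[np.asarray(self.qtl_snp_index)]


# ---------------------------------------------------------------------------
# meiosis
# ---------------------------------------------------------------------------

def simulate_gamete(genome: GenomeSpec, chrom, rng: np.random.Generator):
    """Simulate one gamete for one chromosome.

    Returns ``(crossover_positions, start_origin)``: crossover positions are
    sorted floats on (0, phys_len); the parental-origin mosaic starts at
    ``start_origin`` (0 = P1, 1 = P2) and alternates at each crossover.
    A zero genetic length gives zero crossovers (single-origin chromosome).
    """
    i = genome.chrom_index(chrom)
    n_co = rng.poisson(genome.gen_len[i] / 100.0)
    co = np.sort(rng.uniform(0.0, genome.phys_len[i], size=n_co))
    start = int(rng.integers(0, 2))
    return co, start


def gamete_origin_at(co: np.ndarray, start: int, pos: np.ndarray) -> np.ndarray:
    """Parental origin (0/1) of a gamete at the given positions."""
    return (start + np.searchsorted(co, np.asarray(pos, dtype=float))) % 2


# ---------------------------------------------------------------------------
# population
# ---------------------------------------------------------------------------

def simulate_f2(genome: GenomeSpec, config: SimConfig,
                rng: np.random.Generator | None = None):
    """Simulate an F2 population; returns ``(SimTruth, true SnpMatrix)``.

    Each individual is the union of two independent gametes, so single-locus
    genotype frequencies converge to 1:2:1.  With the default rng (derived
    from ``config.seed``) the output is byte-identical across calls.
    """
    rng = np.random.default_rng([config.seed, 0]) if rng is None else rng
    n = int(config.n_individuals)
    if n < 1:
        raise ValueError("n_individuals must be >= 1")
    samples = [f"F2_{i + 1:03d}" for i in range(n)]

    chroms, pos_all, geno_all = [], [], []
    crossovers: dict = {}
    for c in genome.chrom_names:
        pos = genome.draw_snp_positions(c, rng)
        per_ind = []
        cols = np.empty((pos.size, n), dtype=np.int8)
        for j in range(n):
            co1, s1 = simulate_gamete(genome, c, rng)
            co2, s2 = simulate_gamete(genome, c, rng)
            per_ind.append((co1, s1, co2, s2))
            cols[:, j] = (gamete_origin_at(co1, s1, pos)
                          + gamete_origin_at(co2, s2, pos)).astype(np.int8)
        crossovers[c] = per_ind
        chroms.append(np.full(pos.size, c, dtype=object))
        pos_all.append(pos)
        geno_all.append(cols)

    snps = SnpMatrix(np.concatenate(chroms), np.concatenate(pos_all),
                     np.vstack(geno_all), samples,
                     pattern=np.full(sum(p.size for p in pos_all), "aaxbb",
                                     dtype=object))

    qtl_idx = tuple(_nearest_snp(snps, q.chrom, q.pos) for q in config.qtl)
    truth = SimTruth(genome=genome, snps=snps, crossovers=crossovers,
                     qtl=config.qtl, qtl_snp_index=qtl_idx)
    return truth, snps


def _nearest_snp(snps: SnpMatrix, chrom, pos: int) -> int:
    sl = snps.chrom_slice(str(chrom))
    p = snps.pos[sl]
    return sl.start + int(np.argmin(np.abs(p - int(pos))))


# ---------------------------------------------------------------------------
# GBS observation noise
# ---------------------------------------------------------------------------

def gbs_observe(snps: SnpMatrix, config: SimConfig,
                rng: np.random.Generator | None = None):
    """Apply GBS-like noise to a true genotype matrix.

    Perturbations are applied in order: heterozygote undercall (AB -> AA or
    BB, equal odds), random error (call replaced by one of the two wrong
    categories), missing masking.  Returns ``(observed SnpMatrix, masks)``
    where ``masks`` records which calls were touched by each stage.
    With all rates zero the output equals the input.
    """
    rng = np.random.default_rng([config.seed, 1]) if rng is None else rng
    g = snps.geno.copy()
    shape = g.shape

    under = (g == AB) & (rng.random(shape) < config.het_undercall_rate)
    g[under] = np.where(rng.random(shape) < 0.5, AA, BB)[under]

    err = (g != NA) & (rng.random(shape) < config.error_rate)
    # replace by one of the two categories other than the current call
    shift = rng.integers(1, 3, size=shape)
    g[err] = ((g[err] + shift[err]) % 3).astype(np.int8)

    miss = rng.random(shape) < config.missing_rate
    g[miss] = NA

    observed = SnpMatrix(snps.chrom.copy(), snps.pos.copy(), g,
                         snps.samples,
                         None if snps.pattern is None else snps.pattern.copy())
    masks = {"het_undercall": under, "error": err, "missing": miss}
    return observed, masks


# ---------------------------------------------------------------------------
# phenotypes
# ---------------------------------------------------------------------------

def qtl_variance(a: float, d: float) -> float:
    """Genetic variance contributed by one QTL at exact F2 frequencies."""
    return a * a / 2.0 + d * d / 4.0


def effects_for_r2(r2: float, d_ratio: float = 0.0, var_p: float = 1.0):
    """Additive/dominance effects giving a QTL the target share ``r2`` of a
    total phenotypic variance ``var_p``, with ``d = d_ratio * a``."""
    a = np.sqrt(r2 * var_p / (0.5 + d_ratio ** 2 / 4.0))
    return float(a), float(d_ratio * a)


def simulate_phenotypes(truth: SimTruth, config: SimConfig,
                        rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Generate the trait table from the true QTL genotypes.

    For each trait, ``y = mu + sum(a*x + d*z) + e`` with residual variance
    chosen so the theoretical genetic variance (linkage equilibrium,
    ``sum a^2/2 + d^2/4``) is the fraction h^2 of the total.  Traits without
    QTLs are unit-variance noise.  ``h2 = 0`` with nonzero effects is
    contradictory and raises.
    """
    rng = np.random.default_rng([config.seed, 2]) if rng is None else rng
    n = truth.snps.n_samples
    qg = truth.qtl_genotypes()  # codes 0/1/2
    x = np.select([qg == AA, qg == AB, qg == BB], [1.0, 0.0, -1.0], default=np.nan)
    z = (qg == AB).astype(float)

    out = {}
    for trait in config.traits:
        idx = [k for k, q in enumerate(truth.qtl) if q.trait == trait]
        vg = sum(qtl_variance(truth.qtl[k].a, truth.qtl[k].d) for k in idx)
        y = np.full(n, config.mu_for(trait), dtype=float)
        if vg > 0:
            h2 = config.h2_for(trait)
            if not 0.0 < h2 < 1.0:
                raise ValueError(
                    f"trait {trait!r} has genetic variance {vg:.3g} but h2={h2}; "
                    "h2 must be in (0, 1) when QTL effects are nonzero")
            for k in idx:
                y += truth.qtl[k].a * x[k] + truth.qtl[k].d * z[k]
            ve = vg * (1.0 - h2) / h2
        else:
            ve = 1.0
        y += rng.normal(0.0, np.sqrt(ve), size=n)
        out[trait] = y
    return pd.DataFrame(out, index=truth.snps.samples)


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

def write_population(outdir, truth: SimTruth, observed: SnpMatrix,
                     phenotypes: pd.DataFrame) -> None:
    """Write observed genotypes (VCF + TSV), phenotypes (CSV) and the
    simulation truth (TSV sidecars) under ``outdir``."""
    import os

    os.makedirs(outdir, exist_ok=True)
    contig = dict(zip(truth.genome.chrom_names, truth.genome.phys_len))
    observed.to_vcf(os.path.join(outdir, "genotypes.vcf"), contig_lengths=contig)
    observed.to_tsv(os.path.join(outdir, "genotypes.tsv"))
    phenotypes.rename_axis("individual").to_csv(os.path.join(outdir, "phenotypes.csv"))
    truth.snps.to_tsv(os.path.join(outdir, "truth_genotypes.tsv"))
    rows = []
    for c, per_ind in truth.crossovers.items():
        for j, (co1, s1, co2, s2) in enumerate(per_ind):
            rows.append({"individual": truth.snps.samples[j], "chrom": c,
                         "gamete": 1, "start_origin": s1,
                         "crossovers": ",".join(f"{p:.1f}" for p in co1)})
            rows.append({"individual": truth.snps.samples[j], "chrom": c,
                         "gamete": 2, "start_origin": s2,
                         "crossovers": ",".join(f"{p:.1f}" for p in co2)})
    pd.DataFrame(rows).to_csv(os.path.join(outdir, "truth_crossovers.tsv"),
                              sep="\t", index=False)
    if truth.qtl:
        pd.DataFrame([{"trait": q.trait, "chrom": q.chrom, "pos": q.pos,
                       "a": q.a, "d": q.d} for q in truth.qtl]
                     ).to_csv(os.path.join(outdir, "truth_qtl.tsv"),
                              sep="\t", index=False)
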