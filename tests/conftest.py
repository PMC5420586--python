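import numpy as np
import pytest

import binqtl as bq


@pytest.fixture(scope="session")
def small_genome():
    """Three desk-scale maize-like chromosomes (~77 Mb, ~92 cM)."""
    return bq.GenomeSpec.maize(scale=0.1, n_chrom=3)


@pytest.fixture(scope="session")
def noiseless_population(small_genome):
    """n=199 F2 population with zero observation noise."""
    cfg = bq.SimConfig(n_individuals=199, seed=9, missing_rate=0.0,
                       error_rate=0.0, het_undercall_rate=0.0)
    truth, snps = bq.simulate_f2(small_genome, cfg)
    blocks = bq.call_blocks(snps)
    bins = bq.build_bins(blocks)
    return {"config": cfg, "truth": truth, "snps": snps,
            "blocks": blocks, "bins": bins}


@pytest.fixture(scope="session")
def noisy_population(small_genome):
    """n=199 F2 population under the default GBS noise regime."""
    cfg = bq.SimConfig(n_individuals=199, seed=42)
    truth, snps = bq.simulate_f2(small_genome, cfg)
    observed, masks = bq.gbs_observe(snps, cfg)
    kept, stats = bq.filter_markers(observed)
    bins = bq.build_bins(bq.call_blocks(kept))
    gmap = bq.build_map(bins)
    return {"config": cfg, "truth": truth, "snps": snps, "observed": observed,
            "masks": masks, "kept": kept, "stats": stats, "bins": bins,
            "gmap": gmap}


def true_bin_genotypes(truth, bins, snps):
    """Majority true genotype over each bin's constituent SNPs (oracle used
    by robustness checks); assumes bins were built from the same SNP set."""
    out = np.empty_like(bins.geno)
    ofs = 0
    for i in range(bins.n_bins):
        nn = int(bins.n_snps[i])
        tr = truth.snps.geno[ofs:ofs + nn]
        cnt = np.stack([(tr == k).sum(axis=0) for k in (0, 1, 2)])
        out[i] = cnt.argmax(axis=0)
        ofs += nn
    return out
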