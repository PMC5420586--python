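"""QTL detection on the bin map: composite interval mapping and LASSO.

Composite interval mapping (CIM) walks a cM grid along each chromosome and,
at every position, fits the three-component normal mixture

    y_i = mu + a * x_i + d * z_i + X_cof beta + e_i

over the unobserved QTL genotype (x in {+1, 0, -1} for {QQ, Qq, qq}, z = 1
for Qq), with mixture weights given by the flanking-bin conditional
probabilities under the no-interference F2 transition model.  The fit is by
EM (posterior-weighted least squares; the observed-data likelihood never
decreases).  LOD = log10 of the likelihood ratio against the same model
without (a, d); cofactor bins chosen by forward-backward stepwise regression
absorb background genetic variance and are dropped within a 10-cM exclusion
window of the test position.  Significance is declared against an empirical
genome-wide threshold from trait permutations (genotypes fixed, cofactors
frozen); the chi-square df=2 p-value of the LOD is reported alongside for
plotting, not for declaration.

The LASSO route fits one joint L1-penalized regression on the full
additive + dominance design (two standardized columns per bin), with the
penalty chosen by cross-validation at minimum CV error; nonzero coefficients
are re-fitted by OLS and tested by Wald tests, and a marker is declared at
-log10(p) >= 1.3 (nominal 0.05 — no genome-wide adjustment is needed in a
multiple-regression model with strong shrinkage).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .containers import AA, AB, BB, NA, BinMatrix, GeneticMap
from .linkmap import kosambi_inv

#: nominal LASSO declaration threshold on the -log10(p) scale
LASSO_LOG10P_THRESHOLD = -np.log10(0.05)

LN10 = np.log(10.0)
_X_CODE = np.array([1.0, 0.0, -1.0])  # QQ, Qq, qq
_Z_CODE = np.array([0.0, 1.0, 0.0])


# ---------------------------------------------------------------------------
# flanking-marker genotype probabilities
# ---------------------------------------------------------------------------

def _gamete_joint(r1: float, r2: float) -> np.ndarray:
    """Joint origin probabilities of one gamete at (left flank, QTL, right
    flank): origins 0 = P1 allele, 1 = P2 allele; Markov along the
    chromosome with recombination probabilities r1, r2."""
    t1 = np.array([[1 - r1, r1], [r1, 1 - r1]])
    t2 = np.array([[1 - r2, r2], [r2, 1 - r2]])
    out = np.empty((2, 2, 2))
    for l in range(2):
        for q in range(2):
            for rr in range(2):
                out[l, q, rr] = 0.5 * t1[l, q] * t2[q, rr]
    return out


def _genotype_joint(r1: float, r2: float) -> np.ndarray:
    """Joint probabilities of the F2 genotypes (left, QTL, right), each
    coded 0/1/2 = number of P2 alleles, from two independent gametes."""
    g = _gamete_joint(r1, r2)
    out = np.zeros((3, 3, 3))
    for l1 in range(2):
        for q1 in range(2):
            for r1_ in range(2):
                for l2 in range(2):
                    for q2 in range(2):
                        for r2_ in range(2):
                            out[l1 + l2, q1 + q2, r1_ + r2_] += \
                                g[l1, q1, r1_] * g[l2, q2, r2_]
    return out


def genotype_prob_table(d_left: float, d_right: float) -> np.ndarray:
    """Conditional QTL genotype probabilities given flanking bin genotypes.

    Returns ``T`` of shape (4, 4, 3): ``T[gl, gr]`` is (P(QQ), P(Qq), P(qq))
    for flank codes 0=AA, 1=AB, 2=BB, 3=missing (marginalized).  Distances
    are Kosambi cM, converted to r internally; both flanks missing gives the
    F2 prior (1/4, 1/2, 1/4).
    """
    if d_left < 0 or d_right < 0:
        raise ValueError("flanking distances must be >= 0")
    r1 = kosambi_inv(d_left)
    r2 = kosambi_inv(d_right)
    joint = _genotype_joint(r1, r2)  # (gl, q, gr)
    T = np.empty((4, 4, 3))
    for gl in range(4):
        for gr in range(4):
            j = joint
            sub = j.sum(axis=(0,)) if gl == 3 else j[gl]          # (q, gr)
            vec = sub.sum(axis=1) if gr == 3 else sub[:, gr]       # (q,)
            tot = vec.sum()
            T[gl, gr] = vec / tot if tot > 0 else np.array([0.25, 0.5, 0.25])
    # QTL genotype code order here is #P2 alleles: 0=QQ(P1P1), 1=Qq, 2=qq
    return T


def qtl_genotype_probs(flank_left, flank_right, d_left: float,
                       d_right: float) -> np.ndarray:
    """P(QQ), P(Qq), P(qq) at a test position for each individual.

    ``flank_left``/``flank_right`` are genotype codes (NA allowed) at the
    flanking bins; distances in Kosambi cM.  Rows sum to 1.
    """
    T = genotype_prob_table(d_left, d_right)
    gl = np.asarray(flank_left, dtype=np.int64).copy()
    gr = np.asarray(flank_right, dtype=np.int64).copy()
    gl[(gl < 0) | (gl > 2)] = 3
    gr[(gr < 0) | (gr > 2)] = 3
    return T[gl, gr]


# ---------------------------------------------------------------------------
# design matrices
# ---------------------------------------------------------------------------

def additive_dominance_design(bins: BinMatrix):
    """Additive (+1/0/-1) and dominance (0/1) codes per bin; missing bin
    calls (rare — bins are near-complete by construction) are imputed by the
    F2 prior expectation (x=0, z=0.5)."""
    g = bins.geno
    x = np.select([g == AA, g == AB, g == BB], [1.0, 0.0, -1.0], default=0.0)
    z = np.where(g == AB, 1.0, np.where((g < AA) | (g > BB), 0.5, 0.0))
    return x, z


def select_cofactors(bins: BinMatrix, y: np.ndarray, max_cofactors: int = 5,
                     alpha: float = 0.05) -> list[int]:
    """Forward-backward stepwise choice of cofactor bins.

    Each candidate bin contributes a 2-df (additive + dominance) term; entry
    and stay are judged on the partial F test at ``alpha``, and the set is
    capped at ``max_cofactors``.  Returns bin indices in selection order.
    ``max_cofactors=0`` returns an empty set (plain interval mapping).
    """
    y = np.asarray(y, dtype=float)
    n = y.size
    if np.var(y) == 0:
        raise ValueError("trait is constant")
    if max_cofactors <= 0:
        return []
    x, z = additive_dominance_design(bins)
    selected: list[int] = []

    def rss_of(idx: list[int]) -> float:
        X = np.column_stack([np.ones(n)]
                            + [col for i in idx for col in (x[i], z[i])])
        resid = y - X @ np.linalg.lstsq(X, y, rcond=None)[0]
        return float(resid @ resid)

    rss_cur = rss_of([])
    for _ in range(10 * max_cofactors + 10):
        changed = False
        # forward step
        if len(selected) < max_cofactors:
            best_p, best_i, best_rss = 1.0, None, None
            df2 = n - (1 + 2 * (len(selected) + 1))
            for i in range(bins.n_bins):
                if i in selected or df2 <= 0:
                    continue
                rss_new = rss_of(selected + [i])
                if rss_new <= 0:
                    continue
                F = ((rss_cur - rss_new) / 2.0) / (rss_new / df2)
                p = float(stats.f.sf(max(F, 0.0), 2, df2))
                if p < best_p:
                    best_p, best_i, best_rss = p, i, rss_new
            if best_i is not None and best_p < alpha:
                selected.append(best_i)
                rss_cur = best_rss
                changed = True
        # backward step
        if len(selected) > 1:
            worst_p, worst_i = -1.0, None
            df2 = n - (1 + 2 * len(selected))
            for i in selected:
                others = [j for j in selected if j != i]
                rss_wo = rss_of(others)
                F = ((rss_wo - rss_cur) / 2.0) / (rss_cur / max(df2, 1))
                p = float(stats.f.sf(max(F, 0.0), 2, max(df2, 1)))
                if p > worst_p:
                    worst_p, worst_i = p, i
            if worst_i is not None and worst_p >= alpha:
                selected.remove(worst_i)
                rss_cur = rss_of(selected)
                changed = True
        if not changed:
            break
    return selected


# ---------------------------------------------------------------------------
# mixture fit (EM) at one position
# ---------------------------------------------------------------------------

@dataclass
class CimFit:
    """Converged mixture fit at one scan position."""

    beta: np.ndarray          # cofactor coefficients (incl. intercept)
    a: float
    d: float
    sigma2: float
    loglik: float
    loglik0: float            # cofactor-only model
    converged: bool
    n: int
    var_y: float
    sigma2_0: float
    loglik_path: list = field(default_factory=list)

    @property
    def lod(self) -> float:
        return max((self.loglik - self.loglik0) / LN10, 0.0)

    @property
    def r2(self) -> float:
        """Percent phenotypic variance explained by the QTL term."""
        return 100.0 * max(self.sigma2_0 - self.sigma2, 0.0) / self.var_y


def _ols_loglik(y: np.ndarray, X: np.ndarray):
    beta = np.linalg.lstsq(X, y, rcond=None)[0]
    resid = y - X @ beta
    n = y.size
    s2 = max(float(resid @ resid) / n, 1e-12)
    return beta, s2, -0.5 * n * (1.0 + np.log(2.0 * np.pi * s2))


def fit_mixture(y: np.ndarray, Xc: np.ndarray, pi: np.ndarray,
                tol: float = 1e-8, max_iter: int = 100) -> CimFit:
    """EM fit of the 3-component QTL mixture regression at one position.

    ``Xc`` is the cofactor design (first column the intercept), ``pi`` the
    (n, 3) prior QTL genotype probabilities.  The observed-data
    log-likelihood is monotone across iterations; on non-convergence the
    best iterate is returned with ``converged=False``.
    """
    y = np.asarray(y, dtype=float)
    n = y.size
    p = Xc.shape[1]
    beta0, s2_0, ll0 = _ols_loglik(y, Xc)

    # stacked design: one block of rows per QTL genotype class
    Xs = np.vstack([np.column_stack([Xc,
                                     np.full(n, _X_CODE[g]),
                                     np.full(n, _Z_CODE[g])])
                    for g in range(3)])
    ys = np.tile(y, 3)

    # Haley-Knott initialization
    Ex = pi @ _X_CODE
    Ez = pi @ _Z_CODE
    theta, s2, _ = _ols_loglik(y, np.column_stack([Xc, Ex, Ez]))

    ll_prev = -np.inf
    ll = ll_prev
    converged = False
    path: list = []
    for _ in range(max_iter):
        mu = np.stack([Xc @ theta[:p] + theta[p] * _X_CODE[g]
                       + theta[p + 1] * _Z_CODE[g] for g in range(3)], axis=1)
        log_phi = -0.5 * ((y[:, None] - mu) ** 2 / s2 + np.log(2 * np.pi * s2))
        wl = np.log(np.clip(pi, 1e-300, None)) + log_phi
        m = wl.max(axis=1, keepdims=True)
        lse = m[:, 0] + np.log(np.exp(wl - m).sum(axis=1))
        ll = float(lse.sum())
        path.append(ll)
        w = np.exp(wl - lse[:, None])
        if ll - ll_prev < -1e-6:
            break  # numerical stall; keep previous iterate
        if abs(ll - ll_prev) < tol:
            converged = True
            break
        ll_prev = ll
        sw = np.sqrt(np.clip(w.T.ravel(), 0.0, None))
        theta = np.linalg.lstsq(Xs * sw[:, None], ys * sw, rcond=None)[0]
        resid = ys - Xs @ theta
        s2 = max(float((w.T.ravel() * resid ** 2).sum()) / n, 1e-12)

    ll = max(ll, ll_prev)
    return CimFit(beta=theta[:p], a=float(theta[p]), d=float(theta[p + 1]),
                  sigma2=float(s2), loglik=ll, loglik0=ll0,
                  converged=converged, n=n, var_y=float(np.var(y)),
                  sigma2_0=float(s2_0), loglik_path=path)


def effect_estimates(fit: CimFit):
    """(a, d, R^2%) of a converged peak fit."""
    return fit.a, fit.d, fit.r2


def ad_from_means(mu_qq: float, mu_het: float, mu_q2: float):
    """Additive and dominance effects from the three genotype-class means
    (P1 homozygote, heterozygote, P2 homozygote)."""
    a = (mu_qq - mu_q2) / 2.0
    d = mu_het - (mu_qq + mu_q2) / 2.0
    return a, d


# ---------------------------------------------------------------------------
# the genome scan
# ---------------------------------------------------------------------------

@dataclass
class _Position:
    chrom: str
    cm: float
    pi: np.ndarray        # (n, 3) prior probabilities
    cof_idx: tuple        # cofactors outside the exclusion window


def _grid_positions(bins: BinMatrix, gmap: GeneticMap, step: float,
                    cofactors, window: float, cof_cm):
    """Precompute grid positions with flanking-probability priors and the
    per-position cofactor sets."""
    out = []
    for c in bins.chromosomes:
        idx = bins.chrom_index(c)
        cms = gmap.table.loc[gmap.table["chrom"] == c, "cm"].to_numpy()
        length = cms[-1] if cms.size else 0.0
        grid = np.arange(0.0, length + step / 2, step)
        grid = np.clip(grid, 0.0, length)
        for pos in grid:
            j = int(np.searchsorted(cms, pos + 1e-9))
            if j == 0:
                left = right = idx[0]
                d_l = d_r = 0.0
            elif j >= cms.size:
                left = right = idx[-1]
                d_l = d_r = 0.0
            else:
                left, right = idx[j - 1], idx[j]
                d_l, d_r = pos - cms[j - 1], cms[j] - pos
            if d_l < 1e-9:
                left, right, d_l, d_r = left, left, 0.0, 0.0
            pi = qtl_genotype_probs(bins.geno[left], bins.geno[right], d_l, d_r)
            cof = tuple(i for i in cofactors
                        if not (bins.chrom[i] == c
                                and abs(cof_cm[i] - pos) <= window))
            out.append(_Position(chrom=c, cm=float(pos), pi=pi, cof_idx=cof))
    return out


@dataclass
class ScanResult:
    """Genome-scan profile for one trait.

    ``table`` columns: chrom, cm, lod, neglog10p, a, d, r2.  ``threshold``
    is the permutation LOD threshold when computed (CIM), or the nominal
    -log10(p) threshold for LASSO tracks.
    """

    trait: str
    method: str
    table: pd.DataFrame
    threshold: float | None = None
    cofactors: tuple = ()

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def cim_scan(bins: BinMatrix, gmap: GeneticMap, y, trait: str = "trait",
             cofactors: list[int] | None = None, step: float = 1.0,
             window: float = 10.0, engine: str = "em") -> ScanResult:
    """Composite interval mapping scan of one trait.

    ``cofactors`` are bin indices (from :func:`select_cofactors`); bins
    within ``window`` cM of the test position are excluded locally.
    ``engine="em"`` fits the full mixture; ``engine="hk"`` uses the
    Haley-Knott regression approximation (used internally for permutations).
    A constant trait yields LOD = 0 everywhere.
    """
    y = np.asarray(y, dtype=float)
    n = y.size
    if n != bins.n_samples:
        raise ValueError("phenotype length does not match genotype samples")
    cofactors = list(cofactors or [])
    x, z = additive_dominance_design(bins)
    mid = 0.5 * (bins.start + bins.end)
    cof_cm = gmap.table["cm"].to_numpy()
    positions = _grid_positions(bins, gmap, step, cofactors, window, cof_cm)

    if np.var(y) == 0:
        table = pd.DataFrame({"chrom": [p.chrom for p in positions],
                              "cm": [p.cm for p in positions]})
        table["lod"] = 0.0
        table["neglog10p"] = 0.0
        table["a"] = 0.0
        table["d"] = 0.0
        table["r2"] = 0.0
        return ScanResult(trait=trait, method="CIM", table=table,
                          cofactors=tuple(cofactors))

    rows = []
    for ppos in positions:
        Xc = np.column_stack([np.ones(n)]
                             + [col for i in ppos.cof_idx for col in (x[i], z[i])])
        if engine == "em":
            fit = fit_mixture(y, Xc, ppos.pi)
            lod, a, d, r2 = fit.lod, fit.a, fit.d, fit.r2
        elif engine == "hk":
            Ex = ppos.pi @ _X_CODE
            Ez = ppos.pi @ _Z_CODE
            _, s2_0, ll0 = _ols_loglik(y, Xc)
            th, s2_1, ll1 = _ols_loglik(y, np.column_stack([Xc, Ex, Ez]))
            lod = max((ll1 - ll0) / LN10, 0.0)
            a, d = float(th[-2]), float(th[-1])
            r2 = 100.0 * max(s2_0 - s2_1, 0.0) / float(np.var(y))
        else:
            raise ValueError("engine must be 'em' or 'hk'")
        p = float(stats.chi2.sf(2.0 * LN10 * lod, df=2))
        rows.append((ppos.chrom, ppos.cm, lod,
                     -np.log10(max(p, 1e-300)), a, d, r2))
    table = pd.DataFrame(rows, columns=["chrom", "cm", "lod", "neglog10p",
                                        "a", "d", "r2"])
    return ScanResult(trait=trait, method="CIM", table=table,
                      cofactors=tuple(cofactors))


def permutation_threshold(bins: BinMatrix, gmap: GeneticMap, y,
                          cofactors: list[int] | None = None,
                          n_perm: int = 1000, alpha: float = 0.05,
                          seed: int = 0, step: float = 1.0,
                          window: float = 10.0) -> float:
    """Genome-wide empirical LOD threshold from trait permutations.

    Trait values are shuffled across individuals with genotypes fixed and the
    cofactor set frozen; the (1 - alpha) quantile of the per-permutation
    genome-wide maximum LOD is returned (``alpha=1`` gives the minimum).
    LODs are computed with the vectorized Haley-Knott regression
    approximation of the mixture likelihood.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    y = np.asarray(y, dtype=float)
    n = y.size
    rng = np.random.default_rng(seed)
    Y = rng.permuted(np.tile(y, (n_perm, 1)), axis=1).T  # (n, n_perm)
    cofactors = list(cofactors or [])
    x, z = additive_dominance_design(bins)
    cof_cm = gmap.table["cm"].to_numpy()
    positions = _grid_positions(bins, gmap, step, cofactors, window, cof_cm)

    max_lod = np.zeros(n_perm)
    for ppos in positions:
        Xc = np.column_stack([np.ones(n)]
                             + [col for i in ppos.cof_idx for col in (x[i], z[i])])
        Ex = ppos.pi @ _X_CODE
        Ez = ppos.pi @ _Z_CODE
        X1 = np.column_stack([Xc, Ex, Ez])
        r0 = Y - Xc @ np.linalg.lstsq(Xc, Y, rcond=None)[0]
        r1 = Y - X1 @ np.linalg.lstsq(X1, Y, rcond=None)[0]
        rss0 = np.einsum("ij,ij->j", r0, r0)
        rss1 = np.maximum(np.einsum("ij,ij->j", r1, r1), 1e-12)
        lod = 0.5 * n * np.log10(np.maximum(rss0 / rss1, 1.0))
        np.maximum(max_lod, lod, out=max_lod)
    return float(np.quantile(max_lod, 1.0 - alpha))


# ---------------------------------------------------------------------------
# LASSO scan
# ---------------------------------------------------------------------------

def lasso_scan(bins: BinMatrix, y, trait: str = "trait", folds: int = 10,
               seed: int = 0, n_alphas: int = 30,
               prune_r: float = 0.8) -> ScanResult:
    """Joint L1-penalized additive + dominance scan of one trait.

    Builds the 2M-column standardized design (x and z per bin), picks the
    penalty by ``folds``-fold cross-validation at minimum CV error, re-fits
    the selected columns by OLS and reports per-column Wald -log10(p) in two
    tracks (additive, dominance); unselected columns get p = 1.  The
    declaration threshold is -log10(0.05) = 1.3.  An empty selection is a
    valid outcome (all p = 1).

    Adjacent bins are near-duplicate predictors, and the LASSO often spreads
    one QTL across several of them; refitting all of those together dilutes
    every Wald test.  Selected columns of the same track with genotype
    correlation >= ``prune_r`` are therefore grouped and only the strongest
    (largest standardized coefficient) member of each group enters the refit;
    absorbed columns get p = 1.  Set ``prune_r > 1`` to disable.
    """
    from sklearn.linear_model import Lasso, LassoCV
    from sklearn.model_selection import KFold

    y = np.asarray(y, dtype=float)
    n = y.size
    if n < 20:
        raise ValueError("lasso_scan needs at least 20 individuals")
    x, z = additive_dominance_design(bins)
    M = bins.n_bins
    X = np.vstack([x, z]).T  # (n, 2M): additive block then dominance block
    mean = X.mean(axis=0)
    sd = X.std(axis=0)
    keep = sd > 0
    Xs = (X[:, keep] - mean[keep]) / sd[keep]

    cv = KFold(n_splits=folds, shuffle=True, random_state=seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        # the CV path tolerates a loose stopping rule; the kept solution is
        # re-solved to high precision so the KKT conditions hold tightly
        lcv = LassoCV(cv=cv, alphas=n_alphas, eps=0.05, max_iter=5_000,
                      tol=1e-3)
        lcv.fit(Xs, y)
        final = Lasso(alpha=lcv.alpha_, max_iter=500_000, tol=1e-9)
        final.fit(Xs, y)

    coef_std = np.zeros(2 * M)
    coef_std[keep] = final.coef_
    logp = np.zeros(2 * M)
    sel = np.flatnonzero(coef_std != 0)
    effects = np.zeros(2 * M)
    effects[keep] = np.where(sd[keep] > 0, coef_std[keep] / sd[keep], 0.0)
    if sel.size:
        import statsmodels.api as sm

        refit = _prune_correlated(sel, coef_std, X, M, prune_r)
        if refit.size > n - 10:  # keep the refit well-posed
            order = np.argsort(-np.abs(coef_std[refit]))
            refit = refit[order[:n - 10]]
        Xsel = np.column_stack([np.ones(n), X[:, refit]])
        ols = sm.OLS(y, Xsel).fit()
        pvals = np.clip(ols.pvalues[1:], 1e-300, 1.0)
        logp[refit] = -np.log10(pvals)
        effects[refit] = ols.params[1:]

    mid = (0.5 * (bins.start + bins.end)).astype(float)
    table = pd.DataFrame({
        "marker": bins.names, "chrom": bins.chrom, "pos_bp": mid,
        "add_effect": effects[:M], "add_neglog10p": logp[:M],
        "dom_effect": effects[M:], "dom_neglog10p": logp[M:],
    })
    res = ScanResult(trait=trait, method="LASSO", table=table,
                     threshold=float(LASSO_LOG10P_THRESHOLD))
    res.alpha_ = float(lcv.alpha_)
    res.coef_std_ = coef_std
    res.design_std_ = Xs
    res.kept_ = keep
    return res


def _prune_correlated(sel: np.ndarray, coef_std: np.ndarray, X: np.ndarray,
                      M: int, prune_r: float) -> np.ndarray:
    """Greedy leader clustering of selected columns by |genotype correlation|
    within each track; returns the refit column set (strongest per group)."""
    if prune_r > 1.0:
        return sel
    leaders: list[int] = []
    for track in (0, 1):
        cols = sorted((s for s in sel if (s >= M) == bool(track)),
                      key=lambda s: -abs(coef_std[s]))
        mine: list[int] = []
        for s in cols:
            xs = X[:, s]
            absorbed = False
            for l in mine:
                xl = X[:, l]
                denom = xs.std() * xl.std()
                if denom > 0 and abs(np.mean((xs - xs.mean()) * (xl - xl.mean())) / denom) >= prune_r:
                    absorbed = True
                    break
            if not absorbed:
                mine.append(s)
        leaders.extend(mine)
    return np.array(sorted(leaders), dtype=np.int64)


# ---------------------------------------------------------------------------
# QTL calling
# ---------------------------------------------------------------------------

@dataclass
class QtlHit:
    """One declared QTL in the publication-table layout."""

    trait: str
    name: str
    chrom: str
    peak_cm: float
    peak_mb: float
    flank_left: str
    flank_right: str
    interval_start_bp: int
    interval_end_bp: int
    lod: float
    neglog10p: float
    a: float
    d: float
    r2: float
    method: str
    effect_type: str = ""

    @property
    def interval_100kb(self) -> str:
        return (f"{self.interval_start_bp / 1e5:,.2f}-"
                f"{self.interval_end_bp / 1e5:,.2f}")

    @property
    def physical_length_mb(self) -> float:
        return (self.interval_end_bp - self.interval_start_bp) / 1e6


def call_qtl(scan: ScanResult, bins: BinMatrix, gmap: GeneticMap,
             threshold: float, merge_cm: float = 20.0,
             lod_drop: float = 1.5) -> list[QtlHit]:
    """Declare QTL from a scan profile.

    CIM: contiguous runs of grid positions with LOD >= threshold yield one
    peak each; peaks closer than ``merge_cm`` merge into the higher one; the
    support interval is the ``lod_drop``-LOD descent on each side, reported
    via its flanking bins and their physical span.  LASSO: every bin with
    -log10(p) >= threshold on either track is a hit with its own bin as the
    interval.  Names are ``q<TRAIT>-<k>`` in genome order.
    """
    hits: list[QtlHit] = []
    if scan.method == "LASSO":
        t = scan.table
        for _, row in t.iterrows():
            for track, eff_col, p_col in (("A", "add_effect", "add_neglog10p"),
                                          ("D", "dom_effect", "dom_neglog10p")):
                if row[p_col] >= threshold:
                    i = bins.names.index(row["marker"])
                    cmv = float(gmap.table.iloc[i]["cm"])
                    hits.append(QtlHit(
                        trait=scan.trait, name="", chrom=str(row["chrom"]),
                        peak_cm=cmv, peak_mb=row["pos_bp"] / 1e6,
                        flank_left=row["marker"], flank_right=row["marker"],
                        interval_start_bp=int(bins.start[i]),
                        interval_end_bp=int(bins.end[i]),
                        lod=np.nan, neglog10p=float(row[p_col]),
                        a=float(row[eff_col]) if track == "A" else np.nan,
                        d=float(row[eff_col]) if track == "D" else np.nan,
                        r2=np.nan, method="LASSO", effect_type=track))
        hits.sort(key=lambda h: (_chrom_order(bins, h.chrom), h.peak_mb))
    else:
        t = scan.table
        for c in dict.fromkeys(t["chrom"]):
            tc = t[t["chrom"] == c].reset_index(drop=True)
            lod = tc["lod"].to_numpy()
            cmv = tc["cm"].to_numpy()
            above = lod >= threshold
            if not above.any():
                continue
            # one candidate peak per contiguous above-threshold run
            edges = np.flatnonzero(np.diff(above.astype(int)))
            bounds = np.concatenate([[0], edges + 1, [above.size]])
            peaks = []
            for s, e in zip(bounds[:-1], bounds[1:]):
                if above[s]:
                    peaks.append(s + int(np.argmax(lod[s:e])))
            # merge peaks closer than merge_cm, keeping the higher LOD
            peaks.sort(key=lambda i: cmv[i])
            merged = True
            while merged and len(peaks) > 1:
                merged = False
                for k in range(len(peaks) - 1):
                    if cmv[peaks[k + 1]] - cmv[peaks[k]] < merge_cm:
                        drop = k if lod[peaks[k]] < lod[peaks[k + 1]] else k + 1
                        peaks.pop(drop)
                        merged = True
                        break
            for pk in peaks:
                lo = pk
                while lo > 0 and lod[lo - 1] > lod[pk] - lod_drop:
                    lo -= 1
                hi = pk
                while hi + 1 < lod.size and lod[hi + 1] > lod[pk] - lod_drop:
                    hi += 1
                idx = bins.chrom_index(c)
                cms = gmap.table.loc[gmap.table["chrom"] == c, "cm"].to_numpy()
                li = idx[np.searchsorted(cms, cmv[lo] + 1e-9) - 1] \
                    if np.searchsorted(cms, cmv[lo] + 1e-9) > 0 else idx[0]
                jpos = np.searchsorted(cms, cmv[hi] - 1e-9)
                ri = idx[min(jpos, idx.size - 1)]
                pj = np.searchsorted(cms, cmv[pk]) if cms.size else 0
                pj = min(pj, idx.size - 1)
                peak_mb = 0.5 * (bins.start[idx[pj]] + bins.end[idx[pj]]) / 1e6
                hits.append(QtlHit(
                    trait=scan.trait, name="", chrom=str(c),
                    peak_cm=float(cmv[pk]), peak_mb=float(peak_mb),
                    flank_left=bins.names[li], flank_right=bins.names[ri],
                    interval_start_bp=int(bins.start[li]),
                    interval_end_bp=int(bins.end[ri]),
                    lod=float(lod[pk]),
                    neglog10p=float(tc["neglog10p"].iloc[pk]),
                    a=float(tc["a"].iloc[pk]), d=float(tc["d"].iloc[pk]),
                    r2=float(tc["r2"].iloc[pk]), method="CIM"))
        hits.sort(key=lambda h: (_chrom_order(bins, h.chrom), h.peak_cm))
    for k, h in enumerate(hits):
        h.name = f"q{scan.trait}-{k + 1}"
    return hits


def _chrom_order(bins: BinMatrix, c: str) -> int:
    chroms = [str(x) for x in bins.chromosomes]
    return chroms.index(str(c)) if str(c) in chroms else len(chroms)


def qtl_table(hits: list[QtlHit]) -> pd.DataFrame:
    """Publication-style QTL table (one row per hit)."""
    return pd.DataFrame([{
        "Trait": h.trait, "QTL": h.name, "Chr": h.chrom,
        "Flanking markers": (h.flank_left if h.flank_left == h.flank_right
                             else f"{h.flank_left}-{h.flank_right}"),
        "Positions (Mb)": round(h.peak_mb, 2),
        "Interval (100 Kb)": h.interval_100kb,
        "Physical length (Mb)": round(h.physical_length_mb, 3),
        "LOD": round(h.lod, 1) if np.isfinite(h.lod) else "",
        "ADD": round(h.a, 2) if np.isfinite(h.a) else "",
        "DOM": round(h.d, 2) if np.isfinite(h.d) else "",
        "R2 (%)": round(h.r2, 1) if np.isfinite(h.r2) else "",
        "Method": h.method,
    } for h in hits])
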