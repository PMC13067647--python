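"""Weighted GBLUP, restricted LRT, mixed-model GWAS and signal annotation.

The recombination traits are parent-level means over unequal progeny
counts, so residual variances are heteroscedastic: all models use a
diagonal residual covariance D sigma_e^2 with d_i = 1/n_i (reciprocal
progeny-count weights).

Univariate model:  y = 1 mu + Z u + e,  u ~ N(0, G sigma_g^2),
e ~ N(0, D sigma_e^2); genomic heritability h2 = sigma_g^2 /
(sigma_g^2 + sigma_e^2).  REML is computed exactly on a one-dimensional
profile after rotating by the eigendecomposition of the weight-transformed
G, so the univariate fit involves no iterative linear-mixed-model solver.

Bivariate (cross-sex) model:  y = W b + Z u + e with
u = (u_s, u_d)' ~ N(0, Sigma kron G); fitted by EM-REML with an explicit
iteration cap and non-convergence flag, since boundary cases (small
samples) routinely fail to converge.

GWAS adds a per-SNP fixed effect m (model y = 1 mu + X m + Z u + e) and
tests T = m_hat / SE(m_hat) against a standard normal; by default the
variance components are fixed at the null fit (P3D), with exact per-SNP
REML available behind a flag.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import minimize_scalar

from .maps import PhysicalMap
from .popsim import MISSING

GRM_RIDGE = 1e-8


# ---------------------------------------------------------------------------
# Genotype filtering and GRM
# ---------------------------------------------------------------------------

def filter_missingness(
    genotypes: np.ndarray,
    ids: np.ndarray,
    markers: PhysicalMap,
    indiv_max: float = 0.20,
    marker_max: float = 0.20,
) -> tuple[np.ndarray, np.ndarray, PhysicalMap]:
    """Drop individuals then markers with too many missing calls (<= thresholds kept)."""
    miss_i = np.mean(genotypes == MISSING, axis=1)
    keep_i = miss_i <= indiv_max
    geno = genotypes[keep_i]
    miss_m = np.mean(geno == MISSING, axis=0) if geno.size else np.ones(genotypes.shape[1])
    keep_m = miss_m <= marker_max
    return geno[:, keep_m], ids[keep_i], markers.subset(keep_m)


def build_grm(genotypes: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Genomic relationship matrix, VanRaden method 1 with observed frequencies.

    Missing calls are mean-imputed per marker (for G only); monomorphic
    markers are excluded.  Returns (G, allele frequencies of used markers,
    used-marker index).
    """
    g = genotypes.astype(float)
    g[genotypes == MISSING] = np.nan
    f = np.nanmean(g, axis=0) / 2.0
    poly = (f > 0) & (f < 1) & ~np.isnan(f)
    if not poly.any():
        raise ValueError("no polymorphic markers for the GRM")
    g = g[:, poly]
    f = f[poly]
    g = np.where(np.isnan(g), 2 * f[None, :], g)
    Z = g - 2 * f[None, :]
    denom = 2.0 * np.sum(f * (1 - f))
    G = (Z @ Z.T) / denom
    G = 0.5 * (G + G.T)
    return G, f, np.flatnonzero(poly)


# ---------------------------------------------------------------------------
# Univariate weighted GBLUP (exact REML on the eigen-rotated profile)
# ---------------------------------------------------------------------------

@dataclass
class VarianceComponents:
    sigma_g2: float
    sigma_e2: float
    h2: float
    loglik: float
    converged: bool
    n_iter: int
    mu: np.ndarray
    blup: np.ndarray = field(repr=False, default=None)

    def __post_init__(self) -> None:
        if self.sigma_g2 < 0 or self.sigma_e2 < 0:
            raise ValueError("variance components must be non-negative")


def _reml_profile(z, x, lam_eig, lam):
    """Restricted log-likelihood pieces at ratio lam = sigma_g2/sigma_e2."""
    n, p = x.shape
    v = 1.0 + lam * lam_eig
    xv = x / v[:, None]
    xtvx = x.T @ xv
    beta = np.linalg.solve(xtvx, xv.T @ z)
    r = z - x @ beta
    rss = float(np.sum(r * r / v))
    sigma_e2 = rss / (n - p)
    sign, logdet_x = np.linalg.slogdet(xtvx)
    ll = -0.5 * (
        (n - p) * (np.log(2 * np.pi * sigma_e2) + 1.0)
        + np.sum(np.log(v))
        + logdet_x
    )
    return ll, sigma_e2, beta


def fit_weighted_gblup(
    y: np.ndarray,
    G: np.ndarray,
    weights: np.ndarray | None = None,
    X: np.ndarray | None = None,
    fix_lambda: float | None = None,
    max_iter: int = 100,
) -> VarianceComponents:
    """REML fit of y = X beta + u + e with u ~ N(0, G sg2), e ~ N(0, D se2).

    ``weights`` are the progeny counts n_i (D = diag(1/n_i)); omitted
    weights mean homoscedastic residuals.  ``X`` defaults to an intercept.
    ``fix_lambda`` pins sigma_g2/sigma_e2 (0 gives the no-genomic-variance
    null fit used by the restricted LRT).
    """
    y = np.asarray(y, dtype=float)
    n = y.size
    if G.shape != (n, n):
        raise ValueError("G must match the phenotype vector")
    w = np.ones(n) if weights is None else np.asarray(weights, dtype=float)
    if np.any(w <= 0):
        raise ValueError("weights must be positive")
    X = np.ones((n, 1)) if X is None else np.atleast_2d(X.astype(float))
    sw = np.sqrt(w)
    Gt = G * np.outer(sw, sw)
    Gt = Gt + GRM_RIDGE * np.eye(n)
    lam_eig, U = np.linalg.eigh(Gt)
    lam_eig = np.clip(lam_eig, 0.0, None)
    z = U.T @ (sw * y)
    x = U.T @ (X * sw[:, None])

    n_iter = 0
    if fix_lambda is not None:
        lam = float(fix_lambda)
        converged = True
    else:
        def neg(loglam):
            return -_reml_profile(z, x, lam_eig, 10.0 ** loglam)[0]

        res = minimize_scalar(
            neg, bounds=(-8.0, 6.0), method="bounded",
            options={"xatol": 1e-6, "maxiter": max_iter},
        )
        lam = float(10.0 ** res.x)
        n_iter = int(res.nfev)
        converged = bool(res.success) and n_iter <= max_iter
        # treat a boundary solution at the lower bound as sigma_g2 = 0
        if res.x <= -7.99:
            lam = 0.0
    ll, sigma_e2, beta = _reml_profile(z, x, lam_eig, lam)
    sigma_g2 = lam * sigma_e2
    h2 = sigma_g2 / (sigma_g2 + sigma_e2) if sigma_g2 + sigma_e2 > 0 else 0.0
    V = sigma_g2 * G + sigma_e2 * np.diag(1.0 / w) + GRM_RIDGE * np.eye(n)
    resid = y - X @ beta
    blup = sigma_g2 * (G @ np.linalg.solve(V, resid))
    return VarianceComponents(
        sigma_g2=float(sigma_g2),
        sigma_e2=float(sigma_e2),
        h2=float(h2),
        loglik=float(ll),
        converged=converged,
        n_iter=n_iter,
        mu=beta,
        blup=blup,
    )


def rlrt_genomic_variance(fit_full: VarianceComponents, fit_null: VarianceComponents) -> float:
    """Restricted LRT P value for sigma_g2 > 0.

    The null distribution on the boundary is a 50:50 mixture of a point
    mass at zero and chi-square with 1 df, so P = 0.5 * Pr(chi2_1 > LRT)
    for LRT > 0 and P = 0.5 at LRT = 0.
    """
    lrt = 2.0 * (fit_full.loglik - fit_null.loglik)
    if lrt < 0:
        if lrt < -1e-6:
            warnings.warn(f"negative restricted LRT ({lrt:.3g}) set to 0")
        lrt = 0.0
    if lrt == 0.0:
        return 0.5
    return float(0.5 * stats.chi2.sf(lrt, df=1))


# ---------------------------------------------------------------------------
# Bivariate (cross-sex) GBLUP by EM-REML
# ---------------------------------------------------------------------------

@dataclass
class BivariateComponents:
    sigma: np.ndarray  # 2x2 genetic (co)variance matrix Sigma
    sigma_e2: float
    correlation: float
    b: np.ndarray
    converged: bool
    n_iter: int


def fit_bivariate_gblup(
    y_sires: np.ndarray,
    y_dams: np.ndarray,
    G: np.ndarray,
    weights: np.ndarray | None = None,
    max_iter: int = 100,
    tol: float = 1e-5,
) -> BivariateComponents:
    """Cross-sex GBLUP: u = (u_s, u_d)' ~ N(0, Sigma kron G), sex as fixed effect.

    ``G`` covers all parents, sires first then dams, matching the
    concatenated phenotype vector.  EM-REML with ``max_iter`` cap; a fit
    that has not converged is returned with ``converged=False`` rather
    than raising, mirroring how such analyses behave on small samples.
    """
    ns, nd = y_sires.size, y_dams.size
    if ns == 0 or nd == 0:
        raise ValueError("both sexes must be present")
    n = ns + nd
    if G.shape != (n, n):
        raise ValueError("G must cover sires and dams jointly")
    y = np.concatenate([y_sires, y_dams])
    w = np.ones(n) if weights is None else np.asarray(weights, dtype=float)
    Dinv = w  # D = diag(1/n_i) so D^-1 = diag(n_i)
    W = np.column_stack([np.ones(n), np.r_[np.zeros(ns), np.ones(nd)]])
    p = W.shape[1]
    Ginv = np.linalg.inv(G + GRM_RIDGE * np.eye(n))
    # Z: observation i of sex s loads u_s[i]; u = (u_s stacked over all parents, u_d ditto)
    Z = np.zeros((n, 2 * n))
    Z[np.arange(ns), np.arange(ns)] = 1.0
    Z[ns + np.arange(nd), n + ns + np.arange(nd)] = 1.0

    Sigma = np.array([[np.var(y_sires) / 2 + 1e-6, 0.0], [0.0, np.var(y_dams) / 2 + 1e-6]])
    sigma_e2 = float(np.var(y) / 2 + 1e-6)
    T = np.column_stack([W, Z])
    TD = T * Dinv[:, None]
    TtDT = TD.T @ T
    TtDy = TD.T @ y
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        SigInv = np.linalg.inv(Sigma + 1e-10 * np.eye(2))
        Gbig_inv = np.kron(SigInv, Ginv)
        A = TtDT.copy()
        A[p:, p:] += sigma_e2 * Gbig_inv
        Ainv = np.linalg.inv(A)
        sol = Ainv @ TtDy
        b = sol[:p]
        u = sol[p:]
        us, ud = u[:n], u[n:]
        Cuu = Ainv[p:, p:]
        new = np.empty((2, 2))
        for a_i, ua in ((0, us), (1, ud)):
            for b_i, ub in ((0, us), (1, ud)):
                blk = Cuu[a_i * n : (a_i + 1) * n, b_i * n : (b_i + 1) * n]
                new[a_i, b_i] = (ua @ Ginv @ ub + sigma_e2 * np.trace(Ginv @ blk)) / n
        new = 0.5 * (new + new.T)
        e = y - T @ sol
        trace_term = (p + 2 * n) - sigma_e2 * float(np.sum(Gbig_inv * Cuu))
        sigma_e2_new = float((e * Dinv @ e + sigma_e2 * trace_term) / n)
        delta = max(
            float(np.max(np.abs(new - Sigma))), abs(sigma_e2_new - sigma_e2)
        ) / max(sigma_e2, 1e-12)
        Sigma, sigma_e2 = new, sigma_e2_new
        if delta < tol:
            converged = True
            break
    corr = float(Sigma[0, 1] / np.sqrt(max(Sigma[0, 0] * Sigma[1, 1], 1e-300)))
    corr = float(np.clip(corr, -1.0, 1.0))
    return BivariateComponents(
        sigma=Sigma, sigma_e2=sigma_e2, correlation=corr, b=b,
        converged=converged, n_iter=it,
    )


# ---------------------------------------------------------------------------
# GWAS
# ---------------------------------------------------------------------------

def gwas_scan(
    y: np.ndarray,
    genotypes: np.ndarray,
    markers: PhysicalMap,
    G: np.ndarray,
    weights: np.ndarray | None = None,
    null_fit: VarianceComponents | None = None,
    strong: float = 1e-5,
    suggestive: float = 1e-4,
    per_snp_reml: bool = False,
) -> pd.DataFrame:
    """Single-SNP mixed-model association scan.

    By default variance components are fixed at the null GBLUP fit (P3D)
    and each SNP effect is a generalised-least-squares estimate under the
    null covariance V = sigma_g2 G + sigma_e2 D; ``per_snp_reml`` re-fits
    the variance components for every SNP instead.  Individuals missing a
    SNP's genotype are excluded for that SNP; monomorphic SNPs are
    skipped.  Returns one row per tested SNP with effect, SE,
    T = effect/SE, P = 2[1 - Phi(|T|)], Benjamini-Hochberg adjusted P and
    a strong/suggestive flag.
    """
    y = np.asarray(y, dtype=float)
    n = y.size
    w = np.ones(n) if weights is None else np.asarray(weights, dtype=float)
    if null_fit is None:
        null_fit = fit_weighted_gblup(y, G, weights=w)
    V = null_fit.sigma_g2 * G + null_fit.sigma_e2 * np.diag(1.0 / w)
    V += GRM_RIDGE * np.eye(n)
    Vinv = np.linalg.inv(V)
    one = np.ones(n)
    rows = []
    for s in range(genotypes.shape[1]):
        x = genotypes[:, s].astype(float)
        obs = genotypes[:, s] != MISSING
        xs = x[obs]
        f = xs.mean() / 2.0 if obs.any() else np.nan
        if not obs.any() or f <= 0.0 or f >= 1.0:
            continue
        if per_snp_reml:
            fit = fit_weighted_gblup(
                y[obs], G[np.ix_(obs, obs)], weights=w[obs],
                X=np.column_stack([one[obs], xs]),
            )
            Vs = fit.sigma_g2 * G[np.ix_(obs, obs)] + fit.sigma_e2 * np.diag(1.0 / w[obs])
            Vs += GRM_RIDGE * np.eye(int(obs.sum()))
            Ai = np.linalg.inv(Vs)
        elif obs.all():
            Ai = Vinv
        else:
            Ai = np.linalg.inv(V[np.ix_(obs, obs)])
        Xs = np.column_stack([one[obs], xs])
        XtAX = Xs.T @ Ai @ Xs
        XtAy = Xs.T @ Ai @ y[obs]
        C = np.linalg.inv(XtAX)
        beta = C @ XtAy
        m_hat = float(beta[1])
        se = float(np.sqrt(C[1, 1]))
        T = m_hat / se
        P = float(2.0 * stats.norm.sf(abs(T)))
        rows.append(
            (markers.marker_id[s], int(markers.chrom[s]), int(markers.pos_bp[s]),
             float(f), m_hat, se, T, max(P, 5e-324))
        )
    out = pd.DataFrame(
        rows, columns=["snp", "chrom", "bp", "freq", "effect", "se", "T", "P"]
    )
    if len(out):
        out["P_BH"] = benjamini_hochberg(out["P"].to_numpy())
        out["flag"] = np.where(
            out["P"] < strong, "strong", np.where(out["P"] < suggestive, "suggestive", "")
        )
    return out


def benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    """Step-up FDR adjustment (monotone in rank order)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        raise ValueError("empty P value list")
    from statsmodels.stats.multitest import multipletests

    return multipletests(p, method="fdr_bh")[1]


def region_variance(
    results: pd.DataFrame, chrom: int, begin_bp: int, end_bp: int
) -> dict:
    """Variance explained by the SNPs of a region: sigma_x2 = sum 2 f (1-f) m^2."""
    sel = results[
        (results["chrom"] == chrom)
        & (results["bp"] >= begin_bp)
        & (results["bp"] <= end_bp)
    ]
    if len(sel) == 0:
        raise ValueError("region contains no tested SNP")
    f = sel["freq"].to_numpy()
    m = sel["effect"].to_numpy()
    return {
        "chrom": int(chrom),
        "begin_bp": int(begin_bp),
        "end_bp": int(end_bp),
        "n_snps": int(len(sel)),
        "sigma_x2": float(np.sum(2 * f * (1 - f) * m**2)),
        "min_P": float(sel["P"].min()),
    }


def signal_regions(
    results: pd.DataFrame,
    suggestive: float = 1e-4,
    min_signals: int = 3,
    merge_bp: int = 5_000_000,
) -> pd.DataFrame:
    """Chromosome regions supported by at least ``min_signals`` signals.

    Suggestive-or-stronger SNPs on one chromosome are chained while
    consecutive signals lie within ``merge_bp``; each retained chain is
    summarised by :func:`region_variance`.
    """
    hits = results[results["P"] < suggestive].sort_values(["chrom", "bp"])
    regions = []
    for chrom, sub in hits.groupby("chrom"):
        bp = sub["bp"].to_numpy()
        splits = np.flatnonzero(np.diff(bp) > merge_bp) + 1
        for grp in np.split(np.arange(bp.size), splits):
            if grp.size >= min_signals:
                regions.append(
                    region_variance(results, int(chrom), int(bp[grp[0]]), int(bp[grp[-1]]))
                )
    return pd.DataFrame(regions)


def annotate_signals(
    results: pd.DataFrame,
    gene_table: pd.DataFrame | None,
    window_bp: int = 500_000,
    suggestive: float = 1e-4,
) -> pd.DataFrame:
    """Genes within +-window_bp of each significant or suggestive SNP.

    ``gene_table`` needs columns (chrom, start, end, name).  Genes are
    listed nearest first (distance 0 when the SNP lies inside the gene).
    """
    if gene_table is None or len(gene_table) == 0:
        warnings.warn("no gene table supplied; skipping annotation")
        return pd.DataFrame(columns=["snp", "chrom", "bp", "P", "gene", "distance_bp"])
    hits = results[results["P"] < suggestive]
    rows = []
    for _, snp in hits.iterrows():
        genes = gene_table[gene_table["chrom"] == snp["chrom"]]
        lo, hi = snp["bp"] - window_bp, snp["bp"] + window_bp
        near = genes[(genes["end"] >= lo) & (genes["start"] <= hi)]
        for _, g in near.iterrows():
            if g["start"] <= snp["bp"] <= g["end"]:
                dist = 0
            else:
                dist = int(min(abs(g["start"] - snp["bp"]), abs(g["end"] - snp["bp"])))
            rows.append((snp["snp"], snp["chrom"], snp["bp"], snp["P"], g["name"], dist))
    out = pd.DataFrame(rows, columns=["snp", "chrom", "bp", "P", "gene", "distance_bp"])
    return out.sort_values(["snp", "distance_bp"]).reset_index(drop=True)


# ---------------------------------------------------------------------------
# Fixed-effects sex x breed contrasts
# ---------------------------------------------------------------------------

def anova_sex_breed(traits: pd.DataFrame, trait: str = "nco") -> dict:
    """Weighted linear-model analysis of sex, breed and their interaction.

    ``traits`` needs columns (sex, breed, n_progeny, <trait>); progeny
    number is the weighting term.  Returns the global F table (type II),
    least-squares means per sex and per breed with standard errors, and
    Tukey-adjusted pairwise comparisons within each factor.
    """
    import statsmodels.formula.api as smf
    from statsmodels.stats.anova import anova_lm

    df = traits.rename(columns={trait: "y"}).copy()
    for col in ("sex", "breed"):
        if df[col].nunique() < 2:
            raise ValueError(f"need >= 2 levels of {col}")
    model = smf.wls("y ~ C(sex) * C(breed)", data=df, weights=df["n_progeny"]).fit()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        ftable = anova_lm(model, typ=2)

    def _lsmeans(factor: str) -> tuple[pd.DataFrame, pd.DataFrame]:
        other = "breed" if factor == "sex" else "sex"
        levels = sorted(df[factor].unique())
        other_levels = sorted(df[other].unique())
        means, rows = [], []
        for lev in levels:
            import patsy

            grid = pd.DataFrame({factor: lev, other: other_levels})
            Xmat = patsy.dmatrix(model.model.data.design_info, grid, return_type="dataframe")
            c = Xmat.mean(axis=0).to_numpy()
            est = float(c @ model.params)
            se = float(np.sqrt(c @ model.cov_params().to_numpy() @ c))
            means.append((lev, est, se))
            rows.append(c)
        ls = pd.DataFrame(means, columns=[factor, "lsmean", "se"])
        k = len(levels)
        dfres = model.df_resid
        pairs = []
        for i in range(k):
            for j in range(i + 1, k):
                c = rows[i] - rows[j]
                diff = float(c @ model.params)
                se = float(np.sqrt(c @ model.cov_params().to_numpy() @ c))
                t = diff / se
                padj = float(stats.studentized_range.sf(abs(t) * np.sqrt(2), k, dfres))
                pairs.append((levels[i], levels[j], diff, se, t, min(padj, 1.0)))
        pw = pd.DataFrame(
            pairs, columns=["level_a", "level_b", "diff", "se", "t", "P_tukey"]
        )
        return ls, pw

    ls_sex, pw_sex = _lsmeans("sex")
    ls_breed, pw_breed = _lsmeans("breed")
    return {
        "anova": ftable,
        "model": model,
        "lsmeans_sex": ls_sex,
        "pairwise_sex": pw_sex,
        "lsmeans_breed": ls_breed,
        "pairwise_breed": pw_breed,
    }
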