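"""Genotype x environment association scans.

The environmental drought index of each accession's collection site is
regressed on candidate-gene markers, with population structure handled
three ways of increasing stringency:

* GLM  - ordinary least squares with principal-component covariates;
* MLM  - single-random-effect kinship mixed model
         y = g*beta + PCs*gamma + u + e,  u ~ N(0, sigma_g^2 K),
         fitted by REML with one spectral decomposition of the kinship
         matrix reused across markers (EMMA / P3D style);
* CMLM - the same mixed model after compressing individuals into
         kinship-clustered groups, with the group count chosen by the
         null-model REML likelihood.

A haplotype-level variant treats the haplotype class as a multi-level
fixed factor in the kinship mixed model and reports an omnibus test.

Significance follows the dual convention of candidate-gene designs:
``sig05`` for p < 0.05 and ``sig01`` for p <= 0.01, the latter serving
as an FDR-equivalent cutoff for a small a-priori marker panel.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .structure import HaplotypeSet, pca_genotypes
from .variants import GenotypeMatrix

logger = logging.getLogger(__name__)

RESULT_COLUMNS = ["gene", "marker", "index", "model", "effect", "p", "sig05", "sig01"]

#: Eigenvalue floor used to bend non-positive-semidefinite kinship matrices.
EIG_FLOOR = 1e-6


@dataclass
class ModelSpec:
    """Covariate / random-effect specification shared by the scans."""

    n_pcs: int = 2
    kinship: np.ndarray | None = None  # individuals x individuals
    compression_grid: tuple | None = None  # group counts for CMLM; None = default


def _pc_covariates(gm: GenotypeMatrix, n_pcs: int) -> np.ndarray:
    if n_pcs == 0:
        return np.empty((gm.n, 0))
    scores, _ = pca_genotypes(gm, n_components=n_pcs)
    return scores.drop(columns="taxon").to_numpy()


def _flag(frame: pd.DataFrame) -> pd.DataFrame:
    frame["sig05"] = frame["p"] < 0.05
    frame["sig01"] = frame["p"] <= 0.01
    return frame


# ---------------------------------------------------------------------------
# GLM

def glm_scan(
    gm: GenotypeMatrix,
    env: np.ndarray,
    spec: ModelSpec | None = None,
    index_name: str = "env",
) -> pd.DataFrame:
    """Per-SNP ordinary least squares of the index on genotype + PCs.

    Individuals with a missing genotype are dropped per SNP; SNPs that
    are constant after dropping are skipped with a log entry.  The
    marker p-value is the F-test of the marker term, identical to the
    squared-t test of its coefficient.
    """
    import statsmodels.api as sm

    spec = spec or ModelSpec()
    env = np.asarray(env, dtype=float)
    if len(env) != gm.n:
        raise ValueError("env length does not match individuals")
    pcs = _pc_covariates(gm, spec.n_pcs)
    rows = []
    for j, pos in enumerate(gm.positions):
        g = gm.data[:, j]
        keep = ~np.isnan(g) & np.isfinite(env)
        if np.ptp(g[keep]) == 0:
            logger.info("%s: SNP %s constant after missing-data removal; skipped", gm.gene, pos)
            continue
        x = sm.add_constant(np.column_stack([pcs[keep], g[keep]]), has_constant="add")
        fit = sm.OLS(env[keep], x).fit()
        rows.append(
            {
                "gene": gm.gene,
                "marker": pos,
                "index": index_name,
                "model": "GLM",
                "effect": float(fit.params[-1]),
                "p": float(fit.pvalues[-1]),
            }
        )
    return _flag(pd.DataFrame(rows, columns=RESULT_COLUMNS[:6]))


# ---------------------------------------------------------------------------
# Mixed-model machinery (EMMA-style)

def _bend_kinship(k: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Eigendecompose K, flooring eigenvalues at EIG_FLOOR if needed."""
    k = np.asarray(k, dtype=float)
    lam, u = np.linalg.eigh((k + k.T) / 2.0)
    if lam.min() < 0:
        warnings.warn("kinship not positive semi-definite; eigenvalues floored")
    lam = np.maximum(lam, EIG_FLOOR)
    return lam, u


def _reml_loglik(log_delta: float, lam: np.ndarray, yt: np.ndarray, xt: np.ndarray) -> float:
    """Restricted log-likelihood of delta = sigma_e^2 / sigma_g^2 in the
    eigenbasis of the random-effect covariance."""
    delta = np.exp(log_delta)
    xi = lam + delta
    w = 1.0 / xi
    xtw = xt * w[:, None]
    xwx = xt.T @ xtw
    beta = np.linalg.solve(xwx, xtw.T @ yt)
    r = yt - xt @ beta
    n, p = xt.shape
    rss = float(r @ (w * r))
    sign, logdet_xwx = np.linalg.slogdet(xwx)
    if sign <= 0 or rss <= 0:
        return -np.inf
    q = n - p
    sigma_g2 = rss / q
    return -0.5 * (
        q * np.log(2.0 * np.pi * sigma_g2) + np.sum(np.log(xi)) + logdet_xwx + q
    )


def _fit_delta(lam: np.ndarray, yt: np.ndarray, xt: np.ndarray) -> tuple[float, float]:
    """Grid search plus local refinement of the variance ratio delta."""
    grid = np.linspace(-10.0, 10.0, 41)
    lls = np.array([_reml_loglik(g, lam, yt, xt) for g in grid])
    best = int(np.argmax(lls))
    lo = grid[max(best - 1, 0)]
    hi = grid[min(best + 1, len(grid) - 1)]
    res = optimize.minimize_scalar(
        lambda g: -_reml_loglik(g, lam, yt, xt), bounds=(lo, hi), method="bounded"
    )
    if -res.fun >= lls[best]:
        return float(np.exp(res.x)), float(-res.fun)
    return float(np.exp(grid[best])), float(lls[best])


def _gls_marker_test(w: np.ndarray, yt: np.ndarray, x0t: np.ndarray, gt: np.ndarray):
    """Weighted LS of yt on [x0t, gt]; Wald t-test of the marker term."""
    xt = np.column_stack([x0t, gt])
    n, p = xt.shape
    xtw = xt * w[:, None]
    xwx = xt.T @ xtw
    try:
        xwx_inv = np.linalg.inv(xwx)
    except np.linalg.LinAlgError:
        return float("nan"), float("nan")
    beta = xwx_inv @ (xtw.T @ yt)
    r = yt - xt @ beta
    sigma2 = float(r @ (w * r)) / (n - p)
    se = np.sqrt(sigma2 * xwx_inv[-1, -1])
    if se == 0 or not np.isfinite(se):
        return float(beta[-1]), float("nan")
    t = beta[-1] / se
    return float(beta[-1]), float(2.0 * stats.t.sf(abs(t), n - p))


def _impute_mean(data: np.ndarray) -> np.ndarray:
    x = data.copy()
    col_mean = np.nanmean(x, axis=0)
    idx = np.where(np.isnan(x))
    x[idx] = col_mean[idx[1]]
    return x


def _mixed_scan(
    gm: GenotypeMatrix,
    env: np.ndarray,
    cov: np.ndarray,
    spec: ModelSpec,
    index_name: str,
    model_label: str,
) -> pd.DataFrame:
    """Shared MLM / CMLM marker loop for a given random-effect covariance."""
    env = np.asarray(env, dtype=float)
    lam, u = _bend_kinship(cov)
    pcs = _pc_covariates(gm, spec.n_pcs)
    x0 = np.column_stack([np.ones(gm.n), pcs])
    yt = u.T @ env
    x0t = u.T @ x0
    delta, _ = _fit_delta(lam, yt, x0t)  # P3D: variance ratio from the null model
    w = 1.0 / (lam + delta)
    geno = _impute_mean(gm.data)
    rows = []
    for j, pos in enumerate(gm.positions):
        g = geno[:, j]
        if np.ptp(g) == 0:
            logger.info("%s: SNP %s constant; skipped", gm.gene, pos)
            continue
        effect, p = _gls_marker_test(w, yt, x0t, u.T @ g)
        rows.append(
            {
                "gene": gm.gene,
                "marker": pos,
                "index": index_name,
                "model": model_label,
                "effect": effect,
                "p": p,
            }
        )
    return _flag(pd.DataFrame(rows, columns=RESULT_COLUMNS[:6]))


def mlm_scan(
    gm: GenotypeMatrix,
    env: np.ndarray,
    spec: ModelSpec,
    index_name: str = "env",
) -> pd.DataFrame:
    """Kinship mixed-model scan (EMMA-style REML, P3D across markers)."""
    if spec.kinship is None:
        raise ValueError("mlm_scan requires spec.kinship")
    return _mixed_scan(gm, env, np.asarray(spec.kinship, dtype=float), spec, index_name, "MLM")


def _compression_groups(k: np.ndarray, n_groups: int) -> np.ndarray:
    """Average-linkage clustering of individuals on kinship distance."""
    n = k.shape[0]
    if n_groups >= n:
        return np.arange(n)
    d = 1.0 - k
    np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2.0
    z = linkage(squareform(d, checks=False), method="average")
    return fcluster(z, t=n_groups, criterion="maxclust") - 1


def _compressed_covariance(k: np.ndarray, groups: np.ndarray) -> np.ndarray:
    """Z K_g Z' where K_g is the mean pairwise kinship between groups."""
    labels = np.unique(groups)
    g = len(labels)
    kg = np.zeros((g, g))
    for a_idx, a in enumerate(labels):
        for b_idx, b in enumerate(labels):
            kg[a_idx, b_idx] = k[np.ix_(groups == a, groups == b)].mean()
    z = np.zeros((len(groups), g))
    for a_idx, a in enumerate(labels):
        z[groups == a, a_idx] = 1.0
    return z @ kg @ z.T


def cmlm_scan(
    gm: GenotypeMatrix,
    env: np.ndarray,
    spec: ModelSpec,
    index_name: str = "env",
) -> pd.DataFrame:
    """Compressed mixed-model scan.

    Individuals are clustered on kinship distance (average linkage); for
    each candidate group count the null mixed model is fitted by REML
    and the count with the best restricted likelihood is used for the
    marker tests.  With the group count equal to n the scan reduces
    exactly to ``mlm_scan``.
    """
    if spec.kinship is None:
        raise ValueError("cmlm_scan requires spec.kinship")
    k = np.asarray(spec.kinship, dtype=float)
    n = gm.n
    grid = spec.compression_grid or tuple(
        sorted({1, int(np.ceil(n / 8)), int(np.ceil(n / 4)), int(np.ceil(n / 2)), n})
    )
    env_arr = np.asarray(env, dtype=float)
    pcs = _pc_covariates(gm, spec.n_pcs)
    x0 = np.column_stack([np.ones(n), pcs])
    best = None
    for n_groups in grid:
        groups = _compression_groups(k, n_groups)
        cov = _compressed_covariance(k, groups)
        lam, u = _bend_kinship(cov)
        _, ll = _fit_delta(lam, u.T @ env_arr, u.T @ x0)
        logger.info("%s: CMLM %d groups, null REML loglik %.3f", gm.gene, n_groups, ll)
        if best is None or ll > best[0]:
            best = (ll, n_groups, cov)
    _, n_groups, cov = best
    logger.info("%s: CMLM selected %d groups", gm.gene, n_groups)
    return _mixed_scan(gm, env_arr, cov, spec, index_name, "CMLM")


# ---------------------------------------------------------------------------
# Haplotype-level mixed model

def haplotype_mlm(
    hs: HaplotypeSet,
    ids: list[str],
    env: np.ndarray,
    spec: ModelSpec,
    index_name: str = "env",
    min_carriers: int = 2,
) -> pd.DataFrame:
    """Omnibus mixed-model test of the haplotype class.

    The haplotype class enters the kinship mixed model as a multi-level
    fixed factor (rare classes with fewer than ``min_carriers`` carriers
    pooled into "other"); the p-value is the GLS F-test of the factor.
    Returns a single-row frame; the row is missing (NaN p) when fewer
    than two classes remain or the index has no variance.
    """
    if spec.kinship is None:
        raise ValueError("haplotype_mlm requires spec.kinship")
    env = np.asarray(env, dtype=float)
    labels = np.array([hs.assignments[i] for i in ids])
    counts = {h: int(np.sum(labels == h)) for h in set(labels)}
    pooled = np.array(
        [str(h) if counts[h] >= min_carriers else "other" for h in labels], dtype=object
    )
    classes = sorted(set(pooled))
    result_row = {
        "gene": hs.gene,
        "marker": "haplotype",
        "index": index_name,
        "model": "HAP-MLM",
        "effect": float("nan"),
        "p": float("nan"),
    }
    if len(classes) < 2 or np.ptp(env) == 0:
        return _flag(pd.DataFrame([result_row], columns=RESULT_COLUMNS[:6]))
    # dummy-code against the most frequent class
    ref = max(classes, key=lambda c: np.sum(pooled == c))
    dummies = np.column_stack([(pooled == c).astype(float) for c in classes if c != ref])
    n = len(ids)
    lam, u = _bend_kinship(np.asarray(spec.kinship, dtype=float))
    x0 = np.ones((n, 1))
    yt = u.T @ env
    x0t = u.T @ x0
    delta, _ = _fit_delta(lam, yt, x0t)  # P3D: variance ratio from the null model
    w = 1.0 / (lam + delta)

    def _wrss(xt):
        xtw = xt * w[:, None]
        beta = np.linalg.lstsq(xt.T @ xtw, xtw.T @ yt, rcond=None)[0]
        r = yt - xt @ beta
        return float(r @ (w * r)), xt.shape[1]

    rss0, p0 = _wrss(x0t)
    x1t = np.column_stack([x0t, u.T @ dummies])
    rss1, p1 = _wrss(x1t)
    q = p1 - p0
    df2 = n - p1
    if df2 <= 0 or rss1 <= 0:
        return _flag(pd.DataFrame([result_row], columns=RESULT_COLUMNS[:6]))
    f = ((rss0 - rss1) / q) / (rss1 / df2)
    result_row["effect"] = float((rss0 - rss1) / rss0)  # variance fraction explained
    result_row["p"] = float(stats.f.sf(f, q, df2))
    return _flag(pd.DataFrame([result_row], columns=RESULT_COLUMNS[:6]))


# ---------------------------------------------------------------------------
# Reporting

def significance_report(results: pd.DataFrame, n_sites: dict | None = None) -> pd.DataFrame:
    """Per gene/model/index significance counts.

    ``n_sites`` optionally maps gene -> number of segregating sites so
    the fraction of significant sites can be reported against the full
    panel rather than the tested markers only.
    """
    if results.empty:
        raise ValueError("no association results to summarize")
    frame = _flag(results.copy())
    rows = []
    for (gene, model, index), sub in frame.groupby(["gene", "model", "index"]):
        total = (n_sites or {}).get(gene, len(sub))
        rows.append(
            {
                "gene": gene,
                "model": model,
                "index": index,
                "n_tested": len(sub),
                "n_sig05": int(sub["sig05"].sum()),
                "n_sig01": int(sub["sig01"].sum()),
                "frac_sig05": sub["sig05"].sum() / total if total else 0.0,
                "frac_sig01": sub["sig01"].sum() / total if total else 0.0,
            }
        )
    return pd.DataFrame(rows)
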