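"""Genome binning and the two bin-level association analyses.

Analysis 1: per 10 Mb bin, logistic regression of ROH status (0/1) on the
sequential selection number (KPN), giving the temporal trend of
autozygosity in that bin. Analysis 2: per bin, a single-kinship linear
mixed model of 12-month body weight on within-bin ROH length (bp) and
rearing facility, with a genomic-relationship random effect to absorb
background polygenic covariance; the Wald test of the ROH-length
coefficient measures bin-local inbreeding depression.

The REML engine exploits the eigendecomposition of the GRM: with
V = sigma_e^2 (lambda G + I), the restricted likelihood is a smooth
function of the single variance ratio lambda = sigma_g^2 / sigma_e^2, and
is maximized by one-dimensional bounded optimization; sigma_e^2 is
profiled out in closed form.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .io import ChromSizes


@dataclass
class LMMFit:
    beta: np.ndarray
    se: np.ndarray
    names: list[str]
    sigma_g2: float
    sigma_e2: float
    loglik: float  # restricted log-likelihood at the optimum
    wald_stat: np.ndarray  # per-coefficient chi-square (1 df)
    wald_p: np.ndarray


def make_bins(chrom_sizes: ChromSizes, width: int = 10_000_000) -> pd.DataFrame:
    """Tile each chromosome with fixed-width bins (1-based inclusive);
    the last bin per chromosome is truncated at the chromosome length."""
    if width <= 0:
        raise ValueError("bin width must be positive")
    rows = []
    for chrom, length in chrom_sizes.items():
        start = 1
        while start <= length:
            end = min(start + width - 1, length)
            rows.append((f"{chrom}:{start}-{end}", chrom, start, end))
            start = end + 1
    return pd.DataFrame(rows, columns=["bin_id", "chrom", "start", "end"])


def bin_roh_matrix(
    segments: pd.DataFrame, bins: pd.DataFrame, sample_ids: list[str]
) -> pd.DataFrame:
    """Per-sample, per-bin total ROH overlap in bp (segments spanning a bin
    boundary contribute to both bins). Status is overlap > 0.

    Returns a samples x bins DataFrame of overlap lengths (bp); derive
    status with ``(matrix > 0)``.
    """
    mat = pd.DataFrame(0, index=pd.Index(sample_ids, name="sample_id"),
                       columns=bins["bin_id"], dtype=np.int64)
    if segments.empty:
        return mat
    segments = segments[segments["sample_id"].isin(sample_ids)]
    by_chrom = {c: g.sort_values("start") for c, g in bins.groupby("chrom")}
    for seg in segments.itertuples(index=False):
        grp = by_chrom.get(seg.chrom)
        if grp is None:
            raise ValueError(f"segment on chromosome {seg.chrom!r} outside all bins")
        ov_any = False
        for b in grp.itertuples(index=False):
            lo = max(seg.start, b.start)
            hi = min(seg.end, b.end)
            if hi >= lo:
                mat.loc[seg.sample_id, b.bin_id] += hi - lo + 1
                ov_any = True
        if not ov_any:
            raise ValueError(
                f"segment {seg.chrom}:{seg.start}-{seg.end} overlaps no bin"
            )
    return mat


def filter_uninformative_bins(matrix: pd.DataFrame) -> pd.DataFrame:
    """Drop bins where every sample has an identical ROH length
    (including all-zero bins)."""
    informative = matrix.nunique(axis=0) > 1
    out = matrix.loc[:, informative]
    if out.shape[1] == 0:
        raise ValueError("no informative bins remain")
    return out


def _logit_fit(status: np.ndarray, x: np.ndarray):
    import statsmodels.api as sm

    X = sm.add_constant(x.astype(float))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            model = sm.Logit(status.astype(float), X)
            res = model.fit(disp=False, maxiter=200)
        except Exception:
            return None
    if not np.all(np.isfinite(res.bse)) or np.any(res.bse > 1e4):
        return None  # effective separation: unbounded likelihood
    return res


def analysis1_logistic(matrix: pd.DataFrame, kpn: pd.Series) -> pd.DataFrame:
    """Logistic regression of per-bin ROH status on KPN (selected samples).

    Returns one row per bin: coefficient (log-odds per KPN unit), McFadden
    pseudo-R^2, Wald p-value for the slope, significant (p < 0.01) and a
    convergence flag (False for constant status or separation).
    """
    kpn = kpn.loc[matrix.index]
    rows = []
    for bin_id in matrix.columns:
        status = (matrix[bin_id].to_numpy() > 0).astype(int)
        if status.min() == status.max():
            rows.append((bin_id, np.nan, np.nan, np.nan, False, False))
            continue
        res = _logit_fit(status, kpn.to_numpy(float))
        if res is None:
            rows.append((bin_id, np.nan, np.nan, np.nan, False, False))
            continue
        coef = float(res.params[1])
        p = float(res.pvalues[1])
        mcfadden = float(1.0 - res.llf / res.llnull) if res.llnull != 0 else np.nan
        rows.append((bin_id, coef, mcfadden, p, p < 0.01, True))
    return pd.DataFrame(
        rows, columns=["bin_id", "coefficient", "fit_r2", "p_value", "significant", "converged"]
    )


# ---------------------------------------------------------------------------
# REML engine


def _reml_loglik(log_lam: float, d: np.ndarray, yt: np.ndarray, xt: np.ndarray) -> float:
    lam = np.exp(log_lam)
    w = lam * d + 1.0
    n, p = xt.shape
    xw = xt / w[:, None]
    xtx = xt.T @ xw
    xty = xw.T @ yt
    beta = np.linalg.solve(xtx, xty)
    resid = yt - xt @ beta
    rss = float(resid @ (resid / w))
    sigma_e2 = rss / (n - p)
    sign, logdet_xtx = np.linalg.slogdet(xtx)
    if sign <= 0:
        return -np.inf
    return -0.5 * ((n - p) * np.log(sigma_e2) + np.sum(np.log(w)) + logdet_xtx + (n - p))


def reml_fit(y: np.ndarray, X: np.ndarray, G: np.ndarray,
             coef_names: list[str] | None = None) -> LMMFit:
    """REML fit of y = X beta + g + e, g ~ N(0, sigma_g^2 G), e ~ N(0, sigma_e^2 I).

    G must be symmetric; X full column rank. The variance ratio is found by
    bounded 1-D optimization of the restricted likelihood on a log grid
    refined by Brent's method; beta by GLS at the optimum, with Wald tests
    per coefficient.
    """
    y = np.asarray(y, float).ravel()
    X = np.asarray(X, float)
    G = np.asarray(G, float)
    n, p = X.shape
    if len(y) != n or G.shape != (n, n):
        raise ValueError("y, X and G dimensions are inconsistent")
    if not np.allclose(G, G.T, atol=1e-8):
        raise ValueError("G is not symmetric")
    if np.linalg.matrix_rank(X) < p:
        raise ValueError("X is rank-deficient")
    d, U = np.linalg.eigh(G)
    d = np.clip(d, 0.0, None)
    yt = U.T @ y
    xt = U.T @ X

    grid = np.linspace(np.log(1e-6), np.log(1e6), 49)
    vals = np.array([_reml_loglik(g, d, yt, xt) for g in grid])
    k = int(np.argmax(vals))
    lo = grid[max(k - 1, 0)]
    hi = grid[min(k + 1, len(grid) - 1)]
    res = optimize.minimize_scalar(
        lambda g: -_reml_loglik(g, d, yt, xt), bounds=(lo, hi), method="bounded",
        options={"xatol": 1e-10},
    )
    best_ll = -res.fun
    lam = float(np.exp(res.x))
    # boundary: no genetic variance
    ll0 = _reml_loglik(np.log(1e-12), d, yt, xt)
    if ll0 >= best_ll - 1e-9:
        lam = 0.0
        best_ll = ll0

    w = lam * d + 1.0
    xw = xt / w[:, None]
    xtx = xt.T @ xw
    beta = np.linalg.solve(xtx, xw.T @ yt)
    resid = yt - xt @ beta
    sigma_e2 = float(resid @ (resid / w)) / (n - p)
    sigma_g2 = lam * sigma_e2
    cov = sigma_e2 * np.linalg.inv(xtx)
    se = np.sqrt(np.diag(cov))
    wald = (beta / se) ** 2
    pvals = stats.chi2.sf(wald, df=1)
    names = coef_names or [f"b{i}" for i in range(p)]
    return LMMFit(beta, se, names, sigma_g2, sigma_e2, float(best_ll), wald, pvals)


def _facility_design(facility: pd.Series) -> tuple[np.ndarray, list[str]]:
    levels = sorted(facility.unique())
    if len(levels) < 2:
        return np.empty((len(facility), 0)), []
    cols = [(facility == lv).to_numpy(float) for lv in levels[1:]]
    return np.column_stack(cols), [f"facility[{lv}]" for lv in levels[1:]]


def analysis2_lmm(
    matrix: pd.DataFrame,
    weights: pd.Series,
    facility: pd.Series,
    grm_ids: list[str],
    grm: np.ndarray,
) -> pd.DataFrame:
    """Mixed-model association of body weight with per-bin ROH length.

    Fixed effects: intercept + ROH length (bp) + facility dummies
    (first-level reference); random effect with covariance sigma_g^2 G.
    Samples with missing weight are dropped. Returns per bin the length
    coefficient (kg per bp), Wald p-value, variance components and flags.
    """
    keep = [s for s in matrix.index if s in weights.index and np.isfinite(weights.get(s, np.nan))]
    if len(keep) < 3:
        raise ValueError("too few samples with observed weight")
    gidx = [grm_ids.index(s) for s in keep]
    G = grm[np.ix_(gidx, gidx)]
    y = weights.loc[keep].to_numpy(float)
    fac_X, fac_names = _facility_design(facility.loc[keep])
    rows = []
    for bin_id in matrix.columns:
        length = matrix.loc[keep, bin_id].to_numpy(float)
        if length.min() == length.max():
            rows.append((bin_id, np.nan, np.nan, np.nan, np.nan, False, False))
            continue
        X = np.column_stack([np.ones(len(keep)), length, fac_X])
        fit = reml_fit(y, X, G, ["intercept", "roh_length"] + fac_names)
        p = float(fit.wald_p[1])
        rows.append((bin_id, float(fit.beta[1]), p, fit.sigma_g2, fit.sigma_e2, p < 0.01, True))
    return pd.DataFrame(
        rows,
        columns=["bin_id", "coefficient", "p_value", "sigma_g2", "sigma_e2",
                 "significant", "converged"],
    )


def group_mean_length_change(
    matrix: pd.DataFrame, kpn: pd.Series, cutoff: int = 486
) -> pd.DataFrame:
    """Per-bin mean ROH length of the late group (KPN > cutoff) minus the
    early group (KPN <= cutoff), in bp."""
    kpn = kpn.loc[matrix.index]
    a = matrix.loc[kpn <= cutoff]
    b = matrix.loc[kpn > cutoff]
    if a.empty or b.empty:
        raise ValueError("both KPN groups must be non-empty")
    change = b.mean(axis=0) - a.mean(axis=0)
    return pd.DataFrame({"bin_id": matrix.columns, "mean_change_bp": change.to_numpy()})


def cohort_correlations(froh: pd.Series, kpn: pd.Series, weight: pd.Series) -> pd.DataFrame:
    """Spearman rank correlations among selection number, F_roh and weight."""
    df = pd.DataFrame({"kpn": kpn, "f_roh": froh, "weight": weight}).dropna()
    if len(df) < 3:
        raise ValueError("need >= 3 samples with all of KPN, F_roh and weight")
    pairs = [("kpn", "f_roh"), ("f_roh", "weight"), ("kpn", "weight")]
    rows = []
    for a, b in pairs:
        if df[a].nunique() < 2 or df[b].nunique() < 2:
            rows.append((a, b, np.nan, np.nan, True))
            continue
        rho, p = stats.spearmanr(df[a], df[b])
        rows.append((a, b, float(rho), float(p), False))
    return pd.DataFrame(rows, columns=["var_a", "var_b", "rho", "p_value", "degenerate"])
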