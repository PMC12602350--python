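"""Two-sample Mendelian randomization estimators and diagnostics.

All estimators consume a harmonized table (exposure effects ``beta_x`` with
``se_x``, outcome effects ``beta_y`` with ``se_y``, expressed on one shared
effect allele per SNP) and return an :class:`MRResult` on the exposure's
per-allele scale: the causal effect of a 1-unit (typically 1 SD) change in
the exposure on the outcome (log-odds for case-control outcomes).

The suite mirrors standard two-sample practice:

- Wald ratio for single-SNP instruments; inverse-variance weighted (IVW)
  for two or more SNPs (the primary estimators);
- MR-Egger, weighted median and weighted mode as pleiotropy-robust
  complements for instruments with three or more SNPs;
- MR-LASSO, which gives each SNP its own penalized intercept and re-fits
  IVW on the SNPs whose intercepts shrink to zero;
- Cochran's Q for heterogeneity and the Steiger test for directionality.

First-order (NOME) standard errors are used throughout: the exposure
estimates are treated as fixed in the weights, the convention for summary-
data MR with strong instruments.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import InputError, MethodUnavailableError, UndefinedRatioError

Z95 = 1.959963984540054  # two-sided 95% normal quantile


@dataclass
class MRResult:
    """One estimator's causal-effect estimate."""

    method: str
    beta: float
    se: float
    ci_low: float
    ci_high: float
    pval: float
    n_snp: int
    notes: dict = field(default_factory=dict)


@dataclass
class HeterogeneityResult:
    """Cochran's Q across per-SNP ratio estimates."""

    Q: float
    df: int
    pval: float


@dataclass
class SteigerResult:
    """Directionality check: variance explained in exposure vs outcome."""

    r2_exposure: float
    r2_outcome: float
    direction_correct: bool
    pval: float


def _frame(tab) -> pd.DataFrame:
    """Accept a HarmonizedTable or a bare DataFrame with the x/y columns."""
    df = tab.df if hasattr(tab, "df") else tab
    for col in ("beta_x", "se_x", "beta_y", "se_y"):
        if col not in df.columns:
            raise InputError(f"harmonized table lacks column {col!r}")
    return df


def _normal_result(method: str, beta: float, se: float, n_snp: int,
                   notes: dict | None = None) -> MRResult:
    se = float(se)
    if se > 0:
        z = beta / se
        pval = float(2 * stats.norm.sf(abs(z)))
    else:
        pval = 0.0 if beta != 0 else 1.0
    return MRResult(method, float(beta), se, float(beta - Z95 * se),
                    float(beta + Z95 * se), pval, int(n_snp), notes or {})


# ---------------------------------------------------------------------------
# primary estimators

def wald_ratio(row) -> MRResult:
    """Single-SNP causal estimate: beta_y / beta_x with first-order SE
    se_y / |beta_x|."""
    r = row if isinstance(row, (dict, pd.Series)) else row._asdict()
    bx, by, sy = float(r["beta_x"]), float(r["beta_y"]), float(r["se_y"])
    if bx == 0:
        raise UndefinedRatioError("Wald ratio undefined: exposure beta is 0")
    theta = by / bx
    se = sy / abs(bx)
    return _normal_result("wald", theta, se, 1)


def ivw(tab, effects_model: str = "auto") -> MRResult:
    """Inverse-variance weighted estimate: weighted regression of beta_y on
    beta_x through the origin with weights 1/se_y².

    ``effects_model``: ``fixed``, ``random_multiplicative`` (SE inflated by
    max(1, sqrt(Q/(k-1)))), or ``auto`` — fixed below 4 SNPs, multiplicative
    random effects otherwise.
    """
    df = _frame(tab)
    k = len(df)
    if k < 2:
        raise MethodUnavailableError("IVW needs >= 2 SNPs; use wald_ratio")
    if effects_model == "auto":
        effects_model = "fixed" if k < 4 else "random_multiplicative"
    if effects_model not in ("fixed", "random_multiplicative"):
        raise InputError(f"unknown effects model {effects_model!r}")
    bx = df["beta_x"].to_numpy(dtype=float)
    by = df["beta_y"].to_numpy(dtype=float)
    w = df["se_y"].to_numpy(dtype=float) ** -2.0
    denom = float(np.sum(bx * bx * w))
    theta = float(np.sum(bx * by * w)) / denom
    se = denom ** -0.5
    scale = 1.0
    if effects_model == "random_multiplicative":
        q = float(np.sum(w * (by - theta * bx) ** 2))
        scale = max(1.0, np.sqrt(q / (k - 1)))
    return _normal_result(f"ivw_{'fixed' if effects_model == 'fixed' else 'random'}",
                          theta, se * scale, k,
                          {"effects_model": effects_model})


# ---------------------------------------------------------------------------
# pleiotropy-robust estimators

def _oriented(df: pd.DataFrame):
    """Flip (beta_x, beta_y) jointly so every beta_x >= 0 (Egger convention)."""
    sign = np.where(df["beta_x"].to_numpy(dtype=float) < 0, -1.0, 1.0)
    return (sign * df["beta_x"].to_numpy(dtype=float),
            sign * df["beta_y"].to_numpy(dtype=float),
            df["se_y"].to_numpy(dtype=float))


def egger(tab) -> tuple[MRResult, MRResult]:
    """MR-Egger: weighted regression beta_y = alpha + theta * beta_x.

    SNPs are sign-oriented to beta_x >= 0 first. The intercept alpha
    estimates average directional pleiotropy; SEs are scaled by
    max(1, sqrt(Q_resid/(k-2))) and intervals use t quantiles at k-2 df.
    Returns (slope result, intercept result).
    """
    df = _frame(tab)
    k = len(df)
    if k < 3:
        raise MethodUnavailableError("MR-Egger needs >= 3 SNPs")
    bx, by, sy = _oriented(df)
    w = sy ** -2.0
    X = np.column_stack([np.ones(k), bx])
    xtwx = X.T @ (w[:, None] * X)
    cov_unscaled = np.linalg.inv(xtwx)
    coef = cov_unscaled @ (X.T @ (w * by))
    resid = by - X @ coef
    q_resid = float(np.sum(w * resid ** 2))
    scale = max(1.0, np.sqrt(q_resid / (k - 2)))
    ses = np.sqrt(np.diag(cov_unscaled)) * scale
    tq = stats.t.ppf(0.975, df=k - 2)
    out = []
    for name, b, s in (("egger_slope", coef[1], ses[1]),
                       ("egger_intercept", coef[0], ses[0])):
        if s > 0:
            pval = float(2 * stats.t.sf(abs(b / s), df=k - 2))
        else:
            pval = 0.0 if b != 0 else 1.0
        out.append(MRResult(name, float(b), float(s), float(b - tq * s),
                            float(b + tq * s), pval, k,
                            {"residual_q": q_resid}))
    return out[0], out[1]


def _ratios_and_weights(df: pd.DataFrame):
    bx = df["beta_x"].to_numpy(dtype=float)
    by = df["beta_y"].to_numpy(dtype=float)
    sy = df["se_y"].to_numpy(dtype=float)
    if np.any(bx == 0):
        raise UndefinedRatioError("ratio undefined: an exposure beta is 0")
    return by / bx, (bx / sy) ** 2


def _weighted_median_estimate(ratios: np.ndarray, weights: np.ndarray) -> float:
    order = np.argsort(ratios, kind="stable")
    r = ratios[order]
    w = weights[order] / weights.sum()
    mid = np.cumsum(w) - w / 2
    return float(np.interp(0.5, mid, r))


def _parametric_bootstrap(df: pd.DataFrame, estimator, boot_reps: int,
                          seed: int) -> float:
    """SE of an estimator under resampling of (beta_x, beta_y) from their
    normal sampling distributions (the two samples are independent)."""
    rng = np.random.default_rng(seed)
    bx = df["beta_x"].to_numpy(dtype=float)
    sx = df["se_x"].to_numpy(dtype=float)
    by = df["beta_y"].to_numpy(dtype=float)
    sy = df["se_y"].to_numpy(dtype=float)
    boots = np.empty(boot_reps)
    for i in range(boot_reps):
        bxs = rng.normal(bx, sx)
        bys = rng.normal(by, sy)
        bxs[bxs == 0] = np.finfo(float).tiny  # degenerate draw guard
        boots[i] = estimator(bys / bxs, (bxs / sy) ** 2)
    return float(np.std(boots, ddof=1))


def weighted_median(tab, boot_reps: int = 1000, seed: int = 0) -> MRResult:
    """Weighted median of per-SNP ratios: consistent when valid instruments
    carry a majority of the weight (bx/se_y)². SE by parametric bootstrap."""
    df = _frame(tab)
    k = len(df)
    if k < 3:
        raise MethodUnavailableError("weighted median needs >= 3 SNPs")
    ratios, weights = _ratios_and_weights(df)
    theta = _weighted_median_estimate(ratios, weights)
    se = _parametric_bootstrap(df, _weighted_median_estimate, boot_reps, seed)
    res = _normal_result("weighted_median", theta, se, k)
    res.notes.update(boot_reps=boot_reps, seed=seed)
    return res


def _mode_estimate(ratios: np.ndarray, weights: np.ndarray,
                   bandwidth_factor: float = 1.0) -> float:
    mad = np.median(np.abs(ratios - np.median(ratios)))
    s = 1.4826 * mad
    if s == 0:
        s = float(np.std(ratios))
    if s == 0:  # all ratios identical
        return float(ratios[0])
    h = bandwidth_factor * s * len(ratios) ** (-1 / 5)
    grid = np.linspace(ratios.min() - 3 * h, ratios.max() + 3 * h, 512)
    dens = (weights[None, :] *
            np.exp(-0.5 * ((grid[:, None] - ratios[None, :]) / h) ** 2)).sum(axis=1)
    return float(grid[np.argmax(dens)])


def weighted_mode(tab, bandwidth_factor: float = 1.0, boot_reps: int = 1000,
                  seed: int = 0) -> MRResult:
    """Weighted mode: argmax of a Gaussian-kernel weighted density over the
    per-SNP ratios (bandwidth h = factor * 1.4826*MAD * k^(-1/5)); consistent
    when the largest weight-sharing group of instruments is valid."""
    df = _frame(tab)
    k = len(df)
    if k < 3:
        raise MethodUnavailableError("weighted mode needs >= 3 SNPs")
    ratios, weights = _ratios_and_weights(df)
    theta = _mode_estimate(ratios, weights, bandwidth_factor)
    se = _parametric_bootstrap(
        df, lambda r, w: _mode_estimate(r, w, bandwidth_factor), boot_reps, seed)
    res = _normal_result("weighted_mode", theta, se, k)
    res.notes.update(bandwidth_factor=bandwidth_factor, boot_reps=boot_reps,
                     seed=seed)
    return res


# ---------------------------------------------------------------------------
# MR-LASSO

def _lasso_fit(bx, by, w, lam, max_iter=500, tol=1e-12):
    """Alternating minimization of
    0.5 * sum_j w_j (by_j - a_j - theta*bx_j)^2 + lam * sum_j |a_j|."""
    theta = float(np.sum(bx * by * w) / np.sum(bx * bx * w))
    alpha = np.zeros_like(by)
    for _ in range(max_iter):
        resid = by - theta * bx
        thresh = lam / w
        alpha_new = np.sign(resid) * np.maximum(np.abs(resid) - thresh, 0.0)
        theta_new = float(np.sum(bx * (by - alpha_new) * w) / np.sum(bx * bx * w))
        if np.max(np.abs(alpha_new - alpha)) < tol and abs(theta_new - theta) < tol:
            alpha, theta = alpha_new, theta_new
            break
        alpha, theta = alpha_new, theta_new
    return theta, alpha


def mr_lasso(tab, n_lambda: int = 50, lambda_min_ratio: float = 0.001) -> MRResult:
    """MR-LASSO: per-SNP intercepts alpha_j penalized by lam * sum|alpha_j|,
    solved on a decreasing lambda grid; lambda selected by the heterogeneity
    stopping rule (largest set of SNPs with alpha_j = 0 whose post-selection
    Cochran Q stays below the chi-square 0.05 critical value at its df);
    the final estimate is fixed-effect IVW on the selected SNPs."""
    df = _frame(tab)
    k = len(df)
    if k < 3:
        raise MethodUnavailableError("MR-LASSO needs >= 3 SNPs")
    bx = df["beta_x"].to_numpy(dtype=float)
    by = df["beta_y"].to_numpy(dtype=float)
    w = df["se_y"].to_numpy(dtype=float) ** -2.0

    theta_ivw = float(np.sum(bx * by * w) / np.sum(bx * bx * w))
    lam_max = float(np.max(w * np.abs(by - theta_ivw * bx)))
    if lam_max == 0:  # perfect fit: every SNP valid
        sub = df
        best_valid = np.ones(k, dtype=bool)
        lam_best = 0.0
    else:
        grid = np.geomspace(lam_max, lambda_min_ratio * lam_max, n_lambda)
        best_valid, lam_best, best_size = None, None, -1
        for lam in grid:
            _, alpha = _lasso_fit(bx, by, w, lam)
            valid = alpha == 0
            nv = int(valid.sum())
            if nv < 2 or nv <= best_size:
                continue
            sel = np.flatnonzero(valid)
            th = float(np.sum(bx[sel] * by[sel] * w[sel]) /
                       np.sum(bx[sel] ** 2 * w[sel]))
            q = float(np.sum(w[sel] * (by[sel] - th * bx[sel]) ** 2))
            if nv == 1 or q <= stats.chi2.ppf(0.95, nv - 1):
                best_valid, lam_best, best_size = valid, float(lam), nv
        if best_valid is None:
            raise MethodUnavailableError(
                "MR-LASSO: no lambda yields >= 2 valid SNPs passing the "
                "heterogeneity rule")
        sub = df.loc[best_valid]
    res = ivw(sub, effects_model="fixed")
    res.method = "mr_lasso"
    res.n_snp = int(len(sub))
    res.notes = {"lambda": lam_best, "n_valid": int(len(sub)),
                 "excluded": df.loc[~np.asarray(best_valid), "snp_id"].tolist()
                 if "snp_id" in df.columns else []}
    return res


# ---------------------------------------------------------------------------
# diagnostics

def cochran_q(tab) -> HeterogeneityResult:
    """Cochran's Q over per-SNP ratios around the IVW estimate, with weights
    (beta_x/se_y)²; p from the upper tail of chi-square(k-1)."""
    df = _frame(tab)
    k = len(df)
    if k < 2:
        raise MethodUnavailableError("Cochran's Q needs >= 2 SNPs")
    ratios, w = _ratios_and_weights(df)
    theta = float(np.sum(w * ratios) / np.sum(w))
    q = float(np.sum(w * (ratios - theta) ** 2))
    return HeterogeneityResult(q, k - 1, float(stats.chi2.sf(q, k - 1)))


def _r2_from_p(pvals: np.ndarray, ns: np.ndarray) -> float:
    """Variance explained summed over SNPs, recovering each SNP's t² from its
    p-value at n-2 df: r²_j = t²/(t² + n - 2)."""
    t2 = stats.t.isf(np.clip(pvals, 1e-300, 1.0) / 2, df=ns - 2) ** 2
    return float(np.sum(t2 / (t2 + ns - 2)))


def steiger(tab) -> SteigerResult:
    """Steiger directionality test for quantitative traits.

    Sums per-SNP variance explained in exposure and outcome (from p and n);
    the causal direction exposure -> outcome is supported when the
    instrument explains more variance in the exposure. The p-value compares
    the two correlations via Fisher z with the two sample sizes.
    """
    df = _frame(tab)
    for col in ("p_x", "n_x", "p_y", "n_y"):
        if col not in df.columns or df[col].isna().any():
            raise InputError(f"Steiger test needs complete column {col!r}")
    nx = df["n_x"].to_numpy(dtype=float)
    ny = df["n_y"].to_numpy(dtype=float)
    r2x = _r2_from_p(df["p_x"].to_numpy(dtype=float), nx)
    r2y = _r2_from_p(df["p_y"].to_numpy(dtype=float), ny)
    r2x_c = min(r2x, 1.0 - 1e-12)
    r2y_c = min(r2y, 1.0 - 1e-12)
    zx = np.arctanh(np.sqrt(r2x_c))
    zy = np.arctanh(np.sqrt(r2y_c))
    denom = np.sqrt(1.0 / (nx.mean() - 3) + 1.0 / (ny.mean() - 3))
    z = (zx - zy) / denom
    return SteigerResult(r2x, r2y, bool(r2x > r2y),
                         float(2 * stats.norm.sf(abs(z))))


# ---------------------------------------------------------------------------
# convenience

def primary_estimate(tab, effects_model: str = "auto") -> MRResult:
    """The study's primary estimator: Wald ratio for a single SNP, IVW for
    two or more."""
    df = _frame(tab)
    if len(df) == 0:
        raise InputError("empty harmonized table")
    if len(df) == 1:
        return wald_ratio(df.iloc[0])
    return ivw(df, effects_model)


def sensitivity_suite(tab, seed: int = 0, boot_reps: int = 1000) -> list[MRResult]:
    """Egger slope/intercept, weighted median, weighted mode and MR-LASSO,
    for instruments with >= 3 SNPs. MR-LASSO failures are reported as a
    result row with NaN estimates rather than raised."""
    slope, intercept = egger(tab)
    results = [slope, intercept,
               weighted_median(tab, boot_reps=boot_reps, seed=seed),
               weighted_mode(tab, boot_reps=boot_reps, seed=seed)]
    try:
        results.append(mr_lasso(tab))
    except MethodUnavailableError as exc:
        results.append(MRResult("mr_lasso", np.nan, np.nan, np.nan, np.nan,
                                np.nan, len(_frame(tab)), {"error": str(exc)}))
    return results
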