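"""Pleiotropy-robust MR estimator panel on uncorrelated instruments.

All estimators consume a :class:`~mrpanel.harmonize.HarmonizedSet` of
aligned variant-exposure effects bx (SE sx) and variant-outcome effects by
(SE sy).  The inverse-variance weighted (IVW) estimator is the weighted
regression of by on bx through the origin and is consistent only when
every instrument is valid; MR-Egger relaxes the exclusion restriction to
the InSIDE condition by freeing the intercept; the weighted median is
consistent when at least half the instrument weight is valid; the
mode-based estimator when the largest homogeneous cluster of instruments
is valid; and MR-PRESSO tests for and removes individual outlying
instruments.  Ratio-estimate variances are first order (sy²/bx²)
throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from mrpanel.harmonize import HarmonizedSet
from mrpanel.io_config import logger


@dataclass(frozen=True)
class MREstimate:
    """One method's causal estimate on the log-odds-ratio scale."""

    method: str
    beta: float
    se: float
    ci_low: float
    ci_high: float
    pval: float
    n_snp: int
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (self.se > 0):
            raise ValueError("standard error must be positive")
        if not (self.ci_low <= self.beta <= self.ci_high):
            raise ValueError("confidence interval must bracket the estimate")

    @property
    def odds_ratio(self) -> float:
        return float(np.exp(self.beta))

    @property
    def ci_or(self) -> tuple[float, float]:
        return float(np.exp(self.ci_low)), float(np.exp(self.ci_high))


def _normal_estimate(method: str, beta: float, se: float, n_snp: int, extras: dict | None = None) -> MREstimate:
    zq = stats.norm.ppf(0.975)
    pval = 2.0 * stats.norm.sf(abs(beta) / se)
    return MREstimate(method, float(beta), float(se), float(beta - zq * se),
                      float(beta + zq * se), float(pval), n_snp, extras or {})


def _ivw_core(bx: np.ndarray, by: np.ndarray, sy: np.ndarray) -> tuple[float, float]:
    """Multiplicative random-effects IVW point estimate and SE (floor 1)."""
    w = 1.0 / sy**2
    denom = float(np.sum(w * bx**2))
    theta = float(np.sum(w * bx * by)) / denom
    j = bx.size
    rss = float(np.sum(w * (by - theta * bx) ** 2))
    scale = max(1.0, np.sqrt(rss / (j - 1))) if j > 1 else 1.0
    return theta, scale / np.sqrt(denom)


def ivw_uncorrelated(h: HarmonizedSet) -> MREstimate:
    """IVW for independent instruments: weights 1/sy², multiplicative
    random-effects SE with the overdispersion factor floored at 1."""
    if h.n_variants < 2:
        raise ValueError("IVW needs at least 2 instruments")
    theta, se = _ivw_core(h.bx, h.by, h.sy)
    return _normal_estimate("ivw", theta, se, h.n_variants)


def egger(h: HarmonizedSet) -> MREstimate:
    """MR-Egger: weighted regression of by on bx with a free intercept.

    Exposure effects are oriented nonnegative (negating by jointly), the
    convention under which the intercept estimates the average directional
    pleiotropic effect.  Inference uses the t-distribution with J−2 degrees
    of freedom and a multiplicative overdispersion factor floored at 1.
    """
    j = h.n_variants
    if j < 3:
        raise ValueError("MR-Egger needs at least 3 instruments")
    sign = np.where(h.bx < 0, -1.0, 1.0)
    bx, by, sy = sign * h.bx, sign * h.by, h.sy
    w = 1.0 / sy**2
    x = np.column_stack([np.ones(j), bx])
    xtwx = x.T @ (w[:, None] * x)
    xtwy = x.T @ (w * by)
    coef = np.linalg.solve(xtwx, xtwy)
    resid = by - x @ coef
    rss = float(np.sum(w * resid**2))
    scale2 = max(1.0, rss / (j - 2))
    cov = scale2 * np.linalg.inv(xtwx)
    slope, slope_se = float(coef[1]), float(np.sqrt(cov[1, 1]))
    intercept, intercept_se = float(coef[0]), float(np.sqrt(cov[0, 0]))
    df = j - 2
    tq = stats.t.ppf(0.975, df)
    pval = 2.0 * stats.t.sf(abs(slope) / slope_se, df)
    intercept_p = 2.0 * stats.t.sf(abs(intercept) / intercept_se, df)
    return MREstimate(
        method="mr_egger",
        beta=slope,
        se=slope_se,
        ci_low=slope - tq * slope_se,
        ci_high=slope + tq * slope_se,
        pval=float(pval),
        n_snp=j,
        extras={
            "egger_intercept": intercept,
            "egger_intercept_se": intercept_se,
            "egger_intercept_p": float(intercept_p),
            "overdispersion": float(np.sqrt(scale2)),
        },
    )


def _ratio_weights(h: HarmonizedSet) -> tuple[np.ndarray, np.ndarray, HarmonizedSet]:
    """Per-variant ratio estimates and first-order inverse-variance weights.

    Variants with bx = 0 have no defined ratio and are dropped with a
    warning before anything else happens.
    """
    keep = h.bx != 0
    if not np.all(keep):
        logger.warning("dropping %d variant(s) with zero exposure effect", int((~keep).sum()))
        h = h.subset([v for v, k in zip(h.variant_ids, keep) if k])
    theta = h.by / h.bx
    w = h.bx**2 / h.sy**2
    return theta, w, h


def _weighted_median_point(theta: np.ndarray, w: np.ndarray) -> float:
    order = np.argsort(theta)
    th, ww = theta[order], w[order]
    s = (np.cumsum(ww) - ww / 2.0) / ww.sum()
    return float(np.interp(0.5, s, th))


def weighted_median(h: HarmonizedSet, n_boot: int = 1000, seed: int = 0) -> MREstimate:
    """Weighted median of the per-variant ratio estimates.

    The estimate interpolates the ratio at standardized cumulative weight
    0.5; the SE comes from a seeded parametric bootstrap resampling
    (bx_j, by_j) from normals with their reported SEs.
    """
    if h.n_variants < 3:
        raise ValueError("weighted median needs at least 3 instruments")
    theta, w, h = _ratio_weights(h)
    point = _weighted_median_point(theta, w)
    se = _bootstrap_se(h, n_boot, seed, _weighted_median_point)
    return _normal_estimate("weighted_median", point, se, h.n_variants,
                            {"boot_n": n_boot, "seed": seed})


def _weighted_mode_point(theta: np.ndarray, w: np.ndarray, phi: float = 1.0) -> float:
    """Argmax of a weighted Gaussian kernel density over the ratio estimates."""
    if theta.size == 1 or np.ptp(theta) == 0:
        return float(theta[0])
    wn = w / w.sum()
    mu = float(np.sum(wn * theta))
    sd = float(np.sqrt(np.sum(wn * (theta - mu) ** 2)))
    order = np.argsort(theta)
    cw = np.cumsum(wn[order])
    q25 = float(np.interp(0.25, cw, theta[order]))
    q75 = float(np.interp(0.75, cw, theta[order]))
    iqr = q75 - q25
    spread = min(x for x in (sd, iqr / 1.34) if x > 0) if (sd > 0 or iqr > 0) else 0.0
    bandwidth = phi * 0.9 * spread * theta.size ** (-1 / 5)
    if bandwidth <= 0:
        return float(theta[np.argmax(w)])
    grid = np.linspace(theta.min() - 3 * bandwidth, theta.max() + 3 * bandwidth, 512)
    dens = np.sum(wn[None, :] * np.exp(-0.5 * ((grid[:, None] - theta[None, :]) / bandwidth) ** 2), axis=1)
    return float(grid[np.argmax(dens)])


def weighted_mode(h: HarmonizedSet, phi: float = 1.0, n_boot: int = 1000, seed: int = 0) -> MREstimate:
    """Mode-based estimator: the peak of a weighted kernel density of ratios.

    Bandwidth is phi · 0.9 · min(sd, IQR/1.34) · J^(−1/5) over the weighted
    ratio distribution (a weighted Silverman rule); SE by seeded parametric
    bootstrap.
    """
    if h.n_variants < 3:
        raise ValueError("mode-based estimator needs at least 3 instruments")
    theta, w, h = _ratio_weights(h)
    point = _weighted_mode_point(theta, w, phi)
    se = _bootstrap_se(h, n_boot, seed, lambda t, ww: _weighted_mode_point(t, ww, phi))
    return _normal_estimate("weighted_mode", point, se, h.n_variants,
                            {"boot_n": n_boot, "seed": seed, "phi": phi})


def _bootstrap_se(h: HarmonizedSet, n_boot: int, seed: int, point_fn) -> float:
    rng = np.random.default_rng(seed)
    ests = np.empty(n_boot)
    for b in range(n_boot):
        bx = rng.normal(h.bx, h.sx)
        by = rng.normal(h.by, h.sy)
        bx = np.where(bx == 0, 1e-300, bx)
        theta = by / bx
        w = bx**2 / h.sy**2
        ests[b] = point_fn(theta, w)
    se = float(np.std(ests, ddof=1))
    return max(se, 1e-12)


def _loo_ivw_theta(bx: np.ndarray, by: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Leave-one-out IVW estimates for every variant, vectorized."""
    sxy = np.sum(w * bx * by)
    sxx = np.sum(w * bx**2)
    return (sxy - w * bx * by) / (sxx - w * bx**2)


def mr_presso(h: HarmonizedSet, n_sim: int = 1000, seed: int = 0,
              alpha_outlier: float = 0.05) -> MREstimate:
    """MR-PRESSO: global pleiotropy test, outlier detection, corrected estimate.

    The observed residual sum of squares uses leave-one-out IVW fits,
    RSS = Σ_j (by_j − θ̂₋j·bx_j)²/sy_j²; its null distribution comes from
    ``n_sim`` seeded parametric simulations of by under the fitted model.
    Per-variant exceedance p-values (Bonferroni-corrected) flag outliers at
    ``alpha_outlier``; the headline estimate is the outlier-corrected IVW
    when outliers exist, and is absent (NaN beta, IVW inference carried in
    extras) otherwise.  All empirical p-values use +1 smoothing so p = 0 is
    impossible.  The distortion p compares the outlier-removal shift with
    shifts from removing random subsets of the same size.
    """
    j = h.n_variants
    if j < 4:
        raise ValueError("MR-PRESSO needs at least 4 instruments")
    if n_sim < 100:
        raise ValueError("n_sim must be at least 100")
    rng = np.random.default_rng(seed)
    w = 1.0 / h.sy**2
    theta_loo = _loo_ivw_theta(h.bx, h.by, w)
    resid2_obs = w * (h.by - theta_loo * h.bx) ** 2
    rss_obs = float(resid2_obs.sum())

    # parametric null: by* ~ N(θ̂₋j bx_j, sy_j), refit leave-one-out each time
    exceed_global = 0
    exceed_var = np.zeros(j)
    for _ in range(n_sim):
        by_sim = rng.normal(theta_loo * h.bx, h.sy)
        tl = _loo_ivw_theta(h.bx, by_sim, w)
        r2 = w * (by_sim - tl * h.bx) ** 2
        if r2.sum() >= rss_obs:
            exceed_global += 1
        exceed_var += r2 >= resid2_obs
    global_p = (exceed_global + 1) / (n_sim + 1)
    outlier_p = np.minimum((exceed_var + 1) / (n_sim + 1) * j, 1.0)  # Bonferroni
    outliers = [h.variant_ids[i] for i in np.flatnonzero(outlier_p < alpha_outlier)]

    theta_all, se_all = _ivw_core(h.bx, h.by, h.sy)
    extras: dict = {
        "presso_global_p": float(global_p),
        "presso_outlier_ids": tuple(outliers),
        "presso_outlier_p": {h.variant_ids[i]: float(outlier_p[i]) for i in range(j)},
        "n_sim": n_sim,
        "seed": seed,
        "raw_ivw_beta": theta_all,
        "raw_ivw_se": se_all,
    }

    if not outliers:
        extras["presso_distortion_p"] = None
        est = _normal_estimate("mr_presso", theta_all, se_all, j, extras)
        # Table-style convention: no outliers → no corrected estimate to headline
        object.__setattr__(est, "beta", float("nan"))
        object.__setattr__(est, "ci_low", float("nan"))
        object.__setattr__(est, "ci_high", float("nan"))
        object.__setattr__(est, "pval", float("nan"))
        return est

    keep = [v for v in h.variant_ids if v not in set(outliers)]
    if len(keep) < 2:
        raise ValueError("too few instruments remain after outlier removal")
    hc = h.subset(keep)
    theta_c, se_c = _ivw_core(hc.bx, hc.by, hc.sy)

    # distortion test: is the observed shift extreme among random removals?
    shift_obs = abs(theta_c - theta_all)
    n_rand = min(n_sim, 500)
    exceed = 0
    for _ in range(n_rand):
        drop = rng.choice(j, size=len(outliers), replace=False)
        mask = np.ones(j, dtype=bool)
        mask[drop] = False
        t_r, _ = _ivw_core(h.bx[mask], h.by[mask], h.sy[mask])
        if abs(t_r - theta_all) >= shift_obs:
            exceed += 1
    extras["presso_distortion_p"] = float((exceed + 1) / (n_rand + 1))
    return _normal_estimate("mr_presso", theta_c, se_c, len(keep), extras)


def mvmr_ivw(bx_matrix: np.ndarray, sx_matrix: np.ndarray, by: np.ndarray,
             sy: np.ndarray, exposure_names: list[str] | None = None) -> list[MREstimate]:
    """Multivariable IVW: weighted regression of by on K exposure-effect columns.

    No intercept; weights 1/sy²; per-exposure direct effects with
    multiplicative random-effects SEs (floor 1, residual df J−K).  An
    exposure whose effect column is identically zero carries no information
    and is excluded from the fit (its estimate is reported as 0 with an
    infinite SE), so the remaining exposures reduce to the nested model; a
    genuinely collinear design is an error.
    """
    bx = np.atleast_2d(np.asarray(bx_matrix, dtype=float))
    by = np.asarray(by, dtype=float)
    sy = np.asarray(sy, dtype=float)
    j, k = bx.shape
    if k < 2:
        raise ValueError("multivariable IVW needs at least 2 exposures")
    if j <= k:
        raise ValueError("need more instruments than exposures")
    names = exposure_names or [f"exposure_{i + 1}" for i in range(k)]
    active = [i for i in range(k) if np.any(bx[:, i] != 0)]
    ka = len(active)
    if ka == 0:
        raise ValueError("all exposure columns are zero")
    xa = bx[:, active]
    w = 1.0 / sy**2
    xtwx = xa.T @ (w[:, None] * xa)
    if np.linalg.cond(xtwx) > 1e12:
        raise np.linalg.LinAlgError("rank-deficient multivariable design")
    coef = np.linalg.solve(xtwx, xa.T @ (w * by))
    resid = by - xa @ coef
    rss = float(np.sum(w * resid**2))
    scale2 = max(1.0, rss / (j - ka))
    cov = scale2 * np.linalg.inv(xtwx)
    out: list[MREstimate] = []
    pos = {i: a for a, i in enumerate(active)}
    zq = stats.norm.ppf(0.975)
    for i in range(k):
        if i in pos:
            a = pos[i]
            out.append(_normal_estimate(f"mvmr_ivw[{names[i]}]", float(coef[a]),
                                        float(np.sqrt(cov[a, a])), j,
                                        {"df": j - ka, "overdispersion": float(np.sqrt(scale2))}))
        else:
            out.append(MREstimate(f"mvmr_ivw[{names[i]}]", 0.0, float("inf"),
                                  float("-inf"), float("inf"), 1.0, j,
                                  {"zero_exposure_column": True}))
    return out
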