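"""Correlated-instrument IVW: GLS with an LD-derived error covariance.

With correlated instruments the outcome effects are not independent; the
inverse-variance weighted estimator becomes generalized least squares with
error covariance Ω, Ω_jk = σ_Yj σ_Yk ρ_jk built from the outcome standard
errors and the signed LD correlations.  When many instruments are in tight
LD, Ω is near-singular and its inverse is numerically meaningless; the
remedy implemented here performs unscaled principal component analysis on
the weighted correlation matrix Ψ, Ψ_jk = (β_Xj/σ_Yj)(β_Xk/σ_Yk)ρ_jk,
projects the effect vectors and Ω onto the leading eigenvectors covering a
configured share of the spectrum, and runs the same GLS in the reduced
space.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from mrpanel.io_config import LDMatrix
from mrpanel.harmonize import HarmonizedSet

#: Above this condition number Ω is treated as numerically singular.
CONDITION_CAP = 1e8


@dataclass(frozen=True)
class TransformedSet:
    """Effect vectors and covariance in the reduced eigenspace."""

    bx_t: np.ndarray
    by_t: np.ndarray
    omega_t: np.ndarray
    k: int
    var_explained_achieved: float

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("must retain at least one component")
        if self.omega_t.shape != (self.k, self.k):
            raise ValueError("omega_t dimension does not match k")


def build_omega(sy: np.ndarray, ld: LDMatrix | np.ndarray) -> np.ndarray:
    """Outcome-error covariance Ω_jk = sy_j · sy_k · ρ_jk."""
    sy = np.asarray(sy, dtype=float)
    r = ld.r if isinstance(ld, LDMatrix) else np.asarray(ld, dtype=float)
    if np.any(sy <= 0):
        raise ValueError("outcome standard errors must be positive")
    if r.shape != (sy.size, sy.size):
        raise ValueError("LD dimension does not match sy")
    return np.outer(sy, sy) * r


def gls_ivw(bx: np.ndarray, by: np.ndarray, omega: np.ndarray, method: str = "ivw_correlated"):
    """Generalized-least-squares IVW through the origin.

    θ̂ = (bxᵀΩ⁻¹by)/(bxᵀΩ⁻¹bx); the base SE 1/√(bxᵀΩ⁻¹bx) is inflated by
    the multiplicative random-effects factor max(1, √(RSS/(J−1))) where RSS
    is the Ω-weighted residual sum of squares.  Raises on a numerically
    singular Ω (condition number above :data:`CONDITION_CAP`) — the caller
    should then fall back to :func:`pca_transform`.
    """
    from mrpanel.estimators import MREstimate  # local import to avoid a cycle

    bx = np.asarray(bx, dtype=float)
    by = np.asarray(by, dtype=float)
    omega = np.asarray(omega, dtype=float)
    j = bx.size
    if j < 1:
        raise ValueError("need at least one (transformed) instrument")
    cond = np.linalg.cond(omega)
    if not np.isfinite(cond) or cond > CONDITION_CAP:
        raise np.linalg.LinAlgError(
            f"omega is numerically singular (condition number {cond:.3g} > {CONDITION_CAP:.0g}); "
            "use pca_transform"
        )
    oi_bx = np.linalg.solve(omega, bx)
    oi_by = np.linalg.solve(omega, by)
    denom = float(bx @ oi_bx)
    theta = float(bx @ oi_by) / denom
    resid = by - theta * bx
    rss = float(resid @ np.linalg.solve(omega, resid))
    scale = max(1.0, np.sqrt(rss / (j - 1))) if j > 1 else 1.0
    se = scale / np.sqrt(denom)
    z = theta / se
    pval = 2.0 * stats.norm.sf(abs(z))
    zq = stats.norm.ppf(0.975)
    return MREstimate(
        method=method,
        beta=theta,
        se=se,
        ci_low=theta - zq * se,
        ci_high=theta + zq * se,
        pval=float(pval),
        n_snp=j,
        extras={"rss": rss, "overdispersion": scale, "condition_number": float(cond)},
    )


def pca_transform(bx: np.ndarray, by: np.ndarray, sy: np.ndarray,
                  ld: LDMatrix | np.ndarray, var_explained: float = 0.99) -> TransformedSet:
    """Unscaled PCA reduction of a correlated-instrument system.

    Eigendecomposes (without centering or scaling) the weighted correlation
    matrix Ψ_jk = (bx_j/sy_j)(bx_k/sy_k)ρ_jk, retains the minimal number of
    leading components whose cumulative eigenvalue share reaches
    ``var_explained`` (eigenvalues clipped at zero for the share), and
    projects bx, by and Ω onto them.
    """
    if not (0 < var_explained <= 1):
        raise ValueError("var_explained must lie in (0, 1]")
    bx = np.asarray(bx, dtype=float)
    by = np.asarray(by, dtype=float)
    sy = np.asarray(sy, dtype=float)
    r = ld.r if isinstance(ld, LDMatrix) else np.asarray(ld, dtype=float)
    w = bx / sy
    psi = np.outer(w, w) * r
    psi = (psi + psi.T) / 2.0  # guard against symmetry drift
    evals, evecs = np.linalg.eigh(psi)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    share = np.clip(evals, 0.0, None)
    total = share.sum()
    if total <= 0:
        raise ValueError("weighted correlation matrix has no positive spectrum")
    cum = np.cumsum(share) / total
    k = int(np.searchsorted(cum, var_explained - 1e-12) + 1)
    k = min(k, bx.size)
    p = evecs[:, :k]
    omega = build_omega(sy, r)
    return TransformedSet(
        bx_t=p.T @ bx,
        by_t=p.T @ by,
        omega_t=p.T @ omega @ p,
        k=k,
        var_explained_achieved=float(cum[k - 1]),
    )


def pca_ivw(h: HarmonizedSet, var_explained: float = 0.99):
    """Primary correlated-instrument IVW with automatic PCA reduction.

    Runs GLS-IVW on the PCA-transformed system; with ``var_explained = 1``
    on a well-conditioned system this equals the untransformed GLS
    estimate.  Requires the harmonized set to carry an LD matrix; identity
    LD (uncorrelated IVW) is used when it does not.
    """
    ld = h.ld.r if h.ld is not None else np.eye(h.n_variants)
    t = pca_transform(h.bx, h.by, h.sy, ld, var_explained)
    est = gls_ivw(t.bx_t, t.by_t, t.omega_t, method="ivw_correlated_pca")
    est.extras.update({"k_components": t.k, "var_explained_achieved": t.var_explained_achieved,
                       "n_variants": h.n_variants})
    # the estimate is built on k transformed components but reflects all variants
    object.__setattr__(est, "n_snp", h.n_variants)
    return est
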