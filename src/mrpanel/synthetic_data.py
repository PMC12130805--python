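"""Synthetic GWAS summary statistics with known causal ground truth.

The generator works entirely at the summary level — the level at which all
two-sample MR arithmetic operates.  Observed variant-exposure effects are
drawn jointly Gaussian around true per-variant effects γ with covariance
S·R·S (S the diagonal of per-variant standard errors, R the LD correlation
matrix); variant-outcome effects for subtype s are centred on θ_s·γ_j + α_j,
where θ_s is the causal log-odds ratio for that subtype and α_j a direct
(pleiotropic) effect bypassing the exposure.  Standard errors follow the
usual large-sample approximations: se ≈ 1/√(2f(1−f)n) for a standardized
quantitative trait and se ≈ 1/√(2f(1−f)·n·φ(1−φ)) for a case-control
log-odds ratio with case fraction φ.

Default outcome sample sizes reproduce the five-subtype breast-cancer
design this package is exercised against: luminal A-like (45,253 cases),
luminal B/HER2-negative-like (6,350), luminal B-like (6,427),
HER2-enriched-like (2,884) and triple negative (8,602), all sharing one
pool of 91,477 controls.  The shared controls induce a small positive noise
correlation between subtype statistics at the same variant; its weight is
configurable and defaults to 0 (independent noise), the working assumption
that the correlation from control overlap is minimal.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from mrpanel.io_config import LDMatrix, VariantAssoc

#: Effective case counts per hormone-receptor subtype and the shared control count.
DEFAULT_SUBTYPE_CASES: dict[str, int] = {
    "luminal_A": 45253,
    "luminal_B_HER2neg": 6350,
    "luminal_B": 6427,
    "HER2_enriched": 2884,
    "triple_negative": 8602,
}
DEFAULT_N_CONTROLS = 91477

_PALINDROMIC_PAIRS = (("A", "T"), ("T", "A"), ("C", "G"), ("G", "C"))
_NONPALINDROMIC_PAIRS = (("A", "G"), ("A", "C"), ("G", "A"), ("C", "A"),
                         ("T", "G"), ("T", "C"), ("G", "T"), ("C", "T"))


@dataclass(frozen=True)
class SimTruth:
    """Generative ground truth for one synthetic two-sample MR study."""

    gamma: np.ndarray                          # true per-variant exposure effects
    theta_by_subtype: dict[str, float]         # causal log-OR per outcome subtype
    alpha: np.ndarray | None = None            # direct (pleiotropic) outcome effects
    ld: LDMatrix | None = None                 # instrument LD; None = independent
    n_exposure: int = 250_000
    subtype_cases: Mapping[str, int] = field(default_factory=lambda: dict(DEFAULT_SUBTYPE_CASES))
    n_controls_shared: int = DEFAULT_N_CONTROLS
    pleio_fraction: float = 0.0
    pleio_mean: float = 0.0
    palindromic_fraction: float = 0.0          # fraction of variants given A/T or C/G pairs
    shared_control_weight: float = 0.0         # cross-subtype noise correlation weight in [0,1)
    female_attenuation: float = 1.0            # multiplier sex-combined γ → female-specific γ

    def __post_init__(self) -> None:
        gamma = np.asarray(self.gamma, dtype=float)
        object.__setattr__(self, "gamma", gamma)
        if self.alpha is not None:
            alpha = np.asarray(self.alpha, dtype=float)
            if alpha.shape != gamma.shape:
                raise ValueError("alpha and gamma must have identical shapes")
            object.__setattr__(self, "alpha", alpha)
        if not (0 <= self.pleio_fraction <= 1):
            raise ValueError("pleio_fraction must lie in [0, 1]")
        if not (0 <= self.shared_control_weight < 1):
            raise ValueError("shared_control_weight must lie in [0, 1)")
        if any(c <= 0 for c in self.subtype_cases.values()) or self.n_controls_shared <= 0:
            raise ValueError("case and control counts must be positive")
        if self.ld is not None and self.ld.size != gamma.size:
            raise ValueError("LD dimension does not match gamma")

    @property
    def n_variants(self) -> int:
        return int(self.gamma.size)

    def alpha_or_zero(self) -> np.ndarray:
        return np.zeros(self.n_variants) if self.alpha is None else self.alpha


def make_ld(block_sizes: Sequence[int], rho: float) -> LDMatrix:
    """Block-diagonal AR(1) LD: within a block entry (i, j) = rho^|i−j|.

    Positive definite for |rho| < 1, which makes it a safe sampling
    covariance factor and a well-posed GLS weight.
    """
    if abs(rho) >= 1:
        raise ValueError("|rho| must be < 1")
    if any(b <= 0 for b in block_sizes):
        raise ValueError("block sizes must be positive")
    total = int(sum(block_sizes))
    r = np.zeros((total, total))
    offset = 0
    for b in block_sizes:
        idx = np.arange(b)
        r[offset:offset + b, offset:offset + b] = rho ** np.abs(idx[:, None] - idx[None, :])
        offset += b
    ids = tuple(f"rs{i + 1}" for i in range(total))
    return LDMatrix(ids, r)


def _assign_alleles(rng: np.random.Generator, n: int, palindromic_fraction: float,
                    eaf_window: tuple[float, float] = (0.40, 0.60)) -> tuple[list[tuple[str, str]], np.ndarray]:
    """Allele pairs and EAFs; designated palindromic variants get ambiguous EAFs."""
    n_pal = int(round(palindromic_fraction * n))
    pal_idx = set(rng.choice(n, size=n_pal, replace=False).tolist()) if n_pal else set()
    pairs: list[tuple[str, str]] = []
    eaf = np.empty(n)
    for j in range(n):
        if j in pal_idx:
            pairs.append(_PALINDROMIC_PAIRS[rng.integers(len(_PALINDROMIC_PAIRS))])
            eaf[j] = rng.uniform(*eaf_window)
        else:
            pairs.append(_NONPALINDROMIC_PAIRS[rng.integers(len(_NONPALINDROMIC_PAIRS))])
            eaf[j] = rng.uniform(0.05, 0.95)
    return pairs, eaf


def _quantitative_se(eaf: np.ndarray, n: int) -> np.ndarray:
    return 1.0 / np.sqrt(2.0 * eaf * (1.0 - eaf) * n)


def _binary_se(eaf: np.ndarray, n_total: int, case_fraction: float) -> np.ndarray:
    return 1.0 / np.sqrt(2.0 * eaf * (1.0 - eaf) * n_total * case_fraction * (1.0 - case_fraction))


def _correlated_noise(rng: np.random.Generator, se: np.ndarray, ld: LDMatrix | None) -> np.ndarray:
    z = rng.standard_normal(se.size)
    if ld is None:
        return se * z
    chol = np.linalg.cholesky(ld.r + 1e-12 * np.eye(ld.size))
    return se * (chol @ z)


def simulate_exposure(truth: SimTruth, seed: int, trait_id: str = "exposure",
                      female: bool = False) -> list[VariantAssoc]:
    """Draw one exposure GWAS: betas ~ N(γ, S·R·S), SEs from EAF and sample size.

    With ``female=True`` the mean is γ scaled by the configured female
    attenuation and the noise corresponds to a half-size (female-only)
    study sample.
    """
    rng = np.random.default_rng(seed)
    n_var = truth.n_variants
    pairs, eaf = _assign_alleles(rng, n_var, truth.palindromic_fraction)
    n_sample = max(2, truth.n_exposure // 2) if female else truth.n_exposure
    se = _quantitative_se(eaf, n_sample)
    mean = truth.gamma * (truth.female_attenuation if female else 1.0)
    beta = mean + _correlated_noise(rng, se, truth.ld)
    pvals = 2.0 * stats.norm.sf(np.abs(beta) / se)
    ids = truth.ld.variant_ids if truth.ld is not None else tuple(f"rs{j + 1}" for j in range(n_var))
    return [
        VariantAssoc(
            variant_id=ids[j],
            effect_allele=pairs[j][0],
            other_allele=pairs[j][1],
            beta=float(beta[j]),
            se=float(se[j]),
            pval=float(max(pvals[j], 5e-324)),
            eaf=float(eaf[j]),
            n=n_sample,
            trait_id=trait_id,
        )
        for j in range(n_var)
    ]


def simulate_outcomes(truth: SimTruth, seed: int,
                      exposure: Sequence[VariantAssoc] | None = None) -> dict[str, list[VariantAssoc]]:
    """Draw one case-control GWAS per subtype around θ_s·γ_j + α_j.

    When an exposure table is supplied its allele assignments and EAFs are
    reused so the pair harmonizes trivially; otherwise alleles are drawn
    afresh.  A nonzero ``shared_control_weight`` w mixes a common standard
    normal into every subtype's noise at the same variant (correlation w
    between subtypes), mimicking the shared-control design.
    """
    rng = np.random.default_rng(seed)
    n_var = truth.n_variants
    if exposure is not None:
        if len(exposure) != n_var:
            raise ValueError("exposure table length does not match truth")
        pairs = [(r.effect_allele, r.other_allele) for r in exposure]
        eaf = np.array([0.5 if r.eaf is None else r.eaf for r in exposure])
        ids = [r.variant_id for r in exposure]
    else:
        pairs, eaf = _assign_alleles(rng, n_var, truth.palindromic_fraction)
        ids = list(truth.ld.variant_ids) if truth.ld is not None else [f"rs{j + 1}" for j in range(n_var)]
    alpha = truth.alpha_or_zero()
    w = truth.shared_control_weight
    shared = rng.standard_normal(n_var) if w > 0 else None
    chol = None
    if truth.ld is not None:
        chol = np.linalg.cholesky(truth.ld.r + 1e-12 * np.eye(n_var))
    out: dict[str, list[VariantAssoc]] = {}
    for subtype, n_cases in truth.subtype_cases.items():
        if subtype not in truth.theta_by_subtype:
            raise KeyError(f"unknown subtype {subtype!r}: no causal effect configured")
        theta = truth.theta_by_subtype[subtype]
        n_total = n_cases + truth.n_controls_shared
        phi = n_cases / n_total
        se = _binary_se(eaf, n_total, phi)
        z = rng.standard_normal(n_var)
        if shared is not None:
            z = math.sqrt(w) * shared + math.sqrt(1.0 - w) * z
        if chol is not None:
            z = chol @ z
        beta = theta * truth.gamma + alpha + se * z
        pvals = 2.0 * stats.norm.sf(np.abs(beta) / se)
        out[subtype] = [
            VariantAssoc(
                variant_id=ids[j],
                effect_allele=pairs[j][0],
                other_allele=pairs[j][1],
                beta=float(beta[j]),
                se=float(se[j]),
                pval=float(max(pvals[j], 5e-324)),
                eaf=float(eaf[j]),
                n=n_total,
                trait_id=subtype,
            )
            for j in range(n_var)
        ]
    return out


def plant_pleiotropy(truth: SimTruth, fraction: float, mean: float, sd: float, seed: int) -> SimTruth:
    """Assign direct outcome effects α_j ~ N(mean, sd²) to ⌈fraction·J⌉ random variants.

    mean ≠ 0 produces directional pleiotropy (a nonzero Egger intercept in
    expectation); mean = 0 with sd > 0 produces balanced pleiotropy.  The
    draws are independent of γ, so the InSIDE condition holds by
    construction.
    """
    if not (0 <= fraction <= 1):
        raise ValueError("fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    n_var = truth.n_variants
    alpha = np.zeros(n_var)
    n_pleio = math.ceil(fraction * n_var)
    if n_pleio:
        idx = rng.choice(n_var, size=n_pleio, replace=False)
        alpha[idx] = mean if sd == 0 else rng.normal(mean, sd, size=n_pleio)
    return replace(truth, alpha=alpha, pleio_fraction=fraction, pleio_mean=mean)


def default_truth(n_variants: int = 50, theta: float = 0.2, gamma_scale: float = 0.05,
                  seed: int = 0, theta_by_subtype: Mapping[str, float] | None = None,
                  ld: LDMatrix | None = None, **kwargs) -> SimTruth:
    """Convenience constructor: strong instruments of configurable explained variance.

    Per-variant effect magnitudes are drawn uniformly on
    [0.4, 2.0] × gamma_scale with random signs: every instrument clears the
    genome-wide significance threshold at the default exposure sample size
    (emulating a well-powered discovery GWAS) while the magnitudes stay
    dispersed, as real GWAS effect-size distributions are — the dispersion
    is what gives slope-based estimators such as MR-Egger their leverage.
    At the defaults a 50-variant set explains roughly 8% of exposure
    variance.
    """
    rng = np.random.default_rng(seed)
    gamma = gamma_scale * rng.uniform(0.4, 2.0, size=n_variants) * rng.choice([-1.0, 1.0], size=n_variants)
    if theta_by_subtype is None:
        theta_by_subtype = {s: theta for s in DEFAULT_SUBTYPE_CASES}
    return SimTruth(gamma=gamma, theta_by_subtype=dict(theta_by_subtype), ld=ld, **kwargs)
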