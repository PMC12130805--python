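"""Instrument selection and strength, power, and sample-overlap diagnostics."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from mrpanel.io_config import VariantAssoc


@dataclass(frozen=True)
class InstrumentDiag:
    """Strength and design diagnostics for one instrument set.

    ``r2_total`` is the variance explained in the exposure by the
    instruments, ideally estimated in an independent sample to avoid
    winner's-curse inflation of F.
    """

    r2_total: float
    f_overall: float
    f_min: float
    f_max: float
    n_iv: int
    power: float
    overlap_pct: float

    def __post_init__(self) -> None:
        if self.f_overall < 0 or self.f_min < 0 or self.f_max < 0:
            raise ValueError("F statistics must be nonnegative")
        if not (0 <= self.overlap_pct <= 100):
            raise ValueError("overlap percentage must lie in [0, 100]")


def select_instruments(sumstats: Sequence[VariantAssoc], p_threshold: float = 5e-8) -> list[str]:
    """IDs of variants with p strictly below the significance threshold.

    Order is stable: ascending p-value, ties broken by variant ID.
    """
    hits = [(r.pval, r.variant_id) for r in sumstats if r.pval < p_threshold]
    return [v for _, v in sorted(hits)]


def f_statistic(r2: float, n: int, k: int = 1) -> float:
    """F statistic from variance explained: (r²/k) / ((1−r²)/(n−k−1)).

    With k = 1 this reduces to the familiar single-variant form
    r²(n−2)/(1−r²).
    """
    if not (0 < r2 < 1):
        raise ValueError("r2 must lie strictly in (0, 1)")
    if n <= k + 1 or k < 1:
        raise ValueError("need n > k + 1 >= 2")
    return (r2 / k) / ((1.0 - r2) / (n - k - 1))


def per_variant_f(bx: np.ndarray, sx: np.ndarray) -> np.ndarray:
    """Approximate per-variant F as the squared Wald z of the exposure effect."""
    return (np.asarray(bx) / np.asarray(sx)) ** 2


def mr_power(n: int, case_fraction: float, r2: float, or_alt: float, alpha: float = 0.05) -> float:
    """Approximate power of a binary-outcome MR Wald test.

    The causal log-OR standard error is approximated by
    1/√(n·r²·φ(1−φ)); power is Φ(|ln OR|/se − z_{1−α/2}), symmetric in
    OR ↔ 1/OR.
    """
    if not (0 < case_fraction < 1):
        raise ValueError("case fraction must lie in (0, 1)")
    if n <= 0 or not (0 < r2 < 1) or or_alt <= 0 or not (0 < alpha < 1):
        raise ValueError("invalid power-calculation argument")
    se = 1.0 / np.sqrt(n * r2 * case_fraction * (1.0 - case_fraction))
    z_crit = stats.norm.ppf(1.0 - alpha / 2.0)
    return float(stats.norm.cdf(abs(np.log(or_alt)) / se - z_crit))


def max_overlap_pct(n_overlap: int, n_gwas: int) -> float:
    """Maximum participant overlap as a percentage, rounded to one decimal."""
    if n_gwas <= 0:
        raise ValueError("n_gwas must be positive")
    if not (0 <= n_overlap <= n_gwas):
        raise ValueError("need 0 <= n_overlap <= n_gwas")
    return round(100.0 * n_overlap / n_gwas, 1)


def diagnose(r2_total: float, n_exposure: int, n_iv: int,
             n_outcome: int, case_fraction: float, or_alt: float,
             alpha: float = 0.05, n_overlap: int = 0,
             bx: np.ndarray | None = None, sx: np.ndarray | None = None) -> InstrumentDiag:
    """Assemble the full diagnostic record for one (exposure, outcome) pair."""
    f_all = f_statistic(r2_total, n_exposure, n_iv)
    if bx is not None and sx is not None and len(bx):
        fs = per_variant_f(np.asarray(bx), np.asarray(sx))
        f_min, f_max = float(fs.min()), float(fs.max())
    else:
        f_min = f_max = f_all
    return InstrumentDiag(
        r2_total=r2_total,
        f_overall=f_all,
        f_min=f_min,
        f_max=f_max,
        n_iv=n_iv,
        power=mr_power(n_outcome, case_fraction, r2_total, or_alt, alpha),
        overlap_pct=max_overlap_pct(n_overlap, n_exposure),
    )
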