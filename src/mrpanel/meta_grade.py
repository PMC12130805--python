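"""Cross-outcome heterogeneity meta-analysis and evidence grading.

Causal estimates for the same risk factor across several disease subtypes
are compared with a DerSimonian–Laird random-effects meta-analysis:
Cochran's Q against the fixed-effect pooled estimate, the moment estimator
τ² = max(0, (Q − df)/(Σw − Σw²/Σw)), and I² = max(0, (Q − df)/Q)·100 — the
share of cross-subtype variability beyond chance.  Published panels are
consumed by back-transforming odds ratios and 95% confidence intervals to
log-OR ± SE.

The evidence grade condenses a method panel for one (risk factor, subtype)
cell into four levels: *consistent* (every method p < 0.05), *concordant*
(at least one method p < 0.05 and all effect directions agree),
*inconsistent* (at least one method p < 0.05 but directions disagree) and
*inadequate* (no method p < 0.05).  When MR-PRESSO detects no outliers its
slot is filled with a second copy of the secondary IVW estimate before
tallying.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats


@dataclass(frozen=True)
class MetaResult:
    """Random-effects heterogeneity summary over k outcome-specific estimates."""

    q: float
    df: int
    tau2: float
    i2: float
    pooled: float
    pooled_se: float
    q_pval: float

    def __post_init__(self) -> None:
        if self.tau2 < 0 or not (0 <= self.i2 < 100.0000001):
            raise ValueError("invalid heterogeneity statistics")


@dataclass(frozen=True)
class EvidenceGrade:
    """Four-level grade of the combined evidence in one method panel."""

    grade: str
    n_significant: int
    direction_agreement: bool
    panel_size: int

    GRADES = ("consistent", "concordant", "inconsistent", "inadequate")

    def __post_init__(self) -> None:
        if self.grade not in self.GRADES:
            raise ValueError(f"unknown grade {self.grade!r}")


def se_from_ci(or_value: float, ci_low: float, ci_high: float, level: float = 0.95) -> tuple[float, float]:
    """Recover (log-OR, SE) from a published OR and confidence interval.

    Assumes a symmetric normal interval on the log scale:
    SE = (ln CI_high − ln CI_low) / (2·z_{(1+level)/2}).
    """
    if not (0 < ci_low <= or_value <= ci_high):
        raise ValueError("need 0 < ci_low <= OR <= ci_high")
    if not (0 < level < 1):
        raise ValueError("level must lie in (0, 1)")
    if ci_low == ci_high:
        raise ValueError("degenerate confidence interval (zero width)")
    z = stats.norm.ppf((1 + level) / 2)
    return math.log(or_value), (math.log(ci_high) - math.log(ci_low)) / (2 * z)


def dl_meta(estimates: Sequence[tuple[float, float]]) -> MetaResult:
    """DerSimonian–Laird random-effects meta-analysis of (log-OR, SE) pairs."""
    if len(estimates) < 2:
        raise ValueError("meta-analysis needs at least 2 estimates")
    theta = np.array([e[0] for e in estimates], dtype=float)
    se = np.array([e[1] for e in estimates], dtype=float)
    if np.any(se <= 0):
        raise ValueError("standard errors must be positive")
    w = 1.0 / se**2
    fixed = float(np.sum(w * theta) / np.sum(w))
    q = float(np.sum(w * (theta - fixed) ** 2))
    df = len(estimates) - 1
    c = float(np.sum(w) - np.sum(w**2) / np.sum(w))
    tau2 = max(0.0, (q - df) / c) if c > 0 else 0.0
    i2 = max(0.0, (q - df) / q) * 100.0 if q > 0 else 0.0
    w_re = 1.0 / (se**2 + tau2)
    pooled = float(np.sum(w_re * theta) / np.sum(w_re))
    pooled_se = float(1.0 / np.sqrt(np.sum(w_re)))
    q_pval = float(stats.chi2.sf(q, df))
    return MetaResult(q=q, df=df, tau2=tau2, i2=i2, pooled=pooled, pooled_se=pooled_se, q_pval=q_pval)


def loo_meta(estimates: Sequence[tuple[float, float]], labels: Sequence[str],
             exclude_label: str) -> MetaResult:
    """dl_meta after excluding the estimate carrying ``exclude_label``."""
    if len(estimates) != len(labels):
        raise ValueError("estimates and labels must align")
    if exclude_label not in labels:
        raise KeyError(f"label {exclude_label!r} not present")
    if len(estimates) < 3:
        raise ValueError("leave-one-out meta-analysis needs at least 3 estimates")
    kept = [e for e, lab in zip(estimates, labels) if lab != exclude_label]
    return dl_meta(kept)


def grade_evidence(panel: Sequence[tuple[str, float, float]],
                   presso_found_outliers: bool | None = None,
                   secondary_ivw: tuple[float, float] | None = None) -> EvidenceGrade:
    """Grade one (risk factor, subtype) method panel.

    ``panel`` holds (method, log_or, p) triples.  When
    ``presso_found_outliers`` is False, any MR-PRESSO entry is replaced by
    a second copy of ``secondary_ivw`` before tallying — the convention
    that a clean outlier test validates the secondary IVW estimate.
    Estimates with log_or exactly 0 are direction-neutral and never break
    concordance.
    """
    entries = [(m, b, p) for m, b, p in panel]
    if presso_found_outliers is False and secondary_ivw is not None:
        entries = [(m, b, p) for m, b, p in entries if not m.startswith("mr_presso")]
        b2, p2 = secondary_ivw
        entries.append(("ivw_secondary_dup", b2, p2))
    if not entries:
        raise ValueError("empty method panel")
    for _, _, p in entries:
        if not (0 < p <= 1):
            raise ValueError("panel p-values must lie in (0, 1]")
    n_sig = sum(1 for _, _, p in entries if p < 0.05)
    signs = {1 if b > 0 else -1 for _, b, _ in entries if b != 0}
    agree = len(signs) <= 1
    if n_sig == len(entries):
        grade = "consistent"
    elif n_sig >= 1 and agree:
        grade = "concordant"
    elif n_sig >= 1:
        grade = "inconsistent"
    else:
        grade = "inadequate"
    return EvidenceGrade(grade=grade, n_significant=n_sig,
                         direction_agreement=agree, panel_size=len(entries))
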