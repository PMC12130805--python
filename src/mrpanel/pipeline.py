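"""End-to-end study orchestration: one risk factor panel per outcome subtype.

``run_study`` executes the full design for each (risk factor, outcome)
pair: instrument selection at the configured p-value threshold,
harmonization (palindromic exclusion, optional proxies), the primary
correlated-instrument IVW with PCA reduction on the full instrument set,
the secondary panel (IVW, MR-Egger, weighted median, weighted mode,
MR-PRESSO) on the LD-clumped set, optional multivariable and
female-weighted reruns, then cross-subtype DerSimonian–Laird
meta-analysis and evidence grading.  A failure in one cell aborts that
cell with a logged reason and never perturbs the others.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from mrpanel import estimators, ld_pca, meta_grade
from mrpanel.harmonize import HarmonizedSet, clump, harmonize
from mrpanel.instruments import select_instruments
from mrpanel.io_config import LDMatrix, RunConfig, VariantAssoc, logger

SECONDARY_METHODS = ("ivw", "mr_egger", "weighted_median", "weighted_mode", "mr_presso")
ALL_METHODS = ("ivw_correlated_pca",) + SECONDARY_METHODS


@dataclass(frozen=True)
class StudySpec:
    """One complete study: a set of risk factors against a set of outcomes."""

    exposures: Mapping[str, Sequence[VariantAssoc]]
    outcomes: Mapping[str, Sequence[VariantAssoc]]
    ld: LDMatrix | None = None
    config: RunConfig = field(default_factory=RunConfig)
    p_thresholds: Mapping[str, float] = field(default_factory=dict)
    female_exposures: Mapping[str, Sequence[VariantAssoc]] = field(default_factory=dict)
    mvmr_partners: Mapping[str, str] = field(default_factory=dict)
    loo_exclude: str | None = None


def swap_female_weights(instruments: Sequence[VariantAssoc],
                        female_sumstats: Sequence[VariantAssoc]) -> tuple[list[VariantAssoc], dict[str, int]]:
    """Replace sex-combined betas/SEs by female-specific ones where available.

    Instruments absent from the female table keep their sex-combined
    values and are flagged; returns the updated records and the
    replaced/retained counts.
    """
    female = {r.variant_id: r for r in female_sumstats}
    out: list[VariantAssoc] = []
    counts = {"replaced": 0, "sex_combined_retained": 0}
    from dataclasses import replace as _replace
    for rec in instruments:
        f = female.get(rec.variant_id)
        if f is None:
            counts["sex_combined_retained"] += 1
            out.append(rec)
        else:
            counts["replaced"] += 1
            out.append(_replace(rec, beta=f.beta, se=f.se, pval=f.pval, n=f.n))
    return out, counts


def _panel_for_cell(exposure: Sequence[VariantAssoc], outcome: Sequence[VariantAssoc],
                    ld: LDMatrix | None, cfg: RunConfig, p_threshold: float,
                    seed: int) -> tuple[list[estimators.MREstimate], dict]:
    """Primary + secondary estimates for one (risk factor, outcome) cell."""
    iv_ids = select_instruments(exposure, p_threshold)
    if len(iv_ids) < 2:
        raise ValueError(f"only {len(iv_ids)} instruments at p < {p_threshold}")
    exp_sel = [r for r in exposure if r.variant_id in set(iv_ids)]
    hset, drops = harmonize(exp_sel, outcome, eaf_window=cfg.palindromic_eaf_window,
                            ld=ld.subset([v for v in ld.variant_ids
                                          if v in {r.variant_id for r in exp_sel}]) if ld else None)
    if hset.n_variants < 2:
        raise ValueError("fewer than 2 instruments survive harmonization")

    results: list[estimators.MREstimate] = []
    results.append(ld_pca.pca_ivw(hset, cfg.pca_var_explained))

    # robust methods run on the LD-clumped (uncorrelated) instrument set
    if hset.ld is not None:
        pmap = {r.variant_id: r.pval for r in exp_sel}
        kept = clump(list(hset.variant_ids), [pmap[v] for v in hset.variant_ids],
                     hset.ld, cfg.clump_r2_max)
        hclump = hset.subset(kept).without_ld()
    else:
        hclump = hset.without_ld()

    results.append(estimators.ivw_uncorrelated(hclump))
    if hclump.n_variants >= 3:
        results.append(estimators.egger(hclump))
        results.append(estimators.weighted_median(hclump, cfg.n_boot, seed))
        results.append(estimators.weighted_mode(hclump, n_boot=cfg.n_boot, seed=seed + 1))
    if hclump.n_variants >= 4:
        results.append(estimators.mr_presso(hclump, cfg.n_sim_presso, seed + 2, cfg.alpha))
    meta_info = {"drops": drops, "n_primary": hset.n_variants, "n_clumped": hclump.n_variants}
    return results, meta_info


@dataclass
class StudyResult:
    """All per-cell estimates plus cross-subtype meta-analysis and grades."""

    estimates: dict[tuple[str, str], list[estimators.MREstimate]]
    aborted: dict[tuple[str, str], str]
    meta: dict[str, meta_grade.MetaResult]
    meta_loo: dict[str, meta_grade.MetaResult]
    grades: dict[tuple[str, str], meta_grade.EvidenceGrade]

    def report_rows(self) -> list[dict]:
        rows = []
        for (factor, outcome), ests in sorted(self.estimates.items()):
            grade = self.grades.get((factor, outcome))
            for est in ests:
                rows.append({
                    "risk_factor": factor,
                    "outcome": outcome,
                    "method": est.method,
                    "or": float("nan") if math.isnan(est.beta) else est.odds_ratio,
                    "ci_low": float("nan") if math.isnan(est.beta) else math.exp(est.ci_low),
                    "ci_high": float("nan") if math.isnan(est.beta) else math.exp(est.ci_high),
                    "p": est.pval,
                    "n_snp": est.n_snp,
                    "grade": grade.grade if grade else "",
                })
        for (factor, outcome), reason in sorted(self.aborted.items()):
            rows.append({"risk_factor": factor, "outcome": outcome, "method": "aborted",
                         "or": float("nan"), "ci_low": float("nan"), "ci_high": float("nan"),
                         "p": float("nan"), "n_snp": 0, "grade": reason})
        return rows


def run_study(spec: StudySpec) -> StudyResult:
    """Execute the complete design; deterministic given the config seed."""
    cfg = spec.config
    estimates: dict[tuple[str, str], list[estimators.MREstimate]] = {}
    aborted: dict[tuple[str, str], str] = {}
    for fi, (factor, exposure) in enumerate(sorted(spec.exposures.items())):
        p_thr = spec.p_thresholds.get(factor, cfg.p_threshold)
        variants = list(exposure)
        for oi, (outcome_name, outcome) in enumerate(sorted(spec.outcomes.items())):
            cell_seed = cfg.seed + 1009 * fi + 13 * oi
            try:
                ests, _ = _panel_for_cell(variants, outcome, spec.ld, cfg, p_thr, cell_seed)
                estimates[(factor, outcome_name)] = ests
            except Exception as exc:  # noqa: BLE001 — cell isolation is the contract
                logger.warning("cell (%s, %s) aborted: %s", factor, outcome_name, exc)
                aborted[(factor, outcome_name)] = str(exc)

        if factor in spec.female_exposures:
            swapped, counts = swap_female_weights(variants, spec.female_exposures[factor])
            logger.info("female weights for %s: %s", factor, counts)
            for oi, (outcome_name, outcome) in enumerate(sorted(spec.outcomes.items())):
                cell_seed = cfg.seed + 1009 * fi + 13 * oi + 7
                try:
                    ests, _ = _panel_for_cell(swapped, outcome, spec.ld, cfg, p_thr, cell_seed)
                    estimates[(f"{factor}[female]", outcome_name)] = ests
                except Exception as exc:  # noqa: BLE001
                    aborted[(f"{factor}[female]", outcome_name)] = str(exc)

    # cross-subtype heterogeneity on the primary estimates
    meta: dict[str, meta_grade.MetaResult] = {}
    meta_loo: dict[str, meta_grade.MetaResult] = {}
    for factor in {f for f, _ in estimates}:
        cells = [(o, ests[0]) for (f, o), ests in sorted(estimates.items()) if f == factor]
        pairs = [(e.beta, e.se) for _, e in cells]
        labels = [o for o, _ in cells]
        if len(pairs) >= 2:
            meta[factor] = meta_grade.dl_meta(pairs)
        if spec.loo_exclude is not None and spec.loo_exclude in labels and len(pairs) >= 3:
            meta_loo[factor] = meta_grade.loo_meta(pairs, labels, spec.loo_exclude)

    # evidence grade per cell from the full method panel
    grades: dict[tuple[str, str], meta_grade.EvidenceGrade] = {}
    for key, ests in estimates.items():
        panel = []
        presso_outliers: bool | None = None
        secondary: tuple[float, float] | None = None
        for est in ests:
            if est.method == "ivw":
                secondary = (est.beta, est.pval)
            if est.method == "mr_presso":
                presso_outliers = bool(est.extras.get("presso_outlier_ids"))
                if not presso_outliers:
                    continue  # replaced by the duplicated secondary IVW below
            panel.append((est.method, est.beta, est.pval))
        grades[key] = meta_grade.grade_evidence(panel, presso_outliers, secondary)
    return StudyResult(estimates=estimates, aborted=aborted, meta=meta,
                       meta_loo=meta_loo, grades=grades)
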