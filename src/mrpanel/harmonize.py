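"""Allele harmonization, proxy substitution and LD clumping.

Exposure and outcome summary statistics must refer to the same effect
allele before any ratio of effects is meaningful.  Harmonization resolves
allele order and strand: outcome effects are negated when the studies
report opposite effect alleles, strand-flipped records are matched through
base complementation, and palindromic variants (A/T or C/G pairs, identical
to their own complement) are resolved by effect-allele-frequency
concordance — or excluded outright when the exposure EAF lies inside the
ambiguous window around 0.5, where frequency cannot identify the strand.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np

from mrpanel.io_config import LDMatrix, VariantAssoc, logger

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


def complement(allele: str) -> str:
    """Watson–Crick complement of a single-base allele."""
    try:
        return _COMPLEMENT[allele]
    except KeyError:
        raise ValueError(f"not a valid allele: {allele!r}") from None


@dataclass(frozen=True)
class HarmonizedSet:
    """Aligned exposure/outcome effect vectors ready for estimation.

    ``flags[j]`` records the harmonization action for variant j:
    ``kept``, ``flipped``, or ``proxy:<original_id>`` (possibly combined,
    e.g. ``proxy:rs1|flipped``).
    """

    variant_ids: tuple[str, ...]
    bx: np.ndarray
    sx: np.ndarray
    by: np.ndarray
    sy: np.ndarray
    ld: LDMatrix | None = None
    flags: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        arrays = {}
        for name in ("bx", "sx", "by", "sy"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (len(self.variant_ids),):
                raise ValueError(f"{name} length does not match variant_ids")
            arrays[name] = arr
        if np.any(arrays["sx"] <= 0) or np.any(arrays["sy"] <= 0):
            raise ValueError("standard errors must be positive")
        for name, arr in arrays.items():
            object.__setattr__(self, name, arr)
        if self.ld is not None and self.ld.variant_ids != self.variant_ids:
            raise ValueError("LD matrix IDs must equal variant_ids in order")
        if not self.flags:
            object.__setattr__(self, "flags", tuple("kept" for _ in self.variant_ids))

    @property
    def n_variants(self) -> int:
        return len(self.variant_ids)

    def subset(self, ids: Sequence[str]) -> "HarmonizedSet":
        index = {v: i for i, v in enumerate(self.variant_ids)}
        idx = [index[v] for v in ids]
        return HarmonizedSet(
            variant_ids=tuple(ids),
            bx=self.bx[idx], sx=self.sx[idx], by=self.by[idx], sy=self.sy[idx],
            ld=self.ld.subset(ids) if self.ld is not None else None,
            flags=tuple(self.flags[i] for i in idx),
        )

    def without_ld(self) -> "HarmonizedSet":
        return replace(self, ld=None)


def harmonize_pair(exp: VariantAssoc, out: VariantAssoc,
                   eaf_window: tuple[float, float] = (0.40, 0.60)):
    """Align one outcome record to the exposure's effect allele.

    Returns ``(harmonized_outcome, flag)`` on success or ``(None, reason)``
    when the variant must be dropped.  Resolution order: direct allele
    match; swapped alleles (outcome beta negated, EAF complemented); the
    same two cases after strand complementation; palindromic variants
    resolved by EAF-side concordance unless the exposure EAF falls inside
    the ambiguous window (inclusive), in which case the variant is dropped
    as ``palindromic_ambiguous``; anything else is an ``allele_mismatch``.
    """
    if exp.variant_id != out.variant_id:
        raise ValueError(f"variant_id mismatch: {exp.variant_id} vs {out.variant_id}")
    ea, oa = exp.effect_allele, exp.other_allele

    if exp.is_palindromic:
        # A/T and C/G pairs are their own strand complement: allele labels
        # cannot identify orientation, only frequency can.
        if {out.effect_allele, out.other_allele} != {ea, oa}:
            return None, "allele_mismatch"
        lo, hi = eaf_window
        if exp.eaf is not None and lo <= exp.eaf <= hi:
            return None, "palindromic_ambiguous"
        if exp.eaf is None or out.eaf is None:
            return None, "eaf_missing"
        # express the outcome on the exposure's allele labels, then let
        # frequency concordance decide the strand orientation
        if out.effect_allele == ea:
            beta, eaf = out.beta, out.eaf
        else:
            beta, eaf = -out.beta, 1.0 - out.eaf
        if (exp.eaf < 0.5) != (eaf < 0.5):
            beta, eaf = -beta, 1.0 - eaf
        flag = "kept" if beta == out.beta else "flipped"
        return replace(out, effect_allele=ea, other_allele=oa, beta=beta, eaf=eaf), flag

    for strand_flip in (False, True):
        o_ea = complement(out.effect_allele) if strand_flip else out.effect_allele
        o_oa = complement(out.other_allele) if strand_flip else out.other_allele
        if (o_ea, o_oa) == (ea, oa):
            rec = replace(out, effect_allele=ea, other_allele=oa)
            return rec, "kept" if not strand_flip else "kept_strand"
        if (o_ea, o_oa) == (oa, ea):
            rec = replace(
                out,
                effect_allele=ea,
                other_allele=oa,
                beta=-out.beta,
                eaf=None if out.eaf is None else 1.0 - out.eaf,
            )
            return rec, "flipped" if not strand_flip else "flipped_strand"
    return None, "allele_mismatch"


def find_proxies(missing_ids: Sequence[str], ld_ref: LDMatrix,
                 candidate_ids: Sequence[str], r2_min: float = 0.8,
                 exposure_pvals: Mapping[str, float] | None = None) -> dict[str, str]:
    """Map instruments absent from the outcome data to LD proxies.

    For each missing ID the candidate with the highest r² ≥ ``r2_min`` is
    chosen; ties break by smaller exposure p-value, then lexicographic ID.
    Candidates already claimed as proxies are not reused.  IDs with no
    qualifying proxy are reported (logged) and simply absent from the map.
    """
    index = {v: i for i, v in enumerate(ld_ref.variant_ids)}
    pvals = exposure_pvals or {}
    mapping: dict[str, str] = {}
    claimed: set[str] = set()
    for mid in missing_ids:
        if mid not in index:
            logger.info("find_proxies: %s not in LD reference", mid)
            continue
        best: tuple[float, float, str] | None = None
        for cand in candidate_ids:
            if cand == mid or cand in claimed or cand not in index:
                continue
            r2 = float(ld_ref.r[index[mid], index[cand]] ** 2)
            if r2 < r2_min:
                continue
            key = (-r2, pvals.get(cand, 1.0), cand)
            if best is None or key < best:
                best = key
        if best is None:
            logger.info("find_proxies: no proxy at r2 >= %s for %s", r2_min, mid)
            continue
        mapping[mid] = best[2]
        claimed.add(best[2])
    return mapping


def clump(ids: Sequence[str], pvals: Sequence[float], ld_ref: LDMatrix,
          r2_max: float = 0.001) -> list[str]:
    """Greedy LD clumping: keep index variants, discard correlated neighbours.

    Repeatedly selects the unclaimed variant with the smallest p-value
    (ties broken lexicographically by ID) and removes every remaining
    variant with r² > ``r2_max`` to it.  Output order is selection order,
    hence deterministic and independent of input ordering.
    """
    if len(ids) != len(pvals):
        raise ValueError("ids and pvals must align")
    index = {v: i for i, v in enumerate(ld_ref.variant_ids)}
    remaining = sorted(zip(pvals, ids))
    retained: list[str] = []
    while remaining:
        _, lead = remaining[0]
        retained.append(lead)
        li = index[lead]
        remaining = [
            (p, v) for p, v in remaining[1:]
            if float(ld_ref.r[li, index[v]] ** 2) <= r2_max
        ]
    return retained


def harmonize(exposure: Sequence[VariantAssoc], outcome: Sequence[VariantAssoc],
              eaf_window: tuple[float, float] = (0.40, 0.60),
              ld: LDMatrix | None = None,
              ld_ref: LDMatrix | None = None,
              proxy_r2_min: float = 0.8,
              require_in_reference: bool = False) -> tuple[HarmonizedSet, dict[str, int]]:
    """Harmonize an instrument set against one outcome GWAS.

    Instruments missing from the outcome table are proxied through
    ``ld_ref`` when supplied (the proxy's own alleles are harmonized
    afresh and the signed LD correlation transfers the effect direction).
    With ``require_in_reference`` instruments absent from ``ld_ref`` are
    dropped as ``not_in_reference``, emulating a reference-panel
    availability filter.  Returns the harmonized set and a drop-reason
    count dictionary.
    """
    out_by_id = {r.variant_id: r for r in outcome}
    drops: dict[str, int] = {}
    rows: list[tuple[str, float, float, float, float, str]] = []

    ref_ids = set(ld_ref.variant_ids) if ld_ref is not None else None
    missing = [e.variant_id for e in exposure if e.variant_id not in out_by_id]
    proxy_map: dict[str, str] = {}
    if missing and ld_ref is not None:
        instrument_ids = {e.variant_id for e in exposure}
        candidates = [v for v in out_by_id if v not in instrument_ids]
        proxy_map = find_proxies(missing, ld_ref, candidates, proxy_r2_min,
                                 exposure_pvals=None)

    ref_index = {v: i for i, v in enumerate(ld_ref.variant_ids)} if ld_ref is not None else {}
    for exp in exposure:
        if ref_ids is not None and require_in_reference and exp.variant_id not in ref_ids:
            drops["not_in_reference"] = drops.get("not_in_reference", 0) + 1
            continue
        proxy_note = ""
        out = out_by_id.get(exp.variant_id)
        sign = 1.0
        if out is None:
            proxy_id = proxy_map.get(exp.variant_id)
            if proxy_id is None:
                drops["missing_in_outcome"] = drops.get("missing_in_outcome", 0) + 1
                continue
            out = out_by_id[proxy_id]
            r_signed = ld_ref.r[ref_index[exp.variant_id], ref_index[proxy_id]]
            sign = 1.0 if r_signed >= 0 else -1.0
            proxy_note = f"proxy:{exp.variant_id}"
            out = replace(out, variant_id=exp.variant_id,
                          effect_allele=exp.effect_allele, other_allele=exp.other_allele,
                          beta=sign * out.beta)
            harmonized, flag = out, "kept"
        else:
            harmonized, flag = harmonize_pair(exp, out, eaf_window)
        if harmonized is None:
            drops[flag] = drops.get(flag, 0) + 1
            continue
        final_flag = f"{proxy_note}|{flag}" if proxy_note else flag
        rows.append((exp.variant_id, exp.beta, exp.se, harmonized.beta, harmonized.se, final_flag))

    ids = tuple(r[0] for r in rows)
    hset = HarmonizedSet(
        variant_ids=ids,
        bx=np.array([r[1] for r in rows]),
        sx=np.array([r[2] for r in rows]),
        by=np.array([r[3] for r in rows]),
        sy=np.array([r[4] for r in rows]),
        ld=ld.subset(ids) if ld is not None and ids else None,
        flags=tuple(r[5] for r in rows),
    )
    if drops:
        logger.info("harmonize: dropped %s", drops)
    return hset, drops
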