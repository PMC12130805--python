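"""File formats, run configuration and provenance for the MR pipeline.

Summary statistics travel as tab-separated tables with GWAS-SSF-style
lowercase column names (``variant_id``, ``effect_allele``, ``other_allele``,
``effect_allele_frequency``, ``beta``, ``standard_error``, ``p_value``, ``n``).
LD matrices are square TSVs of signed correlations keyed by variant ID on
both axes.  Run configuration is a flat ``key: value`` text file mirroring
:class:`RunConfig`.
"""

from __future__ import annotations

import hashlib
import logging
import math
import sys
from collections import Counter
from dataclasses import dataclass, field, fields, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("mrpanel")

VALID_ALLELES = frozenset("ACGT")

MANDATORY_COLUMNS = (
    "variant_id",
    "effect_allele",
    "other_allele",
    "beta",
    "standard_error",
    "p_value",
)
OPTIONAL_COLUMNS = ("effect_allele_frequency", "n")


def setup_logging(level: str = "INFO") -> None:
    """Route timestamped, level-tagged pipeline logs to standard error."""
    handler = logging.StreamHandler(sys.stderr)
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(name)s: %(message)s"))
    logger.handlers[:] = [handler]
    logger.setLevel(level.upper())


@dataclass(frozen=True)
class VariantAssoc:
    """One variant's association with one trait.

    ``beta`` is on the log-odds scale for binary traits and in SD or
    natural units for quantitative traits; ``eaf`` is the effect-allele
    frequency and may be missing (``None``).
    """

    variant_id: str
    effect_allele: str
    other_allele: str
    beta: float
    se: float
    pval: float
    eaf: float | None = None
    n: int | None = None
    trait_id: str = ""

    def validate(self) -> str | None:
        """Return a drop reason if any invariant is violated, else None."""
        if self.effect_allele not in VALID_ALLELES or self.other_allele not in VALID_ALLELES:
            return "invalid_allele"
        if self.effect_allele == self.other_allele:
            return "identical_alleles"
        if not (self.se > 0) or not math.isfinite(self.se):
            return "nonpositive_se"
        if not (0 < self.pval <= 1):
            return "pval_out_of_range"
        if not math.isfinite(self.beta):
            return "nonfinite_beta"
        if self.eaf is not None and not (0 <= self.eaf <= 1):
            return "eaf_out_of_range"
        if self.n is not None and self.n <= 0:
            return "nonpositive_n"
        return None

    @property
    def is_palindromic(self) -> bool:
        return {self.effect_allele, self.other_allele} in ({"A", "T"}, {"C", "G"})


@dataclass(frozen=True)
class LDMatrix:
    """Signed linkage-disequilibrium correlation matrix over named variants."""

    variant_ids: tuple[str, ...]
    r: np.ndarray

    def __post_init__(self) -> None:
        r = np.asarray(self.r, dtype=float)
        if r.ndim != 2 or r.shape[0] != r.shape[1]:
            raise ValueError("LD matrix must be square")
        if r.shape[0] != len(self.variant_ids):
            raise ValueError("LD matrix dimension does not match number of variant IDs")
        if np.any(np.abs(r) > 1 + 1e-6):
            raise ValueError("LD correlations must lie in [-1, 1]")
        object.__setattr__(self, "r", r)

    @property
    def size(self) -> int:
        return len(self.variant_ids)

    def subset(self, ids: Sequence[str]) -> "LDMatrix":
        """Restrict to ``ids`` in the given order."""
        index = {v: i for i, v in enumerate(self.variant_ids)}
        try:
            idx = [index[v] for v in ids]
        except KeyError as exc:
            raise KeyError(f"variant {exc.args[0]!r} absent from LD matrix") from None
        return LDMatrix(tuple(ids), self.r[np.ix_(idx, idx)])

    def r2(self, a: str, b: str) -> float:
        index = {v: i for i, v in enumerate(self.variant_ids)}
        return float(self.r[index[a], index[b]] ** 2)


@dataclass(frozen=True)
class RunConfig:
    """Thresholds and seeds steering one pipeline run.

    Defaults mirror standard two-sample MR practice: genome-wide
    significance for instrument selection, proxies at r² ≥ 0.8, clumping at
    r² ≤ 0.001, exclusion of palindromic variants with effect-allele
    frequency in [0.40, 0.60], and 99% variance retained in the PCA
    transformation of near-singular LD matrices.
    """

    exposure_path: str = ""
    outcome_paths: tuple[str, ...] = ()
    p_threshold: float = 5e-8
    proxy_r2_min: float = 0.8
    clump_r2_max: float = 0.001
    palindromic_eaf_window: tuple[float, float] = (0.40, 0.60)
    pca_var_explained: float = 0.99
    alpha: float = 0.05
    n_boot: int = 1000
    n_sim_presso: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.palindromic_eaf_window
        if not (0 <= lo <= hi <= 1):
            raise ValueError("palindromic EAF window must satisfy 0 <= low <= high <= 1")
        if not (0 < self.p_threshold < 1):
            raise ValueError("p_threshold must lie in (0, 1)")
        if not (0 <= self.proxy_r2_min <= 1) or not (0 <= self.clump_r2_max <= 1):
            raise ValueError("r2 thresholds must lie in [0, 1]")
        if not (0 < self.pca_var_explained <= 1):
            raise ValueError("pca_var_explained must lie in (0, 1]")
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must lie in (0, 1)")

    def digest(self) -> str:
        """Short hash of all configuration fields, for provenance headers."""
        payload = "|".join(f"{f.name}={getattr(self, f.name)}" for f in fields(self))
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    def with_seed(self, seed: int) -> "RunConfig":
        return replace(self, seed=seed)


def parse_config(path: str | Path) -> RunConfig:
    """Parse a flat ``key: value`` configuration file into a RunConfig."""
    kwargs: dict = {}
    for raw in Path(path).read_text().splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if ":" not in line:
            raise ValueError(f"malformed config line: {raw!r}")
        key, value = (part.strip() for part in line.split(":", 1))
        if key == "outcome_paths":
            kwargs[key] = tuple(v.strip() for v in value.split(",") if v.strip())
        elif key == "palindromic_eaf_window":
            lo, hi = (float(v) for v in value.split(","))
            kwargs[key] = (lo, hi)
        elif key in ("n_boot", "n_sim_presso", "seed"):
            kwargs[key] = int(value)
        elif key in ("exposure_path",):
            kwargs[key] = value
        else:
            kwargs[key] = float(value)
    return RunConfig(**kwargs)


def read_sumstats(path: str | Path, trait_id: str = "") -> list[VariantAssoc]:
    """Read a summary-statistics TSV into validated :class:`VariantAssoc` records.

    Alleles are upper-cased on ingest.  Rows violating the record invariants
    (non-positive SE, p outside (0,1], non-ACGT alleles, ...) are dropped and
    the per-reason counts logged; a missing mandatory column is a hard error.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"variant_id": str})
    if df.empty and df.columns.size == 0:
        raise ValueError(f"empty summary-statistics file: {path}")
    for col in MANDATORY_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"missing mandatory column {col!r} in {path}")
    records: list[VariantAssoc] = []
    drops: Counter[str] = Counter()
    has_eaf = "effect_allele_frequency" in df.columns
    has_n = "n" in df.columns
    for row in df.itertuples(index=False):
        eaf = getattr(row, "effect_allele_frequency", None) if has_eaf else None
        if eaf is not None and (isinstance(eaf, float) and math.isnan(eaf)):
            eaf = None
        n = getattr(row, "n", None) if has_n else None
        if n is not None and (isinstance(n, float) and math.isnan(n)):
            n = None
        rec = VariantAssoc(
            variant_id=str(row.variant_id),
            effect_allele=str(row.effect_allele).upper(),
            other_allele=str(row.other_allele).upper(),
            beta=float(row.beta),
            se=float(row.standard_error),
            pval=float(row.p_value),
            eaf=None if eaf is None else float(eaf),
            n=None if n is None else int(n),
            trait_id=trait_id,
        )
        reason = rec.validate()
        if reason is None:
            records.append(rec)
        else:
            drops[reason] += 1
    if drops:
        logger.info("read_sumstats(%s): dropped %s", path.name, dict(drops))
    read_sumstats.last_drop_log = dict(drops)  # type: ignore[attr-defined]
    return records


read_sumstats.last_drop_log = {}  # type: ignore[attr-defined]


def write_sumstats(records: Iterable[VariantAssoc], path: str | Path, header_comment: str | None = None) -> None:
    """Write records to the summary-statistics TSV dialect read_sumstats consumes."""
    rows = [
        {
            "variant_id": r.variant_id,
            "effect_allele": r.effect_allele,
            "other_allele": r.other_allele,
            "effect_allele_frequency": r.eaf,
            "beta": repr(r.beta),
            "standard_error": repr(r.se),
            "p_value": repr(r.pval),
            "n": r.n,
        }
        for r in records
    ]
    df = pd.DataFrame(rows, columns=["variant_id", "effect_allele", "other_allele",
                                     "effect_allele_frequency", "beta", "standard_error", "p_value", "n"])
    path = Path(path)
    with path.open("w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_ld_matrix(path: str | Path) -> LDMatrix:
    """Read a square signed-correlation TSV keyed by variant ID on both axes.

    Symmetry is enforced by averaging (M + Mᵀ)/2 and the diagonal reset to
    exactly 1; a non-square table, mismatched row/column IDs, or any entry
    with |r| > 1 + 1e-6 is a hard error.
    """
    df = pd.read_csv(path, sep="\t", comment="#", index_col=0)
    if df.shape[0] != df.shape[1]:
        raise ValueError(f"LD matrix in {path} is not square: {df.shape}")
    row_ids = [str(i) for i in df.index]
    col_ids = [str(c) for c in df.columns]
    if row_ids != col_ids:
        raise ValueError(f"LD matrix row IDs do not match column IDs in {path}")
    m = df.to_numpy(dtype=float)
    if np.any(np.abs(m) > 1 + 1e-6):
        raise ValueError(f"LD matrix in {path} has |r| > 1")
    m = (m + m.T) / 2.0
    np.fill_diagonal(m, 1.0)
    return LDMatrix(tuple(row_ids), np.clip(m, -1.0, 1.0))


def write_ld_matrix(ld: LDMatrix, path: str | Path) -> None:
    pd.DataFrame(ld.r, index=list(ld.variant_ids), columns=list(ld.variant_ids)).to_csv(path, sep="\t")


REPORT_COLUMNS = ("risk_factor", "outcome", "method", "or_", "ci_low", "ci_high", "p", "n_snp", "grade")


def write_report(rows: Sequence[Mapping], path: str | Path, config: RunConfig | None = None) -> None:
    """Write result rows to a fixed-column TSV with ≥4 significant digits.

    Column order is fixed (risk_factor, outcome, method, or, ci_low, ci_high,
    p, n_snp, grade); a provenance comment header carries the seed and config
    digest when a config is supplied.
    """
    out_cols = [c.rstrip("_") for c in REPORT_COLUMNS]
    lines = ["\t".join(out_cols)]
    for row in rows:
        cells = []
        for col, out in zip(REPORT_COLUMNS, out_cols):
            value = row.get(out, row.get(col, ""))
            if isinstance(value, float):
                cells.append("NA" if math.isnan(value) else f"{value:.9g}")
            else:
                cells.append("" if value is None else str(value))
        lines.append("\t".join(cells))
    with Path(path).open("w") as fh:
        if config is not None:
            fh.write(f"# seed={config.seed} config_digest={config.digest()}\n")
        fh.write("\n".join(lines) + "\n")


def read_report(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", na_values=["NA"])
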