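"""Reading, validating and writing GWAS summary statistics and result tables.

The on-disk canonical format is a delimited text file (TSV by default, CSV
auto-detected) with one row per SNP and the header::

    snp_id  chrom  pos  effect_allele  other_allele  eaf  beta  se  pval  n

Files from other providers are adapted through a ``column_map`` from their
header names to these canonical names.  All result tables written by the
pipeline are plain TSV so that every artifact round-trips through pandas.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: canonical column order for summary-statistic files
SUMSTAT_COLUMNS = [
    "snp_id",
    "chrom",
    "pos",
    "effect_allele",
    "other_allele",
    "eaf",
    "beta",
    "se",
    "pval",
    "n",
]

VALID_ALLELES = {"A", "C", "G", "T"}

TRAIT_CLASSES = ("immune_cell", "inflammatory_factor", "disease")


class DataError(ValueError):
    """Raised when an input file cannot yield a valid panel."""


@dataclass(frozen=True)
class SnpAssociation:
    """One SNP's marginal association with one trait.

    ``beta`` is the additive effect per copy of ``effect_allele`` (log-odds
    for binary traits); ``eaf`` may be NaN when the provider omitted allele
    frequencies.
    """

    snp_id: str
    chrom: str
    pos: int
    effect_allele: str
    other_allele: str
    eaf: float
    beta: float
    se: float
    pval: float
    n: int


@dataclass
class TraitPanel:
    """A validated set of per-SNP summary statistics for one trait.

    Internally a DataFrame with :data:`SUMSTAT_COLUMNS`, canonically sorted
    by ``snp_id`` so that panels compare independent of input row order.
    """

    trait_id: str
    trait_class: str
    data: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        if self.trait_class not in TRAIT_CLASSES:
            raise ValueError(
                f"trait_class must be one of {TRAIT_CLASSES}, got {self.trait_class!r}"
            )
        self.data = (
            self.data[SUMSTAT_COLUMNS]
            .sort_values("snp_id", kind="stable")
            .reset_index(drop=True)
        )

    def __len__(self) -> int:
        return len(self.data)

    @property
    def associations(self) -> list[SnpAssociation]:
        return [SnpAssociation(**rec) for rec in self.data.to_dict("records")]

    def subset(self, snp_ids: Iterable[str]) -> "TraitPanel":
        ids = set(snp_ids)
        return TraitPanel(
            self.trait_id, self.trait_class, self.data[self.data.snp_id.isin(ids)]
        )

    def equals(self, other: "TraitPanel", rtol: float = 1e-12) -> bool:
        if self.trait_id != other.trait_id or self.trait_class != other.trait_class:
            return False
        a, b = self.data, other.data
        if len(a) != len(b):
            return False
        str_cols = ["snp_id", "chrom", "effect_allele", "other_allele"]
        if not (a[str_cols].values == b[str_cols].values).all():
            return False
        if not (a["pos"].values == b["pos"].values).all() or not (
            a["n"].values == b["n"].values
        ).all():
            return False
        for col in ("eaf", "beta", "se", "pval"):
            if not np.allclose(a[col].values, b[col].values, rtol=rtol, equal_nan=True):
                return False
        return True


def _coerce_types(df: pd.DataFrame) -> pd.DataFrame:
    df = df.copy()
    df["snp_id"] = df["snp_id"].astype(str)
    df["chrom"] = df["chrom"].astype(str)
    df["effect_allele"] = df["effect_allele"].astype(str).str.upper()
    df["other_allele"] = df["other_allele"].astype(str).str.upper()
    for col in ("eaf", "beta", "se", "pval"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    df["pos"] = pd.to_numeric(df["pos"], errors="coerce")
    df["n"] = pd.to_numeric(df["n"], errors="coerce")
    return df


def validate_panel_frame(df: pd.DataFrame) -> tuple[pd.DataFrame, dict[str, int]]:
    """Apply row-level invariants, returning (valid rows, drop counts by reason).

    Rows are dropped (never repaired) when: beta/se/pval/pos/n missing or
    non-finite, se <= 0, pval outside (0, 1], alleles not single A/C/G/T or
    equal, eaf outside [0, 1] when present, or snp_id duplicated.  A missing
    eaf is tolerated and only counted in the audit.
    """
    df = _coerce_types(df)
    drops: dict[str, int] = {}

    def drop(mask: pd.Series, reason: str) -> pd.DataFrame:
        nonlocal df
        k = int(mask.sum())
        if k:
            drops[reason] = drops.get(reason, 0) + k
            df = df[~mask]
        return df

    drop(df["beta"].isna() | df["se"].isna() | df["pval"].isna(), "missing_beta_se_p")
    drop(df["pos"].isna() | df["n"].isna(), "missing_pos_n")
    drop(df["se"] <= 0, "nonpositive_se")
    drop((df["pval"] <= 0) | (df["pval"] > 1), "pval_out_of_range")
    bad_allele = (
        ~df["effect_allele"].isin(VALID_ALLELES)
        | ~df["other_allele"].isin(VALID_ALLELES)
        | (df["effect_allele"] == df["other_allele"])
    )
    drop(bad_allele, "invalid_alleles")
    drop((df["eaf"] < 0) | (df["eaf"] > 1), "eaf_out_of_range")
    drop(df["snp_id"].duplicated(keep="first"), "duplicate_snp_id")

    n_missing_eaf = int(df["eaf"].isna().sum())
    if n_missing_eaf:
        logger.warning("%d rows have missing eaf (tolerated)", n_missing_eaf)
    df = df.astype({"pos": np.int64, "n": np.int64})
    return df.reset_index(drop=True), drops


def read_summary_stats(
    path: str | Path,
    *,
    column_map: Mapping[str, str] | None = None,
    trait_id: str | None = None,
    trait_class: str = "disease",
) -> TraitPanel:
    """Read a summary-statistic file into a validated :class:`TraitPanel`.

    ``column_map`` maps *file* header names to canonical names, e.g.
    ``{"b": "beta", "rsid": "snp_id"}``.  Rows violating invariants are
    dropped with a logged count; a file yielding zero valid rows is an error.
    """
    path = Path(path)
    try:
        sep = "," if path.suffix.lower() == ".csv" else "\t"
        raw = pd.read_csv(path, sep=sep)
    except OSError as exc:
        raise DataError(f"cannot read summary statistics from {path}: {exc}") from exc
    if column_map:
        raw = raw.rename(columns=dict(column_map))
    missing = [c for c in SUMSTAT_COLUMNS if c not in raw.columns and c != "eaf"]
    if missing:
        raise DataError(f"{path}: missing mandatory columns {missing}")
    if "eaf" not in raw.columns:
        raw["eaf"] = np.nan
    valid, drops = validate_panel_frame(raw[SUMSTAT_COLUMNS])
    if drops:
        logger.warning("%s: dropped rows by reason: %s", path, drops)
    if valid.empty:
        raise DataError(f"{path}: no valid summary-statistic rows")
    return TraitPanel(trait_id or path.stem, trait_class, valid)


def panel_from_arrays(
    trait_id: str,
    trait_class: str,
    *,
    snp_id: Sequence[str],
    chrom: Sequence[str],
    pos: Sequence[int],
    effect_allele: Sequence[str],
    other_allele: Sequence[str],
    eaf: Sequence[float],
    beta: Sequence[float],
    se: Sequence[float],
    pval: Sequence[float],
    n: Sequence[int],
) -> TraitPanel:
    """Build a panel directly from in-memory arrays (simulator fast path)."""
    df = pd.DataFrame(
        {
            "snp_id": snp_id,
            "chrom": chrom,
            "pos": np.asarray(pos, dtype=np.int64),
            "effect_allele": effect_allele,
            "other_allele": other_allele,
            "eaf": np.asarray(eaf, dtype=float),
            "beta": np.asarray(beta, dtype=float),
            "se": np.asarray(se, dtype=float),
            "pval": np.asarray(pval, dtype=float),
            "n": np.asarray(n, dtype=np.int64),
        }
    )
    return TraitPanel(trait_id, trait_class, df)


def write_table(records: pd.DataFrame | Iterable[Mapping], path: str | Path) -> None:
    """Write any result collection as TSV with deterministic column order.

    Floats are rendered to 12 significant digits so numeric fields round-trip
    within 1e-12 relative tolerance; string and integer fields round-trip
    bit-identically.  An empty collection yields a header-only file when the
    frame carries columns.
    """
    df = records if isinstance(records, pd.DataFrame) else pd.DataFrame(list(records))
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    try:
        df.to_csv(path, sep="\t", index=False, float_format="%.12g")
    except OSError as exc:
        raise DataError(f"cannot write table to {path}: {exc}") from exc


def read_table(path: str | Path) -> pd.DataFrame:
    try:
        return pd.read_csv(path, sep="\t")
    except OSError as exc:
        raise DataError(f"cannot read table from {path}: {exc}") from exc


def write_panel(panel: TraitPanel, path: str | Path) -> None:
    write_table(panel.data, path)


def read_panel(
    path: str | Path, trait_id: str | None = None, trait_class: str = "disease"
) -> TraitPanel:
    return read_summary_stats(path, trait_id=trait_id, trait_class=trait_class)


def write_manifest(manifest: Mapping, path: str | Path) -> None:
    """Write the JSON run manifest (config echo, seeds, filter audits)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True, default=str) + "\n")
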