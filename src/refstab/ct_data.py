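"""Data model and I/O for qPCR Ct tables.

qPCR reactions are run in technical triplicate; the mean Ct of a well set is
used downstream, but only after the deviation rule is applied: if one of the
three Ct values deviates from the other two by more than 0.5 cycles it is
excluded (the mean of the two concordant values is kept); if no two values
are concordant the well set fails and must be re-run.

The central container is :class:`CtTable`: mean Ct values indexed by
sample x gene, with a group label (and optional tissue/sex labels) per
sample and an amplification factor per gene (fold increase of product per
cycle; 2.0 corresponds to 100% efficiency). Genes expressed below the
detection limit of the assay (no amplification within ``max_cycles``) are
excluded before stability analysis, mirroring how GUSB had to be dropped
from the Area X song data set.

File format: long CSV/TSV with header ``sample,group[,tissue],gene,ct`` or
replicate columns ``ct_rep1..3`` (or a ``replicate`` index column); the
sentinel ``ND`` marks no detection. Wide format (one column per gene) is
accepted on read only.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import (
    CtParseError,
    EmptyTableError,
    InsufficientReplicatesError,
    InvalidCtError,
)

__all__ = [
    "QcPolicy",
    "QcOutcome",
    "TriplicateRecord",
    "CtTable",
    "collapse_triplicate",
    "exclude_undetected_genes",
    "read_ct_table",
    "write_ct_table",
    "ct_table_from_long",
]

logger = logging.getLogger(__name__)

#: Sentinel for "no amplification detected" in CSV files.
ND_SENTINEL = "ND"


@dataclass(frozen=True)
class QcPolicy:
    """Quality-control parameters for raw Ct data.

    triplicate_tolerance:
        maximum deviation (cycles) between replicate Cts before one is
        considered an outlier; the published rule uses 0.5.
    max_cycles:
        number of PCR cycles run; Cts at or beyond this are undetected.
    detection_exclusion_fraction:
        fraction of samples allowed to be undetected before a gene is
        excluded from analysis. The default 0 excludes a gene as soon as
        any sample fails to detect it.
    """

    triplicate_tolerance: float = 0.5
    max_cycles: float = 40.0
    detection_exclusion_fraction: float = 0.0

    def __post_init__(self) -> None:
        if self.triplicate_tolerance <= 0:
            raise ValueError("triplicate_tolerance must be > 0")
        if self.max_cycles <= 0:
            raise ValueError("max_cycles must be > 0")
        if not 0.0 <= self.detection_exclusion_fraction <= 1.0:
            raise ValueError("detection_exclusion_fraction must be in [0, 1]")


@dataclass(frozen=True)
class QcOutcome:
    """Result of collapsing one replicate well set.

    ``status`` is ``accepted`` (mean of all values), ``replicate_dropped``
    (mean of the two concordant values; ``dropped_index`` is the 1-based
    replicate position of the outlier) or ``failed`` (no concordant pair;
    ``mean_ct`` is None and the experiment must be repeated).
    """

    status: str
    mean_ct: float | None = None
    dropped_index: int | None = None


@dataclass(frozen=True)
class TriplicateRecord:
    """Raw replicate Cts for one sample x gene well set (None = no value)."""

    sample_id: str
    gene_symbol: str
    replicate_cts: tuple[float | None, ...]


def collapse_triplicate(
    record: TriplicateRecord | Sequence[float | None],
    policy: QcPolicy | None = None,
) -> QcOutcome:
    """Apply the replicate-deviation rule to a well set.

    With all pairwise gaps within tolerance the mean of all values is
    accepted. If exactly one value deviates from *both* others by more than
    the tolerance while those two agree, it is dropped and the mean of the
    concordant pair kept. Otherwise the well set fails.

    The outcome is invariant under permutation of the replicates (up to the
    reported index). Raises :class:`InsufficientReplicatesError` with fewer
    than two present values.
    """
    p = policy or QcPolicy()
    cts = record.replicate_cts if isinstance(record, TriplicateRecord) else tuple(record)
    present = [(i, v) for i, v in enumerate(cts) if v is not None and not math.isnan(v)]
    if len(present) < 2:
        raise InsufficientReplicatesError(
            f"need at least two replicate Cts, got {len(present)}"
        )
    values = [v for _, v in present]
    tol = p.triplicate_tolerance
    if len(values) == 2:
        if abs(values[0] - values[1]) <= tol:
            return QcOutcome("accepted", mean_ct=float(np.mean(values)))
        return QcOutcome("failed")
    # three values: look for a single outlier discordant with a concordant pair
    gaps_ok = [
        abs(values[j] - values[k]) <= tol
        for j, k in ((0, 1), (0, 2), (1, 2))
    ]
    if all(gaps_ok):
        return QcOutcome("accepted", mean_ct=float(np.mean(values)))
    for out in range(3):
        j, k = [i for i in range(3) if i != out]
        pair_ok = abs(values[j] - values[k]) <= tol
        outlier_far = (
            abs(values[out] - values[j]) > tol and abs(values[out] - values[k]) > tol
        )
        if pair_ok and outlier_far:
            return QcOutcome(
                "replicate_dropped",
                mean_ct=float(np.mean([values[j], values[k]])),
                dropped_index=present[out][0] + 1,
            )
    return QcOutcome("failed")


@dataclass
class CtTable:
    """Mean Ct values for a panel of genes over a set of samples.

    values:
        DataFrame indexed by sample id, one column per gene; NaN marks an
        undetected (or QC-failed) well set.
    sample_info:
        DataFrame indexed by sample id with a ``group`` column and any
        further labels (tissue, sex).
    efficiencies:
        Series indexed by gene: amplification factor in fold per cycle
        (2.0 = perfect doubling = 100% efficiency). Must lie in (1, 2.2].
    """

    values: pd.DataFrame
    sample_info: pd.DataFrame
    efficiencies: pd.Series

    def __post_init__(self) -> None:
        self.values = self.values.astype(float)
        if self.values.index.has_duplicates:
            raise ValueError("duplicate sample ids")
        if self.values.columns.has_duplicates:
            raise ValueError("duplicate gene symbols")
        if not self.values.index.equals(self.sample_info.index):
            self.sample_info = self.sample_info.reindex(self.values.index)
        if "group" not in self.sample_info.columns:
            raise ValueError("sample_info must have a 'group' column")
        self.values.index.name = "sample"
        self.sample_info.index.name = "sample"
        self.efficiencies = (
            self.efficiencies.reindex(self.values.columns)
            .astype(float)
            .rename("efficiency")
        )
        self.efficiencies.index.name = None
        if self.efficiencies.isna().any():
            missing = list(self.efficiencies.index[self.efficiencies.isna()])
            raise ValueError(f"genes without efficiency: {missing}")
        bad_eff = (self.efficiencies <= 1.0) | (self.efficiencies > 2.2)
        if bad_eff.any():
            raise ValueError(
                f"efficiencies outside (1, 2.2]: {list(self.efficiencies.index[bad_eff])}"
            )
        if (self.values <= 0).any().any():
            raise InvalidCtError("Ct values must be positive")

    @property
    def samples(self) -> list[str]:
        return list(self.values.index)

    @property
    def genes(self) -> list[str]:
        return list(self.values.columns)

    @property
    def groups(self) -> pd.Series:
        return self.sample_info["group"]

    def subset_genes(self, genes: Sequence[str]) -> "CtTable":
        return CtTable(
            self.values[list(genes)].copy(),
            self.sample_info.copy(),
            self.efficiencies[list(genes)].copy(),
        )


def exclude_undetected_genes(
    table: CtTable, policy: QcPolicy | None = None
) -> tuple[CtTable, list[str]]:
    """Drop genes expressed below the detection limit.

    A Ct is undetected when missing or at/after ``max_cycles``. Genes whose
    undetected fraction exceeds ``detection_exclusion_fraction`` are
    removed; retained values are untouched. Raises
    :class:`EmptyTableError` if nothing survives.
    """
    p = policy or QcPolicy()
    undetected = table.values.isna() | (table.values >= p.max_cycles)
    frac = undetected.mean(axis=0)
    excluded = list(frac.index[frac > p.detection_exclusion_fraction])
    if len(excluded) == len(table.genes):
        raise EmptyTableError("all genes fall below the detection limit")
    if excluded:
        logger.info("excluding undetected genes: %s", excluded)
    kept = [g for g in table.genes if g not in excluded]
    out = table.subset_genes(kept)
    # values at/after max_cycles in retained genes are still not detections
    out.values = out.values.mask(out.values >= p.max_cycles)
    return out, excluded


def _collapse_group(
    sample: str, gene: str, cts: Sequence[float | None], policy: QcPolicy
) -> float:
    outcome = collapse_triplicate(TriplicateRecord(sample, gene, tuple(cts)), policy)
    if outcome.status == "failed":
        logger.warning("QC failed for %s/%s: no concordant replicate pair", sample, gene)
        return float("nan")
    if outcome.status == "replicate_dropped":
        logger.info(
            "dropped replicate %d for %s/%s", outcome.dropped_index, sample, gene
        )
    return outcome.mean_ct


def _parse_ct(raw: str, row: int) -> float:
    text = raw.strip()
    if text == "" or text.upper() == ND_SENTINEL:
        return float("nan")
    try:
        return float(text)
    except ValueError:
        raise CtParseError(f"non-numeric Ct {raw!r}", row=row) from None


def ct_table_from_long(
    df: pd.DataFrame,
    efficiencies: Mapping[str, float] | pd.Series | None = None,
    policy: QcPolicy | None = None,
) -> CtTable:
    """Build a :class:`CtTable` from a long-format frame.

    Expects columns ``sample``, ``group``, ``gene`` and either ``ct``
    (optionally with a ``replicate`` column) or ``ct_rep1..3``; extra label
    columns (``tissue`` etc.) are carried into ``sample_info``. Replicate
    rows are collapsed with :func:`collapse_triplicate`.
    """
    p = policy or QcPolicy()
    df = df.reset_index(drop=True)
    required = {"sample", "group", "gene"}
    missing = required - set(df.columns)
    if missing:
        raise CtParseError(f"missing required columns: {sorted(missing)}")
    rep_cols = [c for c in ("ct_rep1", "ct_rep2", "ct_rep3") if c in df.columns]
    sample_order = list(dict.fromkeys(df["sample"]))
    gene_order = list(dict.fromkeys(df["gene"]))

    records: dict[tuple[str, str], float] = {}
    if rep_cols:
        seen: set[tuple[str, str]] = set()
        for idx, row in df.iterrows():
            key = (row["sample"], row["gene"])
            if key in seen:
                raise CtParseError(f"duplicate well set {key}", row=idx + 1)
            seen.add(key)
            cts = [_parse_ct(str(row[c]), idx + 1) for c in rep_cols]
            cts = [None if math.isnan(v) else v for v in cts]
            if sum(v is not None for v in cts) == 0:
                records[key] = float("nan")
            else:
                records[key] = _collapse_group(*key, cts, p)
    elif "replicate" in df.columns:
        seen_rep: set[tuple[str, str, str]] = set()
        for idx, row in df.iterrows():
            rkey = (row["sample"], row["gene"], str(row["replicate"]))
            if rkey in seen_rep:
                raise CtParseError(f"duplicate replicate row {rkey}", row=idx + 1)
            seen_rep.add(rkey)
        for (sample, gene), sub in df.groupby(["sample", "gene"], sort=False):
            cts = [
                None if math.isnan(v) else v
                for v in (_parse_ct(str(x), i + 1) for i, x in zip(sub.index, sub["ct"]))
            ]
            if sum(v is not None for v in cts) == 0:
                records[(sample, gene)] = float("nan")
            elif len(cts) == 1:
                records[(sample, gene)] = cts[0] if cts[0] is not None else float("nan")
            else:
                records[(sample, gene)] = _collapse_group(sample, gene, cts, p)
    else:
        seen = set()
        for idx, row in df.iterrows():
            key = (row["sample"], row["gene"])
            if key in seen:
                raise CtParseError(f"duplicate (sample, gene) row {key}", row=idx + 1)
            seen.add(key)
            records[key] = _parse_ct(str(row["ct"]), idx + 1)

    values = pd.DataFrame(
        {
            g: [records.get((s, g), float("nan")) for s in sample_order]
            for g in gene_order
        },
        index=pd.Index(sample_order, name="sample"),
    )
    label_cols = [
        c
        for c in df.columns
        if c not in {"sample", "gene", "ct", "replicate", "efficiency", *rep_cols}
    ]
    sample_info = (
        df.drop_duplicates("sample").set_index("sample")[label_cols].loc[sample_order]
    )

    if efficiencies is None:
        if "efficiency" in df.columns:
            eff = (
                df.drop_duplicates("gene")
                .set_index("gene")["efficiency"]
                .astype(float)
                .loc[gene_order]
            )
        else:
            logger.info("no efficiencies supplied; assuming perfect doubling (2.0)")
            eff = pd.Series(2.0, index=gene_order)
    else:
        eff = pd.Series(dict(efficiencies)).reindex(gene_order)
    return CtTable(values, sample_info, eff)


def read_ct_table(
    path: str | Path,
    efficiencies: Mapping[str, float] | pd.Series | None = None,
    policy: QcPolicy | None = None,
    fmt: str = "long",
) -> CtTable:
    """Read a Ct table from CSV/TSV.

    ``fmt="long"`` expects the canonical long layout (see module docs);
    ``fmt="wide"`` expects ``sample,group[,labels...]`` followed by one
    column per gene. ``ND`` cells become missing values, never zeros.
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    raw = pd.read_csv(path, sep=sep, dtype=str)
    if fmt == "wide":
        meta_cols = [c for c in raw.columns if c in {"sample", "group", "tissue", "sex"}]
        gene_cols = [c for c in raw.columns if c not in meta_cols]
        long = raw.melt(
            id_vars=meta_cols, value_vars=gene_cols, var_name="gene", value_name="ct"
        )
        return ct_table_from_long(long, efficiencies, policy)
    if fmt != "long":
        raise ValueError(f"unknown format {fmt!r}")
    return ct_table_from_long(raw, efficiencies, policy)


def write_ct_table(table: CtTable, path: str | Path) -> None:
    """Write a table in canonical long format (round-trips exactly).

    Cts are written with ``repr`` precision; missing values as ``ND``; per-
    gene efficiencies in an ``efficiency`` column.
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    rows = []
    for sample in table.samples:
        labels = table.sample_info.loc[sample]
        for gene in table.genes:
            v = table.values.at[sample, gene]
            rows.append(
                {
                    "sample": sample,
                    **labels.to_dict(),
                    "gene": gene,
                    "ct": ND_SENTINEL if pd.isna(v) else repr(float(v)),
                    "efficiency": repr(float(table.efficiencies[gene])),
                }
            )
    pd.DataFrame(rows).to_csv(path, sep=sep, index=False)
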