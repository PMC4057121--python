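"""BestKeeper-style descriptive stability analysis on raw Ct values.

BestKeeper judges candidate reference genes directly on their Ct values:

* the sample standard deviation of a gene's Cts (low = stable; genes with
  SD > 1.5 cycles are flagged as a caution, not removed — in heterogeneous
  tissue the whole panel can exceed the guideline);
* the coefficient of variation, 100 x SD / mean Ct;
* the Pearson correlation of the gene's Cts with the BestKeeper index, the
  per-sample geometric mean of all candidates' Cts — a good reference gene
  should track the panel-wide signal.

The original tool leaves the weighting of the three measures to the
experimenter. Here, each measure ranks the genes separately (SD and CV
ascending, r descending, average ranks on ties) and the final rank is the
mean of the three per-measure ranks. When two genes tie on mean rank, the
one whose three per-measure ranks have the smaller spread (max - min) is
preferred — a gene equally stable in all three measures beats one that is
excellent in some and poor in others; remaining ties fall back to input
order.

Correlation is ranked by signed value, not magnitude: a reference gene is
expected to co-vary *positively* with the index, so negative r ranks last.
This choice is logged at analysis time and configurable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .ct_data import CtTable
from .errors import InsufficientGenesError, InvalidCtError, TooFewGenesError

__all__ = [
    "BestKeeperResult",
    "bestkeeper_index",
    "bestkeeper_descriptors",
    "consensus_rank",
    "bestkeeper_analysis",
    "SD_FLAG_THRESHOLD",
]

logger = logging.getLogger(__name__)

SD_FLAG_THRESHOLD = 1.5  # cycles


@dataclass
class BestKeeperResult:
    """Descriptors, per-measure ranks and consensus ranking.

    ``stats`` has one row per gene: ct_sd, ct_cv, r_with_index, sd_flag;
    after :func:`consensus_rank` also rank_sd, rank_cv, rank_r, mean_rank,
    final_rank. ``index`` is the per-sample geometric mean of Cts.
    """

    stats: pd.DataFrame
    index: pd.Series
    selected_pair: tuple[str, str] | None = None
    excluded_from_ranking: list[str] = field(default_factory=list)


def bestkeeper_index(table: CtTable) -> pd.Series:
    """Per-sample geometric mean of all genes' Cts.

    Samples with any missing Ct are dropped (logged). Raises
    :class:`InvalidCtError` on non-positive Cts and
    :class:`TooFewGenesError` below two genes.
    """
    if len(table.genes) < 2:
        raise TooFewGenesError("BestKeeper index needs >= 2 genes")
    values = table.values
    complete = values.notna().all(axis=1)
    if not complete.all():
        logger.info(
            "BestKeeper: dropping incomplete samples %s", list(values.index[~complete])
        )
    values = values.loc[complete]
    if (values <= 0).any().any():
        raise InvalidCtError("Ct values must be positive for a geometric mean")
    return pd.Series(
        stats.gmean(values, axis=1), index=values.index, name="bestkeeper_index"
    )


def bestkeeper_descriptors(table: CtTable) -> BestKeeperResult:
    """SD, CV, correlation with the index and the SD>1.5 flag per gene.

    Requires >= 3 samples with complete data. A zero-variance gene has an
    undefined correlation, reported as missing (never coerced to 0) with a
    warning.
    """
    index = bestkeeper_index(table)
    values = table.values.loc[index.index]
    if len(values) < 3:
        raise TooFewGenesError("BestKeeper descriptors need >= 3 complete samples")
    rows = {}
    for gene in table.genes:
        cts = values[gene]
        sd = float(cts.std(ddof=1))
        cv = 100.0 * sd / float(cts.mean())
        if sd == 0.0 or index.std(ddof=1) == 0.0:
            logger.warning("gene %s: zero variance, correlation undefined", gene)
            r = np.nan
        else:
            r = float(stats.pearsonr(cts, index).statistic)
        rows[gene] = {
            "ct_sd": sd,
            "ct_cv": cv,
            "r_with_index": r,
            "sd_flag": sd > SD_FLAG_THRESHOLD,
        }
    stats_df = pd.DataFrame.from_dict(rows, orient="index").loc[table.genes]
    n_flagged = int(stats_df["sd_flag"].sum())
    if n_flagged:
        logger.info("%d gene(s) exceed the SD>%.1f guideline (kept, flagged)",
                    n_flagged, SD_FLAG_THRESHOLD)
    return BestKeeperResult(stats=stats_df, index=index)


def consensus_rank(result: BestKeeperResult) -> BestKeeperResult:
    """Mean-of-ranks consensus over SD, CV and correlation.

    Per-measure ranks use average ranks for ties; correlation ranks by
    descending signed value (logged). Genes with undefined correlation are
    excluded from the ranking (logged). The selected pair is the two best
    final ranks, ties broken by the smallest per-measure rank spread, then
    input order. Raises :class:`InsufficientGenesError` with < 2 rankable
    genes.
    """
    logger.info("ranking correlation by signed value (descending); negative r ranks last")
    df = result.stats.copy()
    rankable = df.index[df["r_with_index"].notna()]
    excluded = [g for g in df.index if g not in set(rankable)]
    if excluded:
        logger.warning("excluding genes with undefined correlation: %s", excluded)
    if len(rankable) < 2:
        raise InsufficientGenesError("need >= 2 rankable genes")
    sub = df.loc[rankable]
    df.loc[rankable, "rank_sd"] = sub["ct_sd"].rank(method="average", ascending=True)
    df.loc[rankable, "rank_cv"] = sub["ct_cv"].rank(method="average", ascending=True)
    df.loc[rankable, "rank_r"] = sub["r_with_index"].rank(
        method="average", ascending=False
    )
    rank_cols = ["rank_sd", "rank_cv", "rank_r"]
    df["mean_rank"] = df[rank_cols].mean(axis=1)
    df.loc[rankable, "final_rank"] = (
        df.loc[rankable, "mean_rank"].rank(method="min").astype(int)
    )
    spread = df.loc[rankable, rank_cols].max(axis=1) - df.loc[rankable, rank_cols].min(
        axis=1
    )
    input_pos = {g: i for i, g in enumerate(df.index)}
    order = sorted(
        rankable, key=lambda g: (df.at[g, "mean_rank"], spread[g], input_pos[g])
    )
    pair = (order[0], order[1])
    return BestKeeperResult(
        stats=df,
        index=result.index,
        selected_pair=pair,
        excluded_from_ranking=excluded,
    )


def bestkeeper_analysis(table: CtTable) -> BestKeeperResult:
    """Run descriptors plus consensus ranking in one call."""
    return consensus_rank(bestkeeper_descriptors(table))
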