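"""Amplification-efficiency estimation from dilution series.

An assay's efficiency is measured by amplifying a ten-fold dilution series
(five orders of magnitude in the published design) and regressing Ct on
log10 of the relative template concentration. The amplification factor per
cycle is E = 10^(-1/slope); percent efficiency is (E - 1) x 100, so a slope
of -3.32 cycles per decade corresponds to perfect doubling (100%). Assays
are accepted when the percent efficiency falls inside a window, 90-110%
inclusive by default.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .ct_data import QcPolicy, TriplicateRecord, collapse_triplicate
from .errors import DegenerateSeriesError, InsufficientPointsError
from .panel import PanelCriteria

__all__ = ["DilutionSeries", "EfficiencyFit", "fit_efficiency", "read_dilution_series"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class DilutionSeries:
    """Mean Ct at each relative template concentration for one assay."""

    gene_symbol: str
    points: tuple[tuple[float, float], ...]  # (relative concentration, mean Ct)

    def __post_init__(self) -> None:
        if any(conc <= 0 for conc, _ in self.points):
            raise ValueError("concentrations must be strictly positive")


@dataclass(frozen=True)
class EfficiencyFit:
    """Least-squares fit of one dilution series.

    ``slope`` is in cycles per log10-dilution; ``amplification_factor`` is
    E = 10^(-1/slope) (fold per cycle); ``efficiency_pct`` = (E - 1) x 100.
    """

    gene_symbol: str
    slope: float
    intercept: float
    amplification_factor: float
    efficiency_pct: float
    r_squared: float
    accepted: bool


def fit_efficiency(
    series: DilutionSeries,
    window: tuple[float, float] | None = None,
) -> EfficiencyFit:
    """Fit amplification efficiency by OLS of Ct on log10(concentration).

    Raises :class:`InsufficientPointsError` with fewer than three distinct
    concentrations and :class:`DegenerateSeriesError` when the slope is
    non-negative (Ct must rise as template is diluted). The acceptance
    window defaults to the shared panel criterion (90-110% inclusive).
    """
    lo, hi = window if window is not None else PanelCriteria().efficiency_window
    concs = np.array([c for c, _ in series.points], dtype=float)
    cts = np.array([ct for _, ct in series.points], dtype=float)
    if len(np.unique(concs)) < 3:
        raise InsufficientPointsError(
            f"{series.gene_symbol}: need >= 3 distinct concentrations"
        )
    res = stats.linregress(np.log10(concs), cts)
    if res.slope >= 0:
        raise DegenerateSeriesError(
            f"{series.gene_symbol}: non-negative slope {res.slope:.3f}"
        )
    factor = 10.0 ** (-1.0 / res.slope)
    pct = (factor - 1.0) * 100.0
    return EfficiencyFit(
        gene_symbol=series.gene_symbol,
        slope=float(res.slope),
        intercept=float(res.intercept),
        amplification_factor=float(factor),
        efficiency_pct=float(pct),
        r_squared=float(res.rvalue**2),
        accepted=bool(lo <= pct <= hi),
    )


def read_dilution_series(
    path: str | Path,
    collapse_replicates: bool = True,
    policy: QcPolicy | None = None,
) -> list[DilutionSeries]:
    """Read dilution series from CSV: ``gene,concentration,ct`` or
    ``gene,concentration,ct_rep1..3``.

    Replicates at a dilution point are collapsed with the same 0.5-cycle
    deviation rule used for sample wells (set ``collapse_replicates=False``
    to average them verbatim instead); failed points are dropped with a
    warning.
    """
    df = pd.read_csv(path)
    rep_cols = [c for c in ("ct_rep1", "ct_rep2", "ct_rep3") if c in df.columns]
    out: list[DilutionSeries] = []
    for gene, sub in df.groupby("gene", sort=False):
        points: list[tuple[float, float]] = []
        for _, row in sub.iterrows():
            conc = float(row["concentration"])
            if rep_cols:
                cts = [float(row[c]) for c in rep_cols if pd.notna(row[c])]
                if collapse_replicates:
                    outcome = collapse_triplicate(
                        TriplicateRecord(f"dil_{conc:g}", gene, tuple(cts)), policy
                    )
                    if outcome.status == "failed":
                        logger.warning(
                            "dropping discordant dilution point %s/%g", gene, conc
                        )
                        continue
                    points.append((conc, outcome.mean_ct))
                else:
                    points.append((conc, float(np.mean(cts))))
            else:
                points.append((conc, float(row["ct"])))
        out.append(DilutionSeries(gene_symbol=gene, points=tuple(points)))
    return out
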