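"""geNorm gene-stability analysis.

The algorithm assumes that the expression ratio of two ideal reference
genes is constant across samples. For each candidate pair (j, k) it takes
the per-sample log2 ratio of efficiency-corrected relative quantities,
A_jk = log2(Q_j / Q_k), and defines the pairwise variation V_jk as the
standard deviation of A_jk over samples. A gene's stability M_j is the
mean of V_jk over all partners k; low M means the gene co-varies with the
rest of the panel. The least stable gene (highest M) is removed and M is
recomputed, repeatedly, until two genes remain — these two cannot be
separated and share the top rank.

To decide how many reference genes are needed, normalization factors
NF_n (per-sample geometric means of the n most stable genes' quantities)
are compared for successive n: V_n/n+1 is the standard deviation over
samples of log2(NF_n / NF_n+1). When V_n/n+1 falls below 0.15, adding the
(n+1)-th gene no longer changes the normalization materially and n genes
suffice.

Relative quantities follow the efficiency-corrected comparative Ct method:
Q_sg = E_g^(Ctmin_g - Ct_sg), calibrated to each gene's minimum Ct so that
the most concentrated sample has Q = 1. The calibrator choice only rescales
Q per gene and cannot affect M or V.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ct_data import CtTable
from .errors import TooFewGenesError, UndefinedGeneError

__all__ = [
    "GeNormResult",
    "relative_quantities",
    "m_values",
    "stepwise_exclusion",
    "pairwise_variation_v",
    "genorm_analysis",
    "DEFAULT_V_CUTOFF",
]

logger = logging.getLogger(__name__)

DEFAULT_V_CUTOFF = 0.15


def relative_quantities(table: CtTable) -> pd.DataFrame:
    """Efficiency-corrected relative quantities, Q_sg = E_g^(Ctmin_g - Ct_sg).

    Per gene the maximum over samples is exactly 1; missing Cts stay
    missing. Raises :class:`UndefinedGeneError` for a gene with no detected
    Ct (such genes must be excluded upstream).
    """
    all_missing = table.values.isna().all(axis=0)
    if all_missing.any():
        raise UndefinedGeneError(
            f"genes with no detected Ct: {list(all_missing.index[all_missing])}"
        )
    ct_min = table.values.min(axis=0)
    exponent = ct_min - table.values  # <= 0
    return table.efficiencies.astype(float) ** exponent


@dataclass
class GeNormResult:
    """Full output of a geNorm run."""

    m_history: list[pd.Series]  # per-gene M at each exclusion round
    exclusion_order: list[str]  # least stable first
    final_pair: tuple[str, str]
    stability_order: list[str]  # most stable first (pair, then reversed exclusions)
    ranks: pd.Series  # final pair shares rank 1; then 3, 4, ...
    v_values: dict[int, float] = field(default_factory=dict)
    recommended_n: int | None = None
    cutoff_warning: bool = False

    @property
    def m_values(self) -> pd.Series:
        """M values from the first round (all genes)."""
        return self.m_history[0]


def m_values(quantities: pd.DataFrame) -> pd.Series:
    """Per-gene stability M for a matrix of relative quantities.

    M_j = mean over partners k of SD_s(log2(Q_sj / Q_sk)) with the n-1
    sample standard deviation. Samples missing either gene of a pair are
    dropped pairwise. Requires >= 3 genes and >= 2 samples.
    """
    genes = list(quantities.columns)
    if len(genes) < 3:
        raise TooFewGenesError(f"geNorm M needs >= 3 genes, got {len(genes)}")
    if len(quantities.index) < 2:
        raise TooFewGenesError("geNorm M needs >= 2 samples")
    logq = np.log2(quantities)
    out = {}
    for j in genes:
        sds = []
        for k in genes:
            if k == j:
                continue
            ratio = (logq[j] - logq[k]).dropna()
            if len(ratio) < 2:
                logger.warning("pair (%s, %s): <2 complete samples, skipped", j, k)
                continue
            sds.append(ratio.std(ddof=1))
        out[j] = float(np.mean(sds))
    return pd.Series(out, name="M")


def stepwise_exclusion(quantities: pd.DataFrame) -> GeNormResult:
    """Rank genes by repeatedly removing the highest-M gene.

    Ties at the maximum M are broken by excluding the gene that appears
    later in input order (deterministic, logged). The two survivors share
    the final rank; remaining genes rank 3, 4, ... in exclusion order.
    """
    genes = list(quantities.columns)
    if len(genes) < 3:
        raise TooFewGenesError("stepwise exclusion needs >= 3 genes")
    m_history: list[pd.Series] = []
    exclusion_order: list[str] = []
    current = quantities
    while len(current.columns) > 2:
        m = m_values(current)
        m_history.append(m)
        worst_m = m.max()
        ties = [g for g in current.columns if m[g] == worst_m]
        worst = ties[-1]  # later in input order
        if len(ties) > 1:
            logger.info("tie at max M=%.4f among %s; excluding %s", worst_m, ties, worst)
        exclusion_order.append(worst)
        current = current.drop(columns=[worst])
    final_pair = tuple(current.columns)
    stability_order = list(final_pair) + list(reversed(exclusion_order))
    ranks = pd.Series(index=pd.Index(genes, name="gene"), dtype=int)
    for g in final_pair:
        ranks[g] = 1
    for pos, g in enumerate(reversed(exclusion_order), start=3):
        ranks[g] = pos
    return GeNormResult(
        m_history=m_history,
        exclusion_order=exclusion_order,
        final_pair=final_pair,
        stability_order=stability_order,
        ranks=ranks.astype(int),
    )


def pairwise_variation_v(
    quantities: pd.DataFrame,
    stability_order: list[str],
    cutoff: float = DEFAULT_V_CUTOFF,
) -> tuple[dict[int, float], int, bool]:
    """V_n/n+1 values and the recommended reference-gene count.

    NF_n,s is the geometric mean of the n most stable genes' quantities in
    sample s (samples with any of those genes missing are dropped);
    V_n/n+1 = SD_s(log2(NF_n,s / NF_n+1,s)). The recommendation is the
    smallest n (starting at 2) with V_n/n+1 below the cutoff; if no n
    qualifies, all genes are recommended and a warning flag is set.
    """
    n_genes = len(stability_order)
    logq = np.log2(quantities[stability_order])

    def log_nf(n: int) -> pd.Series:
        return logq.iloc[:, :n].mean(axis=1)  # log of geometric mean

    v_values: dict[int, float] = {}
    for n in range(2, n_genes):
        diff = (log_nf(n) - log_nf(n + 1)).dropna()
        v_values[n] = float(diff.std(ddof=1))
    recommended = next((n for n, v in v_values.items() if v < cutoff), None)
    warning = recommended is None
    if warning:
        logger.warning(
            "no V_n/n+1 below %.2f; recommending all %d genes", cutoff, n_genes
        )
        recommended = n_genes
    return v_values, recommended, warning


def genorm_analysis(table: CtTable, cutoff: float = DEFAULT_V_CUTOFF) -> GeNormResult:
    """Run the full geNorm workflow on a Ct table."""
    q = relative_quantities(table)
    result = stepwise_exclusion(q)
    v_values, recommended, warning = pairwise_variation_v(
        q, result.stability_order, cutoff
    )
    result.v_values = v_values
    result.recommended_n = recommended
    result.cutoff_warning = warning
    return result
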