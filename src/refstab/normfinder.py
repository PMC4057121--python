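"""Model-based (NormFinder-style) gene-stability analysis.

Unlike the pairwise geNorm approach, this estimator models each gene's
log2 expression as a sample effect (RNA input, shared by all genes),
a gene effect, a group-specific shift (the systematic bias a candidate
would introduce if used for normalization across experimental groups) and
residual intra-group noise. Candidates are scored by combining the two
sources of error a normalizer can commit:

1. Centre each sample's log2 relative-quantity vector by its across-gene
   mean, removing the common sample effect.
2. Per gene i and group g compute the mean d_ig and sample variance s2_ig
   of the centred values.
3. The raw intergroup component z_ig = d_ig - mean_g'(d_ig') measures the
   gene's group-specific shift. Because z is estimated with error, it is
   shrunk toward zero by the empirical-Bayes factor
   tau2_g / (tau2_g + s2_ig/n_g), where tau2_g is the across-gene variance
   of the raw components in group g less the average sampling variance
   (clamped at zero). Genes with noisy estimates are thus pulled harder
   toward "no shift".
4. The intragroup variance is s2_ig corrected for the variance injected by
   the shared sample-centring (the across-gene average variance divided by
   the gene count); negative corrected estimates clamp to zero.
5. The stability value of gene i is the mean over groups of
   |z~_ig| + sqrt(v_ig / n_g) — absolute shrunken bias plus the standard
   error of the group mean. Lower is more stable.

With a single group the intergroup term vanishes and the ranking reduces
to the corrected intragroup variance. The recommended *pair* of reference
genes minimizes the stability of the pair's average signal: opposite-sign
group shifts cancel, which is how a gene that is not individually
second-best can still form the best pair.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .ct_data import CtTable
from .errors import InsufficientGroupError, TooFewGenesError
from .genorm import relative_quantities

__all__ = ["NormFinderResult", "normfinder_stability", "best_pair_normfinder"]

logger = logging.getLogger(__name__)


@dataclass
class NormFinderResult:
    """Per-gene stability decomposition.

    ``intergroup`` holds the shrunken group components z~_ig (log2 units,
    genes x groups; identically zero in single-group mode), ``intragroup_var``
    the corrected residual variances v_ig (log2^2 units), ``stability`` the
    combined stability values and ``ranking`` integer ranks 1..G (ties by
    input order).
    """

    stability: pd.Series
    intergroup: pd.DataFrame
    intragroup_var: pd.DataFrame
    ranking: pd.Series
    group_sizes: pd.Series
    grouped: bool

    @property
    def best_genes(self) -> list[str]:
        return list(self.ranking.sort_values(kind="stable").index)


def normfinder_stability(
    table: CtTable, groups: pd.Series | None = None
) -> NormFinderResult:
    """Compute stability values for all genes of a Ct table.

    ``groups`` defaults to the table's group labels; pass a single-valued
    series (or a table with one group) for group-free mode. Samples with
    any missing gene are dropped with a warning (the sample-centring step
    needs complete vectors). Raises :class:`InsufficientGroupError` when a
    group has fewer than two usable samples and :class:`TooFewGenesError`
    below three genes.
    """
    if groups is None:
        groups = table.groups
    q = relative_quantities(table)
    complete = q.notna().all(axis=1)
    if not complete.all():
        dropped = list(q.index[~complete])
        logger.warning("dropping samples with missing values: %s", dropped)
        q = q.loc[complete]
        groups = groups.loc[complete]
    genes = list(q.columns)
    n_genes = len(genes)
    if n_genes < 3:
        raise TooFewGenesError(f"need >= 3 genes, got {n_genes}")
    group_labels = list(dict.fromkeys(groups))
    sizes = groups.value_counts()
    small = [g for g in group_labels if sizes[g] < 2]
    if small:
        raise InsufficientGroupError(f"groups with < 2 samples: {small}")

    x = np.log2(q)
    xc = x.sub(x.mean(axis=1), axis=0)  # remove per-sample RNA-input effect

    dbar = xc.groupby(groups).mean().T  # genes x groups
    s2 = xc.groupby(groups).var(ddof=1).T
    dbar = dbar[group_labels]
    s2 = s2[group_labels]
    n_g = pd.Series({g: int(sizes[g]) for g in group_labels})

    # centring-corrected intragroup variance, clamped at zero
    v = (s2 - s2.mean(axis=0) / n_genes).clip(lower=0.0)
    clamped = int((s2 - s2.mean(axis=0) / n_genes < 0).sum().sum())
    if clamped:
        logger.info("clamped %d negative intragroup variance estimates to 0", clamped)

    if len(group_labels) < 2:
        z_shrunk = pd.DataFrame(0.0, index=genes, columns=group_labels)
    else:
        z = dbar.sub(dbar.mean(axis=1), axis=0)
        z_shrunk = pd.DataFrame(index=genes, columns=group_labels, dtype=float)
        for g in group_labels:
            samp_var = v[g] / n_g[g]
            tau2 = max(0.0, float(z[g].var(ddof=1) - samp_var.mean()))
            denom = tau2 + samp_var
            factor = np.where(denom > 0, tau2 / denom.replace(0, np.nan), 0.0)
            z_shrunk[g] = z[g].to_numpy() * np.nan_to_num(factor)

    per_group = z_shrunk.abs() + np.sqrt(v.div(n_g, axis=1))
    stability = per_group.mean(axis=1)
    order = stability.reset_index(drop=True).sort_values(kind="stable").index
    ranking = pd.Series(0, index=stability.index, dtype=int)
    ranking.iloc[order] = np.arange(1, n_genes + 1)
    return NormFinderResult(
        stability=stability.rename("stability"),
        intergroup=z_shrunk,
        intragroup_var=v,
        ranking=ranking.rename("rank"),
        group_sizes=n_g,
        grouped=len(group_labels) >= 2,
    )


def best_pair_normfinder(result: NormFinderResult) -> tuple[str, str]:
    """Recommended reference-gene pair.

    In grouped mode, exhaustively scores every pair by the stability of the
    two genes' average signal: intergroup components averaged, intragroup
    variances combined as the variance of a two-gene mean ((v_i + v_j)/4),
    recombined like the single-gene stability. Opposite group shifts cancel
    in the average, so the best pair need not be the two individually best
    genes. In single-group mode falls back to the two lowest individual
    stability values (logged).
    """
    genes = list(result.stability.index)
    if len(genes) < 2:
        raise TooFewGenesError("need >= 2 genes for a reference pair")
    if not result.grouped:
        logger.info("single-group mode: choosing the two lowest stability values")
        return tuple(result.stability.sort_values(kind="stable").index[:2])
    best: tuple[str, str] | None = None
    best_value = np.inf
    for a, b in itertools.combinations(genes, 2):
        z_pair = (result.intergroup.loc[a] + result.intergroup.loc[b]) / 2.0
        v_pair = (result.intragroup_var.loc[a] + result.intragroup_var.loc[b]) / 4.0
        value = float(
            (z_pair.abs() + np.sqrt(v_pair / result.group_sizes)).mean()
        )
        if value < best_value - 1e-15:
            best, best_value = (a, b), value
    return best
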