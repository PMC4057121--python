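"""End-to-end orchestration: QC, stability ranking, normalization, testing.

``run_pipeline`` takes a collapsed Ct table, excludes below-detection
genes, runs the three stability algorithms side by side on the reference
candidates (genes of interest share the sample set but are held out of the
stability analysis), assembles a side-by-side ranking table with the top
four genes per algorithm highlighted, and finally normalizes each gene of
interest to every algorithm's recommended pair and tests the treatment
versus control groups.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd

from . import __version__
from .bestkeeper import bestkeeper_analysis
from .ct_data import CtTable, QcPolicy, exclude_undetected_genes
from .genorm import DEFAULT_V_CUTOFF, genorm_analysis
from .normfinder import best_pair_normfinder, normfinder_stability
from .quantify import GroupComparison, compare_groups

__all__ = ["PipelineConfig", "StabilityReport", "PipelineReport", "run_pipeline"]

logger = logging.getLogger(__name__)

TOP_HIGHLIGHT = 4  # genes highlighted per algorithm in the report table


@dataclass(frozen=True)
class PipelineConfig:
    """Settings for one pipeline run."""

    genes_of_interest: tuple[str, ...] = ()
    treatment_group: str | None = None
    control_group: str | None = None
    v_cutoff: float = DEFAULT_V_CUTOFF
    qc_policy: QcPolicy = field(default_factory=QcPolicy)
    stability_genes: tuple[str, ...] | None = None  # default: all minus targets
    fold_summary: str = "median"
    seed: int | None = None

    def content_hash(self) -> str:
        payload = json.dumps(
            {
                "genes_of_interest": list(self.genes_of_interest),
                "treatment_group": self.treatment_group,
                "control_group": self.control_group,
                "v_cutoff": self.v_cutoff,
                "qc_policy": [
                    self.qc_policy.triplicate_tolerance,
                    self.qc_policy.max_cycles,
                    self.qc_policy.detection_exclusion_fraction,
                ],
                "stability_genes": (
                    list(self.stability_genes) if self.stability_genes else None
                ),
                "fold_summary": self.fold_summary,
                "seed": self.seed,
            },
            sort_keys=True,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class StabilityReport:
    """Side-by-side ranking of candidates by the three algorithms."""

    ranks: pd.DataFrame  # genes x {genorm, normfinder, bestkeeper}
    pairs: dict[str, tuple[str, str]]
    recommended_n: int
    v_values: dict[int, float]
    excluded_genes: list[str]
    provenance: dict[str, str | int | None]

    def to_table(self) -> pd.DataFrame:
        """Human-readable table; top-4 ranks per algorithm carry a ``*``."""
        out = self.ranks.copy().astype(object)
        for col in out.columns:
            numeric = self.ranks[col]
            for g in out.index:
                mark = "*" if numeric[g] <= TOP_HIGHLIGHT else ""
                out.at[g, col] = f"{int(numeric[g])}{mark}"
        return out


@dataclass
class PipelineReport:
    stability: StabilityReport
    comparisons: dict[tuple[str, str], GroupComparison]  # (target, algorithm)

    def to_json(self) -> str:
        payload = {
            "provenance": self.stability.provenance,
            "ranks": {
                g: {a: int(v) for a, v in row.items()}
                for g, row in self.stability.ranks.iterrows()
            },
            "pairs": {a: list(p) for a, p in self.stability.pairs.items()},
            "recommended_n": self.stability.recommended_n,
            "v_values": {str(n): v for n, v in self.stability.v_values.items()},
            "excluded_genes": self.stability.excluded_genes,
            "comparisons": {
                f"{target}|{algo}": {
                    "reference_pair": list(c.reference_pair),
                    "fold_change": c.fold_change,
                    "fold_change_mean": c.fold_change_mean,
                    "u_statistic": c.u_statistic,
                    "p_value": c.p_value,
                    "significance": c.significance_label,
                }
                for (target, algo), c in self.comparisons.items()
            },
        }
        return json.dumps(payload, indent=2, sort_keys=True)


def run_pipeline(table: CtTable, config: PipelineConfig | None = None) -> PipelineReport:
    """Run QC, the three stability analyses and group comparisons.

    Each stage is independent: rerunning any algorithm on the same cleaned
    table in isolation reproduces its column of the report.
    """
    cfg = config or PipelineConfig()
    clean, excluded = exclude_undetected_genes(table, cfg.qc_policy)
    if cfg.stability_genes is not None:
        candidates = [g for g in cfg.stability_genes if g in clean.genes]
    else:
        candidates = [g for g in clean.genes if g not in set(cfg.genes_of_interest)]
    stab_table = clean.subset_genes(candidates)

    gn = genorm_analysis(stab_table, cutoff=cfg.v_cutoff)
    nf = normfinder_stability(stab_table)
    bk = bestkeeper_analysis(stab_table)

    ranks = pd.DataFrame(
        {
            "genorm": gn.ranks,
            "normfinder": nf.ranking,
            "bestkeeper": bk.stats["final_rank"],
        }
    ).loc[candidates]
    ranks = ranks.astype(int)
    pairs = {
        "genorm": tuple(gn.final_pair),
        "normfinder": best_pair_normfinder(nf),
        "bestkeeper": bk.selected_pair,
    }
    stability = StabilityReport(
        ranks=ranks,
        pairs=pairs,
        recommended_n=gn.recommended_n,
        v_values=gn.v_values,
        excluded_genes=excluded,
        provenance={
            "config_hash": cfg.content_hash(),
            "seed": cfg.seed,
            "version": __version__,
        },
    )

    comparisons: dict[tuple[str, str], GroupComparison] = {}
    if cfg.treatment_group and cfg.control_group:
        for target in cfg.genes_of_interest:
            if target not in clean.genes:
                logger.warning("target %s excluded by QC; skipping comparison", target)
                continue
            for algo, pair in pairs.items():
                comparisons[(target, algo)] = compare_groups(
                    clean,
                    target,
                    list(pair),
                    cfg.treatment_group,
                    cfg.control_group,
                    summary=cfg.fold_summary,
                )
    return PipelineReport(stability=stability, comparisons=comparisons)
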