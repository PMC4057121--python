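"""Synthetic Ct data with the statistical structure the analyses assume.

The generator produces raw triplicate Ct tables from an explicit
generative model so every pipeline stage can be exercised end to end:

    Ct_sgr = baseline_g - effect_{g,group(s)} / log2(E_g)
             + shift_s + noise_sg + rep_noise_sgr

* ``baseline_g`` — the gene's Ct at calibrator RNA input;
* group fold effects are specified in log2 expression units and converted
  to cycles through the gene's own amplification factor E_g, so that
  efficiency correction downstream is genuinely exercised;
* ``shift_s ~ N(0, sample_scaling_sd)`` — per-sample RNA-input scaling,
  applied to every gene of the sample (what normalization must remove);
* ``noise_sg ~ N(0, noise_sd_g)`` — per-sample biological gene noise;
* ``rep_noise_sgr ~ N(0, triplicate_sd)`` — technical replicate noise;
* with probability ``outlier_rate`` per well set, one random replicate is
  displaced by a uniform 0.6–3.0 cycles (either sign) — always far enough
  to trip the 0.5-cycle replicate-deviation rule.

The song preset mirrors the published validation experiment: 12 Area X
microbiopsy samples (5 singing, 7 silent), nine stable reference
candidates whose amplification factors are the zebra finch assay
efficiencies, plus EGR1 and CFOS with a +3 log2 (8-fold) singing effect
and FOXP2 with none. The large per-sample scaling (1.5 cycles) mimics the
variable RNA yield of microbiopsies, which drives raw-Ct standard
deviations above the 1.5-cycle BestKeeper guideline exactly as observed
in that data set.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

from .ct_data import CtTable, QcPolicy, ct_table_from_long
from .efficiency import DilutionSeries

__all__ = [
    "GeneSpec",
    "GroupSpec",
    "SimConfig",
    "simulate_ct_table",
    "simulate_dilution_series",
    "preset_song_config",
    "preset_song_dataset",
    "song_ct_table",
    "SONG_REFERENCE_GENES",
    "SONG_TARGET_GENES",
]


@dataclass(frozen=True)
class GeneSpec:
    """One simulated assay: baseline Ct, amplification factor, biological noise."""

    symbol: str
    baseline_ct: float
    factor: float = 2.0  # fold per cycle; 2.0 = 100% efficiency
    noise_sd: float = 0.0  # cycles, per-sample biological noise

    def __post_init__(self) -> None:
        if not 1.0 < self.factor <= 2.2:
            raise ValueError(f"{self.symbol}: factor must be in (1, 2.2]")
        if self.noise_sd < 0:
            raise ValueError(f"{self.symbol}: noise_sd must be >= 0")


@dataclass(frozen=True)
class GroupSpec:
    """A sample group with per-gene log2 fold effects (unlisted genes: 0)."""

    label: str
    n: int
    effects: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("group size must be >= 1")


@dataclass(frozen=True)
class SimConfig:
    """Full specification of a simulated experiment."""

    genes: tuple[GeneSpec, ...]
    groups: tuple[GroupSpec, ...]
    sample_scaling_sd: float = 0.0  # cycles, shared across genes of a sample
    triplicate_sd: float = 0.0  # cycles, technical replicate noise
    outlier_rate: float = 0.0  # probability per well set
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sample_scaling_sd < 0 or self.triplicate_sd < 0:
            raise ValueError("SDs must be >= 0")
        if not 0.0 <= self.outlier_rate < 1.0:
            raise ValueError("outlier_rate must be in [0, 1)")

    @property
    def efficiencies(self) -> dict[str, float]:
        return {g.symbol: g.factor for g in self.genes}


def simulate_ct_table(config: SimConfig) -> pd.DataFrame:
    """Draw a raw triplicate Ct table (long format) from the model.

    Columns: sample, group, gene, replicate (1..3), ct. Identical config
    and seed give identical output.
    """
    rng = np.random.default_rng(config.seed)
    rows = []
    for group in config.groups:
        for i in range(group.n):
            sample = f"{group.label}_{i + 1}"
            shift = rng.normal(0.0, config.sample_scaling_sd) if config.sample_scaling_sd else 0.0
            for gene in config.genes:
                effect = group.effects.get(gene.symbol, 0.0)
                mean_ct = (
                    gene.baseline_ct
                    - effect / math.log2(gene.factor)
                    + shift
                    + (rng.normal(0.0, gene.noise_sd) if gene.noise_sd else 0.0)
                )
                reps = mean_ct + (
                    rng.normal(0.0, config.triplicate_sd, size=3)
                    if config.triplicate_sd
                    else np.zeros(3)
                )
                if config.outlier_rate and rng.random() < config.outlier_rate:
                    which = rng.integers(0, 3)
                    sign = 1.0 if rng.random() < 0.5 else -1.0
                    reps[which] += sign * rng.uniform(0.6, 3.0)
                for r, ct in enumerate(reps, start=1):
                    rows.append(
                        {
                            "sample": sample,
                            "group": group.label,
                            "gene": gene.symbol,
                            "replicate": r,
                            "ct": float(ct),
                        }
                    )
    return pd.DataFrame(rows)


def simulate_dilution_series(
    gene: str,
    factor: float,
    n_points: int = 5,
    step: float = 10.0,
    noise_sd: float = 0.0,
    seed: int | None = None,
    baseline_ct: float = 20.0,
    n_replicates: int = 3,
) -> DilutionSeries:
    """Dilution series for one assay: Ct = baseline + log(1/d)/log(factor).

    ``step`` is the dilution factor between consecutive points (10 for a
    ten-fold series); ``n_points`` = 5 spans five orders of magnitude.
    Each point is measured ``n_replicates`` times (3 by default, as in the
    standard triplicate design) with per-replicate noise ``noise_sd``; the
    stored Ct is the replicate mean.
    """
    if factor <= 1.0:
        raise ValueError("factor must be > 1")
    if n_points < 3:
        raise ValueError("need at least 3 points")
    if n_replicates < 1:
        raise ValueError("need at least 1 replicate")
    rng = np.random.default_rng(seed)
    points = []
    for i in range(n_points):
        dilution = step**-i
        ct = baseline_ct + math.log(1.0 / dilution) / math.log(factor)
        if noise_sd:
            ct += float(np.mean(rng.normal(0.0, noise_sd, size=n_replicates)))
        points.append((dilution, float(ct)))
    return DilutionSeries(gene_symbol=gene, points=tuple(points))


#: Reference candidates of the song preset. Amplification factors are the
#: zebra finch assay efficiencies (1 + pct/100); GUSB is absent because it
#: falls below the detection limit in Area X microbiopsies.
SONG_REFERENCE_GENES: tuple[GeneSpec, ...] = (
    GeneSpec("18S", baseline_ct=10.0, factor=2.025, noise_sd=0.12),
    GeneSpec("HMBS", baseline_ct=27.0, factor=1.963, noise_sd=0.12),
    GeneSpec("HPRT", baseline_ct=28.0, factor=1.935, noise_sd=0.12),
    GeneSpec("PGK1", baseline_ct=24.0, factor=1.940, noise_sd=0.12),
    GeneSpec("RPS7", baseline_ct=22.0, factor=2.009, noise_sd=0.12),
    GeneSpec("SDHA", baseline_ct=25.0, factor=2.033, noise_sd=0.12),
    GeneSpec("TFRC", baseline_ct=25.0, factor=2.036, noise_sd=0.12),
    GeneSpec("VIM", baseline_ct=23.0, factor=1.958, noise_sd=0.12),
    GeneSpec("YWHAZ", baseline_ct=24.0, factor=1.966, noise_sd=0.12),
)

#: Genes of interest of the song preset (singing-induced immediate early
#: genes and FOXP2).
SONG_TARGET_GENES: tuple[str, ...] = ("EGR1", "CFOS", "FOXP2")


def preset_song_config(
    seed: int = 0, singing_effect_log2: float = 3.0
) -> SimConfig:
    """Configuration of the Area X singing-vs-silent validation design.

    5 singing vs 7 silent males; EGR1 and CFOS carry ``singing_effect_log2``
    (default +3, an 8-fold induction) in the singing group, FOXP2 carries
    none. Set the effect to 0 for a null (no-regulation) experiment.
    """
    genes = SONG_REFERENCE_GENES + (
        GeneSpec("EGR1", baseline_ct=28.0, factor=2.0, noise_sd=0.12),
        GeneSpec("CFOS", baseline_ct=29.0, factor=2.0, noise_sd=0.12),
        GeneSpec("FOXP2", baseline_ct=26.0, factor=2.0, noise_sd=0.12),
    )
    effects = (
        {"EGR1": singing_effect_log2, "CFOS": singing_effect_log2}
        if singing_effect_log2
        else {}
    )
    return SimConfig(
        genes=genes,
        groups=(
            GroupSpec("song", n=5, effects=effects),
            GroupSpec("silent", n=7),
        ),
        sample_scaling_sd=1.5,
        triplicate_sd=0.10,
        outlier_rate=0.02,
        seed=seed,
    )


def preset_song_dataset(
    seed: int = 0, singing_effect_log2: float = 3.0
) -> pd.DataFrame:
    """Raw triplicate table for the song preset (12 samples x 12 genes)."""
    return simulate_ct_table(preset_song_config(seed, singing_effect_log2))


def song_ct_table(
    seed: int = 0,
    singing_effect_log2: float = 3.0,
    policy: QcPolicy | None = None,
) -> CtTable:
    """Song preset simulated, triplicate-collapsed and assembled into a CtTable."""
    config = preset_song_config(seed, singing_effect_log2)
    raw = simulate_ct_table(config)
    return ct_table_from_long(raw, efficiencies=config.efficiencies, policy=policy)
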