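"""Pan-avian reference-gene primer panel and per-species assay screening.

The package ships two plain-CSV fixtures transcribing the published panel:

* ``panel_table1.csv`` — 14 candidate reference genes (18S, ABL, GAPDH, GUSB,
  HMBS, HPRT, PGK1, RPL13, RPL19, RPS7, SDHA, TFRC, VIM, YWHAZ) with forward
  and reverse primer sequences, the amplicon length range across the nine
  species, and the genomic (intron-containing) product size in chicken.
* ``screen_table2.csv`` — the outcome of testing each primer pair on each of
  nine avian species: a measured amplification efficiency (percent), or one
  of the status codes ``nt`` (primer not tested), ``nw`` (tested but not
  working), ``nd`` (efficiency not determined).

On top of the fixtures this module implements the computable acceptance
rules used to establish an assay: primer length 15–25 nt, GC content 40–70%,
amplicon shorter than 250 bp, and amplification efficiency within 90–110%
(inclusive). The published 58 °C melting-temperature criterion is recorded
in :class:`PanelCriteria` as metadata only — no Tm model is implemented, so
it is never checked.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from Bio import SeqIO

from .errors import InvalidSequenceError, UnknownSpeciesError

__all__ = [
    "PrimerPair",
    "AssayScreen",
    "PanelCriteria",
    "ZEBRA_FINCH_STABILITY_PANEL",
    "gc_content",
    "check_primer",
    "count_established",
    "load_primer_panel",
    "load_assay_screens",
    "screened_species",
    "export_primer_fasta",
]

_DNA_ALPHABET = frozenset("ACGT")

#: The 10 candidate reference genes screened for expression stability in the
#: zebra finch (song and tissue data sets). GUSB is part of the screen even
#: though it later falls below the detection limit in Area X microbiopsies.
ZEBRA_FINCH_STABILITY_PANEL: tuple[str, ...] = (
    "18S", "GUSB", "HMBS", "HPRT", "PGK1", "RPS7", "SDHA", "TFRC", "VIM", "YWHAZ",
)


def _validate_seq(seq: str, what: str) -> None:
    if not seq:
        raise InvalidSequenceError(f"{what} is empty")
    bad = set(seq) - _DNA_ALPHABET
    if bad:
        raise InvalidSequenceError(
            f"{what} contains non-ACGT characters: {sorted(bad)!r}"
        )


@dataclass(frozen=True)
class PrimerPair:
    """One candidate gene's forward/reverse primer pair.

    ``amplicon_len_range`` is the (low, high) span of cDNA product lengths
    observed across species; ``genomic_size`` is the genomic product size in
    chicken (None for 18S-like genes without an intron-spanning design).
    """

    gene_symbol: str
    forward_seq: str
    reverse_seq: str
    amplicon_len_range: tuple[int, int]
    genomic_size: int | None = None

    def __post_init__(self) -> None:
        _validate_seq(self.forward_seq, f"{self.gene_symbol} forward primer")
        _validate_seq(self.reverse_seq, f"{self.gene_symbol} reverse primer")
        lo, hi = self.amplicon_len_range
        if lo > hi:
            raise ValueError(
                f"{self.gene_symbol}: amplicon range low {lo} > high {hi}"
            )


#: Status codes used by the assay screen, mapping one-to-one onto the
#: published table's cell types: a printed number, "nt", "nw", "nd".
SCREEN_STATUSES = frozenset({"measured", "nt", "nw", "nd"})


@dataclass(frozen=True)
class AssayScreen:
    """Outcome of testing one primer pair on one species."""

    species: str
    gene_symbol: str
    status: str  # "measured" | "nt" | "nw" | "nd"
    efficiency_pct: float | None = None

    def __post_init__(self) -> None:
        if self.status not in SCREEN_STATUSES:
            raise ValueError(f"unknown screen status {self.status!r}")
        if self.status == "measured":
            if self.efficiency_pct is None or self.efficiency_pct <= 0:
                raise ValueError(
                    f"{self.species}/{self.gene_symbol}: measured status "
                    "requires a positive efficiency"
                )
        elif self.efficiency_pct is not None:
            raise ValueError(
                f"{self.species}/{self.gene_symbol}: status {self.status!r} "
                "cannot carry an efficiency value"
            )


@dataclass(frozen=True)
class PanelCriteria:
    """Computable primer/assay acceptance rules.

    ``target_tm_c`` is design metadata (the panel was designed for a 58 °C
    melting temperature) and is never checked.
    """

    min_len: int = 15
    max_len: int = 25
    min_gc: float = 40.0
    max_gc: float = 70.0
    max_amplicon: int = 250
    efficiency_window: tuple[float, float] = (90.0, 110.0)
    target_tm_c: float = 58.0

    def __post_init__(self) -> None:
        if self.min_len > self.max_len:
            raise ValueError("min_len > max_len")
        if self.min_gc > self.max_gc:
            raise ValueError("min_gc > max_gc")
        lo, hi = self.efficiency_window
        if lo > hi:
            raise ValueError("efficiency window low > high")


def gc_content(seq: str) -> float:
    """Percent G+C of an A/C/G/T sequence.

    Raises :class:`InvalidSequenceError` on empty or non-ACGT input.
    """
    _validate_seq(seq, "sequence")
    gc = sum(1 for b in seq if b in "GC")
    return 100.0 * gc / len(seq)


def check_primer(pair: PrimerPair, criteria: PanelCriteria | None = None) -> list[str]:
    """Check a primer pair against the panel design rules.

    Returns a list of violated-rule identifiers, empty when the pair passes.
    Identifiers are ``{forward,reverse}_too_{short,long}``,
    ``{forward,reverse}_gc_{low,high}`` and ``amplicon_too_long``. The
    amplicon check uses the upper end of the printed length range against a
    strict ``< max_amplicon`` bound.
    """
    c = criteria or PanelCriteria()
    violations: list[str] = []
    for side, seq in (("forward", pair.forward_seq), ("reverse", pair.reverse_seq)):
        if len(seq) < c.min_len:
            violations.append(f"{side}_too_short")
        elif len(seq) > c.max_len:
            violations.append(f"{side}_too_long")
        gc = gc_content(seq)
        if gc < c.min_gc:
            violations.append(f"{side}_gc_low")
        elif gc > c.max_gc:
            violations.append(f"{side}_gc_high")
    if pair.amplicon_len_range[1] >= c.max_amplicon:
        violations.append("amplicon_too_long")
    return violations


def count_established(
    screens: Iterable[AssayScreen],
    species: str,
    criteria: PanelCriteria | None = None,
) -> int:
    """Number of assays established for one species.

    An assay counts as established when its measured efficiency lies inside
    the acceptance window, inclusive at both ends (the published table marks
    90.3 and 107.6 as acceptable but not 89.8, so the interval is closed).
    """
    c = criteria or PanelCriteria()
    lo, hi = c.efficiency_window
    rows = [s for s in screens if s.species == species]
    if not rows:
        raise UnknownSpeciesError(species)
    return sum(
        1
        for s in rows
        if s.status == "measured" and lo <= s.efficiency_pct <= hi
    )


def _fixture(name: str):
    return resources.files("refstab.data").joinpath(name)


def load_primer_panel(path: str | Path | None = None) -> list[PrimerPair]:
    """Read a primer panel CSV (defaults to the packaged 14-gene panel).

    Columns: gene, forward_seq, reverse_seq, amplicon_lo, amplicon_hi,
    genomic_bp (may be empty).
    """
    src = Path(path) if path is not None else _fixture("panel_table1.csv")
    pairs: list[PrimerPair] = []
    seen: set[str] = set()
    with src.open(newline="") as fh:
        for row in csv.DictReader(fh):
            gene = row["gene"]
            if gene in seen:
                raise ValueError(f"duplicate gene {gene!r} in primer panel")
            seen.add(gene)
            genomic = row.get("genomic_bp") or None
            pairs.append(
                PrimerPair(
                    gene_symbol=gene,
                    forward_seq=row["forward_seq"],
                    reverse_seq=row["reverse_seq"],
                    amplicon_len_range=(int(row["amplicon_lo"]), int(row["amplicon_hi"])),
                    genomic_size=int(genomic) if genomic else None,
                )
            )
    return pairs


def load_assay_screens(path: str | Path | None = None) -> list[AssayScreen]:
    """Read an assay-screen CSV (defaults to the packaged nine-species table).

    Columns: species, gene, status (measured/nt/nw/nd), efficiency_pct
    (present iff status is measured). Status codes are never coerced to
    numbers.
    """
    src = Path(path) if path is not None else _fixture("screen_table2.csv")
    screens: list[AssayScreen] = []
    with src.open(newline="") as fh:
        for row in csv.DictReader(fh):
            eff = row.get("efficiency_pct")
            screens.append(
                AssayScreen(
                    species=row["species"],
                    gene_symbol=row["gene"],
                    status=row["status"],
                    efficiency_pct=float(eff) if eff else None,
                )
            )
    return screens


def screened_species(screens: Iterable[AssayScreen]) -> list[str]:
    """Distinct species in screen order of first appearance."""
    out: list[str] = []
    for s in screens:
        if s.species not in out:
            out.append(s.species)
    return out


def export_primer_fasta(pairs: Sequence[PrimerPair], path: str | Path) -> None:
    """Write a panel as FASTA, two records per gene (``<gene>_F``, ``<gene>_R``)."""
    records = []
    for p in pairs:
        records.append(SeqRecord(Seq(p.forward_seq), id=f"{p.gene_symbol}_F", description=""))
        records.append(SeqRecord(Seq(p.reverse_seq), id=f"{p.gene_symbol}_R", description=""))
    SeqIO.write(records, str(path), "fasta")
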