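"""Nucleotide-composition statistics of coding regions.

Covers overall base percentages and (G+C)%, per-codon-position base
frequencies, and the synonymous third-position shares A3/U3/C3/G3 and
(G+C)3. Third-position statistics are restricted to codons of amino acids
with at least two synonymous codons (Met, Trp and stops excluded), so the
four shares sum to 100.

Codons containing ambiguity codes (N, R, Y, ...) are dropped from all
counts; the number dropped per source is recorded on the count table.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from .genetic_code import (
    ALL_CODONS,
    CODON_TO_AA,
    DEGENERACY,
    RNA_BASES,
    SENSE_CODONS,
    STOP_CODONS,
)
from .sequence_io import AMBIGUITY_SAFE, CodingRegion

logger = logging.getLogger("codonbias")


class CompositionError(ValueError):
    """Raised for empty or degenerate composition inputs."""


@dataclass
class CodonCountTable:
    """Counts of all 64 codons for one coding region (or a pooled set)."""

    counts: dict[str, int]
    source_id: str = ""
    dropped_codons: int = 0

    def __post_init__(self) -> None:
        clean = {c: 0 for c in ALL_CODONS}
        for codon, n in self.counts.items():
            if codon not in clean:
                raise CompositionError(f"not a codon: {codon!r}")
            if n < 0:
                raise CompositionError(f"negative count for {codon}")
            clean[codon] = int(n)
        self.counts = clean

    @property
    def total_codons(self) -> int:
        return sum(self.counts.values())

    def __getitem__(self, codon: str) -> int:
        return self.counts[codon]

    def family_total(self, aa: str) -> int:
        from .genetic_code import AA_TO_CODONS

        return sum(self.counts[c] for c in AA_TO_CODONS[aa])


def count_codons(region: CodingRegion) -> CodonCountTable:
    """Frame-0 triplet counts of a coding region.

    Codons containing ambiguity characters are dropped and tallied in
    ``dropped_codons``. (Stop codons can only appear here if the region was
    constructed from unfiltered input; normal reads trim/exclude them.)
    """
    counts: dict[str, int] = {}
    dropped = 0
    for codon in region.codons():
        if set(codon) <= AMBIGUITY_SAFE:
            counts[codon] = counts.get(codon, 0) + 1
        else:
            dropped += 1
    if dropped:
        logger.info("%s: dropped %d ambiguous codons", region.isolate_id, dropped)
    return CodonCountTable(counts=counts, source_id=region.isolate_id, dropped_codons=dropped)


@dataclass(frozen=True)
class CompositionSummary:
    """One isolate's composition row: overall and synonymous third-position
    base percentages, (G+C)%, (G+C)3%, and the effective number of codons."""

    isolate_id: str
    pct_a: float
    pct_u: float
    pct_c: float
    pct_g: float
    pct_gc: float
    a3: float
    u3: float
    c3: float
    g3: float
    gc3: float
    nc: float

    def as_row(self) -> dict[str, float]:
        return {
            "A%": self.pct_a, "A3%": self.a3,
            "U%": self.pct_u, "U3%": self.u3,
            "C%": self.pct_c, "C3%": self.c3,
            "G%": self.pct_g, "G3%": self.g3,
            "(G+C)%": self.pct_gc, "(G+C)3%": self.gc3,
            "Nc": self.nc,
        }


def base_composition(region: CodingRegion) -> tuple[float, float, float, float, float]:
    """Overall A/U/C/G percentages and (G+C)% over all sense-codon positions."""
    counts = count_codons(region)
    return base_composition_from_counts(counts)


def base_composition_from_counts(
    counts: CodonCountTable,
) -> tuple[float, float, float, float, float]:
    tallies = {b: 0 for b in RNA_BASES}
    for codon, n in counts.counts.items():
        for b in codon:
            tallies[b] += n
    total = sum(tallies.values())
    if total == 0:
        raise CompositionError("empty region: no codons to summarize")
    pct = {b: 100.0 * tallies[b] / total for b in RNA_BASES}
    return pct["A"], pct["U"], pct["C"], pct["G"], pct["G"] + pct["C"]


def positional_base_composition(
    counts: CodonCountTable, position: int
) -> dict[str, float]:
    """Base percentages at codon position 1, 2 or 3 over all counted codons."""
    if position not in (1, 2, 3):
        raise CompositionError(f"codon position must be 1, 2 or 3, got {position}")
    total = counts.total_codons
    if total == 0:
        raise CompositionError("no codons counted")
    tallies = {b: 0 for b in RNA_BASES}
    for codon, n in counts.counts.items():
        tallies[codon[position - 1]] += n
    return {b: 100.0 * tallies[b] / total for b in RNA_BASES}


def synonymous_third_composition(
    counts: CodonCountTable,
) -> tuple[float, float, float, float, float]:
    """A3/U3/C3/G3 shares and (G+C)3 at synonymous third positions.

    Restricted to codons of amino acids with >=2 synonymous codons, so the
    four shares sum to 100; (G+C)3 = C3 + G3.
    """
    tallies = {b: 0 for b in RNA_BASES}
    for codon in SENSE_CODONS:
        aa = CODON_TO_AA[codon]
        if DEGENERACY[aa] < 2:
            continue
        tallies[codon[2]] += counts.counts[codon]
    total = sum(tallies.values())
    if total == 0:
        raise CompositionError("no synonymous codons present")
    a3 = 100.0 * tallies["A"] / total
    u3 = 100.0 * tallies["U"] / total
    c3 = 100.0 * tallies["C"] / total
    g3 = 100.0 * tallies["G"] / total
    return a3, u3, c3, g3, c3 + g3


def composition_summary(region: CodingRegion) -> CompositionSummary:
    """Assemble the full composition row for one isolate, including Nc."""
    from .codon_stats import enc

    counts = count_codons(region)
    pct_a, pct_u, pct_c, pct_g, pct_gc = base_composition_from_counts(counts)
    a3, u3, c3, g3, gc3 = synonymous_third_composition(counts)
    nc = enc(counts).nc
    return CompositionSummary(
        isolate_id=region.isolate_id,
        pct_a=pct_a, pct_u=pct_u, pct_c=pct_c, pct_g=pct_g, pct_gc=pct_gc,
        a3=a3, u3=u3, c3=c3, g3=g3, gc3=gc3, nc=nc,
    )


_COLUMNS = [
    "A%", "A3%", "U%", "U3%", "C%", "C3%", "G%", "G3%",
    "(G+C)%", "(G+C)3%", "Nc",
]


def write_composition_table(
    summaries: Sequence[CompositionSummary], path: str | Path
) -> None:
    """TSV with one row per isolate plus an Average row (unrounded means,
    printed at 1 dp)."""
    if not summaries:
        raise CompositionError("no summaries to write")
    with open(path, "w") as fh:
        fh.write("isolate\t" + "\t".join(_COLUMNS) + "\n")
        for s in summaries:
            row = s.as_row()
            fh.write(s.isolate_id + "\t" + "\t".join(f"{row[c]:.1f}" for c in _COLUMNS) + "\n")
        n = len(summaries)
        means = {
            c: sum(s.as_row()[c] for s in summaries) / n for c in _COLUMNS
        }
        fh.write("Average\t" + "\t".join(f"{means[c]:.1f}" for c in _COLUMNS) + "\n")
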