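"""Synonymous codon-usage statistics: RSCU and Wright's effective number
of codons (Nc), plus the neutral expected-Nc curve for the Nc-plot.

RSCU of codon j in an amino-acid family of degeneracy k with counts n_j is

    RSCU_j = k * n_j / sum_j n_j

so a value of 1 means no bias within the family. Nc summarizes bias across
families through per-family codon "homozygosity"

    F_hat = (n * sum_i p_i^2 - 1) / (n - 1),   p_i = n_i / n,

averaged within each degeneracy class (2-, 3-, 4-, 6-fold), and

    Nc = 2 + 9/F2 + 1/F3 + 5/F4 + 3/F6,

capped to the interpretable range [20, 61]. The neutral expectation at
synonymous G+C share s (the curve of the Nc-plot) is

    Nc* = 2 + s + 29 / (s^2 + (1 - s)^2).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

from .composition import CodonCountTable
from .genetic_code import (
    AA_ONE_TO_THREE,
    AA_TO_CODONS,
    DEGENERACY,
    DEGENERACY_CLASSES,
    SYNONYMOUS_AA,
)
from .sequence_io import HostCodonUsage


class CodonStatsError(ValueError):
    pass


@dataclass
class RSCUTable:
    """RSCU values for the 59 informative codons.

    Families with zero total count are *missing*: their codons are absent
    from ``values`` and the family is listed in ``missing_families``.
    """

    values: dict[str, float]
    counts: CodonCountTable
    missing_families: tuple[str, ...] = ()

    def vector(self, impute: float | None = None) -> dict[str, float]:
        """All 59 informative codons; missing entries imputed if requested."""
        from .genetic_code import INFORMATIVE_CODONS

        if impute is None and self.missing_families:
            raise CodonStatsError(
                "RSCU has missing families "
                f"{self.missing_families}; pass impute= to fill them"
            )
        return {
            c: self.values.get(c, impute if impute is not None else 0.0)
            for c in INFORMATIVE_CODONS
        }


def rscu(counts: CodonCountTable) -> RSCUTable:
    """Relative synonymous codon usage from a codon-count table."""
    values: dict[str, float] = {}
    missing: list[str] = []
    for aa in SYNONYMOUS_AA:
        codons = AA_TO_CODONS[aa]
        k = DEGENERACY[aa]
        total = sum(counts.counts[c] for c in codons)
        if total == 0:
            missing.append(aa)
            continue
        for c in codons:
            values[c] = k * counts.counts[c] / total
    return RSCUTable(values=values, counts=counts, missing_families=tuple(missing))


def pooled_counts(tables: Sequence[CodonCountTable]) -> CodonCountTable:
    """Element-wise sum of codon-count tables (cumulative counts)."""
    if not tables:
        raise CodonStatsError("cannot pool an empty list of count tables")
    summed: dict[str, int] = {}
    for t in tables:
        for codon, n in t.counts.items():
            summed[codon] = summed.get(codon, 0) + n
    return CodonCountTable(
        counts=summed,
        source_id="pooled(%d)" % len(tables),
        dropped_codons=sum(t.dropped_codons for t in tables),
    )


@dataclass(frozen=True)
class NcValue:
    """Wright's effective number of codons with its per-class homozygosities."""

    nc: float
    nc_raw: float
    f_bar_by_class: dict[int, float]
    n_aa_observed: int


def _family_homozygosity(counts: CodonCountTable, aa: str) -> tuple[float, int] | None:
    """(F_hat, n) for one family, or None if n < 2 (F_hat undefined)."""
    codons = AA_TO_CODONS[aa]
    n = sum(counts.counts[c] for c in codons)
    if n < 2:
        return None
    sum_p2 = sum((counts.counts[c] / n) ** 2 for c in codons)
    f_hat = (n * sum_p2 - 1) / (n - 1)
    return f_hat, n

def enc(counts: CodonCountTable) -> NcValue:
    """Wright's effective number of codons.

    Families with fewer than 2 codons observed are excluded from their
    class mean. If an entire degeneracy class is unobserved, its
    contribution is estimated: the 3-fold class (Ile alone) uses the mean
    of the 2- and 4-fold reciprocal homozygosities; any other missing class
    uses the mean F over observed classes. The returned ``nc`` is clamped
    to [20, 61]; ``nc_raw`` keeps the unclamped value.
    """
    f_by_class: dict[int, list[float]] = {k: [] for k in DEGENERACY_CLASSES}
    n_aa = 0
    for k, aas in DEGENERACY_CLASSES.items():
        for aa in aas:
            fh = _family_homozygosity(counts, aa)
            if fh is not None and fh[0] > 0:
                f_by_class[k].append(fh[0])
                n_aa += 1
    f_bar = {k: (sum(v) / len(v)) for k, v in f_by_class.items() if v}
    if not f_bar:
        raise CodonStatsError("no amino-acid family has 2 or more codons observed")

    class_sizes = {k: len(aas) for k, aas in DEGENERACY_CLASSES.items()}
    total = 2.0
    for k in sorted(class_sizes):
        if k in f_bar:
            total += class_sizes[k] / f_bar[k]
        elif k == 3 and 2 in f_bar and 4 in f_bar:
            total += 0.5 * (1.0 / f_bar[2] + 1.0 / f_bar[4])
        else:
            mean_f = sum(f_bar.values()) / len(f_bar)
            total += class_sizes[k] / mean_f
    nc_raw = total
    return NcValue(
        nc=min(61.0, max(20.0, nc_raw)),
        nc_raw=nc_raw,
        f_bar_by_class=f_bar,
        n_aa_observed=n_aa,
    )


def expected_enc(s: float) -> float:
    """Neutral (mutation-only) Nc at synonymous G+C share ``s`` in [0, 1]."""
    if not 0.0 <= s <= 1.0:
        raise CodonStatsError(f"GC3s share must be in [0, 1], got {s}")
    return 2.0 + s + 29.0 / (s * s + (1.0 - s) ** 2)


def write_rscu_table(
    virus_rscu: RSCUTable,
    path: str | Path,
    host: HostCodonUsage | None = None,
) -> None:
    """TSV in the published layout: amino acid, codon, N, virus RSCU, and
    optionally the host RSCU column."""
    with open(path, "w") as fh:
        header = "amino_acid\tcodon\tN\trscu_virus"
        if host is not None:
            header += "\trscu_host"
        fh.write(header + "\n")
        for aa in SYNONYMOUS_AA:
            for codon in AA_TO_CODONS[aa]:
                val = virus_rscu.values.get(codon)
                row = [
                    AA_ONE_TO_THREE[aa],
                    codon,
                    str(virus_rscu.counts.counts[codon]),
                    "NA" if val is None else f"{val:.2f}",
                ]
                if host is not None:
                    row.append(f"{host.rscu.get(codon, float('nan')):.2f}")
                fh.write("\t".join(row) + "\n")
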