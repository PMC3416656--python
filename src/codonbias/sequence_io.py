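"""Reading and writing coding sequences and host codon-usage tables.

Coding sequences come from GenBank flat files (one CDS feature each) or
from in-frame multi-FASTA. On read everything is normalized to the RNA
alphabet, terminal stop codons are trimmed, and CDS with internal stops are
excluded with a warning. Host codon-usage tables are parsed from the Kazusa
Codon Usage Database "standard" text layout (codon, frequency per 1000,
count in parentheses).
"""

from __future__ import annotations

import logging
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO

from .genetic_code import (
    AA_TO_CODONS,
    ALL_CODONS,
    CODON_TO_AA,
    DEGENERACY,
    STOP_CODONS,
    dna,
    rna,
)

logger = logging.getLogger("codonbias")

AMBIGUITY_SAFE = frozenset("ACGU")


class SequenceIOError(ValueError):
    """Malformed sequence input (bad frame, bad file, missing codons)."""


@dataclass(frozen=True)
class CodingSequence:
    """One in-frame coding sequence (terminal stop already trimmed).

    ``raw_length_nt`` is the pre-trimming length; the 150-nt ORF filter is
    defined on it so that a 150-nt ORF (49 sense codons + stop) survives.
    """

    isolate_id: str
    orf_name: str
    sequence: str
    raw_length_nt: int

    def __post_init__(self) -> None:
        if len(self.sequence) % 3 != 0:
            raise SequenceIOError(
                f"{self.isolate_id}|{self.orf_name}: length {len(self.sequence)} "
                "is not a multiple of 3"
            )

    @property
    def length_nt(self) -> int:
        return len(self.sequence)

    def codons(self) -> list[str]:
        s = self.sequence
        return [s[i:i + 3] for i in range(0, len(s), 3)]


@dataclass(frozen=True)
class CodingRegion:
    """The concatenated coding region of one isolate (5'->3' ORF order)."""

    isolate_id: str
    orfs: tuple[CodingSequence, ...]

    @property
    def concatenated(self) -> str:
        return "".join(o.sequence for o in self.orfs)

    @property
    def length_nt(self) -> int:
        return sum(o.length_nt for o in self.orfs)

    def codons(self) -> list[str]:
        out: list[str] = []
        for o in self.orfs:
            out.extend(o.codons())
        return out


@dataclass
class HostCodonUsage:
    """A host species' codon-usage table (Kazusa-style).

    ``per_codon`` maps each of the 64 codons to (frequency per 1000, count).
    ``rscu`` is derived from the counts with the standard per-family
    normalization; Met, Trp and stops are omitted from it.
    """

    species: str
    per_codon: dict[str, tuple[float, int]]
    rscu: dict[str, float] = field(init=False)

    def __post_init__(self) -> None:
        missing = [c for c in ALL_CODONS if c not in self.per_codon]
        if missing:
            raise SequenceIOError(
                f"host table for {self.species} is missing codons: "
                + ", ".join(missing)
            )
        for codon, (freq, count) in self.per_codon.items():
            if freq < 0 or count < 0:
                raise SequenceIOError(
                    f"host table for {self.species}: negative entry for {codon}"
                )
        self.rscu = {}
        for aa, codons in AA_TO_CODONS.items():
            k = DEGENERACY[aa]
            if k < 2:
                continue
            total = sum(self.per_codon[c][1] for c in codons)
            if total == 0:
                continue
            for c in codons:
                self.rscu[c] = k * self.per_codon[c][1] / total

    def frequency(self, codon: str) -> float:
        return self.per_codon[codon][0]

    def count(self, codon: str) -> int:
        return self.per_codon[codon][1]


def _trim_and_check(
    isolate_id: str, orf_name: str, nt: str
) -> CodingSequence | None:
    """Normalize to RNA, drop the terminal stop, reject internal stops."""
    seq = rna(nt)
    raw_len = len(seq)
    if raw_len % 3 != 0:
        raise SequenceIOError(
            f"{isolate_id}|{orf_name}: CDS length {raw_len} not divisible by 3"
        )
    codons = [seq[i:i + 3] for i in range(0, len(seq), 3)]
    if codons and codons[-1] in STOP_CODONS:
        codons = codons[:-1]
    internal = [
        i for i, c in enumerate(codons)
        if set(c) <= AMBIGUITY_SAFE and c in STOP_CODONS
    ]
    if internal:
        warnings.warn(
            f"{isolate_id}|{orf_name}: internal stop codon at codon "
            f"{internal[0] + 1}; CDS excluded",
            stacklevel=3,
        )
        logger.warning("excluded CDS with internal stop: %s|%s", isolate_id, orf_name)
        return None
    return CodingSequence(isolate_id, orf_name, "".join(codons), raw_len)


def read_cds_genbank(path: str | Path) -> list[CodingSequence]:
    """Extract all CDS features of a GenBank flat file as CodingSequences.

    Nucleotides are taken in coding orientation (``feature.extract``),
    normalized to RNA, terminal stops trimmed. CDS features whose
    translation would contain an internal stop are excluded with a warning.
    """
    path = Path(path)
    out: list[CodingSequence] = []
    try:
        records = list(SeqIO.parse(str(path), "genbank"))
    except Exception as exc:  # Biopython raises assorted ValueErrors
        raise SequenceIOError(f"cannot parse GenBank file {path}: {exc}") from exc
    if not records:
        raise SequenceIOError(f"no GenBank records in {path}")
    for record in records:
        for feature in record.features:
            if feature.type != "CDS":
                continue
            quals = feature.qualifiers
            name = (
                quals.get("gene", quals.get("product", quals.get("locus_tag", ["CDS"])))
            )[0]
            nt = str(feature.extract(record.seq))
            cds = _trim_and_check(record.id, name, nt)
            if cds is not None:
                out.append(cds)
    return out


def read_cds_fasta(path: str | Path) -> list[CodingSequence]:
    """Read in-frame CDS from multi-FASTA; headers are ``isolate_id|orf_name``."""
    out: list[CodingSequence] = []
    for record in SeqIO.parse(str(path), "fasta"):
        if "|" in record.id:
            isolate_id, orf_name = record.id.split("|", 1)
        else:
            isolate_id, orf_name = record.id, "CDS"
        cds = _trim_and_check(isolate_id, orf_name, str(record.seq))
        if cds is not None:
            out.append(cds)
    return out


def write_cds_fasta(
    cds: Iterable[CodingSequence], path: str | Path, alphabet: str = "rna"
) -> None:
    """Write CodingSequences to multi-FASTA (``isolate|orf`` headers)."""
    if alphabet not in ("rna", "dna"):
        raise ValueError("alphabet must be 'rna' or 'dna'")
    with open(path, "w") as fh:
        for rec in cds:
            seq = rec.sequence if alphabet == "rna" else dna(rec.sequence)
            fh.write(f">{rec.isolate_id}|{rec.orf_name}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i:i + 70] + "\n")


def filter_short_orfs(
    cds: Sequence[CodingSequence], min_nt: int = 150
) -> list[CodingSequence]:
    """Drop ORFs shorter than ``min_nt`` (pre-trimming length); order kept."""
    if min_nt <= 0:
        raise ValueError("min_nt must be positive")
    kept = [c for c in cds if c.raw_length_nt >= min_nt]
    dropped = len(cds) - len(kept)
    if dropped:
        logger.info("ORF length filter (<%d nt): dropped %d of %d", min_nt, dropped, len(cds))
    return kept


def concatenate_coding_region(cds: Sequence[CodingSequence]) -> CodingRegion:
    """Concatenate one isolate's ORFs, in the given (genome) order.

    Overlapping ORFs each contribute their full codon sequence: overlap
    nucleotides are counted once per reading frame they occur in.
    """
    if not cds:
        raise SequenceIOError("cannot build a coding region from zero ORFs")
    ids = {c.isolate_id for c in cds}
    if len(ids) != 1:
        raise SequenceIOError(f"mixed isolate ids in coding region: {sorted(ids)}")
    return CodingRegion(isolate_id=cds[0].isolate_id, orfs=tuple(cds))


_KAZUSA_ENTRY = re.compile(r"([ACGTU]{3})\s+([0-9.]+)\s*\(\s*(\d+)\s*\)")


def parse_host_codon_table(path: str | Path, species: str | None = None) -> HostCodonUsage:
    """Parse a Kazusa Codon Usage Database standard-format text table.

    Entries look like ``UUU 17.6(714298)``; comment lines starting with '#'
    and the ``fields:`` header line are ignored. All 64 codons must be
    present.
    """
    path = Path(path)
    per_codon: dict[str, tuple[float, int]] = {}
    text = path.read_text()
    for line in text.splitlines():
        if line.lstrip().startswith(("#", "fields:")):
            continue
        for codon_raw, freq, count in _KAZUSA_ENTRY.findall(line):
            per_codon[rna(codon_raw)] = (float(freq), int(count))
    return HostCodonUsage(species=species or path.stem, per_codon=per_codon)


def write_codon_counts_tsv(counts: dict[str, int], path: str | Path) -> None:
    """Write a codon-count table as TSV (codon, amino_acid, count)."""
    with open(path, "w") as fh:
        fh.write("codon\tamino_acid\tcount\n")
        for codon in ALL_CODONS:
            aa = CODON_TO_AA.get(codon, "*")
            fh.write(f"{codon}\t{aa}\t{counts.get(codon, 0)}\n")
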