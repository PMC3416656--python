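"""Synthetic coding-region cohorts with controllable codon-usage structure.

The generator states a simple world: each isolate's codons are drawn
independently, amino acids from a fixed frequency vector and synonymous
codons from per-family probability vectors. Group structure (the three
CTV genotype groups) enters only through re-weighting of C-ended codons,
so any separation a downstream analysis finds is a pure codon-usage
signal. Within-group divergence is modelled as synonymous third-position
substitution noise, preserving protein identity.

Defaults emulate the published CTV cohort: 20 isolates in groups of
11/6/3, twelve ORFs totalling 18,498 coding nucleotides (~6,166 codons),
amino-acid and codon frequencies taken from the pooled CTV codon-count
fixture (overall G+C ~= 42%, U-rich third positions).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Sequence

import numpy as np

from .composition import CodonCountTable
from .genetic_code import (
    AA_THREE_TO_ONE,
    AA_TO_CODONS,
    DEGENERACY,
    SYNONYMOUS_AA,
)
from .sequence_io import CodingRegion, CodingSequence, HostCodonUsage


class SyntheticDataError(ValueError):
    pass


# twelve ORF coding lengths (nt, stop excluded), large replicase ORFs first;
# total 18,498 nt = 6,166 codons, inside the published isolate-length range
DEFAULT_ORF_LENGTHS_NT: tuple[int, ...] = (
    9363, 1404, 804, 150, 1704, 1596, 729, 669, 504, 360, 552, 663,
)

DEFAULT_GROUPS: tuple[tuple[str, float, int], ...] = (
    # (label, C-ended codon weight multiplier, isolate count)
    ("YSP", 0.90, 11),
    ("RB", 1.00, 6),
    ("QD", 1.10, 3),
)

DEFAULT_NOISE = 0.02  # per-codon synonymous third-position divergence


@dataclass
class CodonModel:
    """Per-amino-acid codon probabilities plus amino-acid frequencies."""

    per_aa_probs: dict[str, dict[str, float]]
    aa_freqs: dict[str, float]

    def __post_init__(self) -> None:
        for aa, probs in self.per_aa_probs.items():
            s = sum(probs.values())
            if not math.isclose(s, 1.0, abs_tol=1e-9):
                raise SyntheticDataError(f"codon probabilities for {aa} sum to {s}")
            if any(p < 0 for p in probs.values()):
                raise SyntheticDataError(f"negative codon probability for {aa}")
        s = sum(self.aa_freqs.values())
        if not math.isclose(s, 1.0, abs_tol=1e-9):
            raise SyntheticDataError(f"amino-acid frequencies sum to {s}")

    def expected_rscu(self) -> dict[str, float]:
        """Closed-form expected RSCU of sequences drawn from this model."""
        out: dict[str, float] = {}
        for aa, probs in self.per_aa_probs.items():
            k = DEGENERACY[aa]
            if k < 2:
                continue
            for codon, p in probs.items():
                out[codon] = k * p
        return out

    def reweight_c_ended(self, factor: float) -> "CodonModel":
        """A copy with every C-ended synonymous codon's probability scaled
        by ``factor`` and each family renormalized (shifts C3)."""
        new_probs: dict[str, dict[str, float]] = {}
        for aa, probs in self.per_aa_probs.items():
            if DEGENERACY[aa] < 2:
                new_probs[aa] = dict(probs)
                continue
            scaled = {
                c: p * (factor if c.endswith("C") else 1.0)
                for c, p in probs.items()
            }
            tot = sum(scaled.values())
            new_probs[aa] = {c: p / tot for c, p in scaled.items()}
        return CodonModel(per_aa_probs=new_probs, aa_freqs=dict(self.aa_freqs))


def _normalize(weights: dict[str, float]) -> dict[str, float]:
    tot = sum(weights.values())
    if tot <= 0:
        raise SyntheticDataError("cannot normalize non-positive weights")
    return {k: v / tot for k, v in weights.items()}


def load_pooled_ctv_counts() -> CodonCountTable:
    """The shipped cumulative codon counts over 20 CTV full coding regions."""
    text = (
        resources.files("codonbias.data")
        .joinpath("ctv_pooled_counts.tsv")
        .read_text()
    )
    counts: dict[str, int] = {}
    for line in text.splitlines():
        if line.startswith(("#", "amino_acid")) or not line.strip():
            continue
        _aa3, codon, n, *_ = line.split("\t")
        counts[codon] = int(n)
    return CodonCountTable(counts=counts, source_id="CTV_pooled")


def model_from_counts(counts: CodonCountTable) -> CodonModel:
    """Codon model whose probabilities match an observed count table.

    Amino acids absent from the table (for the shipped pooled fixture:
    Met and Trp, which carry no synonymous signal) get frequency 0.
    """
    per_aa: dict[str, dict[str, float]] = {}
    aa_tot: dict[str, float] = {}
    for aa, codons in AA_TO_CODONS.items():
        tot = sum(counts.counts[c] for c in codons)
        aa_tot[aa] = tot
        if tot > 0:
            per_aa[aa] = {c: counts.counts[c] / tot for c in codons}
    return CodonModel(per_aa_probs=per_aa, aa_freqs=_normalize(aa_tot))


def default_ctv_model() -> CodonModel:
    return model_from_counts(load_pooled_ctv_counts())


def model_from_host_table(host: HostCodonUsage, bias_strength: float) -> CodonModel:
    """Interpolate between uniform synonymous usage (bias 0) and the host's
    family-conditional codon frequencies (bias 1); amino-acid frequencies
    are the host's."""
    if not 0.0 <= bias_strength <= 1.0:
        raise SyntheticDataError("bias_strength must be in [0, 1]")
    per_aa: dict[str, dict[str, float]] = {}
    aa_tot: dict[str, float] = {}
    for aa, codons in AA_TO_CODONS.items():
        k = DEGENERACY[aa]
        tot = sum(host.count(c) for c in codons)
        aa_tot[aa] = tot
        if tot == 0:
            continue
        per_aa[aa] = {
            c: (1.0 - bias_strength) / k + bias_strength * host.count(c) / tot
            for c in codons
        }
    return CodonModel(per_aa_probs=per_aa, aa_freqs=_normalize(aa_tot))


def model_from_gc3(s: float, aa_freqs: dict[str, float] | None = None) -> CodonModel:
    """Neutral model at synonymous G+C share ``s``: within each family a
    codon's weight is the mutational probability of its third base
    (G and C each s/2, A and U each (1-s)/2). Used for Nc-plot null
    cohorts."""
    if not 0.0 <= s <= 1.0:
        raise SyntheticDataError("s must be in [0, 1]")
    base_p = {"G": s / 2, "C": s / 2, "A": (1 - s) / 2, "U": (1 - s) / 2}
    if aa_freqs is None:
        aa_freqs = default_ctv_model().aa_freqs
    per_aa: dict[str, dict[str, float]] = {}
    for aa, codons in AA_TO_CODONS.items():
        if aa_freqs.get(aa, 0.0) == 0.0 and DEGENERACY[aa] < 2:
            continue
        per_aa[aa] = _normalize({c: base_p[c[2]] for c in codons})
    return CodonModel(per_aa_probs=per_aa, aa_freqs=aa_freqs)


def simulate_cds(
    model: CodonModel,
    n_codons: int,
    seed: int | np.random.Generator,
    isolate_id: str = "sim",
    orf_name: str = "CDS",
) -> CodingSequence:
    """Draw one in-frame CDS from the model.

    The exact sampled codon counts are retained on the returned record
    (``.sampled_counts``) so tests can check bookkeeping against the
    generator.
    """
    if n_codons < 1:
        raise SyntheticDataError("n_codons must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    aas = [aa for aa, f in sorted(model.aa_freqs.items()) if f > 0]
    aa_p = np.array([model.aa_freqs[aa] for aa in aas])
    aa_p = aa_p / aa_p.sum()
    aa_draw = rng.choice(len(aas), size=n_codons, p=aa_p)
    codons = np.empty(n_codons, dtype=object)
    for idx, aa in enumerate(aas):
        pos = np.nonzero(aa_draw == idx)[0]
        if pos.size == 0:
            continue
        fam = sorted(model.per_aa_probs[aa])
        fam_p = np.array([model.per_aa_probs[aa][c] for c in fam])
        fam_p = fam_p / fam_p.sum()
        picks = rng.choice(len(fam), size=pos.size, p=fam_p)
        for p, k in zip(pos, picks):
            codons[p] = fam[k]
    seq = "".join(codons)
    cds = CodingSequence(
        isolate_id=isolate_id, orf_name=orf_name, sequence=seq,
        raw_length_nt=3 * n_codons,
    )
    sampled: dict[str, int] = {}
    for c in codons:
        sampled[c] = sampled.get(c, 0) + 1
    object.__setattr__(cds, "sampled_counts", sampled)
    return cds


def _third_position_noise(
    seq: str, rate: float, rng: np.random.Generator
) -> str:
    """Synonymous third-position substitutions at the given per-codon rate.

    Substitutions stay within the same first-two-base family block, so
    protein identity is preserved and no stops can appear.
    """
    if rate <= 0:
        return seq
    codons = [seq[i:i + 3] for i in range(0, len(seq), 3)]
    # same-prefix synonymous alternatives per codon
    hit = rng.random(len(codons)) < rate
    for i in np.nonzero(hit)[0]:
        c = codons[i]
        from .genetic_code import CODON_TO_AA

        aa = CODON_TO_AA.get(c)
        if aa is None:
            continue
        alts = [x for x in AA_TO_CODONS[aa] if x[:2] == c[:2] and x != c]
        if alts:
            codons[i] = alts[rng.integers(len(alts))]
    return "".join(codons)


@dataclass
class SyntheticCohortSpec:
    """The stated world of a simulated cohort: group-wise codon models,
    isolate counts, ORF lengths, within-group noise, and the master seed."""

    groups: list[tuple[str, CodonModel, int]]
    orf_lengths_nt: tuple[int, ...] = DEFAULT_ORF_LENGTHS_NT
    substitution_noise: float = DEFAULT_NOISE
    seed: int = 0

    def __post_init__(self) -> None:
        for label, _model, count in self.groups:
            if count < 1:
                raise SyntheticDataError(f"group {label}: count must be >= 1")
        for ln in self.orf_lengths_nt:
            if ln % 3 != 0 or ln < 150:
                raise SyntheticDataError(
                    f"ORF length {ln} must be divisible by 3 and >= 150"
                )


@dataclass
class SyntheticCohort:
    regions: list[CodingRegion]
    group_labels: list[str]
    models: dict[str, CodonModel]
    spec: SyntheticCohortSpec


def default_cohort_spec(seed: int = 0) -> SyntheticCohortSpec:
    """20 CTV-like isolates in three genotype groups differing in C-ended
    codon weight (C3 separation ~ +/-2 percentage points)."""
    base = default_ctv_model()
    groups = [
        (label, base.reweight_c_ended(factor), count)
        for label, factor, count in DEFAULT_GROUPS
    ]
    return SyntheticCohortSpec(groups=groups, seed=seed)


def _quota_codons_for_aas(
    aas: Sequence[str], model: CodonModel, rng: np.random.Generator
) -> list[str]:
    """Codons for a fixed amino-acid sequence realizing the model's
    family-conditional proportions *exactly* (largest-remainder quotas),
    randomly placed.

    Used for group ancestors: codon-usage differences between groups are
    then exactly their model differences (no multinomial sampling noise),
    while the random placement still makes independently built ancestors
    diverge in sequence.
    """
    out: list[str] = [""] * len(aas)
    arr = np.asarray(aas)
    for aa in sorted(set(aas)):
        pos = np.nonzero(arr == aa)[0]
        n = pos.size
        fam = sorted(model.per_aa_probs[aa])
        p = np.array([model.per_aa_probs[aa][c] for c in fam])
        p = p / p.sum()
        quota = np.floor(p * n).astype(int)
        frac = p * n - quota
        for idx in np.argsort(-frac)[: n - quota.sum()]:
            quota[idx] += 1
        codons = [c for c, q in zip(fam, quota) for _ in range(q)]
        rng.shuffle(codons)
        for position, codon in zip(pos, codons):
            out[position] = codon
    return out


def simulate_cohort(spec: SyntheticCohortSpec) -> SyntheticCohort:
    """Simulate the cohort.

    All isolates descend from one root amino-acid sequence. Each group has
    a codon-level ancestor drawn from its model (so groups differ in codon
    usage and diverge as clades), and each isolate is its group's ancestor
    with independent synonymous third-position substitution noise — so
    groups are monophyletic in sequence space while protein identity is
    shared cohort-wide. All randomness flows from ``spec.seed`` through one
    spawned stream per entity (root, groups, isolates), making results
    independent of generation order.
    """
    n_isolates = sum(count for _, _, count in spec.groups)
    n_groups = len(spec.groups)
    streams = np.random.SeedSequence(spec.seed).spawn(1 + n_groups + n_isolates)
    root_rng = np.random.default_rng(streams[0])

    # common root protein per ORF, from the first group's amino-acid profile
    base_freqs = spec.groups[0][1].aa_freqs
    aa_pool = [aa for aa, f in sorted(base_freqs.items()) if f > 0]
    aa_p = np.array([base_freqs[aa] for aa in aa_pool])
    aa_p = aa_p / aa_p.sum()
    orf_aas: list[list[str]] = []
    for ln in spec.orf_lengths_nt:
        draw = root_rng.choice(len(aa_pool), size=ln // 3, p=aa_p)
        orf_aas.append([aa_pool[i] for i in draw])

    regions: list[CodingRegion] = []
    labels: list[str] = []
    models = {label: model for label, model, _ in spec.groups}
    iso = 0
    for g, (label, model, count) in enumerate(spec.groups):
        group_rng = np.random.default_rng(streams[1 + g])
        ancestor_orfs = [
            "".join(_quota_codons_for_aas(aas, model, group_rng))
            for aas in orf_aas
        ]
        for _ in range(count):
            rng = np.random.default_rng(streams[1 + n_groups + iso])
            isolate_id = f"{label}_{iso + 1:02d}"
            orfs = tuple(
                CodingSequence(
                    isolate_id,
                    f"ORF{j + 1}",
                    _third_position_noise(anc, spec.substitution_noise, rng),
                    len(anc),
                )
                for j, anc in enumerate(ancestor_orfs)
            )
            regions.append(CodingRegion(isolate_id=isolate_id, orfs=orfs))
            labels.append(label)
            iso += 1
    return SyntheticCohort(regions=regions, group_labels=labels, models=models, spec=spec)


def write_cohort(
    cohort: SyntheticCohort, fasta_path: str | Path, truth_path: str | Path
) -> None:
    """Multi-FASTA of all ORFs plus a TSV truth file (isolate, group, seed)."""
    from .sequence_io import write_cds_fasta

    all_cds = [orf for region in cohort.regions for orf in region.orfs]
    write_cds_fasta(all_cds, fasta_path)
    with open(truth_path, "w") as fh:
        fh.write("isolate\tgroup\tseed\n")
        for region, label in zip(cohort.regions, cohort.group_labels):
            fh.write(f"{region.isolate_id}\t{label}\t{cohort.spec.seed}\n")
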