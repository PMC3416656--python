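"""Full-analysis orchestration: composition table, pooled RSCU vs host,
Nc-plot data, correspondence analysis, axis-composition correlations,
virus-host correlation, and the NJ tree, written as plain TSV/Newick.

Rounding happens only in the writers; everything internal is full
precision. Every stage failure aborts with the stage name and the
offending record in the message.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import codon_stats, composition, multivariate, phylogeny, sequence_io

logger = logging.getLogger("codonbias")


class PipelineError(RuntimeError):
    """A stage failed; message names the stage and the offending input."""


class EmptyFilterError(PipelineError):
    """The ORF length filter removed every ORF."""


@dataclass
class AnalysisConfig:
    genome_paths: list[Path]          # GenBank or CDS-FASTA, one per isolate
    host_table: Path | None = None
    alignment: Path | None = None     # aligned multi-FASTA for the tree stage
    min_orf_nt: int = 150
    bootstrap_replicates: int = 1000
    distance: str = "k2p"
    correlation_scale: str = "frequency"
    out_dir: Path = Path("results")
    seed: int = 0

    def __post_init__(self) -> None:
        self.genome_paths = [Path(p) for p in self.genome_paths]
        if self.min_orf_nt <= 0 or self.bootstrap_replicates <= 0:
            raise PipelineError("numeric config fields must be positive")


@dataclass
class ReportBundle:
    summaries: list[composition.CompositionSummary]
    pooled_rscu: codon_stats.RSCUTable
    coa: multivariate.COAResult
    correlations: pd.DataFrame
    host_correlation: multivariate.VirusHostCorrelation | None
    tree_newick: str | None
    outputs: dict[str, Path] = field(default_factory=dict)


def _load_isolate(path: Path, min_orf_nt: int) -> sequence_io.CodingRegion:
    if path.suffix.lower() in (".gb", ".gbk", ".genbank"):
        cds = sequence_io.read_cds_genbank(path)
    else:
        cds = sequence_io.read_cds_fasta(path)
    kept = sequence_io.filter_short_orfs(cds, min_orf_nt)
    logger.info("%s: %d ORFs read, %d kept (>=%d nt)", path.name, len(cds), len(kept), min_orf_nt)
    if not kept:
        raise EmptyFilterError(
            f"stage sequence_io: no ORFs of {path} survive the "
            f"{min_orf_nt}-nt filter"
        )
    return sequence_io.concatenate_coding_region(kept)


def run_full_analysis(config: AnalysisConfig) -> ReportBundle:
    """Run every stage and write the report tables into ``config.out_dir``."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, Path] = {}

    # --- stage: read + composition (per-isolate rows) ----------------------
    regions = [_load_isolate(p, config.min_orf_nt) for p in config.genome_paths]
    if len(regions) < 3:
        raise PipelineError("stage composition: need at least 3 isolates")
    try:
        summaries = [composition.composition_summary(r) for r in regions]
    except ValueError as exc:
        raise PipelineError(f"stage composition: {exc}") from exc
    outputs["table1"] = out / "table1.tsv"
    composition.write_composition_table(summaries, outputs["table1"])

    # --- stage: codon counts, pooled RSCU, Nc-plot data --------------------
    count_tables = [composition.count_codons(r) for r in regions]
    pooled = codon_stats.pooled_counts(count_tables)
    pooled_rscu = codon_stats.rscu(pooled)

    host = None
    if config.host_table is not None:
        host = sequence_io.parse_host_codon_table(config.host_table)
    outputs["table2"] = out / "table2.tsv"
    codon_stats.write_rscu_table(pooled_rscu, outputs["table2"], host=host)

    outputs["ncplot"] = out / "ncplot.tsv"
    with open(outputs["ncplot"], "w") as fh:
        fh.write("isolate\tgc3s\tnc\texpected_nc\n")
        for s in summaries:
            fh.write(
                f"{s.isolate_id}\t{s.gc3:.4f}\t{s.nc:.4f}\t"
                f"{codon_stats.expected_enc(s.gc3 / 100.0):.4f}\n"
            )

    # --- stage: correspondence analysis + axis correlations ----------------
    try:
        matrix = multivariate.rscu_matrix(
            [codon_stats.rscu(t) for t in count_tables],
            labels=[r.isolate_id for r in regions],
        )
        coa_result = multivariate.coa(matrix)
        correlations = multivariate.axis_composition_correlations(coa_result, summaries)
    except ValueError as exc:
        raise PipelineError(f"stage multivariate: {exc}") from exc
    outputs["coa_coords"] = out / "coa_coords.tsv"
    coords = coa_result.row_coords.copy()
    coords.insert(0, "inertia_axis1", coa_result.inertia_fraction[0])
    coords.insert(1, "inertia_axis2", coa_result.inertia_fraction[1])
    coords.to_csv(outputs["coa_coords"], sep="\t", float_format="%.6f")
    outputs["table3"] = out / "table3.tsv"
    multivariate.write_correlation_grid(correlations, outputs["table3"])

    # --- stage: virus-host correlation --------------------------------------
    host_corr = None
    if host is not None:
        host_corr = multivariate.virus_host_correlation(
            pooled, host, scale=config.correlation_scale
        )
        outputs["host_correlation"] = out / "host_correlation.tsv"
        with open(outputs["host_correlation"], "w") as fh:
            fh.write("method\tscale\tcoefficient\tp_value\tn\n")
            for res in (host_corr.pearson, host_corr.spearman):
                fh.write(
                    f"{res.method}\t{host_corr.scale}\t{res.coefficient:.4f}\t"
                    f"{res.p_value:.3g}\t{res.n}\n"
                )

    # --- stage: phylogeny ----------------------------------------------------
    tree_newick = None
    if config.alignment is not None:
        alignment = phylogeny.read_alignment_fasta(config.alignment)
    elif len({r.length_nt for r in regions}) == 1:
        # equal-length regions (e.g. a simulated cohort) act as the alignment
        alignment = {r.isolate_id: r.concatenated for r in regions}
    else:
        alignment = None
        logger.warning(
            "stage phylogeny skipped: no alignment given and coding regions "
            "differ in length"
        )
    if alignment is not None:
        try:
            tree = phylogeny.bootstrap_support(
                alignment,
                replicates=config.bootstrap_replicates,
                seed=config.seed,
                distance=config.distance,
            )
        except phylogeny.PhylogenyError as exc:
            raise PipelineError(f"stage phylogeny: {exc}") from exc
        tree_newick = phylogeny.write_newick(tree)
        outputs["tree"] = out / "tree.nwk"
        outputs["tree"].write_text(tree_newick + "\n")

    return ReportBundle(
        summaries=summaries,
        pooled_rscu=pooled_rscu,
        coa=coa_result,
        correlations=correlations,
        host_correlation=host_corr,
        tree_newick=tree_newick,
        outputs=outputs,
    )
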