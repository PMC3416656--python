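"""Correspondence analysis of codon-usage variation and the correlation
machinery: axis-composition Spearman grids and virus-host codon-frequency
correlations.

The correspondence analysis (CA) is the classic chi-square decomposition:
with P the table normalized to sum 1, row masses r and column masses c,
the standardized residual matrix

    S = D_r^{-1/2} (P - r c^T) D_c^{-1/2}

is decomposed by SVD; principal coordinates scale singular vectors by the
singular values, and each axis explains a fraction sigma_i^2 / sum sigma^2
of the total inertia (= chi-square statistic / grand total). Axis signs are
arbitrary; here each axis is oriented so its largest-|loading| column
(codon) loads positively, which makes runs reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .codon_stats import RSCUTable
from .composition import CodonCountTable, CompositionSummary
from .genetic_code import INFORMATIVE_CODONS
from .sequence_io import HostCodonUsage


class MultivariateError(ValueError):
    pass


@dataclass
class COAResult:
    row_coords: pd.DataFrame          # isolates x axes, principal coordinates
    col_coords: pd.DataFrame          # codons x axes
    inertia_fraction: np.ndarray      # per-axis share of total inertia
    total_inertia: float
    degenerate: bool = False          # True when total inertia ~ 0

    @property
    def n_axes(self) -> int:
        return self.row_coords.shape[1]


def rscu_matrix(
    tables: Sequence[RSCUTable], labels: Sequence[str] | None = None
) -> pd.DataFrame:
    """Stack RSCU tables into an isolates x 59 matrix.

    Missing families (zero counts) are imputed with the family-neutral
    value 1.0 so columns stay aligned across isolates.
    """
    if labels is None:
        labels = [t.counts.source_id or f"isolate_{i}" for i, t in enumerate(tables)]
    rows = [t.vector(impute=1.0) for t in tables]
    return pd.DataFrame(rows, index=list(labels), columns=list(INFORMATIVE_CODONS))


def coa(matrix: pd.DataFrame | np.ndarray, n_axes: int | None = None) -> COAResult:
    """Correspondence analysis of a non-negative table (rows = isolates)."""
    if isinstance(matrix, pd.DataFrame):
        X = matrix.to_numpy(dtype=float)
        row_labels = list(matrix.index)
        col_labels = list(matrix.columns)
    else:
        X = np.asarray(matrix, dtype=float)
        row_labels = [f"row{i}" for i in range(X.shape[0])]
        col_labels = [f"col{j}" for j in range(X.shape[1])]
    if X.ndim != 2 or X.shape[0] < 3:
        raise MultivariateError("CA needs a 2-D table with at least 3 rows")
    if np.any(X < 0):
        raise MultivariateError("CA input must be non-negative")
    if np.any(X.sum(axis=1) == 0) or np.any(X.sum(axis=0) == 0):
        raise MultivariateError("CA input has an all-zero row or column")

    grand = X.sum()
    P = X / grand
    r = P.sum(axis=1)
    c = P.sum(axis=0)
    S = (P - np.outer(r, c)) / np.sqrt(np.outer(r, c))
    U, sv, Vt = np.linalg.svd(S, full_matrices=False)

    max_axes = min(X.shape) - 1
    sv = sv[:max_axes]
    U = U[:, :max_axes]
    Vt = Vt[:max_axes]
    total_inertia = float(np.sum(sv**2))

    if n_axes is not None:
        max_axes = min(n_axes, max_axes)
        sv, U, Vt = sv[:max_axes], U[:, :max_axes], Vt[:max_axes]

    if total_inertia < 1e-12 * max(1.0, float(np.mean(X))):
        zeros_r = np.zeros((X.shape[0], max_axes))
        zeros_c = np.zeros((X.shape[1], max_axes))
        axes = [f"Axis{i+1}" for i in range(max_axes)]
        return COAResult(
            row_coords=pd.DataFrame(zeros_r, index=row_labels, columns=axes),
            col_coords=pd.DataFrame(zeros_c, index=col_labels, columns=axes),
            inertia_fraction=np.zeros(max_axes),
            total_inertia=0.0,
            degenerate=True,
        )

    F = (U * sv) / np.sqrt(r)[:, None]        # row principal coordinates
    G = (Vt.T * sv) / np.sqrt(c)[:, None]     # column principal coordinates

    # deterministic sign: largest-|loading| codon positive on each axis
    for j in range(F.shape[1]):
        lead = np.argmax(np.abs(G[:, j]))
        if G[lead, j] < 0:
            F[:, j] *= -1.0
            G[:, j] *= -1.0

    axes = [f"Axis{i+1}" for i in range(F.shape[1])]
    return COAResult(
        row_coords=pd.DataFrame(F, index=row_labels, columns=axes),
        col_coords=pd.DataFrame(G, index=col_labels, columns=axes),
        inertia_fraction=sv**2 / total_inertia,
        total_inertia=total_inertia,
    )


@dataclass(frozen=True)
class CorrelationResult:
    coefficient: float
    p_value: float
    method: Literal["spearman", "pearson"]
    n: int

    @property
    def stars(self) -> str:
        """Significance stars: * for p<0.05, ** for p<0.01 (two-sided)."""
        if self.p_value < 0.01:
            return "**"
        if self.p_value < 0.05:
            return "*"
        return ""


def _check_xy(x, y) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise MultivariateError("x and y must be 1-D vectors of equal length")
    if x.size < 3:
        raise MultivariateError("need at least 3 points")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise MultivariateError("correlation undefined for a constant vector")
    return x, y


def spearman_correlation(x, y) -> CorrelationResult:
    """Spearman rank correlation (average ranks for ties; two-sided
    t-approximation p-value)."""
    x, y = _check_xy(x, y)
    rho, p = stats.spearmanr(x, y)
    return CorrelationResult(float(rho), float(p), "spearman", x.size)


def pearson_correlation(x, y) -> CorrelationResult:
    x, y = _check_xy(x, y)
    r, p = stats.pearsonr(x, y)
    return CorrelationResult(float(r), float(p), "pearson", x.size)


_COMPOSITION_VARS = ("A3", "U3", "G3", "C3")


def axis_composition_correlations(
    coa_result: COAResult,
    summaries: Sequence[CompositionSummary],
    axes: Sequence[str] = ("Axis1", "Axis2"),
) -> pd.DataFrame:
    """Spearman correlations of A3/U3/G3/C3 against the leading CA axes.

    Returns a tidy frame with coefficient, p-value and significance stars
    (the published grid's layout: one row per composition variable).
    """
    if len(summaries) != coa_result.row_coords.shape[0]:
        raise MultivariateError(
            f"{len(summaries)} summaries for {coa_result.row_coords.shape[0]} CA rows"
        )
    comp = {
        "A3": [s.a3 for s in summaries],
        "U3": [s.u3 for s in summaries],
        "G3": [s.g3 for s in summaries],
        "C3": [s.c3 for s in summaries],
    }
    records = []
    for var in _COMPOSITION_VARS:
        rec: dict[str, object] = {"variable": var}
        for axis in axes:
            res = spearman_correlation(comp[var], coa_result.row_coords[axis].to_numpy())
            rec[f"{axis}_rho"] = res.coefficient
            rec[f"{axis}_p"] = res.p_value
            rec[f"{axis}_stars"] = res.stars
        records.append(rec)
    return pd.DataFrame.from_records(records).set_index("variable")


@dataclass(frozen=True)
class VirusHostCorrelation:
    """Virus-host codon-usage correlation, both coefficient types."""

    pearson: CorrelationResult
    spearman: CorrelationResult
    scale: Literal["frequency", "rscu"]
    codons: tuple[str, ...]


def virus_host_correlation(
    virus_counts: CodonCountTable,
    host: HostCodonUsage,
    scale: Literal["frequency", "rscu"] = "frequency",
) -> VirusHostCorrelation:
    """Correlate virus and host codon usage over the 59 informative codons.

    ``scale='frequency'`` compares per-1000-codon frequencies (codon
    abundances); ``scale='rscu'`` compares within-family relative usage.
    Both Pearson and Spearman results are reported.
    """
    if scale not in ("frequency", "rscu"):
        raise MultivariateError(f"unknown scale {scale!r}")
    total = virus_counts.total_codons
    if total == 0:
        raise MultivariateError("virus count table is empty")
    if scale == "frequency":
        vx = [1000.0 * virus_counts.counts[c] / total for c in INFORMATIVE_CODONS]
        hy = [host.frequency(c) for c in INFORMATIVE_CODONS]
    else:
        from .codon_stats import rscu as _rscu

        vtab = _rscu(virus_counts).vector(impute=1.0)
        vx = [vtab[c] for c in INFORMATIVE_CODONS]
        missing = [c for c in INFORMATIVE_CODONS if c not in host.rscu]
        if missing:
            raise MultivariateError(f"host table lacks RSCU for: {missing}")
        hy = [host.rscu[c] for c in INFORMATIVE_CODONS]
    return VirusHostCorrelation(
        pearson=pearson_correlation(vx, hy),
        spearman=spearman_correlation(vx, hy),
        scale=scale,
        codons=INFORMATIVE_CODONS,
    )


def write_correlation_grid(grid: pd.DataFrame, path: str | Path) -> None:
    grid.to_csv(path, sep="\t", float_format="%.4f")
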