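"""Motif-conditioned differential gene expression.

For each (motif, position, cell type, gene) case we ask whether the cells of
that type occupying that motif position express the gene differently from all
cells of the same type.  The statistic is the *delta median*: the median
expression within the motif subset minus the median over all cells of the
type.  Its significance is an exact urn-model tail probability: under random
selection of an equally sized subset, the chance that at least a majority of
the subset lies above the observed offset follows a hypergeometric tail.

Expression values are used raw (no normalization), matching how count-based
spatial panels are typically compared within one cell type.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import hypergeom


@dataclass
class DeltaMedianCase:
    motif_rank: int
    position: int  # 1..W
    cell_type: int
    gene: str
    N_A: int  # cells of this type overall
    N_AM: int  # cells of this type at this motif position
    x0: float  # delta median (motif median - overall median)
    N_H: int  # cells with delta expression above x0
    N_L: int  # cells with delta expression at or below x0
    N_0: int  # majority threshold floor(N_AM/2 + 1)
    log_p: float  # log10 upper-tail probability (mirrored for x0 < 0)

    @property
    def signed_log_p(self) -> float:
        """|log10 p| signed by the direction of the shift (+ up, - down)."""
        s = 1.0 if self.x0 >= 0 else -1.0
        return -s * self.log_p

    @property
    def address(self) -> str:
        return f"{self.motif_rank}-{self.position}-{self.cell_type}"


def delta_median(expr_motif: np.ndarray, expr_all: np.ndarray) -> float:
    """Median expression in the motif subset minus the median over all cells
    of the type."""
    expr_motif = np.asarray(expr_motif, dtype=float)
    expr_all = np.asarray(expr_all, dtype=float)
    if expr_motif.size == 0:
        raise ValueError("motif subset is empty")
    if expr_all.size == 0:
        raise ValueError("cell-type population is empty")
    return float(np.median(expr_motif) - np.median(expr_all))


def dmedian_log_pvalue(
    N_A: int, N_AM: int, N_H: int, N_L: int, x0: float = 1.0, log_base: float = 10.0
) -> float:
    """Exact log p-value of a delta-median shift.

    p0 = sum_{k=N0}^{N_AM} C(N_H, k) C(N_L, N_AM - k) / C(N_A, N_AM) with
    N0 = floor(N_AM / 2 + 1): the probability that a random subset of size
    N_AM contains at least a majority of cells whose delta expression exceeds
    x0.  For a negative shift (x0 < 0) the mirrored lower tail is used: at
    most N_AM - N0 subset cells above x0.
    """
    if N_AM > N_A:
        raise ValueError("subset size N_AM cannot exceed population size N_A")
    if min(N_A, N_AM, N_H, N_L) < 0 or N_H + N_L > N_A:
        raise ValueError("inconsistent counts")
    N0 = math.floor(N_AM / 2 + 1)
    dist = hypergeom(N_H + N_L, N_H, N_AM)
    if x0 >= 0:
        logp = dist.logsf(N0 - 1)
    else:
        logp = dist.logcdf(N_AM - N0)
    return float(logp / math.log(log_base))


def overlap_log_pvalue(k: int, universe: int, n1: int, n2: int,
                       log_base: float = 10.0) -> float:
    """Upper-tail hypergeometric probability of an overlap of at least ``k``
    between two gene sets of sizes ``n1`` and ``n2`` drawn from a universe —
    the standard enrichment check for, e.g., differential-gene lists against
    an external axis-patterning list."""
    if k < 0 or min(universe, n1, n2) < 0 or max(n1, n2) > universe:
        raise ValueError("inconsistent set sizes")
    return float(hypergeom(universe, n1, n2).logsf(k - 1) / math.log(log_base))


def _case_for_subset(
    delta_all: np.ndarray, in_motif: np.ndarray
) -> tuple[float, int, int, int]:
    """(x0, N_H, N_L, N_0) for one subset given per-cell delta expression.

    Cells whose delta expression equals x0 exactly are counted in N_L (ties
    are common in count data; the convention is applied consistently).
    """
    x0 = float(np.median(delta_all[in_motif]))
    N_H = int(np.sum(delta_all > x0))
    N_L = int(len(delta_all) - N_H)
    N_0 = math.floor(int(in_motif.sum()) / 2 + 1)
    return x0, N_H, N_L, N_0


def analyze_motif_expression(
    motifs,
    expression: np.ndarray,
    gene_names: list[str],
    cell_types: np.ndarray,
    cells_by_motif_position: dict | None = None,
    min_cells: int = 3,
    random_control_seed: int | None = None,
    log_base: float = 10.0,
) -> list[DeltaMedianCase]:
    """One delta-median case per (motif, position, cell type, gene).

    Parameters
    ----------
    motifs : list of MotifResult (or any objects with ``rank``).
    expression : (n_cells, n_genes) matrix, raw counts.
    cell_types : (n_cells,) integer codes.
    cells_by_motif_position : mapping (rank, position) -> cell index array.
        Built by the pipeline from each motif's accepted occurrences; required
        here so this module stays independent of graph bookkeeping.
    min_cells : minimum N_AM for a case to be reported.
    random_control_seed : if given, each case is computed on a random subset
        of matched size and type instead of the motif cells (the matched
        null used to sanity-check the statistic).
    """
    if cells_by_motif_position is None:
        raise ValueError("cells_by_motif_position mapping is required")
    expression = np.asarray(expression)
    cell_types = np.asarray(cell_types)
    rng = np.random.default_rng(random_control_seed) if random_control_seed is not None else None
    cases: list[DeltaMedianCase] = []
    for motif in motifs:
        rank = motif.rank if hasattr(motif, "rank") else int(motif)
        for (r, pos), cell_idx in cells_by_motif_position.items():
            if r != rank:
                continue
            cell_idx = np.asarray(cell_idx)
            for ct in np.unique(cell_types[cell_idx]):
                if ct == 0:
                    continue
                sub = cell_idx[cell_types[cell_idx] == ct]
                all_idx = np.flatnonzero(cell_types == ct)
                if len(sub) < min_cells:
                    continue
                if rng is not None:
                    sub = rng.choice(all_idx, size=len(sub), replace=False)
                in_motif = np.isin(all_idx, sub)
                for gi, gene in enumerate(gene_names):
                    expr_all = expression[all_idx, gi].astype(float)
                    if not np.isfinite(expr_all).all():
                        warnings.warn(f"missing expression for gene {gene}; case skipped")
                        continue
                    delta_all = expr_all - np.median(expr_all)
                    x0, N_H, N_L, N_0 = _case_for_subset(delta_all, in_motif)
                    logp = dmedian_log_pvalue(
                        len(all_idx), len(sub), N_H, N_L, x0, log_base
                    )
                    cases.append(DeltaMedianCase(
                        motif_rank=rank, position=pos, cell_type=int(ct), gene=gene,
                        N_A=len(all_idx), N_AM=len(sub), x0=x0,
                        N_H=N_H, N_L=N_L, N_0=N_0, log_p=logp,
                    ))
    return cases


def cases_to_frame(cases: list[DeltaMedianCase], bh_column: bool = True) -> pd.DataFrame:
    """Tabular report; the BH-adjusted column is a labeled extension beyond
    the raw |log p| scale used for ranking."""
    df = pd.DataFrame([
        {
            "motif": c.motif_rank, "position": c.position, "cell_type": c.cell_type,
            "gene": c.gene, "N_A": c.N_A, "N_AM": c.N_AM,
            "delta_median": c.x0, "log10_p": c.log_p,
            "signed_log10_p": c.signed_log_p, "case": c.address,
        }
        for c in cases
    ])
    if bh_column and len(df):
        p = np.power(10.0, df["log10_p"].to_numpy())
        n = len(p)
        order = np.argsort(p)
        ranked = p[order] * n / (np.arange(n) + 1)
        adj = np.minimum.accumulate(ranked[::-1])[::-1]
        out = np.empty(n)
        out[order] = np.clip(adj, 0, 1)
        df["bh_adjusted_p_extension"] = out
    return df
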