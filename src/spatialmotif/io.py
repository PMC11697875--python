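"""Readers and writers: cell tables, expression sidecars, motif reports,
MEME minimal motif format.

Readers validate rather than guess: missing required columns raise with the
column named.  All emitted node indices are 0-based.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .discovery import PWM, MotifResult
from .graph import CellMap

_SYMBOLS = "ABCDEFGHIJKLMNOPQRSTUVWXYZabcdefghijklmnopqrstuvwxyz0123456789"

REQUIRED_COLUMNS = ("x", "y", "cell_type", "section")


def read_cell_table(
    path,
    expression_path=None,
    gene_prefix: str = "gene_",
) -> CellMap:
    """Read a per-cell CSV/TSV with columns x, y[, z], cell_type, section.

    Cell-type labels may be strings; they are mapped to contiguous integer
    codes 1..L in sorted-name order, with the code->name table kept on the
    returned :class:`CellMap`.  Expression may come from columns named
    ``gene_*`` or from a sidecar (dense CSV cells x genes with a header row,
    or MatrixMarket .mtx plus ``<stem>.genes.txt``).
    """
    path = Path(path)
    sep = "\t" if path.suffix in (".tsv", ".txt") else ","
    df = pd.read_csv(path, sep=sep)
    for col in REQUIRED_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"input table is missing required column {col!r}")
    dims = ["x", "y"] + (["z"] if "z" in df.columns else [])
    positions = df[dims].to_numpy(dtype=float)

    raw = df["cell_type"]
    # numeric names sort numerically so integer-coded inputs keep their codes
    names = sorted(raw.astype(str).unique(),
                   key=lambda s: (0, int(s)) if s.isdigit() else (1, s))
    code_of = {name: i + 1 for i, name in enumerate(names)}
    codes = raw.astype(str).map(code_of).to_numpy(dtype=np.int32)
    type_names = {v: k for k, v in code_of.items()}

    expression = None
    gene_names = None
    gene_cols = [c for c in df.columns if c.startswith(gene_prefix)]
    if gene_cols:
        expression = df[gene_cols].to_numpy(dtype=float)
        gene_names = [c[len(gene_prefix):] for c in gene_cols]
    if expression_path is not None:
        ep = Path(expression_path)
        if ep.suffix == ".mtx":
            from scipy.io import mmread

            expression = np.asarray(mmread(ep).todense(), dtype=float)
            genes_file = ep.with_suffix(".genes.txt")
            gene_names = genes_file.read_text().split()
        else:
            edf = pd.read_csv(ep)
            expression = edf.to_numpy(dtype=float)
            gene_names = list(edf.columns)
        if expression.shape[0] != len(df):
            raise ValueError(
                f"expression matrix has {expression.shape[0]} rows but the cell "
                f"table has {len(df)}"
            )
    return CellMap(
        positions=positions,
        cell_types=codes,
        sections=df["section"].to_numpy(),
        type_names=type_names,
        expression=expression,
        gene_names=gene_names,
    )


def from_anndata(adata, spatial_key: str = "spatial", type_key: str = "cell_type",
                 section_key: str = "section") -> CellMap:
    """Build a CellMap from an AnnData container (coordinates in
    ``obsm[spatial_key]``, labels and section in ``obs``)."""
    for key, where in ((type_key, adata.obs), (section_key, adata.obs)):
        if key not in where:
            raise ValueError(f"AnnData is missing obs column {key!r}")
    if spatial_key not in adata.obsm:
        raise ValueError(f"AnnData is missing obsm slot {spatial_key!r}")
    raw = adata.obs[type_key].astype(str)
    names = sorted(raw.unique())
    code_of = {name: i + 1 for i, name in enumerate(names)}
    X = adata.X
    if hasattr(X, "toarray"):
        X = X.toarray()
    return CellMap(
        positions=np.asarray(adata.obsm[spatial_key], dtype=float),
        cell_types=raw.map(code_of).to_numpy(dtype=np.int32),
        sections=adata.obs[section_key].to_numpy(),
        type_names={v: k for k, v in code_of.items()},
        expression=np.asarray(X, dtype=float) if X is not None else None,
        gene_names=list(adata.var_names) if adata.var_names is not None else None,
    )


# ---------------------------------------------------------------------------
# motif reports
# ---------------------------------------------------------------------------

def _word_str(word, type_names=None) -> str:
    if type_names:
        return "|".join(type_names.get(int(s), str(s)) for s in word)
    return "-".join(str(int(s)) for s in word)


def write_motif_report(motifs: list[MotifResult], tsv_path, json_path=None,
                       type_names: dict | None = None) -> None:
    rows = [
        {
            "rank": m.rank,
            "consensus": _word_str(m.consensus, type_names),
            "log10_p_train": m.log_p_train,
            "log10_p_score": m.log_p_score,
            "n_members": len(m.members),
            "n_occurrences": m.n_sites,
            "score_threshold": m.score_threshold,
        }
        for m in motifs
    ]
    pd.DataFrame(rows).to_csv(tsv_path, sep="\t", index=False)
    if json_path is not None:
        payload = [
            {
                "rank": m.rank,
                "consensus": list(m.consensus),
                "log10_p_train": m.log_p_train,
                "log10_p_score": m.log_p_score,
                "pwm": m.pwm.matrix.tolist(),
                "background": m.pwm.background.tolist(),
                "members": [
                    {"word": list(s.word), "Z": s.Z, "N": s.N, "P": s.P}
                    for s in m.members
                ],
                "occupied_nodes": {
                    str(sec): [int(v) for v in nodes]
                    for sec, nodes in m.occupied_nodes.items()
                },
            }
            for m in motifs
        ]
        Path(json_path).write_text(json.dumps(payload, indent=1))


# ---------------------------------------------------------------------------
# MEME minimal motif format
# ---------------------------------------------------------------------------

def write_meme_minimal(pwms: list[PWM], path, names: list[str] | None = None,
                       symbols: str | None = None) -> None:
    """Write PWMs in MEME minimal motif format.

    Cell-type codes 1..L map onto single-character symbols (A, B, C, ... by
    default; pass ``symbols`` to choose, e.g. "ACGT" for interoperability
    with nucleotide motif tools when L = 4).  For L beyond the 62 available
    characters a numbered symbol table is written in a header comment and
    codes are used as-is.
    """
    if not pwms:
        raise ValueError("no PWMs to write")
    L = pwms[0].L
    if any(p.L != L for p in pwms):
        raise ValueError("all PWMs must share one alphabet size")
    if symbols is not None and len(symbols) != L:
        raise ValueError("symbols must provide one character per cell type")
    lines = ["MEME version 4", ""]
    if L <= len(_SYMBOLS):
        alpha = symbols if symbols is not None else _SYMBOLS[:L]
        lines += [f"ALPHABET= {alpha}", ""]
    else:
        alpha = None
        lines += ["# symbol table: type_<i> for cell type code i (alphabet exceeds "
                  "single characters)", f"ALPHABET= type_1..type_{L}", ""]
    b = pwms[0].background
    lines.append("Background letter frequencies")
    if alpha:
        lines.append(" ".join(f"{alpha[i]} {b[i]:.6f}" for i in range(L)))
    else:
        lines.append(" ".join(f"type_{i + 1} {b[i]:.6f}" for i in range(L)))
    lines.append("")
    for i, pwm in enumerate(pwms):
        name = names[i] if names else f"motif_{i + 1}"
        lines.append(f"MOTIF {name}")
        lines.append(
            f"letter-probability matrix: alength= {L} w= {pwm.W} nsites= 20 E= 0"
        )
        for j in range(pwm.W):  # MEME rows are positions
            lines.append(" " + " ".join(f"{pwm.matrix[i_, j]:.9f}" for i_ in range(L)))
        lines.append("")
    Path(path).write_text("\n".join(lines))


def read_meme_minimal(path) -> list[PWM]:
    """Parse a MEME minimal motif file back into PWMs."""
    text = Path(path).read_text().splitlines()
    background = None
    pwms = []
    i = 0
    while i < len(text):
        line = text[i].strip()
        if line.startswith("Background letter frequencies"):
            toks = text[i + 1].split()
            background = np.array([float(t) for t in toks[1::2]])
            i += 2
            continue
        if line.startswith("letter-probability matrix"):
            parts = dict(zip(line.split()[2::2], line.split()[3::2]))
            w = int(parts["w="]) if "w=" in parts else int(line.split("w=")[1].split()[0])
            rows = []
            for j in range(w):
                rows.append([float(x) for x in text[i + 1 + j].split()])
            M = np.array(rows).T  # back to L x W
            b = background if background is not None else np.full(M.shape[0], 1 / M.shape[0])
            pwms.append(PWM(M / M.sum(axis=0, keepdims=True), b))
            i += 1 + w
            continue
        i += 1
    return pwms
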