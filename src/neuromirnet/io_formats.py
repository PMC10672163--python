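"""Readers and writers for every external format the pipeline touches.

TSV is the canonical interchange format; MatrixMarket (MTX) count matrices
are supported read-only with row/column label sidecars. TargetScan
context++ score tables may be gzip-compressed. Parsers never silently
coerce: every dropped or modified row is counted and logged.
"""

from __future__ import annotations

import gzip
import logging
import os
from pathlib import Path

import numpy as np
import pandas as pd
import networkx as nx
import scipy.io
from Bio import SeqIO

from .types import (
    CountMatrix,
    GeneSet,
    NetworkEdge,
    SampleSheet,
    TargetPrediction,
    ValidationError,
)

logger = logging.getLogger(__name__)

__all__ = [
    "read_count_matrix",
    "write_count_matrix",
    "read_sample_sheet",
    "write_sample_sheet",
    "read_targetscan_table",
    "read_gmt",
    "write_gmt",
    "read_fasta",
    "write_fasta",
    "write_network",
    "read_edgelist",
]


class FormatError(ValueError):
    """A file does not conform to its declared format."""


# ---------------------------------------------------------------------------
# count matrices


def read_count_matrix(
    path: str | os.PathLike, format: str = "tsv"
) -> CountMatrix | tuple[CountMatrix, SampleSheet]:
    """Read a feature-by-sample count matrix (features in rows).

    ``format="tsv"`` expects a header row of sample identifiers and the
    feature identifier in the first column. ``format="mtx"`` expects a
    MatrixMarket triplet file with ``<stem>.rows.txt`` / ``<stem>.cols.txt``
    label sidecars. If a ``<stem>.samples.tsv`` sidecar sample sheet exists,
    the pair (matrix, sheet) is returned.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "tsv":
        df = pd.read_csv(path, sep="\t", index_col=0)
        matrix = _frame_to_matrix(df)
    elif format == "mtx":
        mat = scipy.io.mmread(path)
        stem = path.with_suffix("")
        rows = _read_lines(Path(f"{stem}.rows.txt"))
        cols = _read_lines(Path(f"{stem}.cols.txt"))
        dense = np.asarray(mat.todense() if hasattr(mat, "todense") else mat)
        matrix = _frame_to_matrix(pd.DataFrame(dense, index=rows, columns=cols))
    else:
        raise ValueError(f"unknown count-matrix format {format!r}")
    sidecar = path.parent / f"{path.stem.split('.')[0]}.samples.tsv"
    if sidecar.exists() and sidecar != path:
        return matrix, read_sample_sheet(sidecar)
    return matrix


def _frame_to_matrix(df: pd.DataFrame) -> CountMatrix:
    values = df.to_numpy()
    if values.dtype == object or not np.issubdtype(values.dtype, np.number):
        raise FormatError("count matrix contains non-numeric cells")
    if not np.issubdtype(values.dtype, np.integer):
        frac = values != np.floor(values)
        if frac.any():
            i, j = np.argwhere(frac)[0]
            raise FormatError(
                f"non-integer count {values[i, j]} at feature {df.index[i]!r}, "
                f"sample {df.columns[j]!r}"
            )
    try:
        return CountMatrix.from_frame(df)
    except ValidationError as exc:
        raise FormatError(str(exc)) from exc


def _read_lines(path: Path) -> list[str]:
    if not path.exists():
        raise FileNotFoundError(f"MTX label sidecar missing: {path}")
    return [ln.strip() for ln in path.read_text().splitlines() if ln.strip()]


def write_count_matrix(matrix: CountMatrix, path: str | os.PathLike) -> None:
    matrix.to_frame().to_csv(path, sep="\t", index_label="feature_id")


def read_sample_sheet(path: str | os.PathLike) -> SampleSheet:
    return SampleSheet(pd.read_csv(path, sep="\t"))


def write_sample_sheet(sheet: SampleSheet, path: str | os.PathLike) -> None:
    sheet.table.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# TargetScan predictions

_SIMPLE_COLUMNS = ["mirna_family", "gene_id", "transcript_id", "cwcs", "conserved_sites"]


def read_targetscan_table(
    path: str | os.PathLike, dialect: str = "targetscan8"
) -> list[TargetPrediction]:
    """Read a TargetScan-style prediction table into TargetPrediction records.

    ``targetscan8`` accepts the tab-separated context++ scores layout
    (gzip allowed); the CWCS column is matched by case-insensitive name
    containing "context++" or "cwcs". ``simple`` expects the five named
    columns of TargetPrediction. Rows with an empty CWCS are dropped with a
    logged count; per-transcript granularity is preserved.
    """
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as fh:
        df = pd.read_csv(fh, sep="\t", dtype=str)
    if dialect == "simple":
        missing = [c for c in _SIMPLE_COLUMNS if c not in df.columns]
        if missing:
            raise FormatError(
                f"simple dialect missing columns {missing}; expected {_SIMPLE_COLUMNS}"
            )
        cols = dict(zip(_SIMPLE_COLUMNS, _SIMPLE_COLUMNS))
    elif dialect == "targetscan8":
        cols = _match_targetscan_columns(df.columns)
    else:
        raise ValueError(f"unknown TargetScan dialect {dialect!r}")

    cwcs_raw = pd.to_numeric(df[cols["cwcs"]], errors="coerce")
    dropped = int(cwcs_raw.isna().sum())
    if dropped:
        logger.info("read_targetscan_table: dropped %d rows with empty CWCS", dropped)
    keep = df[cwcs_raw.notna()]
    cwcs = cwcs_raw[cwcs_raw.notna()]
    sites_col = cols.get("conserved_sites")
    if sites_col is not None:
        sites = pd.to_numeric(keep[sites_col], errors="coerce").fillna(0).astype(int)
    else:
        sites = pd.Series(0, index=keep.index)
    tx_col = cols.get("transcript_id")
    out = []
    for idx, row in keep.iterrows():
        out.append(
            TargetPrediction(
                mirna_family=str(row[cols["mirna_family"]]),
                gene_id=str(row[cols["gene_id"]]),
                transcript_id=str(row[tx_col]) if tx_col else None,
                cwcs=float(cwcs.loc[idx]),
                conserved_sites=int(sites.loc[idx]),
            )
        )
    return out


def _match_targetscan_columns(columns) -> dict[str, str]:
    """Map TargetScan context++ header names onto TargetPrediction fields."""
    lower = {c.lower(): c for c in columns}

    def find(*needles, required=True):
        for low, orig in lower.items():
            if any(n in low for n in needles):
                return orig
        if required:
            raise FormatError(
                f"TargetScan table missing a column matching {needles}; "
                f"saw columns {list(columns)}"
            )
        return None

    cwcs = find("context++", "cwcs")
    family = find("mirna", "mir family", "family")
    gene = find("gene symbol", "gene id", "gene")
    transcript = find("transcript", required=False)
    sites = find("conserved sites", "conserved_sites", "number of sites", required=False)
    out = {"cwcs": cwcs, "mirna_family": family, "gene_id": gene}
    if transcript:
        out["transcript_id"] = transcript
    if sites:
        out["conserved_sites"] = sites
    return out


# ---------------------------------------------------------------------------
# GMT gene sets


def read_gmt(path: str | os.PathLike) -> list[GeneSet]:
    """Parse a GMT file: term, description, then >=1 gene per line.

    Duplicate genes within one line are de-duplicated; a line with fewer
    than three fields raises a parse error naming the line number.
    """
    sets = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"GMT line {lineno}: expected >=3 tab-separated fields")
            term_id, term_name, *genes = fields
            members = frozenset(g for g in genes if g)
            if not members:
                raise FormatError(f"GMT line {lineno}: no gene members")
            sets.append(GeneSet(term_id=term_id, term_name=term_name, members=members))
    return sets


def write_gmt(sets: list[GeneSet], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for gs in sets:
            fh.write("\t".join([gs.term_id, gs.term_name, *sorted(gs.members)]) + "\n")


# ---------------------------------------------------------------------------
# FASTA (3'UTR sequences)


def read_fasta(path: str | os.PathLike) -> dict[str, str]:
    """Read FASTA into an id -> sequence map (order-preserving)."""
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: dict[str, str], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")


# ---------------------------------------------------------------------------
# network export


def write_network(
    edges: list[NetworkEdge], path: str | os.PathLike, format: str = "edgelist_tsv"
) -> None:
    """Write the bipartite miRNA-mRNA network.

    The edge-list TSV has columns mirna, gene, cwcs, tier. GraphML output
    carries a ``kind`` node attribute (mirna/gene), a ``size`` attribute on
    gene nodes equal to max |CWCS| over incident edges (the display
    convention where node size reflects target confidence), and a ``cwcs``
    edge attribute. Output is byte-stable for a fixed input order.
    """
    if format == "edgelist_tsv":
        df = pd.DataFrame(
            [(e.mirna_id, e.gene_id, e.cwcs, e.tier) for e in edges],
            columns=["mirna", "gene", "cwcs", "tier"],
        )
        df.to_csv(path, sep="\t", index=False)
    elif format == "graphml":
        from .network import build_network

        graph = build_network(edges)
        nx.write_graphml(graph, path)
    else:
        raise ValueError(f"unknown network format {format!r}")


def read_edgelist(path: str | os.PathLike) -> list[NetworkEdge]:
    df = pd.read_csv(path, sep="\t", dtype={"mirna": str, "gene": str})
    return [
        NetworkEdge(
            mirna_id=row["mirna"], gene_id=row["gene"], cwcs=float(row["cwcs"]), tier=row["tier"]
        )
        for _, row in df.iterrows()
    ]
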