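"""Flat-text readers and writers shared across the pipeline.

Covers the edge-list TSV and SIF network dialects, FASTA (through Biopython),
and the three GSEA input formats: GCT (version line ``#1.2``), CLS
(three-line space-delimited phenotype labels) and GMT (one gene set per
line: name, description, tab-separated members).
"""

from __future__ import annotations

import os
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


class ParseError(ValueError):
    """Raised when a record cannot be parsed; carries the line number."""


# ---------------------------------------------------------------------------
# edge lists
# ---------------------------------------------------------------------------

def read_edge_tsv(path: str | os.PathLike) -> list[tuple[str, str]]:
    """Read a miRNA<TAB>target edge list, one edge per line."""
    edges: list[tuple[str, str]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ParseError(f"line {lineno}: expected at least 2 fields, got {len(fields)}")
            edges.append((fields[0], fields[1]))
    return edges


def write_edge_tsv(edges: Iterable[tuple[str, str]], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for m, t in edges:
            fh.write(f"{m}\t{t}\n")


def read_sif(path: str | os.PathLike) -> list[tuple[str, str]]:
    """Read a SIF file; ``source relation target1 target2 ...`` fans out to one
    edge per target.  Tab- and space-delimited records are both accepted."""
    edges: list[tuple[str, str]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) < 3:
                raise ParseError(f"line {lineno}: SIF record needs source, relation and >=1 target")
            src = fields[0]
            for tgt in fields[2:]:
                edges.append((src, tgt))
    return edges


def write_sif(edges: Iterable[tuple[str, str]], path: str | os.PathLike,
              relation: str = "regulates") -> None:
    """Write one SIF line per source, grouping its targets (insertion order kept)."""
    grouped: dict[str, list[str]] = {}
    for m, t in edges:
        grouped.setdefault(m, []).append(t)
    with open(path, "w") as fh:
        for src, tgts in grouped.items():
            fh.write("\t".join([src, relation, *tgts]) + "\n")


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | os.PathLike) -> list[SeqRecord]:
    return list(SeqIO.parse(str(path), "fasta"))


def write_fasta(records: Iterable[SeqRecord] | dict[str, str], path: str | os.PathLike) -> None:
    if isinstance(records, dict):
        records = [SeqRecord(Seq(s), id=name, description="") for name, s in records.items()]
    SeqIO.write(list(records), str(path), "fasta")


# ---------------------------------------------------------------------------
# GCT / CLS / GMT
# ---------------------------------------------------------------------------

def read_gct(path: str | os.PathLike) -> pd.DataFrame:
    """Read a GCT v1.2 expression matrix; returns genes x samples with the
    NAME column as index (Description column dropped)."""
    with open(path) as fh:
        version = fh.readline().strip()
        if version != "#1.2":
            raise ParseError(f"unsupported GCT version line {version!r}")
        dims = fh.readline().split()
        n_genes, n_samples = int(dims[0]), int(dims[1])
        df = pd.read_csv(fh, sep="\t", index_col=0)
    df = df.drop(columns=["Description"], errors="ignore")
    if df.shape != (n_genes, n_samples):
        raise ParseError(f"GCT header says {n_genes}x{n_samples}, table is {df.shape}")
    return df


def write_gct(df: pd.DataFrame, path: str | os.PathLike,
              descriptions: Sequence[str] | None = None) -> None:
    out = df.copy()
    out.insert(0, "Description", list(descriptions) if descriptions is not None else "na")
    with open(path, "w") as fh:
        fh.write("#1.2\n")
        fh.write(f"{df.shape[0]}\t{df.shape[1]}\n")
        out.to_csv(fh, sep="\t", index_label="NAME")


def read_cls(path: str | os.PathLike) -> tuple[list[str], list[str]]:
    """Read a categorical CLS file; returns (per-sample labels, class names)."""
    with open(path) as fh:
        header = fh.readline().split()
        n_samples, n_classes = int(header[0]), int(header[1])
        name_line = fh.readline().split()
        if not name_line or name_line[0] != "#":
            raise ParseError("CLS second line must start with '#'")
        class_names = name_line[1:]
        tokens = fh.readline().split()
    if len(class_names) != n_classes:
        raise ParseError("CLS class-name count disagrees with header")
    if len(tokens) != n_samples:
        raise ParseError("CLS label count disagrees with header")
    # labels may be given as names or 0-based indices
    labels = [class_names[int(t)] if t.isdigit() else t for t in tokens]
    return labels, class_names


def write_cls(labels: Sequence[str], path: str | os.PathLike) -> None:
    class_names = list(dict.fromkeys(labels))
    with open(path, "w") as fh:
        fh.write(f"{len(labels)} {len(class_names)} 1\n")
        fh.write("# " + " ".join(class_names) + "\n")
        fh.write(" ".join(labels) + "\n")


def read_gmt(path: str | os.PathLike) -> dict[str, tuple[str, list[str]]]:
    """Read a GMT file; returns {set name: (description, members)}."""
    sets: dict[str, tuple[str, list[str]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"line {lineno}: GMT record needs name, description, >=1 member")
            sets[fields[0]] = (fields[1], fields[2:])
    return sets


def write_gmt(sets: dict[str, tuple[str, Sequence[str]]], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for name, (desc, members) in sets.items():
            fh.write("\t".join([name, desc, *members]) + "\n")
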