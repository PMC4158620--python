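"""Readers and writers for the pipeline's plain-text formats.

Everything is tab-separated UTF-8 with no quoting.  Positions use 1-based
inclusive coordinates (unlike BED proper, which is 0-based half-open; a
reader flag converts).  Network files round-trip edge attributes at full
printed precision.
"""

from __future__ import annotations

import os

import networkx as nx
import numpy as np
import pandas as pd

from ccnet._util import canonical_pair, log
from ccnet.gpea import GeneSetCollection


class ParseError(ValueError):
    """Malformed input file; message carries the offending line number."""


# -- expression ---------------------------------------------------------------

def read_expression(path) -> pd.DataFrame:
    """Read a genes x samples TSV (header row of sample ids, first column ids).

    Duplicate gene rows are collapsed by the per-sample median (the standard
    summary when several probe sets map to one gene); rows with an empty
    identifier are dropped and logged.
    """
    try:
        frame = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise ParseError(f"{path}: {exc}") from exc
    frame.index = frame.index.astype(str).str.strip()
    blank = (frame.index == "") | (frame.index == "nan")
    if blank.any():
        log.warning("%s: dropped %d rows with empty gene ids", path, int(blank.sum()))
        frame = frame.loc[~blank]
    try:
        values = frame.astype(float)
    except ValueError as exc:
        for lineno, (_, row) in enumerate(frame.iterrows(), start=2):
            try:
                row.astype(float)
            except ValueError:
                raise ParseError(f"{path}: non-numeric value on line {lineno}") from exc
        raise ParseError(f"{path}: non-numeric value") from exc
    if not np.isfinite(values.to_numpy()).all():
        raise ParseError(f"{path}: non-finite expression values")
    if values.index.has_duplicates:
        n_dup = int(values.index.duplicated().sum())
        log.info("%s: collapsed %d duplicate gene rows by median", path, n_dup)
        values = values.groupby(level=0, sort=False).median()
    values.index.name = "gene"
    return values


def write_expression(expr: pd.DataFrame, path) -> None:
    expr.to_csv(path, sep="\t", index_label="gene")


# -- gene sets and lists -------------------------------------------------------

def read_gmt(path) -> GeneSetCollection:
    """Read a GMT file: term id, description, then tab-separated gene ids."""
    entries: dict[str, tuple[str, set[str]]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ParseError(f"{path}: line {lineno}: need term, description, genes")
            term, desc, genes = parts[0], parts[1], [g for g in parts[2:] if g]
            if term in entries:
                raise ParseError(f"{path}: line {lineno}: duplicate term {term!r}")
            if len(set(genes)) < len(genes):
                log.warning("%s: line %d: duplicate genes in %s de-duplicated", path, lineno, term)
            if not genes:
                raise ParseError(f"{path}: line {lineno}: term {term!r} has no genes")
            entries[term] = (desc, set(genes))
    if not entries:
        log.warning("%s: empty GMT file", path)
    return GeneSetCollection(entries)


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for term in sorted(collection):
            genes = "\t".join(sorted(collection.genes(term)))
            fh.write(f"{term}\t{collection.description(term)}\t{genes}\n")


def read_gene_list(path) -> set[str]:
    """One gene id per line; blank lines ignored."""
    with open(path, encoding="utf-8") as fh:
        genes = {line.strip() for line in fh if line.strip()}
    if not genes:
        log.warning("%s: empty gene list", path)
    return genes


def write_gene_list(genes, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for g in sorted(genes):
            fh.write(f"{g}\n")


# -- positions -----------------------------------------------------------------

def read_positions(path, zero_based: bool = False) -> pd.DataFrame:
    """Read a 4-column positions TSV: chrom, start, end, gene.

    Coordinates are 1-based inclusive by default; ``zero_based=True`` accepts
    BED-style 0-based half-open intervals and converts.
    """
    rows = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 4:
                raise ParseError(f"{path}: line {lineno}: expected 4 columns, got {len(parts)}")
            chrom, start_s, end_s, gene = parts
            try:
                start, end = int(start_s), int(end_s)
            except ValueError:
                raise ParseError(f"{path}: line {lineno}: non-integer coordinates") from None
            if zero_based:
                start += 1
            if start < 1 or start >= end:
                raise ParseError(f"{path}: line {lineno}: need 1 <= start < end")
            if gene in rows:
                raise ParseError(f"{path}: line {lineno}: duplicate gene {gene!r}")
            rows[gene] = (chrom, start, end)
    frame = pd.DataFrame.from_dict(rows, orient="index", columns=["chromosome", "start", "end"])
    frame.index.name = "gene"
    return frame.sort_index()


def write_positions(pos: pd.DataFrame, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for gene in sorted(pos.index):
            row = pos.loc[gene]
            fh.write(f"{row['chromosome']}\t{int(row['start'])}\t{int(row['end'])}\t{gene}\n")


# -- networks ------------------------------------------------------------------

_EDGE_COLUMNS = ["count", "ecr", "p_value", "p_adjusted"]


def _fmt(value) -> str:
    if isinstance(value, (int, np.integer)):
        return str(int(value))
    if isinstance(value, float):
        return repr(value)
    return str(value)


def write_network(net: nx.Graph, path, edge_stats: pd.DataFrame | None = None) -> None:
    """Write edges as TSV in canonical order with any known attributes.

    Columns: gene_a, gene_b, then count/ecr/p_value/p_adjusted where
    available (from edge attributes or the ``edge_stats`` frame).  Floats
    are repr-faithful so write -> read -> write is byte-identical.
    """
    def attrs_for(e):
        if edge_stats is not None and e in edge_stats.index:
            a = edge_stats.loc[e].to_dict()
        else:
            a = dict(net.edges[e])
        if "count" in a and a["count"] == a["count"]:  # row extraction may
            a["count"] = int(a["count"])              # upcast int to float
        return a

    edges = sorted(canonical_pair(u, v) for u, v in net.edges)
    present = [c for c in _EDGE_COLUMNS if any(c in attrs_for(e) for e in edges)]
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(["gene_a", "gene_b"] + present) + "\n")
        for e in edges:
            a = attrs_for(e)
            fh.write("\t".join([e[0], e[1]] + [_fmt(a.get(c, "")) for c in present]) + "\n")


def read_network(path) -> tuple[nx.Graph, pd.DataFrame]:
    """Read an edge-list TSV back into a graph plus its edge-stats frame."""
    net = nx.Graph()
    records = {}
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:2] != ["gene_a", "gene_b"]:
            raise ParseError(f"{path}: line 1: expected gene_a/gene_b header")
        extra = header[2:]
        unknown = [c for c in extra if c not in _EDGE_COLUMNS]
        if unknown:
            log.warning("%s: unknown columns kept as opaque attributes: %s", path, unknown)
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != len(header):
                raise ParseError(f"{path}: line {lineno}: ragged row")
            e = canonical_pair(parts[0], parts[1])
            attrs = {}
            for col, raw in zip(extra, parts[2:]):
                if raw == "":
                    continue
                if col == "count":
                    attrs[col] = int(raw)
                elif col in _EDGE_COLUMNS:
                    attrs[col] = float(raw)
                else:
                    attrs[col] = raw
            net.add_edge(*e, **attrs)
            records[e] = attrs
    if records:
        idx = pd.MultiIndex.from_tuples(sorted(records), names=["gene_a", "gene_b"])
        stats = pd.DataFrame([records[e] for e in sorted(records)], index=idx)
    else:
        stats = pd.DataFrame(
            index=pd.MultiIndex.from_arrays([[], []], names=["gene_a", "gene_b"])
        )
    return net, stats


def write_sif(net: nx.Graph, path, relation: str = "mi") -> None:
    """Simple interaction format: gene_a <relation> gene_b."""
    with open(path, "w", encoding="utf-8") as fh:
        for a, b in sorted(canonical_pair(u, v) for u, v in net.edges):
            fh.write(f"{a}\t{relation}\t{b}\n")


# -- misc ----------------------------------------------------------------------

def write_key_values(mapping: dict, path) -> None:
    """Two-column key/value TSV for summary output."""
    with open(path, "w", encoding="utf-8") as fh:
        for key, value in mapping.items():
            fh.write(f"{key}\t{_fmt(value)}\n")


def ensure_dir(path) -> str:
    os.makedirs(path, exist_ok=True)
    return path
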