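"""Readers and writers for the delimited-text formats the pipeline touches.

Expression matrices arrive as plain TSV (first column feature ids, header row
sample ids) or as GEO series-matrix exports (identical layout once the ``!``
comment/metadata lines are dropped).  Missing cells may be encoded as an empty
string, ``NA``, ``NaN`` or ``null`` (case-insensitive).  Readers are strict:
duplicate ids and ragged rows are hard errors naming the offender, and every
dropped/collapsed row is logged so that rows_in = rows_kept + rows_rejected is
always auditable.
"""

from __future__ import annotations

import csv
import logging
import math
from pathlib import Path

import networkx as nx
import pandas as pd

from .types import (
    ExpressionMatrix,
    GeneSetCollection,
    InteractionTable,
    SampleMetadata,
)

log = logging.getLogger("thymonet.io")

MISSING_TOKENS = {"", "na", "nan", "null"}


def _parse_cell(token: str, row: int, col: str, path) -> float:
    token = token.strip()
    if token.lower() in MISSING_TOKENS:
        return math.nan
    try:
        return float(token)
    except ValueError:
        raise ValueError(
            f"{path}: unparseable value {token!r} at data row {row}, column {col!r}"
        ) from None


def read_expression_matrix(path, dialect: str = "tsv") -> ExpressionMatrix:
    """Read a features × samples log2 expression TSV or GEO series matrix."""
    if dialect not in ("tsv", "geo_series_matrix"):
        raise ValueError(f"unknown dialect {dialect!r}")
    path = Path(path)
    with open(path, newline="") as fh:
        lines = [
            ln for ln in fh
            if not (dialect == "geo_series_matrix" and ln.startswith("!"))
        ]
    rows = [r for r in csv.reader(lines, delimiter="\t") if r]
    if dialect == "geo_series_matrix":
        rows = [[c.strip('"') for c in r] for r in rows]
    if len(rows) < 2:
        raise ValueError(f"{path}: no data rows")
    header = rows[0]
    sample_ids = header[1:]
    n_cols = len(header)
    feature_ids: list[str] = []
    data: list[list[float]] = []
    seen: set[str] = set()
    for i, row in enumerate(rows[1:], start=1):
        if len(row) != n_cols:
            raise ValueError(
                f"{path}: ragged row {i} has {len(row)} fields, expected {n_cols}"
            )
        fid = row[0]
        if fid in seen:
            raise ValueError(f"{path}: duplicate feature id {fid!r}")
        seen.add(fid)
        feature_ids.append(fid)
        data.append([_parse_cell(tok, i, sample_ids[j], path)
                     for j, tok in enumerate(row[1:])])
    m = ExpressionMatrix(pd.DataFrame(data, index=feature_ids, columns=sample_ids))
    log.info("read %d features x %d samples from %s (%d missing cells)",
             m.n_features, m.n_samples, path, int(m.missing_mask.sum()))
    return m


def write_expression_matrix(m: ExpressionMatrix, path) -> None:
    df = m.data.copy()
    df.index.name = "feature_id"
    # repr-based float formatting keeps the round trip bit-exact
    df.to_csv(path, sep="\t", na_rep="NA", float_format=None)


def read_sample_metadata(path) -> SampleMetadata:
    """Read a sample table with columns sample_id, age_group, gender[, age_months]."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    for col in ("sample_id", "age_group"):
        if col not in df.columns:
            raise ValueError(f"{path}: metadata lacks required column {col!r}")
    meta = SampleMetadata(df.set_index("sample_id"))
    log.info("read metadata for %d samples from %s", len(meta.sample_ids), path)
    return meta


def write_sample_metadata(meta: SampleMetadata, path) -> None:
    out = meta.table.copy()
    out.index.name = "sample_id"
    out.to_csv(path, sep="\t")


def read_interaction_table(path, kind: str) -> InteractionTable:
    """Read a 2+ column edge list; duplicate (source, target) pairs collapse."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("source", "target"):
        if col not in df.columns:
            raise ValueError(f"{path}: interaction table lacks column {col!r}")
    n_in = len(df)
    df = df.drop_duplicates(subset=["source", "target"]).reset_index(drop=True)
    n_dup = n_in - len(df)
    if n_dup:
        log.info("%s: collapsed %d duplicate edge(s), kept %d", path, n_dup, len(df))
    if not len(df):
        log.warning("%s: empty interaction table", path)
    cols = ["source", "target"] + (["evidence"] if "evidence" in df.columns else [])
    return InteractionTable(kind=kind, edges=df[cols])


def write_interaction_table(table: InteractionTable, path) -> None:
    table.edges.to_csv(path, sep="\t", index=False)


def read_gmt(path) -> GeneSetCollection:
    """Read a GMT gene-set file: name <tab> description <tab> gene1 <tab> ..."""
    sets: dict[str, list[str]] = {}
    desc: dict[str, str] = {}
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}: line {i} has fewer than 3 fields")
            name = parts[0]
            if name in sets:
                raise ValueError(f"{path}: duplicate gene set {name!r}")
            genes = [g for g in parts[2:] if g]
            if not genes:
                raise ValueError(f"{path}: gene set {name!r} is empty")
            sets[name] = genes
            desc[name] = parts[1]
    return GeneSetCollection(sets=sets, descriptions=desc)


def write_gmt(coll: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for name, genes in coll.sets.items():
            fh.write("\t".join([name, coll.descriptions.get(name, "")] + list(genes)))
            fh.write("\n")


def write_network(net: nx.Graph, path, fmt: str = "graphml") -> None:
    """Serialize an integrative network (GraphML or 3+ column edge TSV).

    Node attributes carry role and module colour; edge attributes carry the
    Pearson r, edge type, sign and validation flag.
    """
    if fmt == "graphml":
        nx.write_graphml(net, path)
    elif fmt == "edge_tsv":
        with open(path, "w") as fh:
            fh.write("source\ttarget\tr\tedge_type\tsign\tvalidated\n")
            for u, v, d in sorted(net.edges(data=True)):
                fh.write(
                    f"{u}\t{v}\t{d['r']!r}\t{d['edge_type']}\t{d['sign']}\t"
                    f"{d['validated']}\n"
                )
    else:
        raise ValueError(f"unknown network format {fmt!r}")


def read_network(path, fmt: str = "graphml") -> nx.Graph:
    if fmt == "graphml":
        return nx.read_graphml(path)
    if fmt == "edge_tsv":
        df = pd.read_csv(path, sep="\t")
        g = nx.Graph()
        for row in df.itertuples(index=False):
            g.add_edge(str(row.source), str(row.target), r=float(row.r),
                       edge_type=str(row.edge_type), sign=str(row.sign),
                       validated=bool(row.validated))
        return g
    raise ValueError(f"unknown network format {fmt!r}")
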