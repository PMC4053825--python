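"""Readers and writers for every on-disk artifact.

All tables are plain TSV.  Expression matrices are genes x samples with a
mandatory header of sample ids and a first ``gene_id`` column; sample
metadata travels in a sibling table.  Edge lists come in a plain
two-column dialect and a BioGRID-TAB-style dialect keyed on header columns
containing "Official Symbol".  Readers never coerce invalid values
silently: bad cells raise :class:`ParseError` naming the offending
row/column, and every dropped duplicate edge or self-loop is counted and
logged.

Gene identity for network joins is the upper-cased symbol, matched
exactly; no alias resolution is attempted.
"""

from __future__ import annotations

import logging
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
import yaml

from .datatypes import (ExpressionMatrix, ParseError, REGULATOR_CLASSES,
                        SurvivalCohort, ValidationError)

log = logging.getLogger(__name__)


# ---------------------------------------------------------------- expression

def read_expression(path, dialect: str = "plain_tsv",
                    samples_path=None, kind: str = "healthy_reference") -> ExpressionMatrix:
    """Read a genes x samples expression TSV.

    Without ``samples_path`` every sample gets its own column name as
    context and the given ``kind``.
    """
    if dialect != "plain_tsv":
        raise ValidationError(f"unknown expression dialect {dialect!r}")
    raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str,
                      keep_default_na=False, comment="#")
    if not raw.index.is_unique:
        dup = raw.index[raw.index.duplicated()][0]
        raise ParseError(f"duplicate gene id {dup!r} in {path}")
    values = pd.DataFrame(index=raw.index.rename("gene_id"))
    for col in raw.columns:
        # float() is a correctly-rounded parser, so writes round-trip exactly
        parsed = np.empty(len(raw), float)
        for i, cell in enumerate(raw[col].to_numpy()):
            try:
                parsed[i] = float(cell)
            except (TypeError, ValueError):
                raise ParseError(
                    f"non-numeric value {cell!r} at gene {raw.index[i]!r}, "
                    f"sample {col!r} in {path}") from None
        if np.isnan(parsed).any():
            gene = raw.index[int(np.flatnonzero(np.isnan(parsed))[0])]
            raise ParseError(f"missing value at gene {gene!r}, sample {col!r}")
        values[col] = parsed
    if (values.to_numpy() < 0).any():
        raise ParseError(f"negative expression value in {path}")
    if samples_path is not None:
        samples = pd.read_csv(samples_path, sep="\t", index_col=0,
                              dtype=str, keep_default_na=False, comment="#")
        samples = samples.loc[values.columns]
        return ExpressionMatrix(values=values, samples=samples)
    return ExpressionMatrix.simple(values, kind=kind)


def write_expression(matrix: ExpressionMatrix, path,
                     samples_path=None, header_lines: list[str] | None = None) -> None:
    """Write an expression matrix (and optionally its sample metadata)."""
    _write_tsv(matrix.values, path, index_label="gene_id",
               header_lines=header_lines)
    if samples_path is not None:
        _write_tsv(matrix.samples, samples_path, index_label="sample_id",
                   header_lines=header_lines)


# ---------------------------------------------------------------- edge lists

def read_edge_list(path, dialect: str = "two_column") -> nx.Graph:
    """Read an undirected simple PPI graph.

    ``two_column``: two whitespace-separated symbols per line.
    ``biogrid_tab``: tab-separated with a header; the first two columns
    whose names contain "Official Symbol" supply the interactors.
    Symbols are upper-cased; duplicate edges and self-loops are dropped
    with a logged count.
    """
    pairs: list[tuple[str, str]] = []
    if dialect == "two_column":
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                parts = line.split()
                if len(parts) < 2:
                    raise ParseError(f"line {lineno} of {path}: expected two symbols")
                pairs.append((parts[0], parts[1]))
    elif dialect == "biogrid_tab":
        table = pd.read_csv(path, sep="\t", dtype=str)
        symbol_cols = [c for c in table.columns
                       if "official symbol" in c.lower()]
        if len(symbol_cols) < 2:
            raise ParseError(
                f"{path}: biogrid_tab needs two 'Official Symbol' columns, "
                f"found {symbol_cols}")
        a_col, b_col = symbol_cols[:2]
        pairs = list(zip(table[a_col].astype(str), table[b_col].astype(str)))
    else:
        raise ValidationError(f"unknown edge-list dialect {dialect!r}")
    g = nx.Graph()
    n_self = n_dup = 0
    for a, b in pairs:
        a, b = a.upper(), b.upper()
        if a == b:
            n_self += 1
            continue
        if g.has_edge(a, b):
            n_dup += 1
            continue
        g.add_edge(a, b)
    log.info("read_edge_list: %d edges, %d nodes; dropped %d self-loops, "
             "%d duplicates", g.number_of_edges(), g.number_of_nodes(),
             n_self, n_dup)
    return g


def write_edge_list(g: nx.Graph, path,
                    header_lines: list[str] | None = None) -> None:
    with open(path, "w") as fh:
        for line in header_lines or []:
            fh.write(f"# {line}\n")
        for a, b in sorted(tuple(sorted(e)) for e in g.edges):
            fh.write(f"{a}\t{b}\n")


# ---------------------------------------------------------------- catalogs

def read_complexes(path) -> pd.DataFrame:
    """Read a complex catalog TSV: complex_id <TAB> name <TAB> A;B;C."""
    rows = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise ParseError(f"line {lineno} of {path}: expected 3 fields")
            cid, name, members = parts
            member_tuple = tuple(m for m in members.split(";") if m)
            if not member_tuple:
                raise ParseError(f"line {lineno} of {path}: empty member set")
            if cid in rows:
                raise ParseError(f"duplicate complex id {cid!r} in {path}")
            rows[cid] = {"name": name, "members": member_tuple}
    catalog = pd.DataFrame.from_dict(rows, orient="index",
                                     columns=["name", "members"])
    catalog.index.name = "complex_id"
    return catalog


def write_complexes(catalog: pd.DataFrame, path,
                    header_lines: list[str] | None = None) -> None:
    with open(path, "w") as fh:
        for line in header_lines or []:
            fh.write(f"# {line}\n")
        for cid, row in catalog.iterrows():
            fh.write(f"{cid}\t{row['name']}\t{';'.join(row['members'])}\n")


# ---------------------------------------------------------------- survival

def read_survival(path) -> SurvivalCohort:
    """Read a survival TSV: patient_id, time, event, then one column per gene."""
    table = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    for col in ("time", "event"):
        if col not in table.columns:
            raise ParseError(f"{path}: missing required column {col!r}")
    if (table["time"] <= 0).any():
        bad = table.index[table["time"] <= 0][0]
        raise ParseError(f"{path}: non-positive time for patient {bad!r}")
    gene_cols = [c for c in table.columns if c not in ("time", "event")]
    expr = table[gene_cols].T.astype(float)
    if (expr.to_numpy() < 0).any():
        raise ParseError(f"{path}: negative expression value")
    return SurvivalCohort(data=table[["time", "event"]].copy(), expression=expr)


def write_survival(cohort: SurvivalCohort, path,
                   header_lines: list[str] | None = None) -> None:
    table = pd.concat([cohort.data, cohort.expression.T], axis=1)
    _write_tsv(table, path, index_label="patient_id", header_lines=header_lines)


# ---------------------------------------------------------------- annotation

def read_annotation(path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t", index_col=0, dtype=str, comment="#")
    if not table.index.is_unique:
        dup = table.index[table.index.duplicated()][0]
        raise ParseError(f"duplicate gene id {dup!r} in {path}")
    if "regulator_class" not in table.columns:
        raise ParseError(f"{path}: missing regulator_class column")
    bad = set(table["regulator_class"]) - set(REGULATOR_CLASSES)
    if bad:
        raise ParseError(f"{path}: unknown regulator class(es) {sorted(bad)}")
    if "symbol" not in table.columns:
        table["symbol"] = table.index
    table.index.name = "gene_id"
    return table


def write_annotation(annotation: pd.DataFrame, path,
                     header_lines: list[str] | None = None) -> None:
    _write_tsv(annotation, path, index_label="gene_id",
               header_lines=header_lines)


def read_transcript_map(path) -> pd.Series:
    table = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    if list(table.columns[:2]) != ["transcript_id", "gene_id"]:
        raise ParseError(f"{path}: expected transcript_id, gene_id columns")
    if table["transcript_id"].duplicated().any():
        dup = table["transcript_id"][table["transcript_id"].duplicated()].iloc[0]
        raise ParseError(f"{path}: transcript {dup!r} maps to multiple genes")
    return table.set_index("transcript_id")["gene_id"]


def write_transcript_map(tmap: pd.Series, path) -> None:
    frame = tmap.rename("gene_id").rename_axis("transcript_id").reset_index()
    frame.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------- config

def read_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ParseError(f"{path}: configuration must be a mapping")
    return cfg


def write_config(cfg: dict, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)


# ---------------------------------------------------------------- helpers

def _write_tsv(frame: pd.DataFrame, path, index_label: str,
               header_lines: list[str] | None = None) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        for line in header_lines or []:
            fh.write(f"# {line}\n")
        frame.to_csv(fh, sep="\t", index_label=index_label)


def read_tsv(path) -> pd.DataFrame:
    """Read back a TSV written by :func:`_write_tsv` (skipping # headers)."""
    return pd.read_csv(path, sep="\t", comment="#", index_col=0)
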