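"""Readers and writers for the pipeline's external formats.

Tab-separated text throughout: expression matrix + design TSV, GMT gene-set
files, interaction tables, and network output as edge table / SIF / GraphML.
The TSV dialect is tabs only, ``.`` decimal separator, and ``#`` comment
lines ignored.  Readers never silently drop rows: every rejected record
raises or warns.
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .datatypes import (
    INTERACTION_TYPES,
    ExpressionMatrix,
    GeneSetCollection,
    Interaction,
    InteractionCatalog,
    NetworkEdge,
)

NETWORK_FORMATS = ("edge-table", "sif", "graphml")


def read_expression_tsv(path: str | Path, design_path: str | Path) -> ExpressionMatrix:
    """Read a genes × samples TSV plus a sample design TSV.

    The design file must have columns ``sample``, ``time_hours``,
    ``replicate`` and cover exactly the sample columns of the matrix.
    """
    raw = pd.read_csv(path, sep="\t", comment="#", index_col=0, dtype=str)
    raw.index = raw.index.astype(str)
    raw.index.name = None
    values = pd.DataFrame(index=raw.index)
    for col in raw.columns:
        converted = pd.to_numeric(raw[col], errors="coerce")
        bad = converted.isna()
        if bad.any():
            gene = raw.index[bad][0]
            cell = raw.loc[gene, col]
            raise ValueError(
                f"non-numeric expression value {cell!r} at gene {gene!r}, "
                f"sample column {col!r} in {path}"
            )
        values[col] = converted.astype(float)

    design = pd.read_csv(design_path, sep="\t", comment="#", dtype=str)
    for col in ("sample", "time_hours", "replicate"):
        if col not in design.columns:
            raise ValueError(f"design file {design_path} is missing column {col!r}")
    design = design.set_index("sample")
    design["time_hours"] = design["time_hours"].astype(float)
    design["replicate"] = design["replicate"].astype(int)
    return ExpressionMatrix(values, design)


def write_expression_tsv(
    matrix: ExpressionMatrix, path: str | Path, design_path: str | Path
) -> None:
    matrix.values.to_csv(path, sep="\t", index_label="gene_id")
    out = matrix.design.reset_index()
    out.columns = ["sample", *matrix.design.columns]
    out.to_csv(design_path, sep="\t", index=False)


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a GMT file: one category per line, name<TAB>description<TAB>genes..."""
    categories: dict[str, frozenset[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}:{lineno}: GMT line has {len(fields)} fields, expected >= 3"
                )
            name, desc = fields[0], fields[1]
            if name in categories:
                raise ValueError(f"{path}:{lineno}: duplicate category id {name!r}")
            genes = frozenset(g for g in fields[2:] if g)
            categories[name] = genes
            descriptions[name] = desc
    return GeneSetCollection(categories, descriptions)


def write_gmt(sets: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name in sets:
            genes = "\t".join(sorted(sets[name]))
            fh.write(f"{name}\t{sets.description(name)}\t{genes}\n")


def read_interaction_table(path: str | Path) -> InteractionCatalog:
    """Read a prior-interaction TSV with columns source, target, type.

    Types outside the closed vocabulary are mapped to ``"other"`` with a
    warning, so no record is silently lost.
    """
    table = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    for col in ("source", "target", "type"):
        if col not in table.columns:
            raise ValueError(f"interaction table {path} is missing column {col!r}")
    records = []
    for _, row in table.iterrows():
        itype = row["type"]
        if itype not in INTERACTION_TYPES:
            warnings.warn(
                f"unknown interaction type {itype!r} for "
                f"{row['source']}->{row['target']}; recorded as 'other'"
            )
            itype = "other"
        records.append(Interaction(str(row["source"]), str(row["target"]), itype))
    return InteractionCatalog(records)


def write_interaction_table(catalog: InteractionCatalog, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("source\ttarget\ttype\n")
        for rec in catalog:
            fh.write(f"{rec.source}\t{rec.target}\t{rec.type}\n")


# -- network output -----------------------------------------------------------

_EDGE_COLUMNS = ["source", "target", "weight", "interaction", "provenance"]


def write_network(
    edges: Sequence[NetworkEdge], path: str | Path, format: str = "edge-table"
) -> None:
    """Write edges as an edge table, SIF, or GraphML.

    The edge table mirrors the usual reporting layout (source, target,
    weight, interaction, provenance) and round-trips with
    :func:`read_edge_table`.
    """
    if format not in NETWORK_FORMATS:
        raise ValueError(f"unknown network format {format!r}; use one of {NETWORK_FORMATS}")
    if format == "edge-table":
        frame = pd.DataFrame(
            [(e.source, e.target, e.weight, e.interaction, e.provenance) for e in edges],
            columns=_EDGE_COLUMNS,
        )
        frame.to_csv(path, sep="\t", index=False)  # default repr round-trips floats
    elif format == "sif":
        with open(path, "w") as fh:
            for e in edges:
                fh.write(f"{e.source}\t{e.interaction}\t{e.target}\n")
    else:  # graphml
        graph = nx.DiGraph()
        for e in edges:
            graph.add_edge(
                e.source,
                e.target,
                weight=float(e.weight),
                interaction=e.interaction,
                provenance=e.provenance,
            )
        nx.write_graphml(graph, path)


def read_edge_table(path: str | Path) -> list[NetworkEdge]:
    frame = pd.read_csv(
        path, sep="\t", comment="#", dtype={"source": str, "target": str},
        float_precision="round_trip",
    )
    for col in _EDGE_COLUMNS:
        if col not in frame.columns:
            raise ValueError(f"edge table {path} is missing column {col!r}")
    return [
        NetworkEdge(
            str(r.source), str(r.target), float(r.weight), r.interaction, r.provenance
        )
        for r in frame.itertuples(index=False)
    ]


def read_graphml_network(path: str | Path) -> list[NetworkEdge]:
    graph = nx.read_graphml(path)
    return [
        NetworkEdge(str(u), str(v), float(d["weight"]), d["interaction"], d["provenance"])
        for u, v, d in graph.edges(data=True)
    ]
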