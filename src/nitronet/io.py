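"""Readers and writers for the formats the pipeline touches.

Count tables come as TSV (either orientation, auto-detected or forced) or
BIOM 1.0 JSON; phylogenies as Newick (polytomies optionally resolved to a
deterministic random bifurcation); sample metadata as CSV; networks as
GraphML or edge-list TSV.  All readers validate the invariants the rest of
the package relies on (non-negative integer counts, unique ids, binary
rooted trees) and all writer/reader pairs round-trip losslessly.
"""

from __future__ import annotations

import json
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from skbio import TreeNode

__all__ = [
    "FormatError",
    "IdError",
    "read_count_table",
    "write_count_table",
    "read_sample_frame",
    "read_tree",
    "write_tree",
    "write_network",
    "read_network",
]


class FormatError(ValueError):
    """Malformed or non-numeric content in an input file."""


class IdError(ValueError):
    """Duplicate or inconsistent identifiers."""


def _validate_counts(df: pd.DataFrame) -> pd.DataFrame:
    if df.index.has_duplicates or df.columns.has_duplicates:
        raise IdError("duplicate sample or OTU ids")
    try:
        vals = df.to_numpy(dtype=float)
    except (TypeError, ValueError) as e:
        raise FormatError(f"non-numeric counts: {e}") from None
    if not np.isfinite(vals).all():
        raise FormatError("non-finite counts")
    if (vals < 0).any():
        raise FormatError("negative counts")
    if not np.allclose(vals, np.round(vals)):
        raise FormatError("counts must be integers")
    if df.shape[0] < 2 or df.shape[1] < 2:
        raise FormatError("need at least 2 samples and 2 OTUs")
    out = pd.DataFrame(vals.astype(np.int64), index=df.index.astype(str),
                       columns=df.columns.astype(str))
    return out


def read_count_table(path, fmt: str | None = None, orientation: str = "auto") -> pd.DataFrame:
    """Read a samples x OTUs count table from TSV or BIOM 1.0 JSON.

    ``orientation`` applies to TSV: ``"samples"`` (rows are samples),
    ``"otus"`` (rows are OTUs) or ``"auto"`` — the longer axis is assumed to
    be OTUs, as deposited tables usually have far more OTUs than samples.
    """
    path = Path(path)
    if fmt is None:
        fmt = "biom" if path.suffix == ".biom" else "tsv"
    if fmt == "biom":
        return _read_biom_json(path)
    if fmt != "tsv":
        raise ValueError(f"unknown format {fmt!r}")
    df = pd.read_csv(path, sep="\t", index_col=0)
    if orientation not in ("auto", "samples", "otus"):
        raise ValueError("orientation must be 'auto', 'samples' or 'otus'")
    if orientation == "otus" or (orientation == "auto" and df.shape[0] > df.shape[1]):
        df = df.T
    return _validate_counts(df)


def _read_biom_json(path: Path) -> pd.DataFrame:
    """BIOM 1.0 (JSON) table; rows are observations (OTUs), columns samples."""
    with open(path) as fh:
        doc = json.load(fh)
    try:
        otus = [r["id"] for r in doc["rows"]]
        samples = [c["id"] for c in doc["columns"]]
        shape = doc["shape"]
        mtype = doc["matrix_type"]
        data = doc["data"]
    except (KeyError, TypeError) as e:
        raise FormatError(f"not a BIOM 1.0 JSON table: missing {e}") from None
    M = np.zeros((shape[0], shape[1]))
    if mtype == "dense":
        M[:] = np.asarray(data, dtype=float)
    elif mtype == "sparse":
        for i, j, v in data:
            M[int(i), int(j)] = v
    else:
        raise FormatError(f"unsupported BIOM matrix_type {mtype!r}")
    df = pd.DataFrame(M.T, index=samples, columns=otus)  # -> samples x OTUs
    return _validate_counts(df)


def write_count_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index_label="sample_id")


def read_sample_frame(path, exclude: list[str] | None = None) -> pd.DataFrame:
    """Sample metadata CSV indexed by sample_id.

    Requires ``site``, ``treatment`` and ``plot`` columns; samples listed in
    ``exclude`` are dropped (supports the deposited-data case where a few
    collected samples were excluded from analysis).
    """
    df = pd.read_csv(path, index_col=0)
    df.index = df.index.astype(str)
    if df.index.has_duplicates:
        raise IdError("duplicate sample ids in metadata")
    for col in ("site", "treatment", "plot"):
        if col not in df.columns:
            raise FormatError(f"metadata missing required column {col!r}")
    if exclude:
        df = df.drop(index=[s for s in exclude if s in df.index])
    return df


def read_tree(path, resolve: bool = False, seed: int | None = None) -> TreeNode:
    """Read a rooted binary Newick tree.

    Polytomies raise unless ``resolve=True``, in which case each polytomy is
    resolved into a deterministic random bifurcation (children shuffled with
    ``seed``, ladderized with zero-length inserted branches).
    """
    tree = TreeNode.read(str(path))
    polytomies = [n for n in tree.non_tips(include_self=True) if len(n.children) > 2]
    if polytomies and not resolve:
        raise ValueError(
            f"tree has {len(polytomies)} polytomy(ies), e.g. at root with "
            f"{len(tree.children)} children; pass resolve=True to bifurcate"
        )
    if polytomies:
        rng = np.random.default_rng(seed)
        for node in polytomies:
            order = rng.permutation(len(node.children))
            node.children = [node.children[i] for i in order]
        tree.bifurcate(insert_length=0.0)
    for node in tree.non_tips(include_self=True):
        if len(node.children) != 2:
            raise ValueError("tree could not be resolved to binary")
    for node in tree.traverse():
        if node.length is not None and node.length < 0:
            raise FormatError("negative branch length")
    return tree


def write_tree(tree: TreeNode, path) -> None:
    tree.write(str(path))


def write_network(G: nx.Graph, path, fmt: str = "edge_tsv") -> None:
    """Write a signed weighted graph as GraphML or an edge-list TSV."""
    path = Path(path)
    if fmt == "graphml":
        nx.write_graphml(G, path)
    elif fmt == "edge_tsv":
        with open(path, "w") as fh:
            fh.write("source\ttarget\tweight\n")
            for u, v, d in sorted(G.edges(data=True)):
                fh.write(f"{u}\t{v}\t{d.get('weight', 1.0):.10g}\n")
    else:
        raise ValueError(f"unknown network format {fmt!r}")


def read_network(path, fmt: str = "edge_tsv") -> nx.Graph:
    path = Path(path)
    if fmt == "graphml":
        G = nx.read_graphml(path)
        H = nx.Graph()
        for u, v, d in G.edges(data=True):
            H.add_edge(str(u), str(v), weight=float(d.get("weight", 1.0)))
        H.add_nodes_from(str(n) for n in G.nodes())
        return H
    if fmt != "edge_tsv":
        raise ValueError(f"unknown network format {fmt!r}")
    G = nx.Graph()
    df = pd.read_csv(path, sep="\t")
    for _, row in df.iterrows():
        G.add_edge(str(row["source"]), str(row["target"]), weight=float(row["weight"]))
    return G
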