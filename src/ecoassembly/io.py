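"""Reading, writing and basic preparation of the pipeline's inputs.

Newick phylogenies, sample x OTU count tables (TSV or BIOM 1.0 JSON), sample
metadata with coordinates and environmental variables, replicate pooling,
rarefaction to a common sequencing depth, and great-circle geographic
distances between sites.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
from skbio import TreeNode

logger = logging.getLogger(__name__)

__all__ = [
    "read_newick",
    "write_newick",
    "read_community_table",
    "read_metadata",
    "pool_replicates",
    "rarefy",
    "geographic_distance_matrix",
    "validate_community_matrix",
    "prune_to_shared_taxa",
]

EARTH_RADIUS_KM = 6371.0


def read_newick(path, default_length: float | None = None) -> TreeNode:
    """Read a rooted Newick tree and validate it for downstream use.

    Parameters
    ----------
    path : str or Path
        Newick file.
    default_length : float, optional
        Value substituted for edges without a length.  By default a missing
        length (anywhere except the root) is an error.

    Raises
    ------
    ValueError
        Duplicate tip labels, negative branch lengths, or missing branch
        lengths without a configured default.
    """
    tree = TreeNode.read(str(path), convert_underscores=False)
    tips = [t.name for t in tree.tips()]
    if len(set(tips)) != len(tips):
        dupes = sorted({t for t in tips if tips.count(t) > 1})
        raise ValueError(f"duplicate tip labels in tree: {dupes}")
    for node in tree.traverse(include_self=False):
        if node.length is None:
            if default_length is None:
                raise ValueError(
                    f"edge above {node.name or '<internal>'} has no branch length"
                )
            node.length = default_length
        elif node.length < 0:
            raise ValueError(
                f"negative branch length {node.length} above {node.name or '<internal>'}"
            )
    return tree


def write_newick(tree: TreeNode, path) -> None:
    """Write a tree back to Newick (round-trips patristic distances)."""
    tree.write(str(path))


def _table_from_dense(df: pd.DataFrame, rows_are: str) -> pd.DataFrame:
    if rows_are not in ("samples", "otus"):
        raise ValueError("rows_are must be 'samples' or 'otus' (no auto-detection)")
    if rows_are == "otus":
        df = df.T
    arr = df.to_numpy()
    if not np.issubdtype(arr.dtype, np.number):
        raise ValueError("community table contains non-numeric cells")
    if (arr < 0).any():
        raise ValueError("community table contains negative counts")
    if not np.allclose(arr, np.round(arr)):
        raise ValueError("community table contains non-integer counts")
    if df.size == 0:
        raise ValueError("empty community table")
    return df.astype(np.int64)


def _read_biom_json(path) -> pd.DataFrame:
    """Parse a BIOM 1.0 JSON table (dense or sparse) into OTUs-as-rows."""
    with open(path) as fh:
        doc = json.load(fh)
    otu_ids = [r["id"] for r in doc["rows"]]
    sample_ids = [c["id"] for c in doc["columns"]]
    shape = tuple(doc["shape"])
    mat = np.zeros(shape)
    if doc.get("matrix_type") == "dense":
        mat[:] = np.asarray(doc["data"])
    else:
        for r, c, v in doc["data"]:
            mat[int(r), int(c)] = v
    return pd.DataFrame(mat, index=otu_ids, columns=sample_ids)


def read_community_table(path, rows_are: str = "samples") -> pd.DataFrame:
    """Read a sample x OTU count table from TSV or BIOM 1.0 JSON.

    The caller must state the orientation of a TSV explicitly via
    ``rows_are``; BIOM fixes rows = observations (OTUs) by convention.
    Returns a samples x OTUs integer DataFrame.
    """
    path = Path(path)
    if path.suffix == ".biom":
        return _table_from_dense(_read_biom_json(path), rows_are="otus")
    df = pd.read_csv(path, sep="\t", index_col=0)
    return _table_from_dense(df, rows_are=rows_are)


def read_metadata(path) -> pd.DataFrame:
    """Read per-sample metadata (TSV, first column = sample id).

    Validates coordinate columns ``latitude``/``longitude`` when present.
    """
    meta = pd.read_csv(path, sep="\t", index_col=0)
    if meta.index.duplicated().any():
        raise ValueError("duplicate sample ids in metadata")
    if "latitude" in meta:
        if meta["latitude"].abs().gt(90).any():
            raise ValueError("latitude outside [-90, 90]")
    if "longitude" in meta:
        if meta["longitude"].abs().gt(180).any():
            raise ValueError("longitude outside [-180, 180]")
    return meta


def validate_community_matrix(table: pd.DataFrame) -> None:
    """Assert the count-table invariants (non-negative ints, positive rows)."""
    arr = table.to_numpy()
    if (arr < 0).any():
        raise ValueError("negative counts")
    if (arr.sum(axis=1) == 0).any():
        raise ValueError("sample(s) with zero total count")
    if table.index.duplicated().any() or table.columns.duplicated().any():
        raise ValueError("duplicate sample or OTU ids")


def pool_replicates(table: pd.DataFrame, by: pd.Series) -> pd.DataFrame:
    """Sum replicate samples into site-level communities.

    ``by`` maps each sample id to a pooling key (e.g. site); counts of
    samples sharing a key are summed column-wise.
    """
    missing = table.index.difference(by.index)
    if len(missing):
        raise KeyError(f"samples without a pooling key: {list(missing)[:5]}")
    return table.groupby(by.loc[table.index]).sum()


def rarefy(table: pd.DataFrame, depth: int, seed) -> pd.DataFrame:
    """Subsample every sample without replacement to a common read depth.

    Samples whose total is below ``depth`` are dropped with a logged
    warning.  Subsampling is exact multivariate-hypergeometric draws, so a
    zero count can never become positive and every retained row sums to
    ``depth`` exactly.  Deterministic for a fixed seed.
    """
    if depth <= 0:
        raise ValueError("rarefaction depth must be positive")
    validate_community_matrix(table)
    rng = np.random.default_rng(seed)
    sums = table.sum(axis=1)
    keep = sums >= depth
    if not keep.any():
        raise ValueError(f"all samples below rarefaction depth {depth}")
    dropped = table.index[~keep].tolist()
    if dropped:
        logger.warning("dropping %d sample(s) below depth %d: %s", len(dropped), depth, dropped)
    out = {}
    for sid in table.index[keep]:
        row = table.loc[sid].to_numpy(dtype=np.int64)
        if row.sum() == depth:
            out[sid] = row
        else:
            out[sid] = rng.multivariate_hypergeometric(row, depth)
    res = pd.DataFrame(out, index=table.columns).T
    assert (res.sum(axis=1) == depth).all()
    return res


def geographic_distance_matrix(meta: pd.DataFrame) -> pd.DataFrame:
    """Great-circle (haversine) distance matrix in km between sample sites.

    Spherical Earth with radius 6371 km; symmetric with zero diagonal.
    """
    for col in ("latitude", "longitude"):
        if col not in meta or meta[col].isna().any():
            raise ValueError(f"missing coordinate column or values: {col}")
    lat = np.radians(meta["latitude"].to_numpy(dtype=float))
    lon = np.radians(meta["longitude"].to_numpy(dtype=float))
    dlat = lat[:, None] - lat[None, :]
    dlon = lon[:, None] - lon[None, :]
    a = np.sin(dlat / 2) ** 2 + np.cos(lat[:, None]) * np.cos(lat[None, :]) * np.sin(dlon / 2) ** 2
    d = 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0, 1)))
    np.fill_diagonal(d, 0.0)
    return pd.DataFrame(d, index=meta.index, columns=meta.index)


def prune_to_shared_taxa(
    table: pd.DataFrame, dist: pd.DataFrame, allow_prune: bool = False
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Align a count table with a patristic matrix.

    OTUs in the table but missing from the tree are a hard error by default
    (silent intersection hides data bugs); with ``allow_prune`` the table is
    intersected to the tree's tip set instead, with a logged warning.  The
    distance matrix is always restricted to the OTUs the table actually
    contains (taxa with zero total count do not enter the null pool).
    """
    missing = table.columns.difference(dist.index)
    if len(missing):
        if not allow_prune:
            raise KeyError(
                f"{len(missing)} OTU(s) missing from tree, e.g. {list(missing)[:5]}; "
                "pass allow_prune=True to intersect"
            )
        logger.warning("pruning %d OTU(s) absent from tree", len(missing))
        table = table.drop(columns=missing)
    present = table.columns[table.sum(axis=0) > 0]
    table = table[present]
    return table, dist.loc[present, present]
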