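"""Readers and writers for the pipeline's delimited-table ecosystem.

Everything is plain TSV (features in the first column, sample ids in the
header) plus GMT for gene sets.  Writers emit deterministically ordered
tables so re-runs are byte-identical.
"""

from __future__ import annotations

import logging

import pandas as pd

from .core import (DataError, DesignError, FormatError, GeneSetCollection,
                   OmicsMatrix, RelationMap, SampleDesign)

logger = logging.getLogger("gliomics")


def read_omics_matrix(path, layer: str, design: SampleDesign,
                      scale: str = "linear") -> OmicsMatrix:
    """Read a feature-by-sample TSV into a validated :class:`OmicsMatrix`.

    Rows containing any missing value are dropped and counted
    (quantification requires a value in every sample).
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    missing = set(design.sample_ids) - set(df.columns)
    if missing:
        raise DesignError(f"columns missing from {path}: {sorted(missing)}")
    df = df[list(design.sample_ids)]
    complete = df.dropna()
    n_dropped = len(df) - len(complete)
    if n_dropped:
        logger.info("%s: dropped %d rows with missing values", path, n_dropped)
    return OmicsMatrix(layer, complete, design, scale=scale,
                       n_dropped_missing=n_dropped)


def write_omics_matrix(matrix: OmicsMatrix, path) -> None:
    matrix.data.sort_index().to_csv(path, sep="\t", index_label="feature_id")


def read_gmt(path) -> GeneSetCollection:
    """Read gene sets in the GMT dialect (name, description, members...)."""
    sets = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{ln}: GMT line needs >=3 fields")
            name, members = fields[0], [m for m in fields[2:] if m]
            if len(set(members)) < len(members):
                logger.warning("%s:%d: duplicate members in %s deduplicated",
                               path, ln, name)
            sets[name] = set(members)
    return GeneSetCollection(sets) if sets else GeneSetCollection({}, set())


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for name in sorted(collection.sets):
            members = "\t".join(sorted(collection.sets[name]))
            fh.write(f"{name}\tna\t{members}\n")


def read_relation_table(path, kind: str) -> RelationMap:
    """Read a regulator/target(/site)(/sign) TSV into a RelationMap."""
    df = pd.read_csv(path, sep="\t", dtype={"regulator": str, "target": str})
    if not {"regulator", "target"} <= set(df.columns):
        raise FormatError(f"{path}: needs columns regulator, target")
    if kind == "functional_sites" and "sign" not in df.columns:
        raise DataError(f"{path}: functional_sites requires a sign column")
    return RelationMap(kind, df)


def write_relation_table(rel: RelationMap, path) -> None:
    out = rel.edges.sort_values(["regulator", "target", "site"],
                                na_position="last")
    out.to_csv(path, sep="\t", index=False)


def write_result_table(result, path) -> None:
    """Write any flat stage output with deterministic row and column order.

    Accepts a DataFrame (rows sorted by the first column or the index) or a
    list of dicts; re-running on the same input yields a byte-identical file.
    """
    if isinstance(result, pd.DataFrame):
        df = result.copy()
    else:
        df = pd.DataFrame(list(result))
    if df.empty:
        # header-only file
        df.to_csv(path, sep="\t", index=False)
        return
    if df.index.name is not None:
        df = df.sort_index().reset_index()
    else:
        df = df.sort_values(df.columns[0], kind="mergesort").reset_index(drop=True)
    df.to_csv(path, sep="\t", index=False)


def read_result_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
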