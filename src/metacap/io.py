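"""Readers and writers for the on-disk artifact formats.

TSV (tab-delimited, UTF-8, no quoting; ``NA`` or empty cell = missing) for
tables, JSON for the model catalog, Newick for trees. Count tables are
stored ASVs-as-rows / samples-as-columns, the usual orientation of amplicon
feature tables, and transposed into the samples x ASVs in-memory layout.
"""
from __future__ import annotations

import io as _io
import json
import warnings
from pathlib import Path

import pandas as pd
from skbio import TreeNode

from .containers import (
    RANKS,
    AsvCountTable,
    Model,
    ModelCatalog,
    PhyloTree,
    SampleMetadata,
    TaxonomyTable,
)
from .errors import FormatError

_NA = ("", "NA")


def read_asv_table(path) -> AsvCountTable:
    """Read a count table TSV (rows = ASVs, columns = samples).

    Row and column order is preserved. Duplicate identifiers and negative
    or non-numeric cells raise :class:`FormatError` naming the offender.
    """
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, dtype=str, keep_default_na=False)
    except Exception as exc:  # parse failure
        raise FormatError(f"cannot parse count table {path}: {exc}") from exc
    dup = df.index[df.index.duplicated()]
    if len(dup):
        raise FormatError(f"duplicate ASV identifier: {dup[0]!r}")
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")[1:]
    if len(set(header)) != len(header):
        raise FormatError("duplicate sample identifiers in header")
    df.index.name = None
    num = pd.DataFrame(index=df.index, columns=df.columns, dtype=float)
    for col in df.columns:
        for row in df.index:
            cell = df.loc[row, col]
            try:
                num.loc[row, col] = float(cell)
            except ValueError:
                raise FormatError(
                    f"non-numeric count {cell!r} at ASV {row!r}, sample {col!r}"
                ) from None
            if num.loc[row, col] < 0:
                raise FormatError(f"negative count at ASV {row!r}, sample {col!r}")
    return AsvCountTable(num.T)


def write_asv_table(table: AsvCountTable, path) -> None:
    table.counts.T.to_csv(path, sep="\t", index_label="asv_id")


def _parse_lineage(s: str) -> list:
    parts = [p.strip() for p in s.split(";")]
    if len(parts) > len(RANKS):
        raise FormatError(f"lineage has {len(parts)} fields, at most {len(RANKS)} allowed: {s!r}")
    parts += [""] * (len(RANKS) - len(parts))
    return [None if p in _NA else p for p in parts]


def read_taxonomy(path) -> TaxonomyTable:
    """Read taxonomy TSV: ASV id plus either 7 rank columns or a single
    semicolon-delimited lineage column."""
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, dtype=str, keep_default_na=False)
    except Exception as exc:
        raise FormatError(f"cannot parse taxonomy {path}: {exc}") from exc
    if df.shape[1] == 1:
        rows = [_parse_lineage(v) for v in df.iloc[:, 0]]
        out = pd.DataFrame(rows, index=df.index, columns=list(RANKS))
    elif df.shape[1] == len(RANKS):
        out = df.copy()
        out.columns = list(RANKS)
        out = out.map(lambda v: None if str(v).strip() in _NA else str(v).strip())
    else:
        raise FormatError(
            f"taxonomy {path}: expected 1 lineage column or {len(RANKS)} rank columns, "
            f"got {df.shape[1]}"
        )
    out.index.name = None
    return TaxonomyTable(out)


def write_taxonomy(tax: TaxonomyTable, path) -> None:
    tax.assignments.fillna("NA").to_csv(path, sep="\t", index_label="asv_id")


def read_metadata(path) -> SampleMetadata:
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, dtype=str, keep_default_na=False)
    except Exception as exc:
        raise FormatError(f"cannot parse metadata {path}: {exc}") from exc
    if "group" not in df.columns:
        raise FormatError(f"metadata {path} lacks a 'group' column")
    df.index.name = None
    return SampleMetadata(df)


def write_metadata(meta: SampleMetadata, path) -> None:
    meta.table.to_csv(path, sep="\t", index_label="sample_id")


def read_model_catalog(path) -> ModelCatalog:
    """Read a GSMM catalog from JSON.

    Layout: ``{"models": [{"id", "rank", "name", "reactions": [...]}, ...],
    "subsystems": {"rxn": ["subsystem", ...], ...}}``. Reactions missing
    from the subsystem map fall into ``Unassigned``.
    """
    try:
        with open(path) as fh:
            data = json.load(fh)
    except (OSError, json.JSONDecodeError) as exc:
        raise FormatError(f"cannot parse model catalog {path}: {exc}") from exc
    if "models" not in data:
        raise FormatError(f"model catalog {path} lacks a 'models' array")
    models = []
    for m in data["models"]:
        try:
            models.append(
                Model(
                    model_id=str(m["id"]),
                    rank=str(m["rank"]),
                    name=str(m["name"]),
                    reactions=frozenset(map(str, m["reactions"])),
                )
            )
        except KeyError as exc:
            raise FormatError(f"model entry missing field {exc} in {path}") from exc
    subsystems = {str(k): tuple(map(str, v)) for k, v in data.get("subsystems", {}).items()}
    return ModelCatalog(models=models, subsystems=subsystems)


def write_model_catalog(catalog: ModelCatalog, path) -> None:
    data = {
        "models": [
            {
                "id": m.model_id,
                "rank": m.rank,
                "name": m.name,
                "reactions": sorted(m.reactions),
            }
            for m in catalog.models
        ],
        "subsystems": {k: list(v) for k, v in sorted(catalog.subsystems.items())},
    }
    with open(path, "w") as fh:
        json.dump(data, fh, indent=1, sort_keys=False)


def read_tree(path) -> PhyloTree:
    """Read a rooted Newick tree whose leaves are ASV ids."""
    try:
        tree = TreeNode.read(str(path), format="newick", convert_underscores=False)
    except Exception as exc:
        raise FormatError(f"cannot parse Newick tree {path}: {exc}") from exc
    return PhyloTree(tree)


def parse_tree(newick: str) -> PhyloTree:
    """Parse a Newick string (convenience for tests and examples)."""
    try:
        tree = TreeNode.read(_io.StringIO(newick), format="newick", convert_underscores=False)
    except Exception as exc:
        raise FormatError(f"cannot parse Newick string: {exc}") from exc
    return PhyloTree(tree)


def write_tree(tree: PhyloTree, path) -> None:
    tree.tree.write(str(path), format="newick")


def write_table(df: pd.DataFrame, path, index_label: str = "id") -> None:
    """Write a result table as TSV (shared by the CLI subcommands)."""
    df.to_csv(path, sep="\t", index_label=index_label)


def read_config(path) -> dict:
    """Read a YAML or JSON configuration mapping."""
    import yaml

    p = Path(path)
    try:
        with open(p) as fh:
            if p.suffix.lower() == ".json":
                data = json.load(fh)
            else:
                data = yaml.safe_load(fh)
    except Exception as exc:
        raise FormatError(f"cannot parse config {path}: {exc}") from exc
    if not isinstance(data, dict):
        raise FormatError(f"config {path} must be a mapping")
    return data
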