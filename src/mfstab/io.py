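"""Readers and writers for the tabular and tree inputs.

All tables are UTF-8 TSV with a header row (lossless for taxon names
containing spaces).  Trees are Newick, consumed through scikit-bio.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
import yaml
from skbio import TreeNode

from .design import DESIGN_COLUMNS, DesignError, ExperimentalDesign


class TableError(ValueError):
    """Raised when an abundance or function table violates its invariants."""


# ---------------------------------------------------------------------------
# design

def read_design(source) -> ExperimentalDesign:
    """Read a pot-level design table (TSV path or file-like).

    Pot ids are synthesized as ``{set_id}:{assemblage_id}`` when the column
    is absent, giving stable join keys across tables.
    """
    df = pd.read_csv(source, sep="\t", dtype=str)
    required = [c for c in DESIGN_COLUMNS if c != "pot_id"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise DesignError(f"design table is missing columns: {missing}")
    if "pot_id" not in df.columns:
        df["pot_id"] = df["set_id"] + ":" + df["assemblage_id"]
    return ExperimentalDesign(df)


def write_design(design: ExperimentalDesign, path) -> None:
    design.pots.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# abundance / function tables

def _read_matrix_tsv(source, index_name: str) -> pd.DataFrame:
    df = pd.read_csv(source, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.index.name = index_name
    return df


def read_abundances(source, tree: TreeNode | None = None,
                    design: ExperimentalDesign | None = None) -> pd.DataFrame:
    """Read a pot x taxon abundance table.

    Values are nonnegative biomasses (plants) or counts (fauna).  When a
    tree is supplied every taxon must resolve to exactly one leaf; when a
    design is supplied every row id must be a known pot.
    """
    df = _read_matrix_tsv(source, "pot_id")
    return validate_abundances(df, tree=tree, design=design)


def validate_abundances(df: pd.DataFrame, tree: TreeNode | None = None,
                        design: ExperimentalDesign | None = None) -> pd.DataFrame:
    df = df.astype(float)
    if (df.values < 0).any():
        bad = df.columns[(df.values < 0).any(axis=0)].tolist()
        raise TableError(f"negative abundances in columns: {bad}")
    zero_rows = df.index[(df.values <= 0).all(axis=1)].tolist()
    if zero_rows:
        raise TableError(f"pots with no positive abundance: {zero_rows}")
    if tree is not None:
        leaves = {t.name for t in tree.tips()}
        unresolved = sorted(set(df.columns) - leaves)
        if unresolved:
            raise TableError(f"taxa not found as tree leaves: {unresolved}")
    if design is not None:
        unknown = sorted(set(df.index) - set(design.pot_ids))
        if unknown:
            raise TableError(f"abundance rows for unknown pots: {unknown}")
    return df


def read_functions(source, expected_columns: list[str] | None = None) -> pd.DataFrame:
    """Read a pot x function-variable table; rejects missing cells."""
    df = _read_matrix_tsv(source, "pot_id").astype(float)
    if df.isna().any().any():
        bad = df.columns[df.isna().any(axis=0)].tolist()
        raise TableError(f"missing cells in function columns: {bad}")
    if expected_columns is not None and list(df.columns) != list(expected_columns):
        raise TableError(
            f"function columns {list(df.columns)} do not match the configured "
            f"list {list(expected_columns)}")
    return df


def write_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# trees

def read_tree(source) -> TreeNode:
    """Read a rooted Newick tree; branch lengths must be nonnegative."""
    tree = TreeNode.read(str(source) if isinstance(source, Path) else source,
                         format="newick")
    for node in tree.traverse(include_self=False):
        if node.length is not None and node.length < 0:
            raise TableError(f"negative branch length on node {node.name!r}")
    return tree


def write_tree(tree: TreeNode, path) -> None:
    tree.write(str(path), format="newick")


# ---------------------------------------------------------------------------
# run configuration

def read_run_config(path) -> dict:
    """Load a YAML/JSON run configuration into a plain dict."""
    text = Path(path).read_text()
    if str(path).endswith(".json"):
        return json.loads(text)
    return yaml.safe_load(text)
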