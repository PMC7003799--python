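"""OTU-table I/O and the standard pre-analysis filter chain.

Community tables are pandas DataFrames with samples as the index and taxa
(OTU identifiers) as columns, holding non-negative integer counts.  On disk
the conventional orientation is transposed: taxa as rows, samples as
columns, with a ``#OTU ID`` header cell — the layout QIIME-era tools write.

The filter chain mirrors standard amplicon practice for bloom-microbiome
surveys: drop taxa annotated as eukaryote/archaea/chloroplast/mitochondria,
drop taxa below a total-count floor, remove the host (cyanobacterial)
lineage, rarefy every sample to a common depth, then pool field replicates
per site.
"""

from __future__ import annotations

import warnings
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from skbio import TreeNode

__all__ = [
    "read_otu_table",
    "write_otu_table",
    "read_taxonomy",
    "write_taxonomy",
    "read_coordinates",
    "write_coordinates",
    "read_tree",
    "write_tree",
    "filter_by_taxonomy",
    "filter_low_abundance",
    "remove_group",
    "rarefy",
    "pool_replicates",
    "prune_tree_to_table",
]

OTU_HEADER = "#OTU ID"

# The exclusion list applied to amplicon tables before any analysis.
DEFAULT_EXCLUDED_TERMS = frozenset(
    {"eukaryota", "eukaryote", "archaea", "chloroplast", "mitochondria"}
)


class TableParseError(ValueError):
    """Raised when an on-disk table violates the format contract."""


def _validate_table(table: pd.DataFrame) -> pd.DataFrame:
    if table.shape[0] < 1 or table.shape[1] < 1:
        raise TableParseError("community table needs at least one sample and one taxon")
    if table.index.duplicated().any():
        dup = table.index[table.index.duplicated()][0]
        raise TableParseError(f"duplicate sample id: {dup!r}")
    if table.columns.duplicated().any():
        dup = table.columns[table.columns.duplicated()][0]
        raise TableParseError(f"duplicate taxon id: {dup!r}")
    if (table.values < 0).any():
        taxon = table.columns[np.argwhere(table.values < 0)[0, 1]]
        raise TableParseError(f"negative count in taxon {taxon!r}")
    return table


def read_otu_table(path) -> pd.DataFrame:
    """Read a taxa-by-samples TSV (``#OTU ID`` header) into samples x taxa."""
    try:
        raw = pd.read_csv(path, sep="\t", header=0, index_col=0, dtype=str)
    except pd.errors.ParserError as exc:  # ragged rows etc.
        raise TableParseError(f"malformed OTU table {path}: {exc}") from exc
    if raw.index.name != OTU_HEADER:
        raise TableParseError(
            f"{path}: first header cell must be {OTU_HEADER!r}, got {raw.index.name!r}"
        )
    if raw.isna().any().any():
        row = raw.index[raw.isna().any(axis=1)][0]
        raise TableParseError(f"{path}: ragged or empty field in row {row!r}")
    try:
        counts = raw.astype(np.int64)
    except ValueError as exc:
        raise TableParseError(f"{path}: non-integer count ({exc})") from exc
    if ((raw != counts.astype(str)).to_numpy()).any():
        bad = raw.index[(raw != counts.astype(str)).any(axis=1)][0]
        raise TableParseError(f"{path}: non-integer count in row {bad!r}")
    table = counts.T
    table.index.name = "sample"
    table.columns.name = "taxon"
    return _validate_table(table)


def write_otu_table(table: pd.DataFrame, path) -> None:
    _validate_table(table)
    out = table.T.astype(np.int64)
    out.index.name = OTU_HEADER
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        out.to_csv(fh, sep="\t", lineterminator="\n")


def read_taxonomy(path) -> pd.DataFrame:
    """Read a taxonomy TSV: taxon_id, semicolon-joined lineage[, confidence].

    Returns a DataFrame indexed by taxon id with columns ``lineage`` (the
    raw semicolon string) and ``confidence`` (float, NaN when absent).
    """
    df = pd.read_csv(path, sep="\t", header=0, dtype={0: str, 1: str})
    df = df.rename(
        columns={df.columns[0]: "taxon_id", df.columns[1]: "lineage"}
    )
    if "confidence" not in df.columns:
        df["confidence"] = np.nan
    if df["taxon_id"].duplicated().any():
        dup = df["taxon_id"][df["taxon_id"].duplicated()].iloc[0]
        raise TableParseError(f"{path}: duplicate taxon id {dup!r}")
    if (df["lineage"].fillna("").str.strip() == "").any():
        bad = df.loc[df["lineage"].fillna("").str.strip() == "", "taxon_id"].iloc[0]
        raise TableParseError(f"{path}: empty lineage for taxon {bad!r}")
    return df.set_index("taxon_id")[["lineage", "confidence"]]


def write_taxonomy(taxonomy: pd.DataFrame, path) -> None:
    out = taxonomy.reset_index()
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        out.to_csv(fh, sep="\t", index=False, lineterminator="\n")


def read_coordinates(path) -> pd.DataFrame:
    """Read a site,latitude,longitude CSV (decimal degrees) indexed by site."""
    df = pd.read_csv(path, dtype={0: str})
    df = df.rename(columns={df.columns[0]: "site"}).set_index("site")
    _check_coordinates(df)
    return df[["latitude", "longitude"]]


def _check_coordinates(df: pd.DataFrame) -> None:
    for col, lo, hi in (("latitude", -90.0, 90.0), ("longitude", -180.0, 180.0)):
        if col not in df.columns:
            raise TableParseError(f"coordinates missing column {col!r}")
        bad = df.index[(df[col] < lo) | (df[col] > hi) | df[col].isna()]
        if len(bad):
            raise ValueError(f"{col} out of [{lo}, {hi}] for site {bad[0]!r}")


def write_coordinates(geo: pd.DataFrame, path) -> None:
    _check_coordinates(geo)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        geo.reset_index().to_csv(fh, index=False, lineterminator="\n")


def read_tree(path) -> TreeNode:
    tree = TreeNode.read(str(path), format="newick")
    tips = [t.name for t in tree.tips()]
    if len(tips) != len(set(tips)):
        raise ValueError(f"{path}: duplicate tip labels")
    return tree


def write_tree(tree: TreeNode, path) -> None:
    tree.write(str(path), format="newick")


def lineage_ranks(lineage: str) -> list[str]:
    """Split a semicolon lineage into cleaned rank names.

    Rank prefixes such as ``d__``/``p__`` are stripped so exclusion terms
    compare against bare names.
    """
    ranks = []
    for part in str(lineage).split(";"):
        part = part.strip()
        if len(part) > 3 and part[1:3] == "__":
            part = part[3:]
        if part:
            ranks.append(part)
    return ranks


def _matching_taxa(
    table: pd.DataFrame,
    taxonomy: pd.DataFrame,
    terms: Iterable[str],
    missing: str,
) -> list:
    """Taxa whose lineage has a rank exactly equal (case-insensitively) to a term.

    Matching is exact per rank, never substring, so excluding "bacteria"
    cannot drop e.g. Melainabacteria.
    """
    terms_lc = {str(t).lower() for t in terms}
    hit, absent = [], []
    for taxon in table.columns:
        if taxon not in taxonomy.index:
            absent.append(taxon)
            continue
        ranks = {r.lower() for r in lineage_ranks(taxonomy.at[taxon, "lineage"])}
        if ranks & terms_lc:
            hit.append(taxon)
    if absent:
        if missing == "drop":
            warnings.warn(
                f"{len(absent)} taxa lack taxonomy records and were dropped "
                f"(first: {absent[0]!r})",
                stacklevel=3,
            )
            hit.extend(absent)
        elif missing != "keep":
            raise ValueError(f"missing must be 'drop' or 'keep', got {missing!r}")
    return hit


def filter_by_taxonomy(
    table: pd.DataFrame,
    taxonomy: pd.DataFrame,
    excluded_terms: Iterable[str] = DEFAULT_EXCLUDED_TERMS,
    missing: str = "drop",
) -> pd.DataFrame:
    """Remove taxa whose lineage contains any excluded term at any rank."""
    drop = _matching_taxa(table, taxonomy, excluded_terms, missing)
    return table.drop(columns=drop)


def remove_group(
    table: pd.DataFrame,
    taxonomy: pd.DataFrame,
    group_term: str = "Cyanobacteria",
    missing: str = "keep",
) -> pd.DataFrame:
    """Remove one named lineage group (default: the cyanobacterial host clade)."""
    drop = _matching_taxa(table, taxonomy, [group_term], missing)
    return table.drop(columns=drop)


def filter_low_abundance(table: pd.DataFrame, min_total: int = 100) -> pd.DataFrame:
    """Keep taxa whose count summed across samples is at least ``min_total``."""
    if min_total < 0:
        raise ValueError("min_total must be >= 0")
    keep = table.columns[table.sum(axis=0) >= min_total]
    return table[keep]


def rarefy(table: pd.DataFrame, depth: int | str = "min", seed: int = 0) -> pd.DataFrame:
    """Subsample every sample without replacement to a common depth.

    ``depth="min"`` resolves to the smallest sample total, the usual choice
    when no external depth is imposed.  Taxa left with zero counts in every
    sample are dropped.  A single draw per sample; deterministic given seed.
    """
    _validate_table(table)
    totals = table.sum(axis=1)
    if depth == "min":
        depth = int(totals.min())
    depth = int(depth)
    short = totals.index[totals < depth]
    if len(short):
        raise ValueError(
            f"rarefaction depth {depth} exceeds total of sample {short[0]!r} "
            f"({int(totals[short[0]])})"
        )
    rng = np.random.default_rng(seed)
    out = np.empty(table.shape, dtype=np.int64)
    counts = table.to_numpy(dtype=np.int64)
    for i in range(table.shape[0]):
        out[i] = rng.multivariate_hypergeometric(counts[i], depth)
    rarefied = pd.DataFrame(out, index=table.index, columns=table.columns)
    return rarefied.loc[:, rarefied.sum(axis=0) > 0]


def pool_replicates(table: pd.DataFrame, mapping: Mapping[str, str]) -> pd.DataFrame:
    """Sum replicate samples into their site; output rows are sites."""
    unmapped = [s for s in table.index if s not in mapping]
    if unmapped:
        raise ValueError(f"samples not mapped to a site: {unmapped}")
    sites = pd.Series({s: mapping[s] for s in table.index}, name="site")
    pooled = table.groupby(sites, sort=False).sum()
    pooled.index.name = "sample"
    return pooled


def prune_tree_to_table(tree: TreeNode, table: pd.DataFrame) -> TreeNode:
    """Restrict the tree to the table's taxa; patristic distances unchanged."""
    tips = {t.name for t in tree.tips()}
    missing = sorted(set(table.columns) - tips)
    if missing:
        raise ValueError(f"taxa missing from tree: {missing}")
    pruned = tree.shear(list(table.columns))
    pruned.prune()
    return pruned
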