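"""Readers/writers for the formats the pipeline touches.

Feature tables are plain TSV (one header row, first column = identifier),
optionally preceded by ``#`` comment lines as written by the BIOM TSV export
dialect (a ``#OTU ID``-style line immediately before the data is treated as
the header).  Counts are strict non-negative integers: the Morisita index is
undefined on non-integer counts, so integrality is enforced here at the
boundary rather than deep inside the metric code.

Trees are single-tree Newick files; binary/HDF5 BIOM is deliberately not
supported.
"""

from __future__ import annotations

import io as _io
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal

import numpy as np
import pandas as pd

from .errors import CongruenceError, FormatError
from .tree import Phylogeny

__all__ = [
    "FeatureTable",
    "SampleMetadata",
    "read_feature_table",
    "read_newick",
    "read_metadata",
    "align_table_and_tree",
    "write_tidy",
]


@dataclass
class FeatureTable:
    """Sample-by-taxon count matrix.

    ``counts[i, j]`` is the number of reads of taxon ``taxon_ids[j]`` in
    sample ``sample_ids[i]``; rows are samples throughout the package.
    """

    sample_ids: list[str]
    taxon_ids: list[str]
    counts: np.ndarray  # (n_samples, n_taxa) int64

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise FormatError("counts must be a 2-D matrix")
        if self.counts.shape != (len(self.sample_ids), len(self.taxon_ids)):
            raise FormatError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.taxon_ids)} taxa"
            )
        if not np.issubdtype(self.counts.dtype, np.integer):
            as_int = np.asarray(self.counts).astype(np.int64, casting="unsafe")
            if not np.array_equal(as_int, self.counts):
                raise FormatError("counts must be integers")
            self.counts = as_int
        else:
            self.counts = self.counts.astype(np.int64)
        if np.any(self.counts < 0):
            i, j = np.argwhere(self.counts < 0)[0]
            raise FormatError(
                f"negative count at sample {self.sample_ids[i]!r}, "
                f"taxon {self.taxon_ids[j]!r}"
            )
        for name, ids in (("sample", self.sample_ids), ("taxon", self.taxon_ids)):
            if len(set(ids)) != len(ids):
                seen: set[str] = set()
                dup = next(x for x in ids if x in seen or seen.add(x))
                raise FormatError(f"duplicate {name} id: {dup!r}")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_taxa(self) -> int:
        return len(self.taxon_ids)

    def library_sizes(self) -> np.ndarray:
        """Per-sample read depths N_i."""
        return self.counts.sum(axis=1)

    def relative_abundances(self) -> np.ndarray:
        """Row-normalized counts; all-zero rows stay all-zero."""
        totals = self.library_sizes().astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            rel = self.counts / totals[:, None]
        rel[totals == 0] = 0.0
        return rel

    def occupancy(self) -> np.ndarray:
        """Per-taxon prevalence o_j = fraction of samples with a count > 0."""
        return (self.counts > 0).mean(axis=0)

    def select_samples(self, idx: Iterable[int]) -> "FeatureTable":
        idx = list(idx)
        return FeatureTable(
            [self.sample_ids[i] for i in idx], list(self.taxon_ids), self.counts[idx]
        )

    def select_taxa(self, idx: Iterable[int]) -> "FeatureTable":
        idx = list(idx)
        return FeatureTable(
            list(self.sample_ids), [self.taxon_ids[j] for j in idx], self.counts[:, idx]
        )

    def drop_empty_taxa(self) -> "FeatureTable":
        keep = np.flatnonzero(self.counts.sum(axis=0) > 0)
        return self.select_taxa(keep)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.sample_ids, columns=self.taxon_ids)


@dataclass
class SampleMetadata:
    """Maps each sample to its dataset (host species / study) label."""

    dataset_label: dict[str, str] = field(default_factory=dict)

    def label_for(self, sample_id: str, default: str = "data") -> str:
        return self.dataset_label.get(sample_id, default)


def read_feature_table(
    path: str | Path,
    orientation: Literal["samples-as-rows", "taxa-as-rows"] = "taxa-as-rows",
) -> FeatureTable:
    """Read a TSV count table.

    ``taxa-as-rows`` (the default, matching BIOM TSV exports) expects one row
    per taxon and one column per sample; ``samples-as-rows`` the transpose.
    Leading ``#`` comment lines are skipped; a final ``#``-prefixed line
    containing tabs (the ``#OTU ID`` header of the BIOM dialect) is used as
    the header.
    """
    if orientation not in ("samples-as-rows", "taxa-as-rows"):
        raise FormatError(f"unknown orientation {orientation!r}")
    raw = Path(path).read_text(encoding="utf-8").splitlines()
    start = 0
    while start < len(raw) and raw[start].startswith("#"):
        start += 1
    if start > 0 and "\t" in raw[start - 1]:
        header = raw[start - 1].lstrip("#").lstrip()
        lines = [header] + raw[start:]
    else:
        lines = raw[start:]
    if not lines:
        raise FormatError(f"{path}: no table content found")
    try:
        df = pd.read_csv(_io.StringIO("\n".join(lines)), sep="\t", index_col=0)
    except Exception as exc:
        raise FormatError(f"{path}: could not parse TSV: {exc}") from exc
    if orientation == "taxa-as-rows":
        df = df.T  # -> samples as rows
    sample_ids = [str(s) for s in df.index]
    taxon_ids = [str(t) for t in df.columns]
    values = df.to_numpy()
    numeric = pd.to_numeric(pd.Series(values.ravel()), errors="coerce").to_numpy()
    bad = np.flatnonzero(~np.isfinite(numeric))
    if bad.size:
        i, j = divmod(int(bad[0]), len(taxon_ids))
        raise FormatError(
            f"{path}: non-numeric cell at sample {sample_ids[i]!r}, "
            f"taxon {taxon_ids[j]!r}"
        )
    numeric = numeric.reshape(values.shape)
    frac = np.modf(numeric)[0]
    nonint = np.flatnonzero(np.abs(frac.ravel()) > 0)
    if nonint.size:
        i, j = divmod(int(nonint[0]), len(taxon_ids))
        raise FormatError(
            f"{path}: non-integer count {numeric[i, j]} at sample "
            f"{sample_ids[i]!r}, taxon {taxon_ids[j]!r}"
        )
    if np.any(numeric < 0):
        i, j = np.argwhere(numeric < 0)[0]
        raise FormatError(
            f"{path}: negative count at sample {sample_ids[i]!r}, "
            f"taxon {taxon_ids[j]!r}"
        )
    return FeatureTable(sample_ids, taxon_ids, numeric.astype(np.int64))


def read_newick(path: str | Path) -> Phylogeny:
    """Read a single rooted tree with branch lengths from a Newick file."""
    text = Path(path).read_text(encoding="utf-8").strip()
    if not text:
        raise FormatError(f"{path}: empty Newick file")
    return Phylogeny.from_newick(text)


def read_metadata(path: str | Path) -> SampleMetadata:
    """Read sample metadata TSV with columns ``sample_id``, ``dataset_label``."""
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    for col in ("sample_id", "dataset_label"):
        if col not in df.columns:
            raise FormatError(f"{path}: metadata is missing column {col!r}")
    if df["sample_id"].duplicated().any():
        dup = df.loc[df["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise FormatError(f"{path}: duplicate sample_id {dup!r}")
    return SampleMetadata(dict(zip(df["sample_id"], df["dataset_label"])))


def align_table_and_tree(
    table: FeatureTable,
    tree: Phylogeny,
    policy: Literal["error", "prune-tree", "drop-taxa"] = "error",
) -> tuple[FeatureTable, Phylogeny]:
    """Reconcile the table's taxon set with the tree's leaf set.

    ``error``       — raise if any table taxon is missing from the tree.
    ``prune-tree``  — additionally prune tree leaves absent from the table
                      (collapsing unifurcations; pairwise paths preserved).
    ``drop-taxa``   — drop table taxa that are not tree leaves.
    """
    leaves = set(tree.leaf_labels)
    taxa = set(table.taxon_ids)
    missing = taxa - leaves
    if policy == "error":
        if missing:
            raise CongruenceError(
                f"{len(missing)} table taxa absent from tree, e.g. "
                f"{sorted(missing)[:5]}"
            )
        return table, tree
    if policy == "prune-tree":
        if missing:
            raise CongruenceError(
                f"cannot prune: {len(missing)} table taxa absent from tree, "
                f"e.g. {sorted(missing)[:5]}"
            )
        if taxa == leaves:
            return table, tree
        return table, tree.prune_to(table.taxon_ids)
    if policy == "drop-taxa":
        keep = [j for j, t in enumerate(table.taxon_ids) if t in leaves]
        if not keep:
            raise CongruenceError("no table taxon is a tree leaf")
        return table.select_taxa(keep), tree
    raise FormatError(f"unknown policy {policy!r}")


def _fmt(value: object) -> str:
    if isinstance(value, float) or isinstance(value, np.floating):
        if isinstance(value, float) and math.isnan(value):
            return "NA"
        return f"{value:.10g}"
    return str(value)


def write_tidy(
    records: pd.DataFrame,
    path: str | Path,
    header_comment: str | None = None,
    sort: bool = True,
) -> None:
    """Write a tidy TSV: header row, deterministic row order, floats at 10
    significant digits, NaN serialized as ``NA``.

    Rows are sorted by every non-float column (left to right) so repeated
    runs produce byte-identical files.
    """
    df = records.copy()
    if sort and len(df):
        keys = [c for c in df.columns if not pd.api.types.is_float_dtype(df[c])]
        if keys:
            df = df.sort_values(keys, kind="mergesort").reset_index(drop=True)
    with open(path, "w", encoding="utf-8") as fh:
        if header_comment:
            for line in header_comment.splitlines():
                fh.write(f"# {line}\n")
        fh.write("\t".join(map(str, df.columns)) + "\n")
        for row in df.itertuples(index=False):
            fh.write("\t".join(_fmt(v) for v in row) + "\n")


def read_tidy(path: str | Path) -> pd.DataFrame:
    """Re-read a file produced by :func:`write_tidy`."""
    return pd.read_csv(path, sep="\t", comment="#", na_values=["NA"])
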