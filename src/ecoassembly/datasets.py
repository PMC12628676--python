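"""Core data containers, file IO, cross-reference validation and sample filters.

The central object is :class:`CommunityTable`, a samples x OTUs matrix of read
counts.  Sample design metadata live in a :class:`SampleFrame`; the phylogeny
is a rooted, branch-length-bearing :class:`skbio.TreeNode` whose tips are OTU
ids.  All identifier matching is exact string equality — no trimming or case
folding — so data errors surface instead of being silently papered over.

Canonical table orientation is samples-as-rows; loaders can transpose.
"""

from __future__ import annotations

import io as _io
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import skbio

from ._seeding import substream
from .exceptions import CrossReferenceError, DataValidationError, ParameterError

__all__ = [
    "CommunityTable",
    "SampleFrame",
    "ValidationReport",
    "load_community_table",
    "read_newick",
    "write_newick",
    "load_sample_frame",
    "load_environment_table",
    "validate_dataset",
    "rarefy",
    "filter_low_abundance",
]

HABITATS = ("sediment", "water")


class CommunityTable:
    """Samples x OTUs matrix of non-negative integer read counts.

    Parameters
    ----------
    data : pandas.DataFrame
        Rows indexed by sample id, columns by OTU id, integer counts.

    Notes
    -----
    Construction validates uniqueness of both id axes and non-negativity of
    every cell; values are coerced to int64.  Column order is preserved and
    stable under TSV round-trip.
    """

    def __init__(self, data: pd.DataFrame):
        if data.index.duplicated().any():
            dups = sorted(set(data.index[data.index.duplicated()]))
            raise DataValidationError(f"duplicated sample ids: {dups}")
        if data.columns.duplicated().any():
            dups = sorted(set(data.columns[data.columns.duplicated()]))
            raise DataValidationError(f"duplicated OTU ids: {dups}")
        values = data.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise DataValidationError("community table contains non-numeric cells")
        if np.any(~np.isfinite(values.astype(float))):
            raise DataValidationError("community table contains non-finite cells")
        if np.any(values < 0):
            raise DataValidationError("community table contains negative counts")
        if np.any(values != np.floor(values)):
            raise DataValidationError("community table contains non-integer counts")
        self.data = data.astype(np.int64)
        self.data.index = self.data.index.astype(str)
        self.data.columns = self.data.columns.astype(str)

    # -- basic accessors ---------------------------------------------------
    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def otu_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def counts(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def sample_sums(self) -> pd.Series:
        return self.data.sum(axis=1)

    def relative_abundance(self) -> pd.DataFrame:
        """Per-sample relative abundances; zero-sum rows raise."""
        sums = self.sample_sums
        zero = sums[sums == 0]
        if len(zero):
            raise DataValidationError(f"zero-sum samples: {list(zero.index)}")
        return self.data.div(sums, axis=0)

    def subset_samples(self, ids) -> "CommunityTable":
        return CommunityTable(self.data.loc[list(ids)])

    def subset_otus(self, ids) -> "CommunityTable":
        return CommunityTable(self.data[list(ids)])

    def drop_empty_otus(self) -> "CommunityTable":
        keep = self.data.columns[self.data.sum(axis=0) > 0]
        return CommunityTable(self.data[keep])

    def __eq__(self, other) -> bool:
        return isinstance(other, CommunityTable) and self.data.equals(other.data)

    def __repr__(self) -> str:
        return f"<CommunityTable {self.data.shape[0]} samples x {self.data.shape[1]} OTUs>"

    # -- IO ----------------------------------------------------------------
    def to_tsv(self, path) -> None:
        self.data.to_csv(path, sep="\t", index_label="sample_id")


class SampleFrame:
    """Per-sample design metadata: ecosystem, year, habitat, replicate, site.

    Wraps a DataFrame indexed by sample id with the columns below.  The
    combination (ecosystem, year, habitat, replicate) identifies a sample
    within a habitat analysis.
    """

    REQUIRED = ("ecosystem", "year", "habitat", "replicate", "latitude", "longitude", "date")

    def __init__(self, data: pd.DataFrame):
        missing = [c for c in self.REQUIRED if c not in data.columns]
        if missing:
            raise DataValidationError(f"sample metadata missing columns: {missing}")
        if data.index.duplicated().any():
            dups = sorted(set(data.index[data.index.duplicated()]))
            raise DataValidationError(f"duplicated sample ids in metadata: {dups}")
        bad_hab = sorted(set(data["habitat"]) - set(HABITATS))
        if bad_hab:
            raise DataValidationError(f"unknown habitat values: {bad_hab} (expected {HABITATS})")
        lat = data["latitude"].astype(float)
        lon = data["longitude"].astype(float)
        if ((lat < -90) | (lat > 90)).any():
            raise DataValidationError("latitude outside [-90, 90]")
        if ((lon < -180) | (lon > 180)).any():
            raise DataValidationError("longitude outside [-180, 180]")
        self.data = data.copy()
        self.data.index = self.data.index.astype(str)
        self.data["year"] = self.data["year"].astype(int)
        self.data["latitude"] = lat
        self.data["longitude"] = lon

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    def subset(self, ids) -> "SampleFrame":
        return SampleFrame(self.data.loc[list(ids)])

    def habitat_samples(self, habitat: str) -> list[str]:
        return list(self.data.index[self.data["habitat"] == habitat])

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index_label="sample_id")

    def __repr__(self) -> str:
        return f"<SampleFrame {len(self.data)} samples>"


@dataclass
class ValidationReport:
    """Cross-reference findings between table, metadata and tree."""

    samples_missing_metadata: list[str] = field(default_factory=list)
    metadata_missing_samples: list[str] = field(default_factory=list)
    otus_missing_from_tree: list[str] = field(default_factory=list)
    zero_sum_samples: list[str] = field(default_factory=list)
    zero_sum_otus: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not (
            self.samples_missing_metadata
            or self.otus_missing_from_tree
            or self.zero_sum_samples
            or self.zero_sum_otus
        )


# ---------------------------------------------------------------------------
# Loaders


def load_community_table(path, format: str = "tsv", samples_as_rows: bool | None = None) -> CommunityTable:
    """Read an OTU table from TSV (first column = sample id, header = OTU ids)
    or BIOM v1 JSON.

    ``samples_as_rows=None`` auto-detects orientation for TSV by preferring the
    axis whose labels look like OTU ids is larger; pass True/False to force.
    """
    if format == "tsv":
        df = pd.read_csv(path, sep="\t", index_col=0)
        bad = df.map(lambda v: not (isinstance(v, (int, np.integer)) or (isinstance(v, float) and float(v).is_integer())))
        if bad.to_numpy().any():
            r, c = np.argwhere(bad.to_numpy())[0]
            raise DataValidationError(
                f"non-integer cell at row '{df.index[r]}', column '{df.columns[c]}'"
            )
        if samples_as_rows is False:
            df = df.T
        elif samples_as_rows is None and df.shape[0] > df.shape[1]:
            # More rows than columns usually means OTUs-as-rows dumps.
            df = df.T
        df.index.name = "sample_id"
        return CommunityTable(df)
    if format == "biom":
        return _load_biom_json(path)
    raise ParameterError(f"unknown format: {format!r}")


def _load_biom_json(path) -> CommunityTable:
    """Minimal reader for BIOM format v1.0 (JSON): dense or sparse matrices.

    BIOM stores OTUs as rows and samples as columns; the result is transposed
    into the package's canonical samples-as-rows orientation.
    """
    with open(path) as fh:
        doc = json.load(fh)
    otu_ids = [r["id"] for r in doc["rows"]]
    sample_ids = [c["id"] for c in doc["columns"]]
    shape = tuple(doc["shape"])
    mat = np.zeros(shape, dtype=np.int64)
    if doc.get("matrix_type") == "dense":
        mat[:] = np.asarray(doc["data"])
    else:
        for r, c, v in doc["data"]:
            mat[int(r), int(c)] = v
    df = pd.DataFrame(mat.T, index=sample_ids, columns=otu_ids)
    df.index.name = "sample_id"
    return CommunityTable(df)


def read_newick(path_or_str) -> skbio.TreeNode:
    """Read a rooted Newick tree and check branch lengths are finite and >= 0."""
    if isinstance(path_or_str, str) and path_or_str.lstrip().startswith("("):
        tree = skbio.TreeNode.read(_io.StringIO(path_or_str))
    else:
        tree = skbio.TreeNode.read(str(path_or_str))
    tips = [t.name for t in tree.tips()]
    if len(tips) != len(set(tips)):
        raise DataValidationError("tree has duplicated tip labels")
    for node in tree.traverse(include_self=False):
        bl = node.length
        if bl is None or not np.isfinite(bl) or bl < 0:
            raise DataValidationError(
                f"node {node.name!r} has invalid branch length {bl!r}"
            )
    return tree


def write_newick(tree: skbio.TreeNode, path) -> None:
    tree.write(str(path))


def load_sample_frame(path) -> SampleFrame:
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, sep=sep, index_col=0)
    return SampleFrame(df)


def load_environment_table(path) -> pd.DataFrame:
    """Samples x numeric-variables frame; missing values permitted on input."""
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, sep=sep, index_col=0)
    df.index = df.index.astype(str)
    return df.astype(float)


# ---------------------------------------------------------------------------
# Validation and sample-level filters


def validate_dataset(
    table: CommunityTable,
    meta: SampleFrame | None = None,
    tree: skbio.TreeNode | None = None,
    strict: bool = False,
) -> ValidationReport:
    """Cross-check identifiers among the table, metadata and tree.

    In strict mode any finding raises :class:`CrossReferenceError` listing the
    offending ids; otherwise the findings are returned for the caller to act
    on (e.g. dropping all-zero samples before rarefaction).
    """
    report = ValidationReport()
    if meta is not None:
        meta_ids = set(meta.sample_ids)
        tab_ids = set(table.sample_ids)
        report.samples_missing_metadata = sorted(tab_ids - meta_ids)
        report.metadata_missing_samples = sorted(meta_ids - tab_ids)
    if tree is not None:
        tips = {t.name for t in tree.tips()}
        used = set(table.data.columns[table.data.sum(axis=0) > 0])
        report.otus_missing_from_tree = sorted(used - tips)
    sums = table.sample_sums
    report.zero_sum_samples = sorted(sums.index[sums == 0])
    csums = table.data.sum(axis=0)
    report.zero_sum_otus = sorted(csums.index[csums == 0])
    if strict and not report.ok:
        raise CrossReferenceError(
            "dataset cross-reference failure: "
            f"samples without metadata={report.samples_missing_metadata}, "
            f"OTUs absent from tree={report.otus_missing_from_tree}, "
            f"zero-sum samples={report.zero_sum_samples}, "
            f"zero-sum OTUs={report.zero_sum_otus}"
        )
    return report


def rarefy(table: CommunityTable, depth: int, seed: int = 0) -> tuple[CommunityTable, list[str]]:
    """Subsample every sample to exactly ``depth`` reads without replacement.

    Uses a single multivariate-hypergeometric draw per sample.  Samples with
    fewer than ``depth`` total reads are dropped and returned in the second
    element, mirroring the removal of shallow libraries before rarefaction.
    """
    if depth < 1:
        raise ParameterError(f"rarefaction depth must be >= 1, got {depth}")
    rng = substream(seed, "rarefy")
    sums = table.sample_sums
    dropped = [s for s in table.sample_ids if sums[s] < depth]
    kept = [s for s in table.sample_ids if sums[s] >= depth]
    rows = []
    for s in kept:
        counts = table.data.loc[s].to_numpy()
        if counts.sum() == depth:
            rows.append(counts)
        else:
            rows.append(rng.multivariate_hypergeometric(counts, depth))
    out = pd.DataFrame(np.asarray(rows, dtype=np.int64), index=kept, columns=table.otu_ids)
    out.index.name = "sample_id"
    return CommunityTable(out), dropped


def filter_low_abundance(table: CommunityTable, min_rel_abund: float) -> CommunityTable:
    """Drop OTUs whose table-wide relative abundance is strictly below threshold.

    The comparison is strict ``<`` on total reads over the whole table, so an
    OTU sitting exactly at the threshold is retained.
    """
    if not 0 <= min_rel_abund < 1:
        raise ParameterError(f"min_rel_abund must be in [0, 1), got {min_rel_abund}")
    totals = table.data.sum(axis=0)
    grand = totals.sum()
    if grand == 0:
        raise DataValidationError("cannot filter an all-zero table")
    keep = totals.index[(totals / grand) >= min_rel_abund]
    return CommunityTable(table.data[list(keep)])
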