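"""Feature-table and metadata I/O, validation, and rarefaction.

Count tables are held as dense samples-by-features integer matrices
(:class:`FeatureTable`); sample metadata as a validated pandas frame
(:class:`MetadataTable`).  Supported on-disk formats are plain TSV and
BIOM 2.1 (HDF5, read and written directly through h5py).
"""

from __future__ import annotations

import datetime
import warnings
from dataclasses import dataclass, field

import h5py
import numpy as np
import pandas as pd
import scipy.sparse as sp

__all__ = [
    "FeatureTable",
    "MetadataTable",
    "FeatureTableError",
    "MetadataError",
    "read_feature_table",
    "read_sample_metadata",
    "rarefy_table",
    "write_feature_table",
    "write_results",
]

REQUIRED_METADATA_COLUMNS = ("sample_id", "subject_id", "cohort_id", "group", "age", "sex")
VALID_GROUPS = frozenset({"case", "control"})
VALID_SEXES = frozenset({"M", "F"})


class FeatureTableError(ValueError):
    """Raised when a count table violates its invariants or fails to parse."""


class MetadataError(ValueError):
    """Raised when a metadata table violates its schema or invariants."""


@dataclass
class FeatureTable:
    """Nonnegative integer counts for ``d`` features across samples.

    Parameters
    ----------
    counts:
        ``(n_samples, d)`` array of nonnegative integers.
    sample_ids, feature_ids:
        Unique string identifiers for the rows and columns of ``counts``.
    taxonomy:
        Optional taxonomy string per feature.
    """

    counts: np.ndarray
    sample_ids: list[str]
    feature_ids: list[str]
    taxonomy: list[str] | None = None

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        if counts.ndim != 2:
            raise FeatureTableError(f"counts must be 2-D, got shape {counts.shape}")
        if counts.dtype.kind == "f":
            if not np.all(np.isfinite(counts)) or np.any(counts != np.floor(counts)):
                bad = np.argwhere(~np.isfinite(counts) | (counts != np.floor(counts)))
                i, j = bad[0]
                raise FeatureTableError(
                    f"non-integer count at sample {self.sample_ids[i]!r}, "
                    f"feature {self.feature_ids[j]!r}: {counts[i, j]!r}"
                )
            counts = counts.astype(np.int64)
        elif counts.dtype.kind not in "iu":
            raise FeatureTableError(f"counts must be numeric, got dtype {counts.dtype}")
        counts = counts.astype(np.int64)
        if np.any(counts < 0):
            i, j = np.argwhere(counts < 0)[0]
            raise FeatureTableError(
                f"negative count at sample {self.sample_ids[i]!r}, "
                f"feature {self.feature_ids[j]!r}: {counts[i, j]}"
            )
        self.counts = counts
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.feature_ids = [str(f) for f in self.feature_ids]
        for name, ids, n in (
            ("sample_ids", self.sample_ids, counts.shape[0]),
            ("feature_ids", self.feature_ids, counts.shape[1]),
        ):
            if len(ids) != n:
                raise FeatureTableError(f"{name}: {len(ids)} ids for {n} rows/columns")
            if len(set(ids)) != len(ids):
                dupes = sorted({x for x in ids if ids.count(x) > 1})
                raise FeatureTableError(f"duplicate {name}: {dupes}")
        if self.taxonomy is not None and len(self.taxonomy) != counts.shape[1]:
            raise FeatureTableError("taxonomy length must equal the number of features")

    @property
    def d(self) -> int:
        """Number of features."""
        return self.counts.shape[1]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[0]

    def totals(self) -> np.ndarray:
        """Per-sample sequencing depth (row sums)."""
        return self.counts.sum(axis=1)

    def sample_index(self, sample_id: str) -> int:
        try:
            return self.sample_ids.index(sample_id)
        except ValueError:
            raise KeyError(f"sample {sample_id!r} not in table") from None

    def select_samples(self, sample_ids: list[str]) -> "FeatureTable":
        """Return a new table restricted to ``sample_ids`` (in that order)."""
        idx = [self.sample_index(s) for s in sample_ids]
        return FeatureTable(self.counts[idx], list(sample_ids), list(self.feature_ids), self.taxonomy)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.sample_ids, columns=self.feature_ids)


@dataclass
class MetadataTable:
    """Per-sample metadata with the columns required for matching.

    Required columns: ``sample_id``, ``subject_id``, ``cohort_id``,
    ``group`` (case/control), ``age`` (years), ``sex`` (M/F).
    Optional: ``household_id``, ``timepoint``.  Extra columns are kept
    but ignored by the toolkit.

    ``timepoint_order`` declares the ordering of timepoint labels for
    longitudinal cohorts; it is never inferred lexicographically.
    """

    data: pd.DataFrame
    timepoint_order: list[str] | None = None

    def __post_init__(self) -> None:
        df = self.data.copy()
        missing = [c for c in REQUIRED_METADATA_COLUMNS if c not in df.columns]
        if missing:
            raise MetadataError(f"missing required metadata column(s): {missing}")
        df["sample_id"] = df["sample_id"].astype(str)
        if df["sample_id"].duplicated().any():
            dupes = sorted(df.loc[df["sample_id"].duplicated(), "sample_id"].unique())
            raise MetadataError(f"duplicated sample_id(s): {dupes}")
        bad_group = sorted(set(df["group"].astype(str)) - VALID_GROUPS)
        if bad_group:
            raise MetadataError(f"group values outside {{case, control}}: {bad_group}")
        bad_sex = sorted(set(df["sex"].astype(str)) - VALID_SEXES)
        if bad_sex:
            raise MetadataError(f"sex values outside {{M, F}}: {bad_sex}")
        age = pd.to_numeric(df["age"], errors="coerce")
        bad = df.loc[~np.isfinite(age) | (age < 0), "sample_id"].tolist()
        if bad:
            raise MetadataError(f"unparseable or negative age for sample_id(s): {bad}")
        df["age"] = age.astype(float)
        self.data = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.data)

    @property
    def sample_ids(self) -> list[str]:
        return self.data["sample_id"].tolist()

    def row(self, sample_id: str) -> pd.Series:
        hit = self.data[self.data["sample_id"] == sample_id]
        if hit.empty:
            raise KeyError(f"sample {sample_id!r} not in metadata")
        return hit.iloc[0]

    def select(self, sample_ids: list[str]) -> "MetadataTable":
        sub = self.data[self.data["sample_id"].isin(set(sample_ids))]
        return MetadataTable(sub.copy(), self.timepoint_order)


# ---------------------------------------------------------------------------
# readers / writers


def read_feature_table(
    path,
    dialect: str = "tsv",
    orientation: str = "features-as-rows",
) -> FeatureTable:
    """Read a count table from TSV or BIOM 2.1 (HDF5).

    TSV tables default to the prevalent microbiome convention of features
    as rows and samples as columns; pass ``orientation="samples-as-rows"``
    to override.  BIOM files carry their own orientation.
    """
    if dialect == "biom":
        return _read_biom(path)
    if dialect != "tsv":
        raise ValueError(f"unknown dialect {dialect!r}; expected 'biom' or 'tsv'")
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, comment=None)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise FeatureTableError(f"could not parse TSV table {path}: {exc}") from exc
    for col in df.columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        if coerced.isna().any():
            row = df.index[coerced.isna()][0]
            raise FeatureTableError(f"non-numeric count at row {row!r}, column {col!r}")
        df[col] = coerced
    if orientation == "features-as-rows":
        df = df.T
    elif orientation != "samples-as-rows":
        raise ValueError(f"unknown orientation {orientation!r}")
    return FeatureTable(df.to_numpy(), list(df.index.astype(str)), list(df.columns.astype(str)))


def write_feature_table(
    table: FeatureTable,
    path,
    dialect: str = "tsv",
    orientation: str = "features-as-rows",
) -> None:
    """Write a count table as TSV or BIOM 2.1."""
    if dialect == "biom":
        _write_biom(table, path)
        return
    df = table.to_dataframe()
    if orientation == "features-as-rows":
        df = df.T
        df.index.name = "feature_id"
    else:
        df.index.name = "sample_id"
    df.to_csv(path, sep="\t")


def _read_biom(path) -> FeatureTable:
    """Read a BIOM 2.1 HDF5 table (observation-major CSR)."""
    with h5py.File(path, "r") as h5:
        try:
            obs_ids = [x.decode() if isinstance(x, bytes) else str(x) for x in h5["observation/ids"][:]]
            samp_ids = [x.decode() if isinstance(x, bytes) else str(x) for x in h5["sample/ids"][:]]
            grp = h5["observation/matrix"]
            mat = sp.csr_matrix(
                (grp["data"][:], grp["indices"][:], grp["indptr"][:]),
                shape=(len(obs_ids), len(samp_ids)),
            )
        except KeyError as exc:
            raise FeatureTableError(f"{path} is not a BIOM 2.1 file: missing {exc}") from exc
        taxonomy = None
        if "observation/metadata/taxonomy" in h5:
            tax = h5["observation/metadata/taxonomy"][:]
            taxonomy = ["; ".join(t.decode() if isinstance(t, bytes) else str(t) for t in np.atleast_1d(row)) for row in tax]
    dense = np.asarray(mat.todense()).T  # samples x features
    return FeatureTable(dense, samp_ids, obs_ids, taxonomy)


def _write_biom(table: FeatureTable, path) -> None:
    """Write a minimal BIOM 2.1 HDF5 file (both CSR and CSC groups)."""
    obs_mat = sp.csr_matrix(table.counts.T.astype(np.float64))  # observations x samples
    samp_mat = sp.csr_matrix(table.counts.astype(np.float64))  # samples x observations
    with h5py.File(path, "w") as h5:
        h5.attrs["id"] = "matchrank feature table"
        h5.attrs["type"] = "OTU table"
        h5.attrs["format-url"] = "http://biom-format.org"
        h5.attrs["format-version"] = [2, 1]
        h5.attrs["generated-by"] = "matchrank"
        h5.attrs["creation-date"] = datetime.datetime.now().isoformat()
        h5.attrs["shape"] = [table.d, table.n_samples]
        h5.attrs["nnz"] = int(obs_mat.nnz)
        for name, ids, mat in (
            ("observation", table.feature_ids, obs_mat),
            ("sample", table.sample_ids, samp_mat),
        ):
            g = h5.create_group(name)
            g.create_dataset("ids", data=np.array(ids, dtype="S"))
            m = g.create_group("matrix")
            m.create_dataset("data", data=mat.data)
            m.create_dataset("indices", data=mat.indices.astype(np.int64))
            m.create_dataset("indptr", data=mat.indptr.astype(np.int64))
            g.create_group("metadata")
            g.create_group("group-metadata")


def read_sample_metadata(path, timepoint_order: list[str] | None = None) -> MetadataTable:
    """Read and validate a tab-delimited sample metadata table."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    return MetadataTable(df, timepoint_order=timepoint_order)


def write_sample_metadata(metadata: MetadataTable, path) -> None:
    metadata.data.to_csv(path, sep="\t", index=False)


def rarefy_table(table: FeatureTable, depth: int, seed: int) -> tuple[FeatureTable, list[str]]:
    """Subsample every sample to exactly ``depth`` reads without replacement.

    Each retained sample's counts are a multivariate-hypergeometric draw
    from its observed reads, so per-feature totals sum exactly to
    ``depth``.  Samples whose total is below ``depth`` are dropped and
    returned in the second element.  Deterministic given ``seed``.
    """
    if depth < 1:
        raise ValueError(f"rarefaction depth must be >= 1, got {depth}")
    rng = np.random.default_rng(seed)
    totals = table.totals()
    kept_rows, kept_ids, dropped = [], [], []
    for i, sid in enumerate(table.sample_ids):
        if totals[i] < depth:
            dropped.append(sid)
            continue
        kept_rows.append(rng.multivariate_hypergeometric(table.counts[i], depth))
        kept_ids.append(sid)
    if dropped:
        warnings.warn(
            f"rarefy_table dropped {len(dropped)} sample(s) below depth {depth}: {dropped}",
            stacklevel=2,
        )
    counts = np.array(kept_rows, dtype=np.int64) if kept_rows else np.zeros((0, table.d), dtype=np.int64)
    return FeatureTable(counts, kept_ids, list(table.feature_ids), table.taxonomy), dropped


def write_results(obj, path, draws_path=None) -> None:
    """Write a result object as a TSV summary.

    Accepts a :class:`~matchrank.model.PosteriorDifferentials`, a
    :class:`~matchrank.ranking.ClassificationResult`, a
    :class:`~matchrank.ranking.BalanceResult`, or any object exposing a
    ``summary`` DataFrame.  When ``draws_path`` is given and the object
    carries posterior draws, they are archived to HDF5 with one dataset
    per feature.
    """
    from .model import PosteriorDifferentials  # local import to avoid a cycle
    from .ranking import BalanceResult, ClassificationResult

    if isinstance(obj, PosteriorDifferentials) or hasattr(obj, "summary"):
        summary = obj.summary
        summary.to_csv(path, sep="\t", index=False, float_format="%.10g")
        if draws_path is not None and hasattr(obj, "chain_draws"):
            with h5py.File(draws_path, "w") as h5:
                g = h5.create_group("draws")
                arr = obj.chain_draws  # (chains, draws, d)
                for j, fid in enumerate(obj.feature_ids):
                    g.create_dataset(fid, data=arr[:, :, j])
    elif isinstance(obj, ClassificationResult):
        obj.to_frame().to_csv(path, sep="\t", index=False)
    elif isinstance(obj, BalanceResult):
        obj.to_frame().to_csv(path, sep="\t", index=False, float_format="%.10g")
    else:
        raise TypeError(f"cannot serialize object of type {type(obj).__name__}")
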