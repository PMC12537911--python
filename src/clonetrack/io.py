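"""Readers and writers for repertoire, expression, ortholog and survival tables.

This module holds no science: it parses AIRR-style rearrangement TSVs,
MatrixMarket expression triplets, two-column ortholog maps and survival
CSVs into the in-memory containers the rest of the package consumes
(:class:`RepertoireSample`, :class:`anndata.AnnData`, plain DataFrames).
Readers never mutate counts; the only transformation is the aggregation of
duplicate clonotype rows, which is logged.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import anndata as ad
import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp
import yaml

logger = logging.getLogger(__name__)

#: columns that define bulk clone identity, in canonical order
CLONE_KEY_COLS = ("v_call", "d_call", "j_call", "cdr3_nt")

#: closed vocabularies
SITES = ("left", "right", "hip", "tumor", "product")
FRACTIONS = ("unsorted", "PD1neg", "precursor", "intermediate", "terminal")
CELL_STATES = ("precursor", "intermediate", "terminal", "proliferating", "other")


class ClonetrackError(Exception):
    """Base class for all errors raised by this package."""


class RepertoireFormatError(ClonetrackError):
    """A repertoire file violates the expected AIRR-style layout."""


class EmptySampleError(ClonetrackError):
    """A repertoire file contains no clonotype rows."""


class DimensionError(ClonetrackError):
    """Matrix dimensions disagree with the gene/cell name lists."""


@dataclass
class RepertoireSample:
    """One bulk TCR-seq dataset: a sorted (or unsorted) fraction of one tumor.

    ``clonotypes`` has columns ``v_call, d_call, j_call, cdr3_nt, read_count``
    with one row per distinct clonotype.  ``cells_sorted`` is the number of
    cells that went into the library; ``cells_aliquoted_sc`` is the number
    removed beforehand for single-cell sequencing (used for the aliquot
    correction of read counts).
    """

    sample_id: str
    subject_id: str
    site: str
    day: int
    fraction: str
    clonotypes: pd.DataFrame
    cells_sorted: int = 0
    cells_aliquoted_sc: int = 0

    def __post_init__(self) -> None:
        if self.site not in SITES:
            raise ValueError(f"unknown site: {self.site!r}")
        if self.fraction not in FRACTIONS:
            raise ValueError(f"unknown fraction: {self.fraction!r}")
        if self.cells_aliquoted_sc > self.cells_sorted:
            raise ValueError("cells_aliquoted_sc exceeds cells_sorted")
        df = self.clonotypes
        missing = [c for c in (*CLONE_KEY_COLS, "read_count") if c not in df.columns]
        if missing:
            raise RepertoireFormatError(f"missing column: {missing[0]}")
        if len(df) == 0:
            raise EmptySampleError(f"sample {self.sample_id} has no clonotypes")
        if (df["read_count"] < 1).any():
            raise ValueError("read_count must be >= 1 for every row")
        if df.duplicated(subset=list(CLONE_KEY_COLS)).any():
            raise ValueError("duplicate clonotype keys within a sample")

    @property
    def total_reads(self) -> int:
        return int(self.clonotypes["read_count"].sum())


def _normalize_clonotypes(df: pd.DataFrame) -> pd.DataFrame:
    """Uppercase CDR3s, blank missing D calls, aggregate duplicate keys."""
    df = df.copy()
    df["cdr3_nt"] = df["cdr3_nt"].astype(str).str.upper()
    for col in ("v_call", "d_call", "j_call"):
        df[col] = df[col].fillna("").astype(str)
    n_zero = int((df["read_count"] <= 0).sum())
    if n_zero:
        logger.warning("dropping %d zero-count clonotype rows", n_zero)
        df = df[df["read_count"] > 0]
    before = len(df)
    df = (
        df.groupby(list(CLONE_KEY_COLS), as_index=False, sort=False)["read_count"]
        .sum()
    )
    if len(df) < before:
        logger.warning("aggregated %d duplicate clonotype rows", before - len(df))
    return df.reset_index(drop=True)


#: AIRR Rearrangement dialect column mapping (file column -> internal name)
AIRR_COLUMNS = {
    "v_call": "v_call",
    "d_call": "d_call",
    "j_call": "j_call",
    "junction": "cdr3_nt",
    "duplicate_count": "read_count",
}


def read_repertoire_tsv(
    path: str | Path,
    *,
    sample_id: str,
    subject_id: str,
    site: str,
    day: int,
    fraction: str = "unsorted",
    cells_sorted: int = 0,
    cells_aliquoted_sc: int = 0,
    column_map: Mapping[str, str] | None = None,
) -> RepertoireSample:
    """Read an AIRR-style rearrangement TSV into a :class:`RepertoireSample`.

    Required columns are ``v_call``, ``j_call``, ``junction`` (CDR3
    nucleotide sequence) and ``duplicate_count``; ``d_call`` is optional and
    treated as an empty string when absent.  Rows with identical
    (V, D, J, CDR3) keys are summed; zero-count rows are dropped with a
    logged warning.  ``column_map`` can rename non-standard exports onto the
    AIRR dialect.
    """
    colmap = dict(AIRR_COLUMNS)
    if column_map:
        colmap = {column_map.get(k, k): v for k, v in colmap.items()}
    df = pd.read_csv(path, sep="\t", dtype={c: str for c in colmap if c != "duplicate_count"})
    if len(df) == 0:
        raise EmptySampleError(f"empty repertoire file: {path}")
    for file_col, internal in colmap.items():
        if file_col not in df.columns:
            if internal == "d_call":
                df[file_col] = ""
                continue
            raise RepertoireFormatError(f"missing column: {file_col}")
    df = df.rename(columns=colmap)[[*CLONE_KEY_COLS, "read_count"]]
    df["read_count"] = pd.to_numeric(df["read_count"]).astype(np.int64)
    df = _normalize_clonotypes(df)
    if len(df) == 0:
        raise EmptySampleError(f"no positive-count clonotypes in {path}")
    return RepertoireSample(
        sample_id=sample_id,
        subject_id=subject_id,
        site=site,
        day=day,
        fraction=fraction,
        clonotypes=df,
        cells_sorted=cells_sorted,
        cells_aliquoted_sc=cells_aliquoted_sc,
    )


def write_repertoire_tsv(sample: RepertoireSample, path: str | Path) -> None:
    """Write a sample back to the AIRR dialect (inverse of the reader)."""
    inv = {v: k for k, v in AIRR_COLUMNS.items()}
    out = sample.clonotypes.rename(columns=inv)
    out.to_csv(path, sep="\t", index=False)


def read_expression_mtx(
    matrix_path: str | Path,
    genes_path: str | Path,
    cells_path: str | Path,
) -> ad.AnnData:
    """Read a coordinate MatrixMarket triplet (genes x cells) into AnnData.

    The returned AnnData is cells x genes with an integer sparse ``X``.
    Gene and cell name order is preserved from the input lists.
    """
    mat = scipy.io.mmread(str(matrix_path))
    genes = pd.read_csv(genes_path, header=None, sep="\t")[0].astype(str).tolist()
    cells = pd.read_csv(cells_path, header=None, sep="\t")[0].astype(str).tolist()
    if mat.shape != (len(genes), len(cells)):
        raise DimensionError(
            f"matrix is {mat.shape} but {len(genes)} genes and {len(cells)} cells listed"
        )
    data = np.asarray(mat.data if sp.issparse(mat) else mat).ravel()
    if data.size and not np.allclose(data, np.round(data)):
        raise ValueError("expression matrix entries must be integers")
    x = sp.csr_matrix(mat.T.astype(np.int64))
    if x.nnz and x.data.min() < 0:
        raise ValueError("expression matrix entries must be nonnegative")
    adata = ad.AnnData(X=x)
    adata.obs_names = cells
    adata.var_names = genes
    return adata


def write_expression_mtx(
    adata: ad.AnnData,
    matrix_path: str | Path,
    genes_path: str | Path,
    cells_path: str | Path,
) -> None:
    scipy.io.mmwrite(str(matrix_path), sp.coo_matrix(adata.X.T))
    pd.Series(adata.var_names).to_csv(genes_path, header=False, index=False)
    pd.Series(adata.obs_names).to_csv(cells_path, header=False, index=False)


@dataclass
class OrthologMap:
    """One-to-one human <-> mouse gene symbol map."""

    human_to_mouse: dict[str, str]
    mouse_to_human: dict[str, str]
    n_dropped: int = 0

    def translate(self, genes: Sequence[str], to: str = "mouse") -> list[str]:
        """Map gene symbols, preserving order and dropping unmapped genes."""
        table = self.human_to_mouse if to == "mouse" else self.mouse_to_human
        return [table[g] for g in genes if g in table]


def load_ortholog_map(path: str | Path) -> OrthologMap:
    """Load a two-column (human, mouse) TSV; one-to-many entries are dropped."""
    df = pd.read_csv(path, sep="\t", header=None, names=["human", "mouse"], dtype=str)
    df = df.dropna()
    if len(df) == 0:
        raise ClonetrackError(f"empty ortholog map: {path}")
    multi_h = df["human"].duplicated(keep=False)
    multi_m = df["mouse"].duplicated(keep=False)
    bad = multi_h | multi_m
    n_dropped = int(bad.sum())
    if n_dropped:
        logger.warning("dropping %d one-to-many ortholog entries", n_dropped)
    df = df[~bad]
    if len(df) == 0:
        raise ClonetrackError("no one-to-one entries in ortholog map")
    return OrthologMap(
        human_to_mouse=dict(zip(df["human"], df["mouse"])),
        mouse_to_human=dict(zip(df["mouse"], df["human"])),
        n_dropped=n_dropped,
    )


def read_survival_csv(path: str | Path) -> pd.DataFrame:
    """Read a survival table (subject_id, time, event[, response, score])."""
    df = pd.read_csv(path)
    return validate_survival(df)


def validate_survival(df: pd.DataFrame) -> pd.DataFrame:
    for col in ("subject_id", "time", "event"):
        if col not in df.columns:
            raise RepertoireFormatError(f"missing column: {col}")
    if (df["time"] <= 0).any():
        raise ValueError("survival times must be positive")
    if not df["event"].isin([0, 1]).all():
        raise ValueError("event must be 0 or 1")
    return df


@dataclass
class PipelineConfig:
    """Thresholds, scoring parameters and paths driving an end-to-end run.

    ``fdr_alpha`` gates the beta-binomial expansion calls (BH-adjusted),
    ``deg_alpha``/``stringent_alpha`` gate the signature derivation,
    ``fold_threshold`` is the single-cell cohort expansion rule, and
    ``min_precursor_cells`` is the floor for clone-level score averaging.
    """

    fdr_alpha: float = 0.05
    deg_alpha: float = 0.05
    stringent_alpha: float = 0.01
    fold_threshold: float = 1.5
    min_precursor_cells: int = 5
    n_bins: int = 25
    ctrl_size: int = 50
    seed: int = 0
    top_n_clones: int = 15
    out_dir: str = "clonetrack_out"
    ortholog_map_path: str | None = None
    signature_path: str | None = None
    repertoire_paths: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        for name in ("fdr_alpha", "deg_alpha", "stringent_alpha"):
            a = getattr(self, name)
            if not (0 < a < 1):
                raise ValueError(f"{name} must be in (0, 1)")
        if self.fold_threshold <= 1:
            raise ValueError("fold_threshold must exceed 1")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(payload) - known
        if unknown:
            raise ClonetrackError(f"unknown config keys: {sorted(unknown)}")
        return cls(**payload)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)
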