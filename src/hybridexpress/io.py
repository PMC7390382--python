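"""Counts, sample-metadata and gene-position I/O plus normalization and filtering.

The pipeline's tabular currency is a gene x sample matrix of nonnegative
integer read counts with fixed per-sample library sizes.  Library sizes are
captured once, at first read, as column sums; downstream gene filtering does
not change them unless explicitly requested, so CPM values are stable across
filtering steps.

Formats: counts as TSV (gene ids in the first column, sample ids in the
header) or MatrixMarket with plain-text gene/sample id sidecars; sample
metadata as TSV; gene positions as 4-column BED (0-based half-open).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

__all__ = [
    "CountsMatrix",
    "NormalizedMatrix",
    "CountsFormatError",
    "read_counts",
    "write_counts",
    "read_sample_table",
    "validate_sample_table",
    "read_gene_positions",
    "write_gene_positions",
    "cpm_normalize",
    "filter_min_count",
    "filter_cpm",
]

ROLES = ("P1", "P2", "F1")


class CountsFormatError(ValueError):
    """Raised when an on-disk table violates the counts-matrix contract."""


@dataclass
class CountsMatrix:
    """Nonnegative integer read counts, genes x samples.

    ``library_sizes`` defaults to column sums and is deliberately *not*
    recomputed when genes are filtered, so that filtering does not silently
    change normalization.
    """

    counts: pd.DataFrame
    library_sizes: pd.Series = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        c = self.counts
        if c.index.has_duplicates:
            dups = c.index[c.index.duplicated()].unique().tolist()
            raise CountsFormatError(f"duplicate gene ids: {dups[:5]}")
        if c.columns.has_duplicates:
            dups = c.columns[c.columns.duplicated()].unique().tolist()
            raise CountsFormatError(f"duplicate sample ids: {dups[:5]}")
        vals = c.to_numpy()
        if not np.issubdtype(vals.dtype, np.number):
            raise CountsFormatError("counts must be numeric")
        if np.isnan(vals.astype(float)).any():
            bad = c.columns[np.isnan(vals.astype(float)).any(axis=0)][0]
            raise CountsFormatError(f"NaN count in sample {bad!r}")
        if (vals < 0).any():
            g = c.index[(vals < 0).any(axis=1)][0]
            raise CountsFormatError(f"negative count in gene {g!r}")
        if not np.issubdtype(vals.dtype, np.integer):
            if np.any(vals != np.floor(vals)):
                g = c.index[(vals != np.floor(vals)).any(axis=1)][0]
                raise CountsFormatError(f"non-integer count in gene {g!r}")
            self.counts = c.astype(np.int64)
        if self.library_sizes is None:
            self.library_sizes = self.counts.sum(axis=0)
        self.library_sizes = pd.Series(self.library_sizes, dtype=np.int64).reindex(
            self.counts.columns
        )
        if self.library_sizes.isna().any():
            raise CountsFormatError("library_sizes missing for some samples")
        if (self.library_sizes <= 0).any():
            s = self.library_sizes.index[self.library_sizes <= 0][0]
            raise CountsFormatError(f"non-positive library size for sample {s!r}")

    @property
    def gene_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.counts.columns

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def subset_genes(self, gene_ids) -> "CountsMatrix":
        """Row subset preserving order and the original library sizes."""
        return CountsMatrix(self.counts.loc[gene_ids], self.library_sizes)

    def subset_samples(self, sample_ids) -> "CountsMatrix":
        return CountsMatrix(
            self.counts.loc[:, sample_ids], self.library_sizes.loc[sample_ids]
        )

    def equals(self, other: "CountsMatrix") -> bool:
        return self.counts.equals(other.counts) and self.library_sizes.equals(
            other.library_sizes
        )


@dataclass
class NormalizedMatrix:
    """CPM or log2(CPM + pseudocount) values with an explicit scale tag.

    The scale tag ("cpm" or "log2cpm") guards against double-logging.
    """

    values: pd.DataFrame
    scale: str
    pseudocount: float = 1.0

    def __post_init__(self) -> None:
        if self.scale not in ("cpm", "log2cpm"):
            raise ValueError(f"unknown scale tag {self.scale!r}")

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns


def _sidecar_paths(path: Path) -> tuple[Path, Path]:
    stem = path.with_suffix("")
    return Path(f"{stem}.genes.txt"), Path(f"{stem}.samples.txt")


def read_counts(path, format: str = "tsv") -> CountsMatrix:
    """Read a gene x sample counts table.

    TSV: header row of sample ids, first column gene ids.  MTX: MatrixMarket
    file with ``<stem>.genes.txt`` / ``<stem>.samples.txt`` sidecars (one id
    per line).  Library sizes are the column sums of the full matrix.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "tsv":
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")[1:]
        dup_cols = {c for c in header if header.count(c) > 1}
        if dup_cols:
            raise CountsFormatError(f"duplicate sample ids: {sorted(dup_cols)}")
        try:
            df = pd.read_csv(path, sep="\t", index_col=0)
        except Exception as exc:  # malformed header / ragged rows
            raise CountsFormatError(f"cannot parse {path}: {exc}") from exc
        if df.columns.size == 0:
            raise CountsFormatError(f"{path}: no sample columns in header")
        df.index = df.index.astype(str)
        df.columns = df.columns.astype(str)
        return CountsMatrix(df)
    if format == "mtx":
        genes_path, samples_path = _sidecar_paths(path)
        for p in (genes_path, samples_path):
            if not p.exists():
                raise CountsFormatError(f"missing sidecar file {p}")
        mat = scipy.io.mmread(path)
        genes = genes_path.read_text().split()
        samples = samples_path.read_text().split()
        arr = np.asarray(mat.todense() if scipy.sparse.issparse(mat) else mat)
        if arr.shape != (len(genes), len(samples)):
            raise CountsFormatError(
                f"{path}: matrix shape {arr.shape} does not match sidecars "
                f"({len(genes)} genes, {len(samples)} samples)"
            )
        return CountsMatrix(pd.DataFrame(arr, index=genes, columns=samples))
    raise ValueError(f"unknown format {format!r}")


def write_counts(m: CountsMatrix, path, format: str = "tsv") -> None:
    path = Path(path)
    if format == "tsv":
        m.counts.to_csv(path, sep="\t", index_label="gene_id")
    elif format == "mtx":
        genes_path, samples_path = _sidecar_paths(path)
        scipy.io.mmwrite(str(path), scipy.sparse.coo_matrix(m.counts.to_numpy()))
        genes_path.write_text("\n".join(m.gene_ids) + "\n")
        samples_path.write_text("\n".join(m.sample_ids) + "\n")
    else:
        raise ValueError(f"unknown format {format!r}")


def validate_sample_table(samples: pd.DataFrame) -> pd.DataFrame:
    """Check the sample-metadata contract and return the validated frame.

    Required columns: sample_id, genotype_id, role (P1/P2/F1), time_point,
    replicate.  sample_id and (genotype_id, time_point, replicate) must be
    unique.
    """
    required = ["sample_id", "genotype_id", "role", "time_point", "replicate"]
    missing = [c for c in required if c not in samples.columns]
    if missing:
        raise ValueError(f"sample table missing columns: {missing}")
    if samples["sample_id"].duplicated().any():
        dup = samples.loc[samples["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise ValueError(f"duplicate sample_id {dup!r}")
    bad_roles = set(samples["role"]) - set(ROLES)
    if bad_roles:
        raise ValueError(f"unknown roles {sorted(bad_roles)}; expected {ROLES}")
    key = samples[["genotype_id", "time_point", "replicate"]]
    if key.duplicated().any():
        raise ValueError("duplicate (genotype_id, time_point, replicate) triple")
    if (samples["time_point"].astype(float) < 0).any():
        raise ValueError("negative time_point")
    return samples.reset_index(drop=True)


def read_sample_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "genotype_id": str})
    return validate_sample_table(df)


def read_gene_positions(path) -> pd.DataFrame:
    """Read 4-column BED (chrom, start, end, gene_id), 0-based half-open."""
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        names=["chromosome", "start", "end", "gene_id"],
        dtype={"chromosome": str, "gene_id": str},
        comment="#",
    )
    if df["gene_id"].isna().any():
        raise CountsFormatError(f"{path}: BED needs 4 columns (name = gene id)")
    if (df["start"] >= df["end"]).any():
        g = df.loc[df["start"] >= df["end"], "gene_id"].iloc[0]
        raise CountsFormatError(f"gene {g!r}: start must be < end")
    if df["gene_id"].duplicated().any():
        g = df.loc[df["gene_id"].duplicated(), "gene_id"].iloc[0]
        raise CountsFormatError(f"duplicate annotation for gene {g!r}")
    return df.set_index("gene_id")


def write_gene_positions(annotation: pd.DataFrame, path) -> None:
    out = annotation.reset_index()[["chromosome", "start", "end", "gene_id"]]
    out.to_csv(path, sep="\t", header=False, index=False)


def cpm_normalize(
    m: CountsMatrix, log_scale: bool = False, pseudocount: float = 1.0
) -> NormalizedMatrix:
    """Counts-per-million: counts / library_size * 1e6, optionally log2(x + pc)."""
    lib = m.library_sizes.to_numpy(dtype=float)
    cpm = m.counts.to_numpy(dtype=float) / lib[None, :] * 1e6
    if log_scale:
        vals = np.log2(cpm + pseudocount)
        scale = "log2cpm"
    else:
        vals = cpm
        scale = "cpm"
    return NormalizedMatrix(
        pd.DataFrame(vals, index=m.gene_ids, columns=m.sample_ids),
        scale=scale,
        pseudocount=pseudocount,
    )


def filter_min_count(
    m: CountsMatrix,
    min_count: int = 5,
    max_low_fraction: float = 0.8,
    recompute_library_sizes: bool = False,
) -> CountsMatrix:
    """Drop genes whose count is < min_count in >= max_low_fraction of samples.

    The default (5, 0.8) is the co-expression prefilter: genes with fewer
    than 5 reads in 80% or more of the libraries carry too little signal for
    network or inheritance analysis.
    """
    if not 0 < max_low_fraction <= 1:
        raise ValueError("max_low_fraction must be in (0, 1]")
    low = (m.counts.to_numpy() < min_count).mean(axis=1)
    keep = low < max_low_fraction
    if not keep.any():
        warnings.warn("filter_min_count removed every gene", stacklevel=2)
    sub = m.counts.loc[keep]
    lib = None if recompute_library_sizes else m.library_sizes
    return CountsMatrix(sub, lib)


def filter_cpm(
    m: CountsMatrix,
    cpm_threshold: float = 1.0,
    min_fraction: float = 0.5,
    recompute_library_sizes: bool = False,
) -> CountsMatrix:
    """Keep genes with CPM > cpm_threshold in >= min_fraction of samples.

    Defaults (1, 0.5) are the inheritance-analysis expression filter; the
    permissive variant (0.5, 0.3) admits lower-expressed genes.
    """
    if cpm_threshold < 0 or not 0 < min_fraction <= 1:
        raise ValueError("thresholds must be nonnegative, fraction in (0, 1]")
    cpm = cpm_normalize(m).values.to_numpy()
    keep = (cpm > cpm_threshold).mean(axis=1) >= min_fraction
    if not keep.any():
        warnings.warn("filter_cpm removed every gene", stacklevel=2)
    sub = m.counts.loc[keep]
    lib = None if recompute_library_sizes else m.library_sizes
    return CountsMatrix(sub, lib)
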