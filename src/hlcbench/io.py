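"""Readers, writers, and cross-study merging for every external format.

Count matrices are gene-by-sample tables of non-negative integers, read from
delimited text (genes in rows by default) or MatrixMarket triplets with two
sidecar identifier lists.  Sample metadata is a delimited table with required
columns ``sample_id``, ``study``, ``cell_source``, ``role``; unknown columns
are preserved as annotations.  Gene sets use the GMT convention: one set per
line, name and description followed by tab-separated gene identifiers.

Matrices from different studies are combined on the *intersection* of their
gene identifiers (a zero imputed for an unmeasured gene would masquerade as
biological absence and corrupt downstream distances), with Gencode-style
version suffixes stripped by default since studies quantify against different
annotation patch levels.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from ._errors import FormatError, MergeError, ValidationError

#: cell sources the metadata vocabulary accepts outright; labels containing
#: "HLC" (derived hepatocyte-like-cell variants) are accepted as well.
KNOWN_CELL_SOURCES = frozenset(
    {"PHH/Liver", "FetalHep", "Fib", "PSC", "Chol", "CBD", "HepG2"}
)

PHH_SOURCE = "PHH/Liver"

_ROLES = frozenset({"control", "query"})

_INT_TOL = 1e-6


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class CountMatrix:
    """Gene-by-sample matrix of non-negative integer read counts.

    Wraps a :class:`pandas.DataFrame` with unique gene identifiers as the
    index and unique sample identifiers as columns.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        if df.index.duplicated().any():
            dups = df.index[df.index.duplicated()].unique().tolist()
            raise FormatError(f"duplicate gene identifiers: {dups}")
        if df.columns.duplicated().any():
            dups = df.columns[df.columns.duplicated()].unique().tolist()
            raise FormatError(f"duplicate sample identifiers: {dups}")
        values = df.to_numpy()
        if values.size and not np.issubdtype(values.dtype, np.integer):
            rounded = np.rint(values)
            off = np.abs(values - rounded) > _INT_TOL
            if off.any():
                i, j = np.argwhere(off)[0]
                raise FormatError(
                    f"non-integer count {values[i, j]!r} at "
                    f"({df.index[i]!r}, {df.columns[j]!r})"
                )
            df = pd.DataFrame(
                rounded.astype(np.int64), index=df.index, columns=df.columns
            )
            self.data = df
        if (self.data.to_numpy() < 0).any():
            i, j = np.argwhere(self.data.to_numpy() < 0)[0]
            raise FormatError(
                f"negative count at ({df.index[i]!r}, {df.columns[j]!r})"
            )

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def counts(self) -> np.ndarray:
        """Counts as a genes x samples int array."""
        return self.data.to_numpy()


@dataclass
class SampleMetadata:
    """Per-sample study, cell source, and benchmarking role.

    ``table`` is indexed by sample_id and always carries the columns
    ``study``, ``cell_source``, ``role``, ``culture_duration``,
    ``expandable``; extra input columns ride along as annotations.
    """

    table: pd.DataFrame

    REQUIRED = ("sample_id", "study", "cell_source", "role")
    _OPTIONAL_DEFAULTS = {"culture_duration": "unknown", "expandable": "unknown"}

    def __post_init__(self) -> None:
        t = self.table
        if t.index.duplicated().any():
            dups = t.index[t.index.duplicated()].unique().tolist()
            raise FormatError(f"repeated sample_id: {dups}")
        for col in ("study", "cell_source", "role"):
            if col not in t.columns:
                raise FormatError(f"metadata missing required column {col!r}")
        bad_roles = set(t["role"]) - _ROLES
        if bad_roles:
            raise FormatError(f"unknown role value(s): {sorted(bad_roles)}")
        for col, default in self._OPTIONAL_DEFAULTS.items():
            if col not in t.columns:
                t[col] = default
        unknown = [
            src
            for src in t["cell_source"].unique()
            if src not in KNOWN_CELL_SOURCES and "HLC" not in src
        ]
        if unknown:
            raise FormatError(
                f"cell_source value(s) outside the declared vocabulary: {unknown}"
            )

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table.index)

    def phh_controls(self) -> list[str]:
        """Sample ids of PHH/liver benchmark controls."""
        t = self.table
        mask = (t["cell_source"] == PHH_SOURCE) & (t["role"] == "control")
        return list(t.index[mask])

    def subset(self, sample_ids: Sequence[str]) -> "SampleMetadata":
        return SampleMetadata(self.table.loc[list(sample_ids)].copy())


@dataclass
class GeneSet:
    """A named collection of gene identifiers (one GMT line)."""

    name: str
    description: str = ""
    gene_ids: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if not self.name:
            raise ValidationError("gene set needs a non-empty name")
        self.gene_ids = frozenset(self.gene_ids)

    def __len__(self) -> int:
        return len(self.gene_ids)


class MergeResult(NamedTuple):
    """Merged cross-study matrix plus per-input counts of dropped genes."""

    matrix: CountMatrix
    dropped_per_input: list[int]


# ---------------------------------------------------------------------------
# delimited-text helpers
# ---------------------------------------------------------------------------


def _sniff_delimiter(path: Path) -> str:
    with open(path, newline="") as fh:
        header = fh.readline()
    try:
        return csv.Sniffer().sniff(header, delimiters="\t,;").delimiter
    except csv.Error:
        return "\t"


def _read_table(path: Path) -> pd.DataFrame:
    sep = _sniff_delimiter(path)
    return pd.read_csv(path, sep=sep, index_col=0, comment="#")


# ---------------------------------------------------------------------------
# count matrices
# ---------------------------------------------------------------------------


def read_count_matrix(
    path: str | Path,
    orientation: str = "genes-in-rows",
    genes_path: str | Path | None = None,
    samples_path: str | Path | None = None,
) -> CountMatrix:
    """Read a count matrix from delimited text or MatrixMarket triplets.

    For ``.mtx`` input the gene and sample identifier lists are taken from
    ``genes_path`` / ``samples_path`` (defaulting to ``<stem>.genes.txt`` and
    ``<stem>.samples.txt`` next to the matrix).  Values within 1e-6 of an
    integer are rounded; anything else is rejected.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    if path.suffix == ".mtx":
        genes_path = Path(genes_path) if genes_path else path.with_suffix(".genes.txt")
        samples_path = (
            Path(samples_path) if samples_path else path.with_suffix(".samples.txt")
        )
        mat = scipy.io.mmread(path)
        if scipy.sparse.issparse(mat):
            mat = mat.toarray()
        genes = [ln.strip() for ln in Path(genes_path).read_text().splitlines() if ln.strip()]
        samples = [ln.strip() for ln in Path(samples_path).read_text().splitlines() if ln.strip()]
        if mat.shape != (len(genes), len(samples)):
            raise FormatError(
                f"MTX shape {mat.shape} does not match identifier lists "
                f"({len(genes)} genes, {len(samples)} samples)"
            )
        df = pd.DataFrame(mat, index=genes, columns=samples)
    else:
        df = _read_table(path)
        df.index = df.index.astype(str)
        df.columns = df.columns.astype(str)
        df.index.name = None
        df.columns.name = None
    if orientation == "samples-in-rows":
        df = df.T
    elif orientation != "genes-in-rows":
        raise ValidationError(f"unknown orientation {orientation!r}")
    return CountMatrix(df)


def write_count_matrix(
    matrix: CountMatrix,
    path: str | Path,
    genes_path: str | Path | None = None,
    samples_path: str | Path | None = None,
) -> None:
    """Write a count matrix as TSV, or as MTX + sidecars for ``.mtx`` paths."""
    path = Path(path)
    if path.suffix == ".mtx":
        genes_path = Path(genes_path) if genes_path else path.with_suffix(".genes.txt")
        samples_path = (
            Path(samples_path) if samples_path else path.with_suffix(".samples.txt")
        )
        scipy.io.mmwrite(path, scipy.sparse.coo_matrix(matrix.counts()))
        Path(genes_path).write_text("\n".join(matrix.gene_ids) + "\n")
        Path(samples_path).write_text("\n".join(matrix.sample_ids) + "\n")
    else:
        matrix.data.to_csv(path, sep="\t", index_label="gene_id")


# ---------------------------------------------------------------------------
# metadata
# ---------------------------------------------------------------------------


def read_sample_metadata(path: str | Path) -> SampleMetadata:
    """Read a sample metadata table (TSV/CSV with required columns)."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    sep = _sniff_delimiter(path)
    df = pd.read_csv(path, sep=sep, dtype=str, comment="#").fillna("unknown")
    missing = [c for c in SampleMetadata.REQUIRED if c not in df.columns]
    if missing:
        raise FormatError(f"metadata missing required column(s): {missing}")
    df = df.set_index("sample_id")
    return SampleMetadata(df)


def write_sample_metadata(metadata: SampleMetadata, path: str | Path) -> None:
    metadata.table.to_csv(path, sep="\t", index_label="sample_id")


# ---------------------------------------------------------------------------
# gene sets (GMT)
# ---------------------------------------------------------------------------


def read_gene_sets(path: str | Path) -> list[GeneSet]:
    """Parse a GMT file: name, description, then member genes per line."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    sets: list[GeneSet] = []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise FormatError(
                f"{path}:{lineno}: GMT line needs >=3 tab-separated fields"
            )
        name, desc, genes = fields[0], fields[1], [g for g in fields[2:] if g]
        if len(set(genes)) < len(genes):
            warnings.warn(
                f"{path}:{lineno}: duplicate genes in set {name!r} deduplicated"
            )
        sets.append(GeneSet(name=name, description=desc, gene_ids=frozenset(genes)))
    return sets


def write_gene_sets(sets: Iterable[GeneSet], path: str | Path) -> None:
    with open(path, "w") as fh:
        for gs in sets:
            fh.write("\t".join([gs.name, gs.description, *sorted(gs.gene_ids)]) + "\n")


# ---------------------------------------------------------------------------
# cross-study merging
# ---------------------------------------------------------------------------


def strip_gene_versions(gene_ids: Iterable[str]) -> list[str]:
    """Drop the Gencode-style version suffix after the first '.'."""
    return [g.split(".", 1)[0] for g in gene_ids]


def merge_studies(
    matrices: Sequence[CountMatrix], strip_versions: bool = True
) -> MergeResult:
    """Combine per-study count matrices on their shared genes.

    Gene identifiers are optionally version-stripped, the intersection across
    inputs is taken, genes are sorted, and sample columns concatenated.
    Returns the merged matrix and, per input, the number of genes it lost to
    the intersection.
    """
    if not matrices:
        raise ValidationError("merge_studies needs at least one matrix")
    frames = []
    for m in matrices:
        df = m.data
        if strip_versions:
            stripped = strip_gene_versions(df.index)
            if len(set(stripped)) != len(stripped):
                dup = pd.Index(stripped)
                dups = dup[dup.duplicated()].unique().tolist()
                raise MergeError(
                    f"version stripping collapses gene ids: {dups}"
                )
            df = df.set_axis(stripped, axis=0)
        frames.append(df)

    shared = set(frames[0].index)
    for df in frames[1:]:
        shared &= set(df.index)
    if not shared:
        raise MergeError("no genes shared across all input matrices")
    order = sorted(shared)

    all_samples = [s for df in frames for s in df.columns]
    seen: set[str] = set()
    collisions = sorted({s for s in all_samples if s in seen or seen.add(s)})
    if collisions:
        raise MergeError(f"sample id collision(s) across studies: {collisions}")

    dropped = [df.shape[0] - len(order) for df in frames]
    merged = pd.concat([df.loc[order] for df in frames], axis=1)
    return MergeResult(CountMatrix(merged), dropped)
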