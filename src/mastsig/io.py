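"""Readers, writers and core containers shared by every pipeline stage.

The central container is :class:`CountMatrix`: a genes-by-samples table of
non-negative integer counts with a per-sample metadata frame.  Genes are
always rows and samples always columns; every reader enforces this
orientation and the integrality/uniqueness invariants at parse time.

Supported on-disk formats are delimited matrices (TSV/CSV with gene
identifiers in the first column and sample identifiers in the header),
MatrixMarket coordinate files with sidecar row/column name files, and GMT
gene-set files.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse


class ValidationError(ValueError):
    """Raised when an input violates a container invariant."""


@dataclass
class CountMatrix:
    """Genes x samples matrix of non-negative integer counts.

    Parameters
    ----------
    counts
        Dense integer array, shape ``(n_genes, n_samples)``.
    gene_ids
        Unique gene identifiers, one per row.
    sample_ids
        Unique sample (or cell) identifiers, one per column.
    meta
        Per-sample annotations (condition, donor, disease, cluster,
        trajectory, pseudotime ... as applicable), indexed by sample id.
        Stages check only the fields they need.
    """

    counts: np.ndarray
    gene_ids: list[str]
    sample_ids: list[str]
    meta: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise ValidationError("counts must be a 2-D genes x samples array")
        if not np.issubdtype(self.counts.dtype, np.integer):
            rounded = np.round(self.counts)
            if not np.allclose(self.counts, rounded, atol=1e-8):
                raise ValidationError("counts must be integral")
            self.counts = rounded.astype(np.int64)
        if (self.counts < 0).any():
            raise ValidationError("counts must be non-negative")
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        if len(self.gene_ids) != self.counts.shape[0]:
            raise ValidationError(
                f"{len(self.gene_ids)} gene ids for {self.counts.shape[0]} rows"
            )
        if len(self.sample_ids) != self.counts.shape[1]:
            raise ValidationError(
                f"{len(self.sample_ids)} sample ids for {self.counts.shape[1]} columns"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            dupes = _duplicates(self.gene_ids)
            raise ValidationError(f"duplicate gene ids: {dupes}")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            dupes = _duplicates(self.sample_ids)
            raise ValidationError(f"duplicate sample ids: {dupes}")
        if self.meta is None or len(self.meta) == 0:
            self.meta = pd.DataFrame(index=pd.Index(self.sample_ids, name="sample"))
        else:
            if list(self.meta.index) != self.sample_ids:
                try:
                    self.meta = self.meta.loc[self.sample_ids]
                except KeyError as exc:
                    raise ValidationError(
                        "meta rows do not correspond to sample ids"
                    ) from exc

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.gene_ids, columns=self.sample_ids)

    def subset_genes(self, genes: Sequence[str]) -> "CountMatrix":
        idx = {g: i for i, g in enumerate(self.gene_ids)}
        rows = [idx[g] for g in genes if g in idx]
        return CountMatrix(
            self.counts[rows, :],
            [self.gene_ids[i] for i in rows],
            list(self.sample_ids),
            self.meta.copy(),
        )

    def subset_samples(self, samples: Sequence[str]) -> "CountMatrix":
        idx = {s: j for j, s in enumerate(self.sample_ids)}
        cols = [idx[s] for s in samples if s in idx]
        kept = [self.sample_ids[j] for j in cols]
        return CountMatrix(
            self.counts[:, cols], list(self.gene_ids), kept, self.meta.loc[kept]
        )


def _duplicates(ids: Sequence[str]) -> list[str]:
    seen: set[str] = set()
    dup: list[str] = []
    for x in ids:
        if x in seen and x not in dup:
            dup.append(x)
        seen.add(x)
    return dup


@dataclass
class GeneSetCollection:
    """Named, ordered gene lists (GMT semantics).

    ``sets`` maps a set name to its ordered gene list; ``descriptions``
    carries the GMT description field.  For the minimal cytokine-activated
    signatures the set names are the condition classes and ``provenance``
    may hold per-gene selection weights (elastic-net coefficient magnitudes).
    """

    sets: dict[str, list[str]]
    descriptions: dict[str, str] = field(default_factory=dict)
    provenance: dict[str, dict[str, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, genes in self.sets.items():
            if len(genes) == 0:
                raise ValidationError(f"gene set {name!r} is empty")
        for name in self.sets:
            self.descriptions.setdefault(name, "")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets)

    def __getitem__(self, name: str) -> list[str]:
        return self.sets[name]

    @property
    def names(self) -> list[str]:
        return list(self.sets)


#: A SignatureSet is a GeneSetCollection whose set names are condition
#: classes; kept as an alias so signatures read like what they are.
SignatureSet = GeneSetCollection


def read_counts(path: str | Path, format: str | None = None) -> CountMatrix:
    """Read a genes x samples count matrix from TSV, CSV or MatrixMarket MTX.

    For ``mtx``, sidecar files ``<stem>.rownames.txt`` and
    ``<stem>.colnames.txt`` (one identifier per line) must sit next to the
    matrix; MatrixMarket coordinates are 1-based per the format standard.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        format = {".tsv": "tsv", ".txt": "tsv", ".csv": "csv", ".mtx": "mtx"}.get(
            path.suffix.lower(), "tsv"
        )
    if format == "mtx":
        return _read_mtx(path)
    sep = "\t" if format == "tsv" else ","
    try:
        df = pd.read_csv(path, sep=sep, index_col=0)
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise ValidationError(f"malformed {format} file {path}: {exc}") from exc
    if df.index.has_duplicates:
        raise ValidationError(
            f"duplicate gene ids in {path}: {_duplicates(list(df.index))}"
        )
    values = df.to_numpy()
    if values.dtype == object or not np.issubdtype(values.dtype, np.number):
        bad = _first_non_numeric(df)
        raise ValidationError(f"non-numeric entry in {path} at {bad}")
    if (values < 0).any():
        g, s = np.argwhere(values < 0)[0]
        raise ValidationError(
            f"negative count at gene {df.index[g]!r}, sample {df.columns[s]!r}"
        )
    return CountMatrix(values, list(df.index), [str(c) for c in df.columns])


def _first_non_numeric(df: pd.DataFrame) -> str:
    for g in df.index:
        for s in df.columns:
            try:
                float(df.loc[g, s])
            except (TypeError, ValueError):
                return f"gene {g!r}, sample {s!r}"
    return "unknown position"


def _read_mtx(path: Path) -> CountMatrix:
    stem = path.with_suffix("")
    rows_file = Path(str(stem) + ".rownames.txt")
    cols_file = Path(str(stem) + ".colnames.txt")
    for f in (rows_file, cols_file):
        if not f.exists():
            raise FileNotFoundError(f"missing MTX sidecar file {f}")
    mat = spio.mmread(path)
    if sparse.issparse(mat):
        mat = mat.toarray()
    genes = rows_file.read_text().split()
    samples = cols_file.read_text().split()
    return CountMatrix(np.asarray(mat), genes, samples)


def write_counts(cm: CountMatrix, path: str | Path, format: str | None = None) -> None:
    """Write a CountMatrix to TSV/CSV, or to MTX with sidecar name files."""
    path = Path(path)
    if format is None:
        format = {".tsv": "tsv", ".csv": "csv", ".mtx": "mtx"}.get(
            path.suffix.lower(), "tsv"
        )
    if format == "mtx":
        stem = path.with_suffix("")
        spio.mmwrite(path, sparse.coo_matrix(cm.counts))
        Path(str(stem) + ".rownames.txt").write_text("\n".join(cm.gene_ids) + "\n")
        Path(str(stem) + ".colnames.txt").write_text("\n".join(cm.sample_ids) + "\n")
        return
    sep = "\t" if format == "tsv" else ","
    cm.to_frame().to_csv(path, sep=sep, index_label="gene")


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Parse a GMT file: ``name<TAB>description<TAB>gene1<TAB>gene2...``."""
    sets: dict[str, list[str]] = {}
    desc: dict[str, str] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValidationError(
                f"{path}:{lineno}: GMT line needs name, description and >=1 gene"
            )
        name = fields[0]
        if name in sets:
            raise ValidationError(f"{path}:{lineno}: duplicate set name {name!r}")
        genes = [g for g in fields[2:] if g]
        if not genes:
            raise ValidationError(f"{path}:{lineno}: set {name!r} has no genes")
        sets[name] = genes
        desc[name] = fields[1]
    return GeneSetCollection(sets, desc)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    lines = [
        "\t".join([name, collection.descriptions.get(name, "")] + list(genes))
        for name, genes in collection.sets.items()
    ]
    Path(path).write_text("\n".join(lines) + "\n")


def attach_metadata(
    cm: CountMatrix, table: pd.DataFrame | Mapping[str, Mapping[str, object]]
) -> CountMatrix:
    """Return a copy of ``cm`` with per-sample metadata attached.

    ``table`` is indexed by sample id.  Every sample in the matrix must be
    present; extra table rows are ignored with a warning.  Sample order is
    preserved.
    """
    if not isinstance(table, pd.DataFrame):
        table = pd.DataFrame.from_dict(dict(table), orient="index")
    missing = [s for s in cm.sample_ids if s not in table.index]
    if missing:
        raise ValidationError(f"metadata missing for samples: {missing}")
    extra = [s for s in table.index if s not in set(cm.sample_ids)]
    if extra:
        warnings.warn(f"ignoring {len(extra)} metadata rows with no matching sample")
    meta = table.loc[cm.sample_ids].copy()
    meta.index.name = "sample"
    return CountMatrix(cm.counts.copy(), list(cm.gene_ids), list(cm.sample_ids), meta)
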