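"""Reading and writing droplet protein count matrices.

The in-memory container is :class:`CountMatrix`: a sparse, non-negative
integer UMI matrix oriented proteins x barcodes, with protein and barcode
identifiers and a per-protein isotype-control flag. Readers accept the two
formats droplet pipelines actually emit — Cell Ranger-style MatrixMarket
triplet directories (``matrix.mtx[.gz]`` + ``barcodes.tsv[.gz]`` +
``features.tsv[.gz]``) and dense delimited tables — and normalize both to
the internal orientation. Gzip is handled transparently for all text inputs.
"""

from __future__ import annotations

import gzip
import io
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import h5py
import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

logger = logging.getLogger(__name__)

DEFAULT_FEATURE_TYPE = "Antibody Capture"
#: case-insensitive substring used to auto-flag isotype controls; antibody
#: panels name these inconsistently ("Isotype_ctrl", "IgG1 isotype", ...)
DEFAULT_ISOTYPE_PATTERN = "isotype"


class FormatError(ValueError):
    """Malformed input file (dimension mismatch, ragged rows, bad header)."""


@dataclass
class CountMatrix:
    """Proteins x barcodes UMI count matrix with identifiers.

    Parameters
    ----------
    counts
        Non-negative integer matrix, one row per protein, one column per
        droplet barcode. Stored sparse (CSR) internally.
    protein_ids, barcode_ids
        Ordered, duplicate-free identifier lists matching the matrix axes.
    isotype_flags
        Boolean per protein; True marks an isotype-control antibody.
    """

    counts: sp.csr_matrix
    protein_ids: np.ndarray
    barcode_ids: np.ndarray
    isotype_flags: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if not sp.issparse(self.counts):
            self.counts = sp.csr_matrix(np.asarray(self.counts))
        self.counts = self.counts.tocsr()
        self.protein_ids = np.asarray(self.protein_ids, dtype=object)
        self.barcode_ids = np.asarray(self.barcode_ids, dtype=object)
        if self.isotype_flags is None:
            self.isotype_flags = flag_isotypes(self.protein_ids)
        self.isotype_flags = np.asarray(self.isotype_flags, dtype=bool)
        self.validate()

    # -- invariants -------------------------------------------------------
    def validate(self) -> None:
        n_prot, n_bc = self.counts.shape
        if len(self.protein_ids) != n_prot:
            raise ValueError(
                f"{len(self.protein_ids)} protein ids for {n_prot} matrix rows"
            )
        if len(self.barcode_ids) != n_bc:
            raise ValueError(
                f"{len(self.barcode_ids)} barcode ids for {n_bc} matrix columns"
            )
        if len(self.isotype_flags) != n_prot:
            raise ValueError("isotype_flags must have one entry per protein")
        for name, ids in (("protein", self.protein_ids), ("barcode", self.barcode_ids)):
            if len(set(ids)) != len(ids):
                raise ValueError(f"duplicate {name} ids")
        data = self.counts.data
        if data.size:
            if np.any(data < 0):
                raise ValueError("negative counts")
            if not np.allclose(data, np.round(data)):
                raise ValueError("non-integer counts")

    # -- convenience ------------------------------------------------------
    @property
    def n_proteins(self) -> int:
        return self.counts.shape[0]

    @property
    def n_barcodes(self) -> int:
        return self.counts.shape[1]

    def dense(self) -> np.ndarray:
        """Counts as a dense float array (proteins x barcodes)."""
        return np.asarray(self.counts.todense(), dtype=float)

    def barcode_index(self, ids: Sequence[str]) -> np.ndarray:
        lookup = {b: j for j, b in enumerate(self.barcode_ids)}
        try:
            return np.array([lookup[b] for b in ids], dtype=int)
        except KeyError as exc:
            raise KeyError(f"unknown barcode id: {exc.args[0]!r}") from None

    def subset_proteins(self, keep: np.ndarray) -> "CountMatrix":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        return CountMatrix(
            counts=self.counts[keep, :],
            protein_ids=self.protein_ids[keep],
            barcode_ids=self.barcode_ids.copy(),
            isotype_flags=self.isotype_flags[keep],
        )

    def equals(self, other: "CountMatrix") -> bool:
        return (
            self.counts.shape == other.counts.shape
            and (self.counts != other.counts).nnz == 0
            and np.array_equal(self.protein_ids, other.protein_ids)
            and np.array_equal(self.barcode_ids, other.barcode_ids)
            and np.array_equal(self.isotype_flags, other.isotype_flags)
        )


def flag_isotypes(
    protein_ids: Iterable[str],
    names: Sequence[str] | None = None,
    pattern: str | None = None,
) -> np.ndarray:
    """Boolean isotype-control flag per protein.

    Exact-match against ``names`` if given, else regex ``pattern``, else the
    default case-insensitive substring ``"isotype"``.
    """
    ids = list(protein_ids)
    if names is not None:
        names_set = set(names)
        missing = names_set - set(ids)
        if missing:
            raise KeyError(f"isotype names not in panel: {sorted(missing)}")
        return np.array([p in names_set for p in ids], dtype=bool)
    rx = re.compile(pattern if pattern is not None else DEFAULT_ISOTYPE_PATTERN,
                    re.IGNORECASE)
    return np.array([bool(rx.search(p)) for p in ids], dtype=bool)


# ---------------------------------------------------------------------------
# readers


def _open_text(path: Path) -> io.TextIOBase:
    if str(path).endswith(".gz"):
        return io.TextIOWrapper(gzip.open(path, "rb"))
    return open(path, "rt")


def _find_file(directory: Path, stem: str) -> Path:
    for suffix in ("", ".gz"):
        p = directory / f"{stem}{suffix}"
        if p.exists():
            return p
    raise FileNotFoundError(
        f"missing {stem}[.gz] in {directory}"
    )


def read_mtx_dir(
    path: str | Path,
    feature_type_filter: str = DEFAULT_FEATURE_TYPE,
    isotype_names: Sequence[str] | None = None,
    isotype_pattern: str | None = None,
) -> CountMatrix:
    """Read a Cell Ranger-style MatrixMarket directory.

    Expects ``matrix.mtx``, ``barcodes.tsv`` and ``features.tsv`` (optionally
    gzipped). ``features.tsv`` has at least id/name columns; a third column
    carries the feature type, and only rows matching ``feature_type_filter``
    are kept (default ``"Antibody Capture"``). A two-column features file is
    treated as all-antibody.
    """
    directory = Path(path)
    if not directory.is_dir():
        raise FileNotFoundError(f"not a directory: {directory}")
    mtx_path = _find_file(directory, "matrix.mtx")
    bc_path = _find_file(directory, "barcodes.tsv")
    feat_path = _find_file(directory, "features.tsv")

    with _open_text(mtx_path) as fh:
        mat = sp.csr_matrix(scipy.io.mmread(fh))
    with _open_text(bc_path) as fh:
        barcodes = [line.strip().split("\t")[0] for line in fh if line.strip()]
    with _open_text(feat_path) as fh:
        feat_rows = [line.rstrip("\n").split("\t") for line in fh if line.strip()]

    if mat.shape[0] != len(feat_rows):
        raise FormatError(
            f"matrix has {mat.shape[0]} rows but features file lists "
            f"{len(feat_rows)} features"
        )
    if mat.shape[1] != len(barcodes):
        raise FormatError(
            f"matrix has {mat.shape[1]} columns but barcodes file lists "
            f"{len(barcodes)} barcodes"
        )

    names = [row[1] if len(row) > 1 else row[0] for row in feat_rows]
    types = [row[2] if len(row) > 2 else feature_type_filter for row in feat_rows]
    keep = np.array([t == feature_type_filter for t in types], dtype=bool)
    if not keep.any():
        raise FormatError(
            f"no features of type {feature_type_filter!r} in {feat_path}"
        )
    kept_names = [n for n, k in zip(names, keep) if k]
    return CountMatrix(
        counts=mat[np.flatnonzero(keep), :],
        protein_ids=np.array(kept_names, dtype=object),
        barcode_ids=np.array(barcodes, dtype=object),
        isotype_flags=flag_isotypes(kept_names, isotype_names, isotype_pattern),
    )


def read_dense(
    path: str | Path,
    proteins_in: str = "rows",
    sep: str | None = None,
    isotype_names: Sequence[str] | None = None,
    isotype_pattern: str | None = None,
) -> CountMatrix:
    """Read a dense delimited count table (header row + ID column).

    ``proteins_in`` says which axis of the *file* holds proteins; the result
    is always oriented proteins x barcodes.
    """
    path = Path(path)
    if proteins_in not in ("rows", "columns"):
        raise ValueError("proteins_in must be 'rows' or 'columns'")
    if sep is None:
        name = path.name[:-3] if path.name.endswith(".gz") else path.name
        sep = "\t" if name.endswith((".tsv", ".txt")) else ","
    try:
        df = pd.read_csv(path, sep=sep, index_col=0)
    except pd.errors.ParserError as exc:
        raise FormatError(f"malformed table {path}: {exc}") from exc
    if proteins_in == "columns":
        df = df.T
    values = df.to_numpy()
    if not np.issubdtype(values.dtype, np.number):
        raise FormatError(f"non-numeric entries in {path}")
    bad = ~np.isfinite(values) | (values < 0) | (values != np.round(values))
    if bad.any():
        rows, cols = np.nonzero(bad)
        cells = [
            f"({df.index[r]}, {df.columns[c]})={values[r, c]}"
            for r, c in list(zip(rows, cols))[:10]
        ]
        raise ValueError(
            f"counts must be non-negative integers; offending cells: {cells}"
        )
    protein_ids = [str(p) for p in df.index]
    return CountMatrix(
        counts=sp.csr_matrix(values.astype(np.int64)),
        protein_ids=np.array(protein_ids, dtype=object),
        barcode_ids=np.array([str(b) for b in df.columns], dtype=object),
        isotype_flags=flag_isotypes(protein_ids, isotype_names, isotype_pattern),
    )


def read_barcode_list(path: str | Path) -> list[str]:
    """Plain-text barcode list, one barcode per line (gzip ok)."""
    with _open_text(Path(path)) as fh:
        return [line.strip().split("\t")[0] for line in fh if line.strip()]


def subset_barcodes(m: CountMatrix, ids: Sequence[str]) -> CountMatrix:
    """Restrict and reorder columns to ``ids`` (must all exist)."""
    idx = m.barcode_index(list(ids))
    return CountMatrix(
        counts=m.counts[:, idx] if len(idx) else sp.csr_matrix((m.n_proteins, 0), dtype=m.counts.dtype),
        protein_ids=m.protein_ids.copy(),
        barcode_ids=np.array(list(ids), dtype=object),
        isotype_flags=m.isotype_flags.copy(),
    )


# ---------------------------------------------------------------------------
# writers


def write_mtx_dir(m: CountMatrix, path: str | Path,
                  feature_type: str = DEFAULT_FEATURE_TYPE) -> None:
    """Write a CountMatrix as a MatrixMarket triplet directory."""
    directory = Path(path)
    directory.mkdir(parents=True, exist_ok=True)
    scipy.io.mmwrite(str(directory / "matrix.mtx"), sp.coo_matrix(m.counts))
    with open(directory / "barcodes.tsv", "w") as fh:
        fh.writelines(f"{b}\n" for b in m.barcode_ids)
    with open(directory / "features.tsv", "w") as fh:
        fh.writelines(f"{p}\t{p}\t{feature_type}\n" for p in m.protein_ids)


def write_normalized(
    values: np.ndarray,
    path: str | Path,
    fmt: str = "csv",
    protein_ids: Sequence[str] | None = None,
    barcode_ids: Sequence[str] | None = None,
) -> None:
    """Write a normalized (real-valued) proteins x cells matrix.

    ``fmt='csv'`` round-trips to 1e-9, ``'hdf5'`` exactly, ``'mtx'`` as a
    dense-array MatrixMarket file with sidecar id lists.
    """
    values = np.asarray(values, dtype=float)
    if not np.all(np.isfinite(values)):
        raise ValueError("normalized values must be finite (found NaN/inf)")
    path = Path(path)
    n_prot, n_cell = values.shape
    protein_ids = list(protein_ids) if protein_ids is not None else [
        f"p{i}" for i in range(n_prot)
    ]
    barcode_ids = list(barcode_ids) if barcode_ids is not None else [
        f"bc{j}" for j in range(n_cell)
    ]
    if fmt == "csv":
        pd.DataFrame(values, index=protein_ids, columns=barcode_ids).to_csv(
            path, float_format="%.12g"
        )
    elif fmt == "hdf5":
        with h5py.File(path, "w") as h5:
            h5.create_dataset("values", data=values)
            h5.create_dataset("protein_ids", data=np.array(protein_ids, dtype="S"))
            h5.create_dataset("barcode_ids", data=np.array(barcode_ids, dtype="S"))
    elif fmt == "mtx":
        path.mkdir(parents=True, exist_ok=True)
        scipy.io.mmwrite(str(path / "matrix.mtx"), values)
        with open(path / "barcodes.tsv", "w") as fh:
            fh.writelines(f"{b}\n" for b in barcode_ids)
        with open(path / "features.tsv", "w") as fh:
            fh.writelines(f"{p}\n" for p in protein_ids)
    else:
        raise ValueError(f"unknown format {fmt!r} (csv|mtx|hdf5)")


def read_normalized(path: str | Path, fmt: str = "csv"):
    """Read back a matrix written by :func:`write_normalized`.

    Returns ``(values, protein_ids, barcode_ids)``.
    """
    path = Path(path)
    if fmt == "csv":
        df = pd.read_csv(path, index_col=0)
        return df.to_numpy(dtype=float), list(df.index), list(df.columns)
    if fmt == "hdf5":
        with h5py.File(path, "r") as h5:
            return (
                h5["values"][...],
                [s.decode() for s in h5["protein_ids"][...]],
                [s.decode() for s in h5["barcode_ids"][...]],
            )
    if fmt == "mtx":
        with _open_text(_find_file(path, "matrix.mtx")) as fh:
            values = np.asarray(scipy.io.mmread(fh))
        if sp.issparse(values):  # pragma: no cover - coordinate fallback
            values = values.toarray()
        proteins = [l.strip() for l in open(path / "features.tsv") if l.strip()]
        barcodes = [l.strip() for l in open(path / "barcodes.tsv") if l.strip()]
        return values, proteins, barcodes
    raise ValueError(f"unknown format {fmt!r}")
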