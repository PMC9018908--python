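"""Partitioning raw droplet barcodes into cells and empty (background) droplets.

Droplet experiments emit far more barcodes than cells: most droplets hold a
capture bead but no cell, and their protein counts reflect ambient antibody
only. Cell-containing and empty droplets separate by roughly an order of
magnitude in protein library size, so when no external cell-barcode list is
available the split is found automatically from the bimodal log10 library
size distribution (two-component mixture fit, reusing :mod:`.mixtures`).
A protein-level QC filter drops antibodies with essentially no signal in
cells (maximum UMI count below 5 across all cells, by default).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .io_matrices import CountMatrix
from .mixtures import em_fit_1d

logger = logging.getLogger(__name__)

DEFAULT_MIN_BACKGROUND = 500
DEFAULT_MIN_MAX_COUNT = 5
DEFAULT_QC_QUANTILE = 0.995


@dataclass
class DropletPartition:
    """Cell / background split of raw barcodes with the thresholds used.

    ``thresholds = (background_lower, background_upper, cell_lower)`` in UMI
    counts; barcodes between ``background_upper`` and ``cell_lower`` belong
    to neither set (ambiguous droplets contaminate either estimate).
    """

    cell_barcodes: list[str]
    background_barcodes: list[str]
    library_size: pd.Series
    thresholds: tuple[float, float, float]
    method: str = "explicit"

    def __post_init__(self) -> None:
        overlap = set(self.cell_barcodes) & set(self.background_barcodes)
        if overlap:
            raise ValueError(f"barcodes in both partitions: {sorted(overlap)[:5]}")

    @property
    def excluded_barcodes(self) -> list[str]:
        assigned = set(self.cell_barcodes) | set(self.background_barcodes)
        return [b for b in self.library_size.index if b not in assigned]

    def to_frame(self) -> pd.DataFrame:
        label = {}
        for b in self.cell_barcodes:
            label[b] = "cell"
        for b in self.background_barcodes:
            label[b] = "background"
        rows = [
            (b, label.get(b, "excluded"), int(self.library_size[b]))
            for b in self.library_size.index
        ]
        return pd.DataFrame(rows, columns=["barcode", "label", "library_size"])

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def library_sizes(m: CountMatrix) -> np.ndarray:
    """Total ADT UMI count per barcode (column sums)."""
    return np.asarray(m.counts.sum(axis=0)).ravel()


def _auto_split(lib: np.ndarray, seed: int) -> tuple[float, float]:
    """Bimodality split on log10(library size + 1) over nonzero barcodes.

    Fits k=1 and k=2 mixtures; if BIC prefers the unimodal model or the
    component bands overlap, the caller must supply explicit thresholds.
    Returns ``(background_upper, cell_lower)`` on the count scale.
    """
    nz = lib[lib > 0]
    x = np.log10(nz + 1.0)
    fit1 = em_fit_1d(x, k=1, seed=seed)
    fit2 = em_fit_1d(x, k=2, restarts=3, seed=seed)
    bg_upper_log = fit2.means[0] + 2.0 * fit2.sds[0]
    cell_lower_log = fit2.means[1] - 2.0 * fit2.sds[1]
    if fit1.bic >= fit2.bic or bg_upper_log >= cell_lower_log:
        raise ValueError(
            "library-size distribution looks unimodal; cannot auto-partition "
            "droplets — pass cell_ids or an explicit background_range"
        )
    return float(10.0 ** bg_upper_log - 1.0), float(10.0 ** cell_lower_log - 1.0)


def partition_droplets(
    m: CountMatrix,
    cell_ids: Sequence[str] | None = None,
    background_range: tuple[float, float] | None = None,
    min_background: int = DEFAULT_MIN_BACKGROUND,
    seed: int = 0,
) -> DropletPartition:
    """Partition raw barcodes into cell and background droplets.

    With ``cell_ids`` (e.g. the filtered Cell Ranger barcode list), the
    background is every other barcode whose library size lies within
    ``background_range`` (default: [1, smallest cell library - 1]). Without
    ``cell_ids``, a two-component mixture on log10 library size assigns the
    low mode to background and the high mode to cells, leaving the barcodes
    between the modes unassigned.
    """
    lib = library_sizes(m)
    lib_s = pd.Series(lib, index=list(m.barcode_ids))

    if cell_ids is not None:
        cell_set = set(cell_ids)
        known = set(m.barcode_ids)
        missing = cell_set - known
        if missing:
            raise KeyError(f"cell_ids not in matrix: {sorted(missing)[:5]}")
        cell_mask = np.array([b in cell_set for b in m.barcode_ids], dtype=bool)
        if cell_mask.all():
            raise ValueError("cell_ids cover every barcode; background is empty")
        cell_lower = float(lib[cell_mask].min()) if cell_mask.any() else np.inf
        if background_range is None:
            lo, hi = 1.0, max(1.0, cell_lower - 1.0)
        else:
            lo, hi = float(background_range[0]), float(background_range[1])
        bg_mask = ~cell_mask & (lib >= lo) & (lib <= hi)
        method = "cell_ids"
    else:
        if background_range is not None:
            lo, hi = float(background_range[0]), float(background_range[1])
            bg_mask = (lib >= lo) & (lib <= hi)
            cell_lower = hi  # cells start where the background band ends
            cell_mask = lib > hi
            method = "explicit_range"
        else:
            bg_upper, cell_lower = _auto_split(lib, seed=seed)
            lo, hi = 1.0, bg_upper
            bg_mask = (lib >= lo) & (lib <= hi)
            cell_mask = lib >= cell_lower
            method = "mixture_split"

    n_bg = int(bg_mask.sum())
    if n_bg < min_background:
        raise ValueError(
            f"only {n_bg} background droplets found (< min_background="
            f"{min_background}); supply an explicit background_range"
        )
    if n_bg < 5000:
        logger.warning(
            "only %d background droplets; ambient mean/SD estimates may be "
            "unstable (typical raw outputs provide tens of thousands)", n_bg,
        )
    return DropletPartition(
        cell_barcodes=[b for b, c in zip(m.barcode_ids, cell_mask) if c],
        background_barcodes=[b for b, g in zip(m.barcode_ids, bg_mask) if g],
        library_size=lib_s,
        thresholds=(lo, hi, float(cell_lower)),
        method=method,
    )


def filter_low_signal_proteins(
    m: CountMatrix,
    cells: Sequence[str],
    min_max_count: int = DEFAULT_MIN_MAX_COUNT,
) -> tuple[CountMatrix, list[str]]:
    """Drop proteins with max UMI count below ``min_max_count`` across cells.

    The decision uses cell columns only; removal applies to the whole
    matrix (cell and background columns alike).
    """
    cell_idx = m.barcode_index(list(cells))
    if cell_idx.size == 0:
        raise ValueError("no cell barcodes given")
    sub = m.counts[:, cell_idx]
    max_per_protein = np.asarray(sub.max(axis=1).todense()).ravel() if sub.nnz else np.zeros(m.n_proteins)
    keep = max_per_protein >= min_max_count
    if not keep.any():
        raise ValueError(
            f"every protein has max cell count < {min_max_count}; nothing left"
        )
    removed = [str(p) for p in m.protein_ids[~keep]]
    removed_iso = [str(p) for p in m.protein_ids[~keep & m.isotype_flags]]
    if removed_iso:
        warnings.warn(
            f"isotype control(s) removed by the low-signal filter: {removed_iso}",
            RuntimeWarning,
        )
    if removed:
        logger.info("removed %d low-signal protein(s): %s", len(removed), removed)
    return m.subset_proteins(keep), removed


def qc_background(
    m: CountMatrix,
    p: DropletPartition,
    upper_quantile: float = DEFAULT_QC_QUANTILE,
) -> DropletPartition:
    """Drop background droplets above an upper library-size quantile.

    Guards the ambient estimate against cell-containing droplets that
    slipped into the background band (doublet-like large barcodes); cells
    are untouched.
    """
    if not (0 < upper_quantile <= 1):
        raise ValueError("upper_quantile must be in (0, 1]")
    bg_lib = p.library_size[p.background_barcodes].to_numpy(dtype=float)
    if bg_lib.size <= 1:
        return p
    cutoff = float(np.quantile(bg_lib, upper_quantile))
    keep = [b for b, v in zip(p.background_barcodes, bg_lib) if v <= cutoff]
    n_drop = len(p.background_barcodes) - len(keep)
    if n_drop:
        logger.info("background QC removed %d droplet(s) above %.1f UMI", n_drop, cutoff)
    lo, hi, cell_lower = p.thresholds
    return DropletPartition(
        cell_barcodes=list(p.cell_barcodes),
        background_barcodes=keep,
        library_size=p.library_size,
        thresholds=(lo, min(hi, cutoff), cell_lower),
        method=p.method + "+qc",
    )
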