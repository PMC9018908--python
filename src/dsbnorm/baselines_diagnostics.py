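"""Baseline ADT transforms and model-assumption diagnostics.

Baselines: the centered log-ratio transform in both of its margins (across
proteins within each cell, the original convention; or across cells within
each protein, the later and now more common one) and library-size-scaled log
normalization. These are comparison transforms, not part of the dsb pipeline.

Diagnostics check, on any dataset, the assumptions the denoising step rests
on: that a two-component mixture fits most cells best (BIC sweep over
k = 1..6), that the per-cell background mean mu1, the isotype controls, the
library size and the technical component lambda share variance, and that
group-level normalized values are not driven by what sits in empty droplets
(correlation of per-group medians with the 98th-percentile log10 empty
level).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dsb_core import (
    ambient_correct,
    cell_background_means,
    dsb_normalize,
    estimate_ambient,
    technical_component,
)
from .droplet_selection import library_sizes
from .io_matrices import CountMatrix, flag_isotypes
from .mixtures import sweep_cells

logger = logging.getLogger(__name__)

DEFAULT_POSITIVITY_THRESHOLD = 3.5
EMPTY_REFERENCE_QUANTILE = 0.98


def clr(m: CountMatrix, margin: str = "cells", pseudo: float = 1.0) -> np.ndarray:
    """Centered log-ratio transform of the count matrix.

    ``margin='proteins'``: center ln(count + pseudo) within each cell across
    proteins (values sum to zero per cell). ``margin='cells'``: center
    within each protein across cells.
    """
    if pseudo <= 0:
        raise ValueError("pseudo must be positive")
    L = np.log(m.dense() + pseudo)
    if margin == "proteins":
        return L - L.mean(axis=0, keepdims=True)
    if margin == "cells":
        return L - L.mean(axis=1, keepdims=True)
    raise ValueError("margin must be 'cells' or 'proteins'")


def log_libsize_normalize(m: CountMatrix, scale: float = 1e4) -> np.ndarray:
    """``ln(1 + scale * count / library_size)`` per entry."""
    if scale <= 0:
        raise ValueError("scale must be positive")
    lib = library_sizes(m).astype(float)
    if np.any(lib == 0):
        raise ValueError("zero library size column(s); cannot normalize")
    return np.log1p(scale * m.dense() / lib[None, :])


@dataclass
class DiagnosticsReport:
    """Model-assumption diagnostics for a dataset."""

    bic_table: pd.DataFrame        # cell_id, best_k, bic_k1..bic_kK
    k2_fraction: float
    noise_corr: pd.DataFrame       # isotypes, mu1, library_size, lambda
    positivity: pd.DataFrame | None = None   # group x protein medians + flags
    empty_vs_group: pd.DataFrame | None = None
    group_corr: pd.Series | None = None      # Pearson r per group
    threshold: float = DEFAULT_POSITIVITY_THRESHOLD


def assumption_report(
    cells: CountMatrix,
    background: CountMatrix,
    isotype_names=None,
    pseudocount: float = 10.0,
    k_max: int = 6,
    restarts: int = 3,
    seed: int = 0,
    threshold: float = DEFAULT_POSITIVITY_THRESHOLD,
    groups: pd.Series | dict | None = None,
    min_group_size: int = 5,
) -> DiagnosticsReport:
    """Run the dsb model diagnostics on a cells/background pair.

    Performs step I, sweeps per-cell mixture order k = 1..``k_max`` by BIC,
    and assembles the noise-variable correlation structure. With per-cell
    ``groups`` (barcode -> label) it adds per-group per-protein median dsb
    values, positivity calls at ``threshold``, and their correlation with
    the empty-droplet 98th-percentile reference.
    """
    iso_flags = (
        flag_isotypes(cells.protein_ids, names=list(isotype_names))
        if isotype_names is not None
        else cells.isotype_flags
    )
    profile = estimate_ambient(background, P=pseudocount)
    keep = np.isin(cells.protein_ids, profile.protein_ids)
    cells_used = cells.subset_proteins(keep) if not keep.all() else cells
    iso_flags = iso_flags[keep]
    Y = ambient_correct(cells_used, profile)

    best_k, fits = sweep_cells(Y.T, k_max=k_max, restarts=restarts, seed=seed)
    k2_fraction = float(np.mean(best_k == 2))
    bic_cols = {f"bic_k{k}": fits[k].bic for k in fits}
    bic_table = pd.DataFrame(
        {"cell_id": cells_used.barcode_ids, "best_k": best_k, **bic_cols}
    )

    mu1, _ = cell_background_means(Y, restarts=restarts, seed=seed)
    iso_values = Y[iso_flags, :].T
    iso_ids = [str(p) for p in cells_used.protein_ids[iso_flags]]
    tc = technical_component(
        mu1,
        iso_values if iso_values.shape[1] else None,
        cell_ids=cells_used.barcode_ids,
        column_names=["mu1"] + iso_ids if iso_values.shape[1] else ["mu1"],
    )
    lib = library_sizes(cells_used).astype(float)
    noise_vars = {name: iso_values[:, j] for j, name in enumerate(iso_ids)}
    noise_vars["mu1"] = mu1
    noise_vars["library_size"] = lib
    noise_vars["lambda"] = tc.lam
    noise_df = pd.DataFrame(noise_vars)
    noise_corr = noise_df.corr(method="pearson")

    positivity = empty_vs_group = group_corr = None
    if groups is not None:
        groups = pd.Series(groups)
        norm = dsb_normalize(
            cells_used, background, P=pseudocount,
            isotype_names=iso_ids or None,
            use_isotype=bool(iso_ids), restarts=restarts, seed=seed,
        )
        vals = norm.to_frame()
        empty_ref = np.quantile(
            np.log10(background.dense() + 1.0), EMPTY_REFERENCE_QUANTILE, axis=1
        )
        empty_ref = pd.Series(empty_ref, index=background.protein_ids)
        empty_ref = empty_ref.reindex(norm.protein_ids)
        pos_rows, evg_rows, corr_vals = [], [], {}
        for g, members in groups.groupby(groups):
            ids = [b for b in members.index if b in set(norm.cell_ids)]
            if len(ids) < min_group_size:
                warnings.warn(
                    f"group {g!r} has {len(ids)} cells (< {min_group_size}); skipped",
                    RuntimeWarning,
                )
                continue
            med = vals[ids].median(axis=1)
            for p in med.index:
                pos_rows.append(
                    {"group": g, "protein": p, "median_dsb": med[p],
                     "positive": bool(med[p] > threshold)}
                )
                evg_rows.append(
                    {"group": g, "protein": p, "median_dsb": med[p],
                     "empty_q98_log10": empty_ref[p]}
                )
            if len(med) >= 2:
                corr_vals[g] = float(np.corrcoef(med.to_numpy(), empty_ref.to_numpy())[0, 1])
        positivity = pd.DataFrame(pos_rows)
        empty_vs_group = pd.DataFrame(evg_rows)
        group_corr = pd.Series(corr_vals, name="pearson_r")

    return DiagnosticsReport(
        bic_table=bic_table,
        k2_fraction=k2_fraction,
        noise_corr=noise_corr,
        positivity=positivity,
        empty_vs_group=empty_vs_group,
        group_corr=group_corr,
        threshold=threshold,
    )


def negative_population_check(
    cells: CountMatrix,
    background: CountMatrix,
    negatives: dict,
) -> pd.DataFrame:
    """Compare protein levels in designated negative cells vs empty droplets.

    ``negatives`` maps protein id -> iterable of cell barcodes known (or
    assumed) not to express that protein. Returns per-protein mean
    ``log10(count + 1)`` in the negative cells and in empties; the overall
    Pearson r across proteins is stored in ``df.attrs['pearson_r']`` (NaN
    when fewer than two proteins are reported).
    """
    log_cells = np.log10(cells.dense() + 1.0)
    log_empty_mean = np.log10(background.dense() + 1.0).mean(axis=1)
    empty_by_protein = dict(zip(background.protein_ids, log_empty_mean))
    prot_index = {p: i for i, p in enumerate(cells.protein_ids)}
    rows = []
    for protein, ids in negatives.items():
        ids = list(ids)
        if not ids:
            continue
        if protein not in prot_index:
            raise KeyError(f"unknown protein {protein!r}")
        cols = cells.barcode_index(ids)
        rows.append(
            {
                "protein": protein,
                "negative_mean_log10": float(log_cells[prot_index[protein], cols].mean()),
                "empty_mean_log10": float(empty_by_protein[protein]),
            }
        )
    df = pd.DataFrame(rows)
    if len(df) >= 2:
        df.attrs["pearson_r"] = float(
            np.corrcoef(df["negative_mean_log10"], df["empty_mean_log10"])[0, 1]
        )
    else:
        df.attrs["pearson_r"] = float("nan")
    return df
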