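"""The dsb normalization algorithm.

Step I (ambient correction): per-protein mean and SD of ln(count + P) over
empty droplets define an ambient noise profile; counts in cell-containing
droplets are rescaled as

    Y[p, i] = (ln(x[p, i] + P) - mu_n[p]) / sigma_n[p]

so a value is read as "standard deviations above the expected ambient
background" of that protein. P is a pseudocount (default 10) guarding the
log at zero and stabilizing small counts.

Step II (cell-to-cell denoising): each cell's technical level is estimated
twice — as mu1, the mean of the lower component of a two-component Gaussian
mixture over that cell's ambient-corrected values (the non-staining protein
background), and as the cell's isotype-control levels. The first principal
component score lambda of the combined noise matrix [mu1, isotypes] is the
cell's "technical component", which is regressed out of Y protein by protein
(ordinary least squares on the centered covariate, keeping the intercept so
per-protein means are preserved).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from . import __version__ as _pkg_version
from .io_matrices import CountMatrix, flag_isotypes
from .mixtures import BatchMixtureFit, fit_cells

logger = logging.getLogger(__name__)

DEFAULT_PSEUDOCOUNT = 10.0


@dataclass
class AmbientProfile:
    """Per-protein ambient noise estimate from empty droplets.

    ``mu_n``/``sigma_n`` are the mean and sample SD (n-1 denominator) of
    ``ln(count + P)`` across background droplets. Proteins with zero
    variance across empties carry no estimable ambient scale and are
    dropped (ids kept in ``dropped_proteins``).
    """

    protein_ids: np.ndarray
    mu_n: np.ndarray
    sigma_n: np.ndarray
    pseudocount: float
    n_background: int
    dropped_proteins: list[str] = field(default_factory=list)


@dataclass
class TechnicalComponent:
    """Per-cell technical noise summary (step II).

    ``lam`` is the first principal-component score of the z-scored noise
    matrix ``[mu1, isotype_1..q]`` across cells, sign-fixed so it correlates
    non-negatively with the row mean of that matrix ("more technical
    signal" is positive). It has zero mean over cells by construction.
    """

    cell_ids: np.ndarray
    mu1: np.ndarray
    isotype_values: np.ndarray  # (cells, q); q may be 0
    lam: np.ndarray
    loadings: np.ndarray
    sign_fixed: bool
    noise_columns: list[str] = field(default_factory=list)


@dataclass
class NormalizedMatrix:
    """dsb-normalized values (proteins x cells) plus provenance.

    Units: standard deviations above the expected ambient background,
    plus/minus the technical-component adjustment when denoising is on.
    """

    values: np.ndarray
    protein_ids: np.ndarray
    cell_ids: np.ndarray
    isotype_flags: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(self.values)):
            raise ValueError("normalized values must be finite")

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.values, index=self.protein_ids, columns=self.cell_ids)


# ---------------------------------------------------------------------------
# step I


def estimate_ambient(background: CountMatrix, P: float = DEFAULT_PSEUDOCOUNT) -> AmbientProfile:
    """Estimate per-protein ambient background from empty droplets."""
    if P <= 0:
        raise ValueError("pseudocount P must be positive")
    if background.n_barcodes < 2:
        raise ValueError(
            f"need at least 2 background droplets, got {background.n_barcodes}"
        )
    logc = np.log(background.dense() + P)
    mu = logc.mean(axis=1)
    sigma = logc.std(axis=1, ddof=1)
    keep = sigma > 1e-12
    dropped = [str(p) for p in background.protein_ids[~keep]]
    if not keep.any():
        raise ValueError("all proteins have zero variance across background droplets")
    if dropped:
        logger.warning(
            "dropping %d protein(s) with zero ambient variance: %s",
            len(dropped), dropped,
        )
    return AmbientProfile(
        protein_ids=background.protein_ids[keep].copy(),
        mu_n=mu[keep],
        sigma_n=sigma[keep],
        pseudocount=float(P),
        n_background=background.n_barcodes,
        dropped_proteins=dropped,
    )


def ambient_correct(cells: CountMatrix, profile: AmbientProfile) -> np.ndarray:
    """Rescale cell counts onto the ambient-SD scale (step I).

    Rows of the result follow the cell matrix's protein order; every cell
    protein must be present in the profile.
    """
    lookup = {p: i for i, p in enumerate(profile.protein_ids)}
    try:
        idx = np.array([lookup[p] for p in cells.protein_ids], dtype=int)
    except KeyError as exc:
        raise KeyError(
            f"protein {exc.args[0]!r} has no ambient profile (dropped or absent)"
        ) from None
    logc = np.log(cells.dense() + profile.pseudocount)
    return (logc - profile.mu_n[idx][:, None]) / profile.sigma_n[idx][:, None]


# ---------------------------------------------------------------------------
# step II


def cell_background_means(
    Y: np.ndarray,
    restarts: int = 3,
    seed: int = 0,
    tol: float = 1e-6,
    max_iter: int = 200,
    k: int = 2,
) -> tuple[np.ndarray, BatchMixtureFit]:
    """Per-cell background mean mu1 from a k=2 mixture over proteins.

    ``Y`` is the ambient-corrected matrix (proteins x cells). For k = 2 the
    background mean is the lower component's mean. For k >= 3 it is the mean
    of the *dominant* (highest-weight) component among the k-1 lower ones:
    the non-staining background proteins are the most numerous low
    population in a cell, and a low-weight extra component typically models
    a few tail proteins rather than the background itself. Cells whose
    mixture fit falls back (constant protein vector) get mu1 = mean of the
    values below the cell's median and stay flagged in the returned fits.
    """
    Y = np.asarray(Y, dtype=float)
    n_prot, n_cells = Y.shape
    if n_prot < 4:
        raise ValueError(
            f"per-cell mixture needs >= 4 proteins, got {n_prot}"
        )
    fits = fit_cells(Y.T, k=k, restarts=restarts, seed=seed, tol=tol, max_iter=max_iter)
    if k <= 2:
        mu1 = fits.means[:, 0].copy()
    else:
        dominant = np.argmax(fits.weights[:, : k - 1], axis=1)
        mu1 = fits.means[np.arange(n_cells), dominant]
    fb = np.flatnonzero(fits.fallback_used)
    for i in fb:
        col = Y[:, i]
        below = col[col < np.median(col)]
        mu1[i] = below.mean() if below.size else col.mean()
    return mu1, fits


def technical_component(
    mu1: np.ndarray,
    isotype_values: np.ndarray | None,
    cell_ids: Sequence[str] | None = None,
    column_names: Sequence[str] | None = None,
) -> TechnicalComponent:
    """First principal component of the per-cell noise matrix.

    Columns (mu1 plus each isotype's ambient-corrected level) are centered
    and unit-scaled across cells before the PCA, so lambda is invariant to
    per-column rescaling. Zero-variance columns are dropped with a warning.
    """
    mu1 = np.asarray(mu1, dtype=float).ravel()
    n_cells = mu1.size
    if n_cells < 2:
        raise ValueError("technical component needs at least 2 cells")
    if isotype_values is None:
        isotype_values = np.empty((n_cells, 0))
    iso = np.asarray(isotype_values, dtype=float)
    if iso.ndim == 1:
        iso = iso[:, None]
    if iso.shape[0] != n_cells:
        raise ValueError("isotype_values rows must match cells")
    noise = np.column_stack([mu1, iso])
    names = list(column_names) if column_names is not None else (
        ["mu1"] + [f"isotype_{j + 1}" for j in range(iso.shape[1])]
    )

    sd = noise.std(axis=0, ddof=1)
    keep = sd > 1e-12
    if not keep.all():
        dropped = [names[j] for j in np.flatnonzero(~keep)]
        warnings.warn(
            f"dropping zero-variance noise column(s): {dropped}", RuntimeWarning
        )
    if not keep.any():
        raise ValueError("all noise-matrix columns have zero variance")
    noise = noise[:, keep]
    names = [n for n, k_ in zip(names, keep) if k_]
    z = (noise - noise.mean(axis=0)) / noise.std(axis=0, ddof=1)

    u, s, vt = np.linalg.svd(z, full_matrices=False)
    lam = u[:, 0] * s[0]
    loadings = vt[0]
    row_mean = z.mean(axis=1)
    sign_fixed = False
    if np.dot(lam - lam.mean(), row_mean - row_mean.mean()) < 0:
        lam = -lam
        loadings = -loadings
        sign_fixed = True
    lam = lam - lam.mean()  # numerically exact zero mean
    return TechnicalComponent(
        cell_ids=np.asarray(cell_ids if cell_ids is not None else np.arange(n_cells), dtype=object),
        mu1=mu1,
        isotype_values=iso,
        lam=lam,
        loadings=loadings,
        sign_fixed=sign_fixed,
        noise_columns=names,
    )


def remove_technical(Y: np.ndarray, tc: TechnicalComponent) -> np.ndarray:
    """Regress the technical component out of each protein (step II output).

    Per protein p the OLS fit ``Y_p = alpha_p + beta_p * (lambda - mean)``
    is removed, returning intercept plus residuals: per-protein means are
    preserved and residuals are orthogonal to lambda. A constant lambda
    leaves Y unchanged (slope undefined) with a warning.
    """
    Y = np.asarray(Y, dtype=float)
    lam = np.asarray(tc.lam, dtype=float).ravel()
    if Y.shape[1] != lam.size:
        raise ValueError("lambda length must match the number of cells")
    if not np.all(np.isfinite(lam)):
        raise ValueError("lambda must be finite")
    lam_c = lam - lam.mean()
    ss = float(np.dot(lam_c, lam_c))
    if ss <= 1e-300:
        warnings.warn(
            "technical component is constant; returning input unchanged",
            RuntimeWarning,
        )
        return Y.copy()
    beta = Y @ lam_c / ss  # (proteins,)
    return Y - beta[:, None] * lam_c[None, :]


# ---------------------------------------------------------------------------
# the single-call pipeline


def dsb_normalize(
    cells: CountMatrix,
    background: CountMatrix,
    P: float = DEFAULT_PSEUDOCOUNT,
    denoise: bool = True,
    use_isotype: bool = True,
    isotype_names: Sequence[str] | None = None,
    restarts: int = 3,
    tol: float = 1e-6,
    max_iter: int = 200,
    seed: int = 0,
) -> NormalizedMatrix:
    """Run the full dsb pipeline on cell and background count matrices.

    ``estimate_ambient -> ambient_correct`` always; when ``denoise`` is on,
    ``cell_background_means -> technical_component -> remove_technical``
    follow. Isotype proteins are normalized and returned like any other
    protein but stay flagged so downstream clustering can exclude them.
    """
    overlap = set(cells.barcode_ids) & set(background.barcode_ids)
    if overlap:
        raise ValueError(
            f"{len(overlap)} barcode(s) appear in both cells and background, "
            f"e.g. {sorted(overlap)[:3]}"
        )
    shared = set(cells.protein_ids) & set(background.protein_ids)
    if not shared:
        raise ValueError("cells and background share no proteins")

    if isotype_names is not None:
        iso_flags = flag_isotypes(cells.protein_ids, names=list(isotype_names))
    else:
        iso_flags = cells.isotype_flags.copy()

    profile = estimate_ambient(background, P=P)
    profile_set = set(profile.protein_ids)
    keep = np.array([p in profile_set for p in cells.protein_ids], dtype=bool)
    if not keep.all():
        logger.warning(
            "excluding %d cell protein(s) without ambient profile: %s",
            int((~keep).sum()), list(cells.protein_ids[~keep]),
        )
    cells_used = cells.subset_proteins(keep) if not keep.all() else cells
    iso_flags = iso_flags[keep]
    Y = ambient_correct(cells_used, profile)

    provenance: dict = {
        "package": "dsbnorm",
        "version": _pkg_version,
        "pseudocount": float(P),
        "denoise": bool(denoise),
        "use_isotype": bool(use_isotype),
        "isotype_proteins": [str(p) for p in cells_used.protein_ids[iso_flags]],
        "n_cells": cells_used.n_barcodes,
        "n_background": background.n_barcodes,
        "n_proteins": cells_used.n_proteins,
        "dropped_zero_variance_proteins": profile.dropped_proteins,
        "seed": int(seed),
        "em": {"restarts": restarts, "tol": tol, "max_iter": max_iter},
    }

    if not denoise:
        return NormalizedMatrix(
            values=Y,
            protein_ids=cells_used.protein_ids.copy(),
            cell_ids=cells_used.barcode_ids.copy(),
            isotype_flags=iso_flags,
            provenance=provenance,
        )

    if use_isotype and not iso_flags.any():
        raise ValueError(
            "use_isotype=True but no isotype-control proteins found; pass "
            "isotype_names, or set use_isotype=False to denoise on the "
            "mixture background mean alone"
        )

    mu1, fits = cell_background_means(
        Y, restarts=restarts, seed=seed, tol=tol, max_iter=max_iter
    )
    iso_values = Y[iso_flags, :].T if (use_isotype and iso_flags.any()) else None
    iso_cols = (
        ["mu1"] + [str(p) for p in cells_used.protein_ids[iso_flags]]
        if iso_values is not None
        else ["mu1"]
    )
    tc = technical_component(
        mu1, iso_values, cell_ids=cells_used.barcode_ids, column_names=iso_cols
    )
    values = remove_technical(Y, tc)
    provenance["n_fallback_cells"] = int(fits.fallback_used.sum())
    provenance["noise_columns"] = tc.noise_columns
    return NormalizedMatrix(
        values=values,
        protein_ids=cells_used.protein_ids.copy(),
        cell_ids=cells_used.barcode_ids.copy(),
        isotype_flags=iso_flags,
        provenance=provenance,
    )
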