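"""Spectral preprocessing chain for SERS serum spectra.

Order of operations (see the methods note for the rationale where the
workflow leaves room):

1. wavenumber range selection (400-1800 cm^-1) and interpolation by local
   quadratic regression (loess-style, tricube weights) onto a uniform
   2 cm^-1 grid;
2. technical-replicate averaging (requires the common grid, hence after
   interpolation);
3. iterative modified-polynomial (modpoly) baseline subtraction, degree 4;
4. cropping to 430-1730 cm^-1 to drop baseline edge artifacts;
5. vector normalization (unit Euclidean norm) — last, so the final
   representation has exactly unit norm on the cropped range.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .spectra import RaggedSpectra, SpectraSet


@dataclass
class PreprocessConfig:
    select_range: tuple = (400.0, 1800.0)  # cm^-1
    grid_spacing: float = 2.0  # cm^-1
    smoother_span: float = 0.008  # fraction of input points per local fit
    baseline_degree: int = 4
    baseline_tol: float = 1e-4  # relative L2 change of the fitted baseline
    baseline_max_iter: int = 100
    final_crop: tuple = (430.0, 1730.0)  # cm^-1

    def __post_init__(self) -> None:
        lo, hi = self.select_range
        clo, chi = self.final_crop
        if not (lo <= clo and chi <= hi):
            raise ValueError("select_range must contain final_crop")
        if self.grid_spacing <= 0 or self.baseline_tol <= 0:
            raise ValueError("grid_spacing and baseline_tol must be > 0")
        if self.baseline_degree < 0:
            raise ValueError("baseline_degree must be >= 0")

    @property
    def grid(self) -> np.ndarray:
        lo, hi = self.select_range
        n = int(round((hi - lo) / self.grid_spacing)) + 1
        return lo + self.grid_spacing * np.arange(n)


# ---------------------------------------------------------------------------
# loess-style interpolation
# ---------------------------------------------------------------------------

def loess_matrix(x_in: np.ndarray, grid: np.ndarray, span: float,
                 degree: int = 2) -> np.ndarray:
    """Linear smoother matrix L with (L @ y)[j] = local polynomial fit of
    (x_in, y) evaluated at grid[j].

    Each output point uses the ``max(degree+1, round(span*n))`` nearest input
    points with tricube weights. Precomputing L makes interpolating a whole
    intensity matrix a single matmul.
    """
    x_in = np.asarray(x_in, dtype=float)
    n = x_in.size
    k = max(degree + 1, int(round(span * n)))
    k = min(k, n)
    L = np.zeros((grid.size, n))
    for j, x0 in enumerate(grid):
        d = np.abs(x_in - x0)
        idx = np.argpartition(d, k - 1)[:k]
        dmax = d[idx].max()
        if dmax == 0:
            dmax = 1.0
        w = (1.0 - (d[idx] / (1.0001 * dmax)) ** 3) ** 3
        t = x_in[idx] - x0
        X = np.vander(t, degree + 1, increasing=True)
        WX = w[:, None] * X
        # value at x0 = first coefficient of the weighted LS fit
        beta_rows = np.linalg.solve(X.T @ WX, WX.T)
        L[j, idx] = beta_rows[0]
    return L


def interpolate_to_grid(axis: np.ndarray, intensities: np.ndarray,
                        config: PreprocessConfig | None = None):
    """Interpolate spectra from an arbitrary increasing axis onto the uniform
    analysis grid via local quadratic regression.

    ``intensities`` may be 1-D (one spectrum) or 2-D (rows = spectra).
    Raises if the input axis does not cover the selection range.
    """
    config = config or PreprocessConfig()
    grid = config.grid
    axis = np.asarray(axis, dtype=float)
    if axis[0] > grid[0] or axis[-1] < grid[-1]:
        raise ValueError(
            f"input axis [{axis[0]:.1f}, {axis[-1]:.1f}] does not cover the "
            f"selection range [{grid[0]:.1f}, {grid[-1]:.1f}] cm^-1"
        )
    L = loess_matrix(axis, grid, config.smoother_span)
    y = np.asarray(intensities, dtype=float)
    out = y @ L.T if y.ndim == 2 else L @ y
    return grid, out


# ---------------------------------------------------------------------------
# replicate averaging
# ---------------------------------------------------------------------------

def average_replicates(ss: SpectraSet) -> SpectraSet:
    """Collapse technical replicates: one spectrum per sample_id, the
    arithmetic mean of its replicates. Requires a shared axis (interpolate
    first for unaligned raw data)."""
    if isinstance(ss, RaggedSpectra):
        raise ValueError(
            "replicates sit on differing axes; interpolate to the common "
            "grid before averaging"
        )
    meta = ss.meta
    order = meta["sample_id"].drop_duplicates().tolist()
    rows, spectra = [], []
    for sid in order:
        mask = (meta["sample_id"] == sid).to_numpy()
        spectra.append(ss.intensities[mask].mean(axis=0))
        first = meta.loc[mask].iloc[0].to_dict()
        first["spectrum_id"] = sid
        first["replicate"] = 1
        first["n_replicates_averaged"] = int(mask.sum())
        rows.append(first)
    return SpectraSet(axis=ss.axis.copy(), intensities=np.vstack(spectra),
                      meta=pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# modified-polynomial baseline
# ---------------------------------------------------------------------------

def modpoly_baseline(
    y: np.ndarray,
    x: np.ndarray | None = None,
    degree: int = 4,
    tol: float = 1e-4,
    max_iter: int = 100,
):
    """Iterative modified-polynomial-fitting baseline estimate.

    Fit a least-squares polynomial to the working curve, clip the working
    curve to the fit (``min(curve, fit)``) so peaks cannot inflate the
    baseline, and iterate until the fitted curve's relative L2 change drops
    below ``tol`` or ``max_iter`` is reached.

    Returns ``(corrected, baseline, converged)``; non-convergence sets the
    flag and warns but does not raise.
    """
    y = np.asarray(y, dtype=float)
    n = y.size
    if degree >= n:
        raise ValueError(f"polynomial degree {degree} >= number of points {n}")
    if x is None:
        x = np.arange(n, dtype=float)
    work = y.copy()
    fit_prev = None
    converged = False
    scale = np.linalg.norm(y)
    if scale == 0:
        scale = 1.0
    for _ in range(max_iter):
        poly = np.polynomial.Polynomial.fit(x, work, degree)
        fit = poly(x)
        if fit_prev is not None:
            # relative to the spectrum scale: the fit itself can be ~0 for
            # baseline-free input, which would make a fit-normed criterion
            # never trigger
            change = np.linalg.norm(fit - fit_prev) / scale
            if change < tol:
                converged = True
                fit_prev = fit
                break
        fit_prev = fit
        work = np.minimum(work, fit)
    if not converged:
        warnings.warn(
            f"modpoly baseline did not converge in {max_iter} iterations",
            RuntimeWarning,
            stacklevel=2,
        )
    baseline = fit_prev
    return y - baseline, baseline, converged


# ---------------------------------------------------------------------------
# normalization and cropping
# ---------------------------------------------------------------------------

def vector_normalize(y: np.ndarray) -> np.ndarray:
    """Scale spectra (1-D, or rows of a 2-D array) to unit Euclidean norm."""
    y = np.asarray(y, dtype=float)
    if y.ndim == 1:
        norm = np.linalg.norm(y)
        if norm == 0:
            raise ValueError("cannot vector-normalize an all-zero spectrum")
        return y / norm
    norms = np.linalg.norm(y, axis=1, keepdims=True)
    if np.any(norms == 0):
        raise ValueError("cannot vector-normalize an all-zero spectrum")
    return y / norms


def crop_range(axis: np.ndarray, intensities: np.ndarray,
               lo: float = 430.0, hi: float = 1730.0):
    """Keep grid points p with lo <= p <= hi (closed interval)."""
    axis = np.asarray(axis, dtype=float)
    if lo < axis[0] or hi > axis[-1]:
        raise ValueError(
            f"crop [{lo}, {hi}] extends beyond the grid "
            f"[{axis[0]}, {axis[-1]}]"
        )
    mask = (axis >= lo) & (axis <= hi)
    if not mask.any():
        raise ValueError(f"crop [{lo}, {hi}] keeps no grid point")
    y = np.asarray(intensities, dtype=float)
    return axis[mask], (y[:, mask] if y.ndim == 2 else y[mask])


# ---------------------------------------------------------------------------
# full pipeline
# ---------------------------------------------------------------------------

def preprocess_pipeline(
    data: SpectraSet | RaggedSpectra,
    config: PreprocessConfig | None = None,
    average: bool = True,
):
    """Run the full chain; returns ``(SpectraSet, provenance)`` where
    provenance is a list of per-step dicts (step name + key parameters)."""
    config = config or PreprocessConfig()
    provenance: list[dict] = []

    # 1. interpolate to uniform grid
    if isinstance(data, RaggedSpectra):
        grid = config.grid
        mats = []
        for _, ax, y in data.spectra:
            _, yi = interpolate_to_grid(ax, y, config)
            mats.append(yi)
        ss = SpectraSet(axis=grid, intensities=np.vstack(mats),
                        meta=data.meta.copy())
    else:
        grid, Y = interpolate_to_grid(data.axis, data.intensities, config)
        ss = SpectraSet(axis=grid, intensities=Y, meta=data.meta.copy())
    provenance.append(
        {
            "step": "interpolate",
            "range_cm1": list(config.select_range),
            "spacing_cm1": config.grid_spacing,
            "smoother_span": config.smoother_span,
            "n_points": int(grid.size),
        }
    )

    # 2. replicate averaging
    if average:
        n_before = ss.n_spectra
        ss = average_replicates(ss)
        provenance.append(
            {"step": "average_replicates", "n_in": n_before, "n_out": ss.n_spectra}
        )

    # 3. baseline correction
    corrected = np.empty_like(ss.intensities)
    n_unconverged = 0
    for i in range(ss.n_spectra):
        corrected[i], _, conv = modpoly_baseline(
            ss.intensities[i],
            x=ss.axis,
            degree=config.baseline_degree,
            tol=config.baseline_tol,
            max_iter=config.baseline_max_iter,
        )
        n_unconverged += 0 if conv else 1
    ss = SpectraSet(ss.axis, corrected, ss.meta)
    provenance.append(
        {
            "step": "modpoly_baseline",
            "degree": config.baseline_degree,
            "tol": config.baseline_tol,
            "max_iter": config.baseline_max_iter,
            "n_unconverged": n_unconverged,
        }
    )

    # 4. crop
    axis, Y = crop_range(ss.axis, ss.intensities, *config.final_crop)
    provenance.append(
        {"step": "crop", "range_cm1": list(config.final_crop),
         "n_points": int(axis.size)}
    )

    # 5. vector normalization
    Y = vector_normalize(Y)
    provenance.append({"step": "vector_normalize", "norm": "L2"})

    return SpectraSet(axis, Y, ss.meta), provenance
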