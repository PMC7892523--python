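"""In-memory containers for SERS spectra and their sample metadata.

A :class:`SpectraSet` holds a shared wavenumber axis, an intensity matrix
(one row per spectrum), and a per-spectrum metadata table. It is the object
every stage of the pipeline consumes and produces. Spectra read from long
tables whose axes differ end up in a :class:`RaggedSpectra`, which must be
interpolated to a common grid before any multivariate step.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: metadata columns that must always be present
REQUIRED_META = ("spectrum_id", "sample_id", "replicate")
#: optional metadata columns preserved verbatim
OPTIONAL_META = ("class", "batch", "day", "operator")

CLASS_COLUMN = "class"


@dataclass
class SpectraSet:
    """Wavenumber axis + intensity matrix + per-spectrum metadata.

    Parameters
    ----------
    axis : ndarray, shape (n_points,)
        Wavenumbers in cm^-1, strictly increasing.
    intensities : ndarray, shape (n_spectra, n_points)
        Intensities in arbitrary units; one row per spectrum.
    meta : DataFrame
        One row per spectrum; must carry ``spectrum_id``, ``sample_id`` and
        ``replicate``; ``class`` (H0T/CTR), ``batch``, ``day`` and
        ``operator`` are optional.
    """

    axis: np.ndarray
    intensities: np.ndarray
    meta: pd.DataFrame

    def __post_init__(self) -> None:
        self.axis = np.asarray(self.axis, dtype=float)
        self.intensities = np.atleast_2d(np.asarray(self.intensities, dtype=float))
        if not isinstance(self.meta, pd.DataFrame):
            self.meta = pd.DataFrame(self.meta)
        self.meta = self.meta.reset_index(drop=True)

    # -- basic introspection -------------------------------------------------
    @property
    def n_spectra(self) -> int:
        return self.intensities.shape[0]

    @property
    def n_points(self) -> int:
        return self.axis.shape[0]

    @property
    def labels(self) -> pd.Series:
        if CLASS_COLUMN not in self.meta.columns:
            raise KeyError("SpectraSet metadata has no 'class' column")
        return self.meta[CLASS_COLUMN]

    @property
    def sample_ids(self) -> pd.Series:
        return self.meta["sample_id"]

    def subset(self, mask) -> "SpectraSet":
        """Row-subset (boolean mask or integer positions) of spectra + meta."""
        mask = np.asarray(mask)
        if mask.dtype == bool:
            idx = np.flatnonzero(mask)
        else:
            idx = mask
        return SpectraSet(
            axis=self.axis.copy(),
            intensities=self.intensities[idx],
            meta=self.meta.iloc[idx].reset_index(drop=True),
        )

    def copy(self) -> "SpectraSet":
        return SpectraSet(self.axis.copy(), self.intensities.copy(), self.meta.copy())

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        lo = self.axis[0] if self.n_points else float("nan")
        hi = self.axis[-1] if self.n_points else float("nan")
        return (
            f"SpectraSet(n_spectra={self.n_spectra}, n_points={self.n_points}, "
            f"range=({lo:.1f}, {hi:.1f}) cm^-1)"
        )


@dataclass
class RaggedSpectra:
    """Spectra on per-spectrum axes, pending interpolation to a shared grid."""

    spectra: list  # list of (spectrum_id, axis, intensities)
    meta: pd.DataFrame
    aligned: bool = field(default=False)

    @property
    def n_spectra(self) -> int:
        return len(self.spectra)


def validate_spectra(ss: SpectraSet) -> list[str]:
    """Check every SpectraSet invariant; return a list of violation strings.

    Never raises: an empty report means the set is valid.
    """
    report: list[str] = []
    n_meta = len(ss.meta)
    n_int = ss.intensities.shape[0]
    if n_meta != n_int:
        report.append(
            f"metadata rows ({n_meta}) != intensity rows ({n_int})"
        )
    if ss.intensities.ndim == 2 and ss.intensities.shape[1] != ss.n_points:
        report.append(
            f"axis length ({ss.n_points}) != intensity columns "
            f"({ss.intensities.shape[1]})"
        )
    if ss.n_points > 1 and not np.all(np.diff(ss.axis) > 0):
        report.append("axis not strictly increasing")
    for col in REQUIRED_META:
        if col not in ss.meta.columns:
            report.append(f"metadata missing required column '{col}'")
    if "replicate" in ss.meta.columns:
        try:
            reps = pd.to_numeric(ss.meta["replicate"])
            if (reps < 1).any():
                report.append("replicate indices must be >= 1")
        except (ValueError, TypeError):
            report.append("replicate column is not numeric")
    if "spectrum_id" in ss.meta.columns and ss.meta["spectrum_id"].duplicated().any():
        dups = ss.meta.loc[ss.meta["spectrum_id"].duplicated(), "spectrum_id"]
        report.append(f"duplicated spectrum_id(s): {sorted(set(dups))}")
    # non-finite intensities, cited by spectrum and wavenumber
    bad = ~np.isfinite(ss.intensities)
    if bad.any():
        rows, cols = np.nonzero(bad)
        for r, c in zip(rows[:10], cols[:10]):  # cap the listing
            sid = (
                ss.meta["spectrum_id"].iloc[r]
                if "spectrum_id" in ss.meta.columns and r < len(ss.meta)
                else f"row {r}"
            )
            wn = ss.axis[c] if c < ss.n_points else float("nan")
            report.append(
                f"non-finite intensity for spectrum {sid} at {wn:.1f} cm^-1"
            )
        if bad.sum() > 10:
            report.append(f"... {int(bad.sum())} non-finite values in total")
    return report
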