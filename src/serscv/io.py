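"""Delimited-text reading/writing of spectra tables and sample metadata.

Two spectra layouts are supported:

* **wide** — first column is the wavenumber; every further column is one
  spectrum (header = spectrum_id). All spectra share the axis.
* **long** — three columns ``spectrum_id, wavenumber, intensity``. Spectra
  may sit on differing axes; in that case the reader returns a
  :class:`~serscv.spectra.RaggedSpectra` flagged as unaligned, and the
  preprocessing interpolation step must run before any multivariate stage.

The canonical dialect is UTF-8, comma-delimited, '.' decimal, with a header
row; both delimiter and decimal mark are parameters because deposited
datasets vary.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .spectra import RaggedSpectra, SpectraSet


class SpectraIOError(ValueError):
    """Raised when a spectra/metadata file violates the format contract."""


def _read_csv(path, delimiter: str, decimal: str) -> pd.DataFrame:
    return pd.read_csv(path, sep=delimiter, decimal=decimal)


def _to_numeric(df: pd.DataFrame, cols, path) -> pd.DataFrame:
    for col in cols:
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna() & df[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad)[0])
            raise SpectraIOError(
                f"{path}: non-numeric cell at data row {row + 1}, "
                f"column '{col}' (value {df[col].iloc[row]!r})"
            )
        df[col] = converted
    return df


def _check_axis(axis: np.ndarray, path) -> None:
    if axis.size > 1 and not np.all(np.diff(axis) > 0):
        raise SpectraIOError(f"{path}: wavenumber axis not strictly increasing")


def read_spectra_table(
    spectra_path,
    meta_path=None,
    layout: str = "wide",
    delimiter: str = ",",
    decimal: str = ".",
):
    """Read spectra (+ optional metadata) into a SpectraSet.

    Returns a :class:`SpectraSet` when all spectra share one axis, else (long
    layout only) a :class:`RaggedSpectra` flagged unaligned. Every spectrum
    must have a metadata row when ``meta_path`` is given; a missing
    ``spectrum_id`` is a hard error naming the id.
    """
    if layout not in ("wide", "long"):
        raise ValueError(f"layout must be 'wide' or 'long', got {layout!r}")
    df = _read_csv(spectra_path, delimiter, decimal)

    if layout == "wide":
        wn_col = df.columns[0]
        df = _to_numeric(df, df.columns, spectra_path)
        axis = df[wn_col].to_numpy(dtype=float)
        _check_axis(axis, spectra_path)
        spectrum_ids = [str(c) for c in df.columns[1:]]
        intensities = df[df.columns[1:]].to_numpy(dtype=float).T
        meta = _read_meta(meta_path, spectrum_ids, delimiter, decimal)
        return SpectraSet(axis=axis, intensities=intensities, meta=meta)

    # long layout
    expected = {"spectrum_id", "wavenumber", "intensity"}
    if not expected.issubset(df.columns):
        raise SpectraIOError(
            f"{spectra_path}: long layout needs columns {sorted(expected)}, "
            f"found {list(df.columns)}"
        )
    df = _to_numeric(df, ["wavenumber", "intensity"], spectra_path)
    groups = []
    for sid, g in df.groupby("spectrum_id", sort=False):
        ax = g["wavenumber"].to_numpy(dtype=float)
        _check_axis(ax, spectra_path)
        groups.append((str(sid), ax, g["intensity"].to_numpy(dtype=float)))
    spectrum_ids = [sid for sid, _, _ in groups]
    meta = _read_meta(meta_path, spectrum_ids, delimiter, decimal)
    first_axis = groups[0][1]
    aligned = all(
        ax.shape == first_axis.shape and np.array_equal(ax, first_axis)
        for _, ax, _ in groups
    )
    if aligned:
        return SpectraSet(
            axis=first_axis,
            intensities=np.vstack([y for _, _, y in groups]),
            meta=meta,
        )
    return RaggedSpectra(spectra=groups, meta=meta, aligned=False)


def _read_meta(meta_path, spectrum_ids, delimiter, decimal) -> pd.DataFrame:
    if meta_path is None:
        return pd.DataFrame(
            {
                "spectrum_id": spectrum_ids,
                "sample_id": spectrum_ids,
                "replicate": 1,
            }
        )
    meta = _read_csv(meta_path, delimiter, decimal)
    if "spectrum_id" not in meta.columns:
        raise SpectraIOError(f"{meta_path}: metadata needs a 'spectrum_id' column")
    meta["spectrum_id"] = meta["spectrum_id"].astype(str)
    known = set(meta["spectrum_id"])
    missing = [sid for sid in spectrum_ids if sid not in known]
    if missing:
        raise SpectraIOError(
            f"{meta_path}: no metadata row for spectrum_id "
            f"{missing[0]!r}" + (f" (+{len(missing) - 1} more)" if len(missing) > 1 else "")
        )
    # keep metadata in spectrum order
    meta = meta.set_index("spectrum_id").loc[spectrum_ids].reset_index()
    return meta


def write_spectra_table(ss: SpectraSet, spectra_path, meta_path,
                        layout: str = "wide") -> None:
    """Write a SpectraSet to delimited text; round-trips exactly through
    :func:`read_spectra_table` (float64 repr is lossless)."""
    if layout == "wide":
        data = {"wavenumber": ss.axis}
        ids = (
            ss.meta["spectrum_id"].astype(str).tolist()
            if "spectrum_id" in ss.meta.columns
            else [f"spec{i}" for i in range(ss.n_spectra)]
        )
        for i, sid in enumerate(ids):
            data[sid] = ss.intensities[i] if ss.n_spectra else []
        pd.DataFrame(data).to_csv(spectra_path, index=False)
    elif layout == "long":
        ids = ss.meta["spectrum_id"].astype(str).tolist()
        rows = {
            "spectrum_id": np.repeat(ids, ss.n_points),
            "wavenumber": np.tile(ss.axis, ss.n_spectra),
            "intensity": ss.intensities.ravel(),
        }
        pd.DataFrame(rows).to_csv(spectra_path, index=False)
    else:
        raise ValueError(f"layout must be 'wide' or 'long', got {layout!r}")
    ss.meta.to_csv(meta_path, index=False)
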