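"""Interpretive aggregation of the optimized partial models.

PCA loadings are sign-ambiguous, so cross-model medians are meaningless
until every model's components are sign-aligned against one reference PCA
fitted on the full preprocessed dataset. The reference feeds only this
post-hoc aggregation, never prediction, so the leakage-free figures of
merit are untouched.

Provided aggregates: per-sample median LD scores, per-sample median PC
scores with a Mann-Whitney U class comparison per component, pointwise
median loadings with interquartile ranges, class difference spectra, and
nearest-band metabolite assignment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .pcalda import fit_pca
from .simulate import BandLibrary
from .spectra import SpectraSet


@dataclass
class ReferencePCA:
    mean: np.ndarray
    loadings: np.ndarray  # n_points x a


def fit_reference_pca(X: np.ndarray, a_max: int) -> ReferencePCA:
    """One PCA on the full dataset; the sign/orientation reference for
    aggregating loadings and scores across models (visualization only)."""
    mean, loadings, _ = fit_pca(X, a_max)
    return ReferencePCA(mean=mean, loadings=loadings)


def align_component_signs(model_loadings: np.ndarray,
                          reference_loadings: np.ndarray) -> np.ndarray:
    """Flip each component of ``model_loadings`` so its inner product with
    the corresponding reference component is nonnegative. Zero inner product
    keeps sign +1. Idempotent; dimension mismatch raises."""
    L = np.asarray(model_loadings, dtype=float)
    R = np.asarray(reference_loadings, dtype=float)
    if L.shape[0] != R.shape[0]:
        raise ValueError(
            f"loading length {L.shape[0]} != reference length {R.shape[0]}"
        )
    a = L.shape[1]
    if R.shape[1] < a:
        raise ValueError(
            f"reference has {R.shape[1]} components, model needs {a}"
        )
    signs = np.ones(a)
    for k in range(a):
        ip = float(L[:, k] @ R[:, k])
        signs[k] = -1.0 if ip < 0 else 1.0
    return L * signs


def _model_signs(fm, reference: ReferencePCA) -> np.ndarray:
    L = fm.fit.loadings
    signs = np.ones(L.shape[1])
    for k in range(L.shape[1]):
        if float(L[:, k] @ reference.loadings[:, k]) < 0:
            signs[k] = -1.0
    return signs


# ---------------------------------------------------------------------------
# LD scores
# ---------------------------------------------------------------------------

def median_ld_scores(results) -> pd.DataFrame:
    """Per-sample median LD score over the repetitions in which the sample
    fell in a test fold (once per repetition).

    The discriminant is already oriented toward the positive class (the LD
    score is the positive-class log posterior odds), so no extra
    sign-fixing is needed and global orientation flips cannot change the
    output.
    """
    pred = results.predictions()
    agg = (
        pred.groupby("sample_id")
        .agg(
            median_ld=("ld_score", "median"),
            n_scores=("ld_score", "size"),
            truth=("truth", "first"),
        )
        .reset_index()
    )
    return agg


# ---------------------------------------------------------------------------
# PC scores
# ---------------------------------------------------------------------------

def median_pc_scores_by_class(results, reference: ReferencePCA,
                              n_components: int = 4):
    """Per-sample median PC score (components 1..n_components) across all
    models in whose *test* fold the sample fell, plus a two-sided
    Mann-Whitney U class comparison per component.

    A model contributes to component k only if it retained at least k
    components; samples never scored on a component get NaN there.
    """
    collect: dict[str, dict[int, list[float]]] = {}
    truth_of: dict[str, str] = {}
    for rep in results.repetitions:
        for fm in rep.fold_models:
            signs = _model_signs(fm, reference)
            scores = fm.test_scores * signs
            sub = rep.predictions[
                rep.predictions["sample_id"].isin(fm.test_ids)
            ]
            truths = dict(zip(sub["sample_id"], sub["truth"]))
            for i, sid in enumerate(fm.test_ids):
                truth_of[sid] = truths.get(sid, truth_of.get(sid))
                store = collect.setdefault(sid, {})
                for k in range(min(fm.a_opt, n_components)):
                    store.setdefault(k, []).append(float(scores[i, k]))
    rows = []
    for sid, store in collect.items():
        row = {"sample_id": sid, "truth": truth_of[sid]}
        for k in range(n_components):
            vals = store.get(k, [])
            row[f"pc{k + 1}"] = float(np.median(vals)) if vals else np.nan
        rows.append(row)
    table = pd.DataFrame(rows).sort_values("sample_id").reset_index(drop=True)

    classes = pd.unique(table["truth"])
    p_values = {}
    for k in range(n_components):
        col = f"pc{k + 1}"
        x = table.loc[table["truth"] == classes[0], col].dropna().to_numpy()
        y = table.loc[table["truth"] == classes[1], col].dropna().to_numpy()
        if len(x) and len(y):
            _, p = mann_whitney_u(x, y)
        else:
            p = float("nan")
        p_values[col] = p
    return table, p_values


def mann_whitney_u(x, y) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test.

    U counts pairs with x_i > y_j (ties half credit). The p-value is exact
    (full enumeration of rank assignments) when both groups have at most 10
    untied observations, otherwise the normal approximation with tie and
    continuity corrections is used.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be nonempty")
    has_ties = len(np.unique(np.concatenate([x, y]))) < x.size + y.size
    if x.size <= 10 and y.size <= 10 and not has_ties:
        res = stats.mannwhitneyu(x, y, alternative="two-sided", method="exact")
    else:
        res = stats.mannwhitneyu(
            x, y, alternative="two-sided", method="asymptotic",
            use_continuity=True,
        )
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# loadings
# ---------------------------------------------------------------------------

@dataclass
class LoadingSummary:
    """Pointwise median and IQR of the sign-aligned loadings, per component."""

    axis: np.ndarray | None
    median: dict  # component (1-based) -> spectrum-shaped median vector
    iqr_lo: dict
    iqr_hi: dict
    n_models: dict  # component -> number of contributing models
    notes: list


def median_loadings_iqr(results, reference: ReferencePCA,
                        n_components: int | None = None) -> LoadingSummary:
    """Median and 25th/75th percentile of each retained component's loading
    across all optimized models, after sign alignment. Models that retained
    fewer than k components contribute nothing to component k."""
    a_max = results.config.a_max if n_components is None else n_components
    per_pc: dict[int, list[np.ndarray]] = {k: [] for k in range(1, a_max + 1)}
    for fm in results.iter_models():
        aligned = align_component_signs(
            fm.fit.loadings, reference.loadings[:, : fm.fit.loadings.shape[1]]
        )
        for k in range(1, min(fm.fit.loadings.shape[1], a_max) + 1):
            per_pc[k].append(aligned[:, k - 1])
    median, lo, hi, n_models, notes = {}, {}, {}, {}, []
    for k, stack in per_pc.items():
        if not stack:
            notes.append(f"component {k} retained by zero models; omitted")
            continue
        arr = np.vstack(stack)
        median[k] = np.median(arr, axis=0)
        lo[k] = np.percentile(arr, 25, axis=0)
        hi[k] = np.percentile(arr, 75, axis=0)
        n_models[k] = arr.shape[0]
    return LoadingSummary(axis=results.axis, median=median, iqr_lo=lo,
                          iqr_hi=hi, n_models=n_models, notes=notes)


# ---------------------------------------------------------------------------
# difference spectra and band assignment
# ---------------------------------------------------------------------------

def difference_spectrum(ss: SpectraSet, positive_class: str = "H0T"):
    """Pointwise class medians/IQRs of the (already normalized) spectra and
    the median difference positive - negative."""
    labels = ss.labels.to_numpy()
    classes = pd.unique(labels)
    if positive_class not in classes or len(classes) != 2:
        raise ValueError(
            f"need two classes including {positive_class!r}, got {list(classes)}"
        )
    pos = ss.intensities[labels == positive_class]
    neg = ss.intensities[labels != positive_class]
    out = {
        "axis": ss.axis,
        "median_pos": np.median(pos, axis=0),
        "median_neg": np.median(neg, axis=0),
        "iqr_pos": (np.percentile(pos, 25, axis=0), np.percentile(pos, 75, axis=0)),
        "iqr_neg": (np.percentile(neg, 25, axis=0), np.percentile(neg, 75, axis=0)),
    }
    out["difference"] = out["median_pos"] - out["median_neg"]
    return out


def assign_bands(positions, library: BandLibrary, tol: float = 6.0) -> list[dict]:
    """Annotate band positions with the nearest library band within ``tol``
    cm^-1 ('unassigned' otherwise); ties break toward the smaller offset."""
    if tol <= 0:
        raise ValueError("tol must be > 0")
    out = []
    for p in np.atleast_1d(np.asarray(positions, dtype=float)):
        best = None
        best_d = np.inf
        for band in library.entries:
            d = abs(band.center - p)
            if d < best_d:
                best, best_d = band, d
        if best is not None and best_d <= tol:
            out.append(
                {
                    "position": float(p),
                    "metabolite": best.metabolite,
                    "center": best.center,
                    "offset": float(p - best.center),
                    "direction": best.class_direction,
                }
            )
        else:
            out.append(
                {
                    "position": float(p),
                    "metabolite": "unassigned",
                    "center": None,
                    "offset": None,
                    "direction": None,
                }
            )
    return out


def loading_extrema(axis: np.ndarray, loading: np.ndarray,
                    min_prominence: float = 0.0) -> np.ndarray:
    """Wavenumbers of local extrema of |loading| (interior local maxima of
    the absolute value), used to read band structure off a median loading."""
    mag = np.abs(np.asarray(loading, dtype=float))
    peaks, props = _find_peaks(mag, min_prominence)
    return np.asarray(axis)[peaks]


def _find_peaks(mag: np.ndarray, min_prominence: float):
    from scipy.signal import find_peaks

    return find_peaks(mag, prominence=min_prominence if min_prominence > 0 else None)
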