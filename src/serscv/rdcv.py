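"""Repeated double (nested) cross-validation of PCA-LDA classifiers.

An inner stratified k-fold loop (default k=7), run on the outer-training
partition only, selects the number of principal components by the
one-standard-error rule on the cross-validation misclassification error. An
outer stratified k-fold loop (default k=3) then validates the re-fitted
optimized model on the untouched outer fold. The whole scheme is repeated
(default 100 times) with fresh fold randomizations, producing
``n_rep * k_outer`` optimized partial models, per-repetition confusion
matrices (summed over outer folds), pooled prediction probabilities, and
per-sample LD/PC score archives.

Train and test partitions never mix: the PCA centering mean, loadings and
discriminant are estimated from training folds only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import metrics as _metrics
from .pcalda import PCALDA, PCALDAResults, fit_lda, fit_pca, lda_scores
from .spectra import SpectraSet


@dataclass
class RDCVConfig:
    k_outer: int = 3
    k_inner: int = 7
    a_max: int = 7
    n_rep: int = 100
    positive_class: str = "H0T"
    seed: int | None = None

    def validate(self, class_counts: dict | None = None) -> None:
        if self.k_outer < 2 or self.k_inner < 2:
            raise ValueError("k_outer and k_inner must be >= 2")
        if self.a_max < 1:
            raise ValueError("a_max must be >= 1")
        if self.n_rep < 1:
            raise ValueError("n_rep must be >= 1")
        if class_counts is not None:
            smallest = min(class_counts.values())
            if smallest < self.k_outer:
                raise ValueError(
                    f"smallest class ({smallest}) has fewer members than "
                    f"k_outer={self.k_outer}"
                )


# ---------------------------------------------------------------------------
# folds and the 1-SE rule
# ---------------------------------------------------------------------------

def make_stratified_folds(labels, k: int, rng: np.random.Generator) -> np.ndarray:
    """Stratified fold assignment: within each class, shuffle members and
    deal them round-robin into k folds, so per-class fold sizes differ by at
    most one. Returns an integer fold index (0..k-1) per sample."""
    labels = np.asarray(labels)
    fold_of = np.empty(len(labels), dtype=int)
    start = 0  # rotate the dealing start between classes so the remainder
    for cls in pd.unique(labels):  # members do not pile up in fold 0
        idx = np.flatnonzero(labels == cls)
        if len(idx) < k:
            raise ValueError(
                f"class {cls!r} has {len(idx)} members, fewer than k={k}"
            )
        perm = rng.permutation(idx)
        fold_of[perm] = (start + np.arange(len(perm))) % k
        start = (start + len(perm)) % k
    return fold_of


def one_standard_error_rule(mean_err, se_err) -> int:
    """Smallest component count whose CV error is within one standard error
    of the minimum. Returns a 1-based count; ties at the minimum break
    toward fewer components."""
    mean_err = np.asarray(mean_err, dtype=float)
    se_err = np.asarray(se_err, dtype=float)
    if mean_err.size == 0 or mean_err.shape != se_err.shape:
        raise ValueError("mean_err and se_err must be equal-length, nonempty")
    a_best = int(np.argmin(mean_err))
    threshold = mean_err[a_best] + se_err[a_best]
    a_opt = int(np.argmax(mean_err <= threshold))  # first index satisfying
    return a_opt + 1


@dataclass
class InnerCVResult:
    mean_err: np.ndarray  # misclassification fraction per a = 1..a_max
    se_err: np.ndarray  # SE over inner folds
    a_opt: int


def inner_cv_select_ncomp(
    X: np.ndarray,
    y: np.ndarray,
    config: RDCVConfig,
    rng: np.random.Generator,
) -> InnerCVResult:
    """Inner stratified k-fold CV over the candidate component counts.

    For each inner fold: PCA (centering only) on the inner-training part,
    then an LDA per candidate a on the leading a score columns, scored by
    misclassification fraction on the held-out inner fold. A fold draw that
    leaves a single-class fold is re-dealt (new rng draw, at most 10 tries).
    """
    k = config.k_inner
    a_max = config.a_max
    for _attempt in range(10):
        fold_of = make_stratified_folds(y, k, rng)
        ok = all(
            len(np.unique(y[fold_of != j])) == 2
            and len(np.unique(y[fold_of == j])) >= 1
            for j in range(k)
        )
        if ok:
            break
    else:
        raise RuntimeError("could not deal inner folds with two classes in "
                           "every training part (10 attempts)")

    err = np.full((k, a_max), np.nan)
    for j in range(k):
        tr = fold_of != j
        te = ~tr
        mean, loadings, _ = fit_pca(X[tr], a_max)
        tr_scores = (X[tr] - mean) @ loadings
        te_scores = (X[te] - mean) @ loadings
        a_eff = loadings.shape[1]
        for a in range(1, a_max + 1):
            aa = min(a, a_eff)  # rank-deficient folds clamp to available PCs
            lda = fit_lda(tr_scores[:, :aa], y[tr], config.positive_class)
            ld = lda_scores(lda, te_scores[:, :aa])
            pred = np.where(ld > 0, lda.classes[1], lda.classes[0])
            err[j, a - 1] = np.mean(pred != y[te])
    mean_err = err.mean(axis=0)
    se_err = err.std(axis=0, ddof=1) / np.sqrt(k)
    a_opt = one_standard_error_rule(mean_err, se_err)
    return InnerCVResult(mean_err=mean_err, se_err=se_err, a_opt=a_opt)


# ---------------------------------------------------------------------------
# one repetition of the double CV
# ---------------------------------------------------------------------------

@dataclass
class FoldModel:
    """One optimized partial model: fitted on k_outer-1 folds, validated on
    the remaining fold."""

    fit: PCALDAResults
    a_opt: int
    inner: InnerCVResult
    train_ids: np.ndarray  # sample ids used for fitting
    test_ids: np.ndarray  # sample ids predicted
    test_scores: np.ndarray  # n_test x a_opt PC scores under this model


@dataclass
class RepetitionResult:
    fold_models: list[FoldModel]
    predictions: pd.DataFrame  # sample_id, truth, predicted, posterior, ld_score, outer_fold
    confusion: dict  # tp, fp, tn, fn summed over outer folds

    @property
    def a_opts(self) -> list[int]:
        return [fm.a_opt for fm in self.fold_models]


def run_double_cv(
    X: np.ndarray,
    y: np.ndarray,
    sample_ids: np.ndarray,
    config: RDCVConfig,
    rng: np.random.Generator,
) -> RepetitionResult:
    """One double-CV pass: outer stratified folds, inner component selection
    on each outer-training part only, optimized model refit on the full
    outer-training part, prediction of the untouched outer fold."""
    fold_of = make_stratified_folds(y, config.k_outer, rng)
    fold_models: list[FoldModel] = []
    pred_frames = []
    tp = fp = tn = fn = 0
    pos = config.positive_class
    for j in range(config.k_outer):
        tr = fold_of != j
        te = ~tr
        inner = inner_cv_select_ncomp(X[tr], y[tr], config, rng)
        res = PCALDA(X[tr], y[tr], inner.a_opt, pos).fit()
        scores_te = res.transform(X[te])
        pred = res.predict(X[te])
        pred.insert(0, "sample_id", sample_ids[te])
        pred.insert(1, "truth", y[te])
        pred["outer_fold"] = j
        pred_frames.append(pred)
        is_pos = y[te] == pos
        pred_pos = pred["predicted"].to_numpy() == pos
        tp += int(np.sum(is_pos & pred_pos))
        fn += int(np.sum(is_pos & ~pred_pos))
        fp += int(np.sum(~is_pos & pred_pos))
        tn += int(np.sum(~is_pos & ~pred_pos))
        fold_models.append(
            FoldModel(
                fit=res,
                a_opt=inner.a_opt,
                inner=inner,
                train_ids=np.asarray(sample_ids)[tr].copy(),
                test_ids=np.asarray(sample_ids)[te].copy(),
                test_scores=scores_te,
            )
        )
    predictions = pd.concat(pred_frames, ignore_index=True)
    confusion = {"tp": tp, "fp": fp, "tn": tn, "fn": fn}
    return RepetitionResult(fold_models=fold_models, predictions=predictions,
                            confusion=confusion)


# ---------------------------------------------------------------------------
# model / results pair
# ---------------------------------------------------------------------------

class RDCV:
    """Repeated double cross-validation of a PCA-LDA classifier.

    Build from a preprocessed :class:`SpectraSet` (one spectrum per sample,
    class labels present) or from a plain matrix + labels, then call
    :meth:`fit`.
    """

    def __init__(self, X, y, sample_ids=None, config: RDCVConfig | None = None,
                 axis=None):
        self.X = np.asarray(X, dtype=float)
        self.y = np.asarray(y)
        if sample_ids is None:
            sample_ids = np.array([f"s{i}" for i in range(len(self.y))])
        self.sample_ids = np.asarray(sample_ids)
        self.config = config or RDCVConfig()
        self.axis = None if axis is None else np.asarray(axis, dtype=float)
        counts = pd.Series(self.y).value_counts().to_dict()
        if len(counts) != 2:
            raise ValueError(f"need exactly two classes, got {list(counts)}")
        self.config.validate(counts)

    @classmethod
    def from_spectra(cls, ss: SpectraSet, config: RDCVConfig | None = None) -> "RDCV":
        return cls(
            ss.intensities,
            ss.labels.to_numpy(),
            sample_ids=ss.sample_ids.to_numpy(),
            config=config,
            axis=ss.axis,
        )

    def fit(self, verbose: bool = False) -> "RDCVResults":
        cfg = self.config
        seed_seq = np.random.SeedSequence(cfg.seed)
        child_seqs = seed_seq.spawn(cfg.n_rep)
        repetitions = []
        for r in range(cfg.n_rep):
            rng = np.random.default_rng(child_seqs[r])
            repetitions.append(
                run_double_cv(self.X, self.y, self.sample_ids, cfg, rng)
            )
            if verbose and (r + 1) % 10 == 0:  # pragma: no cover
                print(f"repetition {r + 1}/{cfg.n_rep}")
        return RDCVResults(self, repetitions)


class RDCVResults:
    """Archive of all repetitions: models, predictions, confusions.

    Heavier summaries (figures of merit, ROC, interpretation aggregates) are
    computed lazily through the metrics / interpretation modules.
    """

    def __init__(self, model: RDCV, repetitions: list[RepetitionResult]):
        self.model = model
        self.config = model.config
        self.repetitions = repetitions

    # -- bookkeeping ---------------------------------------------------------
    @property
    def n_models(self) -> int:
        return sum(len(rep.fold_models) for rep in self.repetitions)

    @property
    def axis(self):
        return self.model.axis

    def iter_models(self):
        for rep in self.repetitions:
            yield from rep.fold_models

    @property
    def a_opt_frequency(self) -> np.ndarray:
        """Histogram (length a_max) of the selected component counts over
        all optimized partial models."""
        counts = np.zeros(self.config.a_max, dtype=int)
        for fm in self.iter_models():
            counts[fm.a_opt - 1] += 1
        return counts

    @property
    def modal_a_opt(self) -> int:
        return int(np.argmax(self.a_opt_frequency)) + 1

    def confusions(self) -> pd.DataFrame:
        """Per-repetition confusion matrices (summed over outer folds)."""
        return pd.DataFrame([rep.confusion for rep in self.repetitions])

    def predictions(self) -> pd.DataFrame:
        frames = []
        for r, rep in enumerate(self.repetitions):
            df = rep.predictions.copy()
            df.insert(0, "repetition", r)
            frames.append(df)
        return pd.concat(frames, ignore_index=True)

    def cv_error_curves(self) -> np.ndarray:
        """Inner-loop CV-error curves, one row per optimized model
        (n_models x a_max)."""
        return np.vstack([fm.inner.mean_err for fm in self.iter_models()])

    # -- figures of merit ----------------------------------------------------
    def fom_summary(self, level: float = 0.95):
        return _metrics.summarize_foms(self, level=level)

    def roc_curves(self):
        return [
            _metrics.roc_auc_per_repetition(rep, self.config.positive_class)
            for rep in self.repetitions
        ]

    def cv_auc(self, level: float = 0.95):
        folds = _metrics.fold_predictions(self, self.config.positive_class)
        return _metrics.cv_auc_confidence_interval(folds, level=level)

    # -- interpretation ------------------------------------------------------
    def median_ld_scores(self) -> pd.DataFrame:
        from .interpretation import median_ld_scores

        return median_ld_scores(self)

    def median_loadings(self, reference=None, n_components: int | None = None):
        from .interpretation import fit_reference_pca, median_loadings_iqr

        if reference is None:
            reference = fit_reference_pca(self.model.X, self.config.a_max)
        return median_loadings_iqr(self, reference, n_components=n_components)

    def median_pc_scores(self, reference=None, n_components: int = 4):
        from .interpretation import fit_reference_pca, median_pc_scores_by_class

        if reference is None:
            reference = fit_reference_pca(self.model.X, self.config.a_max)
        return median_pc_scores_by_class(self, reference,
                                         n_components=n_components)

    # -- presentation --------------------------------------------------------
    def summary(self, level: float = 0.95) -> str:
        cfg = self.config
        fom = self.fom_summary(level=level)
        lines = [
            "Repeated double cross-validation of PCA-LDA",
            "=" * 60,
            f"samples: {len(self.model.y)}  "
            f"positive class: {cfg.positive_class}",
            f"outer folds: {cfg.k_outer}  inner folds: {cfg.k_inner}  "
            f"a_max: {cfg.a_max}  repetitions: {cfg.n_rep}",
            f"optimized partial models: {self.n_models}",
            f"selected-components histogram (1..{cfg.a_max}): "
            + " ".join(str(c) for c in self.a_opt_frequency),
            "-" * 60,
            f"{'figure of merit':<16}{'mean %':>8}  {int(level * 100)}% CI",
        ]
        for metric in ("accuracy", "sensitivity", "specificity", "ppv",
                       "npv", "auc"):
            row = fom.table.loc[metric]
            lines.append(
                f"{metric:<16}{row['mean'] * 100:>8.1f}  "
                f"({row['ci_lo'] * 100:.1f}-{row['ci_hi'] * 100:.1f})"
            )
        lines.append("=" * 60)
        return "\n".join(lines)

    # -- plotting (optional, needs matplotlib) -------------------------------
    def plot_roc(self, ax=None):  # pragma: no cover - visual aid
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        curves = self.roc_curves()
        for c in curves:
            ax.plot(c.fpr, c.tpr, color="tab:blue", alpha=0.1)
        grid, mean_tpr = _metrics.average_roc(curves)
        ax.plot(grid, mean_tpr, color="black", lw=2, label="average ROC")
        ax.set_xlabel("false positive rate")
        ax.set_ylabel("true positive rate")
        ax.legend()
        return ax

    def plot_a_opt_frequency(self, ax=None):  # pragma: no cover - visual aid
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        counts = self.a_opt_frequency
        ax.bar(np.arange(1, len(counts) + 1), counts)
        ax.set_xlabel("number of principal components")
        ax.set_ylabel("optimized models")
        return ax
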