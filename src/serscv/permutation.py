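"""Permutation (label-randomization) null for the full RDCV pipeline.

Class labels are permuted at the *sample* level (every spectrum/replicate of
a sample keeps one label), the whole repeated double cross-validation is
re-run on each permuted labeling, and the observed figures of merit are
compared with the null distribution via the add-one permutation p-value
``p = (1 + #{null >= observed}) / (b + 1)``, which can never return 0.

To keep b permutations tractable, the RDCV inside each permutation defaults
to a reduced repetition count (``n_rep_null``); a full-fidelity run is a
parameter away.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .metrics import fom_from_confusion, roc_auc_per_repetition
from .rdcv import RDCV, RDCVConfig
from .spectra import SpectraSet

PERMUTED_METRICS = ("sensitivity", "specificity", "accuracy", "ppv", "npv", "auc")


@dataclass
class PermutationResult:
    b: int
    null_foms: pd.DataFrame  # b rows, one column per metric (mean over reps)
    observed: dict  # observed mean FOMs
    p_values: dict  # one-sided add-one p per metric


def permute_labels(meta: pd.DataFrame, rng: np.random.Generator,
                   class_column: str = "class") -> pd.DataFrame:
    """Randomly reassign class labels at the sample level, preserving the
    label multiset over samples."""
    meta = meta.copy()
    per_sample = meta.drop_duplicates("sample_id")[["sample_id", class_column]]
    labels = per_sample[class_column].to_numpy().copy()
    rng.shuffle(labels)
    mapping = dict(zip(per_sample["sample_id"], labels))
    meta[class_column] = meta["sample_id"].map(mapping)
    return meta


def _mean_foms(results) -> dict:
    pos = results.config.positive_class
    rows = []
    for rep in results.repetitions:
        foms = fom_from_confusion(rep.confusion)
        foms["auc"] = roc_auc_per_repetition(rep, pos).auc
        rows.append(foms)
    return pd.DataFrame(rows).mean().to_dict()


def permutation_test(
    data: SpectraSet,
    config: RDCVConfig,
    b: int = 100,
    rng: np.random.Generator | None = None,
    n_rep_null: int | None = 10,
    observed: dict | None = None,
) -> PermutationResult:
    """Label-permutation significance test of the RDCV figures of merit.

    Parameters
    ----------
    data : preprocessed SpectraSet (one spectrum per sample, labels set)
    config : RDCV configuration used for the observed run
    b : number of permutations (>= 1)
    n_rep_null : repetitions used inside each permutation run
        (None = config.n_rep, the full-fidelity mode)
    observed : observed mean FOMs; computed from a fresh RDCV run with
        ``config`` when not supplied.
    """
    if b < 1:
        raise ValueError("number of permutations b must be >= 1")
    rng = rng or np.random.default_rng(config.seed)
    if observed is None:
        observed = _mean_foms(RDCV.from_spectra(data, config).fit())
    null_cfg = config if n_rep_null is None else replace(config,
                                                         n_rep=n_rep_null)
    rows = []
    for _ in range(b):
        perm_meta = permute_labels(data.meta, rng)
        perm = SpectraSet(data.axis, data.intensities, perm_meta)
        cfg = replace(null_cfg, seed=int(rng.integers(0, 2**31 - 1)))
        rows.append(_mean_foms(RDCV.from_spectra(perm, cfg).fit()))
    null_foms = pd.DataFrame(rows)
    p_values = {}
    for metric in PERMUTED_METRICS:
        obs = observed.get(metric, float("nan"))
        null = null_foms[metric].to_numpy()
        p_values[metric] = float((1 + np.sum(null >= obs)) / (b + 1))
    return PermutationResult(b=b, null_foms=null_foms, observed=observed,
                             p_values=p_values)
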