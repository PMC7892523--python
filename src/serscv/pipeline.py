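"""End-to-end orchestration: simulate/load -> preprocess -> RDCV ->
figures of merit -> permutation -> interpretation, with one master seed and
a manifest of every artifact written.

All outputs are plain CSV/JSON for auditability; every table carries the
run's configuration hash in a leading comment line (read back with
``pandas.read_csv(..., comment='#')``).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .interpretation import (
    difference_spectrum,
    fit_reference_pca,
    median_ld_scores,
    median_loadings_iqr,
    median_pc_scores_by_class,
)
from .io import read_spectra_table, write_spectra_table
from .metrics import average_roc
from .permutation import permutation_test
from .preprocess import PreprocessConfig, preprocess_pipeline
from .rdcv import RDCV, RDCVConfig
from .simulate import SyntheticConfig, generate_dataset
from .spectra import SpectraSet


@dataclass
class RunConfig:
    """Everything one pipeline run needs; serializable to/from a dict."""

    output_dir: str = "serscv_run"
    seed: int = 0
    # synthetic mode (used when spectra_path is None)
    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    # data mode
    spectra_path: str | None = None
    meta_path: str | None = None
    layout: str = "wide"
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    rdcv: RDCVConfig = field(default_factory=RDCVConfig)
    run_permutation: bool = False
    permutation_b: int = 100
    permutation_n_rep: int = 10

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    def config_hash(self) -> str:
        """Hash of the scientific configuration (paths and output location
        excluded, so identical analyses hash identically)."""
        d = self.to_dict()
        d.pop("output_dir", None)
        payload = json.dumps(d, sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def _write_table(df: pd.DataFrame, path: Path, config_hash: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# config_hash={config_hash}\n")
        df.to_csv(fh, index=False)


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage and write artifacts; returns the manifest dict.

    Any stage failure aborts with the stage name, after persisting a
    partial manifest listing the artifacts written so far.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash = config.config_hash()
    manifest: dict = {
        "seed": config.seed,
        "config_hash": chash,
        "version": __version__,
        "config": config.to_dict(),
        "artifacts": {},
        "stages_completed": [],
    }

    def _persist() -> None:
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, default=str)

    stage = "load"
    try:
        # ------------------------------------------------------------ load
        if config.spectra_path is None:
            syn = dataclasses.replace(config.synthetic, seed=config.seed)
            data = generate_dataset(syn)
        else:
            data = read_spectra_table(
                config.spectra_path, config.meta_path, layout=config.layout
            )
        manifest["stages_completed"].append(stage)

        # ------------------------------------------------------ preprocess
        stage = "preprocess"
        processed, provenance = preprocess_pipeline(data, config.preprocess)
        write_spectra_table(
            processed,
            out / "processed_spectra.csv",
            out / "processed_meta.csv",
        )
        with open(out / "preprocess_provenance.json", "w") as fh:
            json.dump({"config_hash": chash, "steps": provenance}, fh, indent=2)
        manifest["artifacts"]["processed_spectra"] = "processed_spectra.csv"
        manifest["artifacts"]["processed_meta"] = "processed_meta.csv"
        manifest["artifacts"]["preprocess_provenance"] = "preprocess_provenance.json"
        manifest["stages_completed"].append(stage)

        # ------------------------------------------------------------ rdcv
        stage = "rdcv"
        rcfg = dataclasses.replace(config.rdcv, seed=config.seed)
        results = RDCV.from_spectra(processed, rcfg).fit()
        _write_table(results.confusions(), out / "confusions.csv", chash)
        hist = pd.DataFrame(
            {
                "n_components": np.arange(1, rcfg.a_max + 1),
                "n_models": results.a_opt_frequency,
            }
        )
        _write_table(hist, out / "a_opt_histogram.csv", chash)
        manifest["artifacts"]["confusions"] = "confusions.csv"
        manifest["artifacts"]["a_opt_histogram"] = "a_opt_histogram.csv"
        manifest["stages_completed"].append(stage)

        # --------------------------------------------------------- metrics
        stage = "metrics"
        fom = results.fom_summary()
        fom_table = fom.table.reset_index(names="metric")
        _write_table(fom_table, out / "fom_summary.csv", chash)
        _write_table(fom.values, out / "fom_per_repetition.csv", chash)
        curves = results.roc_curves()
        grid, mean_tpr = average_roc(curves)
        _write_table(
            pd.DataFrame({"fpr": grid, "mean_tpr": mean_tpr}),
            out / "roc_average.csv",
            chash,
        )
        manifest["artifacts"]["fom_summary"] = "fom_summary.csv"
        manifest["artifacts"]["fom_per_repetition"] = "fom_per_repetition.csv"
        manifest["artifacts"]["roc_average"] = "roc_average.csv"
        manifest["stages_completed"].append(stage)

        # --------------------------------------------------- interpretation
        stage = "interpretation"
        reference = fit_reference_pca(processed.intensities, rcfg.a_max)
        ld = median_ld_scores(results)
        _write_table(ld, out / "ld_scores.csv", chash)
        pc_table, pc_p = median_pc_scores_by_class(results, reference)
        _write_table(pc_table, out / "pc_scores.csv", chash)
        loadings = median_loadings_iqr(results, reference)
        frames = {"wavenumber": processed.axis}
        for k in sorted(loadings.median):
            frames[f"pc{k}_median"] = loadings.median[k]
            frames[f"pc{k}_q25"] = loadings.iqr_lo[k]
            frames[f"pc{k}_q75"] = loadings.iqr_hi[k]
        _write_table(pd.DataFrame(frames), out / "loading_summary.csv", chash)
        diff = difference_spectrum(processed, rcfg.positive_class)
        _write_table(
            pd.DataFrame(
                {
                    "wavenumber": diff["axis"],
                    "median_pos": diff["median_pos"],
                    "median_neg": diff["median_neg"],
                    "difference": diff["difference"],
                }
            ),
            out / "difference_spectrum.csv",
            chash,
        )
        manifest["artifacts"]["ld_scores"] = "ld_scores.csv"
        manifest["artifacts"]["pc_scores"] = "pc_scores.csv"
        manifest["artifacts"]["loading_summary"] = "loading_summary.csv"
        manifest["artifacts"]["difference_spectrum"] = "difference_spectrum.csv"
        manifest["pc_score_p_values"] = pc_p
        manifest["stages_completed"].append(stage)

        # ------------------------------------------------------ permutation
        if config.run_permutation:
            stage = "permutation"
            rng = np.random.default_rng(
                np.random.SeedSequence([config.seed, 0x9E3779B9])
            )
            perm = permutation_test(
                processed,
                rcfg,
                b=config.permutation_b,
                rng=rng,
                n_rep_null=config.permutation_n_rep,
                observed=fom.values.mean().to_dict(),
            )
            _write_table(perm.null_foms, out / "permutation_null.csv", chash)
            manifest["artifacts"]["permutation_null"] = "permutation_null.csv"
            manifest["permutation_p_values"] = perm.p_values
            manifest["stages_completed"].append(stage)

        manifest["summary"] = {
            "n_models": results.n_models,
            "modal_a_opt": results.modal_a_opt,
            "fom_mean_percent": {
                m: round(float(fom.table.loc[m, "mean"]) * 100, 1)
                for m in fom.table.index
            },
        }
        _persist()
        return manifest
    except Exception as err:
        manifest["failed_stage"] = stage
        manifest["error"] = str(err)
        _persist()
        raise RuntimeError(f"pipeline failed in stage '{stage}': {err}") from err
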