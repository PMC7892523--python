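"""Two-class serum-like SERS dataset simulator.

The generator emulates the statistical structure of label-free SERS spectra
of serum deposited on a plasmonic substrate: a purine-dominated band pattern
(Lorentzian bands), a smooth positive polynomial fluorescence baseline,
spectrum-to-spectrum multiplicative enhancement variation, per-sample
metabolite abundance variation shared across technical replicates, and
additive detector noise. The class effect is a multiplicative intensity
shift on metabolite-specific bands: uric-acid bands up in the positive
(H0T) class, hypoxanthine / ergothioneine / glutathione bands down, neutral
background bands unaffected. With ``effect_size = 0`` the class label is
independent of the spectra by construction (the null model).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .spectra import SpectraSet

UP = "up_in_H0T"
DOWN = "down_in_H0T"
NEUTRAL = "neutral"

POSITIVE_CLASS = "H0T"
NEGATIVE_CLASS = "CTR"

#: default Lorentzian full width at half maximum, cm^-1 (typical solution-phase
#: Raman band width)
DEFAULT_FWHM = 12.0


@dataclass(frozen=True)
class Band:
    metabolite: str
    center: float  # cm^-1
    relative_intensity: float  # > 0, dimensionless
    fwhm: float = DEFAULT_FWHM  # cm^-1
    class_direction: str = NEUTRAL


@dataclass
class BandLibrary:
    entries: list[Band]

    def __post_init__(self) -> None:
        for b in self.entries:
            if not (400.0 <= b.center <= 1800.0):
                raise ValueError(f"band center {b.center} outside [400, 1800]")
            if b.fwhm <= 0 or b.relative_intensity <= 0:
                raise ValueError(f"band {b} needs positive fwhm and intensity")
            if b.class_direction not in (UP, DOWN, NEUTRAL):
                raise ValueError(f"unknown class_direction {b.class_direction!r}")

    @property
    def metabolites(self) -> list[str]:
        seen: dict[str, None] = {}
        for b in self.entries:
            seen.setdefault(b.metabolite, None)
        return list(seen)

    def by_direction(self, direction: str) -> list[Band]:
        return [b for b in self.entries if b.class_direction == direction]


def default_band_library() -> BandLibrary:
    """Serum SERS band library: four marker metabolites plus purine background.

    Uric-acid bands (594, 638, 812, 888, 1132 cm^-1) rise in the H0T class;
    hypoxanthine (724, the dominant serum SERS band), ergothioneine (480,
    1220, 1442, 1582) and glutathione (664, 912) fall; three additional
    neutral bands mimic class-independent purine/protein background.
    """
    e = [
        # uric acid — relatively more abundant in the positive class
        Band("uric acid", 594.0, 0.45, class_direction=UP),
        Band("uric acid", 638.0, 0.55, class_direction=UP),
        Band("uric acid", 812.0, 0.35, class_direction=UP),
        Band("uric acid", 888.0, 0.40, class_direction=UP),
        Band("uric acid", 1132.0, 0.35, class_direction=UP),
        # hypoxanthine — the dominant purine band, lower in H0T
        Band("hypoxanthine", 724.0, 1.00, class_direction=DOWN),
        # ergothioneine
        Band("ergothioneine", 480.0, 0.50, class_direction=DOWN),
        Band("ergothioneine", 1220.0, 0.30, class_direction=DOWN),
        Band("ergothioneine", 1442.0, 0.30, class_direction=DOWN),
        Band("ergothioneine", 1582.0, 0.25, class_direction=DOWN),
        # glutathione (weaker, tentative)
        Band("glutathione", 664.0, 0.20, class_direction=DOWN),
        Band("glutathione", 912.0, 0.18, class_direction=DOWN),
        # class-neutral background near the dominant purine region
        Band("background", 655.0, 0.25, fwhm=18.0, class_direction=NEUTRAL),
        Band("background", 740.0, 0.20, fwhm=18.0, class_direction=NEUTRAL),
        Band("background", 1003.0, 0.30, class_direction=NEUTRAL),
    ]
    return BandLibrary(e)


@dataclass
class SyntheticConfig:
    """Parameters of the synthetic two-class SERS study design.

    Defaults mirror the emulated study: 72 samples per class measured in
    three technical replicates. ``effect_size`` (delta) scales the
    class-dependent band multipliers; 0 gives the null model. Intensity
    units are arbitrary detector counts; ``amplitude`` sets the scale of the
    strongest band before baseline/noise.
    """

    n_per_class: int = 72
    n_replicates: int = 3
    effect_size: float = 0.5
    biological_cv: float = 0.1
    baseline_degree: int = 4
    baseline_scale: float = 500.0
    noise_sd: float = 5.0
    intensity_scale_cv: float = 0.15
    amplitude: float = 1000.0
    raw_axis: tuple = (400.0, 1810.0, 1.9, 0.3)  # start, stop, spacing, jitter
    seed: int | None = None
    n_batches: int = 3
    n_days: int = 5
    n_operators: int = 2

    def validate(self) -> None:
        if self.n_per_class < 2:
            raise ValueError("n_per_class must be >= 2")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        for name in ("effect_size", "biological_cv", "baseline_scale",
                     "noise_sd", "intensity_scale_cv", "amplitude"):
            v = float(getattr(self, name))
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and >= 0, got {v}")
        if self.baseline_degree < 0:
            raise ValueError("baseline_degree must be >= 0")
        start, stop, spacing, jitter = self.raw_axis
        if not (stop > start and spacing > 0 and jitter >= 0):
            raise ValueError(f"invalid raw_axis {self.raw_axis}")
        if jitter >= spacing / 2:
            raise ValueError("axis jitter must be < spacing/2 to keep order")


def make_axis(config: SyntheticConfig, rng: np.random.Generator) -> np.ndarray:
    """Non-uniform instrument-like wavenumber axis (jittered pixel grid).

    One extra pixel is prepended before ``start`` so that, jitter included,
    the axis always covers the nominal range and downstream interpolation
    never has to extrapolate at the low edge.
    """
    start, stop, spacing, jitter = config.raw_axis
    base = np.arange(start - spacing, stop + spacing / 2, spacing)
    axis = base + rng.uniform(-jitter, jitter, size=base.shape)
    axis.sort()  # jitter < spacing/2 keeps it strictly increasing anyway
    return axis


def _lorentzian(x: np.ndarray, center: float, fwhm: float) -> np.ndarray:
    hwhm = fwhm / 2.0
    return hwhm**2 / ((x - center) ** 2 + hwhm**2)


def draw_sample_effects(
    library: BandLibrary, config: SyntheticConfig, rng: np.random.Generator
) -> dict[str, float]:
    """Per-metabolite lognormal abundance multipliers (mean 1, CV biological_cv)."""
    cv = config.biological_cv
    if cv == 0:
        return {m: 1.0 for m in library.metabolites}
    sigma = np.sqrt(np.log1p(cv**2))
    mu = -(sigma**2) / 2.0  # mean-1 lognormal
    return {m: float(rng.lognormal(mu, sigma)) for m in library.metabolites}


def class_multiplier(band: Band, class_label: str, effect_size: float,
                     effect: float) -> float:
    """Band intensity multiplier for a class: (1 + delta*effect) on up bands
    in the positive class, its reciprocal on down bands, 1 otherwise."""
    if class_label != POSITIVE_CLASS or band.class_direction == NEUTRAL:
        return 1.0
    m = 1.0 + effect_size * effect
    return m if band.class_direction == UP else 1.0 / m


def simulate_spectrum(
    library: BandLibrary,
    class_label: str,
    sample_effects: dict[str, float],
    config: SyntheticConfig,
    rng: np.random.Generator,
    axis: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """One raw replicate spectrum: bands x class effect + baseline + noise."""
    config.validate()
    if axis is None:
        axis = make_axis(config, rng)
    signal = np.zeros_like(axis)
    for band in library.entries:
        abundance = sample_effects.get(band.metabolite, 1.0)
        m = class_multiplier(band, class_label, config.effect_size,
                             sample_effects.get(band.metabolite, 1.0))
        amp = config.amplitude * band.relative_intensity * abundance * m
        signal += amp * _lorentzian(axis, band.center, band.fwhm)
    # per-spectrum multiplicative enhancement variation
    if config.intensity_scale_cv > 0:
        sigma = np.sqrt(np.log1p(config.intensity_scale_cv**2))
        scale = rng.lognormal(-(sigma**2) / 2.0, sigma)
    else:
        scale = 1.0
    y = scale * signal
    # smooth positive polynomial background
    if config.baseline_scale > 0:
        t = (axis - axis[0]) / (axis[-1] - axis[0])
        coef = rng.uniform(0.0, 1.0, size=config.baseline_degree + 1)
        y = y + config.baseline_scale * np.polynomial.polynomial.polyval(t, coef)
    if config.noise_sd > 0:
        y = y + rng.normal(0.0, config.noise_sd, size=axis.shape)
    return axis, y


def generate_dataset(
    config: SyntheticConfig, library: BandLibrary | None = None
) -> SpectraSet:
    """Full two-class replicated dataset on one shared (jittered) raw axis.

    Samples are assigned to synthetic batches, days and operators in a
    stratified rotation so neither confounds the class label, mirroring a
    design where each measurement day sees an equal number of samples from
    both classes and every substrate batch.
    """
    config.validate()
    if library is None:
        library = default_band_library()
    rng = np.random.default_rng(config.seed)
    axis = make_axis(config, rng)

    rows = []
    spectra = []
    sample_counter = 0
    for class_label in (NEGATIVE_CLASS, POSITIVE_CLASS):
        for i in range(config.n_per_class):
            sample_counter += 1
            sid = f"S{sample_counter:04d}"
            effects = draw_sample_effects(library, config, rng)
            batch = f"B{i % config.n_batches + 1}"
            day = f"D{i % config.n_days + 1}"
            operator = f"OP{i % config.n_operators + 1}"
            for rep in range(1, config.n_replicates + 1):
                _, y = simulate_spectrum(
                    library, class_label, effects, config, rng, axis=axis
                )
                spectra.append(y)
                rows.append(
                    {
                        "spectrum_id": f"{sid}_r{rep}",
                        "sample_id": sid,
                        "class": class_label,
                        "replicate": rep,
                        "batch": batch,
                        "day": day,
                        "operator": operator,
                    }
                )
    return SpectraSet(axis=axis, intensities=np.vstack(spectra),
                      meta=pd.DataFrame(rows))
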