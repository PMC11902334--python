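"""Configuration types for the impedance-cytometry immunoassay pipeline.

The instrument model mirrors a multi-frequency lock-in impedance cytometer:
eight simultaneous excitation frequencies are demodulated into eight
amplitude channels, low-pass filtered at 100 Hz (so only impedance changes
slower than ~10 ms — one bead transit — survive), and digitized.  Peak
amplitudes are recorded in volts downstream of a 1 kV/A trans-impedance
amplifier driven at 400 mV excitation.

``assay_regime()`` returns the frozen synthetic-data preset used throughout
the test-bench: a two-component bound/unbound amplitude mixture whose bound
fraction saturates with analyte concentration, calibrated once so that
per-bead classification is weak (~25–45 % over five classes) while
sample-level aggregation is strong (≥ 96 %).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

from .errors import ConfigError

__all__ = [
    "FrequencyPanel",
    "InstrumentConfig",
    "GeneratorConfig",
    "DetectionParams",
    "SplitSpec",
    "PipelineConfig",
    "DEFAULT_FREQUENCIES_HZ",
    "assay_regime",
    "null_regime",
    "chip1_design",
    "chip2_design",
]

#: The eight demodulation frequencies of the instrument, in Hz.
DEFAULT_FREQUENCIES_HZ = (
    500e3, 700e3, 1e6, 1.5e6, 2e6, 5e6, 10e6, 20e6,
)


@dataclass(frozen=True)
class FrequencyPanel:
    """Ordered panel of excitation/demodulation frequencies (Hz)."""

    frequencies_hz: tuple = DEFAULT_FREQUENCIES_HZ

    def __post_init__(self):
        freqs = tuple(float(f) for f in self.frequencies_hz)
        object.__setattr__(self, "frequencies_hz", freqs)
        if len(freqs) < 1:
            raise ConfigError("frequency panel must contain at least one frequency")
        if any(b <= a for a, b in zip(freqs, freqs[1:])):
            raise ConfigError("frequencies must be strictly increasing")

    def __len__(self) -> int:
        return len(self.frequencies_hz)


@dataclass(frozen=True)
class InstrumentConfig:
    """Front-end settings of the impedance spectroscope.

    ``excitation_voltage`` and ``transimpedance_gain`` are carried as
    metadata (they set the overall amplitude scale); no circuit model is
    evaluated.  ``min_transit_s`` is the minimum bead transit time through
    the sensing gap; anything faster is removed by the low-pass filter.
    """

    excitation_voltage: float = 0.4       # V
    transimpedance_gain: float = 1000.0   # V/A
    lpf_cutoff_hz: float = 100.0          # Hz
    sampling_rate_hz: float = 900.0       # Sa/s
    min_transit_s: float = 0.010          # s

    def __post_init__(self):
        for name in ("excitation_voltage", "transimpedance_gain",
                     "lpf_cutoff_hz", "sampling_rate_hz", "min_transit_s"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        if self.sampling_rate_hz <= 2 * self.lpf_cutoff_hz:
            raise ConfigError(
                "sampling_rate_hz must exceed twice lpf_cutoff_hz "
                f"({self.sampling_rate_hz} <= 2 x {self.lpf_cutoff_hz})"
            )


@dataclass(frozen=True)
class GeneratorConfig:
    """Parameters of the synthetic bead/trace generator.

    Per-bead amplitude model: a bead is "bound" (carries captured analyte)
    with probability ``bound_fraction_curve[concentration]``.  Bound beads
    draw their 8-channel peak-amplitude vector from
    ``Normal(base_mean + effect_size * bound_degree_curve[c] * effect_profile
    + chip_offset, diag(within_class_sd^2))`` — the saturating
    ``bound_degree_curve`` models the mean surface occupancy of a bound
    bead growing with analyte concentration — while unbound beads draw
    from the same distribution without the shift; negative draws are
    truncated at zero (amplitudes are magnitudes).
    """

    panel: FrequencyPanel = field(default_factory=FrequencyPanel)
    instrument: InstrumentConfig = field(default_factory=InstrumentConfig)
    concentrations: tuple = (0.0, 10.0, 25.0, 50.0, 100.0, 300.0, 500.0)  # pg/mL
    base_mean: tuple = (0.25, 0.24, 0.22, 0.20, 0.18, 0.15, 0.12, 0.10)   # V
    effect_size: float = 0.075                                            # V
    effect_profile: tuple = (0.14, 0.19, 0.28, 0.42, 0.56, 0.42, 0.19, 0.09)
    within_class_sd: tuple = (0.01,) * 8                                  # V
    bound_fraction_curve: Mapping[float, float] = field(
        default_factory=lambda: dict(ASSAY_REGIME_BOUND_FRACTIONS)
    )
    bound_degree_curve: Mapping[float, float] = field(
        default_factory=lambda: dict(ASSAY_REGIME_BOUND_DEGREES)
    )
    arrival_rate_hz: float = 0.2       # mean bead arrivals per second (dilute)
    pulse_width_s: float = 0.015       # Gaussian FWHM of a transit pulse, s
    noise_sd: float = 0.002            # V, white noise added before the LPF
    n_chips: int = 2
    chip_offset_sd: float = 0.003      # V, per-chip additive offset SD
    amplitude_family: str = "normal"   # "normal" (truncated) or "lognormal"

    def __post_init__(self):
        object.__setattr__(self, "concentrations",
                           tuple(float(c) for c in self.concentrations))
        object.__setattr__(self, "base_mean", tuple(float(v) for v in self.base_mean))
        object.__setattr__(self, "effect_profile",
                           tuple(float(v) for v in self.effect_profile))
        object.__setattr__(self, "within_class_sd",
                           tuple(float(v) for v in self.within_class_sd))
        object.__setattr__(self, "bound_fraction_curve",
                           {float(k): float(v)
                            for k, v in self.bound_fraction_curve.items()})
        n = len(self.panel)
        if len(self.base_mean) != n or len(self.effect_profile) != n \
                or len(self.within_class_sd) != n:
            raise ConfigError("base_mean, effect_profile and within_class_sd "
                              "must match the panel length")
        if any(sd <= 0 for sd in self.within_class_sd):
            raise ConfigError("within_class_sd must be positive elementwise")
        object.__setattr__(self, "bound_degree_curve",
                           {float(k): float(v)
                            for k, v in self.bound_degree_curve.items()})
        for attr in ("bound_fraction_curve", "bound_degree_curve"):
            curve = getattr(self, attr)
            missing = [c for c in self.concentrations if c not in curve]
            if missing:
                raise ConfigError(f"{attr} missing concentrations {missing}")
            vals = [curve[c] for c in sorted(curve)]
            if any(v < 0 or v > 1 for v in vals):
                raise ConfigError(f"{attr} values must lie in [0, 1]")
            if any(b < a for a, b in zip(vals, vals[1:])):
                raise ConfigError(f"{attr} must be non-decreasing in "
                                  "concentration")
        if self.arrival_rate_hz < 0 or self.noise_sd < 0 or self.chip_offset_sd < 0:
            raise ConfigError("rates, noise and offset SDs must be non-negative")
        if self.pulse_width_s < self.instrument.min_transit_s:
            raise ConfigError("pulse_width_s must be at least the minimum "
                              "transit time")
        if self.arrival_rate_hz * self.instrument.min_transit_s >= 0.2:
            raise ConfigError("arrival_rate_hz too high: pulses would overlap "
                              "(arrival_rate_hz * min_transit_s must be < 0.2)")
        if self.n_chips < 1:
            raise ConfigError("n_chips must be >= 1")
        if self.amplitude_family not in ("normal", "lognormal"):
            raise ConfigError("amplitude_family must be 'normal' or 'lognormal'")

    @property
    def n_channels(self) -> int:
        return len(self.panel)


@dataclass(frozen=True)
class DetectionParams:
    """Peak-detection settings.

    Detection triggers on the reference channel (by convention the lowest
    frequency), at ``threshold_mads`` robust noise scales above baseline;
    events closer than ``min_separation_s`` are merged keeping the larger.
    """

    reference_channel: int = 0
    threshold_mads: float = 5.0
    min_separation_s: float = 0.010
    window_samples: int = 80
    baseline_window_s: float = 2.0

    def __post_init__(self):
        if self.threshold_mads <= 0:
            raise ConfigError("threshold_mads must be positive")
        if self.min_separation_s <= 0:
            raise ConfigError("min_separation_s must be positive")
        if self.window_samples <= 0 or self.window_samples % 2:
            raise ConfigError("window_samples must be a positive even count")
        if self.baseline_window_s <= 0:
            raise ConfigError("baseline_window_s must be positive")
        if self.reference_channel < 0:
            raise ConfigError("reference_channel must be a valid channel index")


@dataclass(frozen=True)
class SplitSpec:
    """Dataset splitting and mock-experiment resampling parameters.

    Defaults follow the assay protocol: a stratified 70:30 train/test
    split, a 30:70 split of the training peaks between the bead-level
    (layer-1) and sample-level (layer-2) models, 100 training mock
    experiments per class, and disjoint test mocks each holding 10 % of a
    class's test peaks (10 mocks per class for quantification, 5 per class
    for the binary task).
    """

    train_fraction: float = 0.70
    layer1_fraction_of_train: float = 0.30
    n_training_mocks_per_class: int = 100
    test_mock_fraction: float = 0.10
    n_test_mocks_per_class: int = 10
    seed: int = 0

    def __post_init__(self):
        for name in ("train_fraction", "layer1_fraction_of_train",
                     "test_mock_fraction"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ConfigError(f"{name} must lie strictly in (0, 1)")
        if self.n_training_mocks_per_class < 1 or self.n_test_mocks_per_class < 1:
            raise ConfigError("mock counts must be >= 1")


@dataclass(frozen=True)
class PipelineConfig:
    """End-to-end pipeline configuration.

    ``task`` selects the quantification (5-way concentration) or binary
    (control vs protein, two chips pooled and balanced) pipeline.  The
    binary task defaults to a linear-discriminant layer 1 and 5 test mocks
    per class; quantification defaults to coarse kNN throughout.
    """

    generator: GeneratorConfig = field(default_factory=lambda: assay_regime())
    detection: DetectionParams = field(default_factory=DetectionParams)
    split: SplitSpec = field(default_factory=SplitSpec)
    task: str = "quantification"
    layer1_kind: str = "coarse_knn"
    master_seed: int = 0
    output_dir: str | None = None
    design: Mapping[float, tuple] | None = None

    def __post_init__(self):
        if self.task not in ("quantification", "binary"):
            raise ConfigError("task must be 'quantification' or 'binary'")
        if self.layer1_kind not in ("coarse_knn", "linear_discriminant"):
            raise ConfigError("layer1_kind must be 'coarse_knn' or "
                              "'linear_discriminant'")

    @classmethod
    def for_task(cls, task: str, master_seed: int = 0, **overrides) -> "PipelineConfig":
        """Build a config with task-consistent defaults applied."""
        defaults: dict = {"task": task, "master_seed": master_seed}
        if task == "binary":
            defaults["layer1_kind"] = "linear_discriminant"
            defaults["split"] = SplitSpec(n_test_mocks_per_class=5)
        defaults.update(overrides)
        return cls(**defaults)


# ---------------------------------------------------------------------------
# Frozen presets
# ---------------------------------------------------------------------------

#: Fraction of beads carrying captured analyte at each assay concentration
#: (pg/mL).  Saturating in concentration; calibrated once, together with
#: ``effect_size`` and ``within_class_sd``, to place the pipeline in the
#: weak-per-bead / strong-per-sample regime.
ASSAY_REGIME_BOUND_FRACTIONS = (
    (0.0, 0.02),
    (10.0, 0.33),
    (25.0, 0.42),
    (50.0, 0.52),
    (100.0, 0.73),
    (300.0, 0.86),
    (500.0, 0.95),
)

#: Mean surface occupancy (0..1 of the saturating amplitude shift) of a
#: *bound* bead at each concentration: bound beads at higher concentration
#: carry more captured protein, so their amplitude shift is larger.
ASSAY_REGIME_BOUND_DEGREES = (
    (0.0, 0.20),
    (10.0, 0.55),
    (25.0, 0.62),
    (50.0, 0.70),
    (100.0, 0.84),
    (300.0, 0.93),
    (500.0, 1.00),
)


def assay_regime() -> GeneratorConfig:
    """The frozen synthetic study preset (defaults of GeneratorConfig)."""
    return GeneratorConfig()


def null_regime() -> GeneratorConfig:
    """The same preset with the analyte effect switched off (delta = 0).

    Under this null every concentration produces identical bead
    distributions, so any classifier must fall to chance.
    """
    return replace(assay_regime(), effect_size=0.0)


def chip1_design(n_experiments: int = 3, n_beads: int = 1000) -> dict:
    """Study design for chip 1: the five assay concentrations."""
    return {c: (n_experiments, n_beads) for c in (0.0, 10.0, 50.0, 100.0, 500.0)}


def chip2_design(n_experiments: int = 3, n_beads: int = 1000) -> dict:
    """Study design for chip 2: adds the 25 and 300 pg/mL fill-in points."""
    return {c: (n_experiments, n_beads)
            for c in (0.0, 10.0, 25.0, 50.0, 100.0, 300.0, 500.0)}
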