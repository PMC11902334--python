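"""Synthetic impedance-cytometry data with known ground truth.

No public recording of the bead assay exists, so this module is the data
source for the whole test bench.  It emulates, with a deliberately simple
generative model, the statistical structure the downstream analysis
assumes:

* each bead yields one 8-frequency peak-amplitude vector (volts);
* a bead is *bound* (carries captured analyte) with a probability that
  saturates with analyte concentration; bound beads get a small fixed
  amplitude shift along a per-channel effect profile — so individual beads
  are nearly uninformative while bead *populations* separate cleanly;
* each chip contributes an additive per-channel amplitude offset (chips
  require individual calibration in practice);
* full traces are Gaussian transit pulses (FWHM ≥ the 10 ms minimum
  transit time) at Poisson arrival times, plus white noise, passed through
  the instrument's first-order 100 Hz low-pass filter.

Every operation is a pure function of its inputs and an integer seed.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .config import GeneratorConfig, FrequencyPanel
from .errors import InputError
from .tables import empty_peak_table, make_peak_table, amplitude_matrix

__all__ = [
    "TraceEvent",
    "ImpedanceTrace",
    "chip_offset",
    "simulate_peak_features",
    "render_trace",
    "simulate_trace",
    "simulate_study",
]

_GAUSS_FWHM = 2.0 * np.sqrt(2.0 * np.log(2.0))  # FWHM / sigma


@dataclass(frozen=True)
class TraceEvent:
    """Ground-truth record of one injected bead transit."""

    time_s: float
    amplitudes: np.ndarray          # per-channel pulse height, V
    concentration: float            # pg/mL


@dataclass
class ImpedanceTrace:
    """Multi-channel demodulated impedance-magnitude time series.

    ``samples`` is (n_timepoints, n_channels) in volts.  ``truth`` holds the
    injected events when the trace is synthetic; provenance fields carry
    the experiment metadata forward into detected peak tables.
    """

    sampling_rate_hz: float
    samples: np.ndarray
    channel_frequencies: FrequencyPanel
    truth: list | None = None
    concentration: float | None = None
    chip_id: str | None = None
    experiment_id: str | None = None

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2:
            raise InputError("trace samples must be 2-D (time x channels)")
        if self.samples.shape[1] != len(self.channel_frequencies):
            raise InputError("trace channel count must match the frequency panel")
        if not np.all(np.isfinite(self.samples)):
            raise InputError("trace samples must be finite")
        if self.truth is not None:
            dur = self.duration_s
            if any(ev.time_s < 0 or ev.time_s > dur for ev in self.truth):
                raise InputError("truth event times must lie within the trace")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[1]

    @property
    def duration_s(self) -> float:
        return self.samples.shape[0] / self.sampling_rate_hz

    @property
    def times_s(self) -> np.ndarray:
        return np.arange(self.samples.shape[0]) / self.sampling_rate_hz


def chip_offset(config: GeneratorConfig, chip_id) -> np.ndarray:
    """Per-channel additive amplitude offset of a chip (V).

    A chip property: deterministic in ``chip_id`` (via a CRC-derived seed)
    so that every experiment on the same chip shares one offset.
    """
    if config.chip_offset_sd == 0:
        return np.zeros(config.n_channels)
    seed = zlib.crc32(f"chip-offset:{chip_id}".encode())
    rng = np.random.default_rng(seed)
    return rng.normal(0.0, config.chip_offset_sd, size=config.n_channels)


def _draw_amplitudes(config: GeneratorConfig, concentration: float,
                     n_beads: int, offset: np.ndarray,
                     rng: np.random.Generator) -> np.ndarray:
    c = float(concentration)
    p_bound = config.bound_fraction_curve[c]
    degree = config.bound_degree_curve[c]
    bound = rng.random(n_beads) < p_bound
    base = np.asarray(config.base_mean) + offset
    shift = config.effect_size * degree * np.asarray(config.effect_profile)
    mean = np.where(bound[:, None], base + shift, base)
    sd = np.asarray(config.within_class_sd)
    if config.amplitude_family == "normal":
        amps = rng.normal(mean, sd)
    else:
        # moment-matched lognormal: same per-channel mean and SD
        sigma2 = np.log1p((sd / mean) ** 2)
        mu = np.log(mean) - sigma2 / 2.0
        amps = rng.lognormal(mu, np.sqrt(sigma2))
    return np.clip(amps, 0.0, None)


def simulate_peak_features(config: GeneratorConfig, concentration: float,
                           n_beads: int, chip_id, experiment_id,
                           seed: int) -> pd.DataFrame:
    """Draw ``n_beads`` per-bead 8-frequency peak-amplitude vectors.

    Returns a peak table labeled with the given concentration, chip and
    experiment.  Deterministic for a fixed seed.
    """
    concentration = float(concentration)
    if concentration not in config.concentrations:
        raise InputError(
            f"concentration {concentration} pg/mL is not in the configured "
            f"label set {config.concentrations}")
    if n_beads < 0:
        raise InputError("n_beads must be non-negative")
    if n_beads == 0:
        return empty_peak_table(config.n_channels)
    rng = np.random.default_rng(seed)
    offset = chip_offset(config, chip_id)
    amps = _draw_amplitudes(config, concentration, n_beads, offset, rng)
    return make_peak_table(amps, concentration, chip_id, experiment_id)


def render_trace(config: GeneratorConfig, events: list, duration_s: float,
                 noise_rng: np.random.Generator | None = None) -> np.ndarray:
    """Render ground-truth events into a filtered multi-channel trace.

    Each event contributes a Gaussian pulse of FWHM ``pulse_width_s`` and
    per-channel height ``event.amplitudes``; white noise of SD ``noise_sd``
    is added and the whole trace is passed through a first-order low-pass
    at ``lpf_cutoff_hz`` (exponential discretization, unit DC gain).
    """
    fs = config.instrument.sampling_rate_hz
    n = int(round(duration_s * fs))
    t = np.arange(n) / fs
    sig = np.zeros((n, config.n_channels))
    sigma = config.pulse_width_s / _GAUSS_FWHM
    for ev in events:
        lo = np.searchsorted(t, ev.time_s - 5 * sigma)
        hi = np.searchsorted(t, ev.time_s + 5 * sigma)
        win = t[lo:hi] - ev.time_s
        sig[lo:hi] += np.exp(-0.5 * (win / sigma) ** 2)[:, None] \
            * np.asarray(ev.amplitudes)[None, :]
    if noise_rng is not None and config.noise_sd > 0:
        sig += noise_rng.normal(0.0, config.noise_sd, size=sig.shape)
    # first-order RC low-pass: y[k] = a*y[k-1] + (1-a)*x[k], a = exp(-dt/tau)
    tau = 1.0 / (2.0 * np.pi * config.instrument.lpf_cutoff_hz)
    a = np.exp(-1.0 / (fs * tau))
    return lfilter([1.0 - a], [1.0, -a], sig, axis=0)


def simulate_trace(config: GeneratorConfig, concentration: float,
                   duration_s: float, seed: int, chip_id="chip1",
                   experiment_id="exp1",
                   edge_margin_s: float = 0.1) -> ImpedanceTrace:
    """Simulate a full multi-channel recording at one concentration.

    Bead arrivals are Poisson with rate ``arrival_rate_hz``, placed
    uniformly inside ``[edge_margin_s, duration_s - edge_margin_s]`` so
    that no transit pulse is clipped by the record boundary.  The injected
    ground truth (time, per-channel height, concentration) is attached to
    the returned trace.
    """
    if duration_s <= 0:
        raise InputError("duration_s must be positive")
    if duration_s < 2 * edge_margin_s + config.pulse_width_s:
        raise InputError(
            f"duration_s={duration_s} too short to hold one transit pulse "
            f"(need > {2 * edge_margin_s + config.pulse_width_s:.3f} s)")
    rng = np.random.default_rng(seed)
    usable = duration_s - 2 * edge_margin_s
    n_events = rng.poisson(config.arrival_rate_hz * usable)
    times = np.sort(rng.uniform(edge_margin_s, duration_s - edge_margin_s,
                                size=n_events))
    feats = simulate_peak_features(
        config, concentration, n_events, chip_id, experiment_id,
        seed=int(rng.integers(0, 2**31)))
    amps = amplitude_matrix(feats)
    events = [TraceEvent(float(tt), amps[i], float(concentration))
              for i, tt in enumerate(times)]
    samples = render_trace(config, events, duration_s, noise_rng=rng)
    return ImpedanceTrace(
        sampling_rate_hz=config.instrument.sampling_rate_hz,
        samples=samples, channel_frequencies=config.panel, truth=events,
        concentration=float(concentration), chip_id=str(chip_id),
        experiment_id=str(experiment_id))


def simulate_study(config: GeneratorConfig, design: dict, seed: int,
                   chip_id="chip1") -> pd.DataFrame:
    """Simulate a whole study on one chip at the feature level.

    ``design`` maps concentration (pg/mL) to ``(n_experiments,
    n_beads_per_experiment)``.  Returns one pooled peak table whose
    experiment identifiers are distinct per (concentration, replicate).
    """
    if not design:
        raise InputError("study design must be non-empty")
    bad = [c for c in design if float(c) not in config.concentrations]
    if bad:
        raise InputError(f"design concentrations {bad} absent from the "
                         "configured label set")
    ss = np.random.SeedSequence(seed)
    tables = []
    items = sorted(design.items(), key=lambda kv: float(kv[0]))
    n_total = sum(int(n_exp) for _, (n_exp, _) in items)
    child_seeds = ss.generate_state(max(n_total, 1)) % (2**31)
    k = 0
    for conc, (n_exp, n_beads) in items:
        for e in range(int(n_exp)):
            exp_id = f"{chip_id}-c{float(conc):g}-e{e + 1}"
            tables.append(simulate_peak_features(
                config, float(conc), int(n_beads), chip_id, exp_id,
                seed=int(child_seeds[k])))
            k += 1
    out = pd.concat(tables, ignore_index=True)
    return out
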