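"""Seeded generators for every input of the hearing-loss pipeline.

Four generators emulate the statistical structure of a longitudinal
locust noise-exposure experiment:

* ``simulate_nerve_trace`` — a hook-electrode recording: background
  compound spiking (homogeneous Poisson superposition of biphasic spike
  kernels) plus tone windows in which the spike rate is elevated so that
  the *expected* sigma ratio at each SPL equals a target 4PL curve, plus
  additive Gaussian instrument noise.
* ``simulate_dose_response`` — per-animal sigma-ratio tables: 4PL group
  truth + animal-level random intercept + residual noise.
* ``simulate_morphometry`` — cell counts and nerve width with linear age
  and treatment effects.
* ``simulate_displacement`` — tympanal displacement growing as a power
  of sound pressure above a vibrometer noise floor.

Rate calibration (documented because it is the load-bearing trick): the
superposition of Poisson-timed zero-integral kernels k(t) at rate r is a
shot-noise process whose marginal characteristic function is, by
Campbell's theorem,

    phi(t) = exp( r * sum_j (cos(t k_j) - 1) / sr  -  s_n^2 t^2 / 2 )

(the imaginary part vanishes because the biphasic kernel takes values in
+/- pairs), where k_j are the kernel samples, sr the sampling rate and
s_n the additive Gaussian noise SD.  The expected rectified level
follows exactly from the characteristic function,

    E|x| = (2/pi) * int_0^inf (1 - phi(t)) / t^2 dt,

which is monotone in r; ``calibrated_rate`` inverts it numerically so
the expected sigma ratio of each tone window equals the target 4PL
curve.  The Gaussian approximation E|x| ~ sqrt(2 (r Ek + s_n^2)/pi)
(variance from Campbell's theorem) seeds the bracket for the inversion.
The default background rate, 800 compound spikes/s, is the summed
spontaneous activity of the ~80 auditory afferents in the nerve.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import integrate, optimize
from scipy.signal import fftconvolve

from .dose_response import FourPLParams, fourpl
from .nerve_signal import NerveTrace

__all__ = [
    "ToneProtocol",
    "NerveSimConfig",
    "DoseResponseSimConfig",
    "MorphometrySimConfig",
    "CONTROL_TRUTH",
    "NOISE_TRUTH",
    "biphasic_kernel",
    "kernel_energy",
    "calibrated_rate",
    "simulate_nerve_trace",
    "simulate_dose_response",
    "simulate_morphometry",
    "simulate_displacement",
]


class SimulationError(ValueError):
    """Raised for invalid generator configuration."""


DEFAULT_SPL_LEVELS = tuple(float(s) for s in range(20, 111, 10))

# Default group truths for the sigma-ratio dose-response curves: a healthy
# ear saturating near sigma ~ 8 with half-maximal response at 75 dB SPL,
# and a noise-exposed ear with a reduced maximum and raised threshold.
CONTROL_TRUTH = FourPLParams(b=-0.15, c=1.0, d=8.0, e=75.0)
NOISE_TRUTH = FourPLParams(b=-0.15, c=1.0, d=5.0, e=85.0)


@dataclass(frozen=True)
class ToneProtocol:
    """Acoustic stimulation schedule for hook-electrode recordings.

    Defaults reproduce the study conditions: 3 kHz pure tones of 0.5 s
    (2 ms rise/fall), three repetitions per SPL from 20 to 110 dB SPL in
    10 dB steps, after 60 s of background activity, sampled at 25 kHz.
    The 1.0 s inter-tone gap leaves background-equivalent windows between
    tones.  Presentation order is ascending SPL (conventional
    audiometry) and is recorded in the trace annotations.
    """

    carrier_frequency: float = 3000.0
    tone_duration: float = 0.5
    ramp_duration: float = 0.002
    repetitions_per_spl: int = 3
    spl_levels: tuple = DEFAULT_SPL_LEVELS
    baseline_duration: float = 60.0
    inter_tone_gap: float = 1.0
    sampling_rate: float = 25000.0

    def __post_init__(self):
        object.__setattr__(self, "spl_levels",
                           tuple(float(s) for s in self.spl_levels))
        for name in ("tone_duration", "ramp_duration", "baseline_duration",
                     "inter_tone_gap", "sampling_rate", "carrier_frequency"):
            if getattr(self, name) <= 0:
                raise SimulationError(f"{name} must be positive")
        if self.tone_duration <= 2 * self.ramp_duration:
            raise SimulationError("tone_duration must exceed 2 * ramp_duration")
        if self.repetitions_per_spl < 1:
            raise SimulationError("repetitions_per_spl must be >= 1")
        if len(self.spl_levels) == 0:
            raise SimulationError("spl_levels must be non-empty")
        if any(b <= a for a, b in zip(self.spl_levels, self.spl_levels[1:])):
            raise SimulationError("spl_levels must be strictly increasing")
        if self.sampling_rate <= 2 * self.carrier_frequency:
            raise SimulationError("sampling_rate must exceed twice the carrier frequency")

    def tone_schedule(self) -> tuple:
        """(onset_s, spl) for every tone, ascending SPL, reps within SPL."""
        onsets = []
        t = self.baseline_duration
        for spl in self.spl_levels:
            for _ in range(self.repetitions_per_spl):
                onsets.append((t, spl))
                t += self.tone_duration + self.inter_tone_gap
        return tuple(onsets)

    @property
    def total_duration(self) -> float:
        n_tones = len(self.spl_levels) * self.repetitions_per_spl
        return self.baseline_duration + n_tones * (self.tone_duration
                                                   + self.inter_tone_gap)

    @property
    def n_samples(self) -> int:
        return int(round(self.sampling_rate * self.total_duration))

    def to_dict(self) -> dict:
        return {
            "carrier_frequency": self.carrier_frequency,
            "tone_duration": self.tone_duration,
            "ramp_duration": self.ramp_duration,
            "repetitions_per_spl": self.repetitions_per_spl,
            "spl_levels": list(self.spl_levels),
            "baseline_duration": self.baseline_duration,
            "inter_tone_gap": self.inter_tone_gap,
            "sampling_rate": self.sampling_rate,
        }


@dataclass(frozen=True)
class NerveSimConfig:
    """Generative settings for a synthetic auditory-nerve trace."""

    evoked_curve: FourPLParams = CONTROL_TRUTH
    background_spike_rate: float = 800.0   # compound spikes/s
    spike_amplitude_uv: float = 40.0
    spike_phase_width_ms: float = 0.5      # per lobe; biphasic kernel is 2 lobes
    gaussian_noise_sd_uv: float = 10.0
    seed: int = 0

    def __post_init__(self):
        if self.background_spike_rate < 0:
            raise SimulationError("background_spike_rate must be >= 0")
        if self.gaussian_noise_sd_uv < 0:
            raise SimulationError("gaussian_noise_sd_uv must be >= 0")
        if self.spike_amplitude_uv <= 0 or self.spike_phase_width_ms <= 0:
            raise SimulationError("spike kernel must have positive amplitude and width")

    def to_dict(self) -> dict:
        return {
            "evoked_curve": self.evoked_curve.to_dict(),
            "background_spike_rate": self.background_spike_rate,
            "spike_amplitude_uv": self.spike_amplitude_uv,
            "spike_phase_width_ms": self.spike_phase_width_ms,
            "gaussian_noise_sd_uv": self.gaussian_noise_sd_uv,
            "seed": self.seed,
        }


def biphasic_kernel(config: NerveSimConfig, sampling_rate: float) -> np.ndarray:
    """Biphasic compound-spike kernel: positive then negative half-sine lobe.

    The two lobes cancel exactly, so the kernel integrates to zero and
    the spike superposition has zero mean.  Refuses sampling rates that
    cannot resolve a lobe (fewer than 2 samples per phase).
    """
    n_lobe = int(round(config.spike_phase_width_ms * 1e-3 * sampling_rate))
    if n_lobe < 2:
        raise SimulationError(
            f"sampling rate {sampling_rate} Hz is below Nyquist for a "
            f"{config.spike_phase_width_ms} ms spike lobe")
    lobe = config.spike_amplitude_uv * np.sin(np.pi * np.arange(n_lobe) / n_lobe)
    return np.concatenate([lobe, -lobe])


def kernel_energy(config: NerveSimConfig, sampling_rate: float) -> float:
    """int k(t)^2 dt of the spike kernel, in uV^2 * s."""
    k = biphasic_kernel(config, sampling_rate)
    return float(np.sum(k ** 2) / sampling_rate)


def expected_rectified_level(rate: float, config: NerveSimConfig,
                             sampling_rate: float) -> float:
    """Exact E|x| of the spike superposition + Gaussian noise at spike rate ``rate``.

    Characteristic-function quadrature: E|x| = (2/pi) int (1-phi(t))/t^2 dt
    with phi from Campbell's theorem (see module docstring).
    """
    k = biphasic_kernel(config, sampling_rate)
    sn2 = config.gaussian_noise_sd_uv ** 2
    var = rate * float(np.sum(k ** 2)) / sampling_rate + sn2

    def integrand(t):
        logphi = rate * np.sum(np.cos(t * k) - 1.0) / sampling_rate - 0.5 * sn2 * t * t
        return -np.expm1(logphi) / (t * t)

    # integrate on a scale set by the marginal SD; phi decays on ~1/sd
    sd = np.sqrt(max(var, 1e-300))
    cut = 50.0 / sd
    head, _ = integrate.quad(integrand, 0.0, cut, limit=400,
                             points=[0.1 / sd, 1.0 / sd, 10.0 / sd])
    tail, _ = integrate.quad(integrand, cut, np.inf, limit=200)
    return float(2.0 * (head + tail) / np.pi)


def calibrated_rate(target_sigma: float, config: NerveSimConfig,
                    sampling_rate: float) -> float:
    """Tone-window spike rate whose expected sigma ratio is ``target_sigma``.

    Solves E|x|(r) = target_sigma * E|x|(background rate) for r, using the
    exact characteristic-function level (monotone in r) with a bracket
    seeded by the Gaussian variance approximation.  Refuses targets that
    would require a negative rate (suppression deeper than removing every
    spike can produce).
    """
    if config.background_spike_rate == 0 and config.gaussian_noise_sd_uv == 0:
        raise SimulationError(
            "zero background rate and zero noise: sigma-ratio denominator would be 0")
    if target_sigma <= 0:
        raise SimulationError("target sigma must be positive")
    if abs(target_sigma - 1.0) < 1e-12:
        return float(config.background_spike_rate)
    base_level = expected_rectified_level(config.background_spike_rate,
                                          config, sampling_rate)
    target_level = target_sigma * base_level
    floor_level = expected_rectified_level(0.0, config, sampling_rate)
    if target_level < floor_level - 1e-12 * max(floor_level, 1.0):
        raise SimulationError(
            f"target sigma {target_sigma} unreachable: would need negative spike rate")

    ek = kernel_energy(config, sampling_rate)
    sn2 = config.gaussian_noise_sd_uv ** 2
    v_base = config.background_spike_rate * ek + sn2
    r_gauss = max((target_sigma ** 2 * v_base - sn2) / ek, 0.0)

    def gap(r):
        return expected_rectified_level(r, config, sampling_rate) - target_level

    hi = max(2.0 * r_gauss, 2.0 * config.background_spike_rate, 1.0)
    while gap(hi) < 0:
        hi *= 2.0
        if hi > 1e12:
            raise SimulationError("calibration bracket expansion failed")
    return float(optimize.brentq(gap, 0.0, hi, xtol=1e-9, rtol=1e-12))


@lru_cache(maxsize=64)
def _calibrated_rates(curve_bytes, bg_rate, amp, width, noise_sd, sr, spls):
    curve = FourPLParams.from_array(np.frombuffer(curve_bytes))
    cfg = NerveSimConfig(evoked_curve=curve, background_spike_rate=bg_rate,
                         spike_amplitude_uv=amp, spike_phase_width_ms=width,
                         gaussian_noise_sd_uv=noise_sd)
    return tuple((spl, calibrated_rate(float(fourpl(spl, curve)), cfg, sr))
                 for spl in spls)


def _poisson_times(rng, rate, a, b):
    if rate <= 0 or b <= a:
        return np.empty(0)
    n = rng.poisson(rate * (b - a))
    return np.sort(a + rng.random(n) * (b - a))


def simulate_nerve_trace(protocol: ToneProtocol, config: NerveSimConfig,
                         meta: dict | None = None) -> NerveTrace:
    """Simulate a full annotated recording under the given protocol.

    Background intervals carry Poisson spikes at the background rate;
    each tone window carries the calibrated rate for its SPL (which may
    be below background when the evoked curve dips under 1).  Spikes are
    binned at the sampling rate and convolved with the biphasic kernel;
    Gaussian instrument noise is added last.  Fully reproducible from
    ``config.seed``.
    """
    sr = protocol.sampling_rate
    if config.background_spike_rate == 0 and config.gaussian_noise_sd_uv == 0:
        raise SimulationError(
            "zero background rate and zero noise: sigma-ratio denominator would be 0")
    kernel = biphasic_kernel(config, sr)
    schedule = protocol.tone_schedule()
    n = protocol.n_samples
    total = protocol.total_duration
    rng = np.random.default_rng(config.seed)

    # calibration is seed-independent; cache it across animals of a cohort
    rates = dict(_calibrated_rates(
        config.evoked_curve.as_array().tobytes(), config.background_spike_rate,
        config.spike_amplitude_uv, config.spike_phase_width_ms,
        config.gaussian_noise_sd_uv, sr, protocol.spl_levels))

    spike_times = []
    cursor = 0.0
    for onset, spl in schedule:
        if onset > cursor:
            spike_times.append(_poisson_times(rng, config.background_spike_rate,
                                              cursor, onset))
        spike_times.append(_poisson_times(rng, rates[spl], onset,
                                          onset + protocol.tone_duration))
        cursor = onset + protocol.tone_duration
    if cursor < total:
        spike_times.append(_poisson_times(rng, config.background_spike_rate,
                                          cursor, total))
    times = np.concatenate(spike_times) if spike_times else np.empty(0)

    counts = np.zeros(n)
    if times.size:
        idx = np.minimum((times * sr).astype(np.int64), n - 1)
        np.add.at(counts, idx, 1.0)
    x = fftconvolve(counts, kernel)[:n]
    if config.gaussian_noise_sd_uv > 0:
        x = x + rng.normal(0.0, config.gaussian_noise_sd_uv, n)

    info = {"seed": config.seed, "config": config.to_dict(),
            "protocol": protocol.to_dict(),
            "tone_rates": {str(k): v for k, v in rates.items()}}
    if meta:
        info.update(meta)
    return NerveTrace(
        samples=x,
        sampling_rate=sr,
        annotations=schedule,
        baseline_span=(0.0, protocol.baseline_duration),
        meta=info,
    )


@dataclass(frozen=True)
class DoseResponseSimConfig:
    """Per-animal sigma-ratio tables with animal random intercepts.

    Defaults follow the study conditions: two treatment groups (control
    vs noise-exposed 4PL truths), 9 animals per group (the hook-electrode
    cohort size), SPLs 20-110 dB in 10 dB steps.  Animal intercepts and
    residuals are Gaussian.
    """

    truth_per_group: dict = field(
        default_factory=lambda: {"control": CONTROL_TRUTH, "noise": NOISE_TRUTH})
    n_animals_per_group: int = 9
    animal_intercept_sd: float = 0.5
    residual_sd: float = 0.3
    spl_levels: tuple = DEFAULT_SPL_LEVELS
    day: int = 1
    seed: int = 0

    def __post_init__(self):
        object.__setattr__(self, "spl_levels",
                           tuple(float(s) for s in self.spl_levels))
        if self.animal_intercept_sd < 0 or self.residual_sd < 0:
            raise SimulationError("standard deviations must be >= 0")
        if self.n_animals_per_group < 2:
            raise SimulationError("n_animals_per_group must be >= 2")
        if len(self.spl_levels) == 0:
            raise SimulationError("spl_levels must be non-empty")

    def to_dict(self) -> dict:
        return {
            "truth_per_group": {g: p.to_dict() for g, p in self.truth_per_group.items()},
            "n_animals_per_group": self.n_animals_per_group,
            "animal_intercept_sd": self.animal_intercept_sd,
            "residual_sd": self.residual_sd,
            "spl_levels": list(self.spl_levels),
            "day": self.day,
            "seed": self.seed,
        }


def simulate_dose_response(config: DoseResponseSimConfig) -> pd.DataFrame:
    """One row per animal x SPL x group: 4PL truth + animal intercept + residual.

    The sigma ratio is a ratio of areas and therefore strictly positive;
    since the generative model is additive Gaussian, draws are floored at
    1e-6 so every table satisfies the sigma > 0 schema invariant.  At the
    default noise levels the floor is hit in well under 0.1% of rows.
    """
    rng = np.random.default_rng(config.seed)
    spls = np.asarray(config.spl_levels)
    rows = []
    for group in sorted(config.truth_per_group):
        truth = config.truth_per_group[group]
        mean_curve = fourpl(spls, truth)
        for i in range(config.n_animals_per_group):
            u = rng.normal(0.0, config.animal_intercept_sd) \
                if config.animal_intercept_sd > 0 else 0.0
            eps = rng.normal(0.0, config.residual_sd, spls.size) \
                if config.residual_sd > 0 else np.zeros(spls.size)
            sig = np.maximum(mean_curve + u + eps, 1e-6)
            for spl, s in zip(spls, sig):
                rows.append({
                    "animal_id": f"{group}_{i:02d}",
                    "treatment": group,
                    "day": config.day,
                    "spl_db": float(spl),
                    "sigma": float(s),
                    "n_reps_averaged": 1,
                })
    return pd.DataFrame(rows)


MORPHOMETRY_MEASURES = ("neuron_count", "organ_cell_count",
                        "nerve_cells_per_100um", "nerve_width_um")
COUNT_MEASURES = ("neuron_count", "organ_cell_count", "nerve_cells_per_100um")


def _default_morph(key):
    # Mueller's organ holds ~80 auditory neurons; neuron number declines with
    # age while supporting-cell counts and (age-wise) nerve width do not.
    table = {
        "baseline_mean": {"neuron_count": 80.0, "organ_cell_count": 450.0,
                          "nerve_cells_per_100um": 55.0, "nerve_width_um": 55.0},
        "age_slope": {"neuron_count": -0.5, "organ_cell_count": 0.0,
                      "nerve_cells_per_100um": 0.0, "nerve_width_um": 0.0},
        "treatment_offset": {"neuron_count": -2.0, "organ_cell_count": 0.0,
                             "nerve_cells_per_100um": -2.0, "nerve_width_um": -4.0},
        "noise_sd": {"neuron_count": 5.0, "organ_cell_count": 30.0,
                     "nerve_cells_per_100um": 6.0, "nerve_width_um": 6.0},
    }
    return dict(table[key])


@dataclass(frozen=True)
class MorphometrySimConfig:
    """Cross-sectional morphometry: separate animals at each day x group."""

    baseline_mean: dict = field(default_factory=lambda: _default_morph("baseline_mean"))
    age_slope: dict = field(default_factory=lambda: _default_morph("age_slope"))
    treatment_offset: dict = field(default_factory=lambda: _default_morph("treatment_offset"))
    noise_sd: dict = field(default_factory=lambda: _default_morph("noise_sd"))
    days: tuple = (0, 6, 12, 18, 24)
    n_per_day_per_group: int = 8
    seed: int = 0

    def __post_init__(self):
        if self.n_per_day_per_group < 0:
            raise SimulationError("n_per_day_per_group must be >= 0")
        for m in MORPHOMETRY_MEASURES:
            if self.baseline_mean.get(m, 1.0) <= 0:
                raise SimulationError(f"baseline mean for {m} must be positive")
            if self.noise_sd.get(m, 0.0) < 0:
                raise SimulationError(f"noise sd for {m} must be >= 0")

    def to_dict(self) -> dict:
        return {
            "baseline_mean": dict(self.baseline_mean),
            "age_slope": dict(self.age_slope),
            "treatment_offset": dict(self.treatment_offset),
            "noise_sd": dict(self.noise_sd),
            "days": list(self.days),
            "n_per_day_per_group": self.n_per_day_per_group,
            "seed": self.seed,
        }


def simulate_morphometry(config: MorphometrySimConfig) -> pd.DataFrame:
    """measure = baseline + age_slope*day + treatment_offset*1[noise] + noise.

    Counts are rounded to the nearest non-negative integer; widths are
    left continuous.
    """
    rng = np.random.default_rng(config.seed)
    rows = []
    counter = itertools.count()
    for day in config.days:
        for group in ("control", "noise"):
            for _ in range(config.n_per_day_per_group):
                row = {"animal_id": f"M{next(counter):03d}",
                       "treatment": group, "day": int(day)}
                for m in MORPHOMETRY_MEASURES:
                    mu = (config.baseline_mean.get(m, 0.0)
                          + config.age_slope.get(m, 0.0) * day
                          + (config.treatment_offset.get(m, 0.0)
                             if group == "noise" else 0.0))
                    sd = config.noise_sd.get(m, 0.0)
                    val = mu + (rng.normal(0.0, sd) if sd > 0 else 0.0)
                    if m in COUNT_MEASURES:
                        val = float(max(round(val), 0))
                    row[m] = float(val)
                rows.append(row)
    return pd.DataFrame(rows)


def simulate_displacement(power_exponent: float = 1.0, scale: float = 1e-3,
                          noise_floor: float = 1.0,
                          spl_levels=DEFAULT_SPL_LEVELS, seed: int = 0,
                          noise_cv: float = 0.1, n_animals: int = 10) -> pd.DataFrame:
    """Tympanal displacement (nm) vs SPL: power law above a noise floor.

    displacement = max(noise_floor*(1+eps1), scale * p^exponent * (1+eps2))
    with p = 10^(SPL/20) the relative sound pressure and eps multiplicative
    Gaussian noise of coefficient of variation ``noise_cv``.  Defaults put
    the signal at the 1 nm floor at 60 dB SPL, rising above it at higher
    levels, as in vibrometry of the locust tympanum.
    """
    if not np.isfinite(power_exponent):
        raise SimulationError("power_exponent must be finite")
    if scale <= 0:
        raise SimulationError("scale must be positive")
    if noise_floor < 0 or noise_cv < 0:
        raise SimulationError("noise_floor and noise_cv must be >= 0")
    rng = np.random.default_rng(seed)
    spls = np.asarray(tuple(spl_levels), dtype=float)
    if spls.size == 0:
        raise SimulationError("spl_levels must be non-empty")
    rows = []
    for i in range(n_animals):
        p = 10.0 ** (spls / 20.0)
        signal = scale * p ** power_exponent
        if noise_cv > 0:
            e1 = rng.normal(0.0, noise_cv, spls.size)
            e2 = rng.normal(0.0, noise_cv, spls.size)
        else:
            e1 = e2 = np.zeros(spls.size)
        disp = np.maximum(noise_floor * (1.0 + e1), signal * (1.0 + e2))
        for spl, dnm in zip(spls, disp):
            rows.append({"animal_id": f"D{i:02d}", "spl_db": float(spl),
                         "displacement_nm": float(dnm)})
    return pd.DataFrame(rows)
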