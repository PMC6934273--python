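"""Surrogate auditory-nerve (AN) fiber spike generator and spike-file adapter.

The GBC model is driven by high-spontaneous-rate AN fibers.  This module
provides a descriptor-level phenomenological generator that reproduces the
input statistics the coincidence model relies on, without modeling the
cochlea itself:

* spontaneous rate ~70 spikes/s;
* a sigmoidal rate-level function saturating above ~40 dB SPL, with an
  onset-adapted peak decaying to the sustained driven rate;
* frequency-dependent phase-locking that decays above ~1 kHz, realized by
  snapping spikes to the preferred stimulus phase with wrapped-Gaussian
  jitter (the concentration-to-VS mapping is the closed-form Fourier
  coefficient of the jitter density, VS = exp(-(2*pi*f*sigma)^2 / 2));
* absolute plus relative (exponential-recovery) refractoriness applied by
  sequential thinning, with the driving rate compensated so that the
  post-thinning rate matches the requested envelope;
* a V-shaped tuning filter in log-frequency, whose low-frequency limb
  plateaus at ``tail_threshold_shift`` dB so that intense low-frequency
  tones still drive high-CF fibers (the "tail" response).

Fibers and trials are statistically independent: the master seed spawns a
child seed per (fiber, trial) via ``numpy.random.SeedSequence(entropy=seed,
spawn_key=(fiber, trial))``, so any single fiber/trial is reproducible in
isolation and adding fibers or trials never perturbs existing ones.

Externally computed AN spike trains can be loaded from the plain-text
spike-time format via :func:`load_an_trains`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional

import numpy as np

from .model import SpikeData
from .io import read_spike_times

__all__ = [
    "StimulusDescriptor",
    "ANSurrogateParameters",
    "rate_envelope",
    "generate_an_trains",
    "load_an_trains",
    "target_vs",
    "tuning_attenuation",
]

_KINDS = ("silence", "tone", "sam")


@dataclass(frozen=True)
class StimulusDescriptor:
    """Parametric description of a sound protocol.

    kind : {"silence", "tone", "sam"}
    frequency : Hz — tone frequency, or SAM carrier frequency.
    level : dB SPL.
    duration : ms.
    rise_fall : ms — linear amplitude ramps at stimulus on- and offset.
    mod_frequency, mod_depth : SAM modulator (Hz, fraction in [0, 1]).
    cf : Hz — characteristic frequency of the driven fiber; defaults to the
        stimulus frequency (on-CF stimulation) when omitted.
    """

    kind: str = "tone"
    frequency: float = 350.0
    level: float = 70.0
    duration: float = 25.0
    rise_fall: float = 3.9
    mod_frequency: float = 100.0
    mod_depth: float = 1.0
    cf: Optional[float] = None

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ValueError(f"unknown stimulus kind {self.kind!r}")
        if not self.duration > 0:
            raise ValueError("duration must be > 0")
        if not 0.0 <= self.mod_depth <= 1.0:
            raise ValueError("mod_depth must be in [0, 1]")
        if self.kind != "silence" and 2 * self.rise_fall > self.duration:
            raise ValueError("rise/fall ramps must fit within the stimulus")

    @property
    def cf_hz(self) -> float:
        return self.frequency if self.cf is None else self.cf

    @classmethod
    def silence(cls, duration: float) -> "StimulusDescriptor":
        return cls(kind="silence", duration=duration, rise_fall=0.0)


@dataclass(frozen=True)
class ANSurrogateParameters:
    """Parameters of the surrogate AN fiber (high-spontaneous-rate class).

    Rates in spikes/s, refractory times in seconds, tuning slopes in dB per
    octave.  ``rate_threshold_level`` / ``rate_saturation_level`` anchor the
    sigmoid rate-level function (5% / 95% points).  ``vs_max``,
    ``vs_corner_freq`` and ``vs_slope`` parameterize the target
    vector-strength decay  vs_max / (1 + (f / corner)^slope); phase-locking
    grows with level along the same sigmoid as the rate, shifted
    ``vs_level_offset`` dB toward lower levels (locking emerges slightly
    below the rate threshold and saturates ~20 dB above it).
    ``tail_threshold_shift`` caps the low-frequency tuning attenuation so
    off-CF low tones become effective ~40 dB above the CF threshold.
    """

    spont_rate: float = 70.0
    max_driven_rate: float = 250.0
    rate_threshold_level: float = 0.0
    rate_saturation_level: float = 40.0
    onset_peak_ratio: float = 3.0
    onset_tau: float = 3.0
    abs_refractory: float = 450e-6
    rel_refractory: float = 512.5e-6
    vs_max: float = 0.85
    vs_corner_freq: float = 1300.0
    vs_slope: float = 2.5
    vs_level_offset: float = 10.0
    tail_threshold_shift: float = 40.0
    tuning_slope_low: float = 30.0
    tuning_slope_high: float = 60.0

    def __post_init__(self) -> None:
        if self.spont_rate < 0 or self.max_driven_rate < 0:
            raise ValueError("rates must be >= 0")
        if self.abs_refractory < 0 or self.rel_refractory < 0:
            raise ValueError("refractory periods must be >= 0")
        if not 0.0 <= self.vs_max < 1.0:
            raise ValueError("vs_max must be in [0, 1)")
        if self.rate_saturation_level <= self.rate_threshold_level:
            raise ValueError("rate_saturation_level must exceed rate_threshold_level")


def tuning_attenuation(freq: float, cf: float, p: ANSurrogateParameters) -> float:
    """Effective-level attenuation (dB) of a tone at ``freq`` for a fiber at ``cf``.

    V-shaped in log-frequency: the high side falls with ``tuning_slope_high``
    dB/octave; the low side with ``tuning_slope_low`` dB/octave but plateaus
    at ``tail_threshold_shift`` dB (the tuning-curve tail).
    """
    if freq <= 0 or cf <= 0:
        raise ValueError("frequencies must be > 0")
    octaves = np.log2(freq / cf)
    if octaves >= 0:
        return float(p.tuning_slope_high * octaves)
    return float(min(p.tuning_slope_low * (-octaves), p.tail_threshold_shift))


def target_vs(freq: float, p: ANSurrogateParameters) -> float:
    """Target sustained vector strength of the surrogate fiber at ``freq``."""
    return float(p.vs_max / (1.0 + (freq / p.vs_corner_freq) ** p.vs_slope))


def _level_sigmoid(level, p: ANSurrogateParameters):
    # Logistic rate-level function: 5% at the threshold level, 95% at saturation.
    mid = 0.5 * (p.rate_threshold_level + p.rate_saturation_level)
    scale = (p.rate_saturation_level - p.rate_threshold_level) / (2.0 * np.log(19.0))
    with np.errstate(over="ignore"):
        return 1.0 / (1.0 + np.exp(-(np.asarray(level) - mid) / scale))


def rate_envelope(
    stim: StimulusDescriptor, p: ANSurrogateParameters, dt: float = 0.01
) -> np.ndarray:
    """Instantaneous firing-rate envelope (spikes/s) on the ``dt`` grid.

    Silence is the flat spontaneous rate.  For tones, a sigmoid-in-level
    driven term is shaped by the stimulus ramps and multiplied by onset
    adaptation (peak ``onset_peak_ratio`` times the sustained driven rate,
    decaying with ``onset_tau``).  SAM additionally modulates the driven
    term by ``1 + mod_depth * sin(2*pi*f_mod*t)`` (rectified).
    """
    n = int(np.floor(stim.duration / dt + 0.5))
    t = (np.arange(n) + 0.5) * dt  # ms, bin centers
    if stim.kind == "silence":
        return np.full(n, p.spont_rate)

    eff_level = stim.level - tuning_attenuation(stim.frequency, stim.cf_hz, p)

    # The linear amplitude ramps act in the level domain (20*log10 of the
    # instantaneous amplitude), so at suprathreshold levels the driven rate
    # saturates within a small fraction of the ramp — the steep common
    # onset that makes converging fibers fire a coincident volley.
    ramp = np.ones(n)
    if stim.rise_fall > 0:
        ramp = np.minimum(t / stim.rise_fall, 1.0)
        ramp = np.minimum(ramp, np.maximum((stim.duration - t) / stim.rise_fall, 0.0))
    with np.errstate(divide="ignore"):
        level_t = eff_level + 20.0 * np.log10(np.maximum(ramp, 1e-12))
    driven = (p.max_driven_rate - p.spont_rate) * _level_sigmoid(level_t, p)

    # Onset adaptation decays from the moment the drive saturates (or the
    # ramp ends, below saturation); the peak driven rate is then
    # onset_peak_ratio times the sustained driven rate.
    if stim.rise_fall > 0 and eff_level > p.rate_saturation_level:
        t_on = stim.rise_fall * 10.0 ** ((p.rate_saturation_level - eff_level) / 20.0)
    else:
        t_on = stim.rise_fall
    onset = 1.0 + (p.onset_peak_ratio - 1.0) * np.exp(
        -np.maximum(t - t_on, 0.0) / p.onset_tau
    )
    driven = driven * onset
    if stim.kind == "sam":
        driven = driven * (1.0 + stim.mod_depth * np.sin(2e-3 * np.pi * stim.mod_frequency * t))
        driven = np.maximum(driven, 0.0)
    return p.spont_rate + driven


def _compensated_drive(env: np.ndarray, p: ANSurrogateParameters) -> np.ndarray:
    """Driving rate whose refractory-thinned output matches ``env``.

    Sequential thinning with an absolute dead time t_abs and exponential
    relative recovery (time constant t_rel) turns a Poisson stream of rate
    lambda into a renewal process with mean ISI approximately
    ``t_abs + 1/lambda + t_rel * (1 - lambda * t_rel)`` (first order in
    lambda*t_rel).  The driving rate is obtained by a damped fixed-point
    inversion of that relation, capped at 3000 spikes/s where the
    expansion breaks down (rates that high only occur at onset peaks).
    """
    t_abs = p.abs_refractory * 1e3  # ms
    t_rel = p.rel_refractory * 1e3
    r = np.asarray(env, dtype=float) / 1000.0  # spikes/ms
    lam = r.copy()
    with np.errstate(divide="ignore", invalid="ignore"):
        for _ in range(6):
            denom = np.where(
                r > 0,
                1.0 / np.maximum(r, 1e-12) - t_abs - t_rel * (1.0 - lam * t_rel),
                np.inf,
            )
            lam = 0.5 * lam + 0.5 * np.where(
                r > 0, 1.0 / np.clip(denom, 1.0 / 3.0, np.inf), 0.0
            )
    return lam * 1000.0


def _thin_refractory(t: np.ndarray, p: ANSurrogateParameters, rng) -> np.ndarray:
    t_abs = p.abs_refractory * 1e3
    t_rel = p.rel_refractory * 1e3
    keep = []
    last = -np.inf
    for ti in t:
        d = ti - last
        if d < t_abs:
            continue
        if t_rel > 0 and rng.random() >= 1.0 - np.exp(-(d - t_abs) / t_rel):
            continue
        keep.append(ti)
        last = ti
    return np.asarray(keep)


def generate_an_trains(
    stim: StimulusDescriptor,
    p: ANSurrogateParameters,
    n_fibers: int,
    n_trials: int,
    seed: int,
    dt: float = 0.01,
) -> List[SpikeData]:
    """Generate ``n_fibers`` independent surrogate AN fiber spike trains.

    Each fiber is a SpikeData with ``n_trials`` trials of the stimulus.
    Spikes are drawn from an inhomogeneous point process with the
    compensated rate envelope; for tonal stimuli they are then snapped to
    the preferred stimulus phase with wrapped-Gaussian jitter matched to
    the target VS curve, and refractoriness is applied by thinning.
    Identical (seed, fiber, trial) triples always reproduce the same train.
    """
    if n_fibers < 1 or n_trials < 1:
        raise ValueError("n_fibers and n_trials must be >= 1")
    env = rate_envelope(stim, p, dt)
    drive = _compensated_drive(env, p)
    lam = drive * dt / 1000.0  # expected count per step
    cum = np.concatenate([[0.0], np.cumsum(lam)])
    total = cum[-1]
    grid = np.arange(env.size + 1) * dt

    snap = stim.kind == "tone"
    p_lock = 0.0
    if snap:
        vs_t = target_vs(stim.frequency, p)
        eff_level = stim.level - tuning_attenuation(stim.frequency, stim.cf_hz, p)
        p_lock = float(_level_sigmoid(eff_level + p.vs_level_offset, p))
        snap = vs_t > 1e-3 and p_lock > 1e-3
    if snap:
        period = 1000.0 / stim.frequency  # ms
        sigma = np.sqrt(-2.0 * np.log(vs_t)) * period / (2.0 * np.pi)
        pref = 0.25  # preferred phase, cycles (arbitrary fixed convention)
        full_lock = p_lock >= 1.0 - 1e-9

    fibers = []
    for fiber in range(n_fibers):
        trials = []
        for trial in range(n_trials):
            ss = np.random.SeedSequence(entropy=seed, spawn_key=(fiber, trial))
            rng = np.random.default_rng(ss)
            n = rng.poisson(total)
            u = np.sort(rng.random(n)) * total
            t = np.interp(u, cum, grid)
            if snap and t.size:
                # below rate saturation only a level-dependent fraction of
                # spikes is snapped onto the preferred phase
                mask = (np.ones(t.size, dtype=bool) if full_lock
                        else rng.random(t.size) < p_lock)
                k = np.floor(t[mask] / period - pref + 0.5)
                t[mask] = (k + pref) * period + rng.normal(0.0, sigma,
                                                           int(mask.sum()))
                t = np.sort(t)
            t = t[(t >= 0.0) & (t < stim.duration)]
            t = _thin_refractory(t, p, rng)
            trials.append(t)
        fibers.append(
            SpikeData(
                trials=trials,
                trial_duration=stim.duration,
                meta={"stimulus": stim, "seed": seed, "fiber": fiber, "source": "surrogate"},
            )
        )
    return fibers


def load_an_trains(
    path,
    n_fibers: Optional[int] = None,
    n_trials: Optional[int] = None,
    trial_duration: Optional[float] = None,
) -> List[SpikeData]:
    """Load AN fiber trains from a spike-time text file (trial, fiber, time_ms).

    Validates grouping by fiber and raises a structural error when the file
    does not contain the expected number of fibers or trials.
    """
    fibers = read_spike_times(path, trial_duration=trial_duration)
    if n_fibers is not None and len(fibers) != n_fibers:
        raise ValueError(f"expected {n_fibers} fibers, file contains {len(fibers)}")
    if n_trials is not None:
        for i, f in enumerate(fibers):
            if f.n_trials != n_trials:
                raise ValueError(
                    f"fiber {i}: expected {n_trials} trials, found {f.n_trials}"
                )
    for f in fibers:
        f.validate()
    return fibers
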