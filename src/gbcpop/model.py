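"""Adaptive coincidence counting model of globular bushy cells (GBCs).

The model neuron receives spike trains from ``m_e`` auditory-nerve fibers.
Every input spike is converted into a rectangular postsynaptic count of
duration ``w_e`` (the coincidence window) and amplitude ``a_e``, so the
summed input at time ``t`` is

    v(t) = a_e * (number of input spikes across all fibers in (t - w_e, t]).

An output spike is emitted whenever ``v(t)`` reaches or exceeds the
adaptive threshold ``theta(t) = theta_S + theta_D(t)`` with a fixed static
part ``theta_S = 1`` and a dynamic part obeying

    t_a * d(theta_D)/dt = -theta_D(t) + s_a * v(t).

After each output spike the model is absolutely refractory for ``t_r`` ms.
The dynamic threshold depends only on the input history: it is not reset by
output spikes and keeps integrating the input during refractoriness.

Because ``v(t)`` is piecewise constant between grid steps (rectangular
inputs on a fixed grid of ``dt`` = 0.01 ms), the threshold ODE admits an
exact per-step digital solution, implemented in :func:`update_threshold`.

Per-step order of operations (at step ``t_j``): (1) compute ``v(t_j)`` from
the input events; (2) if the model is not refractory and
``v(t_j) >= theta_S + theta_D(t_j)``, emit a spike at ``t_j`` and start the
refractory clock; (3) advance ``theta_D`` using ``v(t_j)``.  Thus the
threshold tested at step ``j`` integrates the input strictly before ``j``.

``w_e`` and ``t_r`` are quantized onto the ``dt`` grid by round-half-up
(minimum one step for ``w_e``); an input spike at time ``s`` contributes to
``v(t)`` for ``t`` in the half-open interval ``[s, s + w_e)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Sequence

import numpy as np
from scipy.signal import lfilter

__all__ = [
    "GBCParameters",
    "SimulationConfig",
    "SpikeData",
    "DEFAULT_PARAMS",
    "update_threshold",
    "threshold_trace",
    "bin_input_counts",
    "windowed_counts",
    "emit_spikes",
    "simulate_gbc",
    "quantize_steps",
]


@dataclass(frozen=True)
class GBCParameters:
    """The six parameters of the adaptive coincidence counting model.

    Defaults are the exemplar primary-like-with-notch unit used throughout
    for representative responses.

    Attributes
    ----------
    m_e : int
        Number of excitatory auditory-nerve input fibers (>= 1).
    w_e : float
        Coincidence window = duration of each rectangular input, ms (> 0).
    a_e : float
        Excitatory input amplitude relative to the static threshold
        ``theta_S = 1`` (> 0, dimensionless).
    t_r : float
        Absolute refractory period, ms (>= 0).
    t_a : float
        Threshold adaptation time constant, ms (> 0).
    s_a : float
        Threshold adaptation strength (>= 0, dimensionless).
    """

    m_e: int = 20
    w_e: float = 0.32
    a_e: float = 0.40
    t_r: float = 1.20
    t_a: float = 0.25
    s_a: float = 0.80

    def __post_init__(self) -> None:
        if int(self.m_e) != self.m_e or self.m_e < 1:
            raise ValueError(f"m_e must be a positive integer, got {self.m_e}")
        if not self.w_e > 0:
            raise ValueError(f"w_e must be > 0, got {self.w_e}")
        if not self.a_e > 0:
            raise ValueError(f"a_e must be > 0, got {self.a_e}")
        if self.t_r < 0:
            raise ValueError(f"t_r must be >= 0, got {self.t_r}")
        if not self.t_a > 0:
            raise ValueError(f"t_a must be > 0, got {self.t_a}")
        if self.s_a < 0:
            raise ValueError(f"s_a must be >= 0, got {self.s_a}")

    def as_dict(self) -> Dict[str, float]:
        return {
            "m_e": int(self.m_e),
            "w_e": self.w_e,
            "a_e": self.a_e,
            "t_r": self.t_r,
            "t_a": self.t_a,
            "s_a": self.s_a,
        }


#: The exemplar PL_N parameter set (median of the accepted population at 20 inputs).
DEFAULT_PARAMS = GBCParameters()


@dataclass
class SimulationConfig:
    """Time-grid configuration for the digital simulation.

    ``dt`` is the simulation step in ms (0.01 ms by default); ``duration``
    the length of one trial in ms; ``initial_theta_d`` the dynamic-threshold
    starting value (0 by default; the model starts non-refractory, so a
    spike may be emitted at the very first step).
    """

    dt: float = 0.01
    duration: float = 25.0
    initial_theta_d: float = 0.0

    def __post_init__(self) -> None:
        if not self.dt > 0:
            raise ValueError("dt must be > 0")
        if not self.duration > 0:
            raise ValueError("duration must be > 0")

    @property
    def n_steps(self) -> int:
        return int(np.floor(self.duration / self.dt + 0.5))


@dataclass
class SpikeData:
    """Per-trial spike-time collections with duration metadata.

    ``trials`` is an ordered list of float arrays of spike times in ms,
    each strictly increasing and within ``[0, trial_duration]``.  ``meta``
    carries free-form provenance (stimulus, seed, source).
    """

    trials: List[np.ndarray]
    trial_duration: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.trials = [np.asarray(t, dtype=float) for t in self.trials]

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    @property
    def n_spikes(self) -> int:
        return int(sum(t.size for t in self.trials))

    def pooled(self) -> np.ndarray:
        """All spike times pooled across trials (trial structure dropped)."""
        if not self.trials:
            return np.empty(0)
        return np.concatenate(self.trials)

    def validate(self, min_isi: float = 0.0) -> None:
        """Check spike times lie in the trial and are strictly increasing.

        ``min_isi`` additionally enforces a refractory floor on consecutive
        intervals (used for model output, where ISIs must be >= t_r).
        """
        for i, t in enumerate(self.trials):
            if t.size == 0:
                continue
            if t[0] < 0 or t[-1] > self.trial_duration:
                raise ValueError(
                    f"trial {i}: spike times outside [0, {self.trial_duration}] ms"
                )
            d = np.diff(t)
            if t.size > 1 and not np.all(d > 0):
                raise ValueError(f"trial {i}: spike times not strictly increasing")
            if min_isi > 0 and t.size > 1 and d.min() < min_isi:
                raise ValueError(f"trial {i}: ISI below {min_isi} ms")


def quantize_steps(x: float, dt: float, minimum: int = 0) -> int:
    """Quantize a duration ``x`` (ms) onto the ``dt`` grid, round-half-up."""
    return max(minimum, int(np.floor(x / dt + 0.5)))


def update_threshold(theta_d, v, t_a: float, s_a: float, dt: float):
    """Advance the dynamic threshold by one step of the exact digital solution.

    With the summed input ``v`` held constant over the step, the ODE
    ``t_a * d(theta_D)/dt = -theta_D + s_a * v`` integrates exactly to

        theta_D(t + dt) = exp(-dt/t_a) * theta_D(t)
                          + (1 - exp(-dt/t_a)) * s_a * v(t).

    Accepts scalars or arrays (broadcast).
    """
    if not t_a > 0:
        raise ValueError("t_a must be > 0")
    if not dt > 0:
        raise ValueError("dt must be > 0")
    decay = np.exp(-dt / t_a)
    return decay * np.asarray(theta_d) + (1.0 - decay) * s_a * np.asarray(v)


def threshold_trace(
    v: np.ndarray, t_a: float, s_a: float, dt: float, initial: float = 0.0
) -> np.ndarray:
    """Dynamic threshold time series for a summed-input series ``v``.

    Returns ``theta_d`` with the step-order convention of the model:
    ``theta_d[j]`` is the value tested against ``v[j]`` and integrates
    ``v[0..j-1]`` only.  Works on 1-D series or 2-D (trials, steps) arrays.

    The recursion ``theta_d[j] = a*theta_d[j-1] + (1-a)*s_a*v[j-1]`` is a
    first-order linear filter and is evaluated as such.
    """
    if not t_a > 0 or not dt > 0:
        raise ValueError("t_a and dt must be > 0")
    v = np.asarray(v, dtype=float)
    a = np.exp(-dt / t_a)
    theta = lfilter([0.0, (1.0 - a) * s_a], [1.0, -a], v, axis=-1)
    if initial != 0.0:
        n = v.shape[-1]
        with np.errstate(under="ignore"):
            theta = theta + initial * a ** np.arange(n)
    return theta


def bin_input_counts(
    inputs: Sequence[SpikeData], dt: float, n_steps: int
) -> np.ndarray:
    """Sum input spikes across fibers onto the simulation grid.

    Returns an int array of shape (n_trials, n_steps): the number of input
    spikes (over all fibers) snapped to each grid step, round-half-up.
    """
    n_trials = inputs[0].n_trials
    counts = np.zeros((n_trials, n_steps), dtype=np.int16)
    for fiber in inputs:
        if fiber.n_trials != n_trials:
            raise ValueError("all input fibers must have the same number of trials")
        for i, t in enumerate(fiber.trials):
            if t.size == 0:
                continue
            idx = np.floor(t / dt + 0.5).astype(np.int64)
            if idx.min() < 0 or (t.max() > inputs[0].trial_duration):
                raise ValueError(f"trial {i}: input spike time outside trial")
            idx = idx[idx < n_steps]  # a spike snapped onto the end boundary is dropped
            np.add.at(counts, (i, idx), 1)
    return counts


def windowed_counts(counts: np.ndarray, w_steps: int) -> np.ndarray:
    """Sliding-window sum of grid counts over the trailing ``w_steps`` steps.

    Element ``[..., j]`` is the total count in steps ``(j - w_steps, j]``,
    i.e. the number of input spikes whose rectangular response covers step
    ``j`` (half-open window ``[s, s + w_e)``).
    """
    c = np.cumsum(counts, axis=-1, dtype=np.int64)
    out = c.copy()
    if w_steps < counts.shape[-1]:
        out[..., w_steps:] = c[..., w_steps:] - c[..., :-w_steps]
    return out


def emit_spikes(eligible_idx: np.ndarray, t_r_steps: int) -> np.ndarray:
    """Greedy refractory selection over threshold-crossing step indices.

    Emits at the first eligible step, then suppresses eligible steps closer
    than ``t_r_steps`` to the last emission; a step exactly ``t_r_steps``
    later is allowed (ISI >= t_r on the grid).
    """
    out = []
    last = -np.inf
    for j in eligible_idx:
        if j - last >= t_r_steps:
            out.append(j)
            last = j
    return np.asarray(out, dtype=np.int64)


def run_coincidence(
    counts: np.ndarray, params: GBCParameters, config: SimulationConfig
) -> List[np.ndarray]:
    """Core fast path: output spike times from pre-binned input counts.

    ``counts`` has shape (n_trials, n_steps).  Returns one array of output
    spike times (ms) per trial.
    """
    dt = config.dt
    w_steps = quantize_steps(params.w_e, dt, minimum=1)
    t_r_steps = quantize_steps(params.t_r, dt)
    v = params.a_e * windowed_counts(counts, w_steps)
    theta_d = threshold_trace(v, params.t_a, params.s_a, dt, config.initial_theta_d)
    eligible = v >= 1.0 + theta_d
    out = []
    for trial in range(counts.shape[0]):
        idx = np.flatnonzero(eligible[trial])
        out.append(emit_spikes(idx, t_r_steps) * dt)
    return out


def simulate_gbc(
    inputs: Sequence[SpikeData],
    params: GBCParameters,
    config: SimulationConfig,
) -> SpikeData:
    """Simulate the GBC model for a set of input fiber spike trains.

    Parameters
    ----------
    inputs : sequence of SpikeData
        Exactly ``params.m_e`` fiber trains with identical trial structure.
    params : GBCParameters
    config : SimulationConfig

    Returns
    -------
    SpikeData
        Output spike times per trial; consecutive output spikes within a
        trial are separated by at least ``t_r`` (up to grid quantization).
    """
    if len(inputs) != params.m_e:
        raise ValueError(
            f"expected {params.m_e} input fibers (m_e), got {len(inputs)}"
        )
    dur = inputs[0].trial_duration
    for f in inputs:
        if f.trial_duration != dur:
            raise ValueError("input fibers disagree on trial duration")
        f.validate()
    n_steps = config.n_steps
    counts = bin_input_counts(inputs, config.dt, n_steps)
    trains = run_coincidence(counts, params, config)
    return SpikeData(
        trials=trains,
        trial_duration=config.duration,
        meta={"params": params.as_dict(), "dt": config.dt},
    )
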