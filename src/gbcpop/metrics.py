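"""Spike-train output measures: rates, regularity, phase-locking, histograms.

All sustained measures are computed on the 10-25 ms window after stimulus
onset for 25-ms tone protocols (the steady-state part of the response).
Interspike intervals never straddle trial boundaries.  Metrics that are
undefined on a given train (no spikes, too few ISIs, mean ISI at or below
the dead-time correction) are returned as ``None`` — an explicit flag, not
a silent zero.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np

from .model import SpikeData

__all__ = [
    "ResponseMetrics",
    "Histogram",
    "sustained_window_spikes",
    "vector_strength",
    "entrainment_index",
    "cv_prime",
    "compute_psth",
    "spont_and_driven_rates",
    "period_histogram",
    "isih",
    "pooled_isis",
]

#: Default sustained analysis window (ms after stimulus onset).
SUSTAINED_WINDOW = (10.0, 25.0)

#: Dead-time correction for the modified coefficient of variation (ms).
MU0_MS = 0.5

#: Five-point triangular smoothing kernel (sums to one).
PSTH_KERNEL = np.array([1.0, 2.0, 3.0, 2.0, 1.0]) / 9.0


@dataclass
class ResponseMetrics:
    """Bundle of the five selection measures for one instance and stimulus.

    ``None`` marks an undefined measure (e.g. no spikes).
    """

    sr: Optional[float] = None          # spontaneous rate, spikes/s
    dr: Optional[float] = None          # sound-driven sustained rate, spikes/s
    cv_prime: Optional[float] = None    # modified coefficient of variation
    vs: Optional[float] = None          # vector strength in [0, 1]
    ei: Optional[float] = None          # entrainment index in [0, 1]
    n_spikes_used: int = 0


@dataclass
class Histogram:
    """A PSTH, period histogram or ISI histogram.

    ``bin_edges`` are in ms (PSTH/ISIH) or cycle fraction (period
    histogram); ``smoothed_rate`` (spikes/s per bin) is populated for
    smoothed PSTHs only.
    """

    kind: str
    bin_edges: np.ndarray
    counts: np.ndarray
    smoothed_rate: Optional[np.ndarray] = None
    n_trials: int = 1

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def bin_width(self) -> float:
        return float(self.bin_edges[1] - self.bin_edges[0])


def sustained_window_spikes(
    spikes: SpikeData,
    start: float = SUSTAINED_WINDOW[0],
    end: float = SUSTAINED_WINDOW[1],
) -> SpikeData:
    """Restrict spikes to the half-open sustained window ``[start, end)``.

    Per-trial structure is preserved.
    """
    if not end > start:
        raise ValueError("end must exceed start")
    trials = [t[(t >= start) & (t < end)] for t in spikes.trials]
    return SpikeData(trials=trials, trial_duration=spikes.trial_duration,
                     meta={**spikes.meta, "window": (start, end)})


def vector_strength(spikes: SpikeData, f: float) -> Optional[float]:
    """Vector strength VS = (1/N) |sum_k exp(2*pi*i*f*t_k)| at frequency ``f`` (Hz).

    Spikes are pooled across trials.  Returns ``None`` when there are no
    spikes (undefined, not zero).
    """
    if not f > 0:
        raise ValueError("f must be > 0")
    t = spikes.pooled()
    if t.size == 0:
        return None
    phase = 2.0 * np.pi * f * t / 1000.0
    return float(np.abs(np.mean(np.exp(1j * phase))))


def pooled_isis(spikes: SpikeData) -> np.ndarray:
    """Interspike intervals pooled across trials, computed within trials only."""
    isis = [np.diff(t) for t in spikes.trials if t.size >= 2]
    if not isis:
        return np.empty(0)
    return np.concatenate(isis)


def entrainment_index(spikes: SpikeData, f: float) -> Optional[float]:
    """Fraction of ISIs strictly inside (0.5/f, 1.5/f).

    An EI of 1 means one spike per stimulus cycle; skipped cycles (ISIs of
    two or more periods) and extra within-cycle spikes both lower it.
    Returns ``None`` when there are no ISIs.
    """
    if not f > 0:
        raise ValueError("f must be > 0")
    isis = pooled_isis(spikes)
    if isis.size == 0:
        return None
    period = 1000.0 / f  # ms
    inside = (isis > 0.5 * period) & (isis < 1.5 * period)
    return float(np.count_nonzero(inside) / isis.size)


def cv_prime(spikes: SpikeData, mu0: float = MU0_MS) -> Optional[float]:
    """Modified coefficient of variation CV' = sigma_ISI / (mu_ISI - mu0).

    ``mu0`` (default 0.5 ms) corrects for the dead time of the response;
    sigma is the population (divide-by-N) standard deviation of the pooled
    within-trial ISIs.  Undefined (``None``) with fewer than two ISIs or
    when the mean ISI does not exceed ``mu0``.
    """
    isis = pooled_isis(spikes)
    if isis.size < 2:
        return None
    mu = float(np.mean(isis))
    if mu <= mu0:
        return None
    return float(np.std(isis) / (mu - mu0))


def compute_psth(
    spikes: SpikeData,
    bin_ms: float = 0.1,
    smooth: bool = True,
    t_max: Optional[float] = None,
) -> Histogram:
    """Peristimulus time histogram with optional five-point triangular smoothing.

    Counts are accumulated over all trials in ``bin_ms`` bins from 0 to the
    trial duration.  The smoothed rate is the convolution of the counts
    with the kernel (1,2,3,2,1)/9 converted to spikes/s by dividing by
    (n_trials * bin); the kernel sums to one, so smoothing preserves the
    total count away from the edges.
    """
    if t_max is None:
        t_max = spikes.trial_duration
    n_bins = int(np.ceil(t_max / bin_ms - 1e-9))
    edges = np.arange(n_bins + 1) * bin_ms
    counts, _ = np.histogram(spikes.pooled(), bins=edges)
    smoothed = None
    if smooth:
        sm = np.convolve(counts.astype(float), PSTH_KERNEL, mode="same")
        smoothed = sm / (max(spikes.n_trials, 1) * bin_ms * 1e-3)
    return Histogram(kind="psth", bin_edges=edges, counts=counts,
                     smoothed_rate=smoothed, n_trials=spikes.n_trials)


def spont_and_driven_rates(
    silence_spikes: SpikeData,
    driven_spikes: SpikeData,
    window: Tuple[float, float] = SUSTAINED_WINDOW,
) -> Tuple[float, float]:
    """Spontaneous and sound-driven sustained rates in spikes/s.

    The spontaneous rate is the total silence spike count over the total
    simulated silence time; the driven rate counts spikes in the sustained
    window across trials.
    """
    total_ms = silence_spikes.n_trials * silence_spikes.trial_duration
    sr = silence_spikes.n_spikes / (total_ms * 1e-3) if total_ms > 0 else 0.0
    sus = sustained_window_spikes(driven_spikes, *window)
    span_ms = (window[1] - window[0]) * driven_spikes.n_trials
    dr = sus.n_spikes / (span_ms * 1e-3) if span_ms > 0 else 0.0
    return float(sr), float(dr)


def period_histogram(spikes: SpikeData, f: float, n_bins: int = 50) -> Histogram:
    """Spike counts folded by stimulus phase (cycle fraction in [0, 1))."""
    if not f > 0:
        raise ValueError("f must be > 0")
    t = spikes.pooled()
    phase = np.mod(t * f / 1000.0, 1.0)
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    counts, _ = np.histogram(phase, bins=edges)
    return Histogram(kind="period", bin_edges=edges, counts=counts,
                     n_trials=spikes.n_trials)


def isih(spikes: SpikeData, bin_ms: float = 0.1, t_max: float = 20.0) -> Histogram:
    """Interspike-interval histogram (within-trial ISIs only)."""
    isis = pooled_isis(spikes)
    edges = np.arange(int(np.ceil(t_max / bin_ms)) + 1) * bin_ms
    counts, _ = np.histogram(isis, bins=edges)
    return Histogram(kind="isih", bin_edges=edges, counts=counts,
                     n_trials=spikes.n_trials)


def response_metrics(
    silence: SpikeData,
    high_freq: SpikeData,
    low_freq: SpikeData,
    f_low: float = 350.0,
    window: Tuple[float, float] = SUSTAINED_WINDOW,
) -> ResponseMetrics:
    """Convenience bundle: SR, DR, CV' (high-frequency) and VS, EI (low)."""
    sr, dr = spont_and_driven_rates(silence, high_freq, window)
    sus_hi = sustained_window_spikes(high_freq, *window)
    sus_lo = sustained_window_spikes(low_freq, *window)
    return ResponseMetrics(
        sr=sr,
        dr=dr,
        cv_prime=cv_prime(sus_hi),
        vs=vector_strength(sus_lo, f_low),
        ei=entrainment_index(sus_lo, f_low),
        n_spikes_used=sus_hi.n_spikes + sus_lo.n_spikes,
    )
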