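"""Parameter-grid construction, population screening and validation drivers.

The six model parameters are varied over a Cartesian grid (the full grid
has 7 x 10 x 9 x 9 x 10 x 10 = 567,000 instances).  Every instance is
driven through the selection battery — continuous silence for the
spontaneous rate, a 350 Hz / 70 dB SPL tone for phase-locking and
entrainment, and a 7000 Hz / 70 dB SPL tone for the driven rate,
regularity and PSTH shape — and classified with the PL_N/On_L rules.

AN input trains are generated once per (stimulus, m_e) and shared across
all instances with that fiber count: instance differences are purely
postsynaptic, and sharing the presynaptic drive is what makes the screen
tractable.  With a fixed seed the screen is fully deterministic.

A desk-scale preset (3 values per dimension around the exemplar instance,
729 instances, 100 trials, 20 s of silence) is provided for interactive
use and testing; the full grid is a supported long-running mode.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .an import ANSurrogateParameters, StimulusDescriptor, generate_an_trains
from .classify import check_psth_criteria, extract_psth_features, select_instance
from .metrics import (
    SUSTAINED_WINDOW,
    ResponseMetrics,
    compute_psth,
    cv_prime,
    entrainment_index,
    spont_and_driven_rates,
    sustained_window_spikes,
    vector_strength,
)
from .model import (
    GBCParameters,
    SimulationConfig,
    SpikeData,
    bin_input_counts,
    run_coincidence,
)

__all__ = [
    "PARAM_NAMES",
    "TABLE1_VALUES",
    "DESK_VALUES",
    "ParameterGrid",
    "build_grid",
    "desk_grid",
    "SelectionProtocol",
    "InstanceEvaluator",
    "run_selection",
    "dimensional_stack",
    "PAPER_STACK_LAYOUT",
    "fra_threshold_curve",
    "q10_from_curve",
    "compute_fra",
    "frequency_sweep_bounds",
    "tail_sync_bounds",
    "sam_max_vs",
]

PARAM_NAMES = ("m_e", "w_e", "a_e", "t_r", "t_a", "s_a")

#: Full parameter value lists (7 x 10 x 9 x 9 x 10 x 10 = 567,000 instances).
TABLE1_VALUES: Dict[str, tuple] = {
    "m_e": (9, 12, 16, 20, 25, 30, 36),
    "w_e": (0.08, 0.16, 0.24, 0.32, 0.40, 0.48, 0.56, 0.64, 0.72, 0.80),
    "a_e": (0.24, 0.28, 0.32, 0.36, 0.40, 0.44, 0.48, 0.52, 0.56),
    "t_r": (0.70, 0.80, 0.90, 1.00, 1.10, 1.20, 1.30, 1.40, 1.50),
    "t_a": (0.05, 0.10, 0.15, 0.20, 0.25, 0.30, 0.35, 0.40, 0.45, 0.50),
    "s_a": (0.40, 0.50, 0.60, 0.70, 0.80, 0.90, 1.00, 1.10, 1.20, 1.30),
}

#: Desk-scale preset: the exemplar value and its two grid neighbors per dimension.
DESK_VALUES: Dict[str, tuple] = {
    "m_e": (16, 20, 25),
    "w_e": (0.24, 0.32, 0.40),
    "a_e": (0.36, 0.40, 0.44),
    "t_r": (1.10, 1.20, 1.30),
    "t_a": (0.20, 0.25, 0.30),
    "s_a": (0.70, 0.80, 0.90),
}

#: Dimensional-stack nesting used for the population figures:
#: outer (m_e rows, s_a cols), middle (a_e, t_r), inner (w_e, t_a).
PAPER_STACK_LAYOUT = (("m_e", "s_a"), ("a_e", "t_r"), ("w_e", "t_a"))


@dataclass(frozen=True)
class ParameterGrid:
    """Ordered per-dimension value lists; instance ids enumerate the product.

    Instance id <-> 6-tuple of grid indices is the C-order bijection over
    dimensions in ``PARAM_NAMES`` order.
    """

    values: Dict[str, tuple]

    def __post_init__(self) -> None:
        for name in PARAM_NAMES:
            vals = self.values.get(name)
            if not vals:
                raise ValueError(f"grid dimension {name!r} is empty or missing")
            if list(vals) != sorted(vals):
                raise ValueError(f"grid dimension {name!r} must be sorted")

    @property
    def shape(self) -> Tuple[int, ...]:
        return tuple(len(self.values[n]) for n in PARAM_NAMES)

    @property
    def size(self) -> int:
        return int(np.prod(self.shape))

    def params_at(self, instance_id: int) -> GBCParameters:
        idx = np.unravel_index(instance_id, self.shape)
        kw = {n: self.values[n][i] for n, i in zip(PARAM_NAMES, idx)}
        kw["m_e"] = int(kw["m_e"])
        return GBCParameters(**kw)

    def index_of(self, params: GBCParameters) -> int:
        idx = []
        for n in PARAM_NAMES:
            vals = self.values[n]
            target = getattr(params, n)
            match = [i for i, v in enumerate(vals) if math.isclose(v, target)]
            if not match:
                raise ValueError(f"{n}={target} is not on the grid")
            idx.append(match[0])
        return int(np.ravel_multi_index(tuple(idx), self.shape))

    def __iter__(self):
        for i in range(self.size):
            yield i, self.params_at(i)


def build_grid(overrides: Optional[Dict[str, Sequence[float]]] = None) -> ParameterGrid:
    """The full default grid, optionally overriding per-dimension value lists."""
    values = {n: tuple(TABLE1_VALUES[n]) for n in PARAM_NAMES}
    if overrides:
        for name, vals in overrides.items():
            if name not in PARAM_NAMES:
                raise ValueError(f"unknown grid dimension {name!r}")
            values[name] = tuple(vals)
    return ParameterGrid(values=values)


def desk_grid() -> ParameterGrid:
    """The 3-values-per-dimension desk-scale grid (729 instances)."""
    return ParameterGrid(values={n: tuple(DESK_VALUES[n]) for n in PARAM_NAMES})


@dataclass(frozen=True)
class SelectionProtocol:
    """Stimulus battery for the selection screen.

    Tones are 25-ms bursts with 3.9-ms linear ramps at 70 dB SPL; the
    spontaneous rate comes from one continuous stretch of silence.
    """

    freq_low: float = 350.0
    freq_high: float = 7000.0
    level: float = 70.0
    duration: float = 25.0
    rise_fall: float = 3.9
    n_trials: int = 1000
    spont_duration: float = 100_000.0  # ms of continuous silence

    @classmethod
    def desk(cls, n_trials: int = 100, spont_duration: float = 20_000.0
             ) -> "SelectionProtocol":
        return cls(n_trials=n_trials, spont_duration=spont_duration)


_TAG_IDS = {"silence": 1, "low": 2, "high": 3}


class InstanceEvaluator:
    """Run the full selection battery on arbitrary parameter vectors.

    Caches binned AN input counts per (stimulus, m_e) so that repeated
    evaluations — a grid screen, or off-grid convexity children — reuse the
    same presynaptic drive.  Deterministic given (seed, stimulus, fiber,
    trial); caching cannot change any result, only its cost.
    """

    def __init__(
        self,
        an_params: Optional[ANSurrogateParameters] = None,
        protocol: Optional[SelectionProtocol] = None,
        seed: int = 0,
        dt: float = 0.01,
    ) -> None:
        self.an_params = an_params or ANSurrogateParameters()
        self.protocol = protocol or SelectionProtocol()
        self.seed = int(seed)
        self.dt = dt
        self._counts: Dict[Tuple[str, int], np.ndarray] = {}

    # -- AN input machinery -------------------------------------------------
    def _stimulus(self, tag: str) -> StimulusDescriptor:
        p = self.protocol
        if tag == "silence":
            return StimulusDescriptor.silence(p.spont_duration)
        freq = p.freq_low if tag == "low" else p.freq_high
        return StimulusDescriptor(
            kind="tone", frequency=freq, level=p.level,
            duration=p.duration, rise_fall=p.rise_fall,
        )

    def _stim_seed(self, tag: str) -> int:
        return (self.seed * 1_000_003 + _TAG_IDS[tag] * 9_176 + 17) % 2**31

    def an_counts(self, tag: str, m_e: int) -> np.ndarray:
        """Grid-binned total input counts for ``m_e`` fibers under ``tag``."""
        key = (tag, int(m_e))
        if key not in self._counts:
            stim = self._stimulus(tag)
            n_trials = 1 if tag == "silence" else self.protocol.n_trials
            trains = generate_an_trains(
                stim, self.an_params, n_fibers=int(m_e), n_trials=n_trials,
                seed=self._stim_seed(tag), dt=self.dt,
            )
            n_steps = int(np.floor(stim.duration / self.dt + 0.5))
            self._counts[key] = bin_input_counts(trains, self.dt, n_steps)
        return self._counts[key]

    def an_trains(self, tag: str, m_e: int) -> List[SpikeData]:
        """Raw surrogate fiber trains for ``tag`` (not cached)."""
        stim = self._stimulus(tag)
        n_trials = 1 if tag == "silence" else self.protocol.n_trials
        return generate_an_trains(
            stim, self.an_params, n_fibers=int(m_e), n_trials=n_trials,
            seed=self._stim_seed(tag), dt=self.dt,
        )

    # -- evaluation ---------------------------------------------------------
    def simulate(self, tag: str, params: GBCParameters) -> SpikeData:
        """Model output under one battery stimulus ('silence', 'low', 'high')."""
        stim = self._stimulus(tag)
        counts = self.an_counts(tag, params.m_e)
        cfg = SimulationConfig(dt=self.dt, duration=stim.duration)
        trains = run_coincidence(counts, params, cfg)
        return SpikeData(trials=trains, trial_duration=stim.duration)

    def evaluate(self, params: GBCParameters) -> dict:
        """Full selection battery -> metrics, shape flags and category."""
        silence = self.simulate("silence", params)
        low = self.simulate("low", params)
        high = self.simulate("high", params)

        sr, dr = spont_and_driven_rates(silence, high)
        sus_hi = sustained_window_spikes(high)
        sus_lo = sustained_window_spikes(low)
        cv = cv_prime(sus_hi)
        vs = vector_strength(sus_lo, self.protocol.freq_low)
        ei = entrainment_index(sus_lo, self.protocol.freq_low)

        psth = compute_psth(high, bin_ms=0.1, smooth=True)
        centers = psth.bin_centers
        sus_mask = (centers >= SUSTAINED_WINDOW[0]) & (centers < SUSTAINED_WINDOW[1])
        sustained_rate = float(psth.smoothed_rate[sus_mask].mean()) if sus_mask.any() else 0.0
        features = extract_psth_features(psth, sustained_rate)
        flags = check_psth_criteria(features)

        m350 = ResponseMetrics(vs=vs, ei=ei)
        m7000 = ResponseMetrics(dr=dr, cv_prime=cv)
        result = select_instance(m350, m7000, sr, flags, features)

        return {
            **params.as_dict(),
            "sr": sr, "dr": dr, "cv_prime": cv, "vs": vs, "ei": ei,
            "first_peak_rate": features.first_peak_rate,
            "first_notch_width": features.first_notch_width,
            "p1": flags.p1, "p2": flags.p2, "p3": flags.p3, "p4": flags.p4,
            "category": result.category,
        }

    def accepts_pln(self, params: GBCParameters) -> bool:
        return self.evaluate(params)["category"] == "PLN"

    def clear_cache(self) -> None:
        self._counts.clear()


def run_selection(
    grid: ParameterGrid,
    evaluator: Optional[InstanceEvaluator] = None,
    *,
    an_params: Optional[ANSurrogateParameters] = None,
    protocol: Optional[SelectionProtocol] = None,
    seed: int = 0,
    checkpoint_path=None,
    chunk_size: int = 81,
    progress: bool = False,
) -> pd.DataFrame:
    """Screen every grid instance through the selection battery.

    Returns one row per instance (parameters, metrics, shape flags,
    category).  When ``checkpoint_path`` is given, completed chunks are
    appended to that CSV and an interrupted run resumes from it.
    """
    if evaluator is None:
        evaluator = InstanceEvaluator(an_params=an_params, protocol=protocol, seed=seed)
    done: set = set()
    rows: List[dict] = []
    checkpoint = Path(checkpoint_path) if checkpoint_path else None
    if checkpoint is not None and checkpoint.exists():
        prev = pd.read_csv(checkpoint)
        rows = prev.to_dict("records")
        done = set(prev["instance_id"].astype(int))

    pending: List[dict] = []
    for instance_id, params in grid:
        if instance_id in done:
            continue
        row = {"instance_id": instance_id, **evaluator.evaluate(params)}
        pending.append(row)
        if checkpoint is not None and len(pending) >= chunk_size:
            _append_chunk(checkpoint, pending)
            rows.extend(pending)
            pending = []
            if progress:
                print(f"[gbcpop] screened {len(rows)}/{grid.size} instances")
    if pending:
        if checkpoint is not None:
            _append_chunk(checkpoint, pending)
        rows.extend(pending)
    table = pd.DataFrame(rows).sort_values("instance_id").reset_index(drop=True)
    if table["instance_id"].duplicated().any():
        raise ValueError("duplicate instance ids in population table")
    return table


def _append_chunk(path: Path, rows: List[dict]) -> None:
    pd.DataFrame(rows).to_csv(path, mode="a", header=not path.exists(), index=False)


# ---------------------------------------------------------------------------
# Dimensional stacking
# ---------------------------------------------------------------------------

def dimensional_stack(
    table: pd.DataFrame,
    layout: Sequence[Tuple[str, str]] = PAPER_STACK_LAYOUT,
    value: str = "dr",
    grid: Optional[ParameterGrid] = None,
) -> Tuple[np.ndarray, dict]:
    """Nest the 6-D grid into a single 2-D matrix (dimensional stacking).

    ``layout`` gives three (row, col) dimension pairs, outer to inner: each
    outer cell contains the full middle layer, each middle cell the full
    inner layer.  Every instance occupies exactly one matrix cell.  Returns
    (matrix, annotation) where the annotation records the dimension order
    and per-layer extents.
    """
    names = [n for pair in layout for n in pair]
    if sorted(names) != sorted(PARAM_NAMES):
        raise ValueError("layout must name all six dimensions exactly once")
    if grid is None:
        grid = build_grid(
            {n: sorted(table[n].unique()) for n in PARAM_NAMES}
        )
    shape = dict(zip(PARAM_NAMES, grid.shape))
    row_dims = [pair[0] for pair in layout]
    col_dims = [pair[1] for pair in layout]
    n_rows = int(np.prod([shape[n] for n in row_dims]))
    n_cols = int(np.prod([shape[n] for n in col_dims]))

    idx6 = np.array(np.unravel_index(table["instance_id"].to_numpy(), grid.shape)).T
    col_of = {n: i for i, n in enumerate(PARAM_NAMES)}

    def flat(dims):
        out = np.zeros(len(table), dtype=np.int64)
        for n in dims:
            out = out * shape[n] + idx6[:, col_of[n]]
        return out

    r, c = flat(row_dims), flat(col_dims)
    matrix = np.full((n_rows, n_cols), np.nan)
    if np.unique(r * n_cols + c).size != len(table):
        raise ValueError("layout maps two instances onto one cell")
    matrix[r, c] = table[value].to_numpy(dtype=float)
    annotation = {
        "row_dims": row_dims,
        "col_dims": col_dims,
        "row_extents": [shape[n] for n in row_dims],
        "col_extents": [shape[n] for n in col_dims],
        "value": value,
    }
    return matrix, annotation


# ---------------------------------------------------------------------------
# Frequency response areas
# ---------------------------------------------------------------------------

def fra_threshold_curve(
    rates: np.ndarray, levels: np.ndarray, sr: float, criterion: float = 10.0
) -> np.ndarray:
    """Rate-level threshold per frequency: level where rate crosses SR + criterion.

    ``rates`` has shape (n_freq, n_level); thresholds are linearly
    interpolated between level points and NaN where the criterion is never
    crossed (unbounded).  The crossing must be sustained: the threshold is
    the lowest level above which the rate stays at or above the criterion,
    which keeps single sampling fluctuations at low levels from producing
    spurious thresholds.
    """
    rates = np.asarray(rates, dtype=float)
    levels = np.asarray(levels, dtype=float)
    target = sr + criterion
    out = np.full(rates.shape[0], np.nan)
    for i, r in enumerate(rates):
        above = r >= target
        if not above[-1]:
            continue
        # first index from which the rate never drops below the criterion
        j = int(np.flatnonzero(~above)[-1]) + 1 if not above.all() else 0
        if j == 0:
            out[i] = levels[0]
        else:
            frac = (target - r[j - 1]) / (r[j] - r[j - 1])
            out[i] = levels[j - 1] + frac * (levels[j] - levels[j - 1])
    return out


def q10_from_curve(
    freqs: np.ndarray, thresholds: np.ndarray, cf: Optional[float] = None
) -> float:
    """Q10 = CF / bandwidth of the threshold curve 10 dB above its minimum.

    Crossing frequencies are interpolated linearly in log2-frequency.
    Returns NaN when either flank never reaches 10 dB above the minimum.
    """
    freqs = np.asarray(freqs, dtype=float)
    thr = np.asarray(thresholds, dtype=float)
    valid = np.isfinite(thr)
    if valid.sum() < 3:
        return float("nan")
    imin = int(np.nanargmin(thr))
    target = thr[imin] + 10.0
    if cf is None:
        cf = freqs[imin]
    logf = np.log2(freqs)

    def crossing(indices):
        prev = imin
        for k in indices:
            if not np.isfinite(thr[k]):
                return None
            if thr[k] >= target:
                frac = (target - thr[prev]) / (thr[k] - thr[prev])
                return logf[prev] + frac * (logf[k] - logf[prev])
            prev = k
        return None

    lo = crossing(range(imin - 1, -1, -1))
    hi = crossing(range(imin + 1, len(thr)))
    if lo is None or hi is None:
        return float("nan")
    bw = 2.0**hi - 2.0**lo
    return float(cf / bw)


def compute_fra(
    params: GBCParameters,
    an_params: Optional[ANSurrogateParameters] = None,
    cf: float = 3500.0,
    freqs: Optional[Sequence[float]] = None,
    levels: Optional[Sequence[float]] = None,
    n_trials: int = 50,
    seed: int = 0,
    spont_duration: float = 10_000.0,
    dt: float = 0.01,
) -> dict:
    """Simulated frequency response area of one model instance.

    Drives the instance with tone bursts over a frequency x level grid (all
    input fibers tuned to ``cf``) and derives the threshold curve and Q10.
    """
    an_params = an_params or ANSurrogateParameters()
    if freqs is None:
        freqs = cf * 2.0 ** np.linspace(-2.0, 1.0, 13)
    if levels is None:
        levels = np.arange(0.0, 90.1, 10.0)
    freqs = np.asarray(freqs, dtype=float)
    levels = np.asarray(levels, dtype=float)

    sil = StimulusDescriptor.silence(spont_duration)
    sil_trains = generate_an_trains(sil, an_params, params.m_e, 1,
                                    seed=seed % 2**31, dt=dt)
    cfg = SimulationConfig(dt=dt, duration=spont_duration)
    counts = bin_input_counts(sil_trains, dt, cfg.n_steps)
    sil_out = SpikeData(run_coincidence(counts, params, cfg), spont_duration)
    sr = sil_out.n_spikes / (spont_duration * 1e-3)

    rates = np.zeros((freqs.size, levels.size))
    for i, f in enumerate(freqs):
        for j, lv in enumerate(levels):
            stim = StimulusDescriptor(kind="tone", frequency=float(f),
                                      level=float(lv), cf=cf)
            child = (seed * 92_821 + i * 101 + j + 1) % 2**31
            trains = generate_an_trains(stim, an_params, params.m_e, n_trials,
                                        seed=child, dt=dt)
            cfg = SimulationConfig(dt=dt, duration=stim.duration)
            counts = bin_input_counts(trains, dt, cfg.n_steps)
            out = SpikeData(run_coincidence(counts, params, cfg), stim.duration)
            _, rates[i, j] = spont_and_driven_rates(sil_out, out)

    thresholds = fra_threshold_curve(rates, levels, sr)
    return {
        "freqs": freqs, "levels": levels, "rates": rates, "sr": float(sr),
        "thresholds": thresholds, "q10": q10_from_curve(freqs, thresholds, cf),
    }


# ---------------------------------------------------------------------------
# Validation protocols over an accepted population
# ---------------------------------------------------------------------------

def _simulate_stim(
    stim: StimulusDescriptor,
    params_list: Sequence[GBCParameters],
    an_params: ANSurrogateParameters,
    n_trials: int,
    seed: int,
    dt: float = 0.01,
) -> List[SpikeData]:
    """Drive several instances with one stimulus, sharing AN inputs per m_e."""
    cache: Dict[int, np.ndarray] = {}
    cfg = SimulationConfig(dt=dt, duration=stim.duration)
    outs = []
    for params in params_list:
        if params.m_e not in cache:
            trains = generate_an_trains(stim, an_params, params.m_e, n_trials,
                                        seed=seed, dt=dt)
            cache[params.m_e] = bin_input_counts(trains, dt, cfg.n_steps)
        outs.append(SpikeData(run_coincidence(cache[params.m_e], params, cfg),
                              stim.duration))
    return outs


def frequency_sweep_bounds(
    params_list: Sequence[GBCParameters],
    freqs: Sequence[float],
    an_params: Optional[ANSurrogateParameters] = None,
    seed: int = 0,
    n_trials: int = 100,
    level: float = 70.0,
) -> pd.DataFrame:
    """Population min-max envelopes of VS and EI across tone frequencies."""
    an_params = an_params or ANSurrogateParameters()
    rows = []
    for k, f in enumerate(freqs):
        stim = StimulusDescriptor(kind="tone", frequency=float(f), level=level)
        outs = _simulate_stim(stim, params_list, an_params, n_trials,
                              seed=(seed * 7919 + k) % 2**31)
        vs = [vector_strength(sustained_window_spikes(o), f) for o in outs]
        ei = [entrainment_index(sustained_window_spikes(o), f) for o in outs]
        vs = [v for v in vs if v is not None]
        ei = [e for e in ei if e is not None]
        rows.append({
            "frequency": f,
            "vs_lower": min(vs) if vs else np.nan,
            "vs_upper": max(vs) if vs else np.nan,
            "ei_lower": min(ei) if ei else np.nan,
            "ei_upper": max(ei) if ei else np.nan,
        })
    return pd.DataFrame(rows)


def tail_sync_bounds(
    params_list: Sequence[GBCParameters],
    cfs: Sequence[float],
    an_params: Optional[ANSurrogateParameters] = None,
    seed: int = 0,
    n_trials: int = 100,
    freq: float = 500.0,
    level: float = 95.0,
) -> pd.DataFrame:
    """Tail-sync VS envelopes: intense low-frequency tone across fiber CFs."""
    an_params = an_params or ANSurrogateParameters()
    rows = []
    for k, cf in enumerate(cfs):
        stim = StimulusDescriptor(kind="tone", frequency=freq, level=level,
                                  cf=float(cf))
        outs = _simulate_stim(stim, params_list, an_params, n_trials,
                              seed=(seed * 6977 + k) % 2**31)
        vs = [vector_strength(sustained_window_spikes(o), freq) for o in outs]
        vs = [v for v in vs if v is not None]
        rows.append({
            "cf": cf,
            "vs_lower": min(vs) if vs else np.nan,
            "vs_upper": max(vs) if vs else np.nan,
        })
    return pd.DataFrame(rows)


def sam_max_vs(
    params_list: Sequence[GBCParameters],
    cf: float = 7000.0,
    an_params: Optional[ANSurrogateParameters] = None,
    seed: int = 0,
    levels: Sequence[float] = tuple(np.arange(10.0, 45.1, 5.0)),
    n_trials: int = 80,
    mod_frequency: float = 100.0,
    duration: float = 600.0,
) -> pd.DataFrame:
    """Maximum envelope phase-locking over a SAM level sweep, per instance.

    The carrier matches the fiber CF; VS is measured at the modulation
    frequency on the response after the first 10 ms are discarded.
    """
    an_params = an_params or ANSurrogateParameters()
    best_vs = np.full(len(params_list), np.nan)
    best_level = np.full(len(params_list), np.nan)
    for k, lv in enumerate(levels):
        stim = StimulusDescriptor(kind="sam", frequency=cf, level=float(lv),
                                  duration=duration, mod_frequency=mod_frequency,
                                  mod_depth=1.0)
        outs = _simulate_stim(stim, params_list, an_params, n_trials,
                              seed=(seed * 4139 + k) % 2**31)
        for i, o in enumerate(outs):
            sus = sustained_window_spikes(o, 10.0, duration)
            v = vector_strength(sus, mod_frequency)
            if v is not None and (np.isnan(best_vs[i]) or v > best_vs[i]):
                best_vs[i] = v
                best_level[i] = lv
    return pd.DataFrame({
        "instance": np.arange(len(params_list)),
        "max_vs": best_vs,
        "best_level": best_level,
    })
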