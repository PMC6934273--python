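"""PSTH shape features and the acceptance rules for model GBC instances.

A primary-like-with-notch (PL_N) PSTH has a dominant onset peak, a short
(~1 ms) notch, an optional modest second peak, and sustained firing.  The
shape criteria are applied to the five-point-smoothed PSTH at 0.1-ms bins:

P1  the first notch falls below 90% of the sustained rate;
P2  the first notch width (measured at 90% of the sustained rate) is
    between 0.15 and 1.5 ms;
P3  the second peak rate is below half of the first peak rate;
P4  the second notch is absent or shorter than 0.85 ms.

P1/P2 require a clear notch; P3 rejects chopper-like multiple onset peaks;
P2/P4 reject dip-type responses with a long (> 2 ms) post-onset pause.

A full instance is accepted as PL_N when, in addition, the spontaneous
rate is below 30 spikes/s, the high-frequency (7 kHz, 70 dB SPL) sustained
rate is at least 150 spikes/s, CV' lies in [0.65, 0.95], and low-frequency
(350 Hz, 70 dB SPL) VS and EI both exceed 0.9.  Instances meeting every
criterion except with a sustained rate in [50, 150) are onset-L (On_L).
The boundary conventions (DR >= 150 -> PL_N, [50, 150) -> On_L; CV' range
closed) make the categories disjoint and exhaustive.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Optional

import numpy as np

from .metrics import Histogram, ResponseMetrics

__all__ = [
    "PSTHFeatures",
    "PSTHFlags",
    "ClassificationResult",
    "extract_psth_features",
    "check_psth_criteria",
    "select_instance",
    "CATEGORIES",
]

CATEGORIES = ("PLN", "ONL", "CHOPPER", "DIPPER", "OTHER", "REJECTED_RATES")

#: Selection thresholds (rates in spikes/s).
SR_MAX = 30.0
DR_PLN_MIN = 150.0
DR_ONL_MIN = 50.0
CV_RANGE = (0.65, 0.95)
VS_MIN = 0.9
EI_MIN = 0.9

#: PSTH-shape thresholds.
NOTCH_LEVEL = 0.9          # notch defined below this fraction of the sustained rate
NOTCH1_WIDTH = (0.15, 1.5)  # ms
PEAK2_RATIO = 0.5
NOTCH2_WIDTH_MAX = 0.85    # ms
ONSET_REGION_MS = 5.0      # first-peak search region after stimulus onset
FEATURE_REGION_MS = 15.0   # notch/second-peak search region


@dataclass
class PSTHFeatures:
    """Onset-region features of a smoothed PSTH (rates in spikes/s, ms)."""

    first_peak_rate: float
    first_peak_time: float
    first_notch_min_rate: float
    first_notch_width: float
    second_peak_rate: Optional[float]
    second_notch_width: Optional[float]
    sustained_rate: float


@dataclass(frozen=True)
class PSTHFlags:
    p1: bool
    p2: bool
    p3: bool
    p4: bool

    def all_pass(self) -> bool:
        return self.p1 and self.p2 and self.p3 and self.p4


@dataclass
class ClassificationResult:
    """Category plus the per-criterion booleans that produced it."""

    category: str
    flags: dict


def _runs_below(x: np.ndarray, thr: float):
    """Contiguous index runs where ``x < thr`` as (start, stop) pairs."""
    below = x < thr
    if not below.any():
        return []
    edges = np.flatnonzero(np.diff(below.astype(np.int8)))
    starts = list(edges[~below[edges]] + 1)
    stops = list(edges[below[edges]] + 1)
    if below[0]:
        starts.insert(0, 0)
    if below[-1]:
        stops.append(below.size)
    return list(zip(starts, stops))


def extract_psth_features(
    psth: Histogram,
    sustained_rate: float,
    onset_region: float = ONSET_REGION_MS,
    search_end: float = FEATURE_REGION_MS,
) -> PSTHFeatures:
    """Measure onset peak, notches and second peak from a smoothed PSTH.

    The first peak is the global maximum of the smoothed rate within the
    onset region (0 to ``onset_region`` ms).  Notches are contiguous spans
    where the smoothed rate drops below ``NOTCH_LEVEL`` times the sustained
    rate, searched between the first peak and ``search_end``; the first
    span is the first notch, a later span the second notch.  The second
    peak is the maximum of the rate between the two spans (or up to
    ``search_end`` when no second span exists).  Absent features are
    reported as ``None`` (second peak/notch) or zero width (first notch).
    """
    if psth.smoothed_rate is None:
        raise ValueError("extract_psth_features requires a smoothed PSTH")
    rate = psth.smoothed_rate
    centers = psth.bin_centers
    bw = psth.bin_width

    n_onset = max(1, int(np.searchsorted(centers, onset_region)))
    i1 = int(np.argmax(rate[:n_onset]))
    i_end = int(np.searchsorted(centers, search_end))
    thr = NOTCH_LEVEL * sustained_rate

    seg = rate[i1 + 1 : i_end]
    runs = [(s + i1 + 1, e + i1 + 1) for s, e in _runs_below(seg, thr)]

    if not runs:
        tail = rate[i1:i_end]
        return PSTHFeatures(
            first_peak_rate=float(rate[i1]),
            first_peak_time=float(centers[i1]),
            first_notch_min_rate=float(tail.min()) if tail.size else float(rate[i1]),
            first_notch_width=0.0,
            second_peak_rate=None,
            second_notch_width=None,
            sustained_rate=float(sustained_rate),
        )

    s1, e1 = runs[0]
    notch1_width = (e1 - s1) * bw
    notch1_min = float(rate[s1:e1].min())
    if len(runs) > 1:
        s2, e2 = runs[1]
        notch2_width = (e2 - s2) * bw
        peak_seg = rate[e1:s2]
    else:
        notch2_width = None
        peak_seg = rate[e1:i_end]
    second_peak = float(peak_seg.max()) if peak_seg.size else None

    return PSTHFeatures(
        first_peak_rate=float(rate[i1]),
        first_peak_time=float(centers[i1]),
        first_notch_min_rate=notch1_min,
        first_notch_width=float(notch1_width),
        second_peak_rate=second_peak,
        second_notch_width=notch2_width,
        sustained_rate=float(sustained_rate),
    )


def check_psth_criteria(f: PSTHFeatures) -> PSTHFlags:
    """Apply the four PL_N shape criteria to extracted features."""
    p1 = f.first_notch_min_rate < NOTCH_LEVEL * f.sustained_rate and f.first_notch_width > 0
    p2 = NOTCH1_WIDTH[0] <= f.first_notch_width <= NOTCH1_WIDTH[1]
    p3 = f.second_peak_rate is None or f.second_peak_rate < PEAK2_RATIO * f.first_peak_rate
    p4 = f.second_notch_width is None or f.second_notch_width < NOTCH2_WIDTH_MAX
    return PSTHFlags(p1=bool(p1), p2=bool(p2), p3=bool(p3), p4=bool(p4))


def select_instance(
    m350: ResponseMetrics,
    m7000: ResponseMetrics,
    sr: float,
    psth_flags: PSTHFlags,
    features: Optional[PSTHFeatures] = None,
) -> ClassificationResult:
    """Classify one model instance from its selection-battery measures.

    ``m350`` supplies VS and EI (350 Hz, 70 dB SPL), ``m7000`` the driven
    rate and CV' (7000 Hz, 70 dB SPL), ``sr`` the spontaneous rate.  The
    classifier is a pure function of its arguments; every instance maps to
    exactly one category.
    """
    dr, cv = m7000.dr, m7000.cv_prime
    vs, ei = m350.vs, m350.ei

    undefined = [name for name, val in
                 (("dr", dr), ("cv_prime", cv), ("vs", vs), ("ei", ei))
                 if val is None]
    flags = {
        "sr_ok": sr < SR_MAX,
        "dr_pln": dr is not None and dr >= DR_PLN_MIN,
        "dr_onl": dr is not None and DR_ONL_MIN <= dr < DR_PLN_MIN,
        "cv_ok": cv is not None and CV_RANGE[0] <= cv <= CV_RANGE[1],
        "vs_ok": vs is not None and vs > VS_MIN,
        "ei_ok": ei is not None and ei > EI_MIN,
        **asdict(psth_flags),
    }
    if undefined:
        flags["undefined"] = undefined
        return ClassificationResult(category="REJECTED_RATES", flags=flags)

    rates_ok = (flags["sr_ok"] and flags["cv_ok"] and flags["vs_ok"]
                and flags["ei_ok"] and (flags["dr_pln"] or flags["dr_onl"]))
    if not rates_ok:
        return ClassificationResult(category="REJECTED_RATES", flags=flags)

    if psth_flags.all_pass():
        category = "PLN" if flags["dr_pln"] else "ONL"
    elif not psth_flags.p3:
        category = "CHOPPER"
    elif (not psth_flags.p4) or (
        not psth_flags.p2
        and features is not None
        and features.first_notch_width > NOTCH1_WIDTH[1]
    ):
        category = "DIPPER"
    else:
        category = "OTHER"
    return ClassificationResult(category=category, flags=flags)
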