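"""Fatigue-index and functional-hyperaemia metrics from physiological traces.

The fatigue index (FI) of a sustained twitch-train protocol is
final tension / peak tension, each taken as the mean of five
consecutive twitch peaks: "peak" is the best five-consecutive-twitch
mean anywhere in the protocol (robust to delayed potentiation),
"final" is the last five twitches. FI is reported both as a ratio and
as a percentage.

Functional hyperaemia is the peak/resting blood-flow ratio during
stimulation; vascular conductance (flow/pressure) relative to its
pre-stimulation baseline gives the time course.
"""

from __future__ import annotations

import logging
from typing import Optional

import numpy as np
from scipy.signal import find_peaks

from .datatypes import (
    FatigueResult,
    FlowTrace,
    HyperaemiaResult,
    TensionTrace,
    ValidationError,
)

logger = logging.getLogger(__name__)

MIN_PEAKS_FOR_FI = 10  # five for "peak" plus five for "final"
PEAK_HEIGHT_FRACTION = 0.10  # twitch peaks must exceed 10% of the global max


def detect_twitch_peaks(
    trace: TensionTrace, min_separation: Optional[float] = None
) -> np.ndarray:
    """Indices of twitch peaks within the stimulation window.

    Local maxima above 10% of the global maximum, separated by at
    least ``min_separation`` seconds (default: half the inter-twitch
    interval implied by the dominant twitch spacing is unknown here,
    so callers stimulating at f Hz should pass ``0.5 / f``; without it
    a conservative default of half the median peak spacing is used).
    """
    y = trace.tension
    ymax = float(np.max(y))
    if ymax <= 0:
        raise ValidationError("tension trace is flat at zero; no twitches")
    if min_separation is None:
        # first pass without a distance constraint, then use the median
        # spacing to enforce one detection per twitch
        rough, _ = find_peaks(y, height=PEAK_HEIGHT_FRACTION * ymax)
        if rough.size >= 2:
            min_separation = 0.5 * float(np.median(np.diff(rough))) * trace.dt
        else:
            min_separation = 0.0
    distance = max(1, int(round(min_separation / trace.dt))) if trace.dt > 0 else 1
    peaks, _ = find_peaks(y, height=PEAK_HEIGHT_FRACTION * ymax, distance=distance)
    a, b = trace.stimulation_window
    peaks = peaks[(trace.time[peaks] >= a) & (trace.time[peaks] <= b)]
    if peaks.size < MIN_PEAKS_FOR_FI:
        raise ValidationError(
            f"only {peaks.size} twitch peaks detected; the fatigue index "
            f"needs at least {MIN_PEAKS_FOR_FI} (5 peak + 5 final)"
        )
    return peaks


def fatigue_index(
    trace: TensionTrace, min_separation: Optional[float] = None
) -> FatigueResult:
    """Fatigue index from a twitch-train tension trace.

    peak tension = maximal mean of five consecutive twitch peaks;
    final tension = mean of the last five twitch peaks;
    FI = final / peak (and x100 as a percentage).
    """
    peaks = detect_twitch_peaks(trace, min_separation)
    amps = trace.tension[peaks]
    window_means = np.convolve(amps, np.ones(5) / 5.0, mode="valid")
    k = int(np.argmax(window_means))
    peak_tension = float(window_means[k])
    final_tension = float(np.mean(amps[-5:]))
    fi = final_tension / peak_tension
    return FatigueResult(
        FI=fi,
        FI_percent=100.0 * fi,
        peak_tension=peak_tension,
        final_tension=final_tension,
        peak_window_indices=peaks[k : k + 5],
        final_window_indices=peaks[-5:],
    )


def relative_conductance(
    flow: FlowTrace, smoothing_window_s: float = 1.0
) -> HyperaemiaResult:
    """Relative vascular conductance and the peak/resting flow ratio.

    Conductance is flow/pressure when pressure is recorded, otherwise
    flow alone (logged). Baseline is the pre-stimulation mean; the
    hyperaemia ratio divides the peak of the smoothed flow during or
    after stimulation by the baseline mean flow. Smoothing is a
    centred moving average (default 1 s).
    """
    a, _ = flow.stimulation_window
    pre = flow.time < a
    if not pre.any():
        raise ValidationError("no pre-stimulation baseline samples")
    if flow.pressure is not None:
        cond = flow.flow / flow.pressure
        used_pressure = True
    else:
        logger.info("no pressure trace; using flow as a conductance surrogate")
        cond = flow.flow.copy()
        used_pressure = False
    base_cond = float(np.mean(cond[pre]))
    base_flow = float(np.mean(flow.flow[pre]))
    if base_cond == 0 or base_flow == 0:
        raise ValidationError("zero baseline; relative measures undefined")
    rel = cond / base_cond

    win = max(1, int(round(smoothing_window_s / flow.dt))) if flow.dt > 0 else 1
    kernel = np.ones(win) / win
    smoothed = np.convolve(flow.flow, kernel, mode="same")
    during_or_after = flow.time >= a
    peak_flow = float(np.max(smoothed[during_or_after]))
    return HyperaemiaResult(
        relative_conductance=rel,
        hyperaemia_ratio=peak_flow / base_flow,
        baseline_flow=base_flow,
        peak_flow=peak_flow,
        used_pressure=used_pressure,
    )
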