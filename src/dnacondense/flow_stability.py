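"""Condensate stability under flow: traces, decay fits, molecule counts.

Surface-anchored condensates imaged in two color channels are followed
over time while buffer flows through the chamber.  Per condensate and
frame the statistic is the maximum pixel intensity inside the condensate
mask minus the mean background in a surrounding ring; only condensates
detected in both channels are kept.  Frames are registered to the first
frame by integer-pixel cross-correlation before extraction (the max-pixel
statistic is insensitive to sub-pixel error).

Disassembly kinetics are fitted with bounded single- or double-exponential
decays; for condensate populations anchored by different numbers of
tethers the double model captures a fast minority plus a slow majority.
A corrected-AIC helper selects between the two models.

The number of DNA molecules per condensate is estimated by dividing its
intensity by the intensity of a single dye and by the labeled fraction of
molecules in the mix.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage as ndi
from scipy.optimize import least_squares
from skimage import filters
from skimage.registration import phase_cross_correlation

__all__ = [
    "IntensityTrace",
    "DecayFit",
    "MoleculeCount",
    "extract_traces",
    "fit_decay",
    "select_decay_model",
    "count_molecules",
    "single_dye_intensity_from_calibration",
    "normalize_traces",
]


@dataclass(frozen=True)
class IntensityTrace:
    """Background-subtracted max-pixel intensity of one condensate/channel."""

    condensate_id: int
    channel: int
    times: np.ndarray
    intensity: np.ndarray
    background: np.ndarray


@dataclass(frozen=True)
class DecayFit:
    """Fitted exponential decay.

    For the double model the populations are ordered so that
    ``rates[0] > rates[1]`` (fast first); amplitudes are non-negative.
    """

    model: str  # "single" | "double"
    amplitudes: tuple[float, ...]
    rates: tuple[float, ...]
    offset: float
    residual_sd: float
    aicc: float
    converged: bool = True

    def predict(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        out = np.full_like(t, self.offset)
        for a, k in zip(self.amplitudes, self.rates):
            out = out + a * np.exp(-k * t)
        return out


@dataclass(frozen=True)
class MoleculeCount:
    """Intensity-based estimate of the number of DNA molecules."""

    condensate_id: int
    n_molecules: float
    single_dye_intensity: float
    labeled_fraction: float

    @property
    def n_rounded(self) -> int:
        return int(round(self.n_molecules))


def _register_stack(stack: np.ndarray) -> np.ndarray:
    """Integer-pixel registration of all frames/channels to frame 0.

    The shift is estimated on channel 0 by cross-correlation and applied
    to both channels of each frame.
    """
    out = stack.copy()
    ref = stack[0, 0]
    for f in range(1, stack.shape[0]):
        shift, _, _ = phase_cross_correlation(ref, stack[f, 0], upsample_factor=1)
        dy, dx = int(round(shift[0])), int(round(shift[1]))
        if dy or dx:
            for c in range(stack.shape[1]):
                out[f, c] = np.roll(np.roll(stack[f, c], dy, axis=0), dx, axis=1)
    return out


def _detect_spots(frame: np.ndarray, min_area: int) -> list[np.ndarray]:
    # Spots are sparse and can span a wide brightness range, so a robust
    # background estimate (median + MAD) beats Otsu here: the dimmest spot
    # must not be swallowed by the gap between bright spots and background.
    if frame.max() == frame.min():
        return []
    med = float(np.median(frame))
    mad = float(np.median(np.abs(frame - med))) * 1.4826
    thr = med + max(6.0 * mad, 0.05 * (frame.max() - med))
    labels, nlab = ndi.label(frame > thr)
    return [
        labels == lab
        for lab in range(1, nlab + 1)
        if (labels == lab).sum() >= min_area
    ]


def extract_traces(
    stack: np.ndarray,
    frame_interval: float = 1.0,
    ring_inner: int = 2,
    ring_outer: int = 5,
    min_area: int = 4,
    match_radius: float = 3.0,
    register: bool = True,
) -> list[IntensityTrace]:
    """Per-condensate intensity traces from a two-channel time series.

    Parameters
    ----------
    stack : ndarray, shape (T, 2, H, W)
        Time series with two color channels.
    ring_inner, ring_outer : int
        The background ring is the mask dilated by ``ring_outer`` minus
        the mask dilated by ``ring_inner`` pixels.
    match_radius : float
        Maximum centroid distance (px) for a condensate to count as
        present in both channels; unmatched condensates are dropped.

    Returns
    -------
    list of IntensityTrace
        Two traces (one per channel) per retained condensate, intensity =
        max pixel in mask minus ring-mean background, per frame.  Empty
        if the first frame contains no condensates in both channels.
    """
    stack = np.asarray(stack, dtype=float)
    if stack.ndim != 4 or stack.shape[1] != 2:
        raise ValueError("expected stack of shape (T, 2, H, W)")
    if stack.shape[0] < 2:
        raise ValueError("need at least 2 frames")
    if register:
        stack = _register_stack(stack)

    masks = [_detect_spots(stack[0, c], min_area) for c in (0, 1)]
    cents = [
        [np.argwhere(m).mean(axis=0) for m in masks[c]] for c in (0, 1)
    ]
    pairs = []  # (mask0, mask1) per dual-channel condensate
    used1: set[int] = set()
    for i, c0 in enumerate(cents[0]):
        best, best_d = None, match_radius
        for j, c1 in enumerate(cents[1]):
            if j in used1:
                continue
            d = float(np.hypot(*(c0 - c1)))
            if d <= best_d:
                best, best_d = j, d
        if best is not None:
            used1.add(best)
            pairs.append((masks[0][i], masks[1][best]))

    times = np.arange(stack.shape[0]) * frame_interval
    traces = []
    for cid, pair in enumerate(pairs):
        for channel, mask in enumerate(pair):
            inner = ndi.binary_dilation(mask, iterations=ring_inner)
            outer = ndi.binary_dilation(mask, iterations=ring_outer)
            ring = outer & ~inner
            bg = np.array(
                [stack[f, channel][ring].mean() for f in range(stack.shape[0])]
            )
            peak = np.array(
                [stack[f, channel][mask].max() for f in range(stack.shape[0])]
            )
            traces.append(
                IntensityTrace(
                    condensate_id=cid,
                    channel=channel,
                    times=times,
                    intensity=peak - bg,
                    background=bg,
                )
            )
    return traces


def _decay_residuals(params, t, y, model, with_offset):
    if model == "single":
        a, k = params[0], params[1]
        pred = a * np.exp(-k * t)
        rest = params[2:]
    else:
        a1, k1, a2, k2 = params[0], params[1], params[2], params[3]
        pred = a1 * np.exp(-k1 * t) + a2 * np.exp(-k2 * t)
        rest = params[4:]
    if with_offset:
        pred = pred + rest[0]
    return pred - y


def fit_decay(
    trace,
    model: str = "single",
    with_offset: bool = False,
    times: Optional[np.ndarray] = None,
) -> DecayFit:
    """Bounded least-squares fit of an exponential decay to a trace.

    ``trace`` may be an :class:`IntensityTrace` or a plain intensity
    array (then pass ``times``).  Amplitudes are bounded below by 0 and
    rates kept non-negative; for the double model the returned
    populations are sorted fast-to-slow.  The offset term is off by
    default (full decay to zero).

    Raises
    ------
    ValueError
        For fewer than 10 points or an unknown model.
    """
    if isinstance(trace, IntensityTrace):
        t, y = trace.times, trace.intensity
    else:
        y = np.asarray(trace, dtype=float)
        t = np.asarray(times, dtype=float) if times is not None else np.arange(y.size, dtype=float)
    if y.size < 10:
        raise ValueError("need >= 10 points to fit a decay")
    if model not in ("single", "double"):
        raise ValueError(f"unknown model {model!r}")

    span = max(float(y.max() - min(0.0, float(y.min()))), 1e-12)
    t_span = float(t[-1] - t[0]) or 1.0
    k0 = 2.0 / t_span
    if model == "single":
        p0 = [span, k0]
        lo, hi = [0.0, 0.0], [np.inf, np.inf]
    else:
        p0 = [0.3 * span, 10.0 * k0, 0.7 * span, 0.3 * k0]
        lo, hi = [0.0, 0.0, 0.0, 0.0], [np.inf, np.inf, np.inf, np.inf]
    if with_offset:
        p0 = p0 + [float(y[-3:].mean())]
        lo, hi = lo + [-np.inf], hi + [np.inf]

    res = least_squares(
        _decay_residuals, p0, bounds=(lo, hi), args=(t, y, model, with_offset),
        max_nfev=20000,
    )
    p = res.x
    if model == "single":
        amplitudes, rates = (float(p[0]),), (float(p[1]),)
        n_par = 2
    else:
        pops = sorted(
            [(float(p[1]), float(p[0])), (float(p[3]), float(p[2]))], reverse=True
        )
        rates = (pops[0][0], pops[1][0])
        amplitudes = (pops[0][1], pops[1][1])
        n_par = 4
    offset = float(p[n_par]) if with_offset else 0.0
    n_par += int(with_offset)
    rss = float(np.sum(res.fun**2))
    n = y.size
    # corrected Akaike information criterion (Gaussian errors, +1 for sigma)
    kk = n_par + 1
    aicc = n * math.log(max(rss / n, 1e-300)) + 2 * kk
    if n - kk - 1 > 0:
        aicc += 2 * kk * (kk + 1) / (n - kk - 1)
    dof = max(1, n - n_par)
    return DecayFit(
        model=model,
        amplitudes=amplitudes,
        rates=rates,
        offset=offset,
        residual_sd=math.sqrt(rss / dof),
        aicc=aicc,
        converged=bool(res.success),
    )


def select_decay_model(trace, with_offset: bool = False, times=None) -> DecayFit:
    """Fit single and double decays and return the lower-AICc model."""
    single = fit_decay(trace, "single", with_offset=with_offset, times=times)
    double = fit_decay(trace, "double", with_offset=with_offset, times=times)
    return double if double.aicc < single.aicc else single


def count_molecules(
    condensate_intensity: float,
    single_dye_intensity: float,
    labeled_fraction: float,
    condensate_id: int = 0,
) -> MoleculeCount:
    """Estimate molecules per condensate from its fluorescence intensity.

    ``n = I_condensate / I_single_dye / labeled_fraction``; reported as a
    continuous estimate (``n_rounded`` gives the nearest integer).

    Raises
    ------
    ValueError
        For non-positive dye intensity or a labeled fraction outside
        ``(0, 1]``.
    """
    if single_dye_intensity <= 0:
        raise ValueError("single_dye_intensity must be positive")
    if not 0.0 < labeled_fraction <= 1.0:
        raise ValueError("labeled_fraction must lie in (0, 1]")
    n = condensate_intensity / single_dye_intensity / labeled_fraction
    return MoleculeCount(
        condensate_id=condensate_id,
        n_molecules=float(n),
        single_dye_intensity=float(single_dye_intensity),
        labeled_fraction=float(labeled_fraction),
    )


def single_dye_intensity_from_calibration(spot_intensities: Sequence[float]) -> float:
    """Single-dye unit intensity: median over calibration single spots."""
    arr = np.asarray(spot_intensities, dtype=float)
    if arr.size == 0:
        raise ValueError("no calibration spots given")
    return float(np.median(arr))


def normalize_traces(traces: Sequence[IntensityTrace], n_first: int = 3):
    """Aggregate decay curves across condensates.

    Each trace is divided by the mean of its first ``n_first`` frames;
    returns ``(times, mean, sem)`` across traces, the form in which decay
    curves are reported for condensate ensembles.
    """
    if len(traces) == 0:
        raise ValueError("no traces to aggregate")
    t = traces[0].times
    curves = np.vstack(
        [tr.intensity / tr.intensity[:n_first].mean() for tr in traces]
    )
    mean = curves.mean(axis=0)
    sem = curves.std(axis=0, ddof=1) / math.sqrt(curves.shape[0]) if len(traces) > 1 else np.zeros_like(mean)
    return t, mean, sem
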