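"""FRAP recovery-curve normalization and single-exponential fitting.

A fluorescence-recovery-after-photobleaching trace is normalized so that
the pre-bleach mean maps to 1 and the first post-bleach frame to 0, and is
then fitted with the single-exponential recovery model::

    FRAP(t) = a * (1 - exp(-k t))

where ``a`` is the apparent mobile fraction (the recovery plateau) and
``k`` the apparent exchange rate; the half-time of recovery is
``t_1/2 = -ln(1/2) / k``.  The model assumes exchange-limited recovery of
a single component; the immobile fraction ``1 - a`` absorbs any
contribution from molecules that never exchange (including surface-stuck
ones).  No correction for bleaching during acquisition is applied by
default; an optional mono-exponential acquisition-bleach correction is
available behind a flag.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "DegenerateTraceError",
    "FRAPCurve",
    "FRAPFit",
    "normalize_frap",
    "fit_frap",
    "frap_model",
]

#: acquisition cadence used throughout: 300 frames at 0.8 s intervals
DEFAULT_FRAME_INTERVAL = 0.8
DEFAULT_N_FRAMES = 300

A_BOUNDS = (0.0, 1.2)
K_BOUNDS = (1e-5, 10.0)


class DegenerateTraceError(ValueError):
    """Raised when a trace has no bleach contrast to normalize against."""


@dataclass(frozen=True)
class FRAPCurve:
    """A normalized recovery trace.

    ``times`` start at 0 at the first post-bleach frame; ``intensities``
    are normalized so the pre-bleach mean is 1 and the first post-bleach
    value 0.
    """

    times: np.ndarray
    intensities: np.ndarray
    frame_interval: float = DEFAULT_FRAME_INTERVAL
    n_prebleach: int = 0

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        y = np.asarray(self.intensities, dtype=float)
        if t.shape != y.shape or t.ndim != 1:
            raise ValueError("times and intensities must be matching 1-D arrays")
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        if not np.all(np.isfinite(y)):
            raise ValueError("intensities must be finite")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "intensities", y)


@dataclass(frozen=True)
class FRAPFit:
    """Fitted recovery parameters.

    ``t_half = ln(2) / rate_k`` holds exactly by construction.
    """

    mobile_fraction_a: float
    rate_k: float
    t_half: float
    covariance: np.ndarray
    residual_sd: float
    stderr_a: float
    stderr_k: float
    at_bounds: bool = False

    def confidence_interval(self, z: float = 1.96) -> dict:
        """Normal-approximation confidence intervals for ``a`` and ``k``."""
        return {
            "a": (self.mobile_fraction_a - z * self.stderr_a,
                  self.mobile_fraction_a + z * self.stderr_a),
            "k": (self.rate_k - z * self.stderr_k,
                  self.rate_k + z * self.stderr_k),
        }


def frap_model(t: np.ndarray, a: float, k: float) -> np.ndarray:
    """The recovery model ``a * (1 - exp(-k t))``."""
    return a * (1.0 - np.exp(-k * np.asarray(t, dtype=float)))


def normalize_frap(
    raw_trace: np.ndarray,
    n_prebleach: int,
    frame_interval: float = DEFAULT_FRAME_INTERVAL,
    bleach_correction_rate: Optional[float] = None,
) -> FRAPCurve:
    """Affinely rescale a raw trace onto the normalized FRAP convention.

    The mean of the ``n_prebleach`` frames before the bleach maps to 1 and
    the first post-bleach frame to 0, matching the model's ``FRAP(0) = 0``.
    If ``bleach_correction_rate`` (1/s) is given, the post-bleach trace is
    first divided by ``exp(-rate * t)`` to undo mono-exponential
    acquisition bleaching.

    Raises
    ------
    DegenerateTraceError
        If the pre-bleach mean equals the first post-bleach value.
    ValueError
        If fewer than 10 post-bleach frames are present or
        ``n_prebleach < 1``.
    """
    raw = np.asarray(raw_trace, dtype=float)
    if n_prebleach < 1:
        raise ValueError("n_prebleach must be >= 1")
    post = raw[n_prebleach:]
    if post.size < 10:
        raise ValueError(f"need >= 10 post-bleach points, got {post.size}")
    pre_mean = float(np.mean(raw[:n_prebleach]))
    t = np.arange(post.size) * frame_interval
    if bleach_correction_rate is not None:
        post = post / np.exp(-bleach_correction_rate * t)
    first = float(post[0])
    if pre_mean == first:
        raise DegenerateTraceError(
            "zero dynamic range: pre-bleach mean equals first post-bleach value"
        )
    norm = (post - first) / (pre_mean - first)
    return FRAPCurve(
        times=t,
        intensities=norm,
        frame_interval=frame_interval,
        n_prebleach=int(n_prebleach),
    )


def _initial_guess(t: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    tail = max(1, y.size // 10)
    a0 = float(np.clip(np.mean(y[-tail:]), 1e-3, A_BOUNDS[1]))
    half = a0 / 2.0
    above = np.nonzero(y >= half)[0]
    t_half0 = t[above[0]] if above.size and above[0] > 0 else t[-1] / 4.0
    k0 = float(np.clip(math.log(2.0) / max(t_half0, t[1] - t[0]), *K_BOUNDS))
    return a0, k0


def fit_frap(curve: FRAPCurve) -> FRAPFit:
    """Bounded least-squares fit of the recovery model to a curve.

    ``a`` is constrained to ``[0, 1.2]`` (values slightly above 1 tolerate
    normalization noise) and ``k`` to ``[1e-5, 10]`` 1/s.  A fit whose
    rate lands on a bound is flagged via ``at_bounds`` rather than
    rejected.

    Raises
    ------
    ValueError
        If the curve has fewer than 10 points or negative times.
    RuntimeError
        If the optimizer fails to converge.
    """
    t, y = curve.times, curve.intensities
    if t.size < 10:
        raise ValueError("need >= 10 points to fit")
    if t[0] < 0:
        raise ValueError("times must be >= 0")
    p0 = _initial_guess(t, y)
    try:
        popt, pcov = curve_fit(
            frap_model,
            t,
            y,
            p0=p0,
            bounds=([A_BOUNDS[0], K_BOUNDS[0]], [A_BOUNDS[1], K_BOUNDS[1]]),
            maxfev=10000,
        )
    except RuntimeError as err:
        raise RuntimeError(f"FRAP fit did not converge: {err}") from err
    a, k = float(popt[0]), float(popt[1])
    resid = y - frap_model(t, a, k)
    dof = max(1, t.size - 2)
    residual_sd = float(np.sqrt(np.sum(resid**2) / dof))
    stderr = np.sqrt(np.clip(np.diag(pcov), 0.0, np.inf))
    at_bounds = bool(
        np.isclose(k, K_BOUNDS[0]) or np.isclose(k, K_BOUNDS[1])
        or np.isclose(a, A_BOUNDS[1])
    )
    if at_bounds:
        warnings.warn("FRAP fit parameter at bound; estimate unreliable", stacklevel=2)
    return FRAPFit(
        mobile_fraction_a=a,
        rate_k=k,
        t_half=math.log(2.0) / k,
        covariance=pcov,
        residual_sd=residual_sd,
        stderr_a=float(stderr[0]),
        stderr_k=float(stderr[1]),
        at_bounds=at_bounds,
    )
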