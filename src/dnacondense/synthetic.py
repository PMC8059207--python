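"""Synthetic inputs with known ground truth for every analysis stage.

Each generator is fully deterministic under a fixed seed and returns the
ground truth alongside the data, so every stage of the package has at
least one recovery test that needs no external data:

- :func:`gen_frap` -- normalized recovery curves ``a (1 - exp(-k t))``
  plus Gaussian noise at the standard acquisition cadence (300 frames,
  0.8 s interval).  Presets bundle the mobile-fraction / time-constant
  regimes observed for short-DNA condensates under the three condensation
  chemistries (see :data:`PRESETS`).
- :func:`gen_shapes` -- images of round discs, ellipses, and irregular
  blobs grown by seeded Eden aggregation, with per-object programmed
  aspect-ratio targets.
- :func:`gen_flow_stack` -- two-channel spot time series with programmed
  per-spot molecule numbers, labeled fractions, exponential intensity
  decay, optional stage drift, and shot/read noise.
- :func:`gen_condition_grid` -- a (DNA length x concentration) condition
  table emulating an experimental fluidity phase diagram, in which the
  mobile-fraction transition precedes the aspect-ratio transition with
  increasing length.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from dnacondense.frap import (
    DEFAULT_FRAME_INTERVAL,
    DEFAULT_N_FRAMES,
    FRAPCurve,
    frap_model,
)

__all__ = [
    "PRESETS",
    "GeneratorSpec",
    "gen_frap",
    "gen_frap_raw",
    "gen_shapes",
    "gen_flow_stack",
    "gen_condition_grid",
]

#: FRAP parameter regimes for short-DNA condensates: (mobile fraction a,
#: apparent time constant tau in seconds, k = 1/tau).  psi_short: PEG/Mg
#: condensation; h1_short: linker-histone condensation; chromatin_short:
#: reconstituted chromatin + H1; h1_low_conc: long DNA near the critical
#: concentration under H1 condensation.
PRESETS = {
    "psi_short": {"mobile_fraction": 0.66, "tau_s": 99.0},
    "h1_short": {"mobile_fraction": 0.58, "tau_s": 60.0},
    "chromatin_short": {"mobile_fraction": 0.40, "tau_s": 69.0},
    "h1_low_conc": {"mobile_fraction": 0.25, "tau_s": 60.0},
}


@dataclass(frozen=True)
class GeneratorSpec:
    """Named parameter bundle for the generators.

    Identical ``(seed, spec)`` pairs produce identical outputs.
    """

    seed: int
    preset: str = "psi_short"
    noise_sd: float = 0.02
    geometry: dict = field(default_factory=dict)


def _preset_params(preset: str) -> tuple[float, float]:
    if preset not in PRESETS:
        raise ValueError(f"unknown preset {preset!r}; choose from {sorted(PRESETS)}")
    p = PRESETS[preset]
    return p["mobile_fraction"], 1.0 / p["tau_s"]


def gen_frap(
    seed: int,
    preset: str = "psi_short",
    mobile_fraction: Optional[float] = None,
    rate_k: Optional[float] = None,
    noise_sd: float = 0.02,
    n_frames: int = DEFAULT_N_FRAMES,
    frame_interval: float = DEFAULT_FRAME_INTERVAL,
) -> tuple[FRAPCurve, dict]:
    """A normalized FRAP curve with Gaussian noise and its ground truth.

    Explicit ``mobile_fraction``/``rate_k`` override the preset.  With
    ``noise_sd = 0`` the curve equals the closed-form model exactly.
    """
    a, k = _preset_params(preset)
    if mobile_fraction is not None:
        a = mobile_fraction
    if rate_k is not None:
        k = rate_k
    rng = np.random.default_rng(seed)
    t = np.arange(n_frames) * frame_interval
    y = frap_model(t, a, k)
    if noise_sd > 0:
        y = y + rng.normal(0.0, noise_sd, size=t.size)
    curve = FRAPCurve(times=t, intensities=y, frame_interval=frame_interval)
    truth = {"mobile_fraction": a, "rate_k": k, "t_half": math.log(2.0) / k,
             "noise_sd": noise_sd}
    return curve, truth


def gen_frap_raw(
    seed: int,
    preset: str = "psi_short",
    noise_sd: float = 0.02,
    n_prebleach: int = 5,
    n_frames: int = DEFAULT_N_FRAMES,
    frame_interval: float = DEFAULT_FRAME_INTERVAL,
    gain: float = 1.0,
    offset: float = 0.0,
    bleach_depth: float = 1.0,
) -> tuple[np.ndarray, dict]:
    """A raw arbitrary-unit trace (pre-bleach frames included).

    The underlying normalized curve is mapped through the affine transform
    ``raw = gain * signal + offset``; ``bleach_depth`` scales how far the
    bleach drops below the pre-bleach level (1 = full bleach to 0).
    Ground truth includes the noiseless normalized curve so normalization
    can be checked to machine precision.
    """
    a, k = _preset_params(preset)
    rng = np.random.default_rng(seed)
    t_post = np.arange(n_frames) * frame_interval
    norm = frap_model(t_post, a, k)
    pre = np.ones(n_prebleach)
    signal = np.concatenate([pre, (1.0 - bleach_depth) + bleach_depth * norm])
    raw = gain * signal + offset
    if noise_sd > 0:
        raw = raw + gain * rng.normal(0.0, noise_sd, size=raw.size)
    truth = {
        "mobile_fraction": a,
        "rate_k": k,
        "normalized": norm,
        "gain": gain,
        "offset": offset,
        "n_prebleach": n_prebleach,
    }
    return raw, truth


# ---------------------------------------------------------------------------
# shape images


def _render_ellipse(shape, cy, cx, ra, rb, theta):
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    dy, dx = yy - cy, xx - cx
    u = dx * math.cos(theta) + dy * math.sin(theta)
    v = -dx * math.sin(theta) + dy * math.cos(theta)
    return (u / ra) ** 2 + (v / rb) ** 2 <= 1.0


def _eden_blob(rng, n_pixels: int, roughness: float) -> np.ndarray:
    """Grow an irregular blob by seeded Eden aggregation.

    Growth sites are empty 4-neighbours of the cluster; each is weighted
    by ``exp(roughness * cos(angle to a random elongation axis))`` so that
    ``roughness = 0`` gives a compact quasi-round cluster and larger
    values increasingly anisotropic, irregular ones.
    """
    size = int(4 * math.sqrt(n_pixels)) + 8
    grid = np.zeros((size, size), dtype=bool)
    c = size // 2
    grid[c, c] = True
    axis = rng.uniform(0, math.pi)
    ax_y, ax_x = math.sin(axis), math.cos(axis)
    frontier = {(c + 1, c), (c - 1, c), (c, c + 1), (c, c - 1)}
    for _ in range(n_pixels - 1):
        cand = list(frontier)
        w = np.empty(len(cand))
        for i, (y, x) in enumerate(cand):
            dy, dx = y - c, x - c
            r = math.hypot(dy, dx) or 1.0
            w[i] = math.exp(roughness * abs(dy * ax_y + dx * ax_x) / r)
        w /= w.sum()
        y, x = cand[rng.choice(len(cand), p=w)]
        grid[y, x] = True
        frontier.discard((y, x))
        for ny, nx in ((y + 1, x), (y - 1, x), (y, x + 1), (y, x - 1)):
            if 0 <= ny < size and 0 <= nx < size and not grid[ny, nx]:
                frontier.add((ny, nx))
    ys, xs = np.nonzero(grid)
    return grid[ys.min() : ys.max() + 1, xs.min() : xs.max() + 1]


def gen_shapes(
    seed: int,
    n_discs: int = 0,
    n_ellipses: int = 0,
    n_blobs: int = 0,
    image_shape: tuple[int, int] = (512, 512),
    radius_range: tuple[float, float] = (15.0, 30.0),
    ellipse_axis_ratio: float = 2.0,
    roughness: float = 1.0,
    foreground: float = 1.0,
    noise_sd: float = 0.0,
    max_tries: int = 2000,
) -> tuple[np.ndarray, pd.DataFrame]:
    """An image of non-touching condensate mimics plus its truth table.

    Discs mimic liquid-like (region I) condensates (target aspect ratio
    0), ellipses have the analytic target ``(ra-rb)/(ra+rb)``, and Eden
    blobs mimic solid-like irregular aggregates (target recorded as the
    aspect ratio measured on the noise-free generating mask).

    Raises
    ------
    ValueError
        If the requested objects cannot be packed without touching.
    """
    rng = np.random.default_rng(seed)
    h, w = image_shape
    img = np.zeros(image_shape, dtype=float)
    rows = []
    placed: list[tuple[float, float, float]] = []  # cy, cx, bounding radius

    def place(bound: float) -> tuple[float, float]:
        for _ in range(max_tries):
            cy = rng.uniform(bound + 2, h - bound - 2)
            cx = rng.uniform(bound + 2, w - bound - 2)
            if all(
                math.hypot(cy - py, cx - px) > bound + pb + 4
                for py, px, pb in placed
            ):
                placed.append((cy, cx, bound))
                return cy, cx
        raise ValueError(
            f"cannot pack {n_discs + n_ellipses + n_blobs} objects of radius "
            f"~{bound:.0f} px into {image_shape} without touching"
        )

    obj = 0
    for _ in range(n_discs):
        r = rng.uniform(*radius_range)
        cy, cx = place(r)
        mask = _render_ellipse(image_shape, cy, cx, r, r, 0.0)
        img[mask] = foreground
        obj += 1
        rows.append(
            {"object": obj, "kind": "disc", "target_aspect_ratio": 0.0,
             "cy": cy, "cx": cx, "area_px": int(mask.sum())}
        )
    for _ in range(n_ellipses):
        rb = rng.uniform(*radius_range)
        ra = rb * ellipse_axis_ratio
        theta = rng.uniform(0, math.pi)
        cy, cx = place(ra)
        mask = _render_ellipse(image_shape, cy, cx, ra, rb, theta)
        img[mask] = foreground
        obj += 1
        ar = (ra - rb) / (ra + rb)
        rows.append(
            {"object": obj, "kind": "ellipse", "target_aspect_ratio": ar,
             "cy": cy, "cx": cx, "area_px": int(mask.sum())}
        )
    for _ in range(n_blobs):
        r = rng.uniform(*radius_range)
        n_px = int(math.pi * r * r)
        blob = _eden_blob(rng, n_px, roughness)
        bound = math.hypot(*blob.shape) / 2.0
        cy, cx = place(bound)
        from dnacondense.morphology import aspect_ratio as _ar

        truth_ar = _ar(blob).aspect_ratio
        y0, x0 = int(cy - blob.shape[0] // 2), int(cx - blob.shape[1] // 2)
        sub = img[y0 : y0 + blob.shape[0], x0 : x0 + blob.shape[1]]
        sub[blob] = foreground
        obj += 1
        rows.append(
            {"object": obj, "kind": "blob", "target_aspect_ratio": truth_ar,
             "cy": cy, "cx": cx, "area_px": int(blob.sum())}
        )
    if noise_sd > 0:
        img = img + rng.normal(0.0, noise_sd, size=img.shape)
    truth = pd.DataFrame(
        rows,
        columns=["object", "kind", "target_aspect_ratio", "cy", "cx", "area_px"],
    )
    return img, truth


# ---------------------------------------------------------------------------
# two-channel flow stacks


def gen_flow_stack(
    seed: int,
    n_spots: int = 6,
    n_frames: int = 50,
    frame_interval: float = 1.0,
    image_shape: tuple[int, int] = (96, 192),
    molecule_numbers: Optional[Sequence[int]] = None,
    labeled_fraction: float = 0.5,
    single_dye_intensity: float = 100.0,
    decay_populations: Sequence[tuple[float, float]] = ((1.0, 0.0),),
    background: float = 50.0,
    drift_per_frame: tuple[float, float] = (0.0, 0.0),
    read_noise_sd: float = 0.0,
    shot_noise: bool = False,
    spot_radius: int = 2,
    both_channels: bool = True,
) -> tuple[np.ndarray, pd.DataFrame]:
    """A two-channel spot time series with programmed decays + truth table.

    Each spot represents one surface-anchored condensate of ``m`` DNA
    molecules of which ``round(m * labeled_fraction)`` carry the label of
    each channel; its peak intensity is ``n_labeled * single_dye_intensity``
    decaying as the spot's population prescribes.  ``decay_populations``
    is a sequence of ``(weight, rate)`` pairs; each spot is assigned a
    population with the given probabilities (zero rate = stable spot).
    Spots are uniform discs so the max-pixel statistic is exact in the
    noise-free case.  With ``both_channels=False`` the last spot is
    rendered in channel 0 only (to exercise the dual-channel filter).

    Returns
    -------
    (stack, truth)
        ``stack`` has shape ``(T, 2, H, W)``; ``truth`` one row per spot.
    """
    rng = np.random.default_rng(seed)
    h, w = image_shape
    if molecule_numbers is None:
        molecule_numbers = rng.integers(2, 51, size=n_spots)
    mols = np.asarray(molecule_numbers, dtype=int)
    if mols.size != n_spots:
        raise ValueError("molecule_numbers length must equal n_spots")

    # spots on a jittered grid, away from edges and each other
    margin = spot_radius + 8
    n_cols = int(math.ceil(math.sqrt(n_spots * w / h)))
    n_rows = int(math.ceil(n_spots / n_cols))
    ys = np.linspace(margin, h - margin, n_rows)
    xs = np.linspace(margin, w - margin, n_cols)
    centers = [
        (ys[i // n_cols], xs[i % n_cols]) for i in range(n_spots)
    ]

    weights = np.array([p[0] for p in decay_populations], dtype=float)
    weights /= weights.sum()
    pop_idx = rng.choice(len(decay_populations), size=n_spots, p=weights)
    rates = np.array([decay_populations[i][1] for i in pop_idx])

    n_labeled = np.maximum(1, np.round(mols * labeled_fraction).astype(int))
    peak0 = n_labeled * single_dye_intensity

    t = np.arange(n_frames) * frame_interval
    stack = np.full((n_frames, 2, h, w), float(background))
    yy, xx = np.mgrid[0:h, 0:w]
    for f in range(n_frames):
        oy = drift_per_frame[0] * f
        ox = drift_per_frame[1] * f
        for s, (cy, cx) in enumerate(centers):
            if not both_channels and s == n_spots - 1:
                channels = (0,)
            else:
                channels = (0, 1)
            amp = peak0[s] * math.exp(-rates[s] * t[f])
            mask = (yy - (cy + oy)) ** 2 + (xx - (cx + ox)) ** 2 <= spot_radius**2
            for c in channels:
                frame = stack[f, c]
                frame[mask] = background + amp
    if shot_noise:
        stack = rng.poisson(np.clip(stack, 0, None)).astype(float)
    if read_noise_sd > 0:
        stack = stack + rng.normal(0.0, read_noise_sd, size=stack.shape)

    truth = pd.DataFrame(
        {
            "spot": np.arange(n_spots),
            "cy": [c[0] for c in centers],
            "cx": [c[1] for c in centers],
            "n_molecules": mols,
            "n_labeled": n_labeled,
            "peak_intensity": peak0,
            "decay_rate": rates,
            "population": pop_idx,
            "in_both_channels": [
                both_channels or s < n_spots - 1 for s in range(n_spots)
            ],
        }
    )
    return stack, truth


# ---------------------------------------------------------------------------
# condition grids


def _logistic(x: float, x0: float, slope: float) -> float:
    return 1.0 / (1.0 + math.exp(-(x - x0) / slope))


def gen_condition_grid(
    seed: int,
    lengths_bp: Sequence[float] = (12, 200, 1000, 2500, 10000, 48500),
    concentrations: Optional[Sequence[float]] = None,
    noise_sd: float = 0.02,
    mf_inflection_bp: float = 600.0,
    ar_inflection_bp: float = 6000.0,
    transition_width_decades: float = 0.25,
) -> pd.DataFrame:
    """A (length x concentration) condition table with truth labels.

    Mobile fraction falls and aspect ratio rises with DNA length through
    logistic transitions; the mobile-fraction inflection
    (``mf_inflection_bp``, default 0.6 kb) precedes the aspect-ratio
    inflection (default 6 kb), producing the three-region structure:
    dynamic round (I) -> static round (II) -> static irregular (III).
    The critical concentration decreases with length; grid cells below it
    are flagged as containing no visible condensates.  Concentrations
    default to a log grid from 10 ng/mL to 100 ug/mL.
    """
    rng = np.random.default_rng(seed)
    if concentrations is None:
        concentrations = np.logspace(-8, -4, 5)  # g/mL
    rows = []
    for L in lengths_bp:
        lg = math.log10(L)
        mf_mean = 0.10 + 0.55 * (
            1.0 - _logistic(lg, math.log10(mf_inflection_bp), transition_width_decades)
        )
        ar_mean = 0.05 + 0.45 * _logistic(
            lg, math.log10(ar_inflection_bp), transition_width_decades
        )
        if mf_mean > 0.35:
            region = "I"
        elif ar_mean > 0.25:
            region = "III"
        else:
            region = "II"
        # critical concentration decreasing with length: 50 ug/mL at 12 bp
        # down to ~5 ng/mL at 48.5 kb
        log_ccrit = -4.3 - 1.1 * (lg - math.log10(12.0))
        c_crit = 10.0**log_ccrit
        for c in concentrations:
            detected = c >= c_crit
            mf = np.nan
            ar = np.nan
            if detected:
                # condensates are rounder close to the critical concentration
                depth = min(math.log10(c / c_crit), 2.0)
                mf = float(np.clip(mf_mean + rng.normal(0, noise_sd), 0, 1))
                ar = float(
                    np.clip(ar_mean + 0.015 * depth + rng.normal(0, noise_sd), 0, 1)
                )
            rows.append(
                {
                    "dna_length_bp": float(L),
                    "dna_concentration": float(c),
                    "detected": bool(detected),
                    "mean_aspect_ratio": ar,
                    "mean_mobile_fraction": mf,
                    "truth_region": region if detected else "no condensates",
                }
            )
    return pd.DataFrame(rows)
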