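"""Seeded generators emulating every assay's raw inputs.

Each generator draws from a single ``numpy.random.default_rng(seed)`` stream
and returns the simulated raw data together with a truth dictionary holding
the programmed parameter values, so recovery tests never re-derive them.
Identical spec + seed gives bit-identical output.

What is emulated (and what is not): plate noise is i.i.d. Gaussian (no
plate-position or batch effects); calcium transients are a smooth gamma
pulse peaking near 60 s and returning to baseline by 240 s (no photobleach
drift or oscillations); colony movies are rasterized ellipses with
exponential area growth, programmed elongation, centroid drift + random
walk, and bright speckle pixels painted into the phase image (no
segmentation errors, merging or splitting).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .colonies import MaskFrame

__all__ = [
    "MTTPlateSpec",
    "CalciumSpec",
    "ColonyMovieSpec",
    "GroupedSpec",
    "gen_mtt_plate",
    "gen_calcium_traces",
    "calcium_pulse",
    "gen_colony_movie",
    "gen_grouped",
]


# ---------------------------------------------------------------- MTT plates

@dataclass(frozen=True)
class MTTPlateSpec:
    """Truth for a simulated viability plate (inhibition Hill curve).

    Defaults describe a micromolar-range inhibitor: IC50 100 µM (1e-4 M),
    slope 1.5, full span 100 -> 0 % of control, 5-percentage-point Gaussian
    noise, 8 half-log concentrations, triplicate wells.
    """

    seed: int
    bottom: float = 0.0
    top: float = 100.0
    ic50: float = 1e-4
    hill_slope: float = 1.5
    noise_sd: float = 5.0
    concentrations: tuple = tuple(np.logspace(-6, -2.5, 8))
    n_replicates: int = 3
    n_control_wells: int = 6
    control_absorbance: float = 1.0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError(f"noise_sd must be >= 0, got {self.noise_sd!r}")


def _hill_curve(conc, bottom, top, ic50, slope):
    conc = np.asarray(conc, dtype=float)
    return bottom + (top - bottom) / (1.0 + (conc / ic50) ** slope)


def gen_mtt_plate(spec: MTTPlateSpec) -> tuple[pd.DataFrame, dict]:
    """Raw absorbance plate table with untreated control wells.

    Responses follow the programmed Hill curve in % of control plus noise;
    absorbance = (response / 100) × control absorbance level, so the
    normalization round-trip recovers the programmed percentages.
    """
    rng = np.random.default_rng(spec.seed)
    conc = np.asarray(spec.concentrations, dtype=float)
    true_pct = _hill_curve(conc, spec.bottom, spec.top, spec.ic50, spec.hill_slope)
    rows = []
    for j in range(spec.n_control_wells):
        pct = 100.0 + rng.normal(0.0, spec.noise_sd)
        rows.append({
            "concentration": 0.0,
            "well": f"CTRL{j + 1}",
            "absorbance": pct / 100.0 * spec.control_absorbance,
        })
    for i, c in enumerate(conc):
        for j in range(spec.n_replicates):
            pct = true_pct[i] + rng.normal(0.0, spec.noise_sd)
            rows.append({
                "concentration": float(c),
                "well": f"C{i + 1}R{j + 1}",
                "absorbance": pct / 100.0 * spec.control_absorbance,
            })
    truth = {
        "bottom": spec.bottom, "top": spec.top, "ic50": spec.ic50,
        "hill_slope": spec.hill_slope, "noise_sd": spec.noise_sd,
        "true_pct": true_pct.tolist(),
    }
    return pd.DataFrame(rows), truth


# ---------------------------------------------------------- calcium traces

def calcium_pulse(t: np.ndarray, t_peak: float = 60.0, shape: float = 4.0) -> np.ndarray:
    """Unit-peak gamma pulse: (t/t_peak)^k · exp(k·(1 − t/t_peak)), 0 for t<0.

    With k = 4 and t_peak = 60 s the pulse peaks at 60 s and falls below
    0.2% of the peak by 240 s, matching transients that peak at about one
    minute and decay to baseline within four minutes.
    """
    t = np.asarray(t, dtype=float)
    out = np.zeros_like(t)
    pos = t > 0
    x = t[pos] / t_peak
    out[pos] = x ** shape * np.exp(shape * (1.0 - x))
    return out


@dataclass(frozen=True)
class CalciumSpec:
    """Truth for simulated plate-reader calcium traces.

    ``conditions`` maps condition name -> dict with keys ``amplitude``
    (peak RFU over baseline), optional ``block`` (inhibitor block fraction
    applied to the amplitude) and optional ``sustained`` (plateau mode that
    never returns to baseline). Noise is shot-noise-like: each condition's
    Gaussian noise SD is its own effective amplitude / ``snr``, so the
    signal-to-noise ratio is constant across conditions and a
    zero-amplitude condition is exactly flat.
    """

    seed: int
    conditions: dict = field(default_factory=lambda: {
        "menthol": {"amplitude": 800.0},
        "menthol+TRPA1i": {"amplitude": 800.0, "block": 0.93},
    })
    n_wells_per_condition: int = 3
    baseline_rfu: float = 500.0
    addition_time_s: float = 20.0
    sample_interval_s: float = 4.0
    total_time_s: float = 260.0
    t_peak_s: float = 60.0
    snr: float = 20.0

    def __post_init__(self) -> None:
        for name, p in self.conditions.items():
            if p.get("amplitude", 0.0) < 0:
                raise ValueError(f"condition {name!r}: amplitude must be >= 0")


def gen_calcium_traces(spec: CalciumSpec) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Wide trace table (time + one column per well), well map and truth."""
    rng = np.random.default_rng(spec.seed)
    t = np.arange(0.0, spec.total_time_s + spec.sample_interval_s / 2,
                  spec.sample_interval_s)
    table = {"time": t}
    wells, truth_cond = [], {}
    for name, p in spec.conditions.items():
        amp = p.get("amplitude", 0.0) * (1.0 - p.get("block", 0.0))
        noise_sd = amp / spec.snr if np.isfinite(spec.snr) else 0.0
        if p.get("sustained"):
            signal = amp * (1.0 - np.exp(-(np.maximum(t - spec.addition_time_s, 0.0))
                                         / spec.t_peak_s))
            signal[t < spec.addition_time_s] = 0.0
        else:
            signal = amp * calcium_pulse(t - spec.addition_time_s, spec.t_peak_s)
        truth_cond[name] = {
            "effective_amplitude": amp, "noise_sd": noise_sd,
            "sustained": bool(p.get("sustained", False)),
            "block": p.get("block", 0.0),
        }
        for w in range(spec.n_wells_per_condition):
            well = f"{name}_w{w + 1}"
            table[well] = spec.baseline_rfu + signal + rng.normal(0.0, noise_sd, t.size)
            wells.append({
                "well": well, "condition": name,
                "addition_time": spec.addition_time_s,
            })
    truth = {
        "conditions": truth_cond,
        "baseline_rfu": spec.baseline_rfu,
        "t_peak_s": spec.t_peak_s,
    }
    return pd.DataFrame(table), pd.DataFrame(wells), truth


# ----------------------------------------------------------- colony movies

@dataclass(frozen=True)
class ColonyMovieSpec:
    """Truth for a simulated time-lapse colony movie.

    Colonies are ellipses on a regular grid; per frame, area grows
    exponentially at ``growth_rate_per_h``, the axis ratio interpolates
    linearly from ``axis_ratio_start`` to ``axis_ratio_end``, and the
    centroid moves by a constant drift plus an isotropic Gaussian step.
    Phase images have Gaussian background texture with a programmed
    fraction of bright "dead cell" speckle pixels painted inside each
    colony. Labels are randomly permuted per frame so tracking is
    exercised.
    """

    seed: int
    n_colonies: int = 9
    n_frames: int = 12
    frame_interval_h: float = 4.0
    image_shape: tuple = (512, 512)
    initial_radius_px: float = 22.0
    growth_rate_per_h: float = 0.015          # exponential area growth
    axis_ratio_start: float = 1.0
    axis_ratio_end: float = 1.0
    drift_px_per_frame: tuple = (0.0, 0.0)
    walk_sd_px: float = 1.5
    speckle_fraction: float = 0.0
    background_mean: float = 100.0
    background_sd: float = 5.0
    speckle_offset_sd: float = 6.0            # speckle brightness, in background SDs
    permute_labels: bool = True

    def __post_init__(self) -> None:
        if self.n_frames < 2:
            raise ValueError("need >= 2 frames")
        if not 0.0 <= self.speckle_fraction <= 1.0:
            raise ValueError("speckle_fraction must be in [0, 1]")


def _raster_ellipse(shape, center, semi_major, semi_minor, angle_rad):
    """Boolean mask of an ellipse (row, col center; angle of the major axis)."""
    rr, cc = np.mgrid[0: shape[0], 0: shape[1]]
    dr = rr - center[0]
    dc = cc - center[1]
    ca, sa = np.cos(angle_rad), np.sin(angle_rad)
    u = dr * ca + dc * sa
    v = -dr * sa + dc * ca
    return (u / semi_major) ** 2 + (v / semi_minor) ** 2 <= 1.0


def gen_colony_movie(spec: ColonyMovieSpec) -> tuple[list[MaskFrame], pd.DataFrame, dict]:
    """Movie frames, a frame/colony/label correspondence table, and truth."""
    rng = np.random.default_rng(spec.seed)
    shape = tuple(spec.image_shape)
    side = int(np.ceil(np.sqrt(spec.n_colonies)))
    margin = shape[0] / (side + 1)
    centers = np.array([
        [margin * (1 + i // side), margin * (1 + i % side)]
        for i in range(spec.n_colonies)
    ], dtype=float)
    angles = rng.uniform(0.0, np.pi, spec.n_colonies)
    drift = np.asarray(spec.drift_px_per_frame, dtype=float)

    frames: list[MaskFrame] = []
    corr_rows = []
    pos = centers.copy()
    for fi in range(spec.n_frames):
        t_h = fi * spec.frame_interval_h
        if fi > 0:
            pos = pos + drift + rng.normal(0.0, spec.walk_sd_px, pos.shape)
        growth = np.exp(spec.growth_rate_per_h * t_h)
        frac = fi / (spec.n_frames - 1)
        ratio = spec.axis_ratio_start + frac * (spec.axis_ratio_end - spec.axis_ratio_start)
        # area = pi*a*b grows by `growth`; a/b = ratio
        base_area = np.pi * spec.initial_radius_px ** 2 * growth
        b = np.sqrt(base_area / (np.pi * ratio))
        a = ratio * b

        label_ids = np.arange(1, spec.n_colonies + 1)
        if spec.permute_labels:
            label_ids = rng.permutation(label_ids)
        label_img = np.zeros(shape, dtype=np.int32)
        phase = rng.normal(spec.background_mean, spec.background_sd, shape)
        for ci in range(spec.n_colonies):
            mask = _raster_ellipse(shape, pos[ci], a, b, angles[ci])
            label_img[mask] = label_ids[ci]
            if spec.speckle_fraction > 0:
                idx = np.nonzero(mask)
                n_pix = idx[0].size
                n_bright = int(round(spec.speckle_fraction * n_pix))
                pick = rng.choice(n_pix, size=n_bright, replace=False)
                phase[idx[0][pick], idx[1][pick]] = (
                    spec.background_mean
                    + spec.speckle_offset_sd * spec.background_sd
                    + rng.normal(0.0, 1.0, n_bright)
                )
            corr_rows.append({
                "frame": fi, "colony": ci, "label": int(label_ids[ci]),
                "center_row": pos[ci, 0], "center_col": pos[ci, 1],
                "semi_major": a, "semi_minor": b, "angle_rad": angles[ci],
            })
        frames.append(MaskFrame(label_img, phase, timestamp_h=t_h))
    truth = {
        "growth_rate_per_h": spec.growth_rate_per_h,
        "axis_ratio_start": spec.axis_ratio_start,
        "axis_ratio_end": spec.axis_ratio_end,
        "speckle_fraction": spec.speckle_fraction,
        "walk_sd_px": spec.walk_sd_px,
        "drift_px_per_frame": list(drift),
    }
    return frames, pd.DataFrame(corr_rows), truth


# ------------------------------------------------------------- grouped data

@dataclass(frozen=True)
class GroupedSpec:
    """Truth for tidy grouped measurements feeding the statistics layer.

    ``group_means`` maps label -> mean; the first listed label is the
    control. With ``n_times`` set, a complete time × group design is drawn;
    ``effect_onset`` (frame index, 0-based) switches treated means from the
    control mean to their programmed mean from that frame on. ``lognormal``
    draws log-normal errors (to exercise the transform fallback).
    """

    seed: int
    group_means: dict = field(default_factory=lambda: {
        "control": 100.0, "treated": 100.0,
    })
    sd: float = 10.0
    n_per_group: int = 9
    n_times: int | None = None
    time_step: float = 4.0
    effect_onset: int | None = None
    lognormal: bool = False


def gen_grouped(spec: GroupedSpec) -> tuple[pd.DataFrame, dict]:
    """Tidy (value, group[, time]) table with programmed group means."""
    rng = np.random.default_rng(spec.seed)
    labels = list(spec.group_means)
    control = labels[0]
    rows = []
    times = range(spec.n_times) if spec.n_times else [None]
    for ti in times:
        for g in labels:
            mean = spec.group_means[g]
            if (
                ti is not None and spec.effect_onset is not None
                and g != control and ti < spec.effect_onset
            ):
                mean = spec.group_means[control]
            if spec.lognormal:
                mu = np.log(mean) if mean > 0 else 0.0
                vals = rng.lognormal(mu, spec.sd, spec.n_per_group)
            else:
                vals = rng.normal(mean, spec.sd, spec.n_per_group)
            for v in vals:
                row = {"value": float(v), "group": g}
                if ti is not None:
                    row["time"] = ti * spec.time_step
                rows.append(row)
    truth = {
        "control": control,
        "group_means": dict(spec.group_means),
        "sd": spec.sd,
        "effect_onset": spec.effect_onset,
        "effect_onset_time": (
            spec.effect_onset * spec.time_step if spec.effect_onset is not None else None
        ),
        "lognormal": spec.lognormal,
    }
    return pd.DataFrame(rows), truth
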