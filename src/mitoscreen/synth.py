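"""Seeded generators for every input the pipeline consumes, with ground truth.

The generators reproduce the statistical structure of the screening
campaign the package analyzes, so that recovery of known quantities can be
asserted end-to-end:

* drug screen — 1,134 compounds on duplicate 96-well plates (88 treatment
  wells each; 3 WT, 3 MT, 2 FCCP control wells in column 1).  Background
  normalized values follow a two-component Gaussian mixture with a
  dominant high component (mean 0.734, SD 0.085, weight 0.91) and a
  moment-matched low component so the pooled mean/SD are 0.687/0.173;
  ~20 planted rescuers sit in [0.95, 1.20], with background draws
  rejection-capped below 0.90 so planted-hit counts are exact;
* siRNA screen — 336 genes, Normal(0.710, 0.084) background with a
  configurable right tail, 9 planted rescuers, 4 WT / 4 MT control wells;
* two-channel ratio images, binary mitochondrial masks, Fluo-4 calcium
  traces (1 frame / 2 s) and SWC neuron trees, each with exhaustive truth.

Control wells are drawn with exact per-plate sample moments and treatment
raw intensities are back-computed from the target normalized values, so
plate normalization reproduces the targets and per-plate Z'-factors land
exactly on their sampled targets inside the configured band.  Duplicate
noise is applied symmetrically around each target, making the replicate
mean exact and the duplicate CV equal to its sampled value (bounded below
the 15% acceptability cap).  Every generator is a pure function of its
config and seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import brentq

from .calcium import FluorescenceTrace
from .images import RatioImage
from .neurites import NeuronNode, NeuronTree
from .screen import Plate, ScreenDataset, WellMeasurement, WellRole, well_name

__all__ = [
    "DrugScreenConfig",
    "SirnaScreenConfig",
    "ScreenTruth",
    "PlacementError",
    "derive_low_component",
    "sample_drug_background",
    "gen_drug_screen",
    "gen_sirna_screen",
    "gen_ratio_image",
    "gen_mito_mask",
    "gen_calcium_traces",
    "gen_neuron_tree",
]

_ROWS = "ABCDEFGH"
CV_CAP_PERCENT = 15.0  # duplicate CVs are drawn strictly below this bound


class PlacementError(RuntimeError):
    """Objects could not be placed in the frame without contact."""


class ConfigError(ValueError):
    pass


def derive_low_component(
    mu_high: float,
    sigma_high: float,
    w_high: float,
    pooled_mean: float,
    pooled_sd: float,
) -> tuple[float, float]:
    """Moment-match the low mixture component from the dominant component
    and the pooled statistics.

    With w the dominant weight, the mixture mean and second moment give
    mu_low = (m - w*mu_high)/(1-w) and
    sigma_low^2 = (m2 - w*(sigma_high^2 + mu_high^2))/(1-w) - mu_low^2,
    where m2 = pooled_sd^2 + pooled_mean^2.
    """
    w_low = 1.0 - w_high
    if not 0 < w_low < 1:
        raise ConfigError(f"w_high must be in (0, 1), got {w_high}")
    mu_low = (pooled_mean - w_high * mu_high) / w_low
    m2 = pooled_sd**2 + pooled_mean**2
    var_low = (m2 - w_high * (sigma_high**2 + mu_high**2)) / w_low - mu_low**2
    if var_low <= 0:
        raise ConfigError("pooled statistics inconsistent with the high component")
    return mu_low, math.sqrt(var_low)


@dataclass
class DrugScreenConfig:
    """Conditions of the compound screen; defaults match the campaign."""

    n_compounds: int = 1134
    mu_high: float = 0.734
    sigma_high: float = 0.085
    w_high: float = 0.91
    pooled_mean: float = 0.687
    pooled_sd: float = 0.173
    mu_low: float | None = None  # derived by moment matching when None
    sigma_low: float | None = None
    n_planted: int = 20
    planted_range: tuple[float, float] = (0.95, 1.20)
    background_cap: float | None = 0.90
    wt_raw_level: float = 1.0
    mt_raw_level: float = 0.69
    fccp_raw_level: float = 0.10
    well_noise_cv: float = 8.5  # mean duplicate CV, percent
    z_prime_range: tuple[float, float] = (0.10, 0.50)
    treatments_per_plate: int = 88
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mu_low is None or self.sigma_low is None:
            self.mu_low, self.sigma_low = derive_low_component(
                self.mu_high, self.sigma_high, self.w_high,
                self.pooled_mean, self.pooled_sd,
            )
        if self.n_planted > self.n_compounds:
            raise ConfigError("n_planted exceeds n_compounds")
        if self.background_cap is not None and self.n_planted > 0:
            if self.planted_range[0] <= self.background_cap:
                raise ConfigError(
                    "planted_range must lie above background_cap for exact hit counts"
                )


@dataclass
class SirnaScreenConfig:
    """Conditions of the gene-knockdown screen."""

    n_genes: int = 336
    mu: float = 0.710
    sigma: float = 0.084
    tail_fraction: float = 0.05
    tail_shift: float = 1.0  # in units of sigma, added before the half-normal tail
    n_planted: int = 9
    planted_range: tuple[float, float] = (0.95, 1.10)
    background_cap: float | None = 0.87
    wt_raw_level: float = 1.0
    mt_raw_level: float = 0.71
    well_noise_cv: float = 8.5
    z_prime_range: tuple[float, float] = (0.302, 0.370)
    treatments_per_plate: int = 80
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_planted > self.n_genes:
            raise ConfigError("n_planted exceeds n_genes")
        if self.background_cap is not None and self.n_planted > 0:
            if self.planted_range[0] <= self.background_cap:
                raise ConfigError(
                    "planted_range must lie above background_cap for exact hit counts"
                )


@dataclass
class ScreenTruth:
    """Per-treatment effect class and exact target normalized value."""

    classes: dict[str, str]  # planted_hit | background_high | background_low | background_tail
    true_values: dict[str, float]
    planted: list[str] = field(default_factory=list)


def _exact_moments(rng: np.random.Generator, n: int, mean: float, sd: float) -> np.ndarray:
    """n draws standardized to exact sample mean and sample SD (ddof=1)."""
    if n < 2:
        raise ValueError("need n >= 2")
    while True:
        z = rng.standard_normal(n)
        z = z - z.mean()
        s = z.std(ddof=1)
        if s > 1e-12:
            return mean + sd * z / s


def sample_drug_background(
    n: int,
    config: DrugScreenConfig,
    rng: np.random.Generator,
    cap: float | None = None,
    use_cap: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw n background values from the two-component mixture.

    Returns (values, component) with component 1 for the dominant high
    component.  Draws above the rejection cap (``config.background_cap``
    unless overridden; pass use_cap=False for pure mixture sampling) are
    redrawn, as are non-positive values.
    """
    bound = (config.background_cap if cap is None else cap) if use_cap else None
    values = np.empty(n)
    comp = np.empty(n, dtype=int)
    for i in range(n):
        while True:
            hi = rng.random() < config.w_high
            v = (
                rng.normal(config.mu_high, config.sigma_high)
                if hi
                else rng.normal(config.mu_low, config.sigma_low)
            )
            if v > 0 and (bound is None or v <= bound):
                break
        values[i] = v
        comp[i] = 1 if hi else 0
    return values, comp


def _sample_cv_percent(rng: np.random.Generator, n: int, mean_cv: float) -> np.ndarray:
    """Duplicate CVs (percent) from a Beta on [0, 15%) with the given mean."""
    if mean_cv <= 0:
        return np.zeros(n)
    if mean_cv >= CV_CAP_PERCENT:
        raise ConfigError(f"well_noise_cv must be < {CV_CAP_PERCENT}")
    a = 2.0
    b = a * (CV_CAP_PERCENT / mean_cv - 1.0)
    return CV_CAP_PERCENT * rng.beta(a, b, size=n)


def _build_plate(
    rng: np.random.Generator,
    plate_id: str,
    control_spec: Sequence[tuple[WellRole, str, float, float, int]],
    treatment_wells: Sequence[tuple[str, str, float]],
    wt_level: float,
    z_target: float,
    window: float,
) -> Plate:
    """Assemble one physical plate with exact control moments.

    control_spec rows: (role, well positions, raw ratio level, n wells).
    treatment_wells rows: (well, treatment_id, target normalized value);
    raw ratios are back-computed as target x WT level so normalization
    reproduces the targets exactly.
    """
    s_total = (1.0 - z_target) * window / 3.0
    u = rng.uniform(0.3, 0.7)
    s_w, s_m = u * s_total, (1.0 - u) * s_total

    wells: list[WellMeasurement] = []

    def add(role: WellRole, well: str, ratio: float, tid: str | None = None) -> None:
        row, col = well[0], int(well[1:])
        f520 = rng.uniform(80.0, 120.0)
        wells.append(
            WellMeasurement(
                plate_id=plate_id,
                row=row,
                col=col,
                role=role,
                f590=ratio * f520,
                f520=f520,
                treatment_id=tid,
            )
        )

    for role, positions, level, n in control_spec:
        if role is WellRole.WT_CONTROL:
            ratios = _exact_moments(rng, n, level, s_w * wt_level)
        elif role is WellRole.MT_CONTROL:
            ratios = _exact_moments(rng, n, level, s_m * wt_level)
        else:
            ratios = _exact_moments(rng, n, level, 0.01 * wt_level)
        for well, ratio in zip(positions, ratios):
            add(role, well, float(ratio))

    for well, tid, target in treatment_wells:
        add(WellRole.TREATMENT, well, target * wt_level, tid)

    return Plate(plate_id, wells)


def _gen_screen(
    rng: np.random.Generator,
    screen_type: str,
    treatment_ids: list[str],
    targets: np.ndarray,
    classes: dict[str, str],
    planted_ids: list[str],
    cfg,
    control_layout,
    treatment_positions: list[str],
) -> tuple[ScreenDataset, ScreenTruth]:
    n = len(treatment_ids)
    per_plate = cfg.treatments_per_plate
    window = abs(1.0 - cfg.mt_raw_level / cfg.wt_raw_level)

    cvs = _sample_cv_percent(rng, n, cfg.well_noise_cv)
    d = cvs / 100.0 / math.sqrt(2.0)
    signs = rng.choice([-1.0, 1.0], size=n)

    plates: list[Plate] = []
    for p in range(math.ceil(n / per_plate)):
        chunk = slice(p * per_plate, min((p + 1) * per_plate, n))
        idx = range(chunk.start, chunk.stop)
        for copy_i, copy in enumerate("AB"):
            plate_id = f"{screen_type[0].upper()}P{p + 1:02d}{copy}"
            z_target = rng.uniform(*cfg.z_prime_range)
            rep_sign = 1.0 if copy_i == 0 else -1.0
            tw = [
                (
                    treatment_positions[i - chunk.start],
                    treatment_ids[i],
                    targets[i] * (1.0 + rep_sign * signs[i] * d[i]),
                )
                for i in idx
            ]
            plates.append(
                _build_plate(
                    rng, plate_id, control_layout, tw,
                    cfg.wt_raw_level, z_target, window,
                )
            )

    truth = ScreenTruth(
        classes=classes,
        true_values={tid: float(v) for tid, v in zip(treatment_ids, targets)},
        planted=planted_ids,
    )
    return ScreenDataset(screen_type, plates), truth


def gen_drug_screen(config: DrugScreenConfig | None = None) -> tuple[ScreenDataset, ScreenTruth]:
    """Synthesize the compound screen: duplicated plates, planted rescuers,
    mixture background, exact control moments.  Deterministic in config.seed."""
    cfg = config or DrugScreenConfig()
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_compounds

    planted_idx = set(rng.choice(n, size=cfg.n_planted, replace=False).tolist())
    ids = [f"DRUG{i + 1:04d}" for i in range(n)]
    targets = np.empty(n)
    classes: dict[str, str] = {}
    for i in range(n):
        if i in planted_idx:
            targets[i] = rng.uniform(*cfg.planted_range)
            classes[ids[i]] = "planted_hit"
        else:
            v, comp = sample_drug_background(1, cfg, rng)
            targets[i] = v[0]
            classes[ids[i]] = "background_high" if comp[0] == 1 else "background_low"

    control_layout = [
        (WellRole.WT_CONTROL, ["A1", "B1", "C1"], cfg.wt_raw_level, 3),
        (WellRole.MT_CONTROL, ["D1", "E1", "F1"], cfg.mt_raw_level, 3),
        (WellRole.FCCP_CONTROL, ["G1", "H1"], cfg.fccp_raw_level, 2),
    ]
    positions = [well_name(r, c) for r in _ROWS for c in range(2, 13)]  # 88 wells
    return _gen_screen(
        rng, "drug", ids, targets, classes,
        sorted(ids[i] for i in planted_idx), cfg, control_layout, positions,
    )


def gen_sirna_screen(config: SirnaScreenConfig | None = None) -> tuple[ScreenDataset, ScreenTruth]:
    """Synthesize the gene-knockdown screen: Normal background with a
    right tail, planted rescuers, 4 WT / 4 MT control wells per plate."""
    cfg = config or SirnaScreenConfig()
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_genes

    planted_idx = set(rng.choice(n, size=cfg.n_planted, replace=False).tolist())
    ids = [f"GENE{i + 1:04d}" for i in range(n)]
    targets = np.empty(n)
    classes: dict[str, str] = {}
    for i in range(n):
        if i in planted_idx:
            targets[i] = rng.uniform(*cfg.planted_range)
            classes[ids[i]] = "planted_hit"
            continue
        tail = rng.random() < cfg.tail_fraction
        while True:
            if tail:
                v = cfg.mu + cfg.sigma * (cfg.tail_shift + abs(rng.standard_normal()))
            else:
                v = rng.normal(cfg.mu, cfg.sigma)
            if v > 0 and (cfg.background_cap is None or v <= cfg.background_cap):
                break
        targets[i] = v
        classes[ids[i]] = "background_tail" if tail else "background_high"

    control_layout = [
        (WellRole.WT_CONTROL, ["A1", "B1", "C1", "D1"], cfg.wt_raw_level, 4),
        (WellRole.MT_CONTROL, ["E1", "F1", "G1", "H1"], cfg.mt_raw_level, 4),
    ]
    positions = [well_name(r, c) for r in _ROWS for c in range(2, 12)]  # 80 wells
    return _gen_screen(
        rng, "sirna", ids, targets, classes,
        sorted(ids[i] for i in planted_idx), cfg, control_layout, positions,
    )


# ---------------------------------------------------------------------------
# imaging


def gen_ratio_image(
    n_cells: int,
    ratios: Sequence[float] | None = None,
    size: int = 256,
    noise_sigma: float = 0.02,
    seed: int = 0,
    radius_range: tuple[float, float] = (8.0, 15.0),
    green_level: float = 100.0,
) -> tuple[RatioImage, dict]:
    """Disc-shaped cells with known per-cell F590/F520 on a dark background.

    Red = ratio * green per pixel, each channel with independent
    multiplicative Gaussian noise of relative SD ``noise_sigma``.
    """
    rng = np.random.default_rng(seed)
    if ratios is None:
        ratios = rng.uniform(0.5, 3.0, size=n_cells)
    ratios = np.asarray(ratios, dtype=float)
    if ratios.size != n_cells:
        raise ConfigError("len(ratios) must equal n_cells")

    green = np.zeros((size, size))
    red = np.zeros((size, size))
    if noise_sigma > 0:  # background: faint positive noise
        green += np.abs(rng.normal(0.0, noise_sigma * green_level, (size, size)))
        red += np.abs(rng.normal(0.0, noise_sigma * green_level, (size, size)))

    centers: list[tuple[float, float]] = []
    radii: list[float] = []
    yy, xx = np.mgrid[0:size, 0:size]
    for i in range(n_cells):
        r = rng.uniform(*radius_range)
        for _ in range(2000):
            cy = rng.uniform(r + 2, size - r - 2)
            cx = rng.uniform(r + 2, size - r - 2)
            if all(
                math.hypot(cy - y0, cx - x0) >= r + r0 + 4
                for (y0, x0), r0 in zip(centers, radii)
            ):
                break
        else:
            raise PlacementError(f"could not place cell {i} in a {size}x{size} frame")
        centers.append((cy, cx))
        radii.append(r)
        disc = (yy - cy) ** 2 + (xx - cx) ** 2 <= r**2
        npix = int(disc.sum())
        g = green_level * (1.0 + rng.normal(0.0, noise_sigma, npix))
        rch = ratios[i] * green_level * (1.0 + rng.normal(0.0, noise_sigma, npix))
        green[disc] = np.maximum(g, 0.0)
        red[disc] = np.maximum(rch, 0.0)

    truth = {
        "centers": centers,
        "radii": radii,
        "ratios": ratios.tolist(),
        "n_cells": n_cells,
    }
    return RatioImage(red=red, green=green), truth


def gen_mito_mask(
    n_objects: int,
    ar_mean: float = 2.5,
    ar_sd: float = 0.8,
    size: int = 512,
    seed: int = 0,
    minor_range: tuple[float, float] = (4.0, 6.0),
) -> tuple[np.ndarray, dict]:
    """Binary mask of rasterized, rotated ellipses with known axes."""
    rng = np.random.default_rng(seed)
    mask = np.zeros((size, size), dtype=bool)
    yy, xx = np.mgrid[0:size, 0:size]
    centers: list[tuple[float, float]] = []
    records = []
    for i in range(n_objects):
        ar = max(1.0, rng.normal(ar_mean, ar_sd))
        b = rng.uniform(*minor_range)
        a = ar * b
        theta = rng.uniform(0.0, math.pi)
        for _ in range(2000):
            cy = rng.uniform(a + 2, size - a - 2)
            cx = rng.uniform(a + 2, size - a - 2)
            if all(
                math.hypot(cy - y0, cx - x0) >= a + r0 + 4
                for (y0, x0), r0 in zip(centers, (rec["semi_major"] for rec in records))
            ):
                break
        else:
            raise PlacementError(f"could not place object {i} in a {size}x{size} frame")
        dy, dx = yy - cy, xx - cx
        u = dx * math.cos(theta) + dy * math.sin(theta)
        v = -dx * math.sin(theta) + dy * math.cos(theta)
        mask |= (u / a) ** 2 + (v / b) ** 2 <= 1.0
        centers.append((cy, cx))
        records.append(
            {
                "center": (cy, cx),
                "semi_major": a,
                "semi_minor": b,
                "aspect_ratio": ar,
                "theta": theta,
            }
        )
    return mask, {"objects": records, "n_objects": n_objects}


# ---------------------------------------------------------------------------
# calcium traces


def _truncated_poisson_rate(target_mean: float, min_events: int) -> float:
    """Poisson rate whose mean conditional on N >= min_events equals target.

    Oscillating cells are defined by showing at least ``min_events``
    transients, so their counts are truncated-Poisson; without this
    correction the group frequency would overshoot the nominal rate.
    """
    k = min_events

    def cond_mean(lam: float) -> float:
        p_lt = sum(math.exp(-lam) * lam**j / math.factorial(j) for j in range(k))
        e_lt = sum(j * math.exp(-lam) * lam**j / math.factorial(j) for j in range(k))
        return (lam - e_lt) / (1.0 - p_lt)

    if target_mean <= k + 1e-6:
        return 1e-3  # conditional mean floor is k; degenerate request
    return brentq(lambda lam: cond_mean(lam) - target_mean, 1e-6, 10 * target_mean)


def gen_calcium_traces(
    n_cells: int,
    p_oscillating: float,
    rate_per_min: float,
    amplitude_mean: float,
    amplitude_sd: float = 0.3,
    duration_s: float = 300.0,
    dt_s: float = 2.0,
    noise_sigma: float = 0.01,
    seed: int = 0,
    baseline: float = 100.0,
    tau_rise_s: float = 1.5,
    tau_decay_s: float = 2.5,
    refractory_s: float = 16.0,
    amplitude_floor: float = 1.2,
    min_events: int = 2,
) -> tuple[list[FluorescenceTrace], dict]:
    """Fluo-4 ROI traces with planted double-exponential transients.

    Each cell oscillates with probability ``p_oscillating``; oscillating
    cells receive a truncated-Poisson number of events (conditional mean =
    rate_per_min * duration / 60) at near-uniform times with a
    ``refractory_s`` minimum separation, peak times snapped to the frame
    grid so the sampled peak equals the drawn amplitude.  Peak F/F0
    amplitudes are Normal(amplitude_mean, amplitude_sd) resampled above
    ``amplitude_floor``.  Noise is additive Gaussian with SD
    ``noise_sigma`` relative to baseline.
    """
    if dt_s <= 0:
        raise ConfigError("dt_s must be > 0")
    rng = np.random.default_rng(seed)
    n_frames = int(round(duration_s / dt_s)) + 1
    t = np.arange(n_frames) * dt_s
    duration = dt_s * (n_frames - 1)
    edge_start, edge_end = 10.0, 6.0

    target_events = rate_per_min * duration / 60.0
    lam = _truncated_poisson_rate(target_events, min_events) if target_events > 0 else 0.0

    traces: list[FluorescenceTrace] = []
    truth_cells = []
    for i in range(n_cells):
        cid = f"CELL{i + 1:04d}"
        osc = rng.random() < p_oscillating
        times: np.ndarray = np.empty(0)
        amps: np.ndarray = np.empty(0)
        if osc and lam > 0:
            max_n = int((duration - edge_start - edge_end) // refractory_s) + 1
            n_ev = 0
            while n_ev < min_events:
                n_ev = min(int(rng.poisson(lam)), max_n)
            span = duration - edge_start - edge_end - (n_ev - 1) * refractory_s
            u = np.sort(rng.uniform(0.0, span, size=n_ev))
            times = edge_start + u + np.arange(n_ev) * refractory_s
            times = np.round(times / dt_s) * dt_s  # snap peaks to the frame grid
            amps = np.empty(n_ev)
            for j in range(n_ev):
                while True:
                    a = rng.normal(amplitude_mean, amplitude_sd)
                    if a >= amplitude_floor:
                        break
                amps[j] = a
        signal = np.ones(n_frames)
        for t0, a in zip(times, amps):
            dt_ev = t - t0
            shape = np.where(
                dt_ev >= 0, np.exp(-dt_ev / tau_decay_s), np.exp(dt_ev / tau_rise_s)
            )
            signal += (a - 1.0) * shape
        values = baseline * (signal + rng.normal(0.0, noise_sigma, n_frames))
        values = np.maximum(values, 1e-6)
        traces.append(FluorescenceTrace(cid, values, dt_s))
        truth_cells.append(
            {
                "cell_id": cid,
                "oscillating": bool(osc and times.size >= min_events),
                "event_times_s": times.tolist(),
                "amplitudes": amps.tolist(),
                "n_events": int(times.size),
            }
        )
    truth = {
        "cells": truth_cells,
        "baseline": baseline,
        "duration_s": duration,
        "p_oscillating": p_oscillating,
        "rate_per_min": rate_per_min,
        "amplitude_mean": amplitude_mean,
    }
    return traces, truth


# ---------------------------------------------------------------------------
# neuron trees


def gen_neuron_tree(
    depth: int = 4,
    segment_length_mean: float = 50.0,
    branching_prob: float = 0.7,
    seed: int = 0,
    n_trunks: int = 3,
) -> tuple[NeuronTree, dict]:
    """Random binary-branching dendritic tree rooted at a soma.

    Truth records the exact total length (sum of realized segment lengths)
    and terminal count, accumulated in build order so metric computations
    reproduce them to float identity.
    """
    if depth < 1:
        raise ConfigError("depth must be >= 1")
    rng = np.random.default_rng(seed)
    nodes: list[NeuronNode] = [NeuronNode(1, 1, 0.0, 0.0, 0.0, 5.0, -1)]
    next_id = [2]
    lengths: list[float] = []
    n_terminals = [0]

    def grow(parent: NeuronNode, direction: np.ndarray, levels_left: int) -> None:
        length = max(1.0, rng.normal(segment_length_mean, 0.2 * segment_length_mean))
        pos = np.array([parent.x, parent.y, parent.z]) + length * direction
        node = NeuronNode(
            next_id[0], 3, float(pos[0]), float(pos[1]), float(pos[2]), 0.5,
            parent.id,
        )
        next_id[0] += 1
        nodes.append(node)
        lengths.append(float(np.linalg.norm(pos - np.array([parent.x, parent.y, parent.z]))))
        if levels_left <= 1:
            n_terminals[0] += 1
            return
        n_children = 2 if rng.random() < branching_prob else 1
        for _ in range(n_children):
            d = direction + 0.6 * rng.standard_normal(3)
            d /= np.linalg.norm(d)
            grow(node, d, levels_left - 1)

    for _ in range(n_trunks):
        d = rng.standard_normal(3)
        d /= np.linalg.norm(d)
        grow(nodes[0], d, depth)

    tree = NeuronTree.from_nodes(nodes)
    truth = {
        "total_length_um": float(sum(lengths)),
        "n_terminals": n_terminals[0],
        "n_nodes": len(nodes),
    }
    return tree, truth
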