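"""Desk-scale reproductions of the spatial-cognition experiments.

Every experiment is a pure function of an :class:`ExperimentConfig` plus a
seed: stripe-pattern formation statistics, phase-displacement calibration,
multi-scale decoding error sweeps, boundary-correction studies, noise
robustness, and the full cognition pipeline (head-direction encoding ->
stripe path integration -> grid assembly -> boundary correction ->
multi-scale decoding -> place readout).

Desk-scale defaults shrink the original 10 m x 10 m / 5000 s / 200x200-cell
runs to sizes that complete in seconds-to-minutes on one CPU while keeping
the structure identical; :meth:`ExperimentConfig.full_scale` restores the
full-scale settings.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, replace

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .trajectory import (
    Arena,
    TrajectorySeries,
    generate_random_walk,
    simulate_odometry,
    write_trajectory,
)
from .stripe import (
    StripeDynamicsFFT,
    StripePlate,
    build_weight_matrix,
    calibrate_displacement_gain,
    most_unstable_period,
    preferred_signs,
    step_rates,
)
from .grid import GridModule, von_mises_rate
from .decode import (
    PlaceCellMap,
    decode_multiscale,
    decode_single_module,
    error_statistics,
    place_response,
)

logger = logging.getLogger("hippocan")

__all__ = [
    "ExperimentConfig",
    "load_config",
    "run_stripe_formation",
    "run_calibration",
    "run_multiscale_study",
    "run_noise_robustness",
    "run_boundary_study",
    "run_full_cognition",
    "CognitionRun",
]


@dataclass
class ExperimentConfig:
    """All tunables of the experiment suite (desk-scale defaults)."""

    # arena / roam
    arena_width: float = 4.0
    arena_height: float = 4.0
    duration: float = 400.0
    traj_dt: float = 0.1
    speed_min: float = 0.0
    speed_max: float = 0.5
    heading_step: float = float(np.pi / 2)  # increments uniform in +/- this

    # stripe plate
    n_cells: int = 120
    lam: float = 20.0
    k: float = 1.0
    alpha: float = 0.35
    tau: float = 0.005
    w_amp: float = 10.0
    can_dt: float = 0.001
    noise_amplitude: float = 0.01

    # calibration roam
    calib_arena: float = 1.0
    calib_duration: float = 120.0

    # grid scales
    lambda0: float = 4.0
    scale_ratio: float = 1.5
    n_scales: int = 3
    cells_per_side: int = 30
    n_max: float = 10.0
    kappa: float = 3.0
    window: float = 1.0

    # odometry error model
    speed_noise_sd: float = 0.2
    heading_noise_sd: float = 0.25
    speed_bias: float = 0.0         # systematic encoder scale error (fraction)
    heading_drift: float = 0.0      # systematic gyro drift, rad/s

    # theta-rhythm drive dither (linearizes slow pattern flow)
    dither_amplitude: float = 0.1
    dither_freq: float = 20.0

    # boundary cells
    segment_length: float = 0.25
    sensing_distance: float = 0.15
    intensity_c: float = 20.0
    injection_s: float = 0.3     # injection duration per band entry

    # study sizes
    n_seeds: int = 20
    decode_trials: int = 200
    study_cells_per_side: tuple = (50, 100)
    noise_levels: tuple = (0.0, 0.1, 0.2)
    noise_repeats: int = 50
    checkpoint_dt: float = 10.0

    def full_scale(self) -> "ExperimentConfig":
        """Full-scale settings: 10 m x 10 m arena, 5000 s, 200^2 cells."""
        return replace(
            self,
            arena_width=10.0,
            arena_height=10.0,
            duration=5000.0,
            lambda0=10.0,
            cells_per_side=200,
            study_cells_per_side=(50, 100, 200),
            segment_length=1.0,
        )

    @property
    def arena(self) -> Arena:
        return Arena(self.arena_width, self.arena_height)

    @property
    def scale_periods(self) -> list[float]:
        return [self.lambda0 / self.scale_ratio**m for m in range(self.n_scales)]

    def to_dict(self) -> dict:
        d = asdict(self)
        d["study_cells_per_side"] = list(self.study_cells_per_side)
        d["noise_levels"] = list(self.noise_levels)
        return d


def load_config(path) -> ExperimentConfig:
    """Read a ``key: value`` (YAML) config file; unknown keys are rejected."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    valid = {f for f in ExperimentConfig.__dataclass_fields__}
    unknown = set(raw) - valid
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    for key in ("study_cells_per_side", "noise_levels"):
        if key in raw:
            raw[key] = tuple(raw[key])
    return ExperimentConfig(**raw)


def _report_header(config: ExperimentConfig, seed: int) -> dict:
    return {"version": __version__, "seed": int(seed), "config": config.to_dict()}


def _write_report(report: dict, outdir, name: str) -> None:
    if outdir is None:
        return
    from pathlib import Path

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / name, "w") as fh:
        json.dump(report, fh, indent=2, default=float)


# ---------------------------------------------------------------------------
# stripe formation
# ---------------------------------------------------------------------------

def run_stripe_formation(
    config: ExperimentConfig, seed: int = 0, outdir=None
) -> dict:
    """Formation-time distribution of the stripe pattern over many seeds.

    All plates share one weight matrix and are integrated as a batch from
    independent small-noise initial states under zero velocity; the report
    gives per-seed formation times (first time the spatial spectrum peaks at
    the expected period and the profile has stopped changing) in ms.
    """
    n = config.n_cells
    W = build_weight_matrix(n, config.lam, config.k, config.w_amp)
    period = most_unstable_period(n, config.lam)
    m_star = int(round(n / period))
    rngs = [np.random.default_rng(s) for s in _spawn(seed, config.n_seeds)]
    S = np.stack([r.uniform(0, config.noise_amplitude, n) for r in rngs])
    B = np.ones(n)
    dt = config.can_dt
    check = max(int(round(0.05 / dt)), 1)
    max_steps = int(round(1.0 / dt))
    formed = np.full(config.n_seeds, np.nan)
    prev = S.copy()
    for i in range(1, max_steps + 1):
        S = step_rates(W, S, B, dt, config.tau)
        if i % check == 0:
            spec = np.abs(np.fft.rfft(S - S.mean(axis=1, keepdims=True), axis=1))
            peak_ok = np.argmax(spec[:, 1:], axis=1) + 1 == m_star
            delta = np.max(np.abs(S - prev), axis=1) / (S.max(axis=1) + 1e-300)
            newly = np.isnan(formed) & peak_ok & (delta < 0.01)
            formed[newly] = i * dt * 1e3
            prev = S.copy()
            if not np.any(np.isnan(formed)):
                break
    times = formed.tolist()
    report = {
        **_report_header(config, seed),
        "pattern_period_cells": period,
        "formation_times_ms": times,
        "median_ms": float(np.nanmedian(formed)),
        "all_formed": bool(not np.any(np.isnan(formed))),
    }
    logger.info("stripe formation: median %.0f ms over %d seeds",
                report["median_ms"], config.n_seeds)
    _write_report(report, outdir, "stripe_formation.json")
    return report


def _spawn(seed: int, n: int) -> list[int]:
    """Derive n child seeds (< 2**31) from a master seed."""
    ss = np.random.SeedSequence(seed)
    return [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n)]


# ---------------------------------------------------------------------------
# calibration
# ---------------------------------------------------------------------------

def run_calibration(
    config: ExperimentConfig, seed: int = 0, outdir=None, plate: StripePlate | None = None
) -> dict:
    """Phase-displacement gain calibration on a random roam.

    Roams a small square arena, drives the plate with the velocity
    projection, and regresses true displacement along the plate direction on
    the unwrapped pattern phase. Reports the correlation, the maximum
    absolute residual of the regression line (meters), and the realized
    stripe spacing L.
    """
    traj_seed, init_seed = _spawn(seed, 2)
    if plate is None:
        plate = StripePlate(
            config.n_cells, config.lam, 0.0, config.k, config.alpha,
            config.tau, config.w_amp,
        )
    arena = Arena(config.calib_arena, config.calib_arena)
    traj = generate_random_walk(
        arena,
        config.calib_duration,
        config.traj_dt,
        (config.speed_min, config.speed_max),
        (-config.heading_step, config.heading_step),
        seed=traj_seed,
    )
    from .stripe import relax_to_pattern

    relax_to_pattern(plate, dt=config.can_dt, seed=init_seed,
                     noise_amplitude=config.noise_amplitude)
    result = calibrate_displacement_gain(plate, traj, dt=config.can_dt)
    report = {
        **_report_header(config, seed),
        "displacement_gain_m_per_cell": result.displacement_gain,
        "correlation": result.r,
        "max_residual_m": result.max_residual,
        "stripe_spacing_L_m": plate.physical_period,
    }
    logger.info("calibration: r=%.5f, max residual %.1f mm, L=%.3f m",
                result.r, result.max_residual * 1e3, plate.physical_period)
    _write_report(report, outdir, "calibration.json")
    return report


# ---------------------------------------------------------------------------
# multi-scale decoding study
# ---------------------------------------------------------------------------

def run_multiscale_study(config: ExperimentConfig, seed: int = 0, outdir=None) -> pd.DataFrame:
    """RMS decode error versus number of scales and cells per plate.

    For each plate size and scale count, Poisson counts are drawn at random
    positions inside the coarsest unit cell and decoded coarse-to-fine.
    """
    rng = np.random.default_rng(_spawn(seed, 1)[0])
    periods = [config.lambda0 / config.scale_ratio**m for m in range(4)]
    rows = []
    for side in config.study_cells_per_side:
        modules = [
            GridModule.regular(p, side, config.n_max, config.kappa) for p in periods
        ]
        # positions drawn once per plate size so scale counts see identical targets
        xs = rng.uniform(-0.25 * config.lambda0, 0.25 * config.lambda0,
                         (config.decode_trials, 2))
        counts = [
            [rng.poisson(von_mises_rate(m, x) * config.window) for m in modules]
            for x in xs
        ]
        for n_scales in range(1, 5):
            errs = np.empty(config.decode_trials)
            for t, x in enumerate(xs):
                est = decode_multiscale(counts[t][:n_scales], modules[:n_scales])
                errs[t] = np.linalg.norm(est.estimate - x)
            rows.append(
                {
                    "cells_per_side": side,
                    "n_cells": side**2,
                    "n_scales": n_scales,
                    "rms_error_m": float(np.sqrt(np.mean(errs**2))),
                    "median_error_m": float(np.median(errs)),
                }
            )
            logger.info("multiscale study: %dx%d cells, %d scales -> RMS %.4f m",
                        side, side, n_scales, rows[-1]["rms_error_m"])
    table = pd.DataFrame(rows)
    if outdir is not None:
        from pathlib import Path

        Path(outdir).mkdir(parents=True, exist_ok=True)
        table.to_csv(Path(outdir) / "multiscale_study.csv", index=False)
    return table


# ---------------------------------------------------------------------------
# noise robustness
# ---------------------------------------------------------------------------

def run_noise_robustness(config: ExperimentConfig, seed: int = 0, outdir=None) -> pd.DataFrame:
    """Decoded-position displacement under Gaussian rate perturbation.

    A fixed position is encoded in one grid module's expected rates; zero-,
    10%- and 20%-amplitude Gaussian noise (relative to the peak rate) is
    added to the activation values, and the position is re-decoded. The
    displacement of the estimate from the noise-free decode is reported per
    noise level.
    """
    rng = np.random.default_rng(_spawn(seed, 1)[0])
    module = GridModule.regular(
        config.lambda0, config.cells_per_side, config.n_max, config.kappa
    )
    x = np.array([-0.3 * config.lambda0, -0.3 * config.lambda0])
    clean_rates = von_mises_rate(module, x)
    baseline = decode_single_module(clean_rates, module).estimate
    rows = []
    for level in config.noise_levels:
        disps = np.empty(config.noise_repeats)
        for i in range(config.noise_repeats):
            noisy = clean_rates + level * config.n_max * rng.normal(size=clean_rates.shape)
            est = decode_single_module(np.maximum(noisy, 0.0), module)
            disps[i] = np.linalg.norm(est.estimate - baseline)
        rows.append(
            {
                "noise_level": level,
                "median_displacement_m": float(np.median(disps)),
                "max_displacement_m": float(np.max(disps)),
                "displacement_frac_of_period": float(np.median(disps) / module.period),
            }
        )
        logger.info("noise %d%%: median displacement %.4f m",
                    int(level * 100), rows[-1]["median_displacement_m"])
    table = pd.DataFrame(rows)
    if outdir is not None:
        from pathlib import Path

        Path(outdir).mkdir(parents=True, exist_ok=True)
        table.to_csv(Path(outdir) / "noise_robustness.csv", index=False)
    return table


# ---------------------------------------------------------------------------
# full cognition pipeline (batched multi-plate engine)
# ---------------------------------------------------------------------------

class _PlateBank:
    """Stacked stripe plates for several runs x scales x directions.

    All plates share one weight matrix; rows differ in orientation, velocity
    scale (one per grid scale), driving trajectory (one per run), and
    boundary-memory state. Batching the Euler updates across rows keeps
    long multi-seed simulations fast.
    """

    ORIENTATIONS = np.array([0.0, np.pi / 3, 2 * np.pi / 3])

    def __init__(self, config: ExperimentConfig, n_runs: int, gain_base: float,
                 L_base: float, seed: int):
        self.config = config
        n = config.n_cells
        self.dyn = StripeDynamicsFFT(n, config.lam, config.k, config.w_amp, config.tau)
        self.signs = preferred_signs(n)
        self.period = most_unstable_period(n, config.lam)
        self.gain_base = gain_base
        periods = config.scale_periods
        self.n_runs, self.n_scales = n_runs, len(periods)
        rows = []
        for run in range(n_runs):
            for m, lam_m in enumerate(periods):
                for th in self.ORIENTATIONS:
                    rows.append((run, m, th, L_base / lam_m))
        self.run_of = np.array([r[0] for r in rows])
        self.scale_of = np.array([r[1] for r in rows])
        self.dirs = np.stack(
            [[np.cos(r[2]), np.sin(r[2])] for r in rows]
        )  # (R, 2)
        self.vscale = np.array([r[3] for r in rows])
        # effective meters-per-cell of each row
        self.row_gain = gain_base / self.vscale
        R = len(rows)
        rngs = [np.random.default_rng(s) for s in _spawn(seed, R)]
        self.S = np.stack([r.uniform(0, config.noise_amplitude, n) for r in rngs])
        self._ev = np.exp(2j * np.pi * np.arange(n) / self.period)
        # relax to pattern, zero velocity
        B = np.ones(n)
        for _ in range(int(round(0.5 / config.can_dt))):
            self.S = self.dyn.step(self.S, B, config.can_dt)
        self._prev_phase = self._phases()
        self.cum_phase = np.zeros(R)

    def _phases(self) -> np.ndarray:
        z = self.S @ self._ev
        return (np.angle(z) % (2 * np.pi)) * self.period / (2 * np.pi)

    def track(self) -> None:
        ph = self._phases()
        d = (ph - self._prev_phase + self.period / 2) % self.period - self.period / 2
        self.cum_phase += d
        self._prev_phase = ph

    def displacements(self) -> np.ndarray:
        """Per-row integrated displacement along the row direction, meters."""
        return self.cum_phase * self.row_gain

    def scale_positions(self, starts: np.ndarray) -> np.ndarray:
        """(n_runs, n_scales, 2) absolute position estimates per scale."""
        d = self.displacements()
        est = (2.0 / 3.0) * (d[:, None] * self.dirs)  # (R, 2) contributions
        out = np.zeros((self.n_runs, self.n_scales, 2))
        np.add.at(out, (self.run_of, self.scale_of), est)
        return out + starts[:, None, :]

    def combined_positions(self, starts: np.ndarray) -> np.ndarray:
        """Precision-weighted (1/lambda_m^2) fusion across scales."""
        per_scale = self.scale_positions(starts)
        w = np.array([p**-2 for p in self.config.scale_periods])
        return (per_scale * w[None, :, None]).sum(axis=1) / w.sum()


@dataclass
class CognitionRun:
    """Outputs of one pipeline run."""

    truth: TrajectorySeries
    odometry: TrajectorySeries
    decoded: np.ndarray            # (N, 2) combined path-integrated estimate
    per_scale: np.ndarray          # (N, n_scales, 2)
    checkpoint_t: np.ndarray
    checkpoint_est: np.ndarray     # (C, 2) grid-rate ML decodes
    checkpoint_err: np.ndarray
    place_centers: np.ndarray      # (P, 2) place-field centers
    place_winner: np.ndarray       # (C, 2) center of the peak place cell


def _simulate_bank(
    config: ExperimentConfig,
    runs: list[tuple[TrajectorySeries, TrajectorySeries, bool]],
    gain_base: float,
    seed: int,
    record_scales: bool = True,
):
    """Advance a plate bank through its runs' odometry inputs.

    ``runs`` holds (truth, odometry, correct) triples of equal length.
    Boundary sensing uses the true position (the wall sensor measures the
    real world); learning and injection follow the boundary-cell memory
    rules. Returns per-run position estimates at every trajectory sample.
    """
    L_base = abs(gain_base) * most_unstable_period(config.n_cells, config.lam)
    bank = _PlateBank(config, len(runs), gain_base, L_base, seed)
    n = config.n_cells
    arena = config.arena
    segments = arena.perimeter_segments(config.segment_length)
    D = len(segments)
    R = len(bank.run_of)
    eligible = np.array(
        [config.scale_periods[m] >= 2 * config.segment_length for m in bank.scale_of]
    )
    correct_flag = np.array([runs[r][2] for r in bank.run_of])
    memory_w = np.zeros((R, D, n))
    learned = np.zeros((R, D), dtype=bool)
    visit_sum = np.zeros((R, D, n))
    visit_cnt = np.zeros((len(runs), D), dtype=int)
    prev_active = np.zeros((len(runs), D), dtype=bool)
    nearest_active = np.zeros((len(runs), D), dtype=bool)
    inject_left = np.zeros((len(runs), D))

    n_samples = len(runs[0][0])
    starts = np.stack([r[0].positions[0] for r in runs])
    decoded = np.zeros((len(runs), n_samples, 2))
    per_scale = (
        np.zeros((len(runs), n_samples, bank.n_scales, 2)) if record_scales else None
    )
    decoded[:, 0] = starts
    if record_scales:
        per_scale[:, 0] = starts[:, None, :]

    vels = np.stack([r[1].velocities for r in runs])  # (n_runs, N, 2)
    true_pos = np.stack([r[0].positions for r in runs])
    sub = max(int(round(config.traj_dt / config.can_dt)), 1)
    half = max(int(round(1.0 / (2.0 * config.dither_freq) / config.can_dt)), 1)
    if sub % (2 * half) != 0:
        raise ValueError(
            "traj_dt must hold an integer number of dither cycles "
            "(adjust dither_freq or traj_dt)"
        )
    dither = config.dither_amplitude * bank.signs[None, :]
    seg_a = segments[:, 0]
    seg_ab = segments[:, 1] - segments[:, 0]
    seg_len2 = np.einsum("ij,ij->i", seg_ab, seg_ab)

    for i in range(n_samples - 1):
        v = vels[:, i]  # (n_runs, 2)
        vproj = np.einsum("rj,rj->r", bank.dirs, v[bank.run_of]) * bank.vscale
        B = 1.0 + config.alpha * bank.signs[None, :] * vproj[:, None]
        # boundary activations from the previous sample's sensing state,
        # limited to the configured injection duration per band entry and to
        # the nearest active region (competing references would conflict)
        injecting = prev_active & (inject_left > 0) & nearest_active
        inject_left[prev_active & (inject_left > 0)] -= config.traj_dt
        act_rows = injecting[bank.run_of] & learned & correct_flag[:, None] & eligible[:, None]
        run_injecting = act_rows.reshape(len(runs), -1, D).any(axis=(1, 2))
        if act_rows.any():
            B = B + config.intensity_c * np.einsum("rd,rdn->rn", act_rows.astype(float), memory_w)
        sgn = 1.0
        for _ in range(sub // half):
            sgn = -sgn
            Bseg = B + sgn * dither
            for _ in range(half):
                bank.S = bank.dyn.step(bank.S, Bseg, config.can_dt)
        bank.track()
        pos = true_pos[:, i + 1]  # (n_runs, 2)
        # distance of each run to each segment
        rel = pos[:, None, :] - seg_a[None, :, :]
        u = np.clip(np.einsum("rdj,dj->rd", rel, seg_ab) / seg_len2, 0.0, 1.0)
        closest = seg_a[None] + u[..., None] * seg_ab[None]
        dists = np.linalg.norm(pos[:, None, :] - closest, axis=2)
        active = dists <= config.sensing_distance
        nearest_active = np.zeros_like(active)
        any_active = active.any(axis=1)
        nearest_idx = np.argmin(np.where(active, dists, np.inf), axis=1)
        nearest_active[np.nonzero(any_active)[0], nearest_idx[any_active]] = True
        # accumulate the visit's rate samples for active segments; skip
        # samples taken while an injection is distorting the pattern
        clean = active & ~run_injecting[:, None]
        if clean.any():
            rows_active = clean[bank.run_of]  # (R, D)
            visit_sum += rows_active[:, :, None] * bank.S[:, None, :]
            visit_cnt += clean
        inject_left[active & ~prev_active] = config.injection_s
        # commit first-visit memories at band exit
        exited = prev_active & ~active
        for run, d in zip(*np.nonzero(exited)):
            rows = np.nonzero(bank.run_of == run)[0]
            fresh = rows[~learned[rows, d]]
            if len(fresh) and visit_cnt[run, d] > 0:
                memory_w[fresh, d] = visit_sum[fresh, d] / (visit_cnt[run, d] * n)
                learned[fresh, d] = True
            visit_sum[rows, d] = 0.0
            visit_cnt[run, d] = 0
        prev_active = active
        est = bank.combined_positions(starts)
        decoded[:, i + 1] = est
        if record_scales:
            per_scale[:, i + 1] = bank.scale_positions(starts)
    return decoded, per_scale


def _perimeter_tour(
    arena: Arena, margin: float, speed: float, dt: float
) -> TrajectorySeries:
    """Scripted wall-following lap (boundary familiarization phase).

    Starts at the arena center, drives to the lower-left corner region, then
    follows the full perimeter counter-clockwise at constant speed, ending
    back at the first corner. Used to let the boundary cells memorize every
    wall segment while accumulated odometry drift is still small.
    """
    w, h = arena.width, arena.height
    m = margin
    waypoints = np.array([
        [w / 2, h / 2], [m, m], [w - m, m], [w - m, h - m], [m, h - m], [m, m],
    ])
    pts = [waypoints[0]]
    for a, b in zip(waypoints[:-1], waypoints[1:]):
        d = np.linalg.norm(b - a)
        n = max(int(np.ceil(d / (speed * dt))), 1)
        seg = a + (b - a) * ((np.arange(1, n + 1) / n)[:, None])
        pts.extend(seg)
    pts = np.asarray(pts)
    steps = np.diff(pts, axis=0)
    heading = np.arctan2(steps[:, 1], steps[:, 0])
    sp = np.linalg.norm(steps, axis=1) / dt
    t = dt * np.arange(len(pts))
    return TrajectorySeries(
        t, pts[:, 0], pts[:, 1],
        np.append(sp, sp[-1]), np.append(heading, heading[-1]),
    )


def _concat_trajectories(a: TrajectorySeries, b: TrajectorySeries) -> TrajectorySeries:
    """Join two series; b must start where a ends (same dt)."""
    dt = a.dt
    speed = np.concatenate([a.speed, b.speed])
    # the junction step covers zero distance (b starts at a's endpoint)
    speed[len(a) - 1] = 0.0
    return TrajectorySeries(
        np.concatenate([a.t, a.t[-1] + dt + b.t]),
        np.concatenate([a.x, b.x]),
        np.concatenate([a.y, b.y]),
        speed,
        np.concatenate([a.heading, b.heading]),
    )


def _calibrated_gain(config: ExperimentConfig, seed: int) -> float:
    report = run_calibration(config, seed)
    return report["displacement_gain_m_per_cell"]


def run_boundary_study(config: ExperimentConfig, seed: int = 0, outdir=None) -> dict:
    """Error growth with and without boundary correction (plus odometry).

    For several roam seeds the same noisy odometry is integrated three ways:
    dead reckoning, uncorrected path integration, and path integration with
    boundary-cell correction at wall contacts. Reports per-seed error
    envelopes over time.
    """
    cal_seed, *run_seeds = _spawn(seed, config.n_seeds + 1)
    single_scale = replace(config, n_scales=1)
    gain = _calibrated_gain(single_scale, cal_seed)
    tour = _perimeter_tour(config.arena, config.sensing_distance * 0.6,
                           0.3, config.traj_dt)
    runs = []
    odos = []
    for s in run_seeds:
        roam = generate_random_walk(
            config.arena, config.duration, config.traj_dt,
            (config.speed_min, config.speed_max),
            (-config.heading_step, config.heading_step),
            seed=s, start=(tour.x[-1], tour.y[-1]),
        )
        truth = _concat_trajectories(tour, roam)
        odo = _noisy_odometry(single_scale, truth, s + 1)
        odos.append(odo)
        runs.append((truth, odo, True))
        runs.append((truth, odo, False))
    decoded, _ = _simulate_bank(single_scale, runs, gain, seed=cal_seed + 1)
    t = runs[0][0].t
    corrected, uncorrected, odo_err = [], [], []
    for j in range(config.n_seeds):
        truth = runs[2 * j][0]
        corrected.append(error_statistics(truth, decoded[2 * j]).envelope)
        uncorrected.append(error_statistics(truth, decoded[2 * j + 1]).envelope)
        odo_err.append(error_statistics(truth, odos[j]).envelope)
    report = {
        **_report_header(config, seed),
        "t": t.tolist(),
        "corrected_envelope": np.stack(corrected).tolist(),
        "uncorrected_envelope": np.stack(uncorrected).tolist(),
        "odometry_envelope": np.stack(odo_err).tolist(),
        "final_corrected_median_m": float(np.median([e[-1] for e in corrected])),
        "final_uncorrected_median_m": float(np.median([e[-1] for e in uncorrected])),
        "final_odometry_median_m": float(np.median([e[-1] for e in odo_err])),
    }
    logger.info(
        "boundary study: final envelopes corrected %.2f m, uncorrected %.2f m, odometry %.2f m",
        report["final_corrected_median_m"],
        report["final_uncorrected_median_m"],
        report["final_odometry_median_m"],
    )
    _write_report(
        {k: v for k, v in report.items() if "envelope" not in k and k != "t"},
        outdir, "boundary_study.json",
    )
    return report


def _noisy_odometry(config: ExperimentConfig, truth: TrajectorySeries, seed: int):
    """White per-step sensor noise plus slow systematic encoder/gyro bias."""
    odo = simulate_odometry(
        truth, config.speed_noise_sd, config.heading_noise_sd, seed=seed
    )
    if config.speed_bias or config.heading_drift:
        sp = odo.speed * (1.0 + config.speed_bias)
        hd = odo.heading + config.heading_drift * odo.t
        base = TrajectorySeries(odo.t, odo.x, odo.y, sp, hd)
        odo = simulate_odometry(base, 0.0, 0.0)
    return odo


def run_full_cognition(config: ExperimentConfig, seed: int = 0, outdir=None):
    """End-to-end pipeline: roam -> encode -> integrate -> correct -> decode.

    Returns a :class:`CognitionRun` with the combined path-integrated
    estimate at every sample and sparse grid-rate maximum-likelihood decode
    checkpoints, plus a report comparing the cognitive path against the
    dead-reckoned odometry baseline.
    """
    cal_seed, traj_seed, odo_seed, chk_seed = _spawn(seed, 4)
    gain = _calibrated_gain(config, cal_seed)
    tour = _perimeter_tour(config.arena, config.sensing_distance * 0.6,
                           0.3, config.traj_dt)
    roam = generate_random_walk(
        config.arena, config.duration, config.traj_dt,
        (config.speed_min, config.speed_max),
        (-config.heading_step, config.heading_step),
        seed=traj_seed, start=(tour.x[-1], tour.y[-1]),
    )
    truth = _concat_trajectories(tour, roam)
    odo = _noisy_odometry(config, truth, odo_seed)
    decoded, per_scale = _simulate_bank(config, [(truth, odo, True)], gain, seed=cal_seed + 1)
    decoded, per_scale = decoded[0], per_scale[0]

    # grid-rate ML decode at sparse checkpoints
    modules = [
        GridModule.regular(p, config.cells_per_side, config.n_max, config.kappa)
        for p in config.scale_periods
    ]
    rng = np.random.default_rng(chk_seed)
    every = max(int(round(config.checkpoint_dt / config.traj_dt)), 1)
    idx = np.arange(0, len(truth), every)
    chk_est = np.empty((len(idx), 2))
    for j, i in enumerate(idx):
        counts = [
            rng.poisson(von_mises_rate(m, per_scale[i, s]) * config.window)
            for s, m in enumerate(modules)
        ]
        est = decode_multiscale(counts, modules, prior=per_scale[i, 0])
        chk_est[j] = est.estimate if not est.undecodable else per_scale[i, 0]
    chk_err = np.linalg.norm(chk_est - truth.positions[idx], axis=1)

    # place-cell readout: single-peaked response over a field map
    delta_sq = min(config.scale_periods) / 10.0
    fields = PlaceCellMap.regular(
        (config.arena_width, config.arena_height), 0.25, delta_sq
    )
    winners = np.stack([
        fields.centers[int(np.argmax(place_response(fields, e)))] for e in chk_est
    ])

    stats, odo_stats, table = error_statistics(truth, decoded, baseline=odo)
    run = CognitionRun(truth, odo, decoded, per_scale, truth.t[idx], chk_est, chk_err,
                       fields.centers, winners)
    report = {
        **_report_header(config, seed),
        "bionic": stats.summary(),
        "odometry": odo_stats.summary(),
        "checkpoint_rms_m": float(np.sqrt(np.mean(chk_err**2))),
        "place_readout_rms_m": float(np.sqrt(np.mean(
            np.linalg.norm(winners - truth.positions[idx], axis=1) ** 2))),
    }
    logger.info("full cognition: bionic RMS %.3f m vs odometry RMS %.3f m",
                stats.rms, odo_stats.rms)
    if outdir is not None:
        from pathlib import Path

        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        write_trajectory(truth, out / "truth.csv")
        write_trajectory(odo, out / "odometry.csv")
        pd.DataFrame(
            {
                "t": truth.t,
                "x_true": truth.x,
                "y_true": truth.y,
                "x_hat": decoded[:, 0],
                "y_hat": decoded[:, 1],
                "error": stats.errors,
            }
        ).to_csv(out / "decoded.csv", index=False)
        table.to_csv(out / "comparison.csv")
        _write_report(report, outdir, "full_cognition.json")
    return run, report
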