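"""Maximum-likelihood position readout from grid-cell population activity.

Single scale
------------
Under independent Poisson spiking with von Mises grid tuning, the
log-posterior of position given counts ``n_j`` is (up to a constant)

    log p(x | n) = (kappa/3) sum_j sum_l n_j cos( w k_l . (x - c_j) ),

maximized in closed form by per-direction population vectors:

    mu_l  = w^-1 arg( sum_j n_j exp(i w k_l . c_j) ),
    mu^   = (2/3) sum_l mu_l k_l,

using ``sum_l k_l k_l^T = (3/2) I`` for unit vectors 60 degrees apart. The
estimate is defined modulo the hexagonal firing lattice.

Multi-scale
-----------
Nested scales (periods decreasing by a fixed ratio) are fused
coarse-to-fine. Writing ``w_m = lambda_m^-2``, the running estimate is
refined by each finer scale's offset:

    x_{m} = x_{m-1} + [ w_m / sum_{q<=m} w_q ] * Delta_m,

which is algebraically the precision-weighted average of the per-scale
solutions (equal cell counts per scale). ``Delta_m`` is computed by wrapping
each direction's phase solution ``mu_l`` around ``k_l . x_{m-1}`` into
(-lambda_m/2, lambda_m/2]: because the three wave directions are linearly
dependent (k_2 = k_1 + k_3), per-direction wraps chosen independently of a
common center are not lattice translates, so the offsets must be taken
relative to the running estimate — this is also the cheapest biologically
plausible rule (offset relative to the current coarse belief).

A dense-lattice posterior scan (:func:`posterior_oracle`) provides the
ground-truth argmax that both decoders are tested against.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .grid import GridModule
from .trajectory import TrajectorySeries

__all__ = [
    "SingleScaleEstimate",
    "DecodeEstimate",
    "PlaceCellMap",
    "decode_single_module",
    "posterior_oracle",
    "PosteriorField",
    "decode_multiscale",
    "multiscale_weighted_average",
    "multiscale_recursive",
    "place_response",
    "error_statistics",
    "ErrorStatistics",
    "wrap_to_halfopen",
]


def wrap_to_halfopen(v, period: float):
    """Map values to the branch (-period/2, period/2]."""
    return -((-np.asarray(v) + period / 2.0) % period - period / 2.0)


@dataclass(frozen=True)
class SingleScaleEstimate:
    """Population-vector solution of one grid scale (modulo its lattice)."""

    mu: np.ndarray          # per-direction projections mu_l, meters (3,)
    estimate: np.ndarray    # mu^ = (2/3) sum mu_l k_l, meters (2,)
    period: float
    undecodable: bool = False


@dataclass(frozen=True)
class DecodeEstimate:
    """Multi-scale readout with its per-scale refinement trace."""

    estimate: np.ndarray              # final x_ML, meters (2,)
    per_scale: tuple                  # per-scale (period, delta, weight) rows
    undecodable: bool = False
    ambiguous: bool = False


def _direction_vectors(counts: np.ndarray, module: GridModule) -> np.ndarray:
    """Complex population vector per wave direction, (3,)."""
    ph = module.wave_number * (module.phase_offsets @ module.wave_dirs.T)  # (M, 3)
    return (counts[:, None] * np.exp(1j * ph)).sum(axis=0)


def decode_single_module(counts: np.ndarray, module: GridModule) -> SingleScaleEstimate:
    """Closed-form ML estimate from one scale's spike counts.

    Flags the result undecodable for zero total counts or a near-zero
    population-vector magnitude in any wave direction.
    """
    counts = np.asarray(counts, dtype=float)
    if counts.shape != (module.n_cells,):
        raise ValueError("counts length must match the module's cell count")
    total = counts.sum()
    if total <= 0:
        return SingleScaleEstimate(np.zeros(3), np.zeros(2), module.period, True)
    z = _direction_vectors(counts, module)
    if np.any(np.abs(z) < 1e-9 * total):
        return SingleScaleEstimate(np.zeros(3), np.zeros(2), module.period, True)
    mu = np.angle(z) / module.wave_number
    est = (2.0 / 3.0) * (mu @ module.wave_dirs)
    return SingleScaleEstimate(mu, est, module.period, False)


@dataclass(frozen=True)
class PosteriorField:
    xs: np.ndarray
    ys: np.ndarray
    p: np.ndarray           # normalized posterior, sums to 1
    argmax: np.ndarray      # (2,)
    ambiguous: bool


def posterior_oracle(
    counts_per_scale,
    modules,
    extent: float,
    resolution: int = 201,
    center=(0.0, 0.0),
) -> PosteriorField:
    """Dense-lattice evaluation of the (joint) log posterior and its argmax.

    Accepts a single (counts, module) pair or parallel sequences of them.
    The search lattice covers ``center +/- extent`` in both coordinates.
    Serves as the brute-force ground truth for both decoders. Flags a tie of
    the maximum at lattice resolution as ambiguous.
    """
    if isinstance(modules, GridModule):
        modules = [modules]
        counts_per_scale = [counts_per_scale]
    xs = np.asarray(center)[0] + np.linspace(-extent, extent, resolution)
    ys = np.asarray(center)[1] + np.linspace(-extent, extent, resolution)
    X, Y = np.meshgrid(xs, ys, indexing="ij")
    pts = np.stack([X.ravel(), Y.ravel()], axis=1)
    logp = np.zeros(len(pts))
    for counts, module in zip(counts_per_scale, modules):
        counts = np.asarray(counts, dtype=float)
        w = module.wave_number
        for l in range(3):
            cc = w * (module.phase_offsets @ module.wave_dirs[l])
            A = np.sum(counts * np.cos(cc))
            Bs = np.sum(counts * np.sin(cc))
            pc = w * (pts @ module.wave_dirs[l])
            logp += (module.kappa / 3.0) * (np.cos(pc) * A + np.sin(pc) * Bs)
    logp -= logp.max()
    p = np.exp(logp)
    p /= p.sum()
    flat = p.reshape(resolution, resolution)
    peak = np.max(logp)
    ambiguous = bool(np.count_nonzero(logp > peak - 1e-12) > 1)
    return PosteriorField(xs, ys, flat, pts[int(np.argmax(logp))], ambiguous)


def multiscale_weighted_average(deltas, periods, cells_per_scale=None) -> np.ndarray:
    """Direct precision-weighted average of per-scale solutions.

    ``x = sum_m M_m s_m^2 delta_m / sum_m M_m s_m^2`` with the scale factor
    ``s_m = lambda_0 / lambda_m`` (so the weight is proportional to
    ``M_m / lambda_m^2``).
    """
    deltas = np.atleast_2d(np.asarray(deltas, float))
    periods = np.asarray(periods, float)
    M = (
        np.ones(len(periods))
        if cells_per_scale is None
        else np.asarray(cells_per_scale, float)
    )
    w = M * (periods[0] / periods) ** 2
    return (w[:, None] * deltas).sum(axis=0) / w.sum()


def multiscale_recursive(deltas, periods) -> np.ndarray:
    """Coarse-to-fine recursion equivalent to the weighted average.

    ``x_{m} = x_{m-1} + [lambda_m^-2 / sum_{q<=m} lambda_q^-2] *
    (delta_m - x_{m-1})`` — identical to
    :func:`multiscale_weighted_average` with equal cell counts.
    """
    deltas = np.atleast_2d(np.asarray(deltas, float))
    periods = np.asarray(periods, float)
    x = deltas[0].astype(float)
    wsum = periods[0] ** -2
    for lam, d in zip(periods[1:], deltas[1:]):
        w = lam**-2
        x = x + (w / (wsum + w)) * (d - x)
        wsum += w
    return x


def decode_multiscale(
    counts_per_scale,
    modules,
    prior=None,
    prior_weight: float = 0.0,
    ambiguity_frac: float = 0.45,
) -> DecodeEstimate:
    """ML position from nested grid scales, coarse to fine.

    ``modules`` must be ordered by strictly decreasing period; the coarsest
    period should cover the arena (the estimate is unique only within its
    unit cell). A ``prior`` position (e.g. the unwrapped coarse
    path-integration readout) may seed the recursion: every scale, including
    the coarsest, then contributes the solution branch nearest the running
    estimate, with ``prior_weight`` acting as the prior's precision
    (``lambda^-2`` units; 0 means the prior only selects branches). Scales
    whose counts are undecodable are skipped; if every scale is undecodable
    the result is flagged. A per-direction offset landing within
    ``(ambiguity_frac, 1/2]`` periods of the branch edge flags the estimate
    as branch-ambiguous.
    """
    periods = [m.period for m in modules]
    if any(b >= a for a, b in zip(periods, periods[1:])):
        raise ValueError("modules must be sorted by strictly decreasing period")
    est = None if prior is None else np.asarray(prior, dtype=float).copy()
    wsum = float(prior_weight)
    trace = []
    ambiguous = False
    for counts, module in zip(counts_per_scale, modules):
        single = decode_single_module(counts, module)
        if single.undecodable:
            continue
        lam = module.period
        if est is None:
            est = single.estimate.copy()
            wsum = lam**-2
            trace.append((lam, est.copy(), 1.0))
            continue
        d_l = wrap_to_halfopen(single.mu - module.wave_dirs @ est, lam)
        if np.any(np.abs(d_l) > ambiguity_frac * lam):
            ambiguous = True
        delta = (2.0 / 3.0) * (d_l @ module.wave_dirs)
        w = lam**-2
        est = est + (w / (wsum + w)) * delta
        wsum += w
        trace.append((lam, delta, w / wsum))
    if est is None or not trace:
        return DecodeEstimate(np.zeros(2) if est is None else est, (), True, False)
    return DecodeEstimate(est, tuple(trace), False, ambiguous)


@dataclass
class PlaceCellMap:
    """Gaussian place fields: ``R_i = exp(-||x - r_i0||^2 / delta_sq)``."""

    centers: np.ndarray       # (P, 2) field centers, meters
    delta_sq: float           # field width parameter, m^2

    def __post_init__(self) -> None:
        if self.delta_sq <= 0:
            raise ValueError("delta_sq must be positive")
        self.centers = np.atleast_2d(np.asarray(self.centers, float))

    @classmethod
    def regular(cls, extent: tuple[float, float], spacing: float, delta_sq: float):
        xs = np.arange(spacing / 2, extent[0], spacing)
        ys = np.arange(spacing / 2, extent[1], spacing)
        X, Y = np.meshgrid(xs, ys, indexing="ij")
        return cls(np.stack([X.ravel(), Y.ravel()], axis=1), delta_sq)


def place_response(fields: PlaceCellMap, x_hat) -> np.ndarray:
    """Place-cell population response to a decoded position (single peak)."""
    d2 = np.sum((fields.centers - np.asarray(x_hat, float)) ** 2, axis=1)
    return np.exp(-d2 / fields.delta_sq)


@dataclass(frozen=True)
class ErrorStatistics:
    errors: np.ndarray          # per-sample Euclidean error, meters
    envelope: np.ndarray        # running maximum of the error
    centroid: np.ndarray        # mean 2-D error vector
    spread: float               # RMS radial spread about the centroid
    rms: float

    def summary(self) -> dict:
        return {
            "rms_m": float(self.rms),
            "max_m": float(self.errors.max()),
            "final_envelope_m": float(self.envelope[-1]),
            "centroid_x_m": float(self.centroid[0]),
            "centroid_y_m": float(self.centroid[1]),
            "spread_m": float(self.spread),
        }


def _as_positions(obj) -> np.ndarray:
    if isinstance(obj, TrajectorySeries):
        return obj.positions
    return np.atleast_2d(np.asarray(obj, float))


def error_statistics(
    true_traj,
    decoded_traj,
    baseline=None,
) -> ErrorStatistics | tuple[ErrorStatistics, ErrorStatistics, pd.DataFrame]:
    """Per-sample position error, running envelope, and 2-D scatter summary.

    With a ``baseline`` path (e.g. dead-reckoned odometry) also returns the
    baseline's statistics and a paired comparison table.
    """
    p_true = _as_positions(true_traj)
    p_dec = _as_positions(decoded_traj)
    if p_true.shape != p_dec.shape:
        raise ValueError("trajectories are misaligned (different lengths)")
    vec = p_dec - p_true
    errors = np.linalg.norm(vec, axis=1)
    centroid = vec.mean(axis=0)
    stats = ErrorStatistics(
        errors,
        np.maximum.accumulate(errors),
        centroid,
        float(np.sqrt(np.mean(np.sum((vec - centroid) ** 2, axis=1)))),
        float(np.sqrt(np.mean(errors**2))),
    )
    if baseline is None:
        return stats
    base_stats = error_statistics(true_traj, baseline)
    table = pd.DataFrame(
        [stats.summary(), base_stats.summary()], index=["decoded", "baseline"]
    )
    return stats, base_stats, table
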