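"""Grid-cell assembly and closed-form grid tuning.

Two complementary views of the same code:

* *Mechanistic*: three stripe plates with orientations 60 degrees apart are
  superposed (rectified sum of band responses) into a hexagonal firing
  pattern that flows with the integrated velocity.
* *Closed form*: for decoding, each grid cell's mean rate is the von Mises
  grid tuning

      Omega(x) = n_max * exp[ (kappa/3) * sum_l ( cos(w k_l . (x - c_j)) - 1 ) ]

  with wave number ``w = 2 pi / period``, unit wave vectors ``k_l`` at
  ``phi_l = -pi/6 + l pi/3`` (l = 1..3), peak rate ``n_max`` and
  concentration ``kappa``. Spike counts are Poisson with mean
  ``Omega * window``.

A stripe band oriented at angle ``a`` varies along ``a + 90 degrees``: the
wave directions (30/90/150 deg) are the normals of stripe plates oriented at
0/60/120 deg.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .stripe import StripePlate

__all__ = [
    "GridModule",
    "wave_vectors",
    "lattice_vectors",
    "unit_cell_offsets",
    "von_mises_rate",
    "sample_poisson_rates",
    "superpose_stripes",
    "rate_map",
    "spatial_autocorrelation",
]


def wave_vectors(orientation: float = 0.0) -> np.ndarray:
    """Three unit wave vectors 60 degrees apart, ``phi_l = -pi/6 + l pi/3``.

    ``orientation`` rotates the whole set (shared across scales).
    """
    phis = -np.pi / 6 + np.arange(1, 4) * np.pi / 3 + orientation
    return np.stack([np.cos(phis), np.sin(phis)], axis=1)


def lattice_vectors(period: float, orientation: float = 0.0) -> np.ndarray:
    """Primitive vectors of the hexagonal firing lattice.

    Translations T with ``k_l . T`` an integer multiple of the period for all
    three wave vectors; rows are the two primitive vectors (length
    ``2 period / sqrt(3)``).
    """
    a = np.array(
        [
            [2.0 * period / np.sqrt(3.0), 0.0],
            [-period / np.sqrt(3.0), period],
        ]
    )
    c, s = np.cos(orientation), np.sin(orientation)
    rot = np.array([[c, -s], [s, c]])
    return a @ rot.T


def unit_cell_offsets(
    period: float, cells_per_side: int, orientation: float = 0.0
) -> np.ndarray:
    """Spatial phase offsets c_j tiling one lattice unit cell, (M, 2)."""
    a = lattice_vectors(period, orientation)
    u = (np.arange(cells_per_side) + 0.5) / cells_per_side
    U, V = np.meshgrid(u, u, indexing="ij")
    return U.reshape(-1, 1) * a[0] + V.reshape(-1, 1) * a[1]


@dataclass
class GridModule:
    """One scale of grid cells sharing a period and orientation.

    ``phase_offsets`` are the cells' spatial phases c_j (meters), tiling one
    unit cell of the hexagonal lattice.
    """

    period: float
    phase_offsets: np.ndarray
    n_max: float = 10.0
    kappa: float = 3.0
    orientation: float = 0.0

    def __post_init__(self) -> None:
        if self.period <= 0 or self.n_max <= 0 or self.kappa < 0:
            raise ValueError("grid module parameters must be positive")
        self.phase_offsets = np.atleast_2d(np.asarray(self.phase_offsets, float))

    @classmethod
    def regular(
        cls,
        period: float,
        cells_per_side: int,
        n_max: float = 10.0,
        kappa: float = 3.0,
        orientation: float = 0.0,
    ) -> "GridModule":
        """Module whose cell phases form a regular grid over the unit cell."""
        return cls(
            period,
            unit_cell_offsets(period, cells_per_side, orientation),
            n_max,
            kappa,
            orientation,
        )

    @property
    def n_cells(self) -> int:
        return len(self.phase_offsets)

    @property
    def wave_number(self) -> float:
        return 2.0 * np.pi / self.period

    @property
    def wave_dirs(self) -> np.ndarray:
        return wave_vectors(self.orientation)

    @property
    def lattice(self) -> np.ndarray:
        return lattice_vectors(self.period, self.orientation)


def von_mises_rate(module: GridModule, x, offsets: np.ndarray | None = None) -> np.ndarray:
    """Expected rate Omega of every cell at position(s) x.

    ``x`` may be a single 2-vector (returns (M,)) or an (N, 2) array
    (returns (N, M)). Rates satisfy ``0 < Omega <= n_max`` and are periodic
    under lattice translations.
    """
    c = module.phase_offsets if offsets is None else np.atleast_2d(offsets)
    x = np.asarray(x, dtype=float)
    single = x.ndim == 1
    xs = np.atleast_2d(x)
    d = xs[:, None, :] - c[None, :, :]  # (N, M, 2)
    ph = module.wave_number * np.tensordot(d, module.wave_dirs, axes=([2], [1]))
    out = module.n_max * np.exp(
        (module.kappa / 3.0) * np.sum(np.cos(ph) - 1.0, axis=-1)
    )
    return out[0] if single else out


def sample_poisson_rates(
    module: GridModule,
    x,
    observation_window: float = 1.0,
    seed=None,
) -> np.ndarray:
    """Independent Poisson spike counts with mean ``Omega_j(x) * window``.

    ``seed`` may be an integer or an already-constructed Generator.
    """
    if observation_window <= 0:
        raise ValueError("observation window must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return rng.poisson(von_mises_rate(module, x) * observation_window)


def band_response(plate: StripePlate, positions: np.ndarray) -> np.ndarray:
    """Evaluate a calibrated plate's current band pattern at 2-D positions.

    The plate's rate profile, anchored at its current phase, is sampled (by
    periodic linear interpolation in cell units) at each position's
    projection onto the plate orientation divided by the displacement gain.
    """
    if plate.displacement_gain is None:
        raise ValueError("plate must be calibrated before evaluating band fields")
    proj = np.atleast_2d(positions) @ plate.direction
    u = (proj / plate.displacement_gain) % plate.n_cells
    i0 = np.floor(u).astype(int) % plate.n_cells
    i1 = (i0 + 1) % plate.n_cells
    frac = u - np.floor(u)
    return (1.0 - frac) * plate.rates[i0] + frac * plate.rates[i1]


def superpose_stripes(
    plates: list[StripePlate],
    positions: np.ndarray,
    threshold: float = 0.0,
) -> np.ndarray:
    """Rectified sum of three band responses: the assembled grid field.

    The plates must hold calibrated gains and orientations 60 degrees apart.
    Returns the superposed rate at each position.
    """
    if len(plates) != 3:
        raise ValueError("grid assembly needs exactly three stripe plates")
    thetas = sorted(p.theta % np.pi for p in plates)
    gaps = np.diff(thetas + [thetas[0] + np.pi])
    if not np.allclose(gaps, np.pi / 3, atol=1e-6):
        raise ValueError("stripe plate orientations must be 60 degrees apart")
    total = sum(band_response(p, positions) for p in plates)
    return np.maximum(total - threshold, 0.0)


def rate_map(
    field_fn,
    arena_extent: tuple[float, float],
    resolution: float,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Sample a scalar field over a rectangle into a 2-D map.

    ``field_fn`` maps (N, 2) positions to (N,) values — e.g. a lambda over
    :func:`von_mises_rate` or :func:`superpose_stripes`. Returns (xs, ys,
    map) with ``map[i, j]`` the value at ``(xs[i], ys[j])``.
    """
    if resolution <= 0:
        raise ValueError("resolution must be positive")
    w, h = arena_extent
    xs = np.arange(0.0, w + resolution / 2, resolution)
    ys = np.arange(0.0, h + resolution / 2, resolution)
    X, Y = np.meshgrid(xs, ys, indexing="ij")
    pts = np.stack([X.ravel(), Y.ravel()], axis=1)
    return xs, ys, np.asarray(field_fn(pts)).reshape(len(xs), len(ys))


def spatial_autocorrelation(field: np.ndarray) -> np.ndarray:
    """Mean-removed 2-D autocorrelation (FFT-based, 'same' size)."""
    f = field - field.mean()
    return signal.fftconvolve(f, f[::-1, ::-1], mode="same")
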