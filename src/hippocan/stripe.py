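"""Stripe-cell 1-D continuous attractor network (CAN).

A ring of rate neurons with purely inhibitory difference-of-Gaussians
coupling spontaneously forms a periodic stripe firing pattern (a 1-D Turing
pattern). Alternating cells carry opposite preferred movement signs; shifting
each cell's inhibitory footprint by a small offset ``k`` toward its preferred
side and modulating the feedforward drive with the velocity projection makes
the pattern flow at a rate proportional to speed along the plate's
orientation. The pattern phase therefore path-integrates displacement along
one direction; a least-squares calibration maps phase (cell units) to meters.

Model
-----
    tau * ds_i/dt + s_i = f( sum_j W_ij s_j + B_i )
    W_ij = A * W0( d(i, j) - k * e_j ),   W0(x) = exp(-g x^2) - exp(-b x^2)
    B_i  = 1 + alpha * e_i * (v . u_theta)

with ``f(x) = max(x, 0)``, ``b = 3 / lam^2``, ``g = 1.035 * b`` (so ``W0 <= 0``
everywhere: all connections inhibitory), ``e_i = +/-1`` alternating with cell
parity, and distances measured on a periodic ring in cell units.

The amplitude ``A`` (``w_amp``, default 10) is a 1-D normalization: inhibition
summed along a single row of cells is an order of magnitude weaker than
summed over a 2-D sheet, and the unit-amplitude kernel is sub-critical on a
ring (no pattern forms). ``A = 10`` puts the most unstable mode at gain
~1.55, comfortably super-critical.

Note the realized stripe period is *not* the kernel parameter ``lam``: the
fastest-growing wavelength of this kernel is about 1.5 lam (30 cells for the
default lam = 20 on a 120-cell ring). :attr:`StripePlate.pattern_period`
exposes the realized period from discrete linear stability; phase readout and
calibration are defined with respect to it.
"""

from __future__ import annotations

from typing import NamedTuple

import numpy as np
from scipy import stats

from .trajectory import TrajectorySeries

__all__ = [
    "StripePlate",
    "build_weight_matrix",
    "most_unstable_period",
    "forward_input",
    "step_dynamics",
    "relax_to_pattern",
    "estimate_phase",
    "PhaseTracker",
    "calibrate_displacement_gain",
    "CalibrationResult",
    "PatternFormationError",
    "UndefinedPhaseError",
    "step_rates",
]


class PatternFormationError(RuntimeError):
    """No stable periodic pattern emerged within the allowed time."""


class UndefinedPhaseError(ValueError):
    """The rate profile is too flat for a population-vector phase."""


def preferred_signs(n_cells: int) -> np.ndarray:
    """Alternating +/-1 preferred-direction signs, +1 on even cells."""
    return np.where(np.arange(n_cells) % 2 == 0, 1.0, -1.0)


def build_weight_matrix(
    n_cells: int, lam: float, k: float, w_amp: float = 10.0
) -> np.ndarray:
    """All-inhibitory recurrent weights with parity-alternating offset.

    ``W[i, j]`` is the weight from cell j to cell i; the center of cell j's
    inhibitory footprint sits ``k`` cells away along j's preferred sign.
    Distances are signed periodic ring distances in cell units.
    """
    if lam <= 0:
        raise ValueError("lam must be positive")
    if k < 0:
        raise ValueError("k must be non-negative")
    if n_cells < 3 * lam:
        raise ValueError("need at least three kernel wavelengths on the ring")
    beta = 3.0 / lam**2
    gamma = 1.035 * beta
    e = preferred_signs(n_cells)
    idx = np.arange(n_cells, dtype=float)
    d = idx[:, None] - idx[None, :] - k * e[None, :]
    d = (d + n_cells / 2.0) % n_cells - n_cells / 2.0
    return w_amp * (np.exp(-gamma * d**2) - np.exp(-beta * d**2))


def most_unstable_period(n_cells: int, lam: float) -> float:
    """Realized pattern period (cells) from discrete linear stability.

    The uniform state destabilizes first at the ring mode whose Fourier gain
    of the (offset-free) kernel is largest; the realized stripe wavelength is
    the ring circumference divided by that mode number (~1.5 lam).
    """
    beta = 3.0 / lam**2
    gamma = 1.035 * beta
    x = (np.arange(n_cells) + n_cells / 2.0) % n_cells - n_cells / 2.0
    w0 = np.exp(-gamma * x**2) - np.exp(-beta * x**2)
    gains = np.fft.rfft(w0).real
    m_star = int(np.argmax(gains[1:]) + 1)
    return n_cells / m_star


class StripePlate:
    """One 1-D stripe-cell continuous attractor ring.

    Parameters
    ----------
    n_cells : ring size (default 120).
    lam : kernel wavelength parameter in cells; ``beta = 3 / lam**2``.
    theta : plate orientation (radians); the plate integrates motion along
        the unit vector ``(cos theta, sin theta)``.
    k : weight offset in cells (small; sets velocity coupling with alpha).
    alpha : velocity gain of the feedforward drive.
    tau : neuron time constant, seconds.
    w_amp : inhibitory kernel amplitude (1-D normalization).
    velocity_scale : multiplies the velocity projection before it enters the
        drive; used to realize different physical periods from one set of
        network parameters (coarser scales use smaller values).
    """

    def __init__(
        self,
        n_cells: int = 120,
        lam: float = 20.0,
        theta: float = 0.0,
        k: float = 1.0,
        alpha: float = 0.35,
        tau: float = 0.005,
        w_amp: float = 10.0,
        velocity_scale: float = 1.0,
    ) -> None:
        self.n_cells = int(n_cells)
        self.lam = float(lam)
        self.theta = float(theta)
        self.k = float(k)
        self.alpha = float(alpha)
        self.tau = float(tau)
        self.w_amp = float(w_amp)
        self.velocity_scale = float(velocity_scale)
        self.weights = build_weight_matrix(self.n_cells, self.lam, self.k, self.w_amp)
        self.signs = preferred_signs(self.n_cells)
        self.rates = np.zeros(self.n_cells)
        self.pattern_period = most_unstable_period(self.n_cells, self.lam)
        self.displacement_gain: float | None = None
        self._formed = False

    @property
    def direction(self) -> np.ndarray:
        return np.array([np.cos(self.theta), np.sin(self.theta)])

    @property
    def physical_period(self) -> float:
        """Stripe spacing L in meters (requires a calibrated gain)."""
        if self.displacement_gain is None:
            raise ValueError("plate has no calibrated displacement gain")
        return abs(self.displacement_gain) * self.pattern_period

    def seed_noise(self, amplitude: float = 0.01, seed: int | None = None) -> None:
        rng = np.random.default_rng(seed)
        self.rates = rng.uniform(0.0, amplitude, self.n_cells)
        self._formed = False

    def copy(self) -> "StripePlate":
        other = StripePlate(
            self.n_cells, self.lam, self.theta, self.k, self.alpha,
            self.tau, self.w_amp, self.velocity_scale,
        )
        other.rates = self.rates.copy()
        other.displacement_gain = self.displacement_gain
        other._formed = self._formed
        return other

    def export_snapshot(self, path) -> None:
        """Write (cell_index, rate) as delimited text."""
        import pandas as pd

        pd.DataFrame({"cell": np.arange(self.n_cells), "rate": self.rates}).to_csv(
            path, index=False, float_format="%.17g"
        )


class StripeDynamicsFFT:
    """Batched CAN stepping via parity-split circular convolution.

    The recurrent weight matrix is two circulant kernels (one per preferred-
    direction parity of the source cell), so ``W @ s`` reduces to two FFT
    convolutions. Numerically identical to the dense product but an order of
    magnitude faster for stacked rate rows; used by the long multi-plate
    pipeline simulations.
    """

    def __init__(self, n_cells: int, lam: float, k: float, w_amp: float, tau: float):
        self.n = int(n_cells)
        self.tau = float(tau)
        beta = 3.0 / lam**2
        gamma = 1.035 * beta
        base = (np.arange(self.n) + self.n / 2.0) % self.n - self.n / 2.0

        def kernel(offset: float) -> np.ndarray:
            d = (base - offset + self.n / 2.0) % self.n - self.n / 2.0
            return w_amp * (np.exp(-gamma * d**2) - np.exp(-beta * d**2))

        self.k_even = np.fft.rfft(kernel(k))     # source cells with e = +1
        self.k_odd = np.fft.rfft(kernel(-k))     # source cells with e = -1
        self.mask_even = (np.arange(self.n) % 2 == 0).astype(float)

    def recurrent(self, S: np.ndarray) -> np.ndarray:
        se = np.fft.rfft(S * self.mask_even, axis=-1)
        so = np.fft.rfft(S * (1.0 - self.mask_even), axis=-1)
        return np.fft.irfft(se * self.k_even + so * self.k_odd, n=self.n, axis=-1)

    def step(self, S: np.ndarray, B: np.ndarray, dt: float) -> np.ndarray:
        return S + (dt / self.tau) * (np.maximum(self.recurrent(S) + B, 0.0) - S)


def step_rates(
    W: np.ndarray, S: np.ndarray, B: np.ndarray, dt: float, tau: float
) -> np.ndarray:
    """One forward-Euler step of the CAN dynamics for stacked rate rows.

    ``S`` and ``B`` may be (n,) or (batch, n); rows evolve independently
    under the shared weight matrix. Rates stay non-negative for dt <= tau
    because the update is a convex blend of the old state and the rectified
    input.
    """
    return S + (dt / tau) * (np.maximum(S @ W.T + B, 0.0) - S)


def forward_input(plate: StripePlate, velocity) -> np.ndarray:
    """Feedforward drive ``B_i = 1 + alpha * e_i * (v . u_theta)``.

    ``velocity`` may be a 2-vector (m/s) or a scalar already projected onto
    the plate's orientation. Zero or orthogonal velocity gives uniform B = 1.
    """
    v = np.asarray(velocity, dtype=float)
    v_proj = float(v @ plate.direction) if v.ndim else float(v)
    v_proj *= plate.velocity_scale
    return 1.0 + plate.alpha * plate.signs * v_proj


def step_dynamics(plate: StripePlate, velocity, dt: float) -> StripePlate:
    """Advance the plate one Euler step; rejects unstable step sizes."""
    if dt > plate.tau / 5.0:
        raise ValueError(
            f"dt = {dt} too large for stability; need dt <= tau/5 = {plate.tau / 5.0}"
        )
    B = forward_input(plate, velocity)
    plate.rates = step_rates(plate.weights, plate.rates, B, dt, plate.tau)
    return plate


def _profile_period(rates: np.ndarray) -> float:
    """Dominant spatial period of a rate profile via the ring spectrum."""
    f = np.abs(np.fft.rfft(rates - rates.mean()))
    if np.all(f[1:] == 0):
        return np.inf
    return len(rates) / (int(np.argmax(f[1:])) + 1)


def relax_to_pattern(
    plate: StripePlate,
    max_duration: float = 1.0,
    noise_amplitude: float = 0.01,
    seed: int | None = None,
    dt: float = 0.001,
    check_interval: float = 0.05,
    settle_tol: float = 0.01,
) -> float:
    """Let the plate form its stripe pattern from small noise, zero velocity.

    Returns the first simulated time (seconds) at which the spatial spectrum
    peaks within 10% of the plate's expected pattern period *and* the profile
    change over the last ``check_interval`` (default 50 ms) has fallen below
    ``settle_tol`` of the peak rate. Raises :class:`PatternFormationError` if
    this does not happen within ``max_duration``.
    """
    plate.seed_noise(noise_amplitude, seed)
    B = forward_input(plate, 0.0)
    n_check = max(int(round(check_interval / dt)), 1)
    n_total = int(round(max_duration / dt))
    prev = plate.rates.copy()
    for i in range(1, n_total + 1):
        plate.rates = step_rates(plate.weights, plate.rates, B, dt, plate.tau)
        if i % n_check == 0:
            period = _profile_period(plate.rates)
            delta = np.max(np.abs(plate.rates - prev)) / (plate.rates.max() + 1e-300)
            prev = plate.rates.copy()
            if abs(period - plate.pattern_period) <= 0.1 * plate.pattern_period and delta < settle_tol:
                plate._formed = True
                return i * dt
    raise PatternFormationError(
        f"no stable period-{plate.pattern_period:g} pattern within {max_duration} s"
    )


def estimate_phase(plate_or_rates, period: float | None = None) -> float:
    """Population-vector phase of the stripe pattern, in cells in [0, period).

    The phase is the argument of ``sum_i s_i exp(2i pi x_i / period)``
    mapped to cell units. A near-flat profile has no defined phase and raises
    :class:`UndefinedPhaseError`.
    """
    if isinstance(plate_or_rates, StripePlate):
        rates = plate_or_rates.rates
        period = plate_or_rates.pattern_period if period is None else period
    else:
        rates = np.asarray(plate_or_rates, dtype=float)
        if period is None:
            raise ValueError("period is required when passing a raw rate vector")
    n = len(rates)
    z = np.sum(rates * np.exp(2j * np.pi * np.arange(n) / period))
    if np.abs(z) < 1e-9 * (1.0 + np.sum(np.abs(rates))):
        raise UndefinedPhaseError("rate profile too flat to define a phase")
    return float((np.angle(z) % (2.0 * np.pi)) * period / (2.0 * np.pi))


class PhaseTracker:
    """Unwraps successive phase samples into a cumulative phase track.

    Nearest-branch continuation: each increment is mapped to
    (-period/2, period/2], so per-sample phase motion must stay below half a
    period (guaranteed by the integration step at realistic speeds).
    """

    def __init__(self, period: float, initial_phase: float = 0.0) -> None:
        self.period = float(period)
        self._prev = float(initial_phase)
        self.cumulative = 0.0

    def update(self, phase: float) -> float:
        d = (phase - self._prev + self.period / 2.0) % self.period - self.period / 2.0
        self.cumulative += d
        self._prev = float(phase)
        return self.cumulative


class CalibrationResult(NamedTuple):
    displacement_gain: float  # meters per cell of phase shift (signed slope)
    r: float                  # |Pearson correlation| of displacement vs phase
    max_residual: float       # max |regression residual| in meters
    phase_track: np.ndarray   # unwrapped phase at trajectory samples (cells)
    displacement: np.ndarray  # true displacement along theta (meters)


def drive_with_trajectory(
    plate: StripePlate,
    traj: TrajectorySeries,
    dt: float = 0.001,
    record_phase: bool = True,
) -> np.ndarray | None:
    """Feed a trajectory's velocities into the plate, phase-tracked.

    The plate must hold a formed pattern. Returns the unwrapped phase track
    at trajectory sample times (cells) when ``record_phase`` is set.
    """
    if not plate._formed:
        relax_to_pattern(plate, dt=dt, seed=0)
    sub = max(int(round(traj.dt / dt)), 1)
    tracker = PhaseTracker(plate.pattern_period, estimate_phase(plate))
    track = np.zeros(len(traj)) if record_phase else None
    vels = traj.velocities
    ev = np.exp(2j * np.pi * np.arange(plate.n_cells) / plate.pattern_period)
    S = plate.rates
    W = plate.weights
    for i in range(len(traj) - 1):
        B = forward_input(plate, vels[i])
        for _ in range(sub):
            S = step_rates(W, S, B, dt, plate.tau)
            tracker.update(
                (np.angle(S @ ev) % (2 * np.pi)) * plate.pattern_period / (2 * np.pi)
            )
        if record_phase:
            track[i + 1] = tracker.cumulative
    plate.rates = S
    return track


def calibrate_displacement_gain(
    plate: StripePlate,
    calibration_traj: TrajectorySeries,
    dt: float = 0.001,
    min_periods: float = 5.0,
) -> CalibrationResult:
    """Least-squares calibration of meters-per-cell from a roam.

    Ordinary least squares of true displacement along the plate's orientation
    against the unwrapped pattern phase. Stores the signed slope on the plate
    as ``displacement_gain`` and reports |r| and the maximum absolute
    residual of the regression line in meters.
    """
    track = drive_with_trajectory(plate, calibration_traj, dt=dt)
    disp = (calibration_traj.positions - calibration_traj.positions[0]) @ plate.direction
    if np.sum(np.abs(np.diff(track))) < min_periods * plate.pattern_period:
        raise ValueError(
            "calibration trajectory too short: needs >= "
            f"{min_periods} pattern periods of motion along the plate direction"
        )
    fit = stats.linregress(track, disp)
    resid = disp - (fit.intercept + fit.slope * track)
    plate.displacement_gain = float(fit.slope)
    return CalibrationResult(
        float(fit.slope), float(abs(fit.rvalue)), float(np.max(np.abs(resid))), track, disp
    )
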