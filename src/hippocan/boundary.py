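"""Boundary cells: wall-band activation, one-shot weight memory, correction.

Each boundary cell d covers one perimeter segment R_d of the arena and fires
(with intensity c) whenever the robot is within the wall-sensing distance of
its segment. On the first visit to a segment the concurrent stripe/grid
firing is memorized as synaptic weights

    W_id = (occupancy-averaged rate of cell i over the visit) / N

with N the number of cells on the plate. On a revisit the remembered
pattern is injected additively into the plate dynamics,

    tau ds_i/dt + s_i = f[ sum_j W_ij s_j + B_i + sum_d W_id B_d ],

which pulls the pattern phase back toward the remembered phase for that
region and thereby cancels accumulated path-integration drift. Drift beyond
half a pattern period is aliased and cannot be corrected toward the true
phase; the memory flags it instead of silently correcting.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .stripe import StripePlate, estimate_phase, forward_input, step_rates
from .trajectory import Arena

__all__ = [
    "BoundaryMemory",
    "activate_boundary_cells",
    "learn_boundary_weights",
    "corrective_step",
]


@dataclass
class BoundaryMemory:
    """Per-region boundary-cell memory for one stripe plate.

    ``weights[d, i]`` is the learned synapse from boundary cell d to plate
    cell i; nonzero only for visited regions.
    """

    arena: Arena
    n_cells: int
    segment_length: float = 1.0
    sensing_distance: float = 0.2
    intensity_c: float = 20.0
    update_on_revisit: bool = False

    def __post_init__(self) -> None:
        self.segments = self.arena.perimeter_segments(self.segment_length)
        self.weights = np.zeros((len(self.segments), self.n_cells))
        self.learned = np.zeros(len(self.segments), dtype=bool)
        self.aliased = np.zeros(len(self.segments), dtype=bool)

    @property
    def n_regions(self) -> int:
        return len(self.segments)

    def export(self, path) -> None:
        """Write learned (region, cell, weight) triples as delimited text."""
        d_idx, i_idx = np.nonzero(self.weights)
        pd.DataFrame(
            {"region": d_idx, "cell": i_idx, "weight": self.weights[d_idx, i_idx]}
        ).to_csv(path, index=False, float_format="%.17g")


def _segment_distances(memory: BoundaryMemory, position: np.ndarray) -> np.ndarray:
    p = np.asarray(position, dtype=float)
    a = memory.segments[:, 0]
    b = memory.segments[:, 1]
    ab = b - a
    denom = np.einsum("ij,ij->i", ab, ab)
    u = np.clip(np.einsum("ij,ij->i", p - a, ab) / np.where(denom == 0, 1, denom), 0, 1)
    c = a + u[:, None] * ab
    return np.linalg.norm(p - c, axis=1)


def activate_boundary_cells(
    position,
    arena: Arena,
    memory: BoundaryMemory,
    sensing_distance: float | None = None,
) -> np.ndarray:
    """Activation vector B_d: intensity c for regions within sensing range."""
    sense = memory.sensing_distance if sensing_distance is None else sensing_distance
    dists = _segment_distances(memory, position)
    return np.where(dists <= sense, memory.intensity_c, 0.0)


def learn_boundary_weights(
    memory: BoundaryMemory,
    region: int,
    cell_rate_samples: np.ndarray,
    plate: StripePlate | None = None,
) -> np.ndarray:
    """Memorize a region's firing snapshot: occupancy-averaged rate / N.

    ``cell_rate_samples`` is (n_samples, n_cells), the plate rates collected
    while inside the region's sensing band. First-visit learning only unless
    the memory was built with ``update_on_revisit``. If a ``plate`` is given,
    a revisit whose current phase is more than half a pattern period away
    from the remembered phase is flagged as aliased.
    """
    samples = np.atleast_2d(np.asarray(cell_rate_samples, dtype=float))
    if samples.size == 0:
        raise ValueError("no rate samples collected for this region")
    if samples.shape[1] != memory.n_cells:
        raise ValueError("rate samples do not match the plate size")
    if memory.learned[region] and not memory.update_on_revisit:
        if plate is not None:
            per = plate.pattern_period
            remembered = estimate_phase(memory.weights[region] * memory.n_cells, per)
            now = estimate_phase(samples.mean(axis=0), per)
            d = (now - remembered + per / 2) % per - per / 2
            memory.aliased[region] = bool(abs(abs(d) - per / 2) < 0.05 * per)
        return memory.weights[region]
    memory.weights[region] = samples.mean(axis=0) / memory.n_cells
    memory.learned[region] = True
    return memory.weights[region]


def corrective_step(
    plate: StripePlate,
    memory: BoundaryMemory,
    activations: np.ndarray,
    velocity,
    dt: float,
) -> StripePlate:
    """One Euler step with the boundary-memory injection term.

    With all activations zero this is bitwise identical to the plain
    dynamics step (the injected term is an exact zero vector). With an
    active, learned region, the additive term ``sum_d W_id B_d`` pulls the
    pattern toward the remembered phase for that region.
    """
    if dt > plate.tau / 5.0:
        raise ValueError("dt too large for stability; need dt <= tau/5")
    activations = np.asarray(activations, dtype=float)
    B = forward_input(plate, velocity) + activations @ memory.weights
    plate.rates = step_rates(plate.weights, plate.rates, B, dt, plate.tau)
    return plate
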