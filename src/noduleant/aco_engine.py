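"""Ant-colony edge detection on the pixel lattice.

Ants walk the 8-connected pixel grid.  The attractiveness of a destination
pixel ``j`` combines the pheromone already deposited there, ``tau(j)``, and
a static heuristic ``eta(j)`` measuring local intensity variation:

    P(i -> j)  proportional to  tau(j)**alpha * eta(j)**beta

over the admissible (in-bounds, not yet visited by this ant) 8-neighbours
of the current pixel ``i``.  Pixels an ant has visited are tabu for that
ant; an ant with no admissible neighbour is respawned at a fresh random
pixel for its remaining steps.  After each construction round the field
evaporates, ``tau <- (1 - rho) * tau``, and every pixel visited during the
round gains ``rho * eta`` per visiting ant.  High accumulated pheromone
marks likely edges; pixels whose pheromone ends above the initial charge
``tau0`` form the final binary edge map.

All randomness comes from one seeded NumPy generator.  Draws occur in a
fixed order — per round, one batch of starting pixels, then per step one
batch of move uniforms followed by respawn positions for dead-ended ants —
so identical seeds give bitwise-identical fields.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace

import numpy as np

from .raster_io import as_gray_raster

__all__ = [
    "AcoParams",
    "default_n_ants",
    "compute_heuristic",
    "run_aco",
    "binarize_pheromone",
    "aco_edges",
]

# 8-neighbourhood offsets in documented, fixed order.
_OFFSETS = np.array(
    [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)],
    dtype=np.int64,
)


def default_n_ants(shape: tuple[int, int]) -> int:
    """Default colony size: sqrt(H*W), rounded."""
    return max(1, round(math.sqrt(shape[0] * shape[1])))


@dataclass(frozen=True)
class AcoParams:
    """Colony configuration.

    alpha weights the pheromone term, beta the heuristic term; rho in (0,1)
    is the per-round evaporation fraction and also scales deposits; tau0 is
    the initial pheromone level.  ``n_ants=None`` resolves to sqrt(H*W) at
    run time.
    """

    n_ants: int | None = None
    n_iterations: int = 10
    steps_per_ant: int = 40
    alpha: float = 1.0
    beta: float = 2.0
    rho: float = 0.1
    tau0: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.rho < 1.0):
            raise ValueError("rho must lie strictly inside (0, 1)")
        if self.tau0 <= 0:
            raise ValueError("tau0 must be > 0")
        if self.alpha < 0 or self.beta < 0:
            raise ValueError("alpha and beta must be >= 0")
        for name in ("n_iterations", "steps_per_ant"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be a positive integer")
        if self.n_ants is not None and self.n_ants < 1:
            raise ValueError("n_ants must be a positive integer")

    def resolved(self, shape: tuple[int, int]) -> "AcoParams":
        """Fill in the image-size-dependent colony size."""
        if self.n_ants is not None:
            return self
        return replace(self, n_ants=default_n_ants(shape))


def compute_heuristic(img: np.ndarray) -> np.ndarray:
    """Normalized local brightness prominence, the ants' static guide.

    For each pixel the raw desirability is the largest amount by which it
    exceeds any of its eight neighbours, ``max_n (I(p) - I(n))`` clamped
    below at 0, with the border replicated.  The field is scaled so its
    maximum is 1; a constant raster yields all zeros.

    The measure is deliberately one-sided: nodules and vessels are
    *bright* structures on a dark parenchyma, and a signed prominence
    puts all desirability on the bright flank of an intensity step.  On a
    thin bright curve (or a binary edge map, the input of the self-feeding
    variants) the support of the field is exactly the foreground pixels —
    a symmetric variation kernel would instead light the pixels on both
    sides of the curve and none on it, and the colony would reconstruct a
    dilated halo rather than the edge itself.
    """
    img = as_gray_raster(img)
    pad = np.pad(img, 1, mode="edge")
    h, w = img.shape

    def sl(dr: int, dc: int) -> np.ndarray:
        return pad[1 + dr : 1 + dr + h, 1 + dc : 1 + dc + w]

    v = np.maximum.reduce(
        [img - sl(dr, dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1) if (dr, dc) != (0, 0)]
    )
    np.clip(v, 0.0, None, out=v)
    vmax = v.max()
    if vmax == 0.0:
        return np.zeros_like(img)
    return v / vmax


def run_aco(
    img: np.ndarray,
    params: AcoParams,
    *,
    check_probabilities: bool = False,
) -> np.ndarray:
    """Accumulate a pheromone field over the raster.

    ``check_probabilities`` enables an internal assertion that every
    sampling step draws from a proper distribution (weights normalizable
    over the admissible neighbours).
    """
    img = as_gray_raster(img)
    h, w = img.shape
    if h < 2 or w < 2:
        raise ValueError("raster must be at least 2x2 for ants to move")
    params = params.resolved(img.shape)
    n = params.n_ants
    eta = compute_heuristic(img)
    eta_flat = eta.ravel()
    tau = np.full(h * w, params.tau0, dtype=np.float64)
    rng = np.random.default_rng(params.seed)
    ants = np.arange(n)

    for _ in range(params.n_iterations):
        visited = np.zeros((n, h * w), dtype=bool)
        pos = rng.integers(0, h * w, size=n)
        visited[ants, pos] = True
        for _ in range(params.steps_per_ant):
            rows, cols = pos // w, pos % w
            nr = rows[:, None] + _OFFSETS[:, 0][None, :]
            nc = cols[:, None] + _OFFSETS[:, 1][None, :]
            inb = (nr >= 0) & (nr < h) & (nc >= 0) & (nc < w)
            nidx = np.where(inb, nr * w + nc, 0)
            admissible = inb & ~visited[ants[:, None], nidx]
            weights = np.where(
                admissible, tau[nidx] ** params.alpha * eta_flat[nidx] ** params.beta, 0.0
            )
            totals = weights.sum(axis=1)
            # All-zero numerators over a non-empty admissible set: uniform.
            flat = (totals == 0.0) & admissible.any(axis=1)
            if flat.any():
                weights[flat] = admissible[flat].astype(np.float64)
                totals = weights.sum(axis=1)
            dead = totals == 0.0
            if check_probabilities and not dead.all():
                live = ~dead
                p = weights[live] / totals[live, None]
                assert np.allclose(p.sum(axis=1), 1.0)
            u = rng.random(n) * totals
            choice = (np.cumsum(weights, axis=1) > u[:, None]).argmax(axis=1)
            new_pos = nidx[ants, choice]
            if dead.any():
                new_pos[dead] = rng.integers(0, h * w, size=int(dead.sum()))
            pos = new_pos
            visited[ants, pos] = True
        tau *= 1.0 - params.rho
        tau += params.rho * eta_flat * visited.sum(axis=0)
    return tau.reshape(h, w)


def binarize_pheromone(field: np.ndarray, tau0: float = 0.1) -> np.ndarray:
    """Threshold a pheromone field into an EdgeMap at the initial charge.

    A pixel is an edge when its accumulated pheromone strictly exceeds
    ``tau0``: over the run, evaporation pulls every pixel below its
    initial level, so ending above it means the colony's reinforcement
    outweighed the decay — the dynamical signature of a repeatedly chosen
    pixel.  The rule needs no new constant and, unlike a histogram split
    of the field, does not let a few heavily travelled structures (long
    vessel-like lines) push the cut above the level of small, lightly
    travelled nodule rings.

    A constant field (no deposits anywhere) has no edges and warns.
    """
    field = np.asarray(field, dtype=np.float64)
    if field.ndim != 2 or not np.all(np.isfinite(field)) or field.min() < 0:
        raise ValueError("pheromone field must be a finite non-negative 2-D array")
    if tau0 <= 0:
        raise ValueError("tau0 must be > 0")
    if field.max() == field.min():
        warnings.warn("constant pheromone field; returning empty edge map", stacklevel=2)
        return np.zeros_like(field, dtype=bool)
    return field > tau0


def aco_edges(img: np.ndarray, params: AcoParams | None = None) -> np.ndarray:
    """Full ant-colony edge detector: heuristic -> pheromone -> binarize."""
    img = as_gray_raster(img)
    if params is None:
        params = AcoParams()
    if np.ptp(img) == 0.0:
        # Constant raster: no heuristic, uniform field, no edges.
        return np.zeros_like(img, dtype=bool)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return binarize_pheromone(run_aco(img, params), tau0=params.tau0)
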