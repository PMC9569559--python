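"""Chemotactic potential and transport velocity on the dual lattice.

The chemotactic mechanism here responds to the *temporal change* of the
chemoattractant rather than its gradient: sprout tips drift with

    vm = grad f,      f = -beta * dc/dt   where dc/dt > 0,   else 0.

While VEGFA rises, dc/dt is largest far from the patch (the spatial factor
grows with distance up to r0), so f is most negative there and grad f
points toward the patch — drift is patch-ward exactly during growth
periods.  While VEGFA falls, f vanishes identically and migration is pure
random motility.

Discretely, f lives on the sub-lattice (cell corners, (i*h, j*h)); the
velocity lives on the main lattice (cell centres) as the average of the
two adjacent difference quotients of f in each direction.  beta enters
once, inside f; the lattice operator is the plain averaged difference
quotient.  Upwind splitting v = v+ - v- (both parts nonnegative, at most
one nonzero) feeds the positivity-preserving scheme.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .vegf_field import VegfParams, concentration_rate

__all__ = [
    "PotentialField",
    "VelocityField",
    "potential",
    "potential_grid",
    "velocity_on_main_lattice",
    "upwind_split",
]


def potential(point, t, params: VegfParams, beta: float):
    """Chemotactic potential f = -beta*dc/dt clamped to rising VEGFA.

    Nonpositive everywhere; identically zero during rest periods.
    """
    ct = concentration_rate(point, t, params)
    return np.where(ct > 0, -beta * ct, 0.0)


@dataclass
class PotentialField:
    """f sampled on the (N+1)x(N+1) sub-lattice at one time step."""

    values: np.ndarray  # shape (N+1, N+1); [i, j] = f(i*h, j*h)
    beta: float
    t: float


def potential_grid(n_cells: int, t: float, params: VegfParams,
                   beta: float) -> PotentialField:
    """Evaluate the potential analytically at every sub-lattice corner."""
    h = 1.0 / n_cells
    coord = np.arange(n_cells + 1) * h
    pts = np.stack(np.meshgrid(coord, coord, indexing="ij"), axis=-1)
    return PotentialField(values=potential(pts, t, params, beta), beta=beta, t=t)


def upwind_split(v):
    """Split a signed velocity component into nonnegative parts.

    Returns (v+, v-) with v+ = max(0, v), v- = max(0, -v); so
    v+ - v- == v and v+ * v- == 0.
    """
    v = np.asarray(v, dtype=float)
    return np.maximum(0.0, v), np.maximum(0.0, -v)


@dataclass
class VelocityField:
    """Transport velocity on the N x N main lattice, with upwind parts."""

    vx: np.ndarray
    vy: np.ndarray
    vx_plus: np.ndarray
    vx_minus: np.ndarray
    vy_plus: np.ndarray
    vy_minus: np.ndarray

    @classmethod
    def from_components(cls, vx: np.ndarray, vy: np.ndarray) -> "VelocityField":
        vxp, vxm = upwind_split(vx)
        vyp, vym = upwind_split(vy)
        return cls(vx, vy, vxp, vxm, vyp, vym)

    @property
    def max_split(self) -> float:
        """Largest split component over all sites and directions."""
        return float(max(self.vx_plus.max(), self.vx_minus.max(),
                         self.vy_plus.max(), self.vy_minus.max()))

    @classmethod
    def zero(cls, n_cells: int) -> "VelocityField":
        z = np.zeros((n_cells, n_cells))
        return cls.from_components(z, z.copy())


def velocity_on_main_lattice(potential_values: np.ndarray,
                             h: float) -> VelocityField:
    """Average-of-two-difference-quotients gradient of f at cell centres.

    ``potential_values`` holds f on the full (N+1)-per-side sub-lattice,
    ``potential_values[i, j] = f(i*h, j*h)``.  For the main-lattice cell
    centred at ((i-1/2)h, (j-1/2)h) the x-component averages the two
    x-difference quotients of f along its lower and upper edges, and
    analogously for y.  Exact for fields linear in x and y.
    """
    f = np.asarray(potential_values, dtype=float)
    if f.ndim != 2 or f.shape[0] != f.shape[1]:
        raise ValueError(f"potential must be square (N+1)x(N+1), got {f.shape}")
    n = f.shape[0] - 1
    if n < 1:
        raise ValueError("need at least a 2x2 sub-lattice")
    if not np.isclose(h * n, 1.0):
        raise ValueError(f"grid spacing h={h} inconsistent with sub-lattice of {n + 1} points")
    dfx = (f[1:, :] - f[:-1, :]) / h        # x-quotients on edges, (N, N+1)
    dfy = (f[:, 1:] - f[:, :-1]) / h        # y-quotients on edges, (N+1, N)
    vx = 0.5 * (dfx[:, 1:] + dfx[:, :-1])   # (N, N)
    vy = 0.5 * (dfy[1:, :] + dfy[:-1, :])   # (N, N)
    return VelocityField.from_components(vx, vy)
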