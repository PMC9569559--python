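"""Positivity- and mass-preserving upwind scheme on a dual lattice.

The sprout-tip density obeys a conservation law

    n_t = -div(-d grad n + n vm)

on the unit square with zero-flux walls.  It is discretised on a dual
lattice: density on cell centres ((i-1/2)h, (j-1/2)h), fluxes on cell
faces.  Advection is upwinded through the split velocity parts, so mass
only flows downwind; diffusive and advective face fluxes vanish on the
domain boundary.  Rearranging the explicit update expresses each new cell
value as a convex combination of the old value and its four neighbours —
a 5-tuple of weights (stay, left, right, down, up) per site that is
nonnegative and sums to one whenever the time step obeys

    tau <= h^2 / (4 (d + h * vhat)),    vhat = max split component.

Those weights double as the movement distribution of the discrete tip
agents, which is what makes the hybrid continuum-discrete simulation
consistent: the continuum solver and the biased random walk share one
stencil.  Both code paths (flux form and probability form) are kept; they
agree to rounding and cross-validate each other.

Array convention: axis 0 is x (index i), axis 1 is y (index j), 0-based
internally; site (i, j) in 1-based lattice coordinates is element
[i-1, j-1].  Cell centres are ((i-1/2)h, (j-1/2)h).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .chemotaxis import VelocityField

__all__ = [
    "DualLattice",
    "DensityField",
    "TransitionProbabilities",
    "StabilityError",
    "advective_flux",
    "total_flux",
    "stable_timestep",
    "transition_probabilities",
    "density_step",
    "density_step_flux",
]


class StabilityError(ValueError):
    """Time step violates the stability bound; weights would go negative."""


@dataclass(frozen=True)
class DualLattice:
    """Main lattice of N x N cell centres plus corner sub-lattice, h = 1/N."""

    n_cells: int

    def __post_init__(self) -> None:
        if self.n_cells < 2:
            raise ValueError("need at least 2 cells per side")

    @property
    def h(self) -> float:
        return 1.0 / self.n_cells

    def site_center(self, i: int, j: int) -> tuple[float, float]:
        """Physical centre of main-lattice site (i, j), 0-based indices."""
        return ((i + 0.5) * self.h, (j + 0.5) * self.h)

    def site_centers(self) -> np.ndarray:
        """(N, N, 2) array of all cell-centre coordinates."""
        c = (np.arange(self.n_cells) + 0.5) * self.h
        return np.stack(np.meshgrid(c, c, indexing="ij"), axis=-1)

    def sub_points(self) -> np.ndarray:
        """(N+1, N+1, 2) array of corner coordinates (i*h, j*h)."""
        c = np.arange(self.n_cells + 1) * self.h
        return np.stack(np.meshgrid(c, c, indexing="ij"), axis=-1)


@dataclass
class DensityField:
    """Sprout-tip density n on the main lattice at time t."""

    values: np.ndarray
    t: float = 0.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("density must be a 2-D main-lattice array")
        if np.any(self.values < 0):
            raise ValueError("density must be nonnegative")

    def mass(self) -> float:
        """Total mass sum(n) * h^2 with h inferred from the array side."""
        h = 1.0 / self.values.shape[0]
        return float(self.values.sum() * h * h)

    def to_csv(self, path) -> None:
        n = self.values.shape[0]
        df = pd.DataFrame(self.values,
                          index=pd.RangeIndex(1, n + 1, name="i"),
                          columns=pd.RangeIndex(1, n + 1, name="j"))
        df.to_csv(path)

    @classmethod
    def from_csv(cls, path, t: float = 0.0) -> "DensityField":
        df = pd.read_csv(path, index_col=0)
        return cls(df.to_numpy(dtype=float), t=t)


def _check_shapes(n: np.ndarray, vel: VelocityField) -> int:
    if n.shape != vel.vx.shape or n.shape != vel.vy.shape:
        raise ValueError(
            f"density {n.shape} and velocity {vel.vx.shape} shapes differ")
    return n.shape[0]


def advective_flux(n: np.ndarray, vel: VelocityField) -> tuple[np.ndarray, np.ndarray]:
    """Upwind advective flux G on interior faces.

    Returns (Gx, Gy) with Gx of shape (N-1, N) on vertical interior faces
    (Gx[i] sits between cell columns i and i+1) and Gy of shape (N, N-1)
    on horizontal interior faces.  Mass leaves a cell only in the
    direction of its own velocity part.
    """
    n = np.asarray(n, dtype=float)
    _check_shapes(n, vel)
    gx = n[:-1, :] * vel.vx_plus[:-1, :] - n[1:, :] * vel.vx_minus[1:, :]
    gy = n[:, :-1] * vel.vy_plus[:, :-1] - n[:, 1:] * vel.vy_minus[:, 1:]
    return gx, gy


def total_flux(n: np.ndarray, g: tuple[np.ndarray, np.ndarray], d: float,
               h: float) -> tuple[np.ndarray, np.ndarray]:
    """Total face flux F = -d*grad n + G with zero-flux boundary closure.

    Returns (Fx, Fy); Fx has shape (N+1, N) including the boundary faces
    Fx[0] = Fx[N] = 0, and analogously Fy of shape (N, N+1).
    """
    if d < 0:
        raise ValueError("motility d must be >= 0")
    n = np.asarray(n, dtype=float)
    gx, gy = g
    nn = n.shape[0]
    fx = np.zeros((nn + 1, n.shape[1]))
    fy = np.zeros((n.shape[0], nn + 1))
    fx[1:-1, :] = -d * (n[1:, :] - n[:-1, :]) / h + gx
    fy[:, 1:-1] = -d * (n[:, 1:] - n[:, :-1]) / h + gy
    return fx, fy


def stable_timestep(d: float, h: float, vel: VelocityField,
                    safety: float = 0.9) -> float:
    """Largest admissible time step times a safety factor.

    tau = safety * h^2 / (4 (d + h * vhat)) with vhat the maximum split
    velocity component over all sites.  The strict safety < 1 keeps the
    stay weight positive at the stability edge.
    """
    if not 0 < safety <= 1:
        raise ValueError("safety factor must lie in (0, 1]")
    if d < 0:
        raise ValueError("motility d must be >= 0")
    vhat = vel.max_split
    if d == 0 and vhat == 0:
        raise StabilityError("no dynamics: d = 0 and velocity vanishes")
    return safety * h * h / (4.0 * (d + h * vhat))


@dataclass
class TransitionProbabilities:
    """Per-site 5-tuple (stay, left, right, down, up) of movement weights.

    Derived from the scheme stencil after re-indexing each weight to the
    site the mover occupies.  Wall-facing moves at boundary sites are
    folded into ``stay`` — the probabilistic counterpart of the zero-flux
    closure — so every tuple is a probability distribution.
    """

    stay: np.ndarray
    left: np.ndarray
    right: np.ndarray
    down: np.ndarray
    up: np.ndarray
    tau: float

    def at(self, i: int, j: int) -> tuple[float, float, float, float, float]:
        """The 5-tuple at 0-based site (i, j)."""
        return (float(self.stay[i, j]), float(self.left[i, j]),
                float(self.right[i, j]), float(self.down[i, j]),
                float(self.up[i, j]))

    def total(self) -> np.ndarray:
        return self.stay + self.left + self.right + self.down + self.up

    def validate(self, atol: float = 1e-12) -> None:
        for name in ("stay", "left", "right", "down", "up"):
            arr = getattr(self, name)
            if arr.min() < -atol:
                raise StabilityError(
                    f"negative {name} probability {arr.min():.3e}; "
                    "time step violates the stability bound")
        err = np.abs(self.total() - 1.0).max()
        if err > 1e-9:
            raise StabilityError(f"probabilities do not normalise (err={err:.3e})")


def transition_probabilities(vel: VelocityField, d: float, h: float,
                             tau: float) -> TransitionProbabilities:
    """Movement weights for every main-lattice site at one time step.

    Interior sites: stay = 1 - 4 d tau/h^2 - (tau/h) * (sum of the site's
    four split components); each directed move = d tau/h^2 + (tau/h) times
    the site's own split component in that direction.  Boundary sites
    redirect the wall-facing move into stay (reflecting closure).
    Raises :class:`StabilityError` if any weight would be negative.
    """
    diff = d * tau / (h * h)
    adv = tau / h
    left = diff + adv * vel.vx_minus
    right = diff + adv * vel.vx_plus
    down = diff + adv * vel.vy_minus
    up = diff + adv * vel.vy_plus
    # Zero-flux walls: no move through the boundary.
    left[0, :] = 0.0
    right[-1, :] = 0.0
    down[:, 0] = 0.0
    up[:, -1] = 0.0
    stay = 1.0 - (left + right + down + up)
    probs = TransitionProbabilities(stay, left, right, down, up, tau)
    probs.validate()
    return probs


def density_step(n: DensityField, probs: TransitionProbabilities) -> DensityField:
    """One explicit step via the probability stencil.

    Each cell redistributes its mass by its own 5-tuple; the new value at
    a site collects the stay share plus the inbound shares of its four
    neighbours.  Conserves total mass and nonnegativity by construction.
    """
    v = n.values
    if v.shape != probs.stay.shape:
        raise ValueError("density and probability shapes differ")
    out = v * probs.stay
    out[:-1, :] += v[1:, :] * probs.left[1:, :]
    out[1:, :] += v[:-1, :] * probs.right[:-1, :]
    out[:, :-1] += v[:, 1:] * probs.down[:, 1:]
    out[:, 1:] += v[:, :-1] * probs.up[:, :-1]
    return DensityField(out, t=n.t + probs.tau)


def density_step_flux(n: DensityField, vel: VelocityField, d: float,
                      h: float, tau: float) -> DensityField:
    """One explicit step in conservative flux form (independent code path).

    n_new = n - (tau/h) * (divergence of the total face flux).  Used to
    cross-validate :func:`density_step`; both derive from the same scheme
    so they agree to rounding.
    """
    v = n.values
    _check_shapes(v, vel)
    fx, fy = total_flux(v, advective_flux(v, vel), d, h)
    out = v - (tau / h) * (fx[1:, :] - fx[:-1, :] + fy[:, 1:] - fy[:, :-1])
    out = np.where(np.abs(out) < 1e-300, 0.0, out)  # flush denormals
    if out.min() < -1e-12:
        raise StabilityError("flux-form step produced negative density")
    return DensityField(np.maximum(out, 0.0), t=n.t + tau)
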