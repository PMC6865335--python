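"""Core coupled-map lattice: state, per-iteration operators, synchronous step.

The model tracks two normalized population fields on a regular square
lattice: ``s`` (sensitive strain) and ``a`` (antagonistic strain), both
scaled to the local carrying capacity so 1.0 means saturation.  Each
iteration applies, synchronously from a frozen copy of the state,

* logistic Lotka-Volterra growth within every compartment, with the
  sensitive growth rate additionally suppressed by a Hill-type function of
  the antagonist density in the 3x3 neighborhood (half-inhibition constant
  ``K_a``, exponent ``hill_n``),
* diffusion: a fraction ``D`` of each population leaves its compartment and
  is distributed to the 8 neighbors (1/6 to each cardinal, 1/12 to each
  diagonal neighbor).

One iteration is the unit of time; the rates r and D absorb the implicit
time step, which is why they must be small for the map to approximate the
underlying continuous competition-diffusion dynamics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = [
    "ModelParams",
    "LatticeState",
    "IterationDeltas",
    "NEIGHBORHOOD_KERNEL",
    "DIFFUSION_KERNEL",
    "neighborhood_antagonist_density",
    "sensitive_growth",
    "antagonist_growth",
    "diffusion_outflow",
    "diffusion_inflow",
    "compute_deltas",
    "step",
    "SimulationError",
]

#: Weights of the antagonist neighborhood average: self 1/2, cardinal 1/12,
#: diagonal 1/24.  Sums to exactly 1.0 (integer numerators over 24).
NEIGHBORHOOD_KERNEL = np.array(
    [[1, 2, 1], [2, 12, 2], [1, 2, 1]], dtype=float
) / 24.0

#: Redistribution weights of diffusing mass: 1/6 to each cardinal neighbor,
#: 1/12 to each diagonal neighbor, nothing retained.  Sums to exactly 1.0.
DIFFUSION_KERNEL = np.array(
    [[1, 2, 1], [2, 0, 2], [1, 2, 1]], dtype=float
) / 12.0

_BOUNDARY_MODES = {"periodic": "wrap", "absorbing": "constant"}

#: Magnitude below which a negative compartment value is treated as float
#: noise and clamped to zero; anything larger signals an invalid parameter
#: regime and raises.
NEGATIVE_TOLERANCE = 1e-12


class SimulationError(RuntimeError):
    """A lattice update left the model's domain of validity."""

    def __init__(self, message: str, iteration: int | None = None):
        super().__init__(message)
        self.iteration = iteration


@dataclass(frozen=True)
class ModelParams:
    """Rate and interaction constants of the two-strain lattice model.

    Parameters
    ----------
    r_s, r_a
        Intrinsic per-iteration growth rates of the sensitive and
        antagonistic strains.  Must lie in (0, 0.5]; values above 0.2 leave
        the regime where the map approximates continuous dynamics and
        trigger a warning.
    D_s, D_a
        Fractions of each population diffusing out of a compartment per
        iteration, in [0, 0.5].
    K_a
        Neighborhood antagonist density at which the sensitive growth rate
        is halved.
    hill_n
        Exponent of the inhibition function (steepness), >= 1.
    alpha, beta
        Lotka-Volterra competition coefficients: ``alpha`` scales the
        effect of antagonists on sensitive growth, ``beta`` the reverse.
        The default 1.5 puts symmetric competition in the bistable
        mutual-exclusion regime, which produces the sharp single-strain
        patches characteristic of mixed colonies.
    """

    r_s: float = 0.1
    r_a: float = 0.1
    D_s: float = 0.01
    D_a: float = 0.01
    K_a: float = 0.08
    hill_n: float = 4.0
    alpha: float = 1.5
    beta: float = 1.5

    def __post_init__(self) -> None:
        # 0 is admitted for the growth rates as the degenerate
        # pure-diffusion case used in conservation diagnostics.
        for name in ("r_s", "r_a"):
            v = getattr(self, name)
            if not (0.0 <= v <= 0.5):
                raise ValueError(f"{name} must be in [0, 0.5], got {v}")
        for name in ("D_s", "D_a"):
            v = getattr(self, name)
            if not (0.0 <= v <= 0.5):
                raise ValueError(f"{name} must be in [0, 0.5], got {v}")
        large = [
            n for n in ("r_s", "r_a", "D_s", "D_a") if getattr(self, n) > 0.2
        ]
        if large:
            warnings.warn(
                f"{', '.join(large)} > 0.2: the discrete map no longer "
                "approximates the continuous competition-diffusion dynamics",
                stacklevel=2,
            )
        if self.K_a <= 0:
            raise ValueError(f"K_a must be positive, got {self.K_a}")
        if self.alpha < 0 or self.beta < 0:
            raise ValueError("alpha and beta must be nonnegative")
        if self.hill_n < 1:
            raise ValueError(f"hill_n must be >= 1, got {self.hill_n}")


@dataclass
class LatticeState:
    """Paired sensitive/antagonist population grids plus boundary convention.

    ``boundary`` is ``"periodic"`` (edges wrap, every compartment has 8
    neighbors) or ``"absorbing"`` (mass diffusing across the edge is lost).
    """

    s: np.ndarray
    a: np.ndarray
    boundary: str = "periodic"

    def __post_init__(self) -> None:
        self.s = np.asarray(self.s, dtype=float)
        self.a = np.asarray(self.a, dtype=float)
        if self.s.ndim != 2 or self.s.shape != self.a.shape:
            raise ValueError(
                f"s and a must be 2-D grids of identical shape, got "
                f"{self.s.shape} and {self.a.shape}"
            )
        if self.boundary not in _BOUNDARY_MODES:
            raise ValueError(
                f"boundary must be one of {sorted(_BOUNDARY_MODES)}, "
                f"got {self.boundary!r}"
            )
        for name, g in (("s", self.s), ("a", self.a)):
            if not np.all(np.isfinite(g)):
                raise ValueError(f"{name} grid contains non-finite values")
            if np.any(g < 0):
                raise ValueError(f"{name} grid contains negative values")

    @property
    def shape(self) -> tuple[int, int]:
        return self.s.shape

    def copy(self) -> "LatticeState":
        return LatticeState(self.s.copy(), self.a.copy(), self.boundary)

    def totals(self) -> tuple[float, float]:
        """Total sensitive and antagonist populations (S, A)."""
        return float(self.s.sum()), float(self.a.sum())


@dataclass
class IterationDeltas:
    """All per-compartment increments of one synchronous iteration."""

    growth_s: np.ndarray
    growth_a: np.ndarray
    out_s: np.ndarray
    out_a: np.ndarray
    in_s: np.ndarray
    in_a: np.ndarray


def _check_grid_for_kernel(grid: np.ndarray, boundary: str) -> None:
    if boundary not in _BOUNDARY_MODES:
        raise ValueError(f"unknown boundary convention {boundary!r}")
    if boundary == "periodic" and min(grid.shape) < 3:
        raise ValueError(
            "periodic neighborhoods need every lattice dimension >= 3 "
            f"(got shape {grid.shape}): a dimension of 1 or 2 would make a "
            "compartment its own neighbor under wraparound"
        )


def neighborhood_antagonist_density(
    a: np.ndarray, boundary: str = "periodic"
) -> np.ndarray:
    """Weighted antagonist density over a compartment and its 8 neighbors.

    Weights: self 1/2, each cardinal neighbor 1/12, each diagonal neighbor
    1/24; they sum to 1, so a spatially uniform field maps to itself.
    Under absorbing boundaries, out-of-lattice neighbors contribute zero.
    """
    a = np.asarray(a, dtype=float)
    _check_grid_for_kernel(a, boundary)
    return ndimage.convolve(
        a, NEIGHBORHOOD_KERNEL, mode=_BOUNDARY_MODES[boundary], cval=0.0
    )


def sensitive_growth(
    s: np.ndarray, a: np.ndarray, n_a: np.ndarray, params: ModelParams
) -> np.ndarray:
    """Per-compartment sensitive reproduction in one iteration.

    Logistic Lotka-Volterra growth whose rate is suppressed by neighborhood
    antagonists through a Hill function:

        ds+ = r_s / (1 + (N_a/K_a)^hill_n) * (1 - s - alpha*a) * s

    The increment is negative where ``s + alpha*a > 1`` (overshoot
    correction) and identically zero where ``s`` is zero.
    """
    s = np.asarray(s, dtype=float)
    a = np.asarray(a, dtype=float)
    n_a = np.asarray(n_a, dtype=float)
    if not (s.shape == a.shape == n_a.shape):
        raise ValueError("s, a and n_a must share a shape")
    rate = params.r_s / (1.0 + (n_a / params.K_a) ** params.hill_n)
    return rate * (1.0 - s - params.alpha * a) * s


def antagonist_growth(
    s: np.ndarray, a: np.ndarray, params: ModelParams
) -> np.ndarray:
    """Per-compartment antagonist reproduction in one iteration.

        da+ = r_a * (1 - a - beta*s) * a

    Unlike the sensitive strain, antagonist growth is not inhibited by
    neighborhood densities.
    """
    s = np.asarray(s, dtype=float)
    a = np.asarray(a, dtype=float)
    if s.shape != a.shape:
        raise ValueError("s and a must share a shape")
    return params.r_a * (1.0 - a - params.beta * s) * a


def diffusion_outflow(x: np.ndarray, d: float) -> np.ndarray:
    """Mass leaving each compartment in one iteration: ``d * x``."""
    if d < 0:
        raise ValueError(f"diffusion fraction must be nonnegative, got {d}")
    return d * np.asarray(x, dtype=float)


def diffusion_inflow(outflow: np.ndarray, boundary: str = "periodic") -> np.ndarray:
    """Redistribute outflows to neighbors (1/6 cardinal, 1/12 diagonal).

    The kernel is symmetric, so the inflow at a compartment is the same
    weighted sum of its neighbors' outflows.  Under periodic boundaries the
    total inflow equals the total outflow; under absorbing boundaries the
    share sent across the lattice edge is lost.
    """
    outflow = np.asarray(outflow, dtype=float)
    _check_grid_for_kernel(outflow, boundary)
    return ndimage.convolve(
        outflow, DIFFUSION_KERNEL, mode=_BOUNDARY_MODES[boundary], cval=0.0
    )


def compute_deltas(state: LatticeState, params: ModelParams) -> IterationDeltas:
    """Evaluate every increment of one iteration from the frozen state."""
    n_a = neighborhood_antagonist_density(state.a, state.boundary)
    out_s = diffusion_outflow(state.s, params.D_s)
    out_a = diffusion_outflow(state.a, params.D_a)
    return IterationDeltas(
        growth_s=sensitive_growth(state.s, state.a, n_a, params),
        growth_a=antagonist_growth(state.s, state.a, params),
        out_s=out_s,
        out_a=out_a,
        in_s=diffusion_inflow(out_s, state.boundary),
        in_a=diffusion_inflow(out_a, state.boundary),
    )


def _apply(x: np.ndarray, growth: np.ndarray, out: np.ndarray,
           inflow: np.ndarray, label: str) -> np.ndarray:
    new = x + growth - out + inflow
    low = new.min()
    if low < -NEGATIVE_TOLERANCE:
        raise SimulationError(
            f"{label} grid went negative ({low:.3e}): parameter regime is "
            "outside the model's domain of validity"
        )
    if low < 0.0:
        new = np.where(new < 0.0, 0.0, new)
    return new


def step(state: LatticeState, params: ModelParams) -> LatticeState:
    """One synchronous iteration: growth, outflow and inflow are all
    computed from the current state, then applied at once.

    Pure function: identical inputs give bit-identical outputs.  Negative
    values within ``NEGATIVE_TOLERANCE`` of zero are clamped (float noise);
    larger violations raise :class:`SimulationError`.
    """
    d = compute_deltas(state, params)
    new_s = _apply(state.s, d.growth_s, d.out_s, d.in_s, "sensitive")
    new_a = _apply(state.a, d.growth_a, d.out_a, d.in_a, "antagonist")
    return LatticeState(new_s, new_a, state.boundary)
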