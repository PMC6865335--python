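"""Summary statistics on simulation output.

sigma (sensitive population fraction), scalar and directional colony radii,
qualitative outcome labels, linear front-growth fits and dose-response
midpoint extraction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize

from .experiments import SimulationResult, SweepResult
from .lattice import LatticeState

__all__ = [
    "OutcomeLabel",
    "DoseResponseFit",
    "LinearGrowthFit",
    "sensitive_fraction",
    "colony_radius",
    "directional_radius",
    "classify_sigma",
    "classify_outcome",
    "fit_dose_response",
    "fit_linear_growth",
]


@dataclass(frozen=True)
class OutcomeLabel:
    """Qualitative colony outcome from the final sensitive fraction.

    ``sensitive_dominant`` iff sigma >= high threshold,
    ``antagonist_dominant`` iff sigma <= low threshold, ``mixed`` otherwise.
    The (0.1, 0.9) defaults are a convention of this package; the source
    observations classify colonies by visual morphology.
    """

    label: str
    sigma_final: float
    thresholds: tuple[float, float]


@dataclass(frozen=True)
class DoseResponseFit:
    """Two-parameter decreasing logistic fit sigma(rho) = 1/(1+(rho/rho50)^h).

    A pragmatic midpoint extractor, not a mechanistic claim.  ``degenerate``
    flags inputs with no transition to fit (fewer than 4 distinct rho, mean
    sigma not spanning 0.5, or a failed optimizer); parameters are NaN then.
    """

    rho50: float
    h: float
    rss: float
    degenerate: bool = False
    message: str = ""


@dataclass(frozen=True)
class LinearGrowthFit:
    """Least-squares line through (iteration, radius) over a window."""

    slope: float
    intercept: float
    r_squared: float
    window: tuple[int, int]
    n_points: int


def sensitive_fraction(state: LatticeState) -> float:
    """sigma = S / (S + A).  Raises on an empty lattice."""
    S, A = state.totals()
    if S + A <= 0:
        raise ValueError("empty lattice: sensitive fraction undefined")
    return S / (S + A)


def colony_radius(grid: np.ndarray, threshold: float = 0.5) -> float:
    """Area-equivalent radius: sqrt(n/pi) with n the compartments >= threshold.

    Rotation- and translation-robust on a lattice, unlike ray casting.
    """
    if not (0.0 < threshold < 1.0):
        raise ValueError("threshold must be in (0, 1)")
    n_above = int(np.count_nonzero(np.asarray(grid) >= threshold))
    return float(np.sqrt(n_above / np.pi))


def directional_radius(
    grid: np.ndarray,
    origin: tuple[int, int],
    direction: tuple[int, int],
    threshold: float = 0.5,
    boundary: str = "absorbing",
    max_steps: int | None = None,
) -> float:
    """Distance from ``origin`` to the farthest above-threshold compartment
    along an axis-aligned ray.

    Returns 0 when the origin itself is below threshold.  Rays truncate at
    an absorbing lattice edge (or after ``max_steps`` compartments, used to
    restrict a scan to the territory of one colony); periodic lattices are
    rejected because a ray has no endpoint under wraparound.
    """
    if boundary == "periodic":
        raise ValueError("directional radius is ill-defined on a periodic lattice")
    grid = np.asarray(grid)
    dr, dc = direction
    if sorted((abs(dr), abs(dc))) != [0, 1]:
        raise ValueError("direction must be a unit axis vector")
    r, c = origin
    if not (0 <= r < grid.shape[0] and 0 <= c < grid.shape[1]):
        raise ValueError("origin lies outside the lattice")
    if grid[r, c] < threshold:
        return 0.0
    last = 0
    t = 0
    while max_steps is None or t < max_steps:
        t += 1
        rr, cc = r + t * dr, c + t * dc
        if not (0 <= rr < grid.shape[0] and 0 <= cc < grid.shape[1]):
            break
        if grid[rr, cc] >= threshold:
            last = t
    return float(last)


def classify_sigma(
    sigma: float, thresholds: tuple[float, float] = (0.1, 0.9)
) -> OutcomeLabel:
    low, high = thresholds
    if not low < high:
        raise ValueError("thresholds must satisfy low < high")
    if sigma >= high:
        label = "sensitive_dominant"
    elif sigma <= low:
        label = "antagonist_dominant"
    else:
        label = "mixed"
    return OutcomeLabel(label=label, sigma_final=float(sigma), thresholds=(low, high))


def classify_outcome(
    result: SimulationResult, thresholds: tuple[float, float] = (0.1, 0.9)
) -> OutcomeLabel:
    """Label a finished run by its final sigma (see :class:`OutcomeLabel`)."""
    return classify_sigma(result.final_sigma, thresholds)


def _logistic(rho: np.ndarray, rho50: float, h: float) -> np.ndarray:
    return 1.0 / (1.0 + (rho / rho50) ** h)


def fit_dose_response(
    sweep: SweepResult | tuple[np.ndarray, np.ndarray],
) -> DoseResponseFit:
    """Fit the decreasing logistic to (rho, mean sigma) and report rho50.

    Accepts a :class:`~colonycml.experiments.SweepResult` or a bare
    ``(rho_values, mean_sigma)`` pair.  Initializer: rho50 = median rho,
    h = 2; both parameters constrained positive.  Degenerate inputs or a
    failed optimization return a flagged fit instead of raising.
    """
    if isinstance(sweep, SweepResult):
        rho = np.asarray(sweep.rho_values, dtype=float)
        sig = np.asarray(sweep.mean_sigma, dtype=float)
    else:
        rho, sig = (np.asarray(v, dtype=float) for v in sweep)
    order = np.argsort(rho)
    rho, sig = rho[order], sig[order]

    def degenerate(msg: str) -> DoseResponseFit:
        return DoseResponseFit(
            rho50=float("nan"), h=float("nan"), rss=float("nan"),
            degenerate=True, message=msg,
        )

    if len(np.unique(rho)) < 4:
        return degenerate("fewer than 4 distinct rho values")
    if np.all(rho <= 0):
        return degenerate("rho values must be positive for a logistic in rho")
    if sig.min() >= 0.5 or sig.max() <= 0.5:
        return degenerate("mean sigma does not span 0.5: no transition to fit")

    def residuals(p: np.ndarray) -> np.ndarray:
        return _logistic(rho, p[0], p[1]) - sig

    try:
        res = optimize.least_squares(
            residuals,
            x0=[float(np.median(rho)), 2.0],
            bounds=([1e-12, 1e-12], [np.inf, np.inf]),
        )
    except Exception as exc:  # pragma: no cover - optimizer edge cases
        return degenerate(f"optimizer failure: {exc}")
    if not res.success:
        return degenerate(f"optimizer did not converge: {res.message}")
    rss = float(np.sum(res.fun**2))
    return DoseResponseFit(rho50=float(res.x[0]), h=float(res.x[1]), rss=rss)


def fit_linear_growth(
    iterations: np.ndarray,
    radii: np.ndarray,
    window: tuple[int, int] = (100, 400),
) -> LinearGrowthFit:
    """Fit radius = slope * iteration + intercept over an iteration window.

    Used to check that an unobstructed colony front advances at constant
    speed once the initial transient has passed.
    """
    iterations = np.asarray(iterations, dtype=float)
    radii = np.asarray(radii, dtype=float)
    lo, hi = window
    mask = (iterations >= lo) & (iterations <= hi)
    if mask.sum() < 3:
        raise ValueError("fewer than 3 points inside the fit window")
    x, y = iterations[mask], radii[mask]
    slope, intercept = np.polyfit(x, y, 1)
    pred = slope * x + intercept
    ss_res = float(np.sum((y - pred) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")
    return LinearGrowthFit(
        slope=float(slope),
        intercept=float(intercept),
        r_squared=r2,
        window=(lo, hi),
        n_points=int(mask.sum()),
    )
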