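"""Experiment drivers: inocula, single runs, ensemble sweeps, colony pairs.

The three in-silico protocols mirror the plate experiments they abstract:

* **mixed colony** — a diluted two-strain inoculum in a small disk at the
  lattice center, grown for a fixed number of iterations; the readout is
  the sensitive population fraction sigma = S / (S + A);
* **sweep over rho** — ensembles of mixed-colony runs across initial
  antagonist proportions, with a paired "resistant" condition in which the
  presence of a resistant strain is modeled as a uniform reduction of the
  antagonist growth rate;
* **single colony / two colonies** — saturated pure-strain disks used to
  measure radial expansion, and the asymmetry a colony develops when it
  grows next to a neighbor (difference between external and internal
  radii).
"""

from __future__ import annotations

import dataclasses
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .lattice import LatticeState, ModelParams, SimulationError, step

logger = logging.getLogger("colonycml")

__all__ = [
    "InoculumSpec",
    "SimulationResult",
    "SweepResult",
    "TwoColonyResult",
    "disk_compartments",
    "init_mixed_colony",
    "init_single_colony",
    "run",
    "sweep_rho",
    "resistant_mode",
    "two_colony_run",
]


@dataclass(frozen=True)
class InoculumSpec:
    """Geometry and stochastic description of an initial colony.

    ``kind`` selects between the stochastic two-strain mixture
    (``"mixed"``: s ~ U[0, s_max], a ~ U[0, s_max * rho] inside the disk,
    emulating a diluted inoculum) and deterministic saturated disks of a
    single strain (``"pure_sensitive"`` / ``"pure_antagonist"``: the chosen
    layer set to 1 inside the disk).

    ``center=None`` places the disk at the lattice center
    (rows // 2, cols // 2).  Disk membership is Euclidean distance between
    compartment centers <= radius, ties included.
    """

    radius: float = 5.0
    kind: str = "mixed"
    center: tuple[int, int] | None = None
    s_max: float = 0.2
    rho: float = 0.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.radius < 1:
            raise ValueError(f"radius must be >= 1, got {self.radius}")
        if self.rho < 0:
            raise ValueError(f"rho must be nonnegative, got {self.rho}")
        if not (0.0 < self.s_max <= 1.0):
            raise ValueError(f"s_max must be in (0, 1], got {self.s_max}")
        if self.kind not in ("mixed", "pure_sensitive", "pure_antagonist"):
            raise ValueError(f"unknown inoculum kind {self.kind!r}")


@dataclass
class SimulationResult:
    """Recorded trajectory of one simulation.

    ``totals`` has columns ``iteration, S, A, sigma`` where S and A are the
    summed sensitive/antagonist populations and sigma = S / (S + A) (NaN on
    an empty lattice).  ``snapshots`` holds (iteration, LatticeState) pairs
    at the requested cadence; ``final_state`` is the state after the last
    iteration.
    """

    totals: pd.DataFrame
    snapshots: list[tuple[int, LatticeState]]
    params_used: ModelParams
    init_used: InoculumSpec | None
    n_iterations: int
    final_state: LatticeState

    @property
    def final_sigma(self) -> float:
        return float(self.totals["sigma"].iloc[-1])


@dataclass
class SweepResult:
    """Final sigma values of an ensemble sweep over initial proportions.

    ``final_sigma`` and ``seeds`` are (n_rho, replicates) matrices; row
    order follows ``rho_values`` as given.  Every cell is independently
    reproducible from its recorded seed.
    """

    rho_values: list[float]
    replicates: int
    final_sigma: np.ndarray
    seeds: np.ndarray
    condition_label: str
    mean_sigma: np.ndarray = field(init=False)
    sd_sigma: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.mean_sigma = self.final_sigma.mean(axis=1)
        if self.replicates > 1:
            self.sd_sigma = self.final_sigma.std(axis=1, ddof=1)
        else:
            self.sd_sigma = np.full(len(self.rho_values), np.nan)

    def to_frame(self) -> pd.DataFrame:
        """Tidy per-replicate table: condition, rho, replicate, seed, final_sigma."""
        records = []
        for i, rho in enumerate(self.rho_values):
            for k in range(self.replicates):
                records.append(
                    (self.condition_label, rho, k, int(self.seeds[i, k]),
                     self.final_sigma[i, k])
                )
        return pd.DataFrame(
            records,
            columns=["condition", "rho", "replicate", "seed", "final_sigma"],
        )

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "condition": self.condition_label,
                "rho": self.rho_values,
                "mean_sigma": self.mean_sigma,
                "sd_sigma": self.sd_sigma,
                "n": self.replicates,
            }
        )


def disk_compartments(
    lattice_shape: tuple[int, int],
    center: tuple[int, int],
    radius: float,
    boundary: str = "periodic",
) -> tuple[np.ndarray, np.ndarray]:
    """Row/col index arrays of compartments within ``radius`` of ``center``.

    Coordinates are returned in row-major order.  A disk that extends past
    the lattice edge raises under absorbing boundaries and wraps (with a
    warning) under periodic ones.
    """
    rows, cols = lattice_shape
    cr, cc = center
    r_int = int(np.floor(radius))
    offs = np.arange(-r_int, r_int + 1)
    dy, dx = np.meshgrid(offs, offs, indexing="ij")
    inside = dy**2 + dx**2 <= radius**2
    yy, xx = cr + dy[inside], cc + dx[inside]
    out = (yy < 0) | (yy >= rows) | (xx < 0) | (xx >= cols)
    if out.any():
        if boundary == "absorbing":
            raise ValueError(
                "inoculum disk extends past the absorbing lattice boundary"
            )
        warnings.warn(
            "inoculum disk wraps around the periodic lattice boundary",
            stacklevel=2,
        )
        yy, xx = yy % rows, xx % cols
    order = np.lexsort((xx, yy))
    yy, xx = yy[order], xx[order]
    if len(np.unique(yy * cols + xx)) != len(yy):
        raise ValueError("disk wraps onto itself: lattice too small for radius")
    return yy, xx


def init_mixed_colony(
    lattice_shape: tuple[int, int],
    spec: InoculumSpec,
    rng: np.random.Generator | None = None,
    boundary: str = "periodic",
) -> LatticeState:
    """Seed a diluted mixed inoculum inside a central disk.

    Inside the disk, s ~ U[0, s_max] and a ~ U[0, s_max * rho],
    independently per compartment; both layers are zero outside.  The two
    layers are drawn from two independent streams spawned from ``spec.seed``
    (or the supplied generator), each filling the disk compartments in
    row-major order, so any inoculum is reproducible from its seed alone.
    """
    if spec.kind != "mixed":
        raise ValueError(f"init_mixed_colony needs kind='mixed', got {spec.kind!r}")
    center = spec.center or (lattice_shape[0] // 2, lattice_shape[1] // 2)
    yy, xx = disk_compartments(lattice_shape, center, spec.radius, boundary)
    if rng is None:
        if spec.seed is None:
            raise ValueError("either spec.seed or an explicit rng is required")
        rng_s, rng_a = (
            np.random.default_rng(c)
            for c in np.random.SeedSequence(spec.seed).spawn(2)
        )
    else:
        rng_s = rng_a = rng
    s = np.zeros(lattice_shape)
    a = np.zeros(lattice_shape)
    s[yy, xx] = rng_s.uniform(0.0, spec.s_max, size=len(yy))
    a[yy, xx] = rng_a.uniform(0.0, spec.s_max * spec.rho, size=len(yy))
    return LatticeState(s, a, boundary)


def init_single_colony(
    lattice_shape: tuple[int, int],
    spec: InoculumSpec,
    boundary: str = "periodic",
) -> LatticeState:
    """Deterministic saturated disk of one strain (the other layer zero)."""
    if spec.kind not in ("pure_sensitive", "pure_antagonist"):
        raise ValueError(
            f"init_single_colony needs a pure_* kind, got {spec.kind!r}"
        )
    center = spec.center or (lattice_shape[0] // 2, lattice_shape[1] // 2)
    yy, xx = disk_compartments(lattice_shape, center, spec.radius, boundary)
    s = np.zeros(lattice_shape)
    a = np.zeros(lattice_shape)
    (s if spec.kind == "pure_sensitive" else a)[yy, xx] = 1.0
    return LatticeState(s, a, boundary)


def _sigma(S: float, A: float) -> float:
    return S / (S + A) if S + A > 0 else float("nan")


def run(
    state: LatticeState,
    params: ModelParams,
    n_iterations: int,
    record_every: int = 1,
    snapshot_every: int | None = None,
    init_used: InoculumSpec | None = None,
) -> SimulationResult:
    """Iterate the synchronous update and record population totals.

    Totals are recorded at iteration 0, at every ``record_every``-th
    iteration and at the final iteration; snapshots likewise at
    ``snapshot_every`` when given.  Errors raised by the update carry the
    failing iteration index.
    """
    if n_iterations < 1:
        raise ValueError(f"n_iterations must be >= 1, got {n_iterations}")
    if record_every < 1:
        raise ValueError("record_every must be >= 1")

    records = []
    snapshots: list[tuple[int, LatticeState]] = []

    def record(it: int, st: LatticeState) -> None:
        S, A = st.totals()
        records.append((it, S, A, _sigma(S, A)))
        logger.debug("iteration %d: S=%.6g A=%.6g sigma=%.6g", it, S, A,
                     records[-1][3])

    record(0, state)
    if snapshot_every:
        snapshots.append((0, state.copy()))
    current = state
    for it in range(1, n_iterations + 1):
        try:
            current = step(current, params)
        except SimulationError as err:
            raise SimulationError(f"iteration {it}: {err}", iteration=it) from err
        if it % record_every == 0 or it == n_iterations:
            record(it, current)
        if snapshot_every and (it % snapshot_every == 0 or it == n_iterations):
            snapshots.append((it, current.copy()))
    totals = pd.DataFrame(records, columns=["iteration", "S", "A", "sigma"])
    totals = totals.drop_duplicates(subset="iteration").reset_index(drop=True)
    return SimulationResult(
        totals=totals,
        snapshots=snapshots,
        params_used=params,
        init_used=init_used,
        n_iterations=n_iterations,
        final_state=current,
    )


#: Default sweep grid: the experimental mixing proportions 10..200%
#: expressed as fractions, plus the three showcase proportions 0.1/0.3/1.0.
DEFAULT_RHO_VALUES = [0.1, 0.25, 0.3, 0.5, 0.75, 1.0, 2.0]


def derive_seed(base_seed: int, rho_rank: int, replicate: int) -> int:
    """Seed of one sweep cell: ``base_seed + replicate + 10**6 * rho_rank``.

    ``rho_rank`` is the rank of the cell's rho among the sorted distinct
    sweep values, so a cell's seed does not depend on the order in which
    rho values were listed.
    """
    return base_seed + replicate + 10**6 * rho_rank


def sweep_rho(
    rho_values: list[float],
    replicates: int,
    params: ModelParams,
    base_seed: int,
    n_iterations: int = 200,
    lattice_shape: tuple[int, int] = (51, 51),
    radius: float = 5.0,
    s_max: float = 0.2,
    condition_label: str | None = None,
) -> SweepResult:
    """Ensemble of mixed-colony runs over initial antagonist proportions.

    Runs ``replicates`` independent simulations per rho and collects the
    final sensitive fractions.  Each cell's seed comes from
    :func:`derive_seed`, so any single cell can be regenerated in
    isolation.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    if not rho_values:
        raise ValueError("rho_values must be non-empty")
    if any(r < 0 for r in rho_values):
        raise ValueError("rho values must be nonnegative")
    ranks = {rho: i for i, rho in enumerate(sorted(set(rho_values)))}
    sigma = np.empty((len(rho_values), replicates))
    seeds = np.empty((len(rho_values), replicates), dtype=np.int64)
    for i, rho in enumerate(rho_values):
        for k in range(replicates):
            seed = derive_seed(base_seed, ranks[rho], k)
            spec = InoculumSpec(radius=radius, kind="mixed", s_max=s_max,
                                rho=rho, seed=seed)
            state = init_mixed_colony(lattice_shape, spec)
            result = run(state, params, n_iterations, record_every=n_iterations)
            sigma[i, k] = result.final_sigma
            seeds[i, k] = seed
    label = condition_label or f"ra={params.r_a:g}"
    return SweepResult(
        rho_values=list(rho_values),
        replicates=replicates,
        final_sigma=sigma,
        seeds=seeds,
        condition_label=label,
    )


def resistant_mode(params: ModelParams, factor: float = 0.9) -> ModelParams:
    """Model a surrounding resistant strain as a uniform antagonist slowdown.

    Resistant cells impose a metabolic cost on antagonists (detection of and
    response to neighboring competitors), captured as a multiplicative
    reduction of ``r_a``; with defaults, 0.1 -> 0.09.  All other parameters
    are untouched.
    """
    if factor <= 0:
        raise ValueError("factor must be positive")
    return dataclasses.replace(params, r_a=params.r_a * factor)


@dataclass
class TwoColonyResult:
    """Directional radii of two neighboring colonies over time.

    ``radii`` columns: iteration, colony (0 = left, 1 = right), internal
    (toward the neighbor), external (away from it), delta_r = external -
    internal.  ``merged`` flags runs truncated when the facing fronts met.
    """

    radii: pd.DataFrame
    merged: bool
    merge_iteration: int | None
    separation: float
    strain_pair: tuple[str, str]


_LAYER_OF = {"sensitive": "s", "antagonist": "a", "empty": None}


def two_colony_run(
    params: ModelParams,
    separation: int = 15,
    strain_pair: tuple[str, str] = ("sensitive", "antagonist"),
    lattice_shape: tuple[int, int] | None = None,
    n_iterations: int = 200,
    radius: float = 5.0,
    threshold: float = 0.5,
    record_every: int = 1,
    boundary: str = "absorbing",
) -> TwoColonyResult:
    """Grow two pure colonies side by side and track front asymmetry.

    Colonies are saturated disks of the strains named in ``strain_pair``
    (``"sensitive"``, ``"antagonist"`` or ``"empty"``), inoculated
    ``separation`` compartments apart on the central row.  Each iteration
    records, for each colony, the distance from its center to the last
    above-threshold compartment toward the neighbor (internal radius) and
    away from it (external radius).  The run truncates with a flag once the
    facing fronts meet.
    """
    from .metrics import directional_radius

    if boundary != "absorbing":
        warnings.warn(
            "two-colony runs use absorbing boundaries so that radii are "
            "well defined; overriding the requested periodic boundary",
            stacklevel=2,
        )
        boundary = "absorbing"
    if lattice_shape is None:
        margin = int(radius + 0.1 * n_iterations + 10)
        side = separation + 2 * margin + 1
        lattice_shape = (side, side)
    rows, cols = lattice_shape
    cr = rows // 2
    c0 = (cols - separation) // 2
    c1 = c0 + separation
    if separation <= 2 * radius:
        raise ValueError("colonies overlap: separation must exceed 2*radius")

    s = np.zeros(lattice_shape)
    a = np.zeros(lattice_shape)
    layers = {"s": s, "a": a}
    centers = [(cr, c0), (cr, c1)]
    for (cy, cx), strain in zip(centers, strain_pair):
        layer = _LAYER_OF[strain]
        if layer is None:
            continue
        yy, xx = disk_compartments(lattice_shape, (cy, cx), radius, boundary)
        layers[layer][yy, xx] = 1.0
    state = LatticeState(s, a, boundary)

    directions = [((0, 1), (0, -1)), ((0, -1), (0, 1))]  # (internal, external)
    # When both colonies live on the same layer, the internal scan stops at
    # the midline between them so the neighbor's mass is never mistaken for
    # the measuring colony's own front; distinct layers need no clamp.
    same_layer = (
        _LAYER_OF[strain_pair[0]] is not None
        and _LAYER_OF[strain_pair[0]] == _LAYER_OF[strain_pair[1]]
    )
    midline_steps = (separation - 1) // 2 if same_layer else None
    records = []
    merged = False
    merge_iteration = None

    def measure(it: int, st: LatticeState) -> tuple[float, float]:
        internals = []
        for idx, ((cy, cx), strain) in enumerate(zip(centers, strain_pair)):
            layer = _LAYER_OF[strain]
            if layer is None:
                internals.append(0.0)
                continue
            grid = st.s if layer == "s" else st.a
            d_int, d_ext = directions[idx]
            internal = directional_radius(grid, (cy, cx), d_int, threshold,
                                          max_steps=midline_steps)
            external = directional_radius(grid, (cy, cx), d_ext, threshold)
            records.append((it, idx, internal, external, external - internal))
            internals.append(internal)
        return internals[0], internals[1]

    measure(0, state)
    for it in range(1, n_iterations + 1):
        state = step(state, params)
        if it % record_every == 0 or it == n_iterations:
            int0, int1 = measure(it, state)
            if int0 + int1 >= separation - 1:
                merged = True
                merge_iteration = it
                logger.info("two-colony fronts met at iteration %d", it)
                break
    radii = pd.DataFrame(
        records,
        columns=["iteration", "colony", "internal", "external", "delta_r"],
    )
    return TwoColonyResult(
        radii=radii,
        merged=merged,
        merge_iteration=merge_iteration,
        separation=float(separation),
        strain_pair=tuple(strain_pair),
    )
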