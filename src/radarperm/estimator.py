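"""Adaptive estimation of the effective skin and interior permittivities.

The estimator treats the image fitness as an unknown function of the
candidate permittivity pair, mapped to the unit square by an affine
rescaling zeta -> (eps_i, eps_s).  It samples the fitness at nested
Smolyak sparse-grid nodes, building a hierarchical interpolant; the first
stages (levels 0-2) are sampled in full, after which refinement is
adaptive:

1. a node whose hierarchical surplus exceeds the tolerance (1% of the
   sampled value range) is flagged;
2. an unflagged node is flagged if the interpolant's value at it changed
   by more than 10x the tolerance over the previous two stages;
3. if nothing is flagged the surface is converged and the run stops;
4. otherwise each remaining unflagged node is flagged with probability
   20%, sparsely populating quiet regions;
5. a flagged node spawns its two hierarchical children in dimension i only
   if its error score times the max-normalised total-effect Sobol' index
   of dimension i still exceeds the tolerance — local refinement weighted
   by dimensional sensitivity.

The Sobol' indices come from a polynomial-chaos projection of the current
interpolant.  The run terminates at the level-10 grid (7169 full-grid
nodes) if the tolerance is never met.  The final interpolant is probed
densely to rank local maxima, which are reported as candidate
permittivity pairs together with the best reconstructed image.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .fitness import FitnessComponents, compute_fitness
from .imaging import DASReconstructor, GridSpec, ImageGrid
from .phantom import Phantom, RadarScan
from .sobol import SobolIndices, project_to_pc, sobol_from_pc
from .sparse_grid import (
    GridNode,
    HierarchicalInterpolant,
    children_1d,
    new_nodes_at_level,
)

__all__ = [
    "PermittivityBox",
    "EstimatorConfig",
    "ComplexPermittivity",
    "LocalMaximum",
    "EstimationResult",
    "FitnessEvaluator",
    "rescale",
    "select_new_nodes",
    "adaptive_refine",
    "find_local_maxima",
    "estimate",
    "refractive_index",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PermittivityBox:
    """Search ranges for (eps_i, eps_s); the unit square maps onto them.

    Defaults cover the span of permittivities plausible for breast tissue
    at microwave frequencies (fat ~2.5 up to gland ~10 for the interior;
    skin estimates range widely).
    """

    eps_i_range: tuple[float, float] = (1.0, 12.0)
    eps_s_range: tuple[float, float] = (2.0, 70.0)

    def __post_init__(self) -> None:
        for lo, hi in (self.eps_i_range, self.eps_s_range):
            if not (1.0 <= lo < hi):
                raise ValueError("ranges must satisfy 1 <= min < max")

    def rescale(self, zeta: np.ndarray) -> tuple[float, float]:
        return rescale(zeta, self)

    def inverse(self, eps_i: float, eps_s: float) -> np.ndarray:
        lo_i, hi_i = self.eps_i_range
        lo_s, hi_s = self.eps_s_range
        return np.array([(eps_i - lo_i) / (hi_i - lo_i), (eps_s - lo_s) / (hi_s - lo_s)])


def rescale(zeta: np.ndarray, box: PermittivityBox) -> tuple[float, float]:
    """Affine map of zeta in [0, 1]^2 to (eps_i, eps_s) in the search box."""
    z = np.asarray(zeta, dtype=float)
    if np.any(z < 0) or np.any(z > 1):
        raise ValueError("zeta must lie in the unit square")
    lo_i, hi_i = box.eps_i_range
    lo_s, hi_s = box.eps_s_range
    return (lo_i + z[0] * (hi_i - lo_i), lo_s + z[1] * (hi_s - lo_s))


@dataclass(frozen=True)
class EstimatorConfig:
    """Tunables of the adaptive loop (defaults as described above)."""

    tol_fraction: float = 0.01
    change_factor: float = 10.0
    random_inclusion_prob: float = 0.2
    max_level: int = 10
    nonadaptive_levels: int = 2
    seed: int = 0
    pc_order: int = 8
    pc_quadrature: int = 12

    def __post_init__(self) -> None:
        if not 0 < self.tol_fraction < 1:
            raise ValueError("tol_fraction must be in (0, 1)")
        if self.change_factor < 1:
            raise ValueError("change_factor must be >= 1")
        if not 0 <= self.random_inclusion_prob <= 1:
            raise ValueError("random_inclusion_prob must be in [0, 1]")
        if self.max_level < self.nonadaptive_levels:
            raise ValueError("max_level must be >= nonadaptive_levels")


@dataclass(frozen=True)
class ComplexPermittivity:
    """eps = eps' + i eps'' of a lossy dielectric."""

    eps_real: float
    eps_imag: float = 0.0

    def __post_init__(self) -> None:
        if self.eps_real < 1 or self.eps_imag < 0:
            raise ValueError("require eps_real >= 1 and eps_imag >= 0")


def refractive_index(cp: ComplexPermittivity) -> float:
    """Real part of the refractive index of a lossy dielectric.

    n' = sqrt((sqrt(eps'^2 + eps''^2) + eps') / 2); the signal speed — and
    hence what delay-based imaging actually estimates — is set by n', so
    for lossy tissue the recovered "permittivity" n'^2 sits slightly above
    the true eps'.
    """
    mag = np.hypot(cp.eps_real, cp.eps_imag)
    return float(np.sqrt((mag + cp.eps_real) / 2.0))


@dataclass(frozen=True)
class LocalMaximum:
    zeta: np.ndarray
    permittivities: tuple[float, float]
    fitness: float


@dataclass
class EstimationResult:
    """Everything a run produces: surface, ranked maxima, best image."""

    interpolant: HierarchicalInterpolant
    best_permittivities: tuple[float, float]
    best_fitness: float
    secondary_maxima: list[LocalMaximum]
    best_image: ImageGrid
    nodes_sampled: int
    termination_reason: str
    box: PermittivityBox
    sobol_history: list[np.ndarray] = field(default_factory=list)


class FitnessEvaluator:
    """Caches fitness evaluations: one DAS reconstruction per unique zeta.

    The delay geometry is precomputed once; each new zeta costs one
    reconstruction plus one fitness computation, and repeated requests are
    served from the cache so no node is ever imaged twice.
    """

    def __init__(
        self,
        scan: RadarScan,
        box: PermittivityBox,
        grid_spec: GridSpec,
        geometry: Phantom,
    ):
        self.box = box
        self.reconstructor = DASReconstructor(scan, grid_spec, geometry)
        self._cache: dict[tuple[float, float], float] = {}
        self.evaluations = 0
        self.cache_hits = 0

    def __call__(self, zeta: np.ndarray) -> float:
        key = (float(zeta[0]), float(zeta[1]))
        if key in self._cache:
            self.cache_hits += 1
            return self._cache[key]
        eps_i, eps_s = self.box.rescale(np.asarray(zeta))
        image = self.reconstructor.reconstruct(eps_i, eps_s)
        comp: FitnessComponents = compute_fitness(image)
        self._cache[key] = comp.f
        self.evaluations += 1
        logger.debug(
            "fitness zeta=(%.4f, %.4f) eps_i=%.3f eps_s=%.3f "
            "f=%.5g s_max=%.4g A=%.4g N=%d d=%.2f P=%.3f",
            key[0], key[1], eps_i, eps_s,
            comp.f, comp.s_max, comp.a_area, comp.n_regions,
            comp.d_edge, comp.p_penalty,
        )
        return comp.f

    def reconstruct(self, eps_i: float, eps_s: float) -> ImageGrid:
        return self.reconstructor.reconstruct(eps_i, eps_s)


# ---------------------------------------------------------------------------
# Node selection (the adaptive rules)
# ---------------------------------------------------------------------------

def select_new_nodes(
    interpolant: HierarchicalInterpolant,
    sobol: SobolIndices,
    config: EstimatorConfig,
    rng: np.random.Generator,
) -> list[GridNode]:
    """Choose the next stage's nodes from the current stage's errors.

    Applies, in order: the surplus-vs-tolerance flag, the
    interpolant-change flag, the empty-selection termination signal, the
    random inclusion of quiet nodes, and the Sobol'-weighted child test
    per dimension.  An empty return signals that the interpolant is within
    tolerance.
    """
    stage = max(n.stage for n in interpolant.nodes)
    current = interpolant.nodes_at_stage(stage)
    vmin, vmax = interpolant.value_range
    tol = config.tol_fraction * (vmax - vmin)

    flagged: list[tuple[GridNode, float]] = []
    unflagged: list[tuple[GridNode, float]] = []
    for node in current:
        surplus = abs(node.surplus)
        prev_stage = stage - 2
        if prev_stage >= 0:
            change = abs(node.value - interpolant.evaluate(node.zeta, max_stage=prev_stage))
        else:
            change = 0.0
        score = max(surplus, change)
        if surplus > tol:
            flagged.append((node, score))
        elif change > config.change_factor * tol:
            flagged.append((node, score))
        else:
            unflagged.append((node, score))

    if not flagged:
        return []

    for node, score in unflagged:
        if rng.random() < config.random_inclusion_prob:
            flagged.append((node, score))

    new: dict = {}
    for node, score in flagged:
        for dim in range(interpolant.dimension):
            if score * sobol.normalized_index[dim] <= tol:
                continue
            for child_level, child_index in children_1d(
                node.levels[dim], node.indices[dim]
            ):
                levels = list(node.levels)
                indices = list(node.indices)
                levels[dim] = child_level
                indices[dim] = child_index
                child = GridNode(levels=tuple(levels), indices=tuple(indices))
                if child.key in interpolant or child.key in new:
                    continue
                new[child.key] = child
    return list(new.values())


# ---------------------------------------------------------------------------
# Local maxima of the fitness surface
# ---------------------------------------------------------------------------

def _local_ascent(
    interpolant: HierarchicalInterpolant, zeta: np.ndarray, step: float
) -> tuple[np.ndarray, float]:
    """Pattern-search hill climb on the interpolant from a probe peak."""
    z = zeta.copy()
    best = interpolant.evaluate(z)
    while step > 1e-4:
        improved = False
        for dim in range(z.size):
            for sign in (+1.0, -1.0):
                cand = z.copy()
                cand[dim] = min(1.0, max(0.0, cand[dim] + sign * step))
                val = interpolant.evaluate(cand)
                if val > best:
                    best, z, improved = val, cand, True
        if not improved:
            step /= 2.0
    return z, float(best)


def find_local_maxima(
    interpolant: HierarchicalInterpolant,
    box: PermittivityBox,
    probe_points: int = 201,
    separation: float = 0.05,
    fitness_floor: float = 0.5,
) -> list[LocalMaximum]:
    """Rank local maxima of the interpolant on a dense unit-square probe.

    A ``probe_points``-per-axis grid locates candidate peaks (plateau-aware
    maximum filter); each is refined by local ascent.  Peaks closer than
    ``separation`` in zeta to a better peak are merged, and only peaks
    within ``fitness_floor`` of the best are reported — the method must
    surface secondary high-likelihood regions, not just the global best.
    """
    axis = np.linspace(0.0, 1.0, probe_points)
    zz1, zz2 = np.meshgrid(axis, axis, indexing="ij")
    pts = np.column_stack([zz1.ravel(), zz2.ravel()])
    vals = interpolant.evaluate(pts).reshape(probe_points, probe_points)

    footprint = ndimage.maximum_filter(vals, size=3, mode="nearest")
    is_peak = (vals >= footprint) & (vals > 0)
    candidates = np.argwhere(is_peak)
    refined: list[LocalMaximum] = []
    step = 1.0 / (probe_points - 1)
    order = np.argsort(vals[is_peak])[::-1]
    for idx in candidates[order][:50]:
        z0 = np.array([axis[idx[0]], axis[idx[1]]])
        z, f = _local_ascent(interpolant, z0, step)
        refined.append(
            LocalMaximum(zeta=z, permittivities=box.rescale(z), fitness=f)
        )

    refined.sort(key=lambda m: -m.fitness)
    kept: list[LocalMaximum] = []
    for m in refined:
        if all(np.linalg.norm(m.zeta - k.zeta) >= separation for k in kept):
            kept.append(m)
    if not kept:
        center = np.array([0.5, 0.5])
        return [LocalMaximum(center, box.rescale(center), float(interpolant.evaluate(center)))]
    best = kept[0].fitness
    return [kept[0]] + [m for m in kept[1:] if m.fitness >= fitness_floor * best]


# ---------------------------------------------------------------------------
# The adaptive refinement loop (generic in the sampled function)
# ---------------------------------------------------------------------------

def adaptive_refine(
    func,
    dimension: int = 2,
    config: EstimatorConfig | None = None,
) -> tuple[HierarchicalInterpolant, str, list[np.ndarray]]:
    """Build an adaptive sparse-grid interpolant of ``func`` on [0, 1]^d.

    ``func(zeta) -> float`` is sampled on the full grids of the
    non-adaptive levels, then refined stage by stage with the
    surplus/change/Sobol' rules until the tolerance is met or the maximum
    level is reached.  Returns the interpolant, the termination reason
    (``"tolerance-met"`` or ``"max-level"``) and the per-stage normalised
    Sobol' indices.
    """
    config = config or EstimatorConfig()
    interpolant = HierarchicalInterpolant(dimension=dimension)
    rng = np.random.default_rng(config.seed)
    sobol_history: list[np.ndarray] = []

    first_levels = min(config.nonadaptive_levels, config.max_level)
    for level in range(first_levels + 1):
        nodes = new_nodes_at_level(dimension, level)
        values = [func(n.zeta) for n in nodes]
        interpolant.add_nodes(nodes, values, stage=level)
        logger.info(
            "stage %d (non-adaptive): %d nodes, %d total",
            level, len(nodes), len(interpolant),
        )

    stage = first_levels
    termination = "max-level"
    while stage < config.max_level:
        pc = project_to_pc(interpolant, config.pc_order, config.pc_quadrature)
        sobol = sobol_from_pc(pc)
        sobol_history.append(sobol.normalized_index.copy())
        new_nodes = select_new_nodes(interpolant, sobol, config, rng)
        if not new_nodes:
            termination = "tolerance-met"
            break
        values = [func(n.zeta) for n in new_nodes]
        interpolant.add_nodes(new_nodes, values, stage=stage + 1)
        stage += 1
        vmin, vmax = interpolant.value_range
        logger.info(
            "stage %d: +%d nodes (%d total), tol=%.4g, sobol=%s",
            stage, len(new_nodes), len(interpolant),
            config.tol_fraction * (vmax - vmin),
            np.array2string(sobol.normalized_index, precision=3),
        )
    return interpolant, termination, sobol_history


# ---------------------------------------------------------------------------
# The full estimation pipeline
# ---------------------------------------------------------------------------

def estimate(
    scan: RadarScan,
    box: PermittivityBox | None = None,
    grid_spec: GridSpec | None = None,
    config: EstimatorConfig | None = None,
    geometry: Phantom | None = None,
) -> EstimationResult:
    """Run the adaptive permittivity estimation on a calibrated scan.

    ``scan`` must already be calibration-subtracted and skin-suppressed.
    ``geometry`` carries the known outer skin contour (its permittivity
    fields are ignored — they are what is being estimated).  Returns the
    fitness interpolant, the ranked permittivity candidates and the image
    reconstructed at the best pair.
    """
    box = box or PermittivityBox()
    grid_spec = grid_spec or GridSpec()
    config = config or EstimatorConfig()
    geometry = geometry or Phantom()
    if scan.traces.size == 0:
        raise ValueError("scan has no traces")

    evaluator = FitnessEvaluator(scan, box, grid_spec, geometry)
    interpolant, termination, sobol_history = adaptive_refine(
        evaluator, dimension=2, config=config
    )
    maxima = find_local_maxima(interpolant, box)
    best = maxima[0]
    best_image = evaluator.reconstruct(*best.permittivities)
    return EstimationResult(
        interpolant=interpolant,
        best_permittivities=best.permittivities,
        best_fitness=best.fitness,
        secondary_maxima=maxima[1:],
        best_image=best_image,
        nodes_sampled=evaluator.evaluations,
        termination_reason=termination,
        box=box,
        sobol_history=sobol_history,
    )
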