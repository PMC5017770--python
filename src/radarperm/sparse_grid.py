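"""Nested Smolyak sparse grids and hierarchical stochastic collocation.

The one-dimensional node families are nested equidistant (Newton-Cotes)
points on [0, 1]: level 0 is the single midpoint 0.5, level 1 adds the
endpoints {0, 1} and every level i >= 2 adds the 2**(i-1) new dyadic
midpoints (odd multiples of 2**-i).  The d-dimensional level-L grid is the
Smolyak union of tensor products with level sum <= L; for d = 2 the
cumulative node counts are 1, 5, 13, 29, 65, 145, 321, ... 7169 at levels
0-10.

Interpolation uses hierarchical piecewise-multilinear hat functions.  Each
node carries a hierarchical surplus — the difference between the sampled
value and the prediction of the interpolant built from all earlier levels —
which doubles as a local error estimate and drives the adaptive refinement
in :mod:`radarperm.estimator`.

Node identity is the exact per-dimension (level, index) pair, so
nestedness and deduplication are exact integer operations; the dyadic
coordinates themselves are exact in binary floating point.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "NodeKey",
    "GridNode",
    "node_zeta_1d",
    "level_points_1d",
    "children_1d",
    "nodes_at_level",
    "new_nodes_at_level",
    "hierarchical_basis",
    "HierarchicalInterpolant",
]

#: Per-dimension (level, index) pairs identifying a node exactly.
NodeKey = tuple[tuple[int, int], ...]


def node_zeta_1d(level: int, index: int) -> float:
    """Coordinate in [0, 1] of 1D node ``index`` at refinement ``level``."""
    if level == 0:
        if index != 0:
            raise ValueError("level 0 has a single node (index 0)")
        return 0.5
    if level == 1:
        if index not in (0, 1):
            raise ValueError("level 1 has nodes 0 and 1")
        return float(index)
    if not 0 <= index < 2 ** (level - 1):
        raise ValueError(f"index {index} out of range for level {level}")
    return (2 * index + 1) / 2**level


def level_points_1d(level: int) -> list[int]:
    """Indices of the nodes *new* at the given 1D level."""
    if level < 0:
        raise ValueError("level must be non-negative")
    if level == 0:
        return [0]
    if level == 1:
        return [0, 1]
    return list(range(2 ** (level - 1)))


def children_1d(level: int, index: int) -> list[tuple[int, int]]:
    """Hierarchical children of a 1D node at the next refinement level.

    The midpoint has the two endpoints as children; each endpoint has a
    single (boundary-refining) child; an interior dyadic node has the two
    adjacent midpoints one level down.
    """
    if level == 0:
        return [(1, 0), (1, 1)]
    if level == 1:
        return [(2, 0)] if index == 0 else [(2, 2**1 - 1)]
    return [(level + 1, 2 * index), (level + 1, 2 * index + 1)]


@dataclass
class GridNode:
    """One sparse-grid node: exact dyadic identity plus sampled data."""

    levels: tuple[int, ...]
    indices: tuple[int, ...]
    value: float = np.nan
    surplus: float = np.nan
    stage: int = -1

    @property
    def key(self) -> NodeKey:
        return tuple(zip(self.levels, self.indices))

    @property
    def zeta(self) -> np.ndarray:
        return np.array(
            [node_zeta_1d(l, i) for l, i in zip(self.levels, self.indices)]
        )

    @property
    def total_level(self) -> int:
        return sum(self.levels)


def new_nodes_at_level(dimension: int, level: int) -> list[GridNode]:
    """Nodes whose Smolyak level sum equals exactly ``level``."""
    if level < 0:
        raise ValueError("level must be non-negative")
    if dimension < 1:
        raise ValueError("dimension must be >= 1")
    nodes: list[GridNode] = []
    for levels in _compositions(level, dimension):
        index_sets = [level_points_1d(l) for l in levels]
        for indices in product(*index_sets):
            nodes.append(GridNode(levels=tuple(levels), indices=tuple(indices)))
    return nodes


def nodes_at_level(dimension: int, level: int) -> list[GridNode]:
    """All nodes of the nested Smolyak grid with level sum <= ``level``."""
    if level < 0:
        raise ValueError("level must be non-negative")
    out: list[GridNode] = []
    for l in range(level + 1):
        out.extend(new_nodes_at_level(dimension, l))
    return out


def _compositions(total: int, parts: int) -> Iterable[tuple[int, ...]]:
    """All tuples of ``parts`` non-negative integers summing to ``total``."""
    if parts == 1:
        yield (total,)
        return
    for first in range(total + 1):
        for rest in _compositions(total - first, parts - 1):
            yield (first,) + rest


def _hat_1d(level: np.ndarray, x: np.ndarray, q: np.ndarray) -> np.ndarray:
    """Hat value at query q for node coordinate x at the given 1D level.

    Level 0 is the constant function 1; level i >= 1 is the piecewise-linear
    hat with half-width 2**-i (support 2**-(i-1)).
    """
    hat = np.maximum(0.0, 1.0 - (2.0**level) * np.abs(q - x))
    return np.where(level == 0, 1.0, hat)


def hierarchical_basis(node: GridNode, zeta: Sequence[float]) -> float:
    """Multilinear hierarchical basis of ``node`` evaluated at ``zeta``."""
    z = np.asarray(zeta, dtype=float)
    if np.any(z < 0) or np.any(z > 1):
        raise ValueError("zeta must lie in [0, 1]^d")
    val = 1.0
    for l, x, q in zip(node.levels, node.zeta, z):
        val *= float(_hat_1d(np.asarray(l), np.asarray(x), np.asarray(q)))
    return val


class HierarchicalInterpolant:
    """Hierarchical sparse-grid interpolant over [0, 1]^d.

    Nodes are added in stages via :meth:`add_nodes`; each new node's
    surplus is its sampled value minus the prediction of the interpolant
    built so far, so the interpolant reproduces every sampled value
    exactly.  ``value_range`` tracks the min/max sampled so far (the basis
    of the adaptive error tolerance) and may widen as sampling proceeds.
    """

    def __init__(self, dimension: int):
        if dimension < 1:
            raise ValueError("dimension must be >= 1")
        self.dimension = dimension
        self.current_level = -1
        self._keys: dict[NodeKey, int] = {}
        self._nodes: list[GridNode] = []
        # Parallel arrays for vectorised evaluation.
        self._levels = np.empty((0, dimension), dtype=int)
        self._zetas = np.empty((0, dimension))
        self._surpluses = np.empty(0)
        self._stages = np.empty(0, dtype=int)

    # -- introspection ----------------------------------------------------
    def __len__(self) -> int:
        return len(self._nodes)

    def __contains__(self, key: NodeKey) -> bool:
        return key in self._keys

    @property
    def nodes(self) -> list[GridNode]:
        return list(self._nodes)

    def nodes_at_stage(self, stage: int) -> list[GridNode]:
        return [n for n in self._nodes if n.stage == stage]

    @property
    def value_range(self) -> tuple[float, float]:
        if not self._nodes:
            return (np.nan, np.nan)
        vals = np.array([n.value for n in self._nodes])
        return (float(vals.min()), float(vals.max()))

    @property
    def max_abs_surplus(self) -> float:
        """Largest surplus magnitude of the latest stage: an error estimate."""
        if not self._nodes:
            return np.nan
        cur = self._stages == self._stages.max()
        return float(np.abs(self._surpluses[cur]).max())

    # -- evaluation -------------------------------------------------------
    def evaluate(
        self,
        zeta: Sequence[float] | np.ndarray,
        max_stage: int | None = None,
        chunk: int = 4096,
    ) -> float | np.ndarray:
        """Interpolant value(s) at one point or an (n, d) batch of points.

        ``max_stage`` restricts the sum to nodes added at stages <= that
        stage, i.e. evaluates an earlier interpolant (used by the adaptive
        loop's interpolant-change rule).
        """
        if not self._nodes:
            raise RuntimeError("interpolant has no sampled nodes")
        z = np.asarray(zeta, dtype=float)
        scalar = z.ndim == 1
        z = np.atleast_2d(z)
        if z.shape[1] != self.dimension:
            raise ValueError("query dimension mismatch")

        if max_stage is None:
            sel = slice(None)
        else:
            sel = self._stages <= max_stage
        levels = self._levels[sel]
        zetas = self._zetas[sel]
        surpluses = self._surpluses[sel]

        out = np.empty(z.shape[0])
        for lo in range(0, z.shape[0], chunk):
            q = z[lo : lo + chunk]
            basis = np.ones((levels.shape[0], q.shape[0]))
            for k in range(self.dimension):
                basis *= _hat_1d(
                    levels[:, k, None], zetas[:, k, None], q[None, :, k]
                )
            out[lo : lo + chunk] = surpluses @ basis
        return float(out[0]) if scalar else out

    # -- construction -----------------------------------------------------
    def add_nodes(
        self,
        new_nodes: Sequence[GridNode],
        sampled_values: Sequence[float],
        stage: int | None = None,
    ) -> None:
        """Attach sampled nodes, computing their hierarchical surpluses.

        Surpluses are the sampled values minus the *previous* interpolant's
        predictions at the new points; the new nodes must all be disjoint
        from the existing set (and from each other).
        """
        if len(new_nodes) != len(sampled_values):
            raise ValueError("nodes and values length mismatch")
        if not new_nodes:
            return
        keys = [n.key for n in new_nodes]
        if len(set(keys)) != len(keys):
            raise ValueError("duplicate node in new_nodes")
        for k in keys:
            if k in self._keys:
                raise ValueError(f"node {k} already present in interpolant")

        zetas = np.array([n.zeta for n in new_nodes])
        values = np.asarray(sampled_values, dtype=float)
        if self._nodes:
            predictions = np.atleast_1d(self.evaluate(zetas))
        else:
            predictions = np.zeros(len(new_nodes))
        surpluses = values - predictions

        if stage is None:
            stage = (int(self._stages.max()) + 1) if len(self._nodes) else 0
        for node, v, s in zip(new_nodes, values, surpluses):
            node.value = float(v)
            node.surplus = float(s)
            node.stage = stage
            self._keys[node.key] = len(self._nodes)
            self._nodes.append(node)

        self._levels = np.vstack([self._levels, [n.levels for n in new_nodes]])
        self._zetas = np.vstack([self._zetas, zetas])
        self._surpluses = np.concatenate([self._surpluses, surpluses])
        self._stages = np.concatenate(
            [self._stages, np.full(len(new_nodes), stage, dtype=int)]
        )
        self.current_level = max(self.current_level, max(n.total_level for n in new_nodes))

    # -- persistence ------------------------------------------------------
    def save(self, h5group) -> None:
        """Serialise nodes, surpluses and level into an open h5py group."""
        h5group.attrs["dimension"] = self.dimension
        h5group.attrs["current_level"] = self.current_level
        h5group.create_dataset("levels", data=self._levels)
        h5group.create_dataset(
            "indices", data=np.array([n.indices for n in self._nodes], dtype=int)
        )
        h5group.create_dataset("values", data=np.array([n.value for n in self._nodes]))
        h5group.create_dataset("surpluses", data=self._surpluses)
        h5group.create_dataset("stages", data=self._stages)

    @classmethod
    def load(cls, h5group) -> "HierarchicalInterpolant":
        interp = cls(int(h5group.attrs["dimension"]))
        levels = h5group["levels"][()]
        indices = h5group["indices"][()]
        values = h5group["values"][()]
        surpluses = h5group["surpluses"][()]
        stages = h5group["stages"][()]
        for stage in np.unique(stages):
            m = stages == stage
            nodes = [
                GridNode(levels=tuple(l), indices=tuple(i))
                for l, i in zip(levels[m], indices[m])
            ]
            # Re-adding stage by stage reproduces the stored surpluses.
            interp.add_nodes(nodes, values[m], stage=int(stage))
        # Nodes were stored stage-ordered, so recomputed surpluses must match.
        order = np.argsort(stages, kind="stable")
        if not np.allclose(interp._surpluses, surpluses[order], atol=1e-9):
            raise ValueError("inconsistent serialized interpolant")
        return interp
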