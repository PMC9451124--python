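"""Area adjacency graphs and intrinsic-CAR precision utilities.

Municipality adjacency ("sharing a common boundary") is represented as an
undirected graph over an *ordered* list of area identifiers.  The ordering is
part of the contract: every vector quantity downstream (covariates, random
effects, posterior draws) is aligned to ``area_ids``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np


@dataclass(frozen=True)
class AdjacencyGraph:
    """Symmetric, self-loop-free adjacency over an ordered set of areas.

    Parameters
    ----------
    area_ids
        Ordered area identifiers; defines the index of every per-area vector.
    neighbors
        Mapping from area id to the ids adjacent to it.  Must be symmetric
        and free of self-loops; violations raise ``ValueError`` on
        construction rather than being silently repaired.
    """

    area_ids: tuple
    neighbors: Mapping[object, frozenset] = field(repr=False)

    def __post_init__(self):
        ids = tuple(self.area_ids)
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate area ids")
        nb = {a: frozenset(self.neighbors.get(a, ())) for a in ids}
        known = set(ids)
        for a, ns in nb.items():
            if a in ns:
                raise ValueError(f"self-loop at area {a!r}")
            for b in ns:
                if b not in known:
                    raise ValueError(f"neighbor {b!r} of {a!r} is not an area")
                if a not in nb[b]:
                    raise ValueError(f"asymmetric adjacency between {a!r} and {b!r}")
        object.__setattr__(self, "area_ids", ids)
        object.__setattr__(self, "neighbors", nb)

    @property
    def n_areas(self) -> int:
        return len(self.area_ids)

    @property
    def index(self) -> dict:
        return {a: i for i, a in enumerate(self.area_ids)}

    def n_edges(self) -> int:
        return sum(len(v) for v in self.neighbors.values()) // 2

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.area_ids)
        for a, ns in self.neighbors.items():
            g.add_edges_from((a, b) for b in ns)
        return g

    def components(self) -> list[np.ndarray]:
        """Connected components as arrays of positional indices, each sorted."""
        idx = self.index
        comps = nx.connected_components(self.to_networkx())
        out = [np.array(sorted(idx[a] for a in c)) for c in comps]
        out.sort(key=lambda c: c[0])
        return out

    def laplacian(self) -> np.ndarray:
        """Dense graph Laplacian D - W in ``area_ids`` order (ICAR precision)."""
        n = self.n_areas
        idx = self.index
        q = np.zeros((n, n))
        for a, ns in self.neighbors.items():
            i = idx[a]
            q[i, i] = len(ns)
            for b in ns:
                q[i, idx[b]] = -1.0
        return q

    @classmethod
    def from_edges(cls, area_ids: Sequence, edges: Iterable[tuple]) -> "AdjacencyGraph":
        nb: dict = {a: set() for a in area_ids}
        for a, b in edges:
            if a == b:
                raise ValueError(f"self-loop at area {a!r}")
            nb[a].add(b)
            nb[b].add(a)
        return cls(tuple(area_ids), {a: frozenset(s) for a, s in nb.items()})


def scale_icar(graph: AdjacencyGraph) -> np.ndarray:
    """Generalized-variance scaling factor of the ICAR prior, per component.

    For each connected component the sum-to-zero-constrained ICAR effect
    ``u ~ N(0, Q^+)`` has marginal variances ``diag(Q^+)`` (Moore-Penrose
    pseudo-inverse of the component Laplacian).  The returned factor is the
    geometric mean of those variances; dividing a draw by its square root —
    equivalently multiplying the precision by the factor — gives the scaled
    structured component with unit generalized marginal variance.

    Returns an array with one entry per component, in ``graph.components()``
    order.  Singleton components get factor ``nan``: their structured effect
    is defined as exactly zero and carries no variance to scale.
    """
    q = graph.laplacian()
    factors = []
    for comp in graph.components():
        if len(comp) == 1:
            factors.append(np.nan)
            continue
        qc = q[np.ix_(comp, comp)]
        # eigh on the symmetric Laplacian; drop the single null eigenvalue
        w, v = np.linalg.eigh(qc)
        pos = w > w[-1] * 1e-10
        diag_pinv = ((v[:, pos] ** 2) / w[pos]).sum(axis=1)
        factors.append(float(np.exp(np.mean(np.log(diag_pinv)))))
    return np.array(factors)


def scaled_icar_precision(graph: AdjacencyGraph) -> np.ndarray:
    """Dense precision of the scaled ICAR field over all areas.

    Each component's Laplacian block is multiplied by its scaling factor so
    the constrained field has unit generalized variance per component.
    Singleton components contribute a zero row/column (their effect is pinned
    to zero by the sampler, not by this matrix).
    """
    q = graph.laplacian().copy()
    for comp, c in zip(graph.components(), scale_icar(graph)):
        if len(comp) == 1:
            continue
        q[np.ix_(comp, comp)] *= c
    return q


def scaled_icar_covariance(graph: AdjacencyGraph) -> np.ndarray:
    """Covariance of the scaled, sum-to-zero-constrained ICAR field.

    Dense n x n matrix: per component the pseudo-inverse of the scaled
    Laplacian (zero across components, zero rows for singletons).
    """
    n = graph.n_areas
    cov = np.zeros((n, n))
    q = scaled_icar_precision(graph)
    for comp in graph.components():
        if len(comp) == 1:
            continue
        qc = q[np.ix_(comp, comp)]
        w, v = np.linalg.eigh(qc)
        pos = w > w[-1] * 1e-10
        cov[np.ix_(comp, comp)] = (v[:, pos] / w[pos]) @ v[:, pos].T
    return cov


def sample_scaled_icar(
    graph: AdjacencyGraph, rng: np.random.Generator, size: int = 1
) -> np.ndarray:
    """Draw ``size`` scaled ICAR fields (sum-to-zero per component).

    Uses the eigendecomposition of each component's scaled Laplacian:
    coordinates along non-null eigenvectors are independent normals with
    variance 1/eigenvalue; the null (constant) direction is omitted, which
    enforces the sum-to-zero constraint exactly.  Singleton components are 0.
    """
    n = graph.n_areas
    out = np.zeros((size, n))
    q = scaled_icar_precision(graph)
    for comp in graph.components():
        if len(comp) == 1:
            continue
        qc = q[np.ix_(comp, comp)]
        w, v = np.linalg.eigh(qc)
        pos = w > w[-1] * 1e-10
        z = rng.standard_normal((size, int(pos.sum())))
        out[:, comp] = (z / np.sqrt(w[pos])) @ v[:, pos].T
    return out if size > 1 else out[0]
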