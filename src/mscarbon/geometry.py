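"""Bases, barycentres, semi-lengths and topological distances at any scale.

The geometric anchors of a tree element at any scale are derived from the
metamer-scale 3-D coordinates:

* the *base* of a metamer is the top of its parent (the root element's base
  is stored on its complex);
* the *barycentre* of a metamer is the midpoint of its base and top;
* the base of a coarse element is the base of its base component (the one
  whose parent lies outside the complex);
* the barycentre of a coarse element is the mean of its components'
  barycentres weighted by their individual lengths;
* the length of a coarse element is the sum of its component lengths, and
  the *semi-length* of any element is the Euclidean distance from its base
  to its barycentre.

The topological distance between two elements i, j at the same scale walks
the tree through their greatest common ancestor (GCA): it sums the lengths
of the elements strictly between each endpoint and the GCA, the two
semi-lengths, and — when the GCA is neither endpoint — the straight-line
gap between the bases of the two path elements directly borne on the GCA
(non-zero at coarse scales where laterals insert at different positions
along a long element).  The self-distance is zero, so an element that is
both source and sink weights itself with the maximum proximity factor.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .mtg import MultiScaleTree, _id_sort_key


def resolve_scale(tree: MultiScaleTree, scale_name: str) -> int:
    """Scale index for a name; 'M' and 'metamer' mean the finest scale."""
    if scale_name in ("M", "metamer"):
        return tree.max_scale
    return tree.scale_index(scale_name)


@dataclass
class GeometryTable:
    """Per-vertex geometric anchors at one scale.

    ``frame`` is indexed by vertex id with columns ``base_{x,y,z}``,
    ``top_{x,y,z}``, ``bary_{x,y,z}``, ``length``, ``semi_length``
    (all metres).
    """

    scale: int
    scale_name: str
    frame: pd.DataFrame
    _engine: Optional["_DistanceEngine"] = field(default=None, repr=False)

    def base(self, v) -> np.ndarray:
        return self.frame.loc[v, ["base_x", "base_y", "base_z"]].to_numpy(float)

    def barycentre(self, v) -> np.ndarray:
        return self.frame.loc[v, ["bary_x", "bary_y", "bary_z"]].to_numpy(float)

    def semi_length(self, v) -> float:
        return float(self.frame.loc[v, "semi_length"])

    def length(self, v) -> float:
        return float(self.frame.loc[v, "length"])


@dataclass
class DistanceMatrix:
    """Symmetric topological distances between components at one scale."""

    ids: list[str]
    values: np.ndarray

    def __post_init__(self):
        self._index = {v: k for k, v in enumerate(self.ids)}

    def loc(self, i: str, j: str) -> float:
        return float(self.values[self._index[i], self._index[j]])

    def submatrix(self, rows: Sequence[str], cols: Sequence[str]) -> np.ndarray:
        r = [self._index[v] for v in rows]
        c = [self._index[v] for v in cols]
        return self.values[np.ix_(r, c)]


class GeometryError(ValueError):
    pass


def _stored_root_base(tree: MultiScaleTree, root_v: str) -> np.ndarray:
    """Base coordinates of the scale root, stored on its complex chain."""
    c = tree.complex_of[root_v]
    while c is not None:
        xyz = tree.prop(c, "top_xyz")
        if xyz is not None:
            return np.asarray(xyz, float)
        c = tree.complex_of[c]
    raise GeometryError(
        f"root element {root_v!r}: no stored coordinates on its complex chain"
    )


def annotate_geometry(tree: MultiScaleTree, scale_name: str = "M") -> GeometryTable:
    """Compute bases, barycentres, lengths and semi-lengths at a scale."""
    finest = tree.max_scale
    scale = resolve_scale(tree, scale_name)
    metamers = tree.vertices_at_scale(finest)
    idx = {v: k for k, v in enumerate(metamers)}
    n = len(metamers)

    top = np.empty((n, 3))
    for v in metamers:
        xyz = tree.prop(v, "top_xyz")
        if xyz is None:
            raise GeometryError(f"metamer {v!r}: missing top coordinates")
        top[idx[v]] = xyz

    base = np.empty((n, 3))
    depth = np.zeros(n, int)
    root = tree.scale_root(finest)
    stack = [root]
    while stack:
        v = stack.pop()
        p = tree.parent_of[v]
        if p is None:
            base[idx[v]] = _stored_root_base(tree, v)
        else:
            base[idx[v]] = top[idx[p]]
            depth[idx[v]] = depth[idx[p]] + 1
        stack.extend(tree.children_of(v))

    bary = 0.5 * (top + base)
    length = np.array([float(tree.prop(v, "length", 0.0) or 0.0) for v in metamers])
    semi = np.linalg.norm(bary - base, axis=1)

    if scale == finest:
        ids = metamers
        frame = _assemble(ids, base, top, bary, length, semi)
        return GeometryTable(scale, scale_name, frame)

    coarse = tree.vertices_at_scale(scale)
    m = len(coarse)
    cbase = np.empty((m, 3))
    ctop = np.empty((m, 3))
    cbary = np.empty((m, 3))
    clen = np.empty(m)
    coarse_idx = {cv: k for k, cv in enumerate(coarse)}
    complex_of_meta = np.array(
        [coarse_idx[tree.complex_at_scale(v, scale)] for v in metamers]
    )
    for k, cv in enumerate(coarse):
        members = np.nonzero(complex_of_meta == k)[0]
        if members.size == 0:
            raise GeometryError(f"coarse vertex {cv!r} has no metamer components")
        base_comp = idx[_finest_base(tree, cv, finest)]
        cbase[k] = base[base_comp]
        w = length[members]
        if w.sum() > 0:
            cbary[k] = (bary[members] * w[:, None]).sum(axis=0) / w.sum()
        else:
            cbary[k] = bary[members].mean(axis=0)
        clen[k] = w.sum()
        ctop[k] = top[members[np.argmax(depth[members])]]
    csemi = np.linalg.norm(cbary - cbase, axis=1)
    frame = _assemble(coarse, cbase, ctop, cbary, clen, csemi)
    return GeometryTable(scale, scale_name, frame)


def _finest_base(tree: MultiScaleTree, cv: str, finest: int) -> str:
    """Base metamer of a complex possibly several scales above the finest."""
    v = cv
    while tree.scale_of[v] < finest:
        v = tree.base_component(v)
    return v


def _assemble(ids, base, top, bary, length, semi) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "base_x": base[:, 0], "base_y": base[:, 1], "base_z": base[:, 2],
            "top_x": top[:, 0], "top_y": top[:, 1], "top_z": top[:, 2],
            "bary_x": bary[:, 0], "bary_y": bary[:, 1], "bary_z": bary[:, 2],
            "length": length, "semi_length": semi,
        },
        index=list(ids),
    )


# --------------------------------------------------------------------------
# distances
# --------------------------------------------------------------------------

class _DistanceEngine:
    """Binary-lifting GCA + root-path prefix sums for one scale.

    Shared across all pairs so that the all-pairs cost is near-quadratic in
    the number of components at the working scale, independent of the
    number of metamers underneath.
    """

    def __init__(self, tree: MultiScaleTree, geom: GeometryTable):
        ids = list(geom.frame.index)
        self.ids = ids
        self.index = {v: k for k, v in enumerate(ids)}
        n = len(ids)
        parent = np.full(n, -1, dtype=np.int64)
        for v in ids:
            p = tree.parent_of[v]
            if p is not None:
                parent[self.index[v]] = self.index[p]
        self.parent = parent

        # depths via repeated sweep over a topological order
        order: list[int] = []
        children: dict[int, list[int]] = {}
        for k, p in enumerate(parent):
            children.setdefault(int(p), []).append(k)
        roots = children.get(-1, [])
        if len(roots) != 1:
            raise GeometryError("scale does not form a single rooted tree")
        stack = [roots[0]]
        depth = np.zeros(n, dtype=np.int64)
        while stack:
            v = stack.pop()
            order.append(v)
            for c in children.get(v, []):
                depth[c] = depth[v] + 1
                stack.append(c)
        self.depth = depth

        length = geom.frame["length"].to_numpy(float)
        cum = np.zeros(n)
        for v in order:
            p = parent[v]
            cum[v] = (cum[p] if p >= 0 else 0.0) + length[v]
        self.cum = cum
        #: cumulative length up to and including the parent (0 at the root)
        self.cum_parent = np.where(parent >= 0, cum[parent], 0.0)

        K = max(1, int(np.ceil(np.log2(max(2, int(depth.max()) + 1)))) + 1)
        up = np.empty((K, n), dtype=np.int64)
        up[0] = np.where(parent >= 0, parent, np.arange(n))
        for k in range(1, K):
            up[k] = up[k - 1][up[k - 1]]
        self.up = up
        self.K = K

        self.base = geom.frame[["base_x", "base_y", "base_z"]].to_numpy(float)
        self.semi = geom.frame["semi_length"].to_numpy(float)

    def _lift(self, v: np.ndarray, steps: np.ndarray) -> np.ndarray:
        v = v.copy()
        for k in range(self.K):
            mask = (steps >> k) & 1 == 1
            if mask.any():
                v[mask] = self.up[k][v[mask]]
        return v

    def query(self, I: np.ndarray, J: np.ndarray) -> np.ndarray:
        """Vectorised distances for index arrays I, J (same length)."""
        I = np.asarray(I, dtype=np.int64)
        J = np.asarray(J, dtype=np.int64)
        dist = np.zeros(len(I))
        neq = I != J
        i, j = I[neq], J[neq]

        di, dj = self.depth[i], self.depth[j]
        a = self._lift(i, np.maximum(di - dj, 0))
        b = self._lift(j, np.maximum(dj - di, 0))

        anc = a == b  # GCA is the shallower endpoint
        out = np.empty(len(i))

        if anc.any():
            ii, jj = i[anc], j[anc]
            deeper = np.where(self.depth[ii] >= self.depth[jj], ii, jj)
            shallower = np.where(self.depth[ii] >= self.depth[jj], jj, ii)
            internal = self.cum_parent[deeper] - self.cum[shallower]
            out[anc] = self.semi[ii] + self.semi[jj] + internal

        gen = ~anc
        if gen.any():
            aa, bb = a[gen], b[gen]
            for k in range(self.K - 1, -1, -1):
                up_a, up_b = self.up[k][aa], self.up[k][bb]
                step = up_a != up_b
                aa = np.where(step, up_a, aa)
                bb = np.where(step, up_b, bb)
            g = self.parent[aa]  # == parent[bb]
            ii, jj = i[gen], j[gen]
            internal = (
                self.cum_parent[ii] + self.cum_parent[jj] - 2.0 * self.cum[g]
            )
            gap = np.linalg.norm(self.base[aa] - self.base[bb], axis=1)
            out[gen] = self.semi[ii] + self.semi[jj] + internal + gap

        dist[neq] = out
        return dist

    def gca_pair(self, i: int, j: int) -> int:
        di, dj = self.depth[i], self.depth[j]
        a = self._lift(np.array([i]), np.array([max(di - dj, 0)]))[0]
        b = self._lift(np.array([j]), np.array([max(dj - di, 0)]))[0]
        if a == b:
            return int(a)
        for k in range(self.K - 1, -1, -1):
            if self.up[k][a] != self.up[k][b]:
                a, b = self.up[k][a], self.up[k][b]
        return int(self.parent[a])


def _engine(tree: MultiScaleTree, geom: GeometryTable) -> _DistanceEngine:
    if geom._engine is None:
        geom._engine = _DistanceEngine(tree, geom)
    return geom._engine


def gca(tree: MultiScaleTree, i: str, j: str, scale_name: str = "M") -> str:
    """Greatest common ancestor of two vertices at the named scale."""
    scale = resolve_scale(tree, scale_name)
    if tree.scale_of[i] != scale or tree.scale_of[j] != scale:
        raise ValueError(
            f"gca: vertices {i!r}, {j!r} must both be at scale {scale_name!r}"
        )
    anc_i = list(tree.ancestors(i))
    anc_j = set(tree.ancestors(j))
    for v in anc_i:
        if v in anc_j:
            return v
    raise ValueError(f"{i!r} and {j!r} are not connected")  # pragma: no cover


def pairwise_distance(
    tree: MultiScaleTree, geom: GeometryTable, i: str, j: str
) -> float:
    """Topological distance in metres between two same-scale elements."""
    eng = _engine(tree, geom)
    return float(
        eng.query(np.array([eng.index[i]]), np.array([eng.index[j]]))[0]
    )


def distance_matrix(
    tree: MultiScaleTree,
    geom: GeometryTable,
    sources: Sequence[str],
    sinks: Sequence[str],
) -> DistanceMatrix:
    """Symmetric distance matrix over the union of sources and sinks."""
    ids = sorted(set(sources) | set(sinks), key=_id_sort_key)
    eng = _engine(tree, geom)
    k = np.array([eng.index[v] for v in ids], dtype=np.int64)
    n = len(ids)
    iu, ju = np.triu_indices(n, k=1)
    vals = np.zeros((n, n))
    if len(iu):
        d = eng.query(k[iu], k[ju])
        vals[iu, ju] = d
        vals[ju, iu] = d
    return DistanceMatrix(ids, vals)
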