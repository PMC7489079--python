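"""Multi-scale tree graph (MTG) container and validation.

A multi-scale tree graph represents a plant simultaneously at several nested
topological scales.  Scale 1 is the coarsest (the whole plant plus an opaque
root compartment); the largest scale index is the finest (the metamer: node +
internode + attached leaf/fruit).  Every vertex at a non-coarsest scale has a
*complex* — the vertex containing it at the next coarser scale — and the
vertices composing a complex (its *components*) form a connected subtree of
their own scale.  Within each scale vertices are linked by a same-scale
parent pointer carrying an edge type: succession ('<', continuation of an
axis) or branching ('+', a lateral).

The root system is represented as one opaque vertex per scale
(``organ_type='root_compartment'``) attached below the trunk base, so the
topological root of every scale is the root compartment.
"""

from __future__ import annotations

import re
from typing import Iterable, Iterator, Optional

EDGE_SUCCESSION = "<"
EDGE_BRANCHING = "+"
EDGE_TYPES = (EDGE_SUCCESSION, EDGE_BRANCHING)

ORGAN_TYPES = ("internode", "leaf", "fruit", "root_compartment", "wood")

#: vertex properties that must be non-negative when present
_NONNEG_PROPS = (
    "length",
    "radius",
    "leaf_area",
    "dry_mass",
    "internode_dry_mass",
    "leaf_dry_mass",
    "fruit_dry_mass",
)

_ID_RE = re.compile(r"^([A-Za-z_]+)(\d+)$")


def _id_sort_key(vid: str):
    """Natural sort key: class letters then numeric index (M2 < M10)."""
    m = _ID_RE.match(vid)
    if m:
        return (m.group(1), int(m.group(2)))
    return (vid, -1)


class TreeValidationError(ValueError):
    """Raised when a multi-scale tree violates a structural invariant."""


class MultiScaleTree:
    """Mutable multi-scale tree graph.

    Parameters
    ----------
    scale_names :
        Mapping of scale index (1 = coarsest) to a human-readable name,
        e.g. ``{1: 'plant', 2: 'GU', 3: 'metamer'}``.
    """

    def __init__(self, scale_names: Optional[dict[int, str]] = None):
        self.scale_names: dict[int, str] = dict(scale_names or {})
        self.scale_of: dict[str, int] = {}
        self.parent_of: dict[str, Optional[str]] = {}
        self.edge_type: dict[str, Optional[str]] = {}
        self.complex_of: dict[str, Optional[str]] = {}
        self.properties: dict[str, dict] = {}

    # -- construction -----------------------------------------------------

    def add_vertex(
        self,
        vid: str,
        scale: int,
        parent: Optional[str] = None,
        edge: Optional[str] = None,
        complex_id: Optional[str] = None,
        **props,
    ) -> str:
        if vid in self.scale_of:
            raise ValueError(f"duplicate vertex id {vid!r}")
        if parent is not None and parent not in self.scale_of:
            raise ValueError(f"unknown parent {parent!r} for {vid!r}")
        if parent is not None and edge not in EDGE_TYPES:
            raise ValueError(f"vertex {vid!r}: edge type must be one of {EDGE_TYPES}")
        if complex_id is not None and complex_id not in self.scale_of:
            raise ValueError(f"unknown complex {complex_id!r} for {vid!r}")
        self.scale_of[vid] = scale
        self.parent_of[vid] = parent
        self.edge_type[vid] = edge if parent is not None else None
        self.complex_of[vid] = complex_id
        self.properties[vid] = dict(props)
        return vid

    # -- basic queries ----------------------------------------------------

    @property
    def vertices(self) -> list[str]:
        """All vertex ids in deterministic (natural ascending) order."""
        return sorted(self.scale_of, key=_id_sort_key)

    @property
    def max_scale(self) -> int:
        return max(self.scale_of.values())

    def scale_index(self, scale_name: str) -> int:
        for idx, name in self.scale_names.items():
            if name == scale_name:
                return idx
        raise KeyError(f"unknown scale name {scale_name!r}; have {sorted(self.scale_names.values())}")

    def vertices_at_scale(self, scale: int) -> list[str]:
        return sorted((v for v, s in self.scale_of.items() if s == scale), key=_id_sort_key)

    def children_of(self, vid: str) -> list[str]:
        return sorted((v for v, p in self.parent_of.items() if p == vid), key=_id_sort_key)

    def scale_root(self, scale: int) -> str:
        roots = [v for v in self.vertices_at_scale(scale) if self.parent_of[v] is None]
        if len(roots) != 1:
            raise TreeValidationError(f"scale {scale} has {len(roots)} roots, expected 1")
        return roots[0]

    def prop(self, vid: str, key: str, default=None):
        return self.properties[vid].get(key, default)

    def set_prop(self, vid: str, key: str, value) -> None:
        self.properties[vid][key] = value

    # -- multi-scale navigation -------------------------------------------

    def components_of(self, vid: str) -> list[str]:
        """Components of a complex, base component first, then natural order.

        The base component is the unique component whose same-scale parent
        lies outside the complex (or has no parent).
        """
        if self.scale_of[vid] == self.max_scale:
            raise ValueError(f"vertex {vid!r} is at the finest scale and has no components")
        comps = sorted(
            (v for v, c in self.complex_of.items() if c == vid), key=_id_sort_key
        )
        if not comps:
            return []
        base = self.base_component(vid, comps)
        return [base] + [c for c in comps if c != base]

    def base_component(self, vid: str, comps: Optional[Iterable[str]] = None) -> str:
        """The unique component whose same-scale parent is outside the complex."""
        if comps is None:
            comps = [v for v, c in self.complex_of.items() if c == vid]
        comp_set = set(comps)
        bases = [
            v for v in comp_set
            if self.parent_of[v] is None or self.parent_of[v] not in comp_set
        ]
        if len(bases) != 1:
            raise TreeValidationError(
                f"complex {vid!r} has {len(bases)} base components, expected 1 "
                f"(components must form a connected subtree)"
            )
        return bases[0]

    def complex_at_scale(self, vid: str, scale: int) -> str:
        """Ancestor complex of ``vid`` at the given (coarser or equal) scale."""
        v = vid
        while self.scale_of[v] > scale:
            c = self.complex_of[v]
            if c is None:
                raise TreeValidationError(f"vertex {v!r} has no complex")
            v = c
        if self.scale_of[v] != scale:
            raise ValueError(f"vertex {vid!r} has no ancestor at scale {scale}")
        return v

    def count_components(self, scale_name: str) -> int:
        """Number of components at a named scale (root compartment counts)."""
        return len(self.vertices_at_scale(self.scale_index(scale_name)))

    def ancestors(self, vid: str) -> Iterator[str]:
        """Same-scale ancestors from ``vid`` (inclusive) up to the scale root."""
        v: Optional[str] = vid
        while v is not None:
            yield v
            v = self.parent_of[v]

    # -- validation --------------------------------------------------------

    def validate(self) -> "MultiScaleTree":
        """Check all structural invariants; raise :class:`TreeValidationError`.

        Returns ``self`` so readers can ``return tree.validate()``.
        """
        if not self.scale_of:
            raise TreeValidationError("empty tree")
        scales = sorted(set(self.scale_of.values()))
        if scales != list(range(1, len(scales) + 1)):
            raise TreeValidationError(f"scale indices must be 1..n, got {scales}")
        finest = scales[-1]

        for vid in self.vertices:
            s = self.scale_of[vid]
            p = self.parent_of[vid]
            if p is not None:
                if self.scale_of[p] != s:
                    raise TreeValidationError(
                        f"vertex {vid!r}: parent {p!r} at different scale"
                    )
                if self.edge_type[vid] not in EDGE_TYPES:
                    raise TreeValidationError(f"vertex {vid!r}: invalid edge type")
            c = self.complex_of[vid]
            if s > 1:
                if c is None:
                    raise TreeValidationError(f"vertex {vid!r}: missing complex")
                if self.scale_of[c] != s - 1:
                    raise TreeValidationError(
                        f"vertex {vid!r}: complex {c!r} not at next-coarser scale"
                    )
            elif c is not None:
                raise TreeValidationError(f"coarsest-scale vertex {vid!r} has a complex")
            for key in _NONNEG_PROPS:
                val = self.properties[vid].get(key)
                if val is not None and val < 0:
                    raise TreeValidationError(f"vertex {vid!r}: negative {key}")

        # one root and no cycles per scale, checked by traversal
        children: dict[str, list[str]] = {v: [] for v in self.scale_of}
        for v, p in self.parent_of.items():
            if p is not None:
                children[p].append(v)
        for s in scales:
            at_scale = self.vertices_at_scale(s)
            roots = [v for v in at_scale if self.parent_of[v] is None]
            if len(roots) != 1:
                raise TreeValidationError(
                    f"scale {s}: expected exactly 1 root, found {len(roots)}"
                )
            seen: set[str] = set()
            stack = [roots[0]]
            while stack:
                v = stack.pop()
                if v in seen:
                    raise TreeValidationError(f"cycle detected at vertex {v!r}")
                seen.add(v)
                stack.extend(children[v])
            if len(seen) != len(at_scale):
                orphan = sorted(set(at_scale) - seen, key=_id_sort_key)[0]
                raise TreeValidationError(
                    f"scale {s}: vertex {orphan!r} unreachable from root "
                    f"(cycle or forest)"
                )

        # components of each complex form a connected subtree with one base
        for s in scales[:-1]:
            for cx in self.vertices_at_scale(s):
                comps = [v for v, c in self.complex_of.items() if c == cx]
                if comps:
                    self.base_component(cx, comps)
                    comp_set = set(comps)
                    for v in comps:
                        p = self.parent_of[v]
                        if p is not None and p in comp_set:
                            continue
                        # v is the base; its siblings must chain inside
                    # connectivity: every non-base must reach base inside set
                    base = self.base_component(cx, comps)
                    for v in comps:
                        w = v
                        while w != base:
                            w = self.parent_of[w]
                            if w is None or w not in comp_set:
                                raise TreeValidationError(
                                    f"complex {cx!r}: component {v!r} disconnected "
                                    f"from base {base!r}"
                                )
        return self

    # -- misc ---------------------------------------------------------------

    def copy(self) -> "MultiScaleTree":
        t = MultiScaleTree(self.scale_names)
        t.scale_of = dict(self.scale_of)
        t.parent_of = dict(self.parent_of)
        t.edge_type = dict(self.edge_type)
        t.complex_of = dict(self.complex_of)
        t.properties = {v: dict(p) for v, p in self.properties.items()}
        return t

    def __len__(self) -> int:
        return len(self.scale_of)

    def __repr__(self) -> str:
        counts = {
            self.scale_names.get(s, s): len(self.vertices_at_scale(s))
            for s in sorted(set(self.scale_of.values()))
        }
        return f"MultiScaleTree({counts})"


def isomorphic(a: MultiScaleTree, b: MultiScaleTree, rel_tol: float = 1e-12) -> bool:
    """True if two trees have identical ids, topology and properties.

    Float properties are compared to ``rel_tol`` relative tolerance,
    everything else exactly.
    """
    if set(a.scale_of) != set(b.scale_of):
        return False
    for v in a.scale_of:
        if a.scale_of[v] != b.scale_of[v]:
            return False
        if a.parent_of[v] != b.parent_of[v] or a.edge_type[v] != b.edge_type[v]:
            return False
        if a.complex_of[v] != b.complex_of[v]:
            return False
        pa, pb = a.properties[v], b.properties[v]
        if set(pa) != set(pb):
            return False
        for k in pa:
            if not _prop_close(pa[k], pb[k], rel_tol):
                return False
    return True


def _prop_close(x, y, rel_tol: float) -> bool:
    if isinstance(x, float) or isinstance(y, float):
        if isinstance(x, (tuple, list)) or isinstance(y, (tuple, list)):
            return False
        ref = max(abs(float(x)), abs(float(y)), 1.0)
        return abs(float(x) - float(y)) <= rel_tol * ref
    if isinstance(x, (tuple, list)) and isinstance(y, (tuple, list)):
        return len(x) == len(y) and all(_prop_close(a, b, rel_tol) for a, b in zip(x, y))
    return x == y
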