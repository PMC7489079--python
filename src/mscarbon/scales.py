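"""Construction of coarse topological scales by grouping metamers.

Five stock decompositions of an apple-like tree are provided, mirroring the
levels at which source-sink carbon exchange is commonly modelled:

``M``    every metamer its own component (the reference, finest scale);
``GU``   growth units, read from a per-metamer ``gu_id`` label;
``TBS``  main trunk + first-order woody branches + current-year leafy shoots;
``BR1``  main trunk + entire first-order branch subtrees (shoots included);
``FU``   fruiting units: each maximal section of exactly 1-year-old wood
         together with the current-year shoots borne on it.

The root system is always one opaque component of its own at every scale.
A built scale is inserted between the whole-plant scale and the metamer
scale, producing a fresh three-scale tree; coarse parent and edge type are
derived from the single finest-scale edge crossing the group boundary, and
the coarse ``length`` is the sum of component lengths.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Optional

from .mtg import EDGE_BRANCHING, MultiScaleTree, TreeValidationError, _id_sort_key

log = logging.getLogger(__name__)

STOCK_SCALES = ("M", "GU", "TBS", "BR1", "FU")


@dataclass
class ScaleSpec:
    """Declarative description of a grouping of metamers.

    ``kind`` selects a stock rule (``gu``, ``tbs``, ``br1``, ``fu``,
    ``metamer``, ``single``) or a user rule: ``labels_fn`` mapping the tree
    to a per-metamer group label, or ``edge_predicate(tree, child, parent)``
    returning True when the two endpoints of a finest-scale edge belong to
    the same group.
    """

    name: str
    kind: str = "labels"
    property_name: str = "gu_id"
    labels_fn: Optional[Callable[[MultiScaleTree], dict[str, object]]] = None
    edge_predicate: Optional[Callable[[MultiScaleTree, str, str], bool]] = None

    def labels(self, tree: MultiScaleTree) -> dict[str, object]:
        if self.kind == "gu":
            return _labels_from_property(tree, self.property_name)
        if self.kind == "tbs":
            return classify_tbs(tree)
        if self.kind == "br1":
            return classify_br1(tree)
        if self.kind == "fu":
            return classify_fu(tree)
        if self.kind == "metamer":
            return {v: v for v in tree.vertices_at_scale(tree.max_scale)}
        if self.kind == "single":
            return {
                v: ("root" if _is_root_organ(tree, v) else "plant")
                for v in tree.vertices_at_scale(tree.max_scale)
            }
        if self.kind == "labels":
            if self.labels_fn is None:
                raise ValueError("ScaleSpec(kind='labels') needs labels_fn")
            return self.labels_fn(tree)
        if self.kind == "edge":
            if self.edge_predicate is None:
                raise ValueError("ScaleSpec(kind='edge') needs edge_predicate")
            return _labels_from_edges(tree, self.edge_predicate)
        raise ValueError(f"unknown grouping rule kind {self.kind!r}")


def stock_spec(scale_name: str) -> ScaleSpec:
    """ScaleSpec for one of the stock scale names (GU/TBS/BR1/FU/M)."""
    kinds = {"GU": "gu", "TBS": "tbs", "BR1": "br1", "FU": "fu", "M": "metamer"}
    if scale_name not in kinds:
        raise KeyError(f"unknown stock scale {scale_name!r}")
    return ScaleSpec(name=scale_name, kind=kinds[scale_name])


# --------------------------------------------------------------------------
# helpers on the metamer scale
# --------------------------------------------------------------------------

def _is_root_organ(tree, v) -> bool:
    return tree.prop(v, "organ_type") == "root_compartment"


def current_year(tree: MultiScaleTree) -> int:
    years = [
        tree.prop(v, "year")
        for v in tree.vertices_at_scale(tree.max_scale)
        if tree.prop(v, "year") is not None
    ]
    if not years:
        raise TreeValidationError("no 'year' property on any metamer")
    return max(years)


def branching_order(tree: MultiScaleTree) -> dict[str, int]:
    """Branching order per metamer: 0 on the trunk axis, +1 per '+' edge."""
    finest = tree.max_scale
    order: dict[str, int] = {}
    root = tree.scale_root(finest)
    stack = [(root, 0)]
    while stack:
        v, o = stack.pop()
        order[v] = o
        for c in tree.children_of(v):
            stack.append((c, o + 1 if tree.edge_type[c] == EDGE_BRANCHING else o))
    return order


def _year_of(tree, v) -> int:
    y = tree.prop(v, "year")
    if y is None:
        raise TreeValidationError(f"vertex {v!r}: missing 'year' property")
    return y


def _subtree(tree, root_v, member=None) -> list[str]:
    """Metamers of the subtree from root_v, optionally filtered by a predicate
    that prunes (children of a rejected vertex are not visited)."""
    out = []
    stack = [root_v]
    while stack:
        v = stack.pop()
        if member is not None and not member(v):
            continue
        out.append(v)
        stack.extend(tree.children_of(v))
    return out


def _leafy_shoot_roots(tree) -> list[str]:
    """Roots of maximal current-year subtrees bearing at least one leaf."""
    yr = current_year(tree)
    roots = []
    for v in tree.vertices_at_scale(tree.max_scale):
        if _is_root_organ(tree, v) or _year_of(tree, v) != yr:
            continue
        p = tree.parent_of[v]
        if p is None or _is_root_organ(tree, p) or _year_of(tree, p) != yr:
            roots.append(v)
    leafy = []
    for r in roots:
        members = _subtree(tree, r, member=lambda v: _year_of(tree, v) == yr)
        if any((tree.prop(v, "leaf_area") or 0.0) > 0 for v in members):
            leafy.append(r)
    return sorted(leafy, key=_id_sort_key)


# --------------------------------------------------------------------------
# stock classifiers
# --------------------------------------------------------------------------

def classify_tbs(tree: MultiScaleTree) -> dict[str, object]:
    """Partition metamers into trunk / first-order branches / leafy shoots.

    The trunk is the order-0 axis; a branch is the woody (non current-year
    leafy) part of a subtree borne laterally on the trunk; a shoot is a
    maximal current-year subtree bearing at least one leaf, wherever borne.
    Leafless current-year growth stays with its supporting trunk or branch.
    """
    finest = tree.max_scale
    order = branching_order(tree)
    labels: dict[str, object] = {}
    yr = current_year(tree)

    # shoots first: they win over trunk/branch membership
    shoot_members: set[str] = set()
    for k, r in enumerate(_leafy_shoot_roots(tree)):
        for v in _subtree(tree, r, member=lambda v: _year_of(tree, v) == yr):
            labels[v] = f"shoot{k}"
            shoot_members.add(v)

    # branch roots: '+'-edge children of trunk metamers, outside shoots
    branch_roots = []
    for v in tree.vertices_at_scale(finest):
        if v in shoot_members or _is_root_organ(tree, v):
            continue
        p = tree.parent_of[v]
        if (
            p is not None
            and not _is_root_organ(tree, p)
            and tree.edge_type[v] == EDGE_BRANCHING
            and order[p] == 0
        ):
            branch_roots.append(v)
    branch_roots.sort(key=_id_sort_key)
    branch_of_root = {r: f"branch{k}" for k, r in enumerate(branch_roots)}

    for v in tree.vertices_at_scale(finest):
        if v in labels:
            continue
        if _is_root_organ(tree, v):
            labels[v] = "root"
            continue
        # walk up to the nearest branch root, if any
        w, lab = v, "trunk"
        while w is not None:
            if w in branch_of_root:
                lab = branch_of_root[w]
                break
            w = tree.parent_of[w]
        labels[v] = lab
    return labels


def classify_br1(tree: MultiScaleTree) -> dict[str, object]:
    """Trunk (with its own shoots), entire first-order branch subtrees, root."""
    tbs = classify_tbs(tree)
    finest = tree.max_scale
    labels: dict[str, object] = {}
    for v in tree.vertices_at_scale(finest):
        if _is_root_organ(tree, v):
            labels[v] = "root"
            continue
        w, lab = v, "trunk"
        while w is not None:
            if isinstance(tbs[w], str) and str(tbs[w]).startswith("branch"):
                lab = tbs[w]
                break
            w = tree.parent_of[w]
        labels[v] = lab
    return labels


def classify_fu(tree: MultiScaleTree) -> dict[str, object]:
    """Fruiting units: 1-year-old wood sections + the shoots borne on them.

    Wood older than one year forms connected supporting-structure groups;
    current-year shoots borne directly on old wood (epicormics) are merged
    into their supporting group and flagged in the log.  A tree with no
    1-year-old wood degenerates to a single unit covering current-year
    growth.
    """
    finest = tree.max_scale
    yr = current_year(tree)
    labels: dict[str, object] = {}
    one_year = [
        v for v in tree.vertices_at_scale(finest)
        if not _is_root_organ(tree, v) and _year_of(tree, v) == yr - 1
    ]

    # connected sections of 1-year wood
    section_of: dict[str, int] = {}
    n_sections = 0
    for v in sorted(one_year, key=_id_sort_key):
        if v in section_of:
            continue
        stack, sec = [v], n_sections
        n_sections += 1
        while stack:
            w = stack.pop()
            if w in section_of:
                continue
            section_of[w] = sec
            p = tree.parent_of[w]
            if p in one_year and p not in section_of:
                stack.append(p)
            for c in tree.children_of(w):
                if c in one_year:
                    stack.append(c)
    for v, sec in section_of.items():
        labels[v] = f"FU{sec}"

    # older wood: connected supporting groups
    old_wood = [
        v for v in tree.vertices_at_scale(finest)
        if not _is_root_organ(tree, v) and _year_of(tree, v) <= yr - 2
    ]
    old_set = set(old_wood)
    wood_group: dict[str, int] = {}
    n_wood = 0
    for v in sorted(old_wood, key=_id_sort_key):
        if v in wood_group:
            continue
        stack, grp = [v], n_wood
        n_wood += 1
        while stack:
            w = stack.pop()
            if w in wood_group:
                continue
            wood_group[w] = grp
            p = tree.parent_of[w]
            if p in old_set:
                stack.append(p)
            for c in tree.children_of(w):
                if c in old_set:
                    stack.append(c)
    for v, grp in wood_group.items():
        labels[v] = f"wood{grp}"

    degenerate = n_sections == 0
    n_epicormic = 0
    for v in tree.vertices_at_scale(finest):
        if v in labels:
            continue
        if _is_root_organ(tree, v):
            labels[v] = "root"
            continue
        if degenerate:
            labels[v] = "FU0"
            continue
        # current-year metamer: inherit the group of the supporting wood
        w = tree.parent_of[v]
        while w is not None and w not in labels:
            w = tree.parent_of[w]
        if w is None or labels[w] == "root":
            labels[v] = "FU0" if n_sections else "wood0"
        else:
            labels[v] = labels[w]
            if str(labels[w]).startswith("wood") and _year_of(tree, v) == yr:
                n_epicormic += 1
    if n_epicormic:
        log.warning(
            "%d current-year metamers borne on old wood (epicormic) merged "
            "into supporting-structure groups", n_epicormic,
        )
    return labels


# --------------------------------------------------------------------------
# generic machinery
# --------------------------------------------------------------------------

def _labels_from_property(tree, prop_name: str) -> dict[str, object]:
    labels = {}
    for v in tree.vertices_at_scale(tree.max_scale):
        if _is_root_organ(tree, v):
            labels[v] = "root"
            continue
        lab = tree.prop(v, prop_name)
        if lab is None:
            raise TreeValidationError(f"vertex {v!r}: missing {prop_name!r} label")
        labels[v] = lab
    return labels


def _labels_from_edges(tree, predicate) -> dict[str, object]:
    finest = tree.max_scale
    labels: dict[str, object] = {}
    n = 0
    root = tree.scale_root(finest)
    stack = [root]
    while stack:
        v = stack.pop()
        p = tree.parent_of[v]
        if (
            p is None
            or _is_root_organ(tree, v) != _is_root_organ(tree, p)
            or not predicate(tree, v, p)
        ):
            labels[v] = f"g{n}"
            n += 1
        else:
            labels[v] = labels[p]
        stack.extend(tree.children_of(v))
    return labels


def build_scale(tree: MultiScaleTree, spec: ScaleSpec) -> MultiScaleTree:
    """Insert the scale described by ``spec`` into a fresh three-scale tree.

    The input tree may itself carry a previously built scale; grouping is
    always done over the metamer scale and the output holds exactly
    plant / ``spec.name`` / metamer.
    """
    labels = spec.labels(tree)
    finest = tree.max_scale
    metamers = tree.vertices_at_scale(finest)
    missing = [v for v in metamers if v not in labels]
    if missing:
        raise TreeValidationError(f"grouping rule left {len(missing)} metamers unlabelled")

    members: dict[object, list[str]] = {}
    for v in metamers:
        members.setdefault(labels[v], []).append(v)
    for lab, mem in list(members.items()):
        if not mem:
            log.warning("group %r contains zero metamers; dropped", lab)
            del members[lab]

    # base metamer of each group = member whose parent is outside the group
    base_of: dict[object, str] = {}
    for lab, mem in members.items():
        mset = set(mem)
        bases = [
            v for v in mem
            if tree.parent_of[v] is None or tree.parent_of[v] not in mset
        ]
        if len(bases) != 1:
            raise TreeValidationError(
                f"grouping rule for scale {spec.name!r} produced a disconnected "
                f"group {lab!r} ({len(bases)} entry points)"
            )
        base_of[lab] = bases[0]
        # connectivity: every member must reach the base inside the group
        for v in mem:
            w = v
            while w != bases[0]:
                w = tree.parent_of[w]
                if w is None or w not in mset:
                    raise TreeValidationError(
                        f"group {lab!r} of scale {spec.name!r} is disconnected at {v!r}"
                    )

    # deterministic group ids, root compartment group first
    def group_key(lab):
        return _id_sort_key(base_of[lab])

    ordered = sorted(members, key=group_key)
    root_meta = tree.scale_root(finest)
    root_lab = labels[root_meta]
    if ordered[0] != root_lab:
        ordered.remove(root_lab)
        ordered.insert(0, root_lab)
    gid_of = {lab: f"G{k}" for k, lab in enumerate(ordered)}

    out = MultiScaleTree({1: "plant", 2: spec.name, 3: "metamer"})
    root_is_comp = _is_root_organ(tree, root_meta)
    if root_is_comp:
        out.add_vertex("P0", 1)
        out.add_vertex("P1", 1, parent="P0", edge="<")
    else:
        out.add_vertex("P1", 1)
    _copy_plant_props(tree, out)

    # group vertices in topological order (base's parent group created first)
    created: set[object] = set()

    def create_group(lab):
        if lab in created:
            return
        base = base_of[lab]
        p = tree.parent_of[base]
        if p is None:
            plant_cx = "P0" if (root_is_comp and _is_root_organ(tree, base)) else "P1"
            out.add_vertex(gid_of[lab], 2, complex_id=plant_cx, label=str(lab),
                           length=_group_length(tree, members[lab]))
        else:
            plab = labels[p]
            create_group(plab)
            plant_cx = "P1"
            out.add_vertex(
                gid_of[lab], 2, parent=gid_of[plab], edge=tree.edge_type[base],
                complex_id=plant_cx, label=str(lab),
                length=_group_length(tree, members[lab]),
            )
        created.add(lab)

    for lab in ordered:
        create_group(lab)

    # metamers, in topological order
    stack = [root_meta]
    while stack:
        v = stack.pop()
        out.add_vertex(
            v, 3, parent=tree.parent_of[v], edge=tree.edge_type[v],
            complex_id=gid_of[labels[v]], **tree.properties[v],
        )
        stack.extend(reversed(tree.children_of(v)))

    return out.validate()


def _copy_plant_props(src: MultiScaleTree, out: MultiScaleTree) -> None:
    """Carry plant-scale properties (e.g. stored root coordinates) across."""
    src_root = src.scale_root(1)
    out.properties[out.scale_root(1)].update(src.properties[src_root])
    src_rest = [v for v in src.vertices_at_scale(1) if v != src_root]
    out_rest = [v for v in out.vertices_at_scale(1) if v != out.scale_root(1)]
    if src_rest and out_rest:
        out.properties[out_rest[0]].update(src.properties[src_rest[0]])


def _group_length(tree, mem) -> float:
    return float(sum(tree.prop(v, "length", 0.0) or 0.0 for v in mem))


def metamer_view(tree: MultiScaleTree) -> MultiScaleTree:
    """A plant/metamer two-scale view of the tree (reference M scale)."""
    finest = tree.max_scale
    root_meta = tree.scale_root(finest)
    root_is_comp = _is_root_organ(tree, root_meta)
    out = MultiScaleTree({1: "plant", 2: "metamer"})
    if root_is_comp:
        out.add_vertex("P0", 1)
        out.add_vertex("P1", 1, parent="P0", edge="<")
    else:
        out.add_vertex("P1", 1)
    _copy_plant_props(tree, out)
    stack = [root_meta]
    while stack:
        v = stack.pop()
        cx = "P0" if (root_is_comp and _is_root_organ(tree, v)) else "P1"
        out.add_vertex(
            v, 2, parent=tree.parent_of[v], edge=tree.edge_type[v],
            complex_id=cx, **tree.properties[v],
        )
        stack.extend(reversed(tree.children_of(v)))
    return out.validate()
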