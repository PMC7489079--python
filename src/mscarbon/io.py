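"""Readers and writers for multi-scale tree graphs.

Two on-disk dialects are supported:

``amapmod``
    A documented subset of the classic AMAPmod/OpenAlea MTG text format:
    a header with CODE / CLASSES / DESCRIPTION / FEATURES sections followed
    by an MTG section in which each line encodes one step of a walk over the
    finest scale.  Edge codes are ``/`` (decomposition), ``<`` (succession)
    and ``+`` (branching); a leading ``^`` continues from the previous
    line's vertex.  Anything outside the subset is a parse error with a line
    number, never a silent skip.

``tabular``
    A flat CSV interchange table, one row per finest-scale vertex, with
    columns ``vertex_id, parent_id, edge_type, organ_type, year,
    top_x, top_y, top_z, radius, length, leaf_area`` plus optional extra
    property columns and at most one ``group:<scale name>`` column giving
    the membership of each vertex in a named intermediate scale.

All internal lengths and coordinates are metres; readers and writers accept
a ``unit`` flag (``m``/``cm``/``mm``) for conversion of coordinates, radii
and lengths.  Leaf areas are always m².
"""

from __future__ import annotations

import csv
import json
import re
from pathlib import Path
from typing import Optional

from .mtg import (
    EDGE_BRANCHING,
    EDGE_SUCCESSION,
    MultiScaleTree,
    _ID_RE,
)

_UNIT_FACTORS = {"m": 1.0, "cm": 0.01, "mm": 0.001}

#: properties carrying a length dimension, subject to unit conversion
_LENGTH_PROPS = ("radius", "length")

_TOKEN_RE = re.compile(r"([/<+])([A-Za-z_]+)(\d+)")

_TABULAR_FIXED = [
    "vertex_id", "parent_id", "edge_type", "organ_type", "year",
    "top_x", "top_y", "top_z", "radius", "length", "leaf_area",
]


class MTGParseError(ValueError):
    def __init__(self, path, lineno, message):
        super().__init__(f"{path}:{lineno}: {message}")
        self.lineno = lineno


# --------------------------------------------------------------------------
# public API
# --------------------------------------------------------------------------

def read_mtg(path, dialect: str = "amapmod", unit: str = "m") -> MultiScaleTree:
    """Read a multi-scale tree from ``path`` and validate it."""
    path = Path(path)
    if dialect == "amapmod":
        tree = _read_amapmod(path)
    elif dialect == "tabular":
        tree = _read_tabular(path)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    _convert_units(tree, _UNIT_FACTORS[unit])
    return tree.validate()


def write_mtg(tree: MultiScaleTree, path, dialect: str = "amapmod", unit: str = "m") -> None:
    """Write a validated tree so that ``read_mtg`` recovers an isomorphic copy."""
    path = Path(path)
    factor = _UNIT_FACTORS[unit]
    if factor != 1.0:
        tree = tree.copy()
        _convert_units(tree, 1.0 / factor)
    if dialect == "amapmod":
        _write_amapmod(tree, path)
    elif dialect == "tabular":
        _write_tabular(tree, path)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


def tree_to_json(tree: MultiScaleTree) -> str:
    """JSON dump of the validated graph (topology + properties)."""
    payload = {
        "scale_names": {str(k): v for k, v in tree.scale_names.items()},
        "vertices": {
            v: {
                "scale": tree.scale_of[v],
                "parent": tree.parent_of[v],
                "edge_type": tree.edge_type[v],
                "complex": tree.complex_of[v],
                "properties": _jsonable(tree.properties[v]),
            }
            for v in tree.vertices
        },
    }
    return json.dumps(payload, indent=1, sort_keys=True)


def tree_from_json(text: str) -> MultiScaleTree:
    payload = json.loads(text)
    tree = MultiScaleTree({int(k): v for k, v in payload["scale_names"].items()})
    items = payload["vertices"]
    # insertion order: parents/complexes before children; do a simple pass loop
    pending = dict(items)
    while pending:
        progressed = False
        for vid in list(pending):
            rec = pending[vid]
            if rec["parent"] in tree.scale_of or rec["parent"] is None:
                if rec["complex"] is None or rec["complex"] in tree.scale_of:
                    props = {
                        k: tuple(v) if isinstance(v, list) else v
                        for k, v in rec["properties"].items()
                    }
                    tree.add_vertex(
                        vid, rec["scale"], rec["parent"], rec["edge_type"],
                        rec["complex"], **props,
                    )
                    del pending[vid]
                    progressed = True
        if not progressed:
            raise ValueError("JSON tree has unresolved parent/complex references")
    return tree.validate()


# --------------------------------------------------------------------------
# helpers
# --------------------------------------------------------------------------

def _jsonable(props: dict) -> dict:
    return {k: list(v) if isinstance(v, tuple) else v for k, v in props.items()}


def _convert_units(tree: MultiScaleTree, factor: float) -> None:
    if factor == 1.0:
        return
    for v in tree.scale_of:
        props = tree.properties[v]
        for key in _LENGTH_PROPS:
            if key in props and props[key] is not None:
                props[key] = props[key] * factor
        if "top_xyz" in props and props["top_xyz"] is not None:
            props["top_xyz"] = tuple(c * factor for c in props["top_xyz"])


def _feature_type(values) -> str:
    import numpy as np
    for v in values:
        if isinstance(v, bool):
            return "ALPHA"
        if isinstance(v, (float, np.floating)):
            return "REAL"
        if isinstance(v, (int, np.integer)):
            continue
        return "ALPHA"
    return "INT"


def _parse_feature(text: str, ftype: str):
    if text == "":
        return None
    if ftype == "INT":
        return int(text)
    if ftype == "REAL":
        return float(text)
    return text


# --------------------------------------------------------------------------
# amapmod dialect
# --------------------------------------------------------------------------

def _write_amapmod(tree: MultiScaleTree, path: Path) -> None:
    scales = sorted(set(tree.scale_of.values()))
    finest = scales[-1]

    # class symbol per vertex = alphabetic id prefix; must be scale-consistent
    class_scale: dict[str, int] = {}
    for v in tree.vertices:
        m = _ID_RE.match(v)
        if not m:
            raise ValueError(
                f"vertex id {v!r} is not of the form <letters><digits>; "
                f"re-index the tree before writing the amapmod dialect"
            )
        sym = m.group(1)
        s = tree.scale_of[v]
        if class_scale.setdefault(sym, s) != s:
            raise ValueError(f"class symbol {sym!r} used at two scales")

    # feature schema: union of scalar property keys, xyz expanded
    feat_values: dict[str, list] = {}
    for v in tree.vertices:
        for k, val in tree.properties[v].items():
            if val is None:
                continue
            if k == "top_xyz":
                for axis, c in zip("xyz", val):
                    feat_values.setdefault(f"top_{axis}", []).append(float(c))
            else:
                feat_values.setdefault(k, []).append(val)
    feat_names = sorted(feat_values)
    feat_types = {k: _feature_type(feat_values[k]) for k in feat_names}

    def feature_row(v: str) -> list[str]:
        props = tree.properties[v]
        row = []
        for k in feat_names:
            if k.startswith("top_") and k[4:] in "xyz" and "top_xyz" in props:
                val = props["top_xyz"]["xyz".index(k[4])]
            else:
                val = props.get(k)
            if val is None:
                row.append("")
            elif feat_types[k] == "REAL":
                row.append(repr(float(val)))
            elif feat_types[k] == "INT":
                row.append(str(int(val)))
            else:
                row.append(str(val))
        return row

    def complexes_chain(v: str) -> list[str]:
        # coarse containers of v from scale 1 down to finest-1
        chain = []
        c = tree.complex_of[v]
        while c is not None:
            chain.append(c)
            c = tree.complex_of[c]
        return chain[::-1]

    lines: list[tuple[str, list[str]]] = []
    declared: set[str] = set()

    def emit_vertex(v: str, prev: Optional[str]) -> None:
        edge = tree.edge_type[v] or "/"
        chain = complexes_chain(v)
        new_chain = [c for c in chain if c not in declared]
        tokens = []
        if prev is not None and tree.parent_of[v] == prev:
            first = True
            code = "^"
            for c in new_chain:
                tokens.append((edge if first else "/") + c)
                first = False
            tokens.append((edge if first else "/") + v)
            code += "".join(tokens)
        else:
            # full path restart: navigate to parent (if any), then create
            parent = tree.parent_of[v]
            code = ""
            if parent is not None:
                for c in complexes_chain(parent):
                    code += "/" + c
                code += "/" + parent
                first = True
                for c in new_chain:
                    code += (edge if first else "/") + c
                    first = False
                code += (edge if first else "/") + v
            else:
                for c in new_chain:
                    code += "/" + c
                code += "/" + v
        declared.update(new_chain)
        declared.add(v)
        lines.append((code, feature_row(v)))

    if finest == 1:
        order = tree.vertices_at_scale(1)
        prev = None
        root = tree.scale_root(1)
        stack = [root]
        order = []
        while stack:
            v = stack.pop()
            order.append(v)
            stack.extend(reversed(tree.children_of(v)))
        for v in order:
            emit_vertex(v, prev)
            prev = v
    else:
        root = tree.scale_root(finest)
        prev = None
        stack = [root]
        while stack:
            v = stack.pop()
            emit_vertex(v, prev)
            prev = v
            kids = tree.children_of(v)
            # depth-first, natural order first
            stack.extend(reversed(kids))
        # property-attachment lines for coarse vertices with properties
        for s in scales[:-1]:
            for cx in tree.vertices_at_scale(s):
                if tree.properties[cx]:
                    code = ""
                    for c in complexes_chain(cx):
                        code += "/" + c
                    code += "/" + cx
                    lines.append((code, feature_row(cx)))

    with open(path, "w") as fh:
        fh.write("CODE:\tFORM-A\n")
        scale_names = ",".join(
            f"{s}={tree.scale_names.get(s, f'scale{s}')}" for s in scales
        )
        fh.write(f"# SCALES: {scale_names}\n")
        fh.write("\nCLASSES:\n")
        fh.write("SYMBOL\tSCALE\tDECOMPOSITION\tINDEXATION\tDEFINITION\n")
        fh.write("$\t0\tFREE\tFREE\tIMPLICIT\n")
        for sym in sorted(class_scale):
            fh.write(f"{sym}\t{class_scale[sym]}\tFREE\tFREE\tEXPLICIT\n")
        fh.write("\nDESCRIPTION:\nLEFT\tRIGHT\tRELTYPE\tMAX\n")
        fh.write("\nFEATURES:\nNAME\tTYPE\n")
        for k in feat_names:
            fh.write(f"{k}\t{feat_types[k]}\n")
        fh.write("\nMTG:\n")
        fh.write("\t".join(["ENTITY-CODE"] + feat_names) + "\n")
        for code, row in lines:
            fh.write("\t".join([code] + row) + "\n")


def _read_amapmod(path: Path) -> MultiScaleTree:
    text = path.read_text().splitlines()
    section = None
    class_scale: dict[str, int] = {}
    feat_names: list[str] = []
    feat_types: dict[str, str] = {}
    scale_names: dict[int, str] = {}
    code_lines: list[tuple[int, str]] = []
    header_seen = False

    for lineno, raw in enumerate(text, start=1):
        line = raw.rstrip("\n")
        if line.startswith("# SCALES:"):
            for item in line.split(":", 1)[1].split(","):
                idx, name = item.strip().split("=")
                scale_names[int(idx)] = name
            continue
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        upper = line.split("\t")[0].strip()
        if upper in ("CODE:", "CLASSES:", "DESCRIPTION:", "FEATURES:", "MTG:"):
            section = upper[:-1]
            continue
        if section == "CLASSES":
            parts = line.split("\t")
            if parts[0] == "SYMBOL":
                continue
            if len(parts) < 2:
                raise MTGParseError(path, lineno, "malformed CLASSES row")
            if parts[0] != "$":
                class_scale[parts[0]] = int(parts[1])
        elif section == "FEATURES":
            parts = line.split("\t")
            if parts[0] == "NAME":
                continue
            if len(parts) < 2:
                raise MTGParseError(path, lineno, "malformed FEATURES row")
            feat_names.append(parts[0])
            feat_types[parts[0]] = parts[1]
        elif section == "MTG":
            if not header_seen:
                if not line.startswith("ENTITY-CODE"):
                    raise MTGParseError(path, lineno, "MTG section must start with ENTITY-CODE header")
                header_seen = True
                continue
            code_lines.append((lineno, line))
        elif section in ("CODE", "DESCRIPTION"):
            continue
        else:
            raise MTGParseError(path, lineno, f"content outside any known section: {line!r}")

    if not class_scale:
        raise MTGParseError(path, 0, "no CLASSES declared")
    finest = max(class_scale.values())
    tree = MultiScaleTree(scale_names or {s: f"scale{s}" for s in sorted(set(class_scale.values()))})

    xyz_parts = {f"top_{a}" for a in "xyz"}

    prev_line_last: Optional[str] = None
    for lineno, line in code_lines:
        cols = line.split("\t")
        code = cols[0]
        features = cols[1:]
        while features and features[-1] == "" and len(features) > len(feat_names):
            features.pop()
        if len(features) > len(feat_names):
            raise MTGParseError(path, lineno, "more feature columns than declared features")

        pos = 0
        continued = code.startswith("^")
        if continued:
            if prev_line_last is None:
                raise MTGParseError(path, lineno, "'^' with no previous line")
            pos = 1
        tokens = []
        while pos < len(code):
            m = _TOKEN_RE.match(code, pos)
            if not m:
                raise MTGParseError(path, lineno, f"bad code near {code[pos:pos+12]!r}")
            tokens.append((m.group(1), m.group(2) + m.group(3), m.group(2)))
            pos = m.end()
        if not tokens:
            raise MTGParseError(path, lineno, "empty entity code")

        # context per scale derived from attachment vertex
        attach: Optional[str] = prev_line_last if continued else None
        context: dict[int, str] = {}
        if attach is not None:
            v = attach
            while v is not None:
                context[tree.scale_of[v]] = v
                v = tree.complex_of[v]

        entry_edge: Optional[str] = None
        last_vertex = None
        for ec, vid, sym in tokens:
            if sym not in class_scale:
                raise MTGParseError(path, lineno, f"undeclared class symbol {sym!r}")
            s = class_scale[sym]
            if vid in tree.scale_of:
                if ec != "/":
                    raise MTGParseError(
                        path, lineno, f"edge {ec!r} before existing vertex {vid!r}; navigation uses '/'"
                    )
                attach = vid
                context = {}
                v: Optional[str] = vid
                while v is not None:
                    context[tree.scale_of[v]] = v
                    v = tree.complex_of[v]
                last_vertex = vid
                continue
            # creation
            if ec in (EDGE_SUCCESSION, EDGE_BRANCHING):
                if entry_edge is None:
                    entry_edge = ec
                elif ec != entry_edge:
                    raise MTGParseError(path, lineno, "conflicting edge codes in one line")
            cx = context.get(s - 1)
            if s > 1 and cx is None:
                raise MTGParseError(path, lineno, f"vertex {vid!r}: no complex in context at scale {s-1}")
            if s == finest:
                parent = attach if (attach is not None and tree.scale_of[attach] == finest) else None
            else:
                parent = None
                if attach is not None:
                    a = attach
                    while a is not None and tree.scale_of[a] > s:
                        a = tree.complex_of[a]
                    if a is not None and tree.scale_of[a] == s:
                        parent = a
            edge = entry_edge if parent is not None else None
            if parent is not None and edge is None:
                raise MTGParseError(
                    path, lineno, f"vertex {vid!r} needs '<' or '+' to attach to {parent!r}"
                )
            try:
                tree.add_vertex(vid, s, parent, edge, cx)
            except ValueError as exc:
                raise MTGParseError(path, lineno, str(exc)) from exc
            context[s] = vid
            last_vertex = vid
            if s == finest:
                attach = vid

        if last_vertex is None:
            raise MTGParseError(path, lineno, "line declared no vertex")
        # attach features to the last vertex of the line
        props = tree.properties[last_vertex]
        xyz = {}
        for name, cell in zip(feat_names, features):
            val = _parse_feature(cell, feat_types[name])
            if val is None:
                continue
            if name in xyz_parts:
                xyz[name[4:]] = float(val)
            else:
                props[name] = val
        if xyz:
            if set(xyz) != {"x", "y", "z"}:
                raise MTGParseError(path, lineno, "partial top_x/top_y/top_z triple")
            props["top_xyz"] = (xyz["x"], xyz["y"], xyz["z"])
        prev_line_last = last_vertex

    return tree


# --------------------------------------------------------------------------
# tabular dialect
# --------------------------------------------------------------------------

def _write_tabular(tree: MultiScaleTree, path: Path) -> None:
    finest = tree.max_scale
    rows = tree.vertices_at_scale(finest)

    group_col = None
    if finest >= 3:
        # one intermediate scale supported in the flat table
        if finest > 3:
            raise ValueError("tabular dialect supports at most one intermediate scale")
        group_col = f"group:{tree.scale_names.get(2, 'scale2')}"

    extra = sorted({
        k
        for v in rows
        for k in tree.properties[v]
        if k not in ("organ_type", "year", "top_xyz", "radius", "length", "leaf_area")
    })
    # base coordinates of the scale root live on its complex chain; persist
    # them as dedicated columns on the root row
    root_v = tree.scale_root(finest)
    root_base = None
    c = tree.complex_of[root_v]
    while c is not None and root_base is None:
        root_base = tree.prop(c, "top_xyz")
        c = tree.complex_of[c]
    base_cols = ["root_base_x", "root_base_y", "root_base_z"] if root_base else []
    header = list(_TABULAR_FIXED) + ([group_col] if group_col else []) + extra + base_cols

    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(header)
        for v in rows:
            p = tree.properties[v]
            xyz = p.get("top_xyz", (None, None, None))
            row = [
                v,
                tree.parent_of[v] or "",
                tree.edge_type[v] or "",
                p.get("organ_type", ""),
                p.get("year", ""),
                *(("" if c is None else repr(float(c))) for c in xyz),
                "" if p.get("radius") is None else repr(float(p["radius"])),
                "" if p.get("length") is None else repr(float(p["length"])),
                "" if p.get("leaf_area") is None else repr(float(p["leaf_area"])),
            ]
            if group_col:
                row.append(tree.complex_of[v])
            for k in extra:
                val = p.get(k, "")
                row.append("" if val is None else val)
            if base_cols:
                if v == root_v:
                    row.extend(repr(float(c)) for c in root_base)
                else:
                    row.extend(["", "", ""])
            w.writerow(row)


def _read_tabular(path: Path) -> MultiScaleTree:
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise MTGParseError(path, 1, "empty file")
        missing = [c for c in _TABULAR_FIXED if c not in reader.fieldnames]
        if missing:
            raise MTGParseError(path, 1, f"missing required columns: {missing}")
        group_cols = [c for c in reader.fieldnames if c.startswith("group:")]
        if len(group_cols) > 1:
            raise MTGParseError(path, 1, "at most one group:<scale> column supported")
        extra = [
            c for c in reader.fieldnames
            if c not in _TABULAR_FIXED and not c.startswith("group:")
            and not c.startswith("root_base_")
        ]
        has_root_base = "root_base_x" in reader.fieldnames
        records = list(reader)

    if not records:
        raise MTGParseError(path, 1, "no vertex rows")

    group_col = group_cols[0] if group_cols else None
    group_scale_name = group_col.split(":", 1)[1] if group_col else None
    has_groups = group_col is not None
    finest = 3 if has_groups else 2
    names = {1: "plant", finest: "metamer"}
    if has_groups:
        names[2] = group_scale_name
    tree = MultiScaleTree(names)

    ids = {r["vertex_id"] for r in records}
    prefix = "" if not (ids & {"P0", "P1"}) else "_"
    p_root, p_plant = prefix + "P0", prefix + "P1"

    root_rows = [r for r in records if not r["parent_id"]]
    if len(root_rows) != 1:
        raise MTGParseError(path, 0, f"expected exactly one root row, found {len(root_rows)}")
    root_row = root_rows[0]
    root_is_compartment = root_row["organ_type"] == "root_compartment"

    # plant scale: root-compartment container (only when present) + plant
    tree.add_vertex(p_root if root_is_compartment else p_plant, 1)
    if root_is_compartment:
        tree.add_vertex(p_plant, 1, parent=p_root, edge=EDGE_SUCCESSION)

    # intermediate scale vertices from the group column
    group_id_of: dict[str, str] = {}
    if has_groups:
        order = [r[group_col] for r in records]
        seen: list[str] = []
        for g in order:
            if g not in seen:
                seen.append(g)
        for k, g in enumerate(seen):
            group_id_of[g] = f"{prefix}G{k}"

    def parse_row_props(r) -> dict:
        props = {}
        if r["organ_type"]:
            props["organ_type"] = r["organ_type"]
        if r["year"]:
            props["year"] = int(r["year"])
        coords = [r["top_x"], r["top_y"], r["top_z"]]
        if all(c != "" for c in coords):
            props["top_xyz"] = tuple(float(c) for c in coords)
        for k in ("radius", "length", "leaf_area"):
            if r[k] != "":
                props[k] = float(r[k])
        for k in extra:
            cell = r.get(k, "")
            if cell in ("", None):
                continue
            try:
                props[k] = int(cell)
            except ValueError:
                try:
                    props[k] = float(cell)
                except ValueError:
                    props[k] = cell
        return props

    # topological insertion order: parents before children
    row_of = {r["vertex_id"]: r for r in records}
    by_parent: dict[str, list[dict]] = {}
    for r in records:
        by_parent.setdefault(r["parent_id"], []).append(r)
    created_groups: set[str] = set()

    def group_complex(r) -> str:
        if not has_groups:
            is_root_comp = r["organ_type"] == "root_compartment"
            return p_root if (is_root_comp and root_is_compartment) else p_plant
        return group_id_of[r[group_col]]

    stack = [root_row]
    n_inserted = 0
    while stack:
        r = stack.pop()
        vid = r["vertex_id"]
        parent = r["parent_id"] or None
        edge = r["edge_type"] or None
        if parent is not None and edge not in (EDGE_SUCCESSION, EDGE_BRANCHING):
            raise MTGParseError(path, 0, f"row {vid!r}: edge_type must be '<' or '+'")
        cx = group_complex(r)
        if has_groups and cx not in created_groups:
            # the coarse vertex inherits parent/edge from the boundary edge
            if parent is None:
                tree.add_vertex(cx, 2, complex_id=(
                    p_root if (root_is_compartment and r["organ_type"] == "root_compartment") else p_plant))
            else:
                parent_r = row_of[parent]
                pcx = group_complex(parent_r)
                is_root_comp = r["organ_type"] == "root_compartment"
                tree.add_vertex(
                    cx, 2, parent=pcx, edge=edge,
                    complex_id=p_root if (root_is_compartment and is_root_comp) else p_plant,
                )
            created_groups.add(cx)
        try:
            tree.add_vertex(
                vid, finest, parent=parent, edge=edge,
                complex_id=cx, **parse_row_props(r),
            )
        except ValueError as exc:
            raise MTGParseError(path, 0, str(exc)) from exc
        n_inserted += 1
        stack.extend(reversed(by_parent.get(vid, [])))

    if n_inserted != len(records):
        raise MTGParseError(path, 0, "rows unreachable from the root (bad parent_id links)")
    if has_root_base and root_row.get("root_base_x", "") != "":
        coarsest = tree.scale_root(1)
        tree.set_prop(coarsest, "top_xyz", tuple(
            float(root_row[f"root_base_{a}"]) for a in "xyz"
        ))
    return tree
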