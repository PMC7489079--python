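"""Seedable generator of apple-like multi-scale trees and supply tables.

The generator emulates the architecture of a young (default 4-year-old)
apple tree: a vertical trunk of growth units of increasing year, first-order
branches borne laterally on older trunk growth units, each branch ageing
towards its tip, current-year leafy shoots terminating branches and borne
laterally on 1-year-old wood, leaves on current-year metamers and fruits on
a fraction of the shoots.  Every metamer carries 3-D coordinates, organ
type, year, growth-unit label and dimensions, so all stock scales (GU, TBS,
BR1, FU) can be built from the output.  The root system is one opaque
compartment below the trunk base.

The companion supply stub replaces a radiative model with exponential light
extinction: each leaf receives ``leaf_area × max_rate × exp(−k × depth)``
grams of carbon per day, where depth is the distance from the top of the
canopy.  It produces the canonical pattern — shaded, deeper leaves
assimilate less — without any claim to radiative realism.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .mtg import EDGE_BRANCHING, EDGE_SUCCESSION, MultiScaleTree


@dataclass
class SynthConfig:
    """Architecture and supply-stub knobs for the synthetic apple tree."""

    seed: int = 42
    tree_age: int = 4                 # current year = tree_age
    n_trunk_gus: int = 4
    trunk_gu_metamers: int = 8
    branch_gu_metamers: int = 5
    branches_per_gu: float = 2.0      # mean of a Poisson draw per old trunk GU
    lateral_shoots_per_gu: float = 2.0  # mean, on 1-year-old wood
    shoot_metamers: int = 5
    metamer_length: float = 0.05      # m (trunk/branch wood)
    shoot_metamer_length: float = 0.02  # m
    leaf_area: float = 0.003          # m^2 per current-year metamer
    fruit_probability: float = 0.6    # per leafy shoot
    initial_fruit_mass: float = 8.0   # g dry matter
    branch_elevation_deg: float = 50.0
    root_length: float = 0.2          # m, opaque root compartment element
    # supply stub
    max_assimilation: float = 6.0     # g C m^-2 day^-1 at full light
    extinction_k: float = 0.5         # m^-1

    def __post_init__(self):
        if not (0.0 <= self.fruit_probability <= 1.0):
            raise ValueError("fruit_probability must be in [0, 1]")
        for name in ("metamer_length", "shoot_metamer_length", "leaf_area",
                     "root_length"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def apple_config(target_metamers: int, seed: int = 42, **overrides) -> SynthConfig:
    """Config whose expected metamer count is close to ``target_metamers``.

    Scales the trunk length and branching density of the default
    architecture; the realised count varies a few percent across seeds.
    """
    cfg = SynthConfig(seed=seed, **overrides)
    # expected metamers for one old trunk GU bearing one branch, estimated
    # from the deterministic parts of the architecture
    probe = _expected_count(cfg)
    factor = max(0.05, target_metamers / probe)
    cfg.branches_per_gu = cfg.branches_per_gu * factor
    if cfg.branches_per_gu > 8:
        # very dense: grow the trunk as well to stay tree-like
        extra = cfg.branches_per_gu / 8
        cfg.n_trunk_gus = max(cfg.n_trunk_gus, int(round(cfg.n_trunk_gus * extra ** 0.5)))
        cfg.branches_per_gu = 8.0
        probe = _expected_count(cfg)
        cfg.branches_per_gu *= max(0.05, target_metamers / probe)
    return cfg


def _expected_count(cfg: SynthConfig) -> float:
    Y = cfg.tree_age
    n = 1 + cfg.n_trunk_gus * cfg.trunk_gu_metamers  # root + trunk
    for g in range(1, cfg.n_trunk_gus + 1):
        year = _gu_year(g, cfg.n_trunk_gus, Y)
        if year < Y:
            per_branch = 0.0
            for by in range(year + 1, Y + 1):
                per_branch += (
                    cfg.shoot_metamers if by == Y else cfg.branch_gu_metamers
                )
                if by == Y - 1:
                    per_branch += cfg.lateral_shoots_per_gu * cfg.shoot_metamers
            n += cfg.branches_per_gu * per_branch
        if year == Y - 1:
            n += cfg.lateral_shoots_per_gu * cfg.shoot_metamers
    return n


def _gu_year(g: int, n_gus: int, age: int) -> int:
    """Year of the g-th trunk growth unit (1-based from the base)."""
    return max(1, math.ceil(g * age / n_gus))


class _Builder:
    def __init__(self, cfg: SynthConfig):
        self.cfg = cfg
        self.rng = np.random.default_rng(cfg.seed)
        self.tree = MultiScaleTree({1: "plant", 2: "metamer"})
        self.n = 0
        self.gu_counter = 0

    def new_id(self) -> str:
        vid = f"M{self.n}"
        self.n += 1
        return vid

    def add_metamer(self, parent, edge, complex_id, **props) -> str:
        vid = self.new_id()
        self.tree.add_vertex(vid, 2, parent=parent, edge=edge,
                             complex_id=complex_id, **props)
        return vid

    def unit_dir(self, mean_dir, jitter=0.08) -> np.ndarray:
        d = np.asarray(mean_dir, float) + self.rng.normal(0.0, jitter, 3)
        return d / np.linalg.norm(d)

    def axis(self, parent, edge, start_xyz, direction, n_metamers, length,
             year, radius, leafy, gu_id) -> tuple[str, np.ndarray]:
        """A growth unit: a chain of metamers; returns (last id, last top)."""
        pos = np.asarray(start_xyz, float)
        last = parent
        e = edge
        for k in range(n_metamers):
            d = self.unit_dir(direction)
            pos = pos + d * length
            props = {
                "organ_type": "internode" if leafy else "wood",
                "year": year,
                "gu_id": gu_id,
                "top_xyz": tuple(pos),
                "radius": radius,
                "length": length,
            }
            if leafy:
                props["leaf_area"] = self.cfg.leaf_area
            last = self.add_metamer(last, e, "P1", **props)
            e = EDGE_SUCCESSION
        return last, pos

    def shoot(self, parent, edge, start_xyz, direction, gu_id=None) -> str:
        cfg = self.cfg
        gu = self.next_gu() if gu_id is None else gu_id
        last, _ = self.axis(
            parent, edge, start_xyz, direction, cfg.shoot_metamers,
            cfg.shoot_metamer_length, cfg.tree_age, 0.002, True, gu,
        )
        if self.rng.random() < cfg.fruit_probability:
            self.tree.set_prop(last, "n_fruits", 1)
        return last

    def next_gu(self) -> int:
        self.gu_counter += 1
        return self.gu_counter

    def branch_dir(self) -> np.ndarray:
        az = self.rng.uniform(0, 2 * math.pi)
        el = math.radians(self.cfg.branch_elevation_deg)
        return np.array(
            [math.cos(az) * math.cos(el), math.sin(az) * math.cos(el), math.sin(el)]
        )


def generate_tree(config: Optional[SynthConfig] = None) -> MultiScaleTree:
    """Deterministic apple-like two-scale tree (plant / metamer).

    The same config (including seed) always produces the identical tree.
    Raises if the configuration yields zero metamers.
    """
    cfg = config or SynthConfig()
    if cfg.n_trunk_gus < 1 or cfg.trunk_gu_metamers < 1:
        raise ValueError("configuration yields zero metamers")
    b = _Builder(cfg)
    t = b.tree
    Y = cfg.tree_age

    t.add_vertex("P0", 1, top_xyz=(0.0, 0.0, -cfg.root_length))
    t.add_vertex("P1", 1, parent="P0", edge=EDGE_SUCCESSION)
    root_m = b.add_metamer(
        None, None, "P0",
        organ_type="root_compartment", year=1, gu_id=0,
        top_xyz=(0.0, 0.0, 0.0), length=cfg.root_length, radius=0.03,
    )

    up = np.array([0.0, 0.0, 1.0])
    pos = np.zeros(3)
    last = root_m
    trunk_tops: list[tuple[str, np.ndarray, int]] = []  # (metamer, top, year)
    for g in range(1, cfg.n_trunk_gus + 1):
        year = _gu_year(g, cfg.n_trunk_gus, Y)
        gu = b.next_gu()
        radius = 0.004 * (Y - year + 2)
        leafy = year == Y
        first_in_gu = b.n
        last, pos = b.axis(
            last, EDGE_SUCCESSION, pos, up, cfg.trunk_gu_metamers,
            cfg.metamer_length, year, radius, leafy, gu,
        )
        for k in range(first_in_gu, b.n):
            vid = f"M{k}"
            trunk_tops.append((vid, np.asarray(t.prop(vid, "top_xyz")), year))

    # branches on old trunk GUs; lateral shoots on 1-year-old wood
    for vid, top, year in trunk_tops:
        if year < Y:
            n_branches = b.rng.poisson(cfg.branches_per_gu / cfg.trunk_gu_metamers)
            for _ in range(n_branches):
                _grow_branch(b, vid, top, year)
        if year == Y - 1:
            n_shoots = b.rng.poisson(cfg.lateral_shoots_per_gu / cfg.trunk_gu_metamers)
            for _ in range(n_shoots):
                b.shoot(vid, EDGE_BRANCHING, top, b.branch_dir())

    if b.n <= 1:
        raise ValueError("configuration yields zero metamers")
    return t.validate()


def _grow_branch(b: _Builder, carrier: str, start: np.ndarray, carrier_year: int):
    cfg = b.cfg
    Y = cfg.tree_age
    direction = b.branch_dir()
    last, pos = carrier, start
    edge = EDGE_BRANCHING
    for year in range(carrier_year + 1, Y + 1):
        gu = b.next_gu()
        if year == Y:
            b.shoot(last, edge, pos, direction, gu_id=gu)
        else:
            first_in_gu = b.n
            radius = 0.003 * (Y - year + 1)
            last, pos = b.axis(
                last, edge, pos, direction, cfg.branch_gu_metamers,
                cfg.metamer_length, year, radius, False, gu,
            )
            if year == Y - 1:
                n_shoots = b.rng.poisson(cfg.lateral_shoots_per_gu)
                members = [f"M{k}" for k in range(first_in_gu, b.n)]
                for _ in range(n_shoots):
                    host = members[b.rng.integers(len(members))]
                    b.shoot(
                        host, EDGE_BRANCHING,
                        np.asarray(b.tree.prop(host, "top_xyz")), b.branch_dir(),
                    )
        edge = EDGE_SUCCESSION


def generate_supply(
    tree: MultiScaleTree, config: Optional[SynthConfig] = None
) -> pd.DataFrame:
    """Per-leaf daily assimilation table from the light-extinction stub.

    Columns ``leaf_vertex_id``, ``gC_per_day``; one row per leaf-bearing
    metamer; deterministic given the tree and config.
    """
    cfg = config or SynthConfig()
    finest = tree.max_scale
    leaves = [
        v for v in tree.vertices_at_scale(finest)
        if (tree.prop(v, "leaf_area") or 0.0) > 0
    ]
    if not leaves:
        return pd.DataFrame({"leaf_vertex_id": [], "gC_per_day": []})
    z = np.array([tree.prop(v, "top_xyz")[2] for v in leaves])
    depth = z.max() - z
    area = np.array([tree.prop(v, "leaf_area") for v in leaves])
    rate = area * cfg.max_assimilation * np.exp(-cfg.extinction_k * depth)
    return pd.DataFrame({"leaf_vertex_id": leaves, "gC_per_day": rate})
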