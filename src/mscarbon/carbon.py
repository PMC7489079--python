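"""Species parameters, biomass initialisation, carbon demands and supplies.

Sink strength of an organ on a given day is its dry mass times an
organ-type-specific *sink activity* (the maximum potential relative growth
rate, in g g⁻¹ °C⁻¹) times the thermal time of the day:

    DM_demand = dry_mass × activity(GDD) × GDD_day        [g dry matter]

Fruit and shoot activities are the normalised derivative of a Gompertz
growth curve of dry weight against cumulated growing degree days (GDD,
daily mean temperature above a 4.5 °C base); old wood uses a constant
activity; leaves use a lookup table bounded to [0, 1.9e-3] g g⁻¹ °C⁻¹.
The root compartment demands the total vegetative shoot demand divided by
the shoot-to-root growth ratio (4.5).

Dry-matter demands are converted to carbon with the assimilate-to-biomass
ratio (2.105263158 g dry matter per g C), making them commensurate with
per-leaf daily net assimilation supplies (g C day⁻¹).  Respiration demand,
when configured, adds a Q10 maintenance term proportional to dry mass and a
growth term proportional to (maintenance + growth demand).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
import yaml

from .mtg import MultiScaleTree
from .scales import _is_root_organ, _leafy_shoot_roots, _subtree, current_year, _year_of

log = logging.getLogger(__name__)

#: organ classes used for sink activities
ORGAN_CLASSES = ("fruit", "shoot", "old_wood", "leaf", "root")


@dataclass(frozen=True)
class GompertzParams:
    """Coefficients of dry_weight = a·exp(b·exp(c·GDD)); b, c negative."""
    a: float
    b: float
    c: float


@dataclass
class SpeciesParams:
    """Allometric and sink-activity constants for an apple-type tree.

    Defaults are the 'Fuji' calibration; respiration coefficients default
    to zero (respiration off) and are user-configurable placeholders taken
    from no published table.
    """

    dry_mass_to_C_mass: float = 2.105263158     # g dry matter per g C
    wood_density: float = 700.0                 # kg m^-3
    spec_leaf_surface: float = 0.08             # kg m^-2
    dry_to_fresh_ratio: float = 0.15
    shoot_to_root_growth: float = 4.5
    # shoot dry weight (g) from length (cm) and thermal time (degC)
    shoot_glm: tuple[float, float, float, float, float] = (
        -3.073409537, 0.706724497, 5.78e-05, 0.020013707, 9.81e-05,
    )
    gompertz: Mapping[str, GompertzParams] = field(
        default_factory=lambda: {
            "fruit": GompertzParams(63.703, -4.896, -0.00104),
            "proleptic_shoot": GompertzParams(2.406, -2.84, -0.00165),
        }
    )
    trunk_activity: float = 3.1e-05             # g g^-1 degC^-1
    leaf_activity_max: float = 1.9e-03          # upper clip of lookup table
    #: lookup table: columns gdd, activity; default constant mid-range value
    leaf_activity_table: Optional[pd.DataFrame] = None
    gdd_base_temp: float = 4.5                  # degC
    initial_fruit_mass: float = 8.0             # g dry matter
    # respiration (user-config placeholders; zero disables respiration)
    q10: float = 2.0
    t_ref: float = 20.0                         # degC
    maintenance_coeff: Mapping[str, float] = field(
        default_factory=lambda: {c: 0.0 for c in ORGAN_CLASSES}
    )
    growth_resp_coeff: float = 0.0

    def __post_init__(self):
        if self.leaf_activity_table is None:
            mid = 0.5 * self.leaf_activity_max
            self.leaf_activity_table = pd.DataFrame(
                {"gdd": [0.0, 4000.0], "activity": [mid, mid]}
            )

    def leaf_activity(self, gdd: float) -> float:
        t = self.leaf_activity_table
        val = float(np.interp(gdd, t["gdd"].to_numpy(), t["activity"].to_numpy()))
        return float(np.clip(val, 0.0, self.leaf_activity_max))

    def shoot_gompertz(self, epicormic: bool = False) -> GompertzParams:
        if epicormic and "epicormic_shoot" not in self.gompertz:
            log.warning("no epicormic shoot coefficients; reusing proleptic values")
        return self.gompertz.get("epicormic_shoot" if epicormic else "proleptic_shoot",
                                 self.gompertz["proleptic_shoot"])

    # -- YAML round trip ---------------------------------------------------

    def to_yaml(self, path) -> None:
        data = {
            "dry_mass_to_C_mass": self.dry_mass_to_C_mass,
            "wood_density": self.wood_density,
            "spec_leaf_surface": self.spec_leaf_surface,
            "dry_to_fresh_ratio": self.dry_to_fresh_ratio,
            "shoot_to_root_growth": self.shoot_to_root_growth,
            "shoot_glm": list(self.shoot_glm),
            "gompertz": {k: [g.a, g.b, g.c] for k, g in self.gompertz.items()},
            "trunk_activity": self.trunk_activity,
            "leaf_activity_max": self.leaf_activity_max,
            "leaf_activity_table": {
                "gdd": self.leaf_activity_table["gdd"].tolist(),
                "activity": self.leaf_activity_table["activity"].tolist(),
            },
            "gdd_base_temp": self.gdd_base_temp,
            "initial_fruit_mass": self.initial_fruit_mass,
            "q10": self.q10,
            "t_ref": self.t_ref,
            "maintenance_coeff": dict(self.maintenance_coeff),
            "growth_resp_coeff": self.growth_resp_coeff,
        }
        Path(path).write_text(yaml.safe_dump(data))

    @classmethod
    def from_yaml(cls, path) -> "SpeciesParams":
        data = yaml.safe_load(Path(path).read_text())
        table = data.pop("leaf_activity_table", None)
        gomp = {
            k: GompertzParams(*v) for k, v in data.pop("gompertz", {}).items()
        }
        kwargs = dict(data)
        kwargs["shoot_glm"] = tuple(kwargs["shoot_glm"])
        if gomp:
            kwargs["gompertz"] = gomp
        sp = cls(**kwargs)
        if table is not None:
            sp.leaf_activity_table = pd.DataFrame(table)
        return sp


# --------------------------------------------------------------------------
# thermal time and sink activities
# --------------------------------------------------------------------------

def gdd_accumulate(daily_mean_temps: Sequence[float], base: float = 4.5) -> np.ndarray:
    """Cumulated growing degree days, daily mean above base, floored at 0."""
    t = np.asarray(daily_mean_temps, float)
    return np.cumsum(np.maximum(t - base, 0.0))


def gompertz_rgr(gdd: Union[float, np.ndarray], params: GompertzParams):
    """Normalised Gompertz derivative (sink activity, g g⁻¹ °C⁻¹).

    Evaluates the ratio form
    (a·b·c·exp(b·exp(c·GDD) + c·GDD)) / (a·exp(b·exp(c·GDD))),
    which simplifies algebraically to b·c·exp(c·GDD).
    """
    a, b, c = params.a, params.b, params.c
    gdd = np.asarray(gdd, float)
    num = a * b * c * np.exp(b * np.exp(c * gdd) + c * gdd)
    den = a * np.exp(b * np.exp(c * gdd))
    out = num / den
    return float(out) if out.ndim == 0 else out


# --------------------------------------------------------------------------
# biomass initialisation (allometry)
# --------------------------------------------------------------------------

def shoot_glm_mass(length_cm: float, gdd: float, coeffs) -> float:
    """Current-year shoot dry weight (g) from length (cm) and thermal time."""
    a, b, c, d, e = coeffs
    if length_cm <= 0:
        raise ValueError(f"shoot length must be positive, got {length_cm}")
    if gdd <= 0:
        raise ValueError("thermal time must be positive for the shoot allometry")
    return math.exp(
        a + b * math.log(length_cm) + c * gdd + d * length_cm
        + e * math.log(length_cm * gdd)
    )


def init_biomass(
    tree: MultiScaleTree, params: SpeciesParams, gdd_cum: float
) -> MultiScaleTree:
    """Set per-organ dry masses (g) on every metamer from allometry.

    Old wood mass is cylinder volume × wood density; leaf mass is leaf area
    × specific leaf dry mass; each current-year shoot's mass comes from the
    shoot GLM on its total length and is spread over its metamers
    proportionally to internode length; every fruit starts at the common
    initial dry weight.  Modifies the tree in place and returns it.
    """
    finest = tree.max_scale
    yr = current_year(tree)
    metamers = tree.vertices_at_scale(finest)

    # shoot masses: per maximal current-year subtree
    shoot_done: set[str] = set()
    shoot_roots = [
        v for v in metamers
        if not _is_root_organ(tree, v) and _year_of(tree, v) == yr
        and (
            tree.parent_of[v] is None
            or _is_root_organ(tree, tree.parent_of[v])
            or _year_of(tree, tree.parent_of[v]) != yr
        )
    ]
    for r in shoot_roots:
        members = _subtree(tree, r, member=lambda v: _year_of(tree, v) == yr)
        lengths = np.array([float(tree.prop(v, "length", 0.0) or 0.0) for v in members])
        total_cm = lengths.sum() * 100.0
        mass = shoot_glm_mass(total_cm, gdd_cum, params.shoot_glm)
        if lengths.sum() > 0:
            weights = lengths / lengths.sum()
        else:  # pragma: no cover - degenerate zero-length shoot
            weights = np.full(len(members), 1.0 / len(members))
        for v, w in zip(members, weights):
            tree.set_prop(v, "internode_dry_mass", mass * w)
            shoot_done.add(v)

    for v in metamers:
        if _is_root_organ(tree, v):
            continue
        if v not in shoot_done:
            r = float(tree.prop(v, "radius", 0.0) or 0.0)
            L = float(tree.prop(v, "length", 0.0) or 0.0)
            # kg m^-3 × m^3 → kg → g
            tree.set_prop(
                v, "internode_dry_mass", math.pi * r * r * L * params.wood_density * 1e3
            )
        la = float(tree.prop(v, "leaf_area", 0.0) or 0.0)
        if la > 0:
            tree.set_prop(v, "leaf_dry_mass", la * params.spec_leaf_surface * 1e3)
        nf = int(tree.prop(v, "n_fruits", 0) or 0)
        if nf > 0:
            tree.set_prop(v, "fruit_dry_mass", nf * params.initial_fruit_mass)
    return tree


# --------------------------------------------------------------------------
# carbon state
# --------------------------------------------------------------------------

@dataclass
class CarbonState:
    """Per-organ carbon bookkeeping at the metamer scale.

    ``organs`` has one row per (metamer, organ) with columns ``vertex``,
    ``organ`` (internode/leaf/fruit/root), ``organ_class`` (activity class),
    ``dry_mass`` (g), ``dm_demand_C``, ``maint_C``, ``growth_resp_C``,
    ``total_demand_C``, ``supply_C``, ``reserve_C`` (all g C).
    """

    organs: pd.DataFrame

    def component_totals(self) -> pd.DataFrame:
        """Demand/supply/mass summed per metamer."""
        return self.organs.groupby("vertex", sort=True)[
            ["dry_mass", "dm_demand_C", "maint_C", "growth_resp_C",
             "total_demand_C", "supply_C", "reserve_C"]
        ].sum()

    @property
    def total_supply(self) -> float:
        return float(self.organs["supply_C"].sum() + self.organs["reserve_C"].sum())

    @property
    def total_demand(self) -> float:
        return float(self.organs["total_demand_C"].sum())


def _organ_rows(tree: MultiScaleTree) -> list[dict]:
    yr = current_year(tree)
    rows = []
    for v in tree.vertices_at_scale(tree.max_scale):
        if _is_root_organ(tree, v):
            rows.append({
                "vertex": v, "organ": "root", "organ_class": "root",
                "dry_mass": float(tree.prop(v, "dry_mass", 0.0) or 0.0),
            })
            continue
        im = tree.prop(v, "internode_dry_mass")
        if im is None:
            raise ValueError(
                f"metamer {v!r}: masses not initialised (run init_biomass first)"
            )
        cls = "shoot" if _year_of(tree, v) == yr else "old_wood"
        rows.append({
            "vertex": v, "organ": "internode", "organ_class": cls,
            "dry_mass": float(im),
        })
        lm = tree.prop(v, "leaf_dry_mass", 0.0) or 0.0
        if lm > 0:
            rows.append({
                "vertex": v, "organ": "leaf", "organ_class": "leaf",
                "dry_mass": float(lm),
            })
        fm = tree.prop(v, "fruit_dry_mass", 0.0) or 0.0
        if fm > 0:
            rows.append({
                "vertex": v, "organ": "fruit", "organ_class": "fruit",
                "dry_mass": float(fm),
            })
    return rows


def compute_demands(
    tree: MultiScaleTree,
    params: SpeciesParams,
    gdd_cum: float,
    gdd_day: float,
    temperature_series: Optional[Sequence[float]] = None,
) -> CarbonState:
    """Assemble the day's per-organ carbon demands (g C).

    ``gdd_cum`` is thermal time since bloom (°C), ``gdd_day`` the day's
    thermal time increment.  ``temperature_series`` (°C, any within-day
    sampling) enables the Q10 maintenance term when maintenance
    coefficients are non-zero.
    """
    rows = _organ_rows(tree)
    organs = pd.DataFrame(rows)

    act = np.zeros(len(organs))
    fruit_act = gompertz_rgr(gdd_cum, params.gompertz["fruit"])
    shoot_act = gompertz_rgr(gdd_cum, params.shoot_gompertz())
    leaf_act = params.leaf_activity(gdd_cum)
    class_act = {
        "fruit": fruit_act,
        "shoot": shoot_act,
        "old_wood": params.trunk_activity,
        "leaf": leaf_act,
        "root": 0.0,
    }
    unknown = set(organs["organ_class"]) - set(class_act)
    if unknown:
        raise ValueError(f"unknown organ classes: {sorted(unknown)}")
    act = organs["organ_class"].map(class_act).to_numpy(float)

    dm_dry = organs["dry_mass"].to_numpy(float) * act * gdd_day  # g dry matter
    dm_C = dm_dry / params.dry_mass_to_C_mass

    # root demand follows total vegetative shoot demand
    shoot_total = dm_C[(organs["organ_class"] == "shoot").to_numpy()].sum()
    dm_C = np.where(
        (organs["organ_class"] == "root").to_numpy(),
        shoot_total / params.shoot_to_root_growth,
        dm_C,
    )

    maint = np.zeros(len(organs))
    if temperature_series is not None and any(
        params.maintenance_coeff.get(c, 0.0) for c in ORGAN_CLASSES
    ):
        temps = np.asarray(temperature_series, float)
        q10_factor = np.mean(params.q10 ** ((temps - params.t_ref) / 10.0))
        mr = organs["organ_class"].map(
            lambda c: params.maintenance_coeff.get(c, 0.0)
        ).to_numpy(float)
        maint = organs["dry_mass"].to_numpy(float) * mr * q10_factor

    grc = params.growth_resp_coeff
    growth_resp = grc * (maint + dm_C)
    organs["dm_demand_C"] = dm_C
    organs["maint_C"] = maint
    organs["growth_resp_C"] = growth_resp
    organs["total_demand_C"] = dm_C + maint + growth_resp
    organs["supply_C"] = 0.0
    organs["reserve_C"] = 0.0
    return CarbonState(organs=organs)


def dm_demand(
    dry_mass: float,
    organ_class: str,
    gdd_cum: float,
    gdd_day: float,
    params: SpeciesParams,
) -> float:
    """Dry-matter demand (g) of one organ for the day (before C conversion)."""
    if organ_class == "fruit":
        act = gompertz_rgr(gdd_cum, params.gompertz["fruit"])
    elif organ_class == "shoot":
        act = gompertz_rgr(gdd_cum, params.shoot_gompertz())
    elif organ_class == "old_wood":
        act = params.trunk_activity
    elif organ_class == "leaf":
        act = params.leaf_activity(gdd_cum)
    else:
        raise ValueError(f"unknown organ class {organ_class!r}")
    return dry_mass * act * gdd_day


def respiration_demand(
    dry_mass: float,
    organ_class: str,
    temperature_series: Sequence[float],
    params: SpeciesParams,
    dm_demand_C: float = 0.0,
) -> tuple[float, float]:
    """(maintenance, growth) respiration demand in g C for one organ-day."""
    temps = np.asarray(temperature_series, float)
    if temps.size == 0:
        raise ValueError("temperature series is empty")
    q10_factor = float(np.mean(params.q10 ** ((temps - params.t_ref) / 10.0)))
    maint = dry_mass * params.maintenance_coeff.get(organ_class, 0.0) * q10_factor
    growth = params.growth_resp_coeff * (maint + dm_demand_C)
    return maint, growth


# --------------------------------------------------------------------------
# supplies
# --------------------------------------------------------------------------

def load_supply(
    tree: MultiScaleTree,
    state: CarbonState,
    supply: Union[pd.DataFrame, Mapping[str, float]],
) -> CarbonState:
    """Attach per-leaf daily net assimilation (g C day⁻¹) to the state.

    ``supply`` maps leaf-bearing metamer ids to g C day⁻¹ (or a DataFrame
    with columns ``leaf_vertex_id``, ``gC_per_day``).  Negative net values
    are clipped to zero with a logged total.  Ids absent from the tree are
    an error.
    """
    if isinstance(supply, pd.DataFrame):
        mapping = dict(zip(supply["leaf_vertex_id"], supply["gC_per_day"]))
    else:
        mapping = dict(supply)
    unknown = [v for v in mapping if v not in tree.scale_of]
    if unknown:
        raise ValueError(f"supply table references unknown leaf ids: {unknown[:5]}")

    clipped = sum(-v for v in mapping.values() if v < 0)
    if clipped > 0:
        log.warning("clipped %.4g g C of negative net assimilation to zero", clipped)
    mapping = {k: max(0.0, float(v)) for k, v in mapping.items()}

    organs = state.organs.copy()
    is_leaf = organs["organ"] == "leaf"
    organs.loc[is_leaf, "supply_C"] = (
        organs.loc[is_leaf, "vertex"].map(mapping).fillna(0.0)
    )
    # supplies keyed on metamers without a leaf row attach to the internode
    leafless = set(mapping) - set(organs.loc[is_leaf, "vertex"])
    if leafless:
        mask = organs["vertex"].isin(leafless) & (organs["organ"] == "internode")
        organs.loc[mask, "supply_C"] = organs.loc[mask, "vertex"].map(mapping)
    return CarbonState(organs=organs)
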