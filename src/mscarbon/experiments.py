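"""Analyses of simulated fruit growth: competition, cross-scale coherence.

Three analyses quantify model behaviour:

* **Neighbourhood comfort index** — for each fruit, the carbon assimilated
  within a Euclidean radius of its metamer's barycentre divided by the
  number of fruits there; the correlation of fruit growth against this
  index across radii shows over what range competition for assimilates
  acts.  Significance is Bonferroni-corrected for the number of radii.
* **Cross-scale comparison** — fruit growth at a coarse scale against the
  mean metamer-scale growth within each coarse component, summarised by
  the RMSE and its coefficient of variation (RMSE over the reference
  mean).
* **Distribution RMSE** — similarity of two normalised growth/weight
  distributions as the RMSE between their shared-grid histogram counts.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .allocation import AllocationResult
from .geometry import annotate_geometry, resolve_scale
from .mtg import MultiScaleTree
from .scales import build_scale, stock_spec

#: neighbourhood radii in metres
DEFAULT_RADII = (0.05, 0.15, 0.25, 0.35, 0.45, 0.55, 0.65, 0.75, 0.95, 1.15, 1.35)


@dataclass
class NeighbourhoodAnalysis:
    """Comfort-index correlations per neighbourhood radius.

    ``table`` has one row per radius: ``radius``, ``r``, ``p``,
    ``significant`` (after Bonferroni), ``n_fruits``; ``per_fruit`` holds
    the underlying (fruit, radius) comfort indices and growth values.
    """

    radii: tuple
    bonferroni_alpha: float
    table: pd.DataFrame
    per_fruit: pd.DataFrame


def comfort_index_correlation(
    tree: MultiScaleTree,
    result_m: AllocationResult,
    radii: Sequence[float] = DEFAULT_RADII,
    method: str = "pearson",
) -> NeighbourhoodAnalysis:
    """Correlate fruit growth with the neighbourhood comfort index.

    ``result_m`` must be a metamer-scale run on ``tree``.  Neighbourhood
    membership is by Euclidean barycentre-to-barycentre distance; the focal
    fruit always counts itself, so the fruit count is >= 1.
    """
    geom = annotate_geometry(tree, "M")
    organs = result_m.organs
    supply = organs.groupby("vertex")["supply_C"].sum()
    fruits = organs[organs["organ"] == "fruit"]
    fruit_v = list(fruits["vertex"])
    growth = fruits["growth_C"].to_numpy(float)

    ids = list(geom.frame.index)
    bary = geom.frame[["bary_x", "bary_y", "bary_z"]].to_numpy(float)
    sup = supply.reindex(ids).fillna(0.0).to_numpy(float)
    is_fruit = np.isin(ids, fruit_v)
    fidx = [ids.index(v) for v in fruit_v]

    # distances fruits x metamers
    d = np.linalg.norm(bary[fidx][:, None, :] - bary[None, :, :], axis=2)

    alpha = 0.05 / len(radii)
    rows, per_fruit_rows = [], []
    corr = stats.pearsonr if method == "pearson" else stats.spearmanr
    for radius in radii:
        member = d <= radius
        c_nbhd = member @ sup
        n_fruits = member[:, is_fruit].sum(axis=1)
        comfort = c_nbhd / np.maximum(n_fruits, 1)
        for v, g, ci, nf in zip(fruit_v, growth, comfort, n_fruits):
            per_fruit_rows.append(
                {"radius": radius, "vertex": v, "growth_C": g,
                 "comfort_index": ci, "n_fruits": int(nf)}
            )
        if len(growth) < 3 or np.std(growth) == 0 or np.std(comfort) == 0:
            rows.append({"radius": radius, "r": np.nan, "p": np.nan,
                         "significant": False, "n_fruits": len(growth)})
            continue
        r, p = corr(growth, comfort)
        rows.append({"radius": radius, "r": float(r), "p": float(p),
                     "significant": bool(p < alpha), "n_fruits": len(growth)})
    return NeighbourhoodAnalysis(
        radii=tuple(radii),
        bonferroni_alpha=alpha,
        table=pd.DataFrame(rows),
        per_fruit=pd.DataFrame(per_fruit_rows),
    )


@dataclass
class CrossScaleComparison:
    """Coarse-scale vs reference metamer-scale fruit growth.

    ``pairs`` has one row per fruit-bearing coarse component with the mean
    metamer-scale growth (``m_scale``) and the coarse-scale growth
    (``coarse``); ``cv_rmse`` is the RMSE divided by the reference mean.
    """

    scale_name: str
    pairs: pd.DataFrame
    rmse: float
    cv_rmse: float


def cross_scale_compare(
    result_coarse: AllocationResult,
    result_m: AllocationResult,
    tree: MultiScaleTree,
    scale_name: str,
) -> CrossScaleComparison:
    """Pair coarse-component fruit growth with the metamer-scale reference.

    ``tree`` must carry the named coarse scale (the working tree of the
    coarse run); both runs must be on the same structure and supplies.
    """
    scale = resolve_scale(tree, scale_name)
    fr_m = result_m.organs[result_m.organs["organ"] == "fruit"]
    fr_c = result_coarse.organs[result_coarse.organs["organ"] == "fruit"]
    if fr_m.empty:
        raise ValueError("reference run has no fruit-bearing components")

    comp_of = {v: tree.complex_at_scale(v, scale) for v in fr_m["vertex"]}
    m_means = (
        fr_m.assign(component=[comp_of[v] for v in fr_m["vertex"]])
        .groupby("component")["growth_C"].mean()
    )
    c_means = (
        fr_c.assign(component=[tree.complex_at_scale(v, scale) for v in fr_c["vertex"]])
        .groupby("component")["growth_C"].mean()
    )
    pairs = pd.DataFrame({"m_scale": m_means, "coarse": c_means}).dropna()
    if pairs.empty:
        raise ValueError(f"scale {scale_name!r} has no fruit-bearing components")
    err = pairs["coarse"].to_numpy() - pairs["m_scale"].to_numpy()
    rmse = float(np.sqrt(np.mean(err ** 2)))
    ref_mean = float(pairs["m_scale"].mean())
    cv = rmse / ref_mean if ref_mean != 0 else np.inf
    return CrossScaleComparison(scale_name, pairs, rmse, cv)


def distribution_rmse(
    simulated: Sequence[float],
    observed: Sequence[float],
    n_bins: int = 20,
    normalization: str = "zscore",
) -> float:
    """RMSE between normalised histogram count fractions of two samples.

    Both samples are normalised (z-score by default, ``minmax``
    optionally), binned on a shared equal-width grid spanning the pooled
    range, and compared as count fractions so unequal sample sizes remain
    comparable.
    """
    sim = np.asarray(simulated, float)
    obs = np.asarray(observed, float)
    if sim.size == 0 or obs.size == 0:
        raise ValueError("both samples must be non-empty")

    def norm(x):
        if normalization == "zscore":
            s = x.std()
            if s == 0:
                raise ValueError("degenerate zero-variance sample")
            return (x - x.mean()) / s
        if normalization == "minmax":
            lo, hi = x.min(), x.max()
            if hi == lo:
                raise ValueError("degenerate zero-range sample")
            return (x - lo) / (hi - lo)
        raise ValueError(f"unknown normalization {normalization!r}")

    sim_n, obs_n = norm(sim), norm(obs)
    lo = min(sim_n.min(), obs_n.min())
    hi = max(sim_n.max(), obs_n.max())
    edges = np.linspace(lo, hi, n_bins + 1)
    h_sim, _ = np.histogram(sim_n, bins=edges)
    h_obs, _ = np.histogram(obs_n, bins=edges)
    f_sim = h_sim / h_sim.sum()
    f_obs = h_obs / h_obs.sum()
    return float(np.sqrt(np.mean((f_sim - f_obs) ** 2)))


def scale_table(
    tree: MultiScaleTree,
    scales: Sequence[str] = ("M", "GU", "TBS", "BR1", "FU"),
) -> pd.DataFrame:
    """Component counts per scale and their percentage of the metamer count."""
    n_m = len(tree.vertices_at_scale(tree.max_scale))
    rows = []
    for name in scales:
        if name == "M":
            count = n_m
        else:
            built = build_scale(tree, stock_spec(name))
            count = built.count_components(name)
        rows.append({"scale": name, "components": count,
                     "pct_of_M": 100.0 * count / n_m})
    return pd.DataFrame(rows).set_index("scale")


def mean_scale_table(trees: Sequence[MultiScaleTree], scales=("M", "GU", "TBS", "BR1", "FU")) -> pd.DataFrame:
    """Mean component percentages across several trees."""
    tables = [scale_table(t, scales) for t in trees]
    out = tables[0].copy()
    out["components"] = np.mean([t["components"] for t in tables], axis=0)
    out["pct_of_M"] = np.mean([t["pct_of_M"] for t in tables], axis=0)
    return out
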