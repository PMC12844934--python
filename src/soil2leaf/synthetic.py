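"""Synthetic orchard datasets with the statistical structure the pipeline assumes.

The published study design (20 sites x 4 trees, paired soil/leaf chemistry,
pigment readings) is emulated so every analysis stage can be exercised and
parameter recovery verified without the unpublished tree-level raw data:

* soil metal per site ~ log-normal(ln geo-mean, ln gsd) across sites;
* leaf metal per tree = true BAF x site soil x log-normal tree noise;
* macronutrients are normal with a site random effect;
* SPAD and chlorophyll a decline linearly with leaf Cd and Pb (truncated at
  zero); chlorophyll b tracks chlorophyll a through a target a/b ratio.

All draws come from a single ``numpy.random.default_rng(seed)`` stream in a
fixed order, so one seed yields one byte-identical dataset.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np

from .core import Compartment, MeasurementTable, ValidationError
from .pigments import CHL_A_COEF, CHL_B_COEF

__all__ = [
    "OrchardSimConfig",
    "generate_orchard_dataset",
    "generate_clustered_orchard",
    "generate_absorbance_readings",
]

METALS = ("Cd", "Pb", "Ni", "Zn", "Cu", "Fe", "Mn")

_DEFAULT_SOIL_GEO_MEAN = {
    "Cd": 0.054, "Pb": 45.0, "Ni": 50.0, "Zn": 84.0, "Cu": 22.0, "Fe": 4.3, "Mn": 3.4,
}
_DEFAULT_SOIL_GSD = {m: 1.35 for m in METALS}
_DEFAULT_TRUE_BAF = {
    "Cd": 3.5, "Pb": 0.021, "Ni": 0.09, "Zn": 0.51, "Cu": 0.52, "Fe": 36.3, "Mn": 11.7,
}
_DEFAULT_NUTRIENT_MEANS = {"N": 2.64, "P": 0.30, "K": 2.01, "Ca": 2.77, "Mg": 0.65, "B": 51.4}
_DEFAULT_NUTRIENT_SITE_SD = {"N": 0.22, "P": 0.035, "K": 0.28, "Ca": 0.45, "Mg": 0.10, "B": 2.4}


@dataclass(frozen=True)
class OrchardSimConfig:
    n_sites: int = 20
    trees_per_site: int = 4
    seed: int = 0
    soil_geo_mean: Mapping[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_SOIL_GEO_MEAN))
    soil_gsd: Mapping[str, float] = field(default_factory=lambda: dict(_DEFAULT_SOIL_GSD))
    true_baf: Mapping[str, float] = field(default_factory=lambda: dict(_DEFAULT_TRUE_BAF))
    tree_noise_gsd: float = 1.12
    nutrient_means: Mapping[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_NUTRIENT_MEANS))
    nutrient_site_sd: Mapping[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_NUTRIENT_SITE_SD))
    nutrient_tree_sd_frac: float = 0.05  # residual sd as fraction of the mean
    stress_slopes: Mapping[str, float] = field(
        default_factory=lambda: {"Cd": -40.0, "Pb": -8.0})
    spad_baseline: float = 52.0
    chla_baseline: float = 62.0
    chl_ab_target: float = 1.9
    pigment_noise_sd: float = 2.0

    def __post_init__(self) -> None:
        if self.n_sites < 1 or self.trees_per_site < 1:
            raise ValidationError("n_sites and trees_per_site must be positive")
        for name, mapping in (("soil_geo_mean", self.soil_geo_mean),
                              ("true_baf", self.true_baf)):
            for k, v in mapping.items():
                if not v > 0:
                    raise ValidationError(f"{name}[{k!r}] must be positive, got {v}")
        for k, v in self.soil_gsd.items():
            if not v >= 1:
                raise ValidationError(f"soil_gsd[{k!r}] must be >= 1, got {v}")
        if not self.tree_noise_gsd >= 1:
            raise ValidationError("tree_noise_gsd must be >= 1")
        if self.pigment_noise_sd < 0 or self.nutrient_tree_sd_frac < 0:
            raise ValidationError("noise parameters must be non-negative")


def generate_orchard_dataset(config: OrchardSimConfig) -> MeasurementTable:
    """Draw one synthetic measurement table per the configured model."""
    rng = np.random.default_rng(config.seed)
    sites = [f"S{i}" for i in range(1, config.n_sites + 1)]
    trees = [f"T{j}" for j in range(1, config.trees_per_site + 1)]
    rows: list[tuple] = []

    elements = sorted(config.true_baf)
    missing = [m for m in elements if m not in config.soil_geo_mean]
    if missing:
        raise ValidationError(f"soil_geo_mean missing elements: {missing}")

    # soil metals: one composite value per site per element
    soil = {}
    for el in elements:
        mu = np.log(config.soil_geo_mean[el])
        sigma = np.log(config.soil_gsd.get(el, 1.0))
        vals = np.exp(rng.normal(mu, sigma, size=config.n_sites))
        soil[el] = dict(zip(sites, vals))
        for s in sites:
            rows.append((s, "T0", Compartment.SOIL.value, el, soil[el][s], "mg/kg"))

    # leaf metals: BAF x soil x multiplicative tree noise
    leaf = {el: {} for el in elements}
    sigma_tree = np.log(config.tree_noise_gsd)
    for el in elements:
        for s in sites:
            noise = (np.exp(rng.normal(0.0, sigma_tree, size=config.trees_per_site))
                     if sigma_tree > 0 else np.ones(config.trees_per_site))
            vals = config.true_baf[el] * soil[el][s] * noise
            for t, v in zip(trees, vals):
                leaf[el][(s, t)] = v
                rows.append((s, t, Compartment.LEAF.value, el, v, "mg/kg"))

    # macronutrients: site random effect + tree residual, truncated at 0
    for nutrient in sorted(config.nutrient_means):
        mean = config.nutrient_means[nutrient]
        site_sd = config.nutrient_site_sd.get(nutrient, 0.0)
        site_eff = rng.normal(mean, site_sd, size=config.n_sites)
        tree_sd = config.nutrient_tree_sd_frac * abs(mean)
        units = "mg/kg" if nutrient == "B" else "%"
        for s, eff in zip(sites, site_eff):
            vals = np.maximum(rng.normal(eff, tree_sd, size=config.trees_per_site), 0.0)
            for t, v in zip(trees, vals):
                rows.append((s, t, Compartment.LEAF.value, nutrient, v, units))

    # pigment/physiology block coupled to leaf Cd and Pb
    for s in sites:
        for t in trees:
            stress = sum(
                slope * leaf[el][(s, t)]
                for el, slope in config.stress_slopes.items()
                if el in leaf
            )
            spad = max(config.spad_baseline + stress
                       + rng.normal(0.0, config.pigment_noise_sd), 0.0)
            chla = max(config.chla_baseline + stress
                       + rng.normal(0.0, config.pigment_noise_sd), 0.0)
            chlb = max(chla / config.chl_ab_target
                       + rng.normal(0.0, config.pigment_noise_sd), 0.0)
            rows.append((s, t, Compartment.LEAF.value, "SPAD", spad, "index"))
            rows.append((s, t, Compartment.LEAF.value, "chlorophyll_a", chla, "ug/g FW"))
            rows.append((s, t, Compartment.LEAF.value, "chlorophyll_b", chlb, "ug/g FW"))

    return MeasurementTable.from_records(rows)


def generate_clustered_orchard(
    config: OrchardSimConfig,
    n_clusters: int = 4,
    separation: float = 1.0,
) -> tuple[MeasurementTable, dict[str, int]]:
    """Dataset with planted site clusters for recovery tests.

    Sites are assigned round-robin to ``n_clusters`` groups; cluster ``c``
    shifts every soil metal geo-mean by ``exp(separation * (c - (K-1)/2))``
    in log space, producing well-separated multivariate site profiles when
    ``separation`` is large.  Returns the table and the true site->cluster map.
    """
    if n_clusters < 1:
        raise ValidationError("n_clusters must be positive")
    sites = [f"S{i}" for i in range(1, config.n_sites + 1)]
    labels = {s: i % n_clusters for i, s in enumerate(sites)}
    tables = []
    rng_offsets = np.arange(n_clusters) - (n_clusters - 1) / 2.0
    for c in range(n_clusters):
        members = [s for s in sites if labels[s] == c]
        if not members:
            continue
        scale = float(np.exp(separation * rng_offsets[c]))
        sub = replace(
            config,
            n_sites=len(members),
            seed=config.seed + 1000 * (c + 1),
            soil_geo_mean={k: v * scale for k, v in config.soil_geo_mean.items()},
        )
        t = generate_orchard_dataset(sub)
        df = t.data.copy()
        rename = dict(zip([f"S{i}" for i in range(1, len(members) + 1)], members))
        df["site_id"] = df["site_id"].map(rename)
        tables.append(MeasurementTable(df))
    merged = tables[0]
    for t in tables[1:]:
        merged = merged.concat(t)
    return merged, labels


def generate_absorbance_readings(
    chl_a_target: float, chl_b_target: float
) -> tuple[float, float]:
    """Invert the pigment equations: absorbances that reproduce the targets.

    Solves the 2x2 linear system; raises if either target is non-positive or
    the implied absorbances are negative (physically impossible reading).
    """
    if not (chl_a_target > 0 and chl_b_target > 0):
        raise ValueError("pigment targets must be strictly positive")
    a_mat = np.array([CHL_A_COEF, CHL_B_COEF], dtype=float)
    rhs = np.array([chl_a_target, chl_b_target], dtype=float)
    a665, a652 = np.linalg.solve(a_mat, rhs)
    if a665 < 0 or a652 < 0:
        raise ValueError(
            f"targets ({chl_a_target}, {chl_b_target}) imply negative absorbance"
        )
    return float(a665), float(a652)
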