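"""Published treatment means of the chickpea rhizosheath experiment.

These are the printed summary tables of the study the pipeline re-implements
(two chickpea cultivars, a drought-sensitive and a drought-tolerant one,
plus an unplanted control, under no/moderate/high glucose-carbon addition;
n = 4). The raw scans and replicate data were never deposited, so these
means are the worked-example input surface: the percent-change claims of
the study are recomputed from them with :func:`rhizoct.stats.percent_change`.

Values are (mean, standard error) as printed; root hair area is a
proportion of total root area, rhizosheath is mg soil per cm root length.
"""

from __future__ import annotations

from rhizoct.stats import percent_change

# Root and shoot traits: main-effect means by cultivar and by carbon rate.
ROOT_TRAIT_MEANS = {
    "root_shoot_ratio": {
        "sensitive": (0.34, 0.03), "tolerant": (0.39, 0.02),
        "none": (0.35, 0.04), "moderate": (0.34, 0.02), "high": (0.41, 0.02),
    },
    "root_hair_area": {
        "sensitive": (0.01, 0.002), "tolerant": (0.02, 0.002),
        "none": (0.02, 0.005), "moderate": (0.03, 0.005), "high": (0.01, 0.0005),
    },
    "shoot_dw_mg": {
        "sensitive": (68.50, 6.60), "tolerant": (45.44, 4.53),
        "none": (63.73, 12.48), "moderate": (61.24, 12.69), "high": (46.00, 9.42),
    },
    "rhizosheath_mg_per_cm": {
        "sensitive": (6.20, 0.37), "tolerant": (6.30, 0.51),
        "none": (5.74, 0.008), "moderate": (6.39, 0.54), "high": (6.62, 0.70),
    },
}

# Habitat and function responses: zone main effects (bulk vs rhizosheath)
# and carbon main effects per planting treatment.
ZONE_MEANS = {
    "porosity_pct": {
        "sensitive": {"bulk": (24.55, 1.32), "rhizosheath": (25.11, 1.29)},
        "tolerant": {"bulk": (23.46, 1.46), "rhizosheath": (27.49, 1.37)},
    },
    "connectivity_pct": {
        "sensitive": {"bulk": (80.91, 3.90), "rhizosheath": (72.57, 4.22)},
        "tolerant": {"bulk": (89.67, 4.84), "rhizosheath": (89.77, 6.99)},
    },
    "respiration": {
        "sensitive": {"bulk": (4.39, 0.12), "rhizosheath": (5.79, 0.65)},
        "tolerant": {"bulk": (4.30, 0.13), "rhizosheath": (5.43, 0.24)},
    },
    "infiltration_cm3": {
        "sensitive": {"bulk": (0.17, 0.002), "rhizosheath": (0.16, 0.03)},
        "tolerant": {"bulk": (0.15, 0.03), "rhizosheath": (0.17, 0.02)},
    },
}

CARBON_MEANS = {
    "porosity_pct": {
        "unplanted": {"none": (27.23, 1.30), "moderate": (26.59, 3.19), "high": (25.17, 4.38)},
        "sensitive": {"none": (23.41, 0.03), "moderate": (23.67, 0.64), "high": (27.40, 0.22)},
        "tolerant": {"none": (25.32, 4.63), "moderate": (24.65, 0.57), "high": (26.46, 0.84)},
    },
    "connectivity_pct": {
        "unplanted": {"none": (99.44, 0.14), "moderate": (99.33, 0.11), "high": (99.07, 0.19)},
        "sensitive": {"none": (73.99, 4.06), "moderate": (84.73, 3.91), "high": (71.50, 4.55)},
        "tolerant": {"none": (78.78, 2.74), "moderate": (98.58, 0.31), "high": (91.80, 2.59)},
    },
    "respiration": {
        "unplanted": {"none": (4.25, 0.33), "moderate": (4.46, 0.18), "high": (5.35, 0.31)},
        "sensitive": {"none": (4.73, 0.57), "moderate": (4.72, 0.27), "high": (5.82, 1.26)},
        "tolerant": {"none": (4.68, 0.51), "moderate": (4.68, 0.51), "high": (5.23, 0.67)},
    },
    "infiltration_cm3": {
        "unplanted": {"none": (0.16, 0.004), "moderate": (0.16, 0.007), "high": (0.17, 0.02)},
        "sensitive": {"none": (0.13, 0.04), "moderate": (0.19, 0.02), "high": (0.18, 0.004)},
        "tolerant": {"none": (0.20, 0.01), "moderate": (0.15, 0.05), "high": (0.13, 0.004)},
    },
}


def zone_percent_change(response: str, cultivar: str) -> float:
    """Rhizosheath-vs-bulk percent change from the published zone means."""
    means = ZONE_MEANS[response][cultivar]
    return percent_change(means["rhizosheath"][0], means["bulk"][0])


def cultivar_percent_change(trait: str, larger: str, smaller: str) -> float:
    """Percent excess of one cultivar's trait mean over another's."""
    means = ROOT_TRAIT_MEANS[trait]
    return percent_change(means[larger][0], means[smaller][0])


def high_carbon_percent_change(response: str, treatment: str) -> float:
    """High-carbon mean vs the average of the no/moderate-carbon means."""
    means = CARBON_MEANS[response][treatment]
    lower = (means["none"][0] + means["moderate"][0]) / 2.0
    return percent_change(means["high"][0], lower)


def worked_examples() -> dict[str, float]:
    """The study's headline percent-change claims, recomputed from the means."""
    return {
        "pct_root_shoot_ratio_tolerant_vs_sensitive": cultivar_percent_change("root_shoot_ratio", "tolerant", "sensitive"),
        "pct_shoot_dw_sensitive_vs_tolerant": cultivar_percent_change("shoot_dw_mg", "sensitive", "tolerant"),
        "pct_porosity_rhizosheath_vs_bulk_tolerant": zone_percent_change("porosity_pct", "tolerant"),
        "pct_respiration_rhizosheath_vs_bulk_sensitive": zone_percent_change("respiration", "sensitive"),
        "pct_respiration_rhizosheath_vs_bulk_tolerant": zone_percent_change("respiration", "tolerant"),
        "pct_porosity_high_carbon_sensitive": high_carbon_percent_change("porosity_pct", "sensitive"),
        "pct_connectivity_moderate_carbon_tolerant": percent_change(
            CARBON_MEANS["connectivity_pct"]["tolerant"]["moderate"][0],
            (CARBON_MEANS["connectivity_pct"]["tolerant"]["none"][0]
             + CARBON_MEANS["connectivity_pct"]["tolerant"]["high"][0]) / 2.0,
        ),
        "pct_respiration_high_carbon_sensitive": high_carbon_percent_change("respiration", "sensitive"),
        "pct_respiration_high_carbon_tolerant": high_carbon_percent_change("respiration", "tolerant"),
        "pct_respiration_high_carbon_unplanted": high_carbon_percent_change("respiration", "unplanted"),
    }
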