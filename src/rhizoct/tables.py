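"""Replicate-level synthetic tables with known effect structure.

Two generators:

* :func:`generate_table` draws one row per cultivar × carbon × replicate and
  fills the path-model variables (carbon score, root traits, rhizosheath
  mass, and rhizosheath-vs-bulk percent-change responses) from a linear
  recursive DAG with user-specified standardized path coefficients. This is
  the ground truth for path-model parameter recovery.

* :func:`generate_zone_table` draws the cultivar × carbon × zone × replicate
  measurement table (one response value per soil zone) with additive factor
  effects, the shape consumed by the ANOVA/Tukey machinery.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

CULTIVARS = ("sensitive", "tolerant", "unplanted")
CARBON_LEVELS = ("none", "moderate", "high")
ZONES = ("rhizosheath", "bulk")

#: Variables of the conceptual carbon → root → habitat → function chain.
SEM_VARIABLES = (
    "carbon_score",
    "root_shoot_ratio",
    "root_hair_area",
    "rhizosheath_mass",
    "d_porosity",
    "d_connectivity",
    "d_respiration",
    "d_infiltration",
)

CARBON_SCORE = {"none": 1, "moderate": 2, "high": 3}


class TableSpecError(ValueError):
    """Invalid table specification (e.g. cyclic edge set)."""


@dataclass
class TableSpec:
    """Design of a replicate-level table driven by a linear recursive DAG.

    ``edges`` maps directed (cause, effect) pairs to standardized path
    coefficients in [-1, 1]. Endogenous variables are generated in
    topological order as weighted sums of their standardized parents plus
    Gaussian noise; by default the residual SD is chosen so each endogenous
    variable has (approximately) unit variance, making the generating
    weights directly comparable to standardized regression slopes.
    """

    n_per_cell: int = 4
    cultivars: tuple[str, ...] = ("sensitive", "tolerant")
    carbons: tuple[str, ...] = CARBON_LEVELS
    variables: tuple[str, ...] = SEM_VARIABLES
    edges: dict[tuple[str, str], float] = field(default_factory=dict)
    noise_sd: dict[str, float] = field(default_factory=dict)
    seed: int = 0

    def validate(self) -> None:
        if self.n_per_cell < 1:
            raise TableSpecError("n_per_cell must be >= 1")
        for (cause, effect), w in self.edges.items():
            for v in (cause, effect):
                if v not in self.variables:
                    raise TableSpecError(f"edge endpoint {v!r} not declared in variables")
            if not -1 <= w <= 1:
                raise TableSpecError(f"standardized coefficient {w} on {cause}->{effect} outside [-1, 1]")
        g = nx.DiGraph(list(self.edges))
        if not nx.is_directed_acyclic_graph(g):
            raise TableSpecError("edge set contains a cycle; a recursive model requires a DAG")


def _standardize(x: np.ndarray) -> np.ndarray:
    sd = x.std(ddof=1)
    if sd == 0:
        return np.zeros_like(x, dtype=float)
    return (x - x.mean()) / sd


def generate_table(spec: TableSpec) -> pd.DataFrame:
    """Generate the replicate-level table implied by ``spec``'s DAG.

    Returns one row per cultivar × carbon × replicate with columns
    ``sample_id, cultivar, carbon, carbon_score, replicate`` plus every
    declared variable. ``carbon_score`` is the ordinal 1/2/3 coding of the
    carbon treatment; all other exogenous variables are standard normal.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)

    rows = []
    for cultivar in spec.cultivars:
        for carbon in spec.carbons:
            for rep in range(1, spec.n_per_cell + 1):
                rows.append((f"{cultivar}-{carbon}-r{rep}", cultivar, carbon, CARBON_SCORE[carbon], rep))
    df = pd.DataFrame(rows, columns=["sample_id", "cultivar", "carbon", "carbon_score", "replicate"])
    n = len(df)

    g = nx.DiGraph()
    g.add_nodes_from(spec.variables)
    for (cause, effect), w in spec.edges.items():
        g.add_edge(cause, effect, weight=w)

    values: dict[str, np.ndarray] = {"carbon_score": df["carbon_score"].to_numpy(dtype=float)}
    for var in nx.topological_sort(g):
        if var == "carbon_score":
            continue
        parents = list(g.predecessors(var))
        if not parents:
            values[var] = rng.normal(0.0, 1.0, size=n)
            continue
        z_parents = np.column_stack([_standardize(values[p]) for p in parents])
        w = np.array([g.edges[p, var]["weight"] for p in parents])
        systematic = z_parents @ w
        if var in spec.noise_sd:
            sd = spec.noise_sd[var]
        else:
            # residual variance completing the standardized variable to ~unit
            # variance given the (sample) correlation of the parents
            r = np.corrcoef(z_parents, rowvar=False) if len(parents) > 1 else np.ones((1, 1))
            explained = float(w @ np.atleast_2d(r) @ w)
            sd = float(np.sqrt(max(1.0 - explained, 0.05)))
        values[var] = systematic + rng.normal(0.0, sd, size=n)
    for var in spec.variables:
        if var not in values:
            values[var] = rng.normal(0.0, 1.0, size=n)
        if var != "carbon_score":
            df[var] = values[var]
    return df


def generate_zone_table(
    n_per_cell: int = 4,
    response: str = "porosity_pct",
    baseline: float = 24.0,
    cultivar_effects: dict[str, float] | None = None,
    carbon_effects: dict[str, float] | None = None,
    zone_effects: dict[str, float] | None = None,
    noise_sd: float = 1.0,
    cultivars: tuple[str, ...] = ("sensitive", "tolerant"),
    carbons: tuple[str, ...] = CARBON_LEVELS,
    zones: tuple[str, ...] = ZONES,
    seed: int = 0,
) -> pd.DataFrame:
    """Cultivar × carbon × zone × replicate table with additive effects.

    ``zone_effects`` maps ``"cultivar:zone"`` (or plain ``"zone"``) to an
    additive shift, so a rhizosheath elevation can be injected for one
    cultivar only. With all effects empty the design is an exact null,
    which is what the ANOVA type-I calibration uses.
    """
    rng = np.random.default_rng(seed)
    cultivar_effects = cultivar_effects or {}
    carbon_effects = carbon_effects or {}
    zone_effects = zone_effects or {}
    rows = []
    for cultivar in cultivars:
        for carbon in carbons:
            for zone in zones:
                for rep in range(1, n_per_cell + 1):
                    mu = (
                        baseline
                        + cultivar_effects.get(cultivar, 0.0)
                        + carbon_effects.get(carbon, 0.0)
                        + zone_effects.get(f"{cultivar}:{zone}", zone_effects.get(zone, 0.0))
                    )
                    rows.append(
                        (
                            f"{cultivar}-{carbon}-{zone}-r{rep}",
                            cultivar,
                            carbon,
                            zone,
                            rep,
                            mu + rng.normal(0.0, noise_sd),
                        )
                    )
    return pd.DataFrame(rows, columns=["sample_id", "cultivar", "carbon", "zone", "replicate", response])
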