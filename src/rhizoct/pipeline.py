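"""End-to-end orchestration: phantoms → segmentation → geometry → stats → SEM.

A single :class:`RunConfig` (YAML-loadable) drives a reproducible emulation
of the rhizosheath study design: 2 cultivars + unplanted × 3 carbon rates ×
n replicates. Every stage writes CSV outputs under the run directory and a
manifest records seed, config hash and package version, so a run is
bit-reproducible from config + seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

import rhizoct
from rhizoct.phantom import PhantomSpec, generate_phantom
from rhizoct.segmentation import threshold_pores, extract_root, make_labels
from rhizoct import geometry as geo
from rhizoct.stats import two_way_anova, one_way_anova, tukey_hsd, percent_change
from rhizoct.tables import TableSpec, generate_table
from rhizoct.sem import PathModelSpec, fit_path_model, compare_models

log = logging.getLogger("rhizoct.pipeline")


class StageError(RuntimeError):
    """Failure attributed to a named pipeline stage."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class RunConfig:
    """Configuration of a full simulation study run."""

    seed: int = 0
    outdir: str = "runs/default"
    # phantom geometry (desk scale: shells to 3 mm at 64 µm voxels)
    shape: tuple[int, int, int] = (64, 96, 96)
    voxel_size: float = 64.0
    root_radius: float = 500.0
    band_edges: tuple[float, ...] = (0.0, 1.0, 2.0, 3.0)
    rhizo_porosity: dict = field(default_factory=lambda: {"sensitive": 0.24, "tolerant": 0.28})
    far_porosity: float = 0.24
    # between-replicate SD of the porosity targets (porosity fraction units):
    # real cores differ in packing; without this, replicate phantoms are so
    # alike that sub-point measurement offsets dominate the ANOVA
    replicate_porosity_sd: float = 0.005
    pore_radius_range: tuple[float, float] = (128.0, 256.0)
    noise_sd: float = 5.0
    # design
    n_replicates: int = 4
    carbons: tuple[str, ...] = ("none", "moderate", "high")
    default_boundary_mm: float = 1.0
    # analysis options
    connectivity: int = 26
    alpha: float = 0.05
    save_volumes: bool = False
    # SEM: generating edges for the synthetic table and the model to fit
    sem_edges: dict = field(default_factory=lambda: {
        "carbon_score->d_respiration": 0.5,
        "carbon_score->root_shoot_ratio": 0.4,
        "root_shoot_ratio->d_porosity": 0.45,
        "root_hair_area->d_connectivity": 0.4,
        "rhizosheath_mass->d_infiltration": 0.5,
    })
    sem_n_per_cell: int = 4

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        cfg = cls(**raw)
        cfg.shape = tuple(cfg.shape)
        cfg.band_edges = tuple(cfg.band_edges)
        cfg.pore_radius_range = tuple(cfg.pore_radius_range)
        cfg.carbons = tuple(cfg.carbons)
        return cfg

    def digest(self) -> str:
        return hashlib.sha256(json.dumps(asdict(self), sort_keys=True, default=str).encode()).hexdigest()[:16]


def _phantom_seed(base: int, tag: str) -> int:
    h = int(hashlib.sha256(f"{base}:{tag}".encode()).hexdigest(), 16)
    return h % (2**31 - 1)


def _simulate_one(config: RunConfig, cultivar: str, carbon: str, rep: int):
    planted = cultivar != "unplanted"
    jitter_rng = np.random.default_rng(_phantom_seed(config.seed, f"jitter-{cultivar}-{carbon}-{rep}"))

    def jittered(phi: float) -> float:
        return float(np.clip(jitter_rng.normal(phi, config.replicate_porosity_sd), 0.02, 0.45))

    profile = []
    far = jittered(config.far_porosity)
    if planted:
        # one generator region per analysis band so every band hits its target
        # exactly (a single large far-field region redistributes coverage
        # towards its interior and would bias band-level contrasts)
        edges = config.band_edges
        profile = [(edges[0], edges[1], jittered(config.rhizo_porosity[cultivar]))]
        profile += [(lo, hi, jittered(config.far_porosity)) for lo, hi in zip(edges[1:], edges[2:])]
    spec = PhantomSpec(
        shape=config.shape,
        voxel_size=config.voxel_size,
        root_radius=config.root_radius if planted else 0.0,
        porosity_profile=profile,
        far_porosity=far,
        pore_radius_range=config.pore_radius_range,
        noise_sd=config.noise_sd,
        seed=_phantom_seed(config.seed, f"{cultivar}-{carbon}-{rep}"),
    )
    return generate_phantom(spec)


def _segment_one(config: RunConfig, volume, planted: bool):
    pores = threshold_pores(volume, method="otsu")
    if not planted:
        return make_labels(pores.mask, np.zeros(volume.shape, dtype=bool), volume.voxel_size)
    centre = tuple(s // 2 for s in volume.shape)
    root = extract_root(volume, seed_point=centre)
    return make_labels(pores.mask & ~root, root, volume.voxel_size)


def run_simulation_study(config: RunConfig) -> dict:
    """Run the full emulated study; returns a dict of output paths."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=logging.INFO)

    profiles_rows, geometry_rows = [], []
    detections = {}
    cultivars = ("sensitive", "tolerant")

    # --- simulate + segment + geometry ------------------------------------
    for cultivar in cultivars + ("unplanted",):
        planted = cultivar != "unplanted"
        cultivar_profiles = []
        per_sample = []
        for carbon in config.carbons:
            for rep in range(1, config.n_replicates + 1):
                sid = f"{cultivar}-{carbon}-r{rep}"
                try:
                    volume, truth = _simulate_one(config, cultivar, carbon, rep)
                except Exception as e:
                    raise StageError("simulate", f"{sid}: {e}") from e
                if config.save_volumes:
                    from rhizoct.volume_io import write_volume

                    write_volume(volume, outdir / f"{sid}.tif")
                try:
                    labels = _segment_one(config, volume, planted)
                except Exception as e:
                    raise StageError("segment", f"{sid}: {e}") from e
                try:
                    if planted:
                        dist = geo.distance_from_root(labels)
                        prof = geo.shell_profile(labels, config.band_edges, sample_id=sid, distance_um=dist)
                        cultivar_profiles.append(prof)
                        per_sample.append((sid, cultivar, carbon, rep, labels, dist))
                        for band, pct in zip(prof.band_labels, prof.porosity_pct):
                            profiles_rows.append((sid, cultivar, carbon, rep, band, pct))
                    else:
                        core = geo.unplanted_core(labels)
                        conn = geo.pore_connectivity(labels, region_mask=core, connectivity=config.connectivity)
                        geometry_rows.append(
                            (sid, cultivar, carbon, rep, "unplanted_core",
                             geo.porosity(core, labels), conn.connectivity_pct)
                        )
                except Exception as e:
                    raise StageError("geometry", f"{sid}: {e}") from e

        if planted:
            try:
                det = geo.detect_rhizosheath(cultivar_profiles, alpha=config.alpha)
            except Exception as e:
                raise StageError("geometry", f"rhizosheath detection ({cultivar}): {e}") from e
            detections[cultivar] = det
            boundary = det.boundary_mm if det.boundary_mm > 0 else config.default_boundary_mm
            for sid, cv, carbon, rep, labels, dist in per_sample:
                rhizo, bulk = geo.extract_regions(labels, dist, boundary)
                for region, mask in (("rhizosheath", rhizo), ("bulk", bulk)):
                    conn = geo.pore_connectivity(labels, region_mask=mask, connectivity=config.connectivity)
                    geometry_rows.append(
                        (sid, cv, carbon, rep, region, geo.porosity(mask, labels), conn.connectivity_pct)
                    )

    profiles_df = pd.DataFrame(
        profiles_rows, columns=["sample_id", "cultivar", "carbon", "replicate", "band", "porosity_pct"]
    )
    geometry_df = pd.DataFrame(
        geometry_rows,
        columns=["sample_id", "cultivar", "carbon", "replicate", "region", "porosity_pct", "connectivity_pct"],
    )
    profiles_df.to_csv(outdir / "profiles.csv", index=False, float_format="%.6f")
    geometry_df.to_csv(outdir / "geometry.csv", index=False, float_format="%.6f")
    det_df = pd.DataFrame(
        [
            {"cultivar": cv, "boundary_mm": d.boundary_mm, "status": d.status}
            for cv, d in detections.items()
        ]
    )
    det_df.to_csv(outdir / "rhizosheath_detection.csv", index=False)

    # --- stats: zone x carbon ANOVA per cultivar + Tukey letters -----------
    anova_rows, letter_rows = [], []
    for cultivar in cultivars:
        sub = geometry_df[(geometry_df.cultivar == cultivar) & geometry_df.region.isin(["rhizosheath", "bulk"])]
        for response in ("porosity_pct", "connectivity_pct"):
            try:
                res = two_way_anova(sub, response, "region", "carbon")
            except Exception as e:
                raise StageError("stats", f"{cultivar}/{response}: {e}") from e
            for term, row in res.table.iterrows():
                anova_rows.append((cultivar, response, term, row.get("df"), row.get("sum_sq"),
                                   row.get("F"), row.get("PR(>F)")))
            tk = tukey_hsd(sub, response, "region", alpha=config.alpha)
            means = sub.groupby("region")[response].mean()
            for grp, letter in tk.letters.items():
                letter_rows.append((cultivar, response, grp, float(means[grp]), letter))
    pd.DataFrame(
        anova_rows, columns=["cultivar", "response", "term", "df", "sum_sq", "F", "p"]
    ).to_csv(outdir / "anova.csv", index=False, float_format="%.6f")
    pd.DataFrame(
        letter_rows, columns=["cultivar", "response", "group", "mean", "letters"]
    ).to_csv(outdir / "group_letters.csv", index=False, float_format="%.6f")

    # --- per-replicate rhizosheath-vs-bulk percent changes -----------------
    feature_rows = []
    wide = geometry_df[geometry_df.region.isin(["rhizosheath", "bulk"])].pivot_table(
        index=["sample_id", "cultivar", "carbon", "replicate"],
        columns="region",
        values=["porosity_pct", "connectivity_pct"],
    )
    for key, row in wide.iterrows():
        sid, cultivar, carbon, rep = key
        feature_rows.append(
            (
                sid, cultivar, carbon, rep,
                percent_change(row[("porosity_pct", "rhizosheath")], row[("porosity_pct", "bulk")]),
                percent_change(row[("connectivity_pct", "rhizosheath")], row[("connectivity_pct", "bulk")]),
            )
        )
    pd.DataFrame(
        feature_rows,
        columns=["sample_id", "cultivar", "carbon", "replicate", "d_porosity", "d_connectivity"],
    ).to_csv(outdir / "percent_changes.csv", index=False, float_format="%.6f")

    # --- synthetic replicate table + path model ----------------------------
    edges = {tuple(k.split("->")): v for k, v in config.sem_edges.items()}
    tspec = TableSpec(n_per_cell=config.sem_n_per_cell, edges=edges, seed=_phantom_seed(config.seed, "sem-table"))
    table = generate_table(tspec)
    table.to_csv(outdir / "sem_table.csv", index=False, float_format="%.6f")
    variables = sorted({v for e in edges for v in e})
    mspec = PathModelSpec(variables=tuple(variables), edges=tuple(edges))
    try:
        import warnings as _w

        with _w.catch_warnings():
            _w.simplefilter("ignore")
            fit = fit_path_model(table, mspec)
    except Exception as e:
        raise StageError("sem", str(e)) from e
    fit.coefficients.to_csv(outdir / "sem_coefficients.csv", index=False, float_format="%.6f")
    (outdir / "sem_summary.txt").write_text(fit.summary() + "\n")

    manifest = {
        "package_version": rhizoct.__version__,
        "seed": config.seed,
        "config_digest": config.digest(),
        "outputs": sorted(p.name for p in outdir.iterdir() if p.is_file()),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return {"outdir": str(outdir), "manifest": manifest, "detections": detections}


def run_geometry_only(labels_path: str | Path, band_edges: tuple[float, ...], out_csv: str | Path,
                      connectivity: int = 26) -> pd.DataFrame:
    """Shell profile + connectivity for one stored label volume."""
    from rhizoct.volume_io import read_volume, LabelVolume

    labels = read_volume(labels_path)
    if not isinstance(labels, LabelVolume):
        raise StageError("geometry", f"{labels_path} is not a label volume")
    dist = geo.distance_from_root(labels)
    prof = geo.shell_profile(labels, band_edges, sample_id=str(labels_path), distance_um=dist)
    df = pd.DataFrame({"band": prof.band_labels, "porosity_pct": prof.porosity_pct,
                       "pore_voxels": prof.pore_counts, "total_voxels": prof.total_counts})
    df.to_csv(out_csv, index=False, float_format="%.6f")
    return df


def run_stats_only(table_path: str | Path, response: str, factors: tuple[str, str], out_csv: str | Path,
                   alpha: float = 0.05) -> pd.DataFrame:
    """Two-way ANOVA + Tukey letters on a stored sample table."""
    table = pd.read_csv(table_path)
    for col in (response, *factors):
        if col not in table.columns:
            raise StageError("stats", f"column {col!r} missing from {table_path}")
    res = two_way_anova(table, response, *factors)
    res.table.to_csv(out_csv, float_format="%.6f")
    return res.table
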