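"""CSV/JSON/YAML formats and the end-to-end pipeline composition.

All coordinates are nanometres with the origin at the field corner; CSV
files carry explicit headers.  The pipeline chains
simulate/ingest -> cluster -> filter -> histogram -> self-consistent fit
-> thermodynamics and emits a JSON-serializable report.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import clustering, distribution, fitting, thermo
from .clustering import ClusterRecord
from .errors import RowError, SchemaError
from .synthetic import GeneratorConfig, LocalizationMap, generate_localization_map, sample_cluster_sizes

__all__ = [
    "read_localizations",
    "write_localizations",
    "write_cluster_table",
    "read_cluster_table",
    "write_distribution",
    "load_config",
    "config_hash",
    "run_pipeline",
]

logger = logging.getLogger(__name__)

LOCALIZATION_COLUMNS = ["cell_id", "frame", "x_nm", "y_nm"]
CLUSTER_COLUMNS = ["cell_id", "cluster_id", "x_nm", "y_nm", "R_nm",
                   "diameter_nm", "count", "n"]


def write_localizations(maps: list[LocalizationMap], path) -> None:
    frames = [pd.DataFrame({"cell_id": m.cell_id, "frame": m.frame,
                            "x_nm": m.x_nm, "y_nm": m.y_nm}) for m in maps]
    out = (pd.concat(frames, ignore_index=True) if frames
           else pd.DataFrame(columns=LOCALIZATION_COLUMNS))
    out.to_csv(path, index=False)


def read_localizations(path, field_size: float | None = None) -> list[LocalizationMap]:
    """Read a localization CSV into one map per cell.

    Raises :class:`SchemaError` on missing columns and :class:`RowError`
    listing 1-based file line numbers of rows with non-finite coordinates.
    """
    df = pd.read_csv(path)
    missing = [c for c in LOCALIZATION_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")
    if df.empty:
        logger.warning("%s: no localizations", path)
        return []
    bad = ~(np.isfinite(df["x_nm"]) & np.isfinite(df["y_nm"])
            & np.isfinite(df["frame"]) & (df["frame"] >= 0))
    if bad.any():
        lines = (df.index[bad] + 2).tolist()  # +1 header, +1 one-based
        raise RowError(f"{path}: malformed rows at lines {lines}", lines=lines)
    maps = []
    for cell_id, group in df.groupby("cell_id", sort=False):
        fs = field_size or float(max(group["x_nm"].max(), group["y_nm"].max()))
        maps.append(LocalizationMap(
            x_nm=group["x_nm"].to_numpy(float),
            y_nm=group["y_nm"].to_numpy(float),
            frame=group["frame"].to_numpy(int),
            field_size=fs, cell_id=str(cell_id)))
    return maps


def write_cluster_table(records: list[ClusterRecord], path) -> None:
    pd.DataFrame([{
        "cell_id": r.cell_id, "cluster_id": r.cluster_id,
        "x_nm": r.centroid_nm[0], "y_nm": r.centroid_nm[1],
        "R_nm": r.R_nm, "diameter_nm": r.diameter_nm,
        "count": r.localization_count, "n": r.n,
    } for r in records], columns=CLUSTER_COLUMNS).to_csv(path, index=False)


def read_cluster_table(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in CLUSTER_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")
    return df


def write_distribution(dist: distribution.SizeDistribution,
                       curve: distribution.FreeEnergyCurve, path) -> None:
    occ = dist.occupied
    pd.DataFrame({
        "bin_center_n": dist.bin_centers[occ],
        "count": dist.counts[occ],
        "P": dist.P[occ],
        "dG_kBT": curve.dG,
    }).to_csv(path, index=False)


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise SchemaError(f"{path}: config must be a mapping")
    return cfg


def config_hash(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()).hexdigest()[:12]


DEFAULT_PIPELINE_CONFIG = {
    "simulate": {
        "a": 1.07e-3, "b": 4.3e-6, "n_clusters": 1000, "n_cells": 5,
        "n_background_molecules": 200, "seed": 0,
    },
    "clustering": {"eps": 40.0, "min_pts": 10, "min_diameter": 50.0},
    "binning": {"bin_width": 3e4, "n_start": 1.5e4},
    "fit": {"fit_fraction": 0.8, "cut_variable": "n"},
    "thermo": {"T": 310.0, "r1_nm": 1.0},
}


def run_pipeline(config: dict, out_dir=None) -> dict:
    """Execute simulate -> cluster -> filter -> histogram -> fit -> thermo.

    ``config`` follows :data:`DEFAULT_PIPELINE_CONFIG`; either a
    ``simulate`` section (synthetic maps) or an ``input`` section with a
    ``localizations`` CSV path must be present.  Returns the JSON-ready
    report; with ``out_dir`` set, also writes CSV intermediates and the
    report itself.
    """
    cfg = {**DEFAULT_PIPELINE_CONFIG, **config}
    chash = config_hash(cfg)
    stage = "setup"
    try:
        stage = "ingest"
        if "input" in cfg and cfg["input"]:
            maps = read_localizations(cfg["input"]["localizations"])
        else:
            sim = {**DEFAULT_PIPELINE_CONFIG["simulate"], **cfg.get("simulate", {})}
            maps = []
            for c in range(sim["n_cells"]):
                gen = GeneratorConfig(
                    a=sim["a"], b=sim["b"], seed=sim["seed"] + c,
                    n_clusters=sim["n_clusters"],
                    n_background_molecules=sim["n_background_molecules"],
                    n_max=sim.get("n_max"),
                    loc_sigma=sim.get("loc_sigma", 20.0),
                    rho_label=sim.get("rho_label", 1e-3))
                sizes = sample_cluster_sizes(gen)
                m, _ = generate_localization_map(sizes, gen, cell_id=f"cell_{c}")
                maps.append(m)

        stage = "cluster"
        clus = {**DEFAULT_PIPELINE_CONFIG["clustering"], **cfg.get("clustering", {})}
        records = []
        for m in maps:
            labels = clustering.dbscan(m.points, eps=clus["eps"], min_pts=clus["min_pts"])
            records.extend(clustering.extract_clusters(
                m.points, labels, cell_id=m.cell_id,
                radius_method=clus.get("radius_method", "span")))
        stage = "filter"
        kept = clustering.filter_clusters(records, min_diameter=clus["min_diameter"])

        stage = "histogram"
        binning = {**DEFAULT_PIPELINE_CONFIG["binning"], **cfg.get("binning", {})}
        n_values = np.array([r.n for r in kept])
        n_values = n_values[n_values >= binning["n_start"]]
        dist = distribution.histogram_sizes(n_values, bin_width=binning["bin_width"],
                                            n_start=binning["n_start"])
        curve = distribution.empirical_free_energy(dist)

        stage = "fit"
        fopts = {**DEFAULT_PIPELINE_CONFIG["fit"], **cfg.get("fit", {})}
        fit = fitting.self_consistent_fit(dist, fit_fraction=fopts["fit_fraction"],
                                          cut_variable=fopts["cut_variable"])

        stage = "thermo"
        report = {
            "config_hash": chash,
            "n_cells": len(maps),
            "n_clusters_detected": len(records),
            "n_clusters_retained": len(kept),
            "fit": fit.to_dict(),
            "saturation_class": fit.saturation_class,
        }
        if fit.saturation_class == "super":
            params = thermo.nucleation_parameters(fit.a, fit.b)
            sem_rc, sem_barrier = thermo.propagate_uncertainty(
                fit.a, fit.b, fit.sem_a, fit.sem_b, fit.cov_ab)
            report["thermo"] = {**params.to_dict(), "sem_Rc_nm": sem_rc,
                                "sem_barrier_kBT": sem_barrier}
            topts = {**DEFAULT_PIPELINE_CONFIG["thermo"], **cfg.get("thermo", {})}
            report["thermo"]["T_K"] = topts["T"]
    except Exception as exc:
        raise type(exc)(f"[stage={stage} config={chash}] {exc}") from exc

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        write_cluster_table(kept, out_dir / "clusters.csv")
        write_distribution(dist, curve, out_dir / "distribution.csv")
        with open(out_dir / "report.json", "w") as fh:
            json.dump(report, fh, indent=2)
    return report
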