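"""End-to-end experiment orchestration.

An :class:`ExperimentSpec` names one of the study's experiment shapes —
``decay`` (SunTag + Fluc smFISH), ``translation`` (smFISH + SunTag IF),
``risc`` (smFISH + AGO IF) or ``triple`` (all three) — over conditions
(+miR-21 vs seed-mutant control) and chase time points (0/30/60 min).
:func:`run_experiment` simulates each (condition, time) field, assigns
compartments, estimates and corrects inter-channel drift, classifies mRNAs,
computes per-cell and bulk metrics, normalizes stability to the matched
control time point, and runs the statistical battery (one-tailed
Mann–Whitney per metric per time point; Dunn's multiple comparisons across
the time course).  Spots-only runs are bit-reproducible from the manifest.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from silencescope.types import CellGeometry, ImageStack
from silencescope.simulate import (SimulationConfig, sample_cell_population,
                                   emit_spot_tables, render_field, DESIGN_CHANNELS)
from silencescope.segment import (segment_nuclei, segment_cells, geometry_from_labels,
                                  assign_compartment, geometry_table)
from silencescope.detect import detect_spots
from silencescope.colocalize import (DriftVector, estimate_drift, classify_mrnas,
                                     partition_free_spots)
from silencescope.quantify import (per_cell_metrics, bulk_metrics, normalize_to_control)
from silencescope.stats import mann_whitney_one_tailed, dunn_test

#: directional presets for the +miR-21 vs mutant one-tailed comparisons:
#: miR-21 reduces stability and translation and increases RISC binding.
MW_TAILS = {"S": "less", "S_norm": "less", "T_eff": "less", "T_fra": "less",
            "A_eff": "greater", "A_fra": "greater"}

#: metrics compared across the time course with Dunn's test, per design
DUNN_METRICS = {"decay": ["S_norm"], "translation": ["T_eff", "T_fra"],
                "risc": ["A_eff", "A_fra"],
                "triple": ["A_eff", "A_fra", "T_eff", "T_fra"]}


@dataclass
class ExperimentSpec:
    """Shape of one experiment: design, conditions, time points, gates."""
    design: str = "triple"
    conditions: tuple[str, ...] = ("miR21", "mutant")
    time_points_min: tuple[float, ...] = (0.0,)
    n_cells_per_condition: int = 50
    suntag_gate_nm: float = 500.0
    ago_gate_nm: float = 250.0
    mode: str = "spots"            # spots | images
    correct_drift: bool = True
    control_condition: str = "mutant"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.design not in DESIGN_CHANNELS:
            raise ValueError(f"unknown design {self.design!r}")
        if self.mode not in ("spots", "images"):
            raise ValueError(f"unknown mode {self.mode!r}")
        self.conditions = tuple(self.conditions)
        self.time_points_min = tuple(float(t) for t in self.time_points_min)


def _condition_seed(seed: int, condition: str, time_min: float) -> int:
    h = hashlib.sha256(f"{seed}|{condition}|{time_min}".encode()).digest()
    return int.from_bytes(h[:4], "little") % (2 ** 31)


def _config_for(spec: ExperimentSpec, base: SimulationConfig,
                condition: str, time_min: float) -> SimulationConfig:
    d = base.to_dict()
    d.update(design=spec.design, condition=condition, time_min=time_min,
             n_cells=spec.n_cells_per_condition,
             seed=_condition_seed(spec.seed, condition, time_min))
    return SimulationConfig.from_dict(d)


def _drift_or_none(mrna: pd.DataFrame, other: pd.DataFrame, pair) -> DriftVector | None:
    try:
        return estimate_drift(mrna, other, channel_pair=pair)
    except ValueError as err:
        warnings.warn(f"drift {pair}: {err}; assuming zero", stacklevel=2)
        return None


def process_field(tables: dict[str, pd.DataFrame], geoms: list[CellGeometry],
                  spec: ExperimentSpec) -> dict:
    """Run segmentation-assignment → drift → classification → metrics on one
    field's per-channel spot tables."""
    tables = {ch: assign_compartment(t, geoms) for ch, t in tables.items()}
    mrna = tables["mrna"]
    drifts = {}
    classified_kw = {}
    for ch, gate in (("suntag", spec.suntag_gate_nm), ("ago", spec.ago_gate_nm)):
        if ch in tables:
            drift = (_drift_or_none(mrna, tables[ch], ("mrna", ch))
                     if spec.correct_drift else None)
            drifts[ch] = drift
            classified_kw[f"drift_{ch}"] = drift
    classified = classify_mrnas(
        mrna, tables.get("suntag"), tables.get("ago"),
        suntag_gate_nm=spec.suntag_gate_nm, ago_gate_nm=spec.ago_gate_nm,
        **classified_kw)
    partitions = {}
    for ch, id_col in (("suntag", "suntag_partner_id"), ("ago", "ago_partner_id")):
        if ch in tables:
            pairs = classified.loc[classified[id_col] >= 0, ["mrna_spot_id", id_col]]
            pairs = pairs.rename(columns={"mrna_spot_id": "mrna_id", id_col: "partner_id"})
            partitions[ch] = partition_free_spots(tables[ch], pairs)
    cells = per_cell_metrics(
        classified, suntag=tables.get("suntag"), ago=tables.get("ago"),
        fluc=tables.get("fluc"), geometry=geoms)
    return {"tables": tables, "drifts": drifts, "classified": classified,
            "partitions": partitions, "cells": cells}


def run_experiment(spec: ExperimentSpec, base_config: SimulationConfig | None = None,
                   out_dir: str | Path | None = None) -> dict:
    """Simulate and analyze every (condition, time) field of an experiment.

    Returns a results bundle with per-cell metrics (long format, with
    ``condition`` and ``time_min`` columns and control-normalized ``S_norm``
    where the design carries a Fluc channel), bulk metrics, classified
    tables, Mann–Whitney and Dunn comparisons, and a manifest sufficient to
    re-run the spots-only analysis bit-identically.
    """
    base_config = base_config or SimulationConfig(design=spec.design)
    fields: dict[tuple[str, float], dict] = {}
    for condition in spec.conditions:
        for t in spec.time_points_min:
            config = _config_for(spec, base_config, condition, t)
            geoms, truth = sample_cell_population(config)
            if spec.mode == "spots":
                tables = emit_spot_tables(truth, config)
            else:
                stacks = render_field(truth, geoms, config)
                nuclei = segment_nuclei(stacks["dapi"])
                cell_labels = segment_cells(stacks["background"], nuclei)
                geoms = geometry_from_labels(nuclei, cell_labels,
                                             pixel_size_nm=config.voxel_size_xy_nm)
                tables = {ch: detect_spots(stacks[ch],
                                           psf_sigma_xy_nm=config.psf_sigma_xy_nm,
                                           psf_sigma_z_nm=config.psf_sigma_z_nm)
                          for ch in config.channels}
            result = process_field(tables, geoms, spec)
            result["truth"] = truth
            result["config"] = config
            fields[(condition, t)] = result

    # ---- control normalization (per time point) and pooling ---------------
    per_cell_rows = []
    bulk: dict[str, dict] = {}
    for (condition, t), result in fields.items():
        cells = result["cells"]
        b = bulk_metrics(cells) if len(cells) else {}
        if spec.design == "decay" and spec.control_condition in spec.conditions:
            control = fields[(spec.control_condition, t)]["cells"]
            cb = bulk_metrics(control) if len(control) else {}
            if cb.get("S_bulk"):
                cells = normalize_to_control(cells, cb)
        cells = cells.copy()
        cells["condition"] = condition
        cells["time_min"] = t
        per_cell_rows.append(cells)
        bulk[f"{condition}@{t:g}min"] = b
    per_cell = pd.concat(per_cell_rows, ignore_index=True)

    # ---- statistics -------------------------------------------------------
    mw_rows = []
    if set(spec.conditions) >= {"miR21", "mutant"}:
        for t in spec.time_points_min:
            a = per_cell[(per_cell.condition == "miR21") & (per_cell.time_min == t)]
            b = per_cell[(per_cell.condition == "mutant") & (per_cell.time_min == t)]
            for metric, tail in MW_TAILS.items():
                if metric not in per_cell.columns:
                    continue
                va = a[metric].dropna().to_numpy()
                vb = b[metric].dropna().to_numpy()
                if len(va) == 0 or len(vb) == 0:
                    continue
                res = mann_whitney_one_tailed(va, vb, alternative=tail)
                mw_rows.append({"time_min": t, "metric": metric, "tail": tail,
                                "U": res.statistic, "p": res.p_value,
                                "band": res.band, "n_miR21": len(va), "n_mutant": len(vb)})
    stats_mw = pd.DataFrame(mw_rows)

    dunn_rows = []
    metrics = [m for m in DUNN_METRICS[spec.design] + (["S_norm"] if spec.design == "decay" else [])
               if m in per_cell.columns]
    if len(spec.time_points_min) >= 2 and set(spec.conditions) >= {"miR21", "mutant"}:
        for metric in dict.fromkeys(metrics):
            groups, labels = [], []
            for t in spec.time_points_min:
                for condition in ("miR21", "mutant"):
                    vals = per_cell[(per_cell.condition == condition)
                                    & (per_cell.time_min == t)][metric].dropna()
                    groups.append(vals.to_numpy())
                    labels.append((condition, t))
            pairs = [(2 * i, 2 * i + 1) for i in range(len(spec.time_points_min))]
            if any(g.size == 0 for g in groups):
                continue
            for res in dunn_test(groups, pairs=pairs):
                i, j = res.comparison
                dunn_rows.append({"metric": metric, "time_min": labels[i][1],
                                  "comparison": f"{labels[i][0]} vs {labels[j][0]}",
                                  "z": res.statistic, "p": res.p_value,
                                  "p_adj": res.p_adjusted, "band": res.band})
    stats_dunn = pd.DataFrame(dunn_rows)

    manifest = {
        "spec": asdict(spec),
        "base_config": base_config.to_dict(),
        "field_seeds": {f"{c}@{t:g}min": fields[(c, t)]["config"].seed
                        for c in spec.conditions for t in spec.time_points_min},
        "config_hash": hashlib.sha256(
            json.dumps({"spec": asdict(spec), "config": base_config.to_dict()},
                       sort_keys=True, default=str).encode()).hexdigest(),
        "package_version": _package_version(),
    }
    bundle = {"per_cell": per_cell, "bulk": bulk, "fields": fields,
              "stats_mw": stats_mw, "stats_dunn": stats_dunn, "manifest": manifest}
    if out_dir is not None:
        _write_bundle(bundle, Path(out_dir))
    return bundle


def _package_version() -> str:
    from silencescope import __version__
    return __version__


def _write_bundle(bundle: dict, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    bundle["per_cell"].to_csv(out_dir / "metrics_per_cell.csv", index=False)
    with open(out_dir / "metrics_bulk.json", "w") as fh:
        json.dump(bundle["bulk"], fh, indent=2)
    classes = pd.concat(
        [res["classified"].assign(condition=c, time_min=t)
         for (c, t), res in bundle["fields"].items()], ignore_index=True)
    classes.to_csv(out_dir / "classes.csv", index=False)
    stats = pd.concat([bundle["stats_mw"].assign(test="mann-whitney"),
                       bundle["stats_dunn"].assign(test="dunn")], ignore_index=True)
    stats.to_csv(out_dir / "stats.csv", index=False)
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(bundle["manifest"], fh, indent=2)


# ---------------------------------------------------------------------------
# dataset I/O
# ---------------------------------------------------------------------------

GEOMETRY_COLUMNS = ["cell_id", "center_y_px", "center_x_px", "cell_ry_px", "cell_rx_px",
                    "nuc_ry_px", "nuc_rx_px", "pixel_size_nm", "field_ny", "field_nx",
                    "nucleus_area_um2", "touches_border"]


def write_dataset(path: str | Path, tables: dict[str, pd.DataFrame] | None = None,
                  geometry: list[CellGeometry] | None = None,
                  stacks: dict[str, ImageStack] | None = None,
                  config: SimulationConfig | None = None) -> None:
    """Write a dataset directory: ``spots_<channel>.csv`` + ``geometry.csv``
    for spot tables, and/or ``<channel>.tif`` stacks, plus ``config.yaml``."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    for ch, table in (tables or {}).items():
        table.to_csv(path / f"spots_{ch}.csv", index=False)
    for ch, stack in (stacks or {}).items():
        stack.to_tiff(path / f"{ch}.tif")
    if geometry:
        rows = []
        for g in geometry:
            if not g.is_analytic:
                raise ValueError("CSV geometry supports analytic (ellipse) cells only; "
                                 "write label TIFFs for mask-backed geometry")
            rows.append({
                "cell_id": g.cell_id, "center_y_px": g.center_px[0],
                "center_x_px": g.center_px[1], "cell_ry_px": g.cell_radii_px[0],
                "cell_rx_px": g.cell_radii_px[1], "nuc_ry_px": g.nucleus_radii_px[0],
                "nuc_rx_px": g.nucleus_radii_px[1], "pixel_size_nm": g.pixel_size_nm,
                "field_ny": g.field_shape_yx[0], "field_nx": g.field_shape_yx[1],
                "nucleus_area_um2": g.nucleus_area_um2, "touches_border": g.touches_border,
            })
        pd.DataFrame(rows, columns=GEOMETRY_COLUMNS).to_csv(path / "geometry.csv", index=False)
    if config is not None:
        config.to_yaml(path / "config.yaml")


def read_dataset(path: str | Path, config: SimulationConfig | None = None) -> dict:
    """Load a dataset directory written by :func:`write_dataset`.

    Returns ``{"tables": {channel: df}, "stacks": {channel: ImageStack},
    "geometry": [CellGeometry], "config": SimulationConfig | None}``.
    Warns when a TIFF's voxel-size metadata disagrees with the config.
    """
    path = Path(path)
    if not path.is_dir():
        raise FileNotFoundError(f"dataset directory {path} not found")
    if config is None and (path / "config.yaml").exists():
        config = SimulationConfig.from_yaml(path / "config.yaml")
    tables = {p.stem.removeprefix("spots_"): pd.read_csv(p)
              for p in sorted(path.glob("spots_*.csv"))}
    stacks = {}
    for p in sorted(path.glob("*.tif")):
        stack = ImageStack.from_tiff(p, channel_name=p.stem)
        if config is not None and not np.isclose(stack.voxel_size_xy_nm,
                                                 config.voxel_size_xy_nm, rtol=1e-3):
            warnings.warn(
                f"{p.name}: voxel size {stack.voxel_size_xy_nm:.1f} nm disagrees "
                f"with config {config.voxel_size_xy_nm:.1f} nm", stacklevel=2)
        stacks[p.stem] = stack
    geometry = []
    if (path / "geometry.csv").exists():
        gdf = pd.read_csv(path / "geometry.csv")
        for _, r in gdf.iterrows():
            geometry.append(CellGeometry(
                cell_id=int(r.cell_id),
                field_shape_yx=(int(r.field_ny), int(r.field_nx)),
                pixel_size_nm=float(r.pixel_size_nm),
                center_px=(float(r.center_y_px), float(r.center_x_px)),
                cell_radii_px=(float(r.cell_ry_px), float(r.cell_rx_px)),
                nucleus_radii_px=(float(r.nuc_ry_px), float(r.nuc_rx_px)),
                touches_border=bool(r.touches_border)))
    return {"tables": tables, "stacks": stacks, "geometry": geometry, "config": config}
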