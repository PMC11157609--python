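"""End-to-end orchestration: configuration, staging, artifacts, manifest.

``run_pipeline`` stitches the full analysis together per species:
thin -> screen variables -> calibrate -> replicate ensemble -> project to
every scenario -> multi-member averaging -> classify/areas -> change
matrices and centroid tracks -> cross-species similarity of migration
vectors.  Every artifact lands under the configured output directory and
is recorded (with a checksum) in the run manifest, so a deterministic
re-run reproduces the outputs bit-identically apart from timing.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as nio
from .calibration import calibrate, candidate_grid, default_fc_combos
from .dynamics import binarize, centroid_track, change_matrix, cosine_similarity
from .mapping import class_areas, classify_suitability, gcm_ensemble, jackknife_importance, replicate_ensemble
from .maxent import project
from .occurrences import OccurrenceSet, SplitSpec, make_splits, thin_to_grid
from .rasters import SuitabilityRaster
from .variable_selection import correlation_matrix, pretrain_contributions, select_variables

#: Defaults matching the published protocol: 75/25 split, 10 bootstrap
#: replicates, RM 0.1-4.0 step 0.1 x 29 FCs, E = 5%, |r| > 0.8 screening,
#: suitability thresholds 0.1/0.3/0.5 and binary threshold 0.1.
DEFAULT_PARAMS = {
    "train_fraction": 0.75,
    "replicates": 10,
    "rm_start": 0.1,
    "rm_stop": 4.0,
    "rm_step": 0.1,
    "fc_combos": None,
    "E": 0.05,
    "alpha": 0.05,
    "proc_iterations": 500,
    "r_threshold": 0.8,
    "thresholds": [0.1, 0.3, 0.5],
    "binary_threshold": 0.1,
    "background_size": 10000,
    "n_hinges": 10,
    "n_thresholds": 10,
}


@dataclass
class RunConfig:
    """Validated pipeline configuration.

    ``scenarios`` maps a scenario/period label to a list of stack
    directories (multiple entries = GCM members to average).
    """

    species: list[dict]                  # each: {"name": ..., "occurrences": path}
    current_stack: Path
    scenarios: dict[str, list[Path]]
    output_dir: Path
    seed: int = 0
    params: dict = field(default_factory=dict)
    base_dir: Path = Path(".")

    def __post_init__(self) -> None:
        merged = dict(DEFAULT_PARAMS)
        merged.update(self.params)
        self.params = merged
        self.current_stack = Path(self.current_stack)
        self.output_dir = Path(self.output_dir)
        self.scenarios = {k: [Path(p) for p in v] for k, v in self.scenarios.items()}

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        path = Path(path)
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        base = path.parent
        cfg = cls(
            species=raw["species"],
            current_stack=base / raw["stacks"]["current"],
            scenarios={k: [base / p for p in v]
                       for k, v in raw["stacks"].get("scenarios", {}).items()},
            output_dir=base / raw.get("output_dir", "out"),
            seed=int(raw.get("seed", 0)),
            params=raw.get("params", {}) or {},
            base_dir=base,
        )
        return cfg

    def validate(self) -> None:
        """Fail fast on unresolvable paths, before any computation."""
        problems = []
        for sp in self.species:
            p = self.base_dir / sp["occurrences"]
            if not p.exists():
                problems.append(str(p))
        for d in [self.current_stack, *(p for v in self.scenarios.values() for p in v)]:
            if not Path(d).exists():
                problems.append(str(d))
        if problems:
            raise FileNotFoundError(f"config references missing path(s): {problems}")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


class _Manifest:
    def __init__(self, config: RunConfig):
        self.doc = {
            "config": {
                "seed": config.seed,
                "params": config.params,
                "species": [sp["name"] for sp in config.species],
                "scenarios": sorted(config.scenarios),
            },
            "outputs": {},
            "timing_s": {},
        }
        self._t0 = None
        self._stage = None

    def start(self, stage: str) -> None:
        self._stage = stage
        self._t0 = time.perf_counter()

    def done(self) -> None:
        self.doc["timing_s"][self._stage] = round(time.perf_counter() - self._t0, 3)

    def record(self, path: Path) -> Path:
        self.doc["outputs"][str(path)] = _sha256(Path(path))
        return path


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full multi-species, multi-scenario analysis.

    Returns the run manifest (also written to ``output_dir/manifest.json``):
    a config snapshot, every artifact path with its SHA-256 checksum, and
    per-stage wall-clock timings.
    """
    config.validate()
    params = config.params
    out_root = Path(config.output_dir)
    out_root.mkdir(parents=True, exist_ok=True)
    manifest = _Manifest(config)

    current = nio.read_stack(config.current_stack)
    scenario_stacks = {
        label: [nio.read_stack(d) for d in dirs]
        for label, dirs in config.scenarios.items()
    }
    grid = candidate_grid(
        params["rm_start"], params["rm_stop"], params["rm_step"],
        params["fc_combos"] if params["fc_combos"] else None,
    )

    per_species_tracks: dict[str, pd.DataFrame] = {}
    for si, sp in enumerate(config.species):
        name = sp["name"]
        out = out_root / name
        out.mkdir(parents=True, exist_ok=True)
        seed = int(config.seed) + 1000 * si

        manifest.start(f"{name}/thin")
        occ = nio.read_occurrences(config.base_dir / sp["occurrences"])
        thinned, report = thin_to_grid(occ, current)
        (out / "thinning_report.json").write_text(json.dumps(report.to_dict(), indent=1))
        manifest.record(out / "thinning_report.json")
        manifest.record(nio.write_occurrences(out / "occurrences_thinned.csv", thinned))
        manifest.done()

        manifest.start(f"{name}/variable_selection")
        corr = correlation_matrix(current, seed=seed)
        contrib = pretrain_contributions(
            thinned, current, seed=seed,
            n_background=params["background_size"],
            n_hinges=params["n_hinges"],
        )
        selection = select_variables(contrib, corr, r_threshold=params["r_threshold"])
        corr.to_frame().to_csv(out / "correlation_matrix.csv")
        contrib.to_frame().to_csv(out / "contributions.csv", index=False)
        selection.exclusion_log().to_csv(out / "variable_exclusions.csv", index=False)
        (out / "variables_retained.json").write_text(json.dumps(selection.retained))
        for f in ("correlation_matrix.csv", "contributions.csv",
                  "variable_exclusions.csv", "variables_retained.json"):
            manifest.record(out / f)
        variables = selection.retained
        if len(variables) < 2:  # degenerate screening; fall back to full set
            variables = current.variable_names
        manifest.done()

        manifest.start(f"{name}/calibration")
        outcome = calibrate(
            thinned, current, grid=grid, seed=seed, variables=variables,
            train_fraction=params["train_fraction"], E=params["E"],
            alpha=params["alpha"], proc_iterations=params["proc_iterations"],
            background_size=params["background_size"],
            n_hinges=params["n_hinges"], n_thresholds=params["n_thresholds"],
        )
        outcome.table().to_csv(out / "candidates.csv", index=False)
        (out / "selection.json").write_text(json.dumps(outcome.to_dict(), indent=1))
        manifest.record(out / "candidates.csv")
        manifest.record(out / "selection.json")
        chosen = outcome.chosen
        manifest.done()

        manifest.start(f"{name}/replicates")
        splits = make_splits(
            thinned,
            SplitSpec(train_fraction=params["train_fraction"],
                      replicate_count=params["replicates"], seed=seed),
        )
        ensemble = replicate_ensemble(
            splits, current, rm=chosen.rm, fc=chosen.fc, seed=seed,
            variables=variables, background_size=params["background_size"],
            n_hinges=params["n_hinges"], n_thresholds=params["n_thresholds"],
            keep_models=True,
        )
        manifest.record(nio.write_suitability(out / "suitability_current.asc",
                                              ensemble.mean_raster))
        pd.DataFrame({"replicate": range(len(ensemble.replicate_aucs)),
                      "auc": ensemble.replicate_aucs}).to_csv(
            out / "replicate_aucs.csv", index=False)
        manifest.record(out / "replicate_aucs.csv")
        manifest.done()

        manifest.start(f"{name}/jackknife")
        jk = jackknife_importance(
            thinned, current, rm=chosen.rm, fc=chosen.fc, seed=seed,
            variables=variables, background_size=params["background_size"],
            n_hinges=params["n_hinges"], n_thresholds=params["n_thresholds"],
        )
        jk.to_csv(out / "jackknife_importance.csv")
        manifest.record(out / "jackknife_importance.csv")
        manifest.done()

        manifest.start(f"{name}/scenarios")
        rasters: dict[str, SuitabilityRaster] = {"current": ensemble.mean_raster}
        for label, members in scenario_stacks.items():
            member_rasters = []
            for member in members:
                reps = [project(m, member, clamp=True) for m in ensemble.models]
                mean_values = np.mean(np.stack([r.values for r in reps]), axis=0)
                member_rasters.append(
                    SuitabilityRaster(grid=member.grid, values=mean_values,
                                      nodata_mask=member.nodata_mask.copy())
                )
            rasters[label] = gcm_ensemble(member_rasters)
            manifest.record(
                nio.write_suitability(out / f"suitability_{label}.asc", rasters[label])
            )
        manifest.done()

        manifest.start(f"{name}/areas_changes")
        area_rows = []
        binaries = {}
        for label, raster in rasters.items():
            classified = classify_suitability(raster, tuple(params["thresholds"]))
            areas = class_areas(classified)
            for cls, row in areas.table.iterrows():
                area_rows.append({"period": label, "class": cls,
                                  "area_km2": row["area_km2"],
                                  "area_1e4_km2": row["area_1e4_km2"]})
            area_rows.append({"period": label, "class": "total_suitable",
                              "area_km2": areas.total_suitable_km2,
                              "area_1e4_km2": areas.total_suitable_km2 / 1e4})
            binaries[label] = binarize(raster, params["binary_threshold"])
        pd.DataFrame(area_rows).to_csv(out / "class_areas.csv", index=False)
        manifest.record(out / "class_areas.csv")

        change_rows = []
        for label in scenario_stacks:
            change = change_matrix(binaries["current"], binaries[label])
            for cat, area in change.areas_km2.items():
                change_rows.append({"scenario": label, "category": cat,
                                    "area_km2": area})
        pd.DataFrame(change_rows).to_csv(out / "change_areas.csv", index=False)
        manifest.record(out / "change_areas.csv")

        labels = ["current", *sorted(scenario_stacks)]
        track = centroid_track(labels, [binaries[l] for l in labels])
        track.points.to_csv(out / "centroids.csv", index=False)
        track.segments.to_csv(out / "centroid_segments.csv", index=False)
        manifest.record(out / "centroids.csv")
        manifest.record(out / "centroid_segments.csv")
        manifest.record(
            nio.write_geojson(out / "centroid_track.geojson",
                              nio.centroid_track_geojson(track))
        )
        per_species_tracks[name] = track.segments
        manifest.done()

    if len(per_species_tracks) >= 2:
        manifest.start("similarity")
        names = list(per_species_tracks)
        rows = []
        for i in range(len(names)):
            for j in range(i + 1, len(names)):
                a, b = per_species_tracks[names[i]], per_species_tracks[names[j]]
                merged = a.merge(b, on=["from", "to"], suffixes=("_a", "_b"))
                for _, row in merged.iterrows():
                    try:
                        cs = cosine_similarity(
                            (row["east_km_a"], row["north_km_a"]),
                            (row["east_km_b"], row["north_km_b"]),
                        )
                    except ValueError:
                        cs = float("nan")
                    rows.append({"species_a": names[i], "species_b": names[j],
                                 "from": row["from"], "to": row["to"],
                                 "cosine_similarity": cs})
        pd.DataFrame(rows).to_csv(out_root / "centroid_similarity.csv", index=False)
        manifest.record(out_root / "centroid_similarity.csv")
        manifest.done()

    manifest_path = out_root / "manifest.json"
    manifest_path.write_text(json.dumps(manifest.doc, indent=1, sort_keys=True))
    return manifest.doc


# ---------------------------------------------------------------------------
# Demo input builder: a small on-disk synthetic study (two species, two
# scenarios) for the end-to-end examples and smoke tests.
# ---------------------------------------------------------------------------

def write_demo_inputs(
    directory,
    seed: int = 0,
    n_rows: int = 60,
    n_cols: int = 60,
    n_occurrences: int = 150,
) -> Path:
    """Write a complete demo study to ``directory``; returns the config path.

    Two species (a pest-like and a host-like niche, both driven by
    minimum winter temperature and annual precipitation), a current
    stack, and two scenario stacks — a moderate and a strong warming
    pathway with latitude-intensifying temperature shifts and a 5.2%
    precipitation increase in the strong case.  Calibration is reduced to
    a 5 RM x 4 FC grid so the whole run stays desk-scale.
    """
    from .synthetic import (
        DEMO_CORRELATION, DEMO_LAYER_SPECS, NicheFunction,
        demo_niche, generate_climate_stack, generate_future_stack,
        sample_occurrences,
    )

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    stack = generate_climate_stack(
        seed=seed, n_rows=n_rows, n_cols=n_cols,
        layer_spec=DEMO_LAYER_SPECS, target_correlation=DEMO_CORRELATION,
        smoothing_length=3.0, sea_border_fraction=0.05,
    )
    niches = {
        "demo_pest": demo_niche(),
        "demo_host": NicheFunction.from_optima(
            variables=["bio06", "bio12"], optima=[40.0, 1300.0],
            widths=[90.0, 800.0], weights=[5.0, 2.0], intercept=2.2,
        ),
    }
    nio.write_stack(directory / "stacks" / "current", stack,
                    manifest_extra={"seed": seed})
    scenarios = {
        "ssp126_2050": generate_future_stack(stack, warming_at_equator=8.0,
                                             warming_gradient_per_degree_lat=0.2,
                                             precip_fraction=0.02),
        "ssp585_2070": generate_future_stack(stack, warming_at_equator=16.0,
                                             warming_gradient_per_degree_lat=0.4,
                                             precip_fraction=0.052),
    }
    for label, sc in scenarios.items():
        nio.write_stack(directory / "stacks" / label, sc,
                        manifest_extra={"seed": seed, "scenario": label})
    species_cfg = []
    for i, (name, niche) in enumerate(niches.items()):
        occ = sample_occurrences(stack, niche, n=n_occurrences,
                                 seed=seed + 10 + i, species=name)
        nio.write_occurrences(directory / f"occurrences_{name}.csv", occ)
        species_cfg.append({"name": name, "occurrences": f"occurrences_{name}.csv"})
    config = {
        "seed": seed,
        "output_dir": "out",
        "species": species_cfg,
        "stacks": {
            "current": "stacks/current",
            "scenarios": {label: [f"stacks/{label}"] for label in scenarios},
        },
        "params": {
            "replicates": 5,
            "rm_start": 0.5, "rm_stop": 2.5, "rm_step": 0.5,
            "fc_combos": ["l", "lq", "lp", "lqp"],
            "proc_iterations": 100,
            "background_size": 2000,
        },
    }
    config_path = directory / "config.yaml"
    with open(config_path, "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=False)
    return config_path
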