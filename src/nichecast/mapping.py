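"""Final-model suitability mapping and evaluation.

Replicate ensembling with ROC/AUC evaluation, jackknife variable
importance, multi-scenario (GCM) raster averaging, four-class
suitability maps at the 0.1 / 0.3 / 0.5 thresholds, and spherical-cell
area accounting.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .maxent import MaxEntModel, fit_maxent, project, sample_background
from .occurrences import OccurrenceSet
from .rasters import ClimateStack, GridGeometry, SuitabilityRaster, cell_area_grid_km2

CLASS_LABELS = ("unsuitable", "low", "moderate", "high")
DEFAULT_THRESHOLDS = (0.1, 0.3, 0.5)


def auc(presence_p: np.ndarray, background_p: np.ndarray) -> float:
    """Rank-based (Mann-Whitney) AUC of presences vs background.

    Ties count half; equals the probability that a random presence cell
    outscores a random background cell.  Invariant under any strictly
    increasing transform of the scores.
    """
    presence_p = np.asarray(presence_p, dtype=float)
    background_p = np.asarray(background_p, dtype=float)
    if presence_p.size == 0 or background_p.size == 0:
        raise ValueError("both score sets must be non-empty")
    n_p, n_b = presence_p.size, background_p.size
    ranks = rankdata(np.concatenate([presence_p, background_p]))
    u = ranks[:n_p].sum() - n_p * (n_p + 1) / 2
    return float(u / (n_p * n_b))


@dataclass
class EnsembleResult:
    mean_raster: SuitabilityRaster
    replicate_aucs: list[float]
    mean_auc: float
    models: list[MaxEntModel] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)


def replicate_ensemble(
    splits: list[tuple[OccurrenceSet, OccurrenceSet]],
    stack: ClimateStack,
    rm: float,
    fc: str,
    seed: int = 0,
    variables: list[str] | None = None,
    background_size: int = 10000,
    n_hinges: int = 10,
    n_thresholds: int = 10,
    keep_models: bool = False,
) -> EnsembleResult:
    """Fit one model per replicate split and average the logistic maps.

    Each replicate's AUC is computed on its held-out test presences
    against the shared background sample; the final suitability raster
    is the cell-wise mean over converged replicates.  Non-converged
    replicates are dropped with a warning.
    """
    if not splits:
        raise ValueError("need at least one replicate split")
    variables = stack.variable_names if variables is None else list(variables)
    all_lon = np.concatenate([np.concatenate([tr.lon, te.lon]) for tr, te in splits])
    all_lat = np.concatenate([np.concatenate([tr.lat, te.lat]) for tr, te in splits])
    prow, pcol = stack.grid.cell_index(all_lon, all_lat)
    brow, bcol = sample_background(
        stack, n=background_size, seed=seed, include_cells=list(zip(prow, pcol))
    )
    bg = stack.env_at_cells(brow, bcol, variables)

    rasters, aucs, models, warnings = [], [], [], []
    for r, (train, test) in enumerate(splits):
        trow, tcol = stack.grid.cell_index(train.lon, train.lat)
        pres = stack.env_at_cells(trow, tcol, variables)
        model = fit_maxent(pres, bg, variables, rm=rm, fc=fc, seed=seed,
                           n_hinges=n_hinges, n_thresholds=n_thresholds)
        if not model.converged:
            warnings.append(f"replicate {r}: model did not converge; dropped")
            continue
        raster = project(model, stack, clamp=True)
        srow, scol = stack.grid.cell_index(test.lon, test.lat)
        test_p = raster.values[srow, scol]
        bg_p = raster.values[brow, bcol]
        aucs.append(auc(test_p, bg_p))
        rasters.append(raster.values)
        if keep_models:
            models.append(model)
    if not rasters:
        raise ValueError("every replicate failed to converge")
    mean_values = np.mean(np.stack(rasters), axis=0)
    mean_raster = SuitabilityRaster(
        grid=stack.grid, values=mean_values,
        nodata_mask=stack.nodata_mask.copy(), kind="logistic",
    )
    return EnsembleResult(
        mean_raster=mean_raster, replicate_aucs=aucs,
        mean_auc=float(np.mean(aucs)), models=models, warnings=warnings,
    )


def jackknife_importance(
    presences: OccurrenceSet,
    stack: ClimateStack,
    rm: float,
    fc: str,
    seed: int = 0,
    variables: list[str] | None = None,
    background_size: int = 10000,
    n_hinges: int = 10,
    n_thresholds: int = 10,
) -> pd.DataFrame:
    """Jackknife variable importance: with-only and without gains.

    For each variable, fits a model using only that variable and another
    using all other variables, reporting the regularized training gains
    alongside the full-model gain (column ``full_gain``).  Per-variable
    fit failures are recorded as NaN, not fatal.
    """
    variables = stack.variable_names if variables is None else list(variables)
    if len(variables) < 2:
        raise ValueError("jackknife needs at least 2 variables")
    prow, pcol = stack.grid.cell_index(presences.lon, presences.lat)
    brow, bcol = sample_background(
        stack, n=background_size, seed=seed, include_cells=list(zip(prow, pcol))
    )

    def fit_gain(vs: list[str]) -> float:
        use_fc = "".join(c for c in fc if c != "p") if len(vs) < 2 else fc
        model = fit_maxent(
            stack.env_at_cells(prow, pcol, vs), stack.env_at_cells(brow, bcol, vs),
            vs, rm=rm, fc=use_fc, seed=seed,
            n_hinges=n_hinges, n_thresholds=n_thresholds,
        )
        return model.regularized_gain if model.converged else float("nan")

    full = fit_gain(variables)
    rows = []
    for v in variables:
        rest = [w for w in variables if w != v]
        try:
            only = fit_gain([v])
        except Exception:
            only = float("nan")
        try:
            without = fit_gain(rest)
        except Exception:
            without = float("nan")
        rows.append({"variable": v, "gain_with_only": only,
                     "gain_without": without, "full_gain": full})
    return pd.DataFrame(rows).set_index("variable")


def gcm_ensemble(rasters: list[SuitabilityRaster]) -> SuitabilityRaster:
    """Cell-wise arithmetic mean of aligned suitability rasters (the
    multi-GCM averaging step)."""
    if not rasters:
        raise ValueError("need at least one raster")
    first = rasters[0]
    for i, r in enumerate(rasters[1:], start=1):
        if not first.same_geometry(r):
            raise ValueError(f"raster {i} grid/mask does not match raster 0")
    values = np.mean(np.stack([r.values for r in rasters]), axis=0)
    return SuitabilityRaster(grid=first.grid, values=values,
                             nodata_mask=first.nodata_mask.copy(), kind=first.kind)


@dataclass
class ClassifiedRaster:
    """Four-level suitability classes on a raster grid.

    Classes are assigned by half-open, lower-inclusive intervals
    [0, t1) unsuitable, [t1, t2) low, [t2, t3) moderate, [t3, 1] high.
    ``classes`` holds -1 at nodata cells.
    """

    grid: GridGeometry
    classes: np.ndarray
    thresholds: tuple[float, float, float]
    nodata_mask: np.ndarray
    labels: tuple[str, ...] = CLASS_LABELS

    @property
    def valid_mask(self) -> np.ndarray:
        return ~self.nodata_mask


def classify_suitability(
    raster: SuitabilityRaster,
    thresholds: tuple[float, float, float] = DEFAULT_THRESHOLDS,
) -> ClassifiedRaster:
    """Reclassify a probability raster into the four suitability levels."""
    t = tuple(thresholds)
    if not (t[0] < t[1] < t[2]):
        raise ValueError("thresholds must be strictly increasing")
    valid = raster.valid_mask
    vals = raster.values
    if np.any((vals[valid] < 0) | (vals[valid] > 1)):
        raise ValueError("suitability values must lie in [0, 1]")
    classes = np.full(raster.grid.shape, -1, dtype=int)
    classes[valid] = np.digitize(vals[valid], t, right=False)
    return ClassifiedRaster(grid=raster.grid, classes=classes, thresholds=t,
                            nodata_mask=raster.nodata_mask.copy())


@dataclass
class AreaTable:
    """Per-class areas (spherical cells, km^2 and 10^4 km^2)."""

    table: pd.DataFrame
    total_valid_km2: float
    total_suitable_km2: float  # low + moderate + high

    def area_km2(self, label: str) -> float:
        return float(self.table.loc[label, "area_km2"])


def class_areas(classified: ClassifiedRaster) -> AreaTable:
    """Sum spherical cell areas per suitability class.

    Cell area on the sphere is R^2 * dlon * (sin lat_n - sin lat_s) with
    R = 6371.0088 km, so area depends on latitude; class areas partition
    the total valid area exactly.
    """
    areas = cell_area_grid_km2(classified.grid)
    valid = classified.valid_mask
    rows = []
    for code, label in enumerate(classified.labels):
        a = float(areas[valid & (classified.classes == code)].sum())
        rows.append({"class": label, "area_km2": a, "area_1e4_km2": a / 1e4})
    table = pd.DataFrame(rows).set_index("class")
    total_valid = float(areas[valid].sum())
    suitable = float(table["area_km2"].iloc[1:].sum())
    return AreaTable(table=table, total_valid_km2=total_valid,
                     total_suitable_km2=suitable)
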