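"""Synthetic study worlds for presence-only niche modelling.

Generates spatially autocorrelated, cross-correlated climate layers on a
lon/lat grid, a known ("true") niche, presence-only occurrence samples
drawn from it, and future-scenario layers with a poleward-intensifying
warming trend and a fractional precipitation increase — the statistical
structure the downstream analysis assumes, without any data downloads.

Spatial autocorrelation comes from Gaussian smoothing of white noise;
cross-layer correlation from mixing independent smoothed fields with a
matrix square root of the target correlation.  Residual deviation from
the targets is measured by tests, not corrected.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from scipy.special import expit

from .occurrences import OccurrenceSet
from .rasters import ClimateStack, GridGeometry, _infer_layer_kind


@dataclass(frozen=True)
class LayerSpec:
    """One synthetic climate layer.

    ``mean`` applies at the grid's central latitude; ``lat_gradient``
    (units per degree latitude, default 0) adds a linear latitudinal
    trend, which is how the generator emulates the strong poleward
    cooling of real temperature layers.  ``kind`` defaults to a
    bioclim-style inference from the name.
    """

    name: str
    mean: float
    sd: float
    kind: str | None = None
    lat_gradient: float = 0.0

    def resolved_kind(self) -> str:
        return self.kind if self.kind is not None else _infer_layer_kind(self.name)


def _as_layer_spec(entry) -> LayerSpec:
    if isinstance(entry, LayerSpec):
        return entry
    return LayerSpec(*entry)


def _correlation_root(target: np.ndarray) -> np.ndarray:
    """Symmetric PSD square root of a correlation matrix.

    Eigen-based rather than Cholesky so that singular targets (e.g. a
    perfect correlation of 1.0) are accepted.
    """
    target = np.asarray(target, dtype=float)
    if target.ndim != 2 or target.shape[0] != target.shape[1]:
        raise ValueError("target_correlation must be square")
    if not np.allclose(target, target.T, atol=1e-10):
        raise ValueError("target_correlation must be symmetric")
    if not np.allclose(np.diag(target), 1.0, atol=1e-10):
        raise ValueError("target_correlation must have unit diagonal")
    w, v = np.linalg.eigh(target)
    if w.min() < -1e-8:
        raise ValueError(
            f"target_correlation is not positive semi-definite "
            f"(smallest eigenvalue {w.min():.3g})"
        )
    return v @ np.diag(np.sqrt(np.clip(w, 0.0, None))) @ v.T


def generate_climate_stack(
    seed: int,
    n_rows: int,
    n_cols: int,
    layer_spec: list,
    target_correlation: np.ndarray | None = None,
    smoothing_length: float = 3.0,
    sea_border_fraction: float = 0.0,
    west: float = 100.0,
    south: float = 18.0,
    cell_size: float = 0.25,
) -> ClimateStack:
    """Simulate a multi-layer climate stack with known structure.

    Each layer is a Gaussian random field (white noise smoothed over
    ``smoothing_length`` cells, standardised), cross-mixed to approach
    ``target_correlation`` over valid cells, then scaled to the layer's
    sd and shifted to its mean plus latitudinal trend.  A contiguous
    border band of ``sea_border_fraction`` of the grid's smaller
    dimension is masked as nodata ("sea").  Deterministic given ``seed``.
    """
    if n_rows < 8 or n_cols < 8:
        raise ValueError("grid must be at least 8 x 8 cells")
    specs = [_as_layer_spec(s) for s in layer_spec]
    k = len(specs)
    if k == 0:
        raise ValueError("layer_spec must not be empty")
    if target_correlation is None:
        target_correlation = np.eye(k)
    root = _correlation_root(target_correlation)
    if root.shape[0] != k:
        raise ValueError("target_correlation size does not match layer_spec")

    rng = np.random.default_rng(seed)
    white = rng.standard_normal((k, n_rows, n_cols))
    fields = np.empty_like(white)
    for i in range(k):
        f = gaussian_filter(white[i], sigma=smoothing_length, mode="reflect")
        std = f.std()
        fields[i] = (f - f.mean()) / std if std > 0 else 0.0
    # decorrelate the smoothed fields exactly over the whole grid before
    # mixing: smoothing shrinks the effective sample size, so raw smoothed
    # noise carries sizeable chance cross-correlations
    flat = fields.reshape(k, -1)
    cov = flat @ flat.T / flat.shape[1]
    w, v = np.linalg.eigh(cov)
    whiten = v @ np.diag(1.0 / np.sqrt(np.maximum(w, 1e-12))) @ v.T
    fields = (whiten @ flat).reshape(k, n_rows, n_cols)
    mixed = np.tensordot(root, fields, axes=(1, 0))

    grid = GridGeometry(west=west, south=south, cell_size=cell_size,
                        n_rows=n_rows, n_cols=n_cols)
    lat = grid.lat_centers()
    lat_mid = 0.5 * (grid.south + grid.north)
    layers: dict[str, np.ndarray] = {}
    kinds: dict[str, str] = {}
    for i, spec in enumerate(specs):
        trend = spec.mean + spec.lat_gradient * (lat - lat_mid)
        layers[spec.name] = trend[:, None] + spec.sd * mixed[i]
        kinds[spec.name] = spec.resolved_kind()

    mask = np.zeros((n_rows, n_cols), dtype=bool)
    band = int(round(sea_border_fraction * min(n_rows, n_cols)))
    if band > 0:
        mask[:band, :] = mask[-band:, :] = True
        mask[:, :band] = mask[:, -band:] = True
    return ClimateStack(grid=grid, layers=layers, nodata_mask=mask, layer_kinds=kinds)


def generate_future_stack(
    current: ClimateStack,
    warming_at_equator: float,
    warming_gradient_per_degree_lat: float,
    precip_fraction: float,
    seed: int = 0,
) -> ClimateStack:
    """Apply a climate-change scenario to a stack.

    Temperature-tagged layers are shifted by
    ``warming_at_equator + gradient * |latitude|`` (warming intensifies
    poleward); precipitation-tagged layers are multiplied by
    ``1 + precip_fraction``.  Grid and nodata mask are unchanged.  The
    transform is deterministic; ``seed`` is accepted for interface
    symmetry with the other generators.
    """
    if precip_fraction <= -1:
        raise ValueError("precip_fraction must be > -1 (precipitation cannot go negative)")
    del seed  # deterministic scenario construction
    lat = np.abs(current.grid.lat_centers())
    shift = (warming_at_equator + warming_gradient_per_degree_lat * lat)[:, None]
    layers = {}
    for name, arr in current.layers.items():
        kind = current.layer_kinds.get(name, "other")
        if kind == "temperature":
            layers[name] = arr + shift
        elif kind == "precipitation":
            layers[name] = arr * (1.0 + precip_fraction)
        else:
            layers[name] = arr.copy()
    return ClimateStack(
        grid=current.grid,
        layers=layers,
        nodata_mask=current.nodata_mask.copy(),
        layer_kinds=dict(current.layer_kinds),
        crs_note=current.crs_note,
    )


@dataclass
class NicheFunction:
    """Ground-truth suitability: inverse-logit of a quadratic in the
    named climate variables, bounded in [0, 1] for any finite input."""

    variables: list[str]
    linear: np.ndarray
    quadratic: np.ndarray
    intercept: float

    def __post_init__(self) -> None:
        self.linear = np.asarray(self.linear, dtype=float)
        self.quadratic = np.asarray(self.quadratic, dtype=float)
        if len(self.linear) != len(self.variables) or len(self.quadratic) != len(self.variables):
            raise ValueError("coefficient lengths must match variables")

    @classmethod
    def from_optima(cls, variables, optima, widths, weights, intercept=2.0):
        """Build a unimodal niche from per-variable optimum/width/weight.

        Each variable contributes ``-weight * ((x - optimum)/width)^2`` to
        the logit, expanded into linear + quadratic coefficients.
        """
        optima = np.asarray(optima, float)
        widths = np.asarray(widths, float)
        weights = np.asarray(weights, float)
        quad = -weights / widths**2
        lin = -2.0 * quad * optima
        const = intercept + np.sum(quad * optima**2)
        return cls(list(variables), lin, quad, float(const))

    def logit(self, env: np.ndarray) -> np.ndarray:
        env = np.asarray(env, dtype=float)
        return self.intercept + env @ self.linear + (env**2) @ self.quadratic

    def suitability(self, env: np.ndarray) -> np.ndarray:
        return expit(self.logit(env))

    def true_suitability(self, stack: ClimateStack) -> np.ndarray:
        """Suitability grid (NaN at nodata) on a stack's geometry."""
        out = np.full(stack.grid.shape, np.nan)
        rows, cols = stack.valid_indices()
        env = stack.env_at_cells(rows, cols, self.variables)
        out[rows, cols] = self.suitability(env)
        return out


def sample_occurrences(
    stack: ClimateStack,
    niche: NicheFunction,
    n: int,
    seed: int,
    species: str = "synthetic_species",
    source: str = "simulated",
    jitter: bool = True,
) -> OccurrenceSet:
    """Draw presence-only points with probability proportional to the
    true suitability of each valid cell; each point sits at its cell
    center with a small uniform jitter inside the cell."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rows, cols = stack.valid_indices()
    env = stack.env_at_cells(rows, cols, niche.variables)
    suit = niche.suitability(env)
    total = suit.sum()
    if total <= 0:
        raise ValueError("all cell suitabilities are zero; nothing to sample")
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(suit), size=n, p=suit / total)
    lon, lat = stack.grid.cell_center(rows[idx], cols[idx])
    if jitter:
        half = 0.5 * stack.grid.cell_size
        lon = lon + rng.uniform(-half, half, size=n) * 0.98
        lat = lat + rng.uniform(-half, half, size=n) * 0.98
    return OccurrenceSet(
        pd.DataFrame(
            {"species": species, "longitude": lon, "latitude": lat, "source": source}
        )
    )


# ---------------------------------------------------------------------------
# Packaged demo world: the fixed study conditions used throughout the tests,
# examples and the acceptance run.
# ---------------------------------------------------------------------------

#: Subtropical-China-like layer set (temperature in degC x 10, precipitation
#: in mm), with strong latitudinal temperature trends and two correlated
#: pairs above |r| = 0.8 (bio01-bio06 and bio12-bio14).
DEMO_LAYER_SPECS = [
    LayerSpec("bio01", mean=160.0, sd=20.0, lat_gradient=-10.0),
    LayerSpec("bio03", mean=45.0, sd=8.0, lat_gradient=-0.5),
    LayerSpec("bio06", mean=30.0, sd=25.0, lat_gradient=-12.0),
    LayerSpec("bio07", mean=250.0, sd=25.0, lat_gradient=6.0),
    LayerSpec("bio12", mean=1200.0, sd=250.0, lat_gradient=-30.0),
    LayerSpec("bio14", mean=40.0, sd=15.0, lat_gradient=-1.5),
]

#: Target cross-layer correlation for the demo world (order as above).
DEMO_CORRELATION = np.array(
    [
        # bio01 bio03 bio06 bio07 bio12 bio14
        [1.00, 0.10, 0.90, -0.40, 0.30, 0.20],
        [0.10, 1.00, 0.20, -0.10, 0.10, 0.05],
        [0.90, 0.20, 1.00, -0.50, 0.35, 0.25],
        [-0.40, -0.10, -0.50, 1.00, -0.20, -0.15],
        [0.30, 0.10, 0.35, -0.20, 1.00, 0.85],
        [0.20, 0.05, 0.25, -0.15, 0.85, 1.00],
    ]
)


def demo_niche() -> NicheFunction:
    """Temperature-limited niche: optimum in the minimum temperature of
    the coldest month (bio06) with a secondary annual-precipitation
    (bio12) response — the two drivers the source system is most
    sensitive to."""
    return NicheFunction.from_optima(
        variables=["bio06", "bio12"],
        optima=[50.0, 1400.0],
        widths=[25.0, 300.0],
        weights=[14.0, 3.0],
        intercept=0.5,
    )


def demo_world(
    seed: int = 0,
    n_occurrences: int = 200,
    n_rows: int = 96,
    n_cols: int = 80,
    sea_border_fraction: float = 0.05,
) -> tuple[ClimateStack, NicheFunction, OccurrenceSet]:
    """The packaged synthetic study world.

    A 96 x 80 grid of 0.25-degree cells spanning 100-120E, 18-42N with
    six bioclim-style layers, a known temperature/precipitation niche,
    and ``n_occurrences`` presence-only points (default 200).
    """
    stack = generate_climate_stack(
        seed=seed,
        n_rows=n_rows,
        n_cols=n_cols,
        layer_spec=DEMO_LAYER_SPECS,
        target_correlation=DEMO_CORRELATION,
        smoothing_length=4.0,
        sea_border_fraction=sea_border_fraction,
    )
    niche = demo_niche()
    occurrences = sample_occurrences(
        stack, niche, n=n_occurrences, seed=seed + 1, species="demo_species"
    )
    return stack, niche, occurrences
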