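"""Occurrence records: containers, coordinate conversion, cleaning,
spatial thinning to one point per grid cell, and bootstrap train/test
splits for replicate model fitting."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .rasters import ClimateStack

#: Decimal places used when comparing coordinates for exact duplication
#: (~0.1 m at the equator; avoids float-noise false uniqueness).
DUPLICATE_DECIMALS = 6


@dataclass
class OccurrenceSet:
    """Presence-only point records (WGS84 decimal degrees)."""

    records: pd.DataFrame  # columns: species, longitude, latitude, source

    COLUMNS = ("species", "longitude", "latitude", "source")

    def __post_init__(self) -> None:
        df = pd.DataFrame(self.records)
        for col in self.COLUMNS:
            if col not in df.columns:
                if col in ("species", "source"):
                    df[col] = "unknown"
                else:
                    raise ValueError(f"occurrence table missing column {col!r}")
        df = df.loc[:, list(self.COLUMNS)].reset_index(drop=True)
        lon = df["longitude"].to_numpy(dtype=float)
        lat = df["latitude"].to_numpy(dtype=float)
        if not (np.all(np.isfinite(lon)) and np.all(np.isfinite(lat))):
            raise ValueError("occurrence coordinates must be finite")
        if np.any(np.abs(lon) > 180) or np.any(np.abs(lat) > 90):
            raise ValueError("coordinates outside [-180,180] x [-90,90]")
        self.records = df

    def __len__(self) -> int:
        return len(self.records)

    @property
    def lon(self) -> np.ndarray:
        return self.records["longitude"].to_numpy(dtype=float)

    @property
    def lat(self) -> np.ndarray:
        return self.records["latitude"].to_numpy(dtype=float)

    def subset(self, idx) -> "OccurrenceSet":
        return OccurrenceSet(self.records.iloc[np.asarray(idx)].reset_index(drop=True))

    @classmethod
    def from_arrays(cls, lon, lat, species="unknown", source="unknown"):
        return cls(
            pd.DataFrame(
                {
                    "species": species,
                    "longitude": np.asarray(lon, dtype=float),
                    "latitude": np.asarray(lat, dtype=float),
                    "source": source,
                }
            )
        )


@dataclass
class ThinningReport:
    """Bookkeeping for the clean/thin pipeline stage."""

    n_input: int
    n_after_dedup: int
    n_after_sea_filter: int
    n_retained: int
    occupied_cell_indices: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        ok = self.n_retained <= self.n_after_sea_filter <= self.n_after_dedup <= self.n_input
        if not ok:
            raise ValueError("thinning counts must be non-increasing")

    def to_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_after_dedup": self.n_after_dedup,
            "n_after_sea_filter": self.n_after_sea_filter,
            "n_retained": self.n_retained,
            "occupied_cell_indices": [list(rc) for rc in self.occupied_cell_indices],
        }


@dataclass
class SplitSpec:
    """Replicate train/test partition settings (bootstrap convention)."""

    train_fraction: float = 0.75
    replicate_count: int = 10
    method: str = "bootstrap"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must lie in (0, 1)")
        if self.replicate_count < 1:
            raise ValueError("replicate_count must be >= 1")


def dms_to_decimal(degrees: int, minutes: int, seconds: float, hemisphere: str) -> float:
    """Convert degrees/minutes/seconds + hemisphere to signed decimal degrees.

    South and West are negative.
    """
    if not 0 <= minutes < 60:
        raise ValueError("minutes must lie in [0, 60)")
    if not 0 <= seconds < 60:
        raise ValueError("seconds must lie in [0, 60)")
    hemisphere = hemisphere.upper().strip()
    if hemisphere not in "NSEW" or len(hemisphere) != 1:
        raise ValueError("hemisphere must be one of N, S, E, W")
    sign = -1.0 if hemisphere in "SW" else 1.0
    return sign * (abs(degrees) + minutes / 60.0 + seconds / 3600.0)


def thin_to_grid(points: OccurrenceSet, stack: ClimateStack) -> tuple[OccurrenceSet, ThinningReport]:
    """Deduplicate, drop nodata/outside points, keep one point per cell.

    Order of operations: exact-coordinate duplicates (after rounding to
    ``DUPLICATE_DECIMALS``) are removed first; points mapping to nodata
    ("sea") cells or falling outside the grid are removed next; finally
    exactly one point is retained per occupied valid cell — the first in
    input order.
    """
    n_input = len(points)
    df = points.records.copy()
    key = list(
        zip(
            np.round(df["longitude"].to_numpy(float), DUPLICATE_DECIMALS),
            np.round(df["latitude"].to_numpy(float), DUPLICATE_DECIMALS),
        )
    )
    deduped = df.loc[~pd.Index(key).duplicated(keep="first")].reset_index(drop=True)
    n_dedup = len(deduped)

    row, col = stack.grid.cell_index(
        deduped["longitude"].to_numpy(float), deduped["latitude"].to_numpy(float)
    )
    inside = row >= 0
    on_land = np.zeros(len(deduped), dtype=bool)
    on_land[inside] = ~stack.nodata_mask[row[inside], col[inside]]
    landed = deduped.loc[on_land].reset_index(drop=True)
    row, col = row[on_land], col[on_land]
    n_sea = len(landed)

    cells = pd.Index(list(zip(row, col)))
    keep = ~cells.duplicated(keep="first")
    thinned = landed.loc[keep].reset_index(drop=True)
    occupied = [(int(r), int(c)) for r, c in zip(row[keep], col[keep])]

    if len(thinned) == 0:
        raise ValueError(
            "no occurrence points remain after cleaning and thinning; "
            "a model cannot be built from an empty presence set"
        )
    report = ThinningReport(
        n_input=n_input,
        n_after_dedup=n_dedup,
        n_after_sea_filter=n_sea,
        n_retained=len(thinned),
        occupied_cell_indices=occupied,
    )
    return OccurrenceSet(thinned), report


def make_splits(
    points: OccurrenceSet,
    spec: SplitSpec,
    max_retries: int = 100,
) -> list[tuple[OccurrenceSet, OccurrenceSet]]:
    """Bootstrap train/test partitions, one pair per replicate.

    Per replicate the training presences are a resample *with replacement*
    of size round(train_fraction * n); the test set is every point never
    drawn into that resample (the classic MaxEnt "bootstrap" replicate
    convention).  Replicates use independent seeded sub-streams, so the
    whole list is deterministic given ``spec.seed``.
    """
    n = len(points)
    if n < 4:
        raise ValueError("need at least 4 points to split")
    n_train = int(round(spec.train_fraction * n))
    n_train = min(max(n_train, 1), n)
    splits: list[tuple[OccurrenceSet, OccurrenceSet]] = []
    for r in range(spec.replicate_count):
        rng = np.random.default_rng([spec.seed & 0x7FFFFFFF, r])
        for _ in range(max_retries):
            train_idx = rng.integers(0, n, size=n_train)
            test_idx = np.setdiff1d(np.arange(n), np.unique(train_idx))
            if test_idx.size > 0:
                break
        else:
            raise ValueError(
                f"replicate {r}: could not draw a bootstrap resample with a "
                f"non-empty test set in {max_retries} attempts"
            )
        splits.append((points.subset(train_idx), points.subset(test_idx)))
    return splits
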