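"""Bioclimatic variable screening.

Mirrors the standard pre-modelling workflow: estimate each variable's
contribution with a quick default-settings model, compute the Pearson
correlation structure of the layers, and for every highly correlated
pair (|r| > 0.8 by default) retain the higher-contribution member,
dropping zero-contribution variables outright.

"Contribution" is permutation importance on training gain: the mean drop
in gain when one variable's values are shuffled across the evaluation
cells, negatives truncated at zero and the table renormalized to sum to
100.  (The historical MaxEnt "percent contribution" depends on the exact
optimization path of that implementation and is not reproducible outside
it; permutation importance measures the same thing and is deterministic
given a seed.)
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .maxent import fit_maxent, sample_background
from .occurrences import OccurrenceSet
from .rasters import ClimateStack


@dataclass
class ContributionTable:
    """Per-variable contribution percentages (sum to 100)."""

    variables: list[str]
    contributions: np.ndarray
    method: str = "permutation importance on training gain"

    def __post_init__(self) -> None:
        self.contributions = np.asarray(self.contributions, dtype=float)
        if len(self.contributions) != len(self.variables):
            raise ValueError("length mismatch")
        if np.any(self.contributions < 0):
            raise ValueError("contributions must be non-negative")
        if abs(self.contributions.sum() - 100.0) > 0.01:
            raise ValueError("contributions must sum to 100")

    def __getitem__(self, variable: str) -> float:
        return float(self.contributions[self.variables.index(variable)])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"variable": self.variables, "contribution_pct": self.contributions}
        )


@dataclass
class CorrelationMatrix:
    """Pearson r over valid cells; NaN marks undefined (zero-variance)."""

    variables: list[str]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        k = len(self.variables)
        if self.matrix.shape != (k, k):
            raise ValueError("matrix shape mismatch")

    def r(self, a: str, b: str) -> float:
        return float(self.matrix[self.variables.index(a), self.variables.index(b)])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=self.variables, columns=self.variables)


@dataclass
class VariableSelection:
    retained: list[str]
    exclusions: list[tuple[str, str]] = field(default_factory=list)  # (variable, reason)

    def exclusion_log(self) -> pd.DataFrame:
        return pd.DataFrame(self.exclusions, columns=["variable", "reason"])


def pretrain_contributions(
    presences: OccurrenceSet,
    stack: ClimateStack,
    seed: int = 0,
    variables: list[str] | None = None,
    fc: str = "lqh",
    rm: float = 1.0,
    n_permutations: int = 5,
    n_background: int = 10000,
    n_hinges: int = 10,
) -> ContributionTable:
    """Contribution of each variable from one default-settings fit.

    Fits a single model on all variables, then for each variable permutes
    its values over the background cells (presence cells included),
    re-expands the features, and records the drop in training gain; the
    per-variable mean drops, truncated at zero, are normalized to 100.
    The default feature set used for the pre-training fit is recorded in
    the table's ``method`` tag.
    """
    if len(presences) < 10:
        raise ValueError("need at least 10 presences for pre-training")
    variables = stack.variable_names if variables is None else list(variables)
    if len(variables) < 2:
        raise ValueError("need at least 2 variables")
    prow, pcol = stack.grid.cell_index(presences.lon, presences.lat)
    if np.any(prow < 0):
        raise ValueError("presence point outside the stack grid")
    brow, bcol = sample_background(
        stack, n=n_background, seed=seed, include_cells=list(zip(prow, pcol))
    )
    bg = stack.env_at_cells(brow, bcol, variables)
    pres = stack.env_at_cells(prow, pcol, variables)
    model = fit_maxent(pres, bg, variables, rm=rm, fc=fc, seed=seed, n_hinges=n_hinges)

    # map presences to their background rows so permutation moves both views
    cell_to_row = {(int(r), int(c)): i for i, (r, c) in enumerate(zip(brow, bcol))}
    pres_rows = np.array([cell_to_row[(int(r), int(c))] for r, c in zip(prow, pcol)])

    def gain_of(bg_env: np.ndarray) -> float:
        F_bg = model.expansion.transform(bg_env)
        F_pres = F_bg[pres_rows]
        scores = F_bg @ model.lambdas
        from scipy.special import logsumexp

        return float(
            F_pres.mean(axis=0) @ model.lambdas - logsumexp(scores) + np.log(len(bg_env))
        )

    full_gain = gain_of(bg)
    rng = np.random.default_rng(seed)
    drops = np.zeros(len(variables))
    for j in range(len(variables)):
        for _ in range(n_permutations):
            perm = bg.copy()
            perm[:, j] = perm[rng.permutation(len(perm)), j]
            drops[j] += (full_gain - gain_of(perm)) / n_permutations
    drops = np.clip(drops, 0.0, None)
    total = drops.sum()
    if total <= 0:
        contributions = np.full(len(variables), 100.0 / len(variables))
        method = f"permutation importance (degenerate: no gain drop); fc={model.fc}, rm={rm}"
    else:
        contributions = 100.0 * drops / total
        method = f"permutation importance on training gain; fc={model.fc}, rm={rm}"
    return ContributionTable(variables=list(variables), contributions=contributions,
                             method=method)


def correlation_matrix(
    stack: ClimateStack,
    sample_cells: int = 10000,
    seed: int = 0,
    variables: list[str] | None = None,
) -> CorrelationMatrix:
    """Pearson correlation of layers over a seeded sample of valid cells.

    Uses all valid cells when there are fewer than ``sample_cells``.
    Zero-variance layers get NaN off-diagonal entries (undefined r) and
    1 on the diagonal.
    """
    variables = stack.variable_names if variables is None else list(variables)
    env = stack.env_matrix(variables)
    if env.shape[0] < 2:
        raise ValueError("need at least 2 valid cells")
    if env.shape[0] > sample_cells:
        rng = np.random.default_rng(seed)
        env = env[rng.choice(env.shape[0], size=sample_cells, replace=False)]
    sd = env.std(axis=0)
    k = len(variables)
    mat = np.full((k, k), np.nan)
    ok = sd > 0
    if ok.any():
        sub = np.corrcoef(env[:, ok], rowvar=False)
        mat[np.ix_(ok, ok)] = np.atleast_2d(sub)
    np.fill_diagonal(mat, 1.0)
    return CorrelationMatrix(variables=variables, matrix=mat)


def select_variables(
    contributions: ContributionTable,
    corr: CorrelationMatrix,
    r_threshold: float = 0.8,
) -> VariableSelection:
    """Drop zero-contribution variables, then resolve correlated pairs.

    Pairs with |r| > threshold are scanned in descending |r| order; in
    each still-violating pair the lower-contribution member is dropped
    (ties broken by keeping the alphabetically first name).  The retained
    set therefore contains no pair above the threshold, and every drop is
    logged with its reason.
    """
    if set(contributions.variables) != set(corr.variables):
        raise ValueError("contribution table and correlation matrix disagree on variables")
    retained = sorted(contributions.variables)
    exclusions: list[tuple[str, str]] = []
    for v in list(retained):
        if contributions[v] == 0:
            retained.remove(v)
            exclusions.append((v, "zero contribution"))

    pairs = []
    for i, a in enumerate(corr.variables):
        for b in corr.variables[i + 1:]:
            r = corr.r(a, b)
            if np.isfinite(r) and abs(r) > r_threshold:
                pairs.append((abs(r), tuple(sorted((a, b)))))
    pairs.sort(key=lambda p: (-p[0], p[1]))
    for r_abs, (a, b) in pairs:
        if a in retained and b in retained:
            ca, cb = contributions[a], contributions[b]
            if ca > cb or (ca == cb and a < b):
                drop, keep = b, a
            else:
                drop, keep = a, b
            retained.remove(drop)
            exclusions.append(
                (drop, f"|r|={r_abs:.3f} with {keep} exceeds {r_threshold:g}; "
                       f"lower contribution ({contributions[drop]:.2f}% vs "
                       f"{contributions[keep]:.2f}%)")
            )
    return VariableSelection(retained=retained, exclusions=exclusions)
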