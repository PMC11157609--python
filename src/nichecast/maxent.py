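"""Regularized maximum-entropy niche model.

The model is the Gibbs distribution over background cells

    q_lambda(x) = exp(lambda . f(x)) / Z,   Z = sum_background exp(lambda . f(x)),

fitted by maximizing the presence log-likelihood penalized by per-feature
L1 weights beta_j (the "regularization"):

    max_lambda  mean_presence(lambda . f) - log Z - sum_j beta_j |lambda_j|.

The penalized objective is concave; it is solved by FISTA-style proximal
gradient ascent with backtracking, which yields exact zeros in lambda and
satisfies the stationarity (KKT) contract

    |mean_presence(f_j) - E_q(f_j)| <= beta_j,  with equality when lambda_j != 0

— the regularized form of the entropy-maximization constraint that model
feature expectations match their empirical presence means.

Features are the classic transformations of the scaled (min-max over the
training background, into [0,1]) environmental variables: linear (L),
quadratic (Q), pairwise product (P), threshold step (T) and two-sided
hinge ramps (H).  Per-feature penalties are
beta_j = RM * beta_class(n_presences) * sd_j(presence features) / sqrt(n_presences),
with the per-class base table shipped below and interpolated in sample
size.  The logistic output maps the raw density through
p = e^H q / (1 + e^H q) with H the entropy of the fitted distribution,
so that "typical" presence-like cells score near 0.5 (prevalence 0.5
convention).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

from .rasters import ClimateStack, GridGeometry, SuitabilityRaster

FEATURE_CLASS_ORDER = "lqpth"

#: Per-class base regularization vs number of presence samples; linearly
#: interpolated, clamped at the ends.  Larger classes carry larger base
#: penalties; hinge is constant.
BETA_TABLES: dict[str, tuple[tuple[float, ...], tuple[float, ...]]] = {
    "l": ((0, 10, 30, 100), (1.0, 1.0, 0.2, 0.05)),
    "q": ((0, 10, 17, 30, 100), (1.3, 0.8, 0.5, 0.25, 0.05)),
    "p": ((0, 10, 17, 30, 100), (2.6, 1.6, 0.9, 0.55, 0.26)),
    "t": ((0, 100), (2.0, 1.0)),
    "h": ((0,), (0.5,)),
}


def beta_class(feature_class: str, n_presences: int) -> float:
    """Interpolated per-class base regularization for a sample size."""
    xs, ys = BETA_TABLES[feature_class]
    return float(np.interp(n_presences, xs, ys))


def normalize_fc(fc: str) -> str:
    """Canonical feature-combination string (subset of 'lqpth', ordered)."""
    letters = set(fc.lower())
    unknown = letters - set(FEATURE_CLASS_ORDER)
    if unknown:
        raise ValueError(f"unknown feature class letter(s): {sorted(unknown)}")
    if not letters:
        raise ValueError("feature combination must not be empty")
    return "".join(c for c in FEATURE_CLASS_ORDER if c in letters)


@dataclass(frozen=True)
class FeatureDef:
    """One expanded feature: class letter, source variable(s), optional
    knot (threshold/hinge) and hinge direction ('forward'/'reverse')."""

    kind: str
    variables: tuple[str, ...]
    knot: float | None = None
    direction: str | None = None

    def label(self) -> str:
        base = f"{self.kind}:{'*'.join(self.variables)}"
        if self.knot is not None:
            d = {"forward": ">", "reverse": "<"}.get(self.direction, "@")
            base += f"{d}{self.knot:.6g}"
        return base


class FeatureExpansion:
    """Deterministic feature expansion with training min/max scaling.

    Scaling maps each variable into [0,1] via its training-background
    range; threshold and hinge knots are evenly spaced within that range.
    Feature order is (class in L,Q,P,T,H order, variable name, knot).
    """

    def __init__(
        self,
        variables: list[str],
        mins: np.ndarray,
        maxs: np.ndarray,
        fc: str,
        n_thresholds: int = 50,
        n_hinges: int = 50,
    ):
        self.variables = list(variables)
        self.mins = np.asarray(mins, dtype=float)
        self.maxs = np.asarray(maxs, dtype=float)
        self.fc = normalize_fc(fc)
        self.n_thresholds = int(n_thresholds)
        self.n_hinges = int(n_hinges)
        if "h" in self.fc and self.n_hinges < 2:
            raise ValueError("hinge expansion needs at least 2 knots")
        span = self.maxs - self.mins
        self._span = np.where(span > 0, span, 1.0)
        self.features: list[FeatureDef] = self._build()

    def _build(self) -> list[FeatureDef]:
        feats: list[FeatureDef] = []
        names = sorted(range(len(self.variables)), key=lambda i: self.variables[i])
        if "l" in self.fc:
            feats += [FeatureDef("l", (self.variables[i],)) for i in names]
        if "q" in self.fc:
            feats += [FeatureDef("q", (self.variables[i],)) for i in names]
        if "p" in self.fc:
            for a in range(len(names)):
                for b in range(a + 1, len(names)):
                    i, j = names[a], names[b]
                    feats.append(FeatureDef("p", (self.variables[i], self.variables[j])))
        if "t" in self.fc:
            for i in names:
                # knots strictly inside the scaled (0,1) range
                for k in range(1, self.n_thresholds + 1):
                    feats.append(
                        FeatureDef("t", (self.variables[i],), knot=k / (self.n_thresholds + 1))
                    )
        if "h" in self.fc:
            for i in names:
                for k in range(self.n_hinges):
                    feats.append(
                        FeatureDef("h", (self.variables[i],),
                                   knot=k / self.n_hinges, direction="forward")
                    )
                for k in range(1, self.n_hinges + 1):
                    feats.append(
                        FeatureDef("h", (self.variables[i],),
                                   knot=k / self.n_hinges, direction="reverse")
                    )
        return feats

    @property
    def n_features(self) -> int:
        return len(self.features)

    def feature_classes(self) -> np.ndarray:
        return np.array([f.kind for f in self.features])

    def scale(self, X: np.ndarray, clamp: bool = False) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if clamp:
            X = np.clip(X, self.mins, self.maxs)
        return (X - self.mins) / self._span

    def transform(self, X: np.ndarray, clamp: bool = False) -> np.ndarray:
        """Expand an (n, n_vars) matrix of raw values into (n, n_features).

        Column order of ``X`` must match ``self.variables``.
        """
        S = self.scale(X, clamp=clamp)
        col = {v: S[:, i] for i, v in enumerate(self.variables)}
        out = np.empty((S.shape[0], self.n_features))
        for jf, f in enumerate(self.features):
            if f.kind == "l":
                out[:, jf] = col[f.variables[0]]
            elif f.kind == "q":
                out[:, jf] = col[f.variables[0]] ** 2
            elif f.kind == "p":
                out[:, jf] = col[f.variables[0]] * col[f.variables[1]]
            elif f.kind == "t":
                out[:, jf] = (col[f.variables[0]] > f.knot).astype(float)
            else:  # hinge, rescaled to [0,1] on the training range
                s = col[f.variables[0]]
                if f.direction == "forward":
                    denom = 1.0 - f.knot
                    out[:, jf] = np.clip((s - f.knot) / denom, 0.0, None)
                else:
                    out[:, jf] = np.clip((f.knot - s) / f.knot, 0.0, None)
        return out

    @classmethod
    def from_background(cls, background: np.ndarray, variables, fc, **kw):
        background = np.asarray(background, dtype=float)
        return cls(
            variables=list(variables),
            mins=background.min(axis=0),
            maxs=background.max(axis=0),
            fc=fc,
            **kw,
        )

    def to_dict(self) -> dict:
        return {
            "variables": self.variables,
            "mins": self.mins.tolist(),
            "maxs": self.maxs.tolist(),
            "fc": self.fc,
            "n_thresholds": self.n_thresholds,
            "n_hinges": self.n_hinges,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FeatureExpansion":
        return cls(d["variables"], np.array(d["mins"]), np.array(d["maxs"]),
                   d["fc"], d["n_thresholds"], d["n_hinges"])


@dataclass
class MaxEntModel:
    """A fitted regularized maximum-entropy model."""

    expansion: FeatureExpansion
    lambdas: np.ndarray
    betas: np.ndarray
    log_z: float            # log normalizer over the training background
    entropy: float          # entropy of q over the training background
    converged: bool
    n_iterations: int
    rm: float
    n_presences: int
    n_background: int
    seed: int | None = None
    kkt_gap: np.ndarray = field(default=None)  # |presence mean - E_q| per feature
    gain: float = 0.0                # unpenalized training gain
    regularized_gain: float = 0.0

    @property
    def fc(self) -> str:
        return self.expansion.fc

    @property
    def k(self) -> int:
        """Number of nonzero coefficients (model complexity for AICc)."""
        return int(np.count_nonzero(self.lambdas))

    def raw_at(self, X: np.ndarray, clamp: bool = True) -> np.ndarray:
        """Raw Gibbs density at raw-variable rows (normalized over the
        training background, so values sum to 1 over that set)."""
        F = self.expansion.transform(X, clamp=clamp)
        return np.exp(F @ self.lambdas - self.log_z)

    def logistic_at(self, X: np.ndarray, clamp: bool = True) -> np.ndarray:
        return logistic_output(self, self.raw_at(X, clamp=clamp))

    def kkt_violation(self) -> float:
        """Max over features of the stationarity-gap excess.

        For every feature |presence mean - E_q| must not exceed beta_j;
        for active features the gap must equal beta_j.  Returns the
        largest violation of either condition (0 means the contract
        holds exactly).
        """
        gap = self.kkt_gap
        excess = gap - self.betas
        active = self.lambdas != 0
        slack = np.zeros_like(gap)
        slack[active] = np.abs(gap[active] - self.betas[active])
        return float(max(excess.max(initial=0.0), slack.max(initial=0.0)))

    def to_json(self) -> str:
        return json.dumps(
            {
                "expansion": self.expansion.to_dict(),
                "lambdas": self.lambdas.tolist(),
                "betas": self.betas.tolist(),
                "log_z": self.log_z,
                "entropy": self.entropy,
                "converged": self.converged,
                "n_iterations": self.n_iterations,
                "rm": self.rm,
                "n_presences": self.n_presences,
                "n_background": self.n_background,
                "seed": self.seed,
                "kkt_gap": self.kkt_gap.tolist(),
                "gain": self.gain,
                "regularized_gain": self.regularized_gain,
                "features": [f.label() for f in self.expansion.features],
            },
            indent=1,
        )

    @classmethod
    def from_json(cls, text: str) -> "MaxEntModel":
        d = json.loads(text)
        return cls(
            expansion=FeatureExpansion.from_dict(d["expansion"]),
            lambdas=np.array(d["lambdas"]),
            betas=np.array(d["betas"]),
            log_z=d["log_z"],
            entropy=d["entropy"],
            converged=d["converged"],
            n_iterations=d["n_iterations"],
            rm=d["rm"],
            n_presences=d["n_presences"],
            n_background=d["n_background"],
            seed=d.get("seed"),
            kkt_gap=np.array(d["kkt_gap"]),
            gain=d.get("gain", 0.0),
            regularized_gain=d.get("regularized_gain", 0.0),
        )


def compute_betas(F_presence: np.ndarray, classes: np.ndarray, rm: float) -> np.ndarray:
    """Per-feature L1 weights beta_j.

    beta_j = RM * beta_class(n) * sd_j(presence features) / sqrt(n), with
    a small floor on sd_j so constant-on-presence features keep a
    nonzero penalty.
    """
    n = F_presence.shape[0]
    sd = F_presence.std(axis=0, ddof=0)
    sd = np.maximum(sd, 1e-6)
    base = np.array([beta_class(c, n) for c in classes])
    return rm * base * sd / np.sqrt(n)


def _penalized_objective(lam, p_bar, F_bg, betas):
    log_z = logsumexp(F_bg @ lam)
    return float(p_bar @ lam - log_z - betas @ np.abs(lam)), log_z


def _kkt_excess(lam, p_bar, F_bg, betas):
    q = np.exp(F_bg @ lam - logsumexp(F_bg @ lam))
    gap = np.abs(p_bar - F_bg.T @ q)
    excess = gap - betas
    active = lam != 0
    slack = np.zeros_like(gap)
    slack[active] = np.abs(gap[active] - betas[active])
    return max(excess.max(initial=0.0), slack.max(initial=0.0))


def fit_features(
    F_presence: np.ndarray,
    F_background: np.ndarray,
    betas: np.ndarray,
    tol: float = 1e-8,
    kkt_tol: float = 1e-5,
    max_iterations: int = 5000,
) -> tuple[np.ndarray, bool, int]:
    """Maximize the L1-penalized presence likelihood over coefficients.

    FISTA (accelerated proximal gradient with soft-thresholding) with
    backtracking on the smooth part and adaptive restart.  Declares
    convergence when the relative change of the penalized objective
    drops below ``tol`` *and* the stationarity gap is within ``kkt_tol``.
    Returns (lambda, converged, n_iterations).
    """
    n_feat = F_background.shape[1]
    p_bar = F_presence.mean(axis=0)
    lam = np.zeros(n_feat)
    y = lam.copy()
    t = 1.0
    L = 1.0  # local Lipschitz estimate, grown by backtracking
    obj, _ = _penalized_objective(lam, p_bar, F_background, betas)
    converged = False
    it = 0
    for it in range(1, max_iterations + 1):
        scores = F_background @ y
        log_z = logsumexp(scores)
        q = np.exp(scores - log_z)
        grad = p_bar - F_background.T @ q          # ascent direction
        smooth_y = float(p_bar @ y - log_z)
        # backtracking: find step 1/L with sufficient increase of the smooth part
        for _ in range(60):
            cand = y + grad / L
            cand = np.sign(cand) * np.maximum(np.abs(cand) - betas / L, 0.0)
            diff = cand - y
            smooth_cand = float(p_bar @ cand - logsumexp(F_background @ cand))
            if smooth_cand >= smooth_y + grad @ diff - 0.5 * L * (diff @ diff):
                break
            L *= 2.0
        new_obj, _ = _penalized_objective(cand, p_bar, F_background, betas)
        # adaptive restart if the accelerated step lost ground
        if new_obj < obj:
            y = lam.copy()
            t = 1.0
            scores = F_background @ y
            log_z = logsumexp(scores)
            q = np.exp(scores - log_z)
            grad = p_bar - F_background.T @ q
            smooth_y = float(p_bar @ y - log_z)
            for _ in range(60):
                cand = y + grad / L
                cand = np.sign(cand) * np.maximum(np.abs(cand) - betas / L, 0.0)
                diff = cand - y
                smooth_cand = float(p_bar @ cand - logsumexp(F_background @ cand))
                if smooth_cand >= smooth_y + grad @ diff - 0.5 * L * (diff @ diff):
                    break
                L *= 2.0
            new_obj, _ = _penalized_objective(cand, p_bar, F_background, betas)
        t_new = 0.5 * (1.0 + np.sqrt(1.0 + 4.0 * t * t))
        y = cand + ((t - 1.0) / t_new) * (cand - lam)
        lam = cand
        t = t_new
        if abs(new_obj - obj) <= tol * (1.0 + abs(new_obj)):
            if _kkt_excess(lam, p_bar, F_background, betas) <= kkt_tol:
                obj = new_obj
                converged = True
                break
        obj = new_obj
        L = max(L / 1.5, 1e-3)  # allow the step to grow again
    return lam, converged, it


def fit_maxent(
    presences: np.ndarray,
    background: np.ndarray,
    variables: list[str],
    rm: float = 1.0,
    fc: str = "lq",
    seed: int | None = None,
    n_thresholds: int = 50,
    n_hinges: int = 50,
    tol: float = 1e-8,
    max_iterations: int = 5000,
) -> MaxEntModel:
    """Fit the regularized maximum-entropy model.

    ``presences`` and ``background`` are (n, n_vars) matrices of raw
    environmental values, columns ordered as ``variables``.  Feature
    scaling (and threshold/hinge knots) come from the background range.
    """
    presences = np.atleast_2d(np.asarray(presences, dtype=float))
    background = np.atleast_2d(np.asarray(background, dtype=float))
    if presences.shape[0] < 2:
        raise ValueError("need at least 2 presence samples")
    if background.shape[0] < 10:
        raise ValueError("need at least 10 background cells")
    if rm <= 0:
        raise ValueError("regularization multiplier must be positive")
    expansion = FeatureExpansion.from_background(
        background, variables, fc, n_thresholds=n_thresholds, n_hinges=n_hinges
    )
    F_bg = expansion.transform(background)
    F_pres = expansion.transform(presences)
    betas = compute_betas(F_pres, expansion.feature_classes(), rm)
    lam, converged, n_iter = fit_features(F_pres, F_bg, betas, tol=tol,
                                          max_iterations=max_iterations)
    scores = F_bg @ lam
    log_z = float(logsumexp(scores))
    log_q = scores - log_z
    q = np.exp(log_q)
    entropy = float(-(q @ log_q))
    p_bar = F_pres.mean(axis=0)
    gain = float(p_bar @ lam - log_z + np.log(F_bg.shape[0]))
    return MaxEntModel(
        expansion=expansion,
        lambdas=lam,
        betas=betas,
        log_z=log_z,
        entropy=entropy,
        converged=converged,
        n_iterations=n_iter,
        rm=float(rm),
        n_presences=presences.shape[0],
        n_background=background.shape[0],
        seed=seed,
        kkt_gap=np.abs(p_bar - F_bg.T @ q),
        gain=gain,
        regularized_gain=gain - float(betas @ np.abs(lam)),
    )


def logistic_output(model: MaxEntModel, raw: np.ndarray | float) -> np.ndarray:
    """Logistic transform of the raw density: p = e^H r / (1 + e^H r).

    H is the entropy of the fitted distribution over the training
    background; at default prevalence 0.5 a cell with "typical" presence
    density scores 0.5.
    """
    if not model.converged:
        raise ValueError("logistic output requires a converged model")
    scaled = np.exp(model.entropy) * np.asarray(raw, dtype=float)
    return scaled / (1.0 + scaled)


def sample_background(
    stack: ClimateStack,
    n: int = 10000,
    seed: int = 0,
    include_cells: list[tuple[int, int]] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Seeded uniform sample of valid cells for model normalization.

    Returns (rows, cols).  ``include_cells`` (e.g. presence cells) are
    always part of the returned set; if the stack has fewer than ``n``
    valid cells, all of them are used.
    """
    rows, cols = stack.valid_indices()
    n_valid = len(rows)
    rng = np.random.default_rng(seed)
    if n_valid <= n:
        picked = np.arange(n_valid)
    else:
        picked = rng.choice(n_valid, size=n, replace=False)
    chosen = {(int(r), int(c)) for r, c in zip(rows[picked], cols[picked])}
    if include_cells:
        chosen.update((int(r), int(c)) for r, c in include_cells)
    cells = sorted(chosen)
    out = np.array(cells, dtype=int)
    return out[:, 0], out[:, 1]


def project(model: MaxEntModel, stack: ClimateStack, clamp: bool = True) -> SuitabilityRaster:
    """Project a fitted model onto a climate stack (logistic output).

    Variables are optionally clamped to the training range before the
    feature expansion, the standard guard against extrapolation when
    transferring to future scenarios; nodata propagates.
    """
    missing = [v for v in model.expansion.variables if v not in stack.layers]
    if missing:
        raise KeyError(f"stack is missing model variable(s): {missing}")
    rows, cols = stack.valid_indices()
    X = stack.env_at_cells(rows, cols, model.expansion.variables)
    p = model.logistic_at(X, clamp=clamp)
    values = np.full(stack.grid.shape, np.nan)
    values[rows, cols] = p
    return SuitabilityRaster(
        grid=stack.grid,
        values=values,
        nodata_mask=stack.nodata_mask.copy(),
        kind="logistic",
    )


def project_raw(model: MaxEntModel, stack: ClimateStack, clamp: bool = True) -> SuitabilityRaster:
    """Raw-density projection (normalized over the training background)."""
    rows, cols = stack.valid_indices()
    X = stack.env_at_cells(rows, cols, model.expansion.variables)
    r = model.raw_at(X, clamp=clamp)
    values = np.full(stack.grid.shape, np.nan)
    values[rows, cols] = r
    return SuitabilityRaster(
        grid=stack.grid, values=values, nodata_mask=stack.nodata_mask.copy(), kind="raw"
    )
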