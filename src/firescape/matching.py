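"""Mahalanobis-distance matching and treatment-effect estimation.

Treatment T is protection status (1 = protected), outcome Y is fire
presence.  Each treated cell is matched, with replacement, to the
control cell(s) minimising the Mahalanobis distance under the pooled
all-units covariance; a per-covariate caliper in standard-deviation
units excludes treated units with no acceptable nearest match.  The ATT
is the matched difference in outcome probability; its standard error is
an Abadie-Imbens style matching variance that accounts for control
reuse.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from firescape.errors import MatchingError
from firescape.grid import GridStack, Raster

#: The nine matching covariates (land cover, categorical, is excluded).
DEFAULT_COVARIATES = (
    "tree_cover",
    "travel_time",
    "elevation",
    "slope",
    "aspect",
    "dist_forest_edge",
    "dist_road",
    "temperature",
    "population_density",
)


@dataclass
class UnitTable:
    """Per-cell unit records: treatment, outcome and covariate vector."""

    frame: pd.DataFrame
    covariates: tuple[str, ...]

    def __post_init__(self) -> None:
        need = {"unit_id", "row", "col", "T", "Y", *self.covariates}
        missing = need - set(self.frame.columns)
        if missing:
            raise ValueError(f"unit table missing columns: {sorted(missing)}")
        if not set(np.unique(self.frame["T"])) <= {0, 1}:
            raise ValueError("T must be binary")
        if not set(np.unique(self.frame["Y"])) <= {0, 1}:
            raise ValueError("Y must be binary")
        if (self.frame["T"] == 1).sum() == 0 or (self.frame["T"] == 0).sum() == 0:
            raise MatchingError("need at least one treated and one control unit")

    @property
    def X(self) -> np.ndarray:
        return self.frame[list(self.covariates)].to_numpy(dtype=float)

    @property
    def T(self) -> np.ndarray:
        return self.frame["T"].to_numpy(dtype=int)

    @property
    def Y(self) -> np.ndarray:
        return self.frame["Y"].to_numpy(dtype=int)

    def __len__(self) -> int:
        return len(self.frame)

    def to_csv(self, path) -> None:
        cols = ["unit_id", "row", "col", "T", "Y", *self.covariates]
        self.frame[cols].to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, covariates: Sequence[str] | None = None) -> "UnitTable":
        df = pd.read_csv(path)
        if covariates is None:
            covariates = [
                c for c in df.columns if c not in ("unit_id", "row", "col", "T", "Y")
            ]
        return cls(df, tuple(covariates))


def build_unit_table(
    stack: GridStack,
    forest_only: bool = False,
    forest_threshold: float = 25.0,
    covariates: Sequence[str] = DEFAULT_COVARIATES,
) -> UnitTable:
    """One unit per complete-case cell of the stack.

    ``forest_only`` restricts to cells with tree cover at or above
    ``forest_threshold`` percent (default 25, the floor of the forest
    range used throughout).
    """
    if stack.protection is None or stack.fire is None:
        raise MatchingError("stack must carry protection and fire rasters")
    covariates = tuple(covariates)
    missing = [c for c in covariates if c not in stack.covariates]
    if missing:
        raise MatchingError(f"stack lacks covariates: {missing}")
    valid = stack.valid_mask()
    if forest_only:
        tc = stack.covariates["tree_cover"].values
        valid &= tc >= forest_threshold
    rows, cols = np.nonzero(valid)
    data = {
        "unit_id": np.arange(rows.size),
        "row": rows,
        "col": cols,
        "T": stack.protection.values[rows, cols].astype(int),
        "Y": stack.fire.values[rows, cols].astype(int),
    }
    for c in covariates:
        data[c] = stack.covariates[c].values[rows, cols].astype(float)
    return UnitTable(pd.DataFrame(data), covariates)


@dataclass
class PropensityModel:
    """Fitted logistic model for Pr(T = 1 | X)."""

    coefficients: np.ndarray  # intercept first
    scores: np.ndarray
    converged: bool
    separation_flagged: bool = False

    def __post_init__(self) -> None:
        if not (np.all(self.scores > 0) and np.all(self.scores < 1)):
            raise ValueError("propensity scores must lie strictly in (0, 1)")


def fit_propensity(units: UnitTable, max_iter: int = 100, tol: float = 1e-8) -> PropensityModel:
    """Newton-fitted logistic regression of T on the covariates.

    Covariates are standardised internally for numerical stability and
    the coefficients mapped back to the raw scale.  Perfect separation is
    flagged and scores clipped to [1e-6, 1 - 1e-6] with a warning.  The
    model is diagnostic: matching runs on Mahalanobis distance.
    """
    X = units.X
    T = units.T.astype(float)
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    Z = (X - mu) / sd
    n, d = Z.shape
    A = np.column_stack([np.ones(n), Z])
    beta = np.zeros(d + 1)
    converged = False
    separation = False
    for _ in range(max_iter):
        eta = A @ beta
        p = 1.0 / (1.0 + np.exp(-eta))
        g = A.T @ (T - p)
        if np.linalg.norm(g) < tol:
            converged = True
            break
        w = p * (1 - p)
        if w.min() < 1e-12:
            separation = True
            w = np.maximum(w, 1e-12)
        H = (A * w[:, None]).T @ A
        try:
            step = np.linalg.solve(H, g)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(H, g, rcond=None)[0]
        # damp huge steps to keep the iteration stable under separation
        nrm = np.linalg.norm(step)
        if nrm > 50:
            step *= 50 / nrm
            separation = True
        beta = beta + step
    scores = 1.0 / (1.0 + np.exp(-(A @ beta)))
    if separation or scores.min() <= 0 or scores.max() >= 1:
        warnings.warn("possible separation in propensity fit; scores clipped")
        separation = True
    scores = np.clip(scores, 1e-6, 1 - 1e-6)
    # back-transform to raw-covariate scale
    raw = np.empty_like(beta)
    raw[1:] = beta[1:] / sd
    raw[0] = beta[0] - np.sum(beta[1:] * mu / sd)
    return PropensityModel(raw, scores, converged, separation)


@dataclass
class MatchedSample:
    """Treated-to-control assignments from Mahalanobis matching."""

    treated_index: np.ndarray  # positional indices into the unit table
    control_sets: list[np.ndarray]  # per matched treated unit
    weights: list[np.ndarray]  # per matched treated unit, sum to 1
    distances: np.ndarray  # best distance per matched treated unit
    excluded_index: np.ndarray  # treated units dropped by the caliper
    covariance: np.ndarray
    caliper_sd: float

    @property
    def n_treated_matched(self) -> int:
        return len(self.treated_index)

    @property
    def n_excluded_caliper(self) -> int:
        return len(self.excluded_index)

    def control_use_weights(self, n_units: int) -> np.ndarray:
        """Total match weight K_j accumulated by each unit (controls only)."""
        k = np.zeros(n_units)
        for cset, w in zip(self.control_sets, self.weights):
            np.add.at(k, cset, w)
        return k


def _pooled_covariance(X: np.ndarray, ridge_tol: float = 1e-8) -> np.ndarray:
    S = np.cov(X, rowvar=False)
    S = np.atleast_2d(S)
    d = S.shape[0]
    try:
        np.linalg.cholesky(S)
    except np.linalg.LinAlgError:
        S = S + np.eye(d) * (ridge_tol * np.trace(S) / d)
    return S


def mahalanobis_match(
    units: UnitTable,
    caliper_sd: float = 1.0,
    with_replacement: bool = True,
    tie_tol: float = 1e-9,
) -> MatchedSample:
    """Nearest-control matching under the Mahalanobis metric.

    For each treated unit the control(s) at minimal Mahalanobis distance
    (pooled all-units covariance; ridge fallback if singular) are
    retained; exact ties share equal weight.  The caliper is
    per-covariate: a nearest match differing from its treated unit by
    more than ``caliper_sd`` sample standard deviations in any covariate
    disqualifies that control, and a treated unit whose entire nearest
    set is disqualified is excluded.  Controls are reusable
    (``with_replacement=False`` is not implemented; the analysis design
    matches with replacement).
    """
    if not with_replacement:
        raise NotImplementedError("only matching with replacement is supported")
    if caliper_sd <= 0:
        raise ValueError("caliper_sd must be positive")
    X = units.X
    T = units.T
    t_idx = np.nonzero(T == 1)[0]
    c_idx = np.nonzero(T == 0)[0]
    if c_idx.size == 0:
        raise MatchingError("no control units")
    S = _pooled_covariance(X)
    VI = np.linalg.inv(S)
    sds = X.std(axis=0, ddof=1)
    sds[sds == 0] = np.inf  # constant covariate can never violate the caliper
    D = cdist(X[t_idx], X[c_idx], metric="mahalanobis", VI=VI)
    treated_kept: list[int] = []
    control_sets: list[np.ndarray] = []
    weights: list[np.ndarray] = []
    dists: list[float] = []
    excluded: list[int] = []
    for k, ti in enumerate(t_idx):
        drow = D[k]
        dmin = drow.min()
        ties = np.nonzero(drow <= dmin + tie_tol * max(1.0, dmin))[0]
        diffs = np.abs(X[c_idx[ties]] - X[ti])  # (n_ties, d)
        ok = (diffs <= caliper_sd * sds).all(axis=1)
        if not ok.any():
            excluded.append(ti)
            continue
        chosen = c_idx[ties[ok]]
        treated_kept.append(ti)
        control_sets.append(np.sort(chosen))
        weights.append(np.full(chosen.size, 1.0 / chosen.size))
        dists.append(float(dmin))
    if not treated_kept:
        raise MatchingError("every treated unit was excluded by the caliper")
    return MatchedSample(
        treated_index=np.array(treated_kept),
        control_sets=control_sets,
        weights=weights,
        distances=np.array(dists),
        excluded_index=np.array(excluded, dtype=int),
        covariance=S,
        caliper_sd=caliper_sd,
    )


@dataclass
class EffectEstimate:
    """ATT on the outcome-probability scale with matching standard error."""

    att: float
    se: float
    t_value: float
    n_treated_matched: int
    n_excluded_caliper: int

    def as_dict(self) -> dict:
        return {
            "att": self.att,
            "se": self.se,
            "t_value": self.t_value,
            "n_treated_matched": self.n_treated_matched,
            "n_excluded_caliper": self.n_excluded_caliper,
        }


def att_estimate(units: UnitTable, matches: MatchedSample) -> EffectEstimate:
    """Matched ATT and Abadie-Imbens style standard error.

    att = mean over matched treated units of (Y_t - sum_c w_tc Y_c).

    The variance adds, to the across-pairs residual term, a correction
    sum_j (K_j^2 - sum_t w_tj^2) * sigma2_j for reuse of control j, with
    sigma2_j estimated from control j's nearest control neighbour in the
    same Mahalanobis metric.
    """
    n_m = matches.n_treated_matched
    if n_m < 2:
        raise MatchingError("need at least 2 matched treated units")
    Y = units.Y.astype(float)
    X = units.X
    y0_hat = np.array(
        [float(w @ Y[cset]) for cset, w in zip(matches.control_sets, matches.weights)]
    )
    diffs = Y[matches.treated_index] - y0_hat
    att = float(diffs.mean())

    # control-reuse correction
    n = len(units)
    K = np.zeros(n)
    K2 = np.zeros(n)
    for cset, w in zip(matches.control_sets, matches.weights):
        np.add.at(K, cset, w)
        np.add.at(K2, cset, w**2)
    used = np.nonzero(K > 0)[0]
    c_idx = np.nonzero(units.T == 0)[0]
    sigma2 = np.zeros(n)
    if used.size and c_idx.size >= 2:
        VI = np.linalg.inv(matches.covariance)
        Dcc = cdist(X[used], X[c_idx], metric="mahalanobis", VI=VI)
        # ignore self-distance
        for r, j in enumerate(used):
            self_pos = np.nonzero(c_idx == j)[0]
            row = Dcc[r].copy()
            if self_pos.size:
                row[self_pos[0]] = np.inf
            nb = c_idx[int(np.argmin(row))]
            sigma2[j] = 0.5 * (Y[j] - Y[nb]) ** 2
    resid_term = float(((diffs - att) ** 2).sum())
    reuse_term = float(((K**2 - K2) * sigma2).sum())
    var = (resid_term + reuse_term) / (n_m**2)
    se = float(np.sqrt(max(var, 0.0)))
    t_value = att / se if se > 0 else np.inf * np.sign(att) if att != 0 else 0.0
    return EffectEstimate(att, se, float(t_value), n_m, matches.n_excluded_caliper)


def _weighted_mean_var(y: np.ndarray, w: np.ndarray) -> tuple[float, float]:
    wsum = w.sum()
    m = float((w * y).sum() / wsum)
    v = float((w * (y - m) ** 2).sum() / wsum)
    return m, v


def balance_report(units: UnitTable, matches: MatchedSample) -> pd.DataFrame:
    """Covariate balance before and after matching.

    Per covariate: treated mean, control mean and variance ratio
    var(treated)/var(control) before matching (all units, unweighted),
    and the same after matching (matched treated units vs. controls
    weighted by match weight).  Population-style (ddof = 0) variances on
    both sides so an exact-twin match yields ratios of exactly 1.
    """
    T = units.T
    X = units.X
    t_all = T == 1
    c_all = T == 0
    K = matches.control_use_weights(len(units))
    t_matched = matches.treated_index
    rows = []
    for j, cov in enumerate(units.covariates):
        x = X[:, j]
        mean_t = float(x[t_all].mean())
        var_t = float(x[t_all].var())
        mean_c_before = float(x[c_all].mean())
        var_c_before = float(x[c_all].var())
        vr_before = var_t / var_c_before if var_c_before > 0 else np.inf
        # after matching: treated side restricted to matched treated units
        var_t_after = float(x[t_matched].var())
        used = K > 0
        mean_c_after, var_c_after = _weighted_mean_var(x[used], K[used])
        if var_c_after > 0:
            vr_after = var_t_after / var_c_after
        else:
            vr_after = np.inf
            warnings.warn(f"zero matched-control variance for {cov}")
        if var_c_before <= 0:
            warnings.warn(f"zero control variance for {cov}")
        rows.append(
            {
                "covariate": cov,
                "mean_treatment": mean_t,
                "mean_control_before": mean_c_before,
                "variance_ratio_before": vr_before,
                "mean_control_after": mean_c_after,
                "variance_ratio_after": vr_after,
            }
        )
    return pd.DataFrame(rows)


def standardized_mean_differences(
    units: UnitTable, matches: MatchedSample | None = None
) -> pd.Series:
    """|SMD| per covariate; unmatched when ``matches`` is None.

    SMD = (treated mean - control mean) / SD(treated before matching).
    """
    X = units.X
    T = units.T
    t_all = T == 1
    sd_t = X[t_all].std(axis=0)
    sd_t[sd_t == 0] = 1.0
    if matches is None:
        diff = X[t_all].mean(axis=0) - X[T == 0].mean(axis=0)
    else:
        K = matches.control_use_weights(len(units))
        used = K > 0
        mc = (K[used, None] * X[used]).sum(axis=0) / K.sum()
        diff = X[matches.treated_index].mean(axis=0) - mc
    return pd.Series(np.abs(diff / sd_t), index=list(units.covariates))


def correlation_screen(
    units: UnitTable, threshold: float = 0.95
) -> tuple[pd.DataFrame, list[tuple[str, str, float]], list[str]]:
    """Pearson correlation matrix over covariates with a collinearity flag.

    Returns (matrix, flagged pairs with |r| >= threshold, names of
    constant covariates that were excluded and reported).
    """
    if len(units) < 3:
        raise MatchingError("need at least 3 units for a correlation screen")
    X = units.X
    names = list(units.covariates)
    sds = X.std(axis=0)
    constant = [n for n, s in zip(names, sds) if s == 0]
    if constant:
        warnings.warn(f"constant covariates excluded from screen: {constant}")
    keep = [i for i, s in enumerate(sds) if s > 0]
    kept_names = [names[i] for i in keep]
    R = np.corrcoef(X[:, keep], rowvar=False)
    R = np.atleast_2d(R)
    mat = pd.DataFrame(R, index=kept_names, columns=kept_names)
    flagged = []
    for a in range(len(keep)):
        for b in range(a + 1, len(keep)):
            r = float(R[a, b])
            if abs(r) >= threshold:
                flagged.append((kept_names[a], kept_names[b], r))
    return mat, flagged, constant
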