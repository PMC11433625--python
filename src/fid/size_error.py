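"""Calibration of fragment-size measurement error on electrophoresis gels.

Two nested models relate the measured size of a DNA molecule to its true
size x:

    measured = beta0 + beta1 * x + eps

``lm``      ordinary least squares: eps iid N(0, sigma^2).
``varpow``  generalized least squares: Var(eps_i) = sigma^2 * |mu_i|^(2*delta)
            (variance grows as a power of the mean) and, within a gel lane,
            corr(eps_i, eps_j) = phi^|rank_i - rank_j| (AR(1) along the
            migration order).

The fitted model is inverted into a *permissive range*: the closed interval
of true sizes whose prediction band (at the configured level) contains the
measured value.  Fragments below ``min_detectable`` (default 100 nt) are
invisible on a gel and are excluded before any comparison.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy import optimize, stats

__all__ = [
    "CalibrationPoint", "CalibrationModel", "CalibrationError",
    "filter_detectable", "fit_lm", "fit_varpow", "permissive_range",
    "read_calibration_tsv",
]

DEFAULT_MIN_DETECTABLE = 100


class CalibrationError(RuntimeError):
    """Raised on a degenerate design or a failed likelihood optimization."""

    def __init__(self, message: str, last_iterate=None):
        super().__init__(message)
        self.last_iterate = last_iterate


@dataclass(frozen=True)
class CalibrationPoint:
    """One (true size, gel estimate) pair, ordered within its lane."""

    expected: float
    measured: float
    lane_id: str = ""
    rank_in_lane: int | None = None

    def __post_init__(self) -> None:
        if self.expected <= 0 or self.measured <= 0:
            raise ValueError("sizes must be positive")


@dataclass(frozen=True)
class CalibrationModel:
    """A fitted size-error model (see module docstring for the equations)."""

    kind: str            # 'lm' or 'varpow'
    beta0: float
    beta1: float
    sigma: float
    delta: float = 0.0
    phi: float = 0.0
    level: float = 0.95
    min_detectable: float = DEFAULT_MIN_DETECTABLE
    loglik: float = float("nan")
    converged: bool = True
    n_points: int = 0

    def __post_init__(self) -> None:
        if not -1.0 < self.phi < 1.0:
            raise ValueError("|phi| must be < 1")
        if self.sigma < 0:
            raise ValueError("sigma must be non-negative")
        if not 0.0 < self.level < 1.0:
            raise ValueError("level must lie in (0, 1)")

    # -- prediction ---------------------------------------------------------
    def predict(self, true_size: float) -> float:
        return self.beta0 + self.beta1 * true_size

    def band_halfwidth(self, true_size: float) -> float:
        """Half width of the level-prediction band at a given true size."""
        z = stats.norm.ppf(0.5 + self.level / 2.0)
        mu = self.predict(true_size)
        return z * self.sigma * abs(mu) ** self.delta

    # -- persistence --------------------------------------------------------
    def to_json(self, path=None) -> str:
        payload = json.dumps({k: getattr(self, k) for k in (
            "kind", "beta0", "beta1", "sigma", "delta", "phi", "level",
            "min_detectable", "loglik", "converged", "n_points")}, indent=1)
        if path is not None:
            Path(path).write_text(payload)
        return payload

    @classmethod
    def from_json(cls, source) -> "CalibrationModel":
        p = Path(str(source))
        text = p.read_text() if p.exists() else str(source)
        return cls(**json.loads(text))


def filter_detectable(lengths, min_detectable: float = DEFAULT_MIN_DETECTABLE):
    """Drop fragment lengths below the gel detectability floor (boundary kept)."""
    return [x for x in lengths if x >= min_detectable]


def _design(points: list[CalibrationPoint]):
    x = np.array([p.expected for p in points], dtype=float)
    y = np.array([p.measured for p in points], dtype=float)
    return np.column_stack([np.ones_like(x), x]), y


def fit_lm(points: list[CalibrationPoint], level: float = 0.95,
           min_detectable: float = DEFAULT_MIN_DETECTABLE) -> CalibrationModel:
    """Ordinary least-squares calibration (iid homoscedastic errors)."""
    if len(points) < 3:
        raise CalibrationError("need at least 3 calibration points")
    if len({p.expected for p in points}) < 2:
        raise CalibrationError("need at least 2 distinct expected sizes")
    X, y = _design(points)
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    n = len(points)
    rss = float(resid @ resid)
    sigma = math.sqrt(rss / (n - 2)) if n > 2 else 0.0
    s2_mle = rss / n
    loglik = (-0.5 * n * (math.log(2 * math.pi) + 1 + math.log(s2_mle))
              if s2_mle > 0 else float("inf"))
    return CalibrationModel(kind="lm", beta0=float(beta[0]), beta1=float(beta[1]),
                            sigma=sigma, level=level,
                            min_detectable=min_detectable, loglik=loglik,
                            n_points=n)


def _lanes(points: list[CalibrationPoint]):
    """Group points by lane; ranks default to migration order (descending size)."""
    lanes: dict[str, list[CalibrationPoint]] = {}
    for p in points:
        lanes.setdefault(p.lane_id, []).append(p)
    out = []
    for members in lanes.values():
        if any(p.rank_in_lane is None for p in members):
            members = sorted(members, key=lambda p: -p.expected)
            members = [replace(p, rank_in_lane=i) for i, p in enumerate(members)]
        ranks = [p.rank_in_lane for p in members]
        if len(set(ranks)) != len(ranks):
            raise CalibrationError("duplicate (lane, rank) in calibration data")
        out.append(sorted(members, key=lambda p: p.rank_in_lane))
    return out


def _gls_loglik(theta, lanes, max_inner: int = 20):
    """Profile log-likelihood at (delta, atanh(phi)); beta and sigma profiled out."""
    delta = float(np.clip(theta[0], -5.0, 5.0))
    phi = math.tanh(theta[1])
    Xs, ys, ranks = [], [], []
    for lane in lanes:
        X, y = _design(lane)
        Xs.append(X)
        ys.append(y)
        ranks.append(np.array([p.rank_in_lane for p in lane], dtype=float))
    Xall = np.vstack(Xs)
    yall = np.concatenate(ys)
    n = len(yall)

    beta, *_ = np.linalg.lstsq(Xall, yall, rcond=None)
    Vinvs = None
    logdet = 0.0
    for _ in range(max_inner):
        logdet = 0.0
        Vinvs = []
        for X, y, r in zip(Xs, ys, ranks):
            mu = np.maximum(np.abs(X @ beta), 1e-8)
            w = mu ** delta
            C = phi ** np.abs(r[:, None] - r[None, :])
            V = C * np.outer(w, w)
            sign, ld = np.linalg.slogdet(V)
            if sign <= 0:
                return -np.inf, beta, 0.0
            logdet += ld
            Vinvs.append(np.linalg.inv(V))
        A = sum(X.T @ Vi @ X for X, Vi in zip(Xs, Vinvs))
        b = sum(X.T @ Vi @ y for X, Vi, y in zip(Xs, Vinvs, ys))
        new_beta = np.linalg.solve(A, b)
        if np.max(np.abs(new_beta - beta)) < 1e-10:
            beta = new_beta
            break
        beta = new_beta

    quad = 0.0
    for X, y, Vi in zip(Xs, ys, Vinvs):
        r = y - X @ beta
        quad += float(r @ Vi @ r)
    s2 = quad / n
    if s2 <= 0:
        return np.inf, beta, 0.0
    ll = -0.5 * (n * math.log(2 * math.pi) + n * math.log(s2) + logdet + n)
    return ll, beta, s2


def fit_varpow(points: list[CalibrationPoint], level: float = 0.95,
               min_detectable: float = DEFAULT_MIN_DETECTABLE,
               maxiter: int = 400) -> CalibrationModel:
    """Maximum-likelihood calibration with power variance and within-lane AR(1).

    beta is profiled out by iterated generalized least squares given
    (delta, phi); sigma^2 is profiled analytically; the remaining
    two-parameter likelihood is maximized numerically over
    (delta, atanh(phi)) starting from the homoscedastic, uncorrelated
    solution, so the fitted log-likelihood can never fall below the lm one.
    """
    lanes = _lanes(points)
    if len(lanes) < 2 or any(len(l) < 3 for l in lanes):
        raise CalibrationError("need >= 2 lanes with >= 3 points each")
    n = sum(len(l) for l in lanes)

    def objective(theta):
        ll, _, _ = _gls_loglik(theta, lanes)
        return -ll if np.isfinite(ll) else 1e12

    res = optimize.minimize(objective, x0=[0.0, 0.0], method="Nelder-Mead",
                            options={"xatol": 1e-6, "fatol": 1e-8,
                                     "maxiter": maxiter})
    ll, beta, s2 = _gls_loglik(res.x, lanes)
    if not np.isfinite(ll):
        raise CalibrationError("varpow likelihood optimization failed",
                               last_iterate=res.x)
    delta = float(np.clip(res.x[0], -5.0, 5.0))
    phi = math.tanh(float(res.x[1]))
    sigma = math.sqrt(s2 * n / max(n - 2, 1))  # small-sample correction as in lm
    return CalibrationModel(kind="varpow", beta0=float(beta[0]),
                            beta1=float(beta[1]), sigma=sigma, delta=delta,
                            phi=phi, level=level, min_detectable=min_detectable,
                            loglik=float(ll), converged=bool(res.success),
                            n_points=n)


def permissive_range(model: CalibrationModel, measured: float) -> tuple[float, float]:
    """Closed interval of true sizes compatible with a measured size.

    A true size x is compatible when ``measured`` lies within the model's
    level-prediction band around beta0 + beta1*x.  The band is inverted by
    solving mu -/+ z*sigma*mu^delta = measured for the mean response mu and
    mapping back through x = (mu - beta0)/beta1.  Collapses to a point for
    sigma = 0.
    """
    if model.beta1 <= 0:
        raise CalibrationError("calibration slope must be positive to invert")
    if measured <= 0:
        raise ValueError("measured size must be positive")
    z = stats.norm.ppf(0.5 + model.level / 2.0)

    def to_x(mu: float) -> float:
        return (mu - model.beta0) / model.beta1

    if model.sigma == 0:
        x = to_x(measured)
        return (x, x)

    zs = z * model.sigma
    if model.delta == 0:
        return (to_x(measured - zs), to_x(measured + zs))

    def halfwidth(mu: float) -> float:
        return zs * abs(mu) ** model.delta

    # Upper endpoint: largest mu with mu - halfwidth(mu) = measured.
    hi = measured + halfwidth(measured)
    while hi - halfwidth(hi) < measured:
        hi *= 2.0
        if hi > 1e12:
            raise CalibrationError("prediction band does not close upward; "
                                   "sigma*delta too large for inversion")
    mu_hi = optimize.brentq(lambda m: m - halfwidth(m) - measured, measured, hi)

    # Lower endpoint: mu with mu + halfwidth(mu) = measured (clipped near 0).
    eps = 1e-9
    if eps + halfwidth(eps) >= measured:
        mu_lo = eps
    else:
        mu_lo = optimize.brentq(lambda m: m + halfwidth(m) - measured,
                                eps, measured)
    return (to_x(mu_lo), to_x(mu_hi))


def read_calibration_tsv(path) -> list[CalibrationPoint]:
    """Read calibration points from a TSV with columns expected, measured, lane_id[, rank]."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    required = {"expected", "measured"}
    if not required <= set(df.columns):
        raise ValueError(f"{path}: need columns {sorted(required)}")
    points = []
    for _, row in df.iterrows():
        points.append(CalibrationPoint(
            expected=float(row["expected"]), measured=float(row["measured"]),
            lane_id=str(row["lane_id"]) if "lane_id" in df.columns else "",
            rank_in_lane=int(row["rank"]) if "rank" in df.columns else None))
    return points
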