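"""Detection-function fitting for line-transect distance sampling.

The probability of detecting a dung pile at perpendicular distance ``x``
from the transect line is g(x), with g(0) = 1. Observed distances on
[0, w] then follow the density f(x) = g(x) / mu, where
mu = integral_0^w g(x) dx is the *effective strip width* (ESW): the
half-width of a perfectly-surveyed strip yielding the same expected count.

Three families are supported, fitted by maximum likelihood and compared by
AIC:

* uniform        g(x) = 1                      (0 free parameters)
* half-normal    g(x) = exp(-x^2 / 2 sigma^2)  (1 parameter)
* hazard-rate    g(x) = 1 - exp(-(x/sigma)^-b) (2 parameters, b > 1)
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np
from scipy import integrate, optimize, stats

__all__ = [
    "FAMILIES",
    "DetectionModel",
    "DetectionFunction",
    "InsufficientDataError",
    "DetectionFitError",
    "fit_detection",
    "effective_strip_width",
    "select_model",
]

FAMILIES = ("uniform", "half-normal", "hazard-rate")
_N_PARAMS = {"uniform": 0, "half-normal": 1, "hazard-rate": 2}


class InsufficientDataError(ValueError):
    """Too few distances to fit a detection function."""


class DetectionFitError(RuntimeError):
    """Optimizer failed to converge; message carries diagnostics."""


@dataclass(frozen=True)
class DetectionModel:
    """A fitted detection function.

    Attributes
    ----------
    family : str
        One of :data:`FAMILIES`.
    params : tuple of float
        Family parameters in metres: ``()`` for uniform, ``(sigma,)`` for
        half-normal, ``(sigma, b)`` for hazard-rate.
    w : float
        Truncation distance (m).
    loglik, aic : float
        Maximized log-likelihood and ``-2 loglik + 2 * n_params``.
    esw : float
        Effective strip width mu (m), ``0 < esw <= w``.
    cv_esw : float
        Delta-method CV of the ESW (fraction; 0 for uniform).
    n : int
        Number of distances used.
    """

    family: str
    params: tuple[float, ...]
    w: float
    loglik: float
    aic: float
    esw: float
    cv_esw: float
    n: int

    def g(self, x):
        """Detection probability at distance x (m)."""
        return _g(self.family, self.params, np.asarray(x, dtype=float))

    def to_json(self) -> str:
        d = asdict(self)
        d["params"] = list(d["params"])
        return json.dumps(d, indent=2)

    @classmethod
    def from_json(cls, s: str) -> "DetectionModel":
        d = json.loads(s)
        d["params"] = tuple(d["params"])
        return cls(**d)


def _g(family: str, params, x):
    if family == "uniform":
        return np.ones_like(x)
    if family == "half-normal":
        (sigma,) = params
        return np.exp(-(x**2) / (2.0 * sigma**2))
    if family == "hazard-rate":
        sigma, b = params
        with np.errstate(divide="ignore", over="ignore"):
            r = np.where(x > 0, (np.asarray(x, float) / sigma) ** (-b), np.inf)
        return -np.expm1(-r)
    raise ValueError(f"unknown family {family!r}")


def _esw(family: str, params, w: float) -> float:
    """mu = integral_0^w g by adaptive quadrature (closed form for uniform)."""
    if family == "uniform":
        return w
    val, err = integrate.quad(lambda x: float(_g(family, params, np.array(x))), 0.0, w,
                              limit=200)
    if not np.isfinite(val):
        raise ArithmeticError(f"non-finite ESW integral for {family} params={params}")
    return val


def _negloglik(family: str, logparams, x: np.ndarray, w: float) -> float:
    params = tuple(np.exp(logparams))
    if family == "hazard-rate":
        params = (params[0], 1.0 + params[1])  # enforce b > 1
    mu = _esw(family, params, w)
    if not np.isfinite(mu) or mu <= 0:
        return np.inf
    g = _g(family, params, x)
    if np.any(g <= 0):
        return np.inf
    return -(np.sum(np.log(g)) - x.size * np.log(mu))


class DetectionFunction:
    """Maximum-likelihood detection-function estimator.

    Parameters
    ----------
    family : str
        ``"uniform"``, ``"half-normal"`` or ``"hazard-rate"``.
    w : float, optional
        Truncation distance (m); default: max observed distance.
    min_n : int
        Minimum number of in-range distances required (default 10).
    n_restarts : int
        Multistart points for the (possibly multimodal) likelihood.

    Attributes (after ``fit``)
    --------------------------
    params_, loglik_, aic_, esw_, cv_esw_ : see :class:`DetectionModel`.
    model_ : DetectionModel
        The frozen fitted-model record.
    """

    def __init__(self, family: str = "half-normal", w: float | None = None,
                 min_n: int = 10, n_restarts: int = 5):
        if family not in FAMILIES:
            raise ValueError(f"family must be one of {FAMILIES}, got {family!r}")
        self.family = family
        self.w = w
        self.min_n = min_n
        self.n_restarts = n_restarts

    def get_params(self, deep: bool = True) -> dict:
        return {"family": self.family, "w": self.w, "min_n": self.min_n,
                "n_restarts": self.n_restarts}

    def set_params(self, **kw) -> "DetectionFunction":
        for k, v in kw.items():
            if k not in self.get_params():
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, distances, y=None) -> "DetectionFunction":
        x = np.sort(np.asarray(distances, dtype=float))
        if x.ndim != 1:
            raise ValueError("distances must be 1-d")
        if np.any(~np.isfinite(x)) or np.any(x < 0):
            raise ValueError("distances must be finite and >= 0")
        w = float(self.w) if self.w is not None else float(x.max()) if x.size else 0.0
        if not w > 0:
            raise ValueError("truncation w must be > 0")
        x = x[x <= w]
        if x.size < self.min_n:
            raise InsufficientDataError(
                f"need >= {self.min_n} distances within [0, {w}], got {x.size}"
            )

        if self.family == "uniform":
            params: tuple[float, ...] = ()
            loglik = -x.size * np.log(w)
        else:
            params, loglik = self._optimize(x, w)
        esw = _esw(self.family, params, w)
        cv = self._cv_esw(params, x, w, esw)
        aic = -2.0 * loglik + 2.0 * _N_PARAMS[self.family]
        self.params_ = params
        self.loglik_ = float(loglik)
        self.aic_ = float(aic)
        self.esw_ = float(esw)
        self.cv_esw_ = float(cv)
        self.w_ = w
        self.model_ = DetectionModel(
            family=self.family, params=tuple(float(p) for p in params), w=w,
            loglik=float(loglik), aic=float(aic), esw=float(esw), cv_esw=float(cv),
            n=int(x.size),
        )
        return self

    # -- internals --------------------------------------------------------
    def _optimize(self, x: np.ndarray, w: float):
        sigma0 = max(float(np.std(x)), 1e-3 * w)
        if self.family == "half-normal":
            starts = [[np.log(sigma0 * f)] for f in (0.25, 0.5, 1.0, 2.0, 4.0)]
        else:  # hazard-rate: optimize (log sigma, log(b-1))
            starts = [[np.log(sigma0 * f), np.log(bm1)]
                      for f, bm1 in ((0.5, 1.0), (1.0, 1.0), (2.0, 1.0), (1.0, 4.0), (0.5, 0.25))]
        starts = starts[: max(1, self.n_restarts)]
        best = None
        with np.errstate(all="ignore"):
            for s0 in starts:
                res = optimize.minimize(
                    lambda lp: _negloglik(self.family, lp, x, w), np.asarray(s0),
                    method="L-BFGS-B",
                    bounds=[(np.log(1e-4 * w), np.log(50 * w))] + (
                        [(np.log(1e-3), np.log(50.0))] if self.family == "hazard-rate" else []),
                )
                if best is None or res.fun < best.fun:
                    best = res
        if best is None or not np.isfinite(best.fun):
            raise DetectionFitError(f"{self.family} fit failed: {best}")
        params = tuple(np.exp(best.x))
        if self.family == "hazard-rate":
            params = (params[0], 1.0 + params[1])
        return params, -float(best.fun)

    def _cv_esw(self, params, x: np.ndarray, w: float, esw: float) -> float:
        """Delta-method CV of mu from the observed information of the MLE."""
        if self.family == "uniform":
            return 0.0
        theta = np.asarray(params, dtype=float)
        eps = 1e-4 * np.maximum(np.abs(theta), 1.0)

        def nll(t):
            if self.family == "hazard-rate" and t[1] <= 1.0:
                return np.inf
            mu = _esw(self.family, tuple(t), w)
            g = _g(self.family, tuple(t), x)
            if mu <= 0 or np.any(g <= 0):
                return np.inf
            return -(np.sum(np.log(g)) - x.size * np.log(mu))

        p = theta.size
        H = np.zeros((p, p))
        f0 = nll(theta)
        for i in range(p):
            for j in range(i, p):
                ei = np.zeros(p); ei[i] = eps[i]
                ej = np.zeros(p); ej[j] = eps[j]
                if i == j:
                    H[i, i] = (nll(theta + ei) - 2 * f0 + nll(theta - ei)) / eps[i] ** 2
                else:
                    H[i, j] = H[j, i] = (
                        nll(theta + ei + ej) - nll(theta + ei - ej)
                        - nll(theta - ei + ej) + nll(theta - ei - ej)
                    ) / (4 * eps[i] * eps[j])
        grad = np.zeros(p)
        for i in range(p):
            ei = np.zeros(p); ei[i] = eps[i]
            grad[i] = (_esw(self.family, tuple(theta + ei), w)
                       - _esw(self.family, tuple(theta - ei), w)) / (2 * eps[i])
        try:
            cov = np.linalg.inv(H)
            var = float(grad @ cov @ grad)
        except np.linalg.LinAlgError:
            return np.nan
        if var < 0:
            return np.nan
        return np.sqrt(var) / esw


# ---------------------------------------------------------------------------
# functional wrappers
# ---------------------------------------------------------------------------

def fit_detection(distances, family: str, w: float | None = None,
                  min_n: int = 10) -> DetectionModel:
    """Fit one detection-function family by maximum likelihood."""
    est = DetectionFunction(family=family, w=w, min_n=min_n)
    return est.fit(distances).model_


def effective_strip_width(model: DetectionModel) -> tuple[float, float]:
    """Return (esw_m, cv_esw) of a fitted model."""
    return model.esw, model.cv_esw


def select_model(candidates: list[DetectionModel]) -> DetectionModel:
    """Pick the minimum-AIC candidate.

    Ties (within 1e-9) go to the model with fewer parameters, then to the
    family order uniform < half-normal < hazard-rate.
    """
    if not candidates:
        raise ValueError("select_model needs at least one candidate")
    order = {f: i for i, f in enumerate(FAMILIES)}
    return min(candidates, key=lambda m: (round(m.aic / 1e-9) * 1e-9, len(m.params), order[m.family]))


def half_normal_p_detect(sigma: float, w: float) -> float:
    """Mean detection probability mu/w for a half-normal g on [0, w]."""
    mu = sigma * np.sqrt(np.pi / 2.0) * (2 * stats.norm.cdf(w / sigma) - 1.0)
    return mu / w
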