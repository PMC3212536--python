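"""Ordinary kriging of per-location dung densities.

The empirical semivariogram gamma(h) = (1/2N_h) sum (v_i - v_j)^2 is binned
over lag distance, a spherical or exponential model is fitted by weighted
least squares (weights = pair counts), and the ordinary-kriging system —
semivariance matrix plus a Lagrange row enforcing weights that sum to one —
is solved at every prediction node. With a zero nugget the predictor is an
exact interpolator at the data points.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize

__all__ = [
    "VariogramModel",
    "KrigedSurface",
    "empirical_semivariogram",
    "fit_variogram",
    "OrdinaryKriging",
    "krige",
]


@dataclass(frozen=True)
class VariogramModel:
    """Isotropic semivariogram model gamma(h).

    spherical:   nugget + psill * (1.5 h/r - 0.5 (h/r)^3) for h < r, sill beyond
    exponential: nugget + psill * (1 - exp(-3 h / r)); r is the practical range
    """

    family: str  # "spherical" | "exponential"
    nugget: float
    partial_sill: float
    range_km: float
    degenerate: bool = False  # range pinned at a bound during fitting

    def __post_init__(self):
        if self.family not in ("spherical", "exponential"):
            raise ValueError(f"unknown variogram family {self.family!r}")
        if self.nugget < 0 or self.partial_sill < 0 or not self.range_km > 0:
            raise ValueError("need nugget >= 0, partial_sill >= 0, range > 0")

    @property
    def sill(self) -> float:
        return self.nugget + self.partial_sill

    def __call__(self, h):
        h = np.asarray(h, dtype=float)
        r = self.range_km
        if self.family == "spherical":
            hr = np.minimum(h / r, 1.0)
            struct = 1.5 * hr - 0.5 * hr**3
        else:
            struct = 1.0 - np.exp(-3.0 * h / r)
        gamma = self.nugget + self.partial_sill * struct
        return np.where(h > 0, gamma, 0.0)


@dataclass
class KrigedSurface:
    """Predictions and kriging variance on a grid of planar points (km)."""

    grid: np.ndarray  # (m, 2)
    predictions: np.ndarray  # (m,)
    kriging_variance: np.ndarray  # (m,)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "x_km": self.grid[:, 0],
                "y_km": self.grid[:, 1],
                "prediction": self.predictions,
                "variance": self.kriging_variance,
            }
        )


def empirical_semivariogram(points, values, n_bins: int = 12,
                            max_lag: float | None = None) -> pd.DataFrame:
    """Binned empirical semivariogram.

    Returns a DataFrame with columns ``lag`` (bin-mean distance), ``gamma``
    and ``pairs``; empty bins are dropped with a warning. Default max_lag is
    half the maximum pairwise distance.
    """
    pts = np.asarray(points, dtype=float)
    v = np.asarray(values, dtype=float)
    if pts.shape[0] < 5:
        raise ValueError("need >= 5 points for a semivariogram")
    d = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1))
    iu = np.triu_indices(pts.shape[0], k=1)
    h = d[iu]
    sq = 0.5 * (v[:, None] - v[None, :]) ** 2
    g = sq[iu]
    if max_lag is None:
        max_lag = 0.5 * h.max()
    if not max_lag > 0:
        raise ValueError("max_lag must be > 0")
    edges = np.linspace(0.0, max_lag, n_bins + 1)
    idx = np.digitize(h, edges[1:-1])
    keep = h <= max_lag
    rows = []
    for b in range(n_bins):
        m = keep & (idx == b)
        if not m.any():
            warnings.warn(f"empty semivariogram bin {b} dropped", stacklevel=2)
            continue
        rows.append({"lag": h[m].mean(), "gamma": g[m].mean(), "pairs": int(m.sum())})
    return pd.DataFrame(rows)


def fit_variogram(empirical: pd.DataFrame, family: str = "spherical") -> VariogramModel:
    """Weighted-least-squares variogram fit (weights = pair counts)."""
    if len(empirical) < 3:
        raise ValueError("need >= 3 non-empty bins to fit a variogram")
    h = empirical["lag"].to_numpy(dtype=float)
    g = empirical["gamma"].to_numpy(dtype=float)
    wts = np.sqrt(empirical["pairs"].to_numpy(dtype=float))
    gmax = max(g.max(), 1e-12)
    hmax = h.max()

    def resid(theta):
        nug, psill, rng = theta
        m = VariogramModel(family, max(nug, 0.0), max(psill, 0.0), max(rng, 1e-9))
        return wts * (m(h) - g)

    x0 = np.array([0.1 * gmax, 0.9 * gmax, 0.5 * hmax])
    lo = [0.0, 0.0, 1e-6 * max(hmax, 1.0)]
    hi = [2 * gmax + 1e-9, 5 * gmax + 1e-9, 10 * hmax]
    sol = optimize.least_squares(resid, x0, bounds=(lo, hi))
    nug, psill, rng = sol.x
    degenerate = bool(rng >= 0.999 * hi[2] or rng <= 1.01 * lo[2])
    if degenerate:
        warnings.warn("variogram range at optimisation bound; fit is degenerate",
                      stacklevel=2)
    return VariogramModel(family, float(nug), float(psill), float(rng),
                          degenerate=degenerate)


class OrdinaryKriging:
    """Ordinary-kriging interpolator with sklearn-style fit/predict.

    Parameters
    ----------
    model : VariogramModel, optional
        Fixed semivariogram; if None one is fitted from the data at
        ``fit`` time (``family``, ``n_bins`` control that fit).
    family : str
        Variogram family used when ``model`` is None.
    on_duplicates : "mean" | "error"
        Duplicate data points make the kriging system singular; average
        their values (default) or raise.
    """

    def __init__(self, model: VariogramModel | None = None, family: str = "spherical",
                 n_bins: int = 12, on_duplicates: str = "mean"):
        self.model = model
        self.family = family
        self.n_bins = n_bins
        self.on_duplicates = on_duplicates

    def get_params(self, deep: bool = True) -> dict:
        return {"model": self.model, "family": self.family, "n_bins": self.n_bins,
                "on_duplicates": self.on_duplicates}

    def set_params(self, **kw) -> "OrdinaryKriging":
        for k, v in kw.items():
            if k not in self.get_params():
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, X, y) -> "OrdinaryKriging":
        pts = np.asarray(X, dtype=float)
        v = np.asarray(y, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2:
            raise ValueError("X must be (n, 2) planar km coordinates")
        pts, v = self._dedupe(pts, v)
        self.X_, self.y_ = pts, v
        self.model_ = self.model
        if self.model_ is None:
            emp = empirical_semivariogram(pts, v, n_bins=self.n_bins)
            self.model_ = fit_variogram(emp, family=self.family)
        n = pts.shape[0]
        d = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1))
        A = np.empty((n + 1, n + 1))
        A[:n, :n] = self.model_(d)
        A[n, :] = 1.0
        A[:, n] = 1.0
        A[n, n] = 0.0
        self._lu = A
        return self

    def _dedupe(self, pts, v):
        _, inv, counts = np.unique(pts, axis=0, return_inverse=True, return_counts=True)
        if (counts > 1).any():
            if self.on_duplicates == "error":
                raise ValueError("duplicate data points make the kriging system singular")
            sums = np.zeros(counts.size)
            np.add.at(sums, inv, v)
            uniq = np.unique(pts, axis=0)
            return uniq, sums / counts
        return pts, v

    def predict(self, X, return_variance: bool = False):
        pts = np.asarray(X, dtype=float)
        if pts.size == 0:
            raise ValueError("prediction grid is empty")
        n = self.X_.shape[0]
        d0 = np.sqrt(((pts[:, None, :] - self.X_[None, :, :]) ** 2).sum(-1))
        B = np.empty((pts.shape[0], n + 1))
        B[:, :n] = self.model_(d0)
        B[:, n] = 1.0
        lam = np.linalg.solve(self._lu, B.T).T  # (m, n+1); last col = Lagrange mult
        preds = lam[:, :n] @ self.y_
        var = np.einsum("ij,ij->i", lam, B)
        var = np.maximum(var, 0.0)  # clip numerical negatives
        if return_variance:
            return preds, var
        return preds

    def kriging_weights(self, X) -> np.ndarray:
        """(m, n) matrix of data weights per prediction node; rows sum to 1."""
        pts = np.asarray(X, dtype=float)
        n = self.X_.shape[0]
        d0 = np.sqrt(((pts[:, None, :] - self.X_[None, :, :]) ** 2).sum(-1))
        B = np.empty((pts.shape[0], n + 1))
        B[:, :n] = self.model_(d0)
        B[:, n] = 1.0
        lam = np.linalg.solve(self._lu, B.T).T
        return lam[:, :n]

    def surface(self, grid) -> KrigedSurface:
        preds, var = self.predict(grid, return_variance=True)
        return KrigedSurface(grid=np.asarray(grid, dtype=float),
                             predictions=preds, kriging_variance=var)


def krige(points, values, model: VariogramModel, grid) -> KrigedSurface:
    """One-shot ordinary kriging onto a grid with a given variogram model."""
    ok = OrdinaryKriging(model=model).fit(points, values)
    return ok.surface(grid)


def regular_grid(xmin, xmax, ymin, ymax, step_km: float) -> np.ndarray:
    """(m, 2) array of node coordinates on a regular planar grid."""
    xs = np.arange(xmin, xmax + step_km / 2, step_km)
    ys = np.arange(ymin, ymax + step_km / 2, step_km)
    gx, gy = np.meshgrid(xs, ys)
    return np.column_stack([gx.ravel(), gy.ravel()])
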