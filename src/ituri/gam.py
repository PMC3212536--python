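"""Quasipoisson density-surface GAMs with an effort offset.

Transect dung counts n_i are modelled as overdispersed Poisson with

    log E[n_i] = log(2 * w_hat * l_i) + beta_0 + sum_k s_k(z_ik)

where the offset log(2 * w_hat * l_i) is the effective area surveyed on
transect i (effective half-strip width w_hat times length l_i), so the
linear predictor models density. Each s_k is a penalized cubic B-spline
smooth (integrated-squared-second-derivative penalty; the penalty null
space is the linear function, so lambda -> infinity collapses a smooth to
a straight line). Overdispersion is handled quasipoisson-style: Poisson
estimating equations, dispersion phi = Pearson chi^2 / (n - edf).

Smoothing parameters minimize the generalized cross-validation score

    GCV(lambda) = n * D(lambda) / (n - edf(lambda))^2

and model simplification proceeds by backward deletion on GCV.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import interpolate, optimize, stats

__all__ = [
    "TermSpec",
    "s",
    "linear",
    "Design",
    "build_design",
    "GamFit",
    "fit_gam",
    "select_smoothing",
    "QuasiPoissonGAM",
    "backward_delete",
    "model_comparison_table",
    "effort_offset",
]


# ---------------------------------------------------------------------------
# term specification
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TermSpec:
    """One model term: a spline smooth of a covariate, or a linear term."""

    name: str
    kind: str = "smooth"  # "smooth" | "linear"
    k: int = 5  # basis dimension (smooths only)

    def __post_init__(self):
        if self.kind not in ("smooth", "linear"):
            raise ValueError(f"kind must be smooth|linear, got {self.kind!r}")
        if self.kind == "smooth" and self.k < 4:
            raise ValueError("cubic smooths need basis dimension k >= 4")

    @property
    def label(self) -> str:
        return f"s({self.name})" if self.kind == "smooth" else self.name


def s(name: str, k: int = 5) -> TermSpec:
    """Smooth term shorthand."""
    return TermSpec(name, "smooth", k)


def linear(name: str) -> TermSpec:
    """Linear term shorthand."""
    return TermSpec(name, "linear")


def effort_offset(esw_m: float, lengths_km) -> np.ndarray:
    """Offset log(2 * esw * l_i): log effective area surveyed per transect.

    Units only shift the intercept; esw in metres and lengths in km give
    area in m*km (0.1 ha) consistently across transects.
    """
    lengths = np.asarray(lengths_km, dtype=float)
    if not esw_m > 0 or np.any(lengths <= 0):
        raise ValueError("esw and lengths must be > 0")
    return np.log(2.0 * esw_m * lengths)


# ---------------------------------------------------------------------------
# B-spline bases and penalties
# ---------------------------------------------------------------------------

def _knots(x: np.ndarray, k: int, degree: int = 3) -> np.ndarray:
    """Open knot vector with interior knots at quantiles of x."""
    n_interior = k - degree - 1
    lo, hi = float(x.min()), float(x.max())
    if hi <= lo:
        raise ValueError("constant covariate cannot enter a smooth")
    if n_interior > 0:
        qs = np.linspace(0, 1, n_interior + 2)[1:-1]
        interior = np.unique(np.quantile(x, qs))
        # fall back to even spacing if quantiles coincide (ties in x)
        if interior.size < n_interior or interior.min() <= lo or interior.max() >= hi:
            interior = np.linspace(lo, hi, n_interior + 2)[1:-1]
    else:
        interior = np.array([])
    return np.concatenate([[lo] * (degree + 1), interior, [hi] * (degree + 1)])


def _basis_matrix(x: np.ndarray, t: np.ndarray, degree: int = 3) -> np.ndarray:
    xc = np.clip(x, t[degree], t[-degree - 1])  # guard fp round-off at edges
    return interpolate.BSpline.design_matrix(xc, t, degree, extrapolate=False).toarray()


def _second_derivative_penalty(t: np.ndarray, k: int, degree: int = 3) -> np.ndarray:
    """S_ij = integral B_i'' B_j'' dx, exact via 2-point Gauss per interval.

    Second derivatives of cubic B-splines are piecewise linear, so their
    products are quadratics integrated exactly by 2-point Gauss-Legendre.
    """
    S = np.zeros((k, k))
    gauss_x = np.array([-1.0, 1.0]) / np.sqrt(3.0)
    breaks = np.unique(t)
    eye = np.eye(k)
    splines = [interpolate.BSpline(t, eye[i], degree) for i in range(k)]
    d2 = [sp.derivative(2) for sp in splines]
    for a, b in zip(breaks[:-1], breaks[1:]):
        half = 0.5 * (b - a)
        mid = 0.5 * (a + b)
        pts = mid + half * gauss_x
        vals = np.array([f(pts) for f in d2])  # (k, 2)
        S += half * (vals @ vals.T)
    return S


@dataclass
class _TermBlock:
    spec: TermSpec
    cols: slice
    knots: np.ndarray | None  # smooths only
    Z: np.ndarray | None  # sum-to-zero constraint basis (k, k-1)
    S: np.ndarray | None  # penalty in constrained coordinates
    center: float  # subtracted mean (linear terms)
    x_range: tuple[float, float]

    def evaluate(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if self.spec.kind == "linear":
            return (x - self.center)[:, None]
        return _basis_matrix(x, self.knots) @ self.Z


@dataclass
class Design:
    """Model matrix (intercept + term blocks) plus per-term penalties."""

    X: np.ndarray
    terms: list[_TermBlock]
    columns: pd.Index  # covariate names used

    @property
    def n_obs(self) -> int:
        return self.X.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]

    def penalty(self, lam: np.ndarray) -> np.ndarray:
        """Full p x p penalty sum lambda_k S_k (zero-padded blocks)."""
        S = np.zeros((self.p, self.p))
        for t, l in zip(self.terms, lam):
            if t.S is not None:
                S[t.cols, t.cols] += l * t.S
        return S

    @property
    def n_smooth(self) -> int:
        return sum(1 for t in self.terms if t.spec.kind == "smooth")

    def model_matrix(self, covariates: pd.DataFrame) -> np.ndarray:
        blocks = [np.ones((len(covariates), 1))]
        for t in self.terms:
            blocks.append(t.evaluate(covariates[t.spec.name].to_numpy(dtype=float)))
        return np.hstack(blocks)


def build_design(covariates: pd.DataFrame, terms: list[TermSpec]) -> Design:
    """Build the model matrix and penalty blocks for a term list.

    Smooth blocks use cubic B-splines with knots at covariate quantiles,
    made identifiable by absorbing the sum-to-zero constraint (columns of
    each smooth block sum to zero over the data); the second-derivative
    penalty is transformed into the constrained coordinates.
    """
    n = len(covariates)
    blocks = [np.ones((n, 1))]
    infos: list[_TermBlock] = []
    col = 1
    for spec in terms:
        if spec.name not in covariates.columns:
            raise KeyError(f"covariate {spec.name!r} not in table")
        x = covariates[spec.name].to_numpy(dtype=float)
        if np.any(~np.isfinite(x)):
            raise ValueError(f"missing/non-finite values in covariate {spec.name!r}")
        if spec.kind == "linear":
            center = float(x.mean())
            if np.ptp(x) == 0:
                raise ValueError(f"constant covariate {spec.name!r}")
            blocks.append((x - center)[:, None])
            infos.append(_TermBlock(spec, slice(col, col + 1), None, None, None,
                                    center, (float(x.min()), float(x.max()))))
            col += 1
            continue
        t = _knots(x, spec.k)
        B = _basis_matrix(x, t)
        S = _second_derivative_penalty(t, spec.k)
        # sum-to-zero constraint: Z spans the null space of the column means
        c = B.mean(axis=0, keepdims=True)
        _, _, Vt = np.linalg.svd(c, full_matrices=True)
        Z = Vt[1:, :].T  # (k, k-1)
        Bz = B @ Z
        Sz = Z.T @ S @ Z
        Sz = 0.5 * (Sz + Sz.T)
        blocks.append(Bz)
        infos.append(_TermBlock(spec, slice(col, col + spec.k - 1), t, Z, Sz,
                                0.0, (float(x.min()), float(x.max()))))
        col += spec.k - 1
    return Design(X=np.hstack(blocks), terms=infos, columns=covariates.columns)


# ---------------------------------------------------------------------------
# penalized IRLS
# ---------------------------------------------------------------------------

def _poisson_deviance(y: np.ndarray, mu: np.ndarray) -> float:
    with np.errstate(divide="ignore", invalid="ignore"):
        term = np.where(y > 0, y * np.log(y / mu), 0.0)
    return float(2.0 * np.sum(term - (y - mu)))


def _null_deviance(y: np.ndarray, offset: np.ndarray) -> float:
    # intercept-only quasipoisson with offset has a closed-form MLE
    beta0 = np.log(y.sum() / np.exp(offset).sum())
    return _poisson_deviance(y, np.exp(beta0 + offset))


class GamFitError(RuntimeError):
    """Penalized IRLS failed to converge; message carries the trace."""


@dataclass
class GamFit:
    """A fitted quasipoisson GAM.

    Key fields: ``deviance_explained`` (percent, 100 (1 - D/D0)),
    ``gcv`` (n D / (n - edf)^2), ``phi`` (Pearson dispersion), per-term
    effective degrees of freedom in ``edf_terms``.
    """

    design: Design
    coef: np.ndarray
    lam: np.ndarray
    offset: np.ndarray
    y: np.ndarray
    mu: np.ndarray
    edf_total: float
    edf_terms: dict[str, float]
    deviance: float
    null_deviance: float
    phi: float
    Vp: np.ndarray  # Bayesian covariance of coef
    iterations: int
    term_labels: list[str] = field(default_factory=list)

    @property
    def deviance_explained(self) -> float:
        if self.null_deviance == 0:
            return 0.0
        return 100.0 * (1.0 - self.deviance / self.null_deviance)

    @property
    def gcv(self) -> float:
        n = self.y.size
        return n * self.deviance / (n - self.edf_total) ** 2

    def predict(self, covariates: pd.DataFrame, offset=None) -> np.ndarray:
        """Expected counts (offset supplied) or density scale (offset=0)."""
        X = self.design.model_matrix(covariates)
        off = np.zeros(len(covariates)) if offset is None else np.asarray(offset, float)
        return np.exp(X @ self.coef + off)

    def partial_effect(self, name: str, grid: np.ndarray | None = None,
                       n_grid: int = 100) -> pd.DataFrame:
        """Centered partial effect of one term on the linear-predictor scale.

        Returns columns ``value``, ``effect``, ``se`` — the data behind a
        gam plot (estimate with pointwise Bayesian standard errors).
        """
        block = next((t for t in self.design.terms if t.spec.name == name), None)
        if block is None:
            raise KeyError(f"no term for covariate {name!r}")
        if grid is None:
            grid = np.linspace(*block.x_range, n_grid)
        grid = np.asarray(grid, dtype=float)
        Xb = block.evaluate(grid)
        beta = self.coef[block.cols]
        eff = Xb @ beta
        V = self.Vp[block.cols, block.cols]
        se = np.sqrt(np.maximum(np.einsum("ij,jk,ik->i", Xb, V, Xb), 0.0))
        return pd.DataFrame({"value": grid, "effect": eff, "se": se})

    def significance_vs_null(self) -> tuple[float, float]:
        """phi-scaled F-test of the model against the intercept-only null."""
        df1 = max(self.edf_total - 1.0, 1e-8)
        df2 = max(self.y.size - self.edf_total, 1e-8)
        F = (self.null_deviance - self.deviance) / df1 / self.phi
        return float(F), float(stats.f.sf(F, df1, df2))

    def summary(self) -> dict:
        return {
            "terms": self.term_labels,
            "lambda": list(map(float, self.lam)),
            "edf": {k: float(v) for k, v in self.edf_terms.items()},
            "edf_total": float(self.edf_total),
            "deviance": float(self.deviance),
            "null_deviance": float(self.null_deviance),
            "deviance_explained_pct": float(self.deviance_explained),
            "gcv": float(self.gcv),
            "phi": float(self.phi),
        }


def fit_gam(y, offset, design: Design, lam, max_iter: int = 200,
            tol: float = 1e-9) -> GamFit:
    """Penalized IRLS for the log-link quasipoisson GAM at fixed lambda."""
    y = np.asarray(y, dtype=float)
    offset = np.asarray(offset, dtype=float)
    if np.any(y < 0) or np.any(~np.isfinite(offset)):
        raise ValueError("counts must be >= 0 and offsets finite")
    lam = np.asarray(lam, dtype=float)
    if lam.size != len(design.terms):
        raise ValueError("one lambda per term required")
    X = design.X
    n, p = X.shape
    S = design.penalty(lam)
    mu = y + 0.5
    eta = np.log(mu)
    beta = np.zeros(p)
    dev = _poisson_deviance(y, mu)
    trace = [dev]
    for it in range(max_iter):
        W = mu  # Poisson working weights under log link
        z = eta - offset + (y - mu) / mu
        XtW = X.T * W
        A = XtW @ X + S
        try:
            beta_new = np.linalg.solve(A, XtW @ z)
        except np.linalg.LinAlgError as exc:
            raise GamFitError(f"singular system at iteration {it}: {exc}") from exc
        eta = X @ beta_new + offset
        eta = np.clip(eta, -30, 30)
        mu = np.exp(eta)
        new_dev = _poisson_deviance(y, mu)
        trace.append(new_dev)
        beta = beta_new
        if abs(new_dev - dev) < tol * (abs(dev) + tol):
            dev = new_dev
            break
        dev = new_dev
    else:
        raise GamFitError(f"IRLS did not converge in {max_iter} iterations; "
                          f"deviance trace tail {trace[-5:]}")
    # effective degrees of freedom: F = (X'WX + S)^-1 X'WX
    W = mu
    XtWX = (X.T * W) @ X
    A = XtWX + S
    Ainv = np.linalg.inv(A)
    F = Ainv @ XtWX
    edf_total = float(np.trace(F))
    edf_terms = {}
    for t in design.terms:
        edf_terms[t.spec.label] = float(np.sum(np.diag(F)[t.cols]))
    pearson = float(np.sum((y - mu) ** 2 / mu))
    phi = pearson / max(n - edf_total, 1e-8)
    Vp = phi * Ainv
    return GamFit(
        design=design, coef=beta, lam=lam, offset=offset, y=y, mu=mu,
        edf_total=edf_total, edf_terms=edf_terms, deviance=dev,
        null_deviance=_null_deviance(y, offset), phi=phi, Vp=Vp,
        iterations=it + 1, term_labels=[t.spec.label for t in design.terms],
    )


def select_smoothing(y, offset, design: Design,
                     log_lambda_range: tuple[float, float] = (-4.0, 6.0),
                     n_grid: int = 6) -> tuple[np.ndarray, GamFit]:
    """Choose smoothing parameters by GCV minimization.

    Coordinate-wise log-lambda grid search (linear terms carry no penalty
    and are pinned at lambda = 0) followed by a Nelder-Mead polish of the
    smooth terms' log-lambdas. Returns (lambda, fit at lambda).
    """
    smooth_idx = [i for i, t in enumerate(design.terms) if t.spec.kind == "smooth"]
    lam = np.zeros(len(design.terms))
    if not smooth_idx:
        fit = fit_gam(y, offset, design, lam)
        return lam, fit

    def gcv_of(loglams: np.ndarray) -> float:
        trial = lam.copy()
        for i, ll in zip(smooth_idx, np.clip(loglams, -8.0, 10.0)):
            trial[i] = 10.0 ** ll
        try:
            return fit_gam(y, offset, design, trial).gcv
        except (GamFitError, np.linalg.LinAlgError):
            return np.inf

    grid = np.linspace(*log_lambda_range, n_grid)
    current = np.full(len(smooth_idx), 0.0)
    for _sweep in range(2):
        for j in range(len(smooth_idx)):
            scores = []
            for g in grid:
                trial = current.copy()
                trial[j] = g
                scores.append(gcv_of(trial))
            current[j] = grid[int(np.argmin(scores))]
    res = optimize.minimize(gcv_of, current, method="Nelder-Mead",
                            options={"xatol": 0.05, "fatol": 1e-8, "maxiter": 200})
    best = res.x if np.isfinite(res.fun) and res.fun <= gcv_of(current) else current
    if not np.isfinite(gcv_of(best)):
        raise GamFitError("GCV non-finite over the whole lambda search region")
    for i, ll in zip(smooth_idx, np.clip(best, -8.0, 10.0)):
        lam[i] = 10.0 ** ll
    return lam, fit_gam(y, offset, design, lam)


# ---------------------------------------------------------------------------
# estimator
# ---------------------------------------------------------------------------

class QuasiPoissonGAM:
    """Density-surface GAM estimator with sklearn-style fit/predict.

    Parameters
    ----------
    terms : list of TermSpec (or built with :func:`s` / :func:`linear`)
    select : bool
        Choose smoothing parameters by GCV (default); otherwise ``lam``
        (scalar or vector) is used as-is.
    lam : float or sequence, optional
        Fixed smoothing parameter(s) when ``select=False``.

    Attributes (after ``fit``)
    --------------------------
    fit_ : GamFit
    coef_, lam_, edf_, deviance_explained_, gcv_, dispersion_ : convenience
        views of the fitted model.
    """

    def __init__(self, terms, select: bool = True, lam=None):
        self.terms = list(terms)
        self.select = select
        self.lam = lam

    def get_params(self, deep: bool = True) -> dict:
        return {"terms": self.terms, "select": self.select, "lam": self.lam}

    def set_params(self, **kw) -> "QuasiPoissonGAM":
        for k, v in kw.items():
            if k not in self.get_params():
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, X: pd.DataFrame, y, offset=None) -> "QuasiPoissonGAM":
        y = np.asarray(y, dtype=float)
        off = np.zeros(len(X)) if offset is None else np.asarray(offset, dtype=float)
        design = build_design(X, self.terms)
        if self.select:
            lam, fit = select_smoothing(y, off, design)
        else:
            lam = np.zeros(len(design.terms))
            if self.lam is not None:
                lam_in = np.atleast_1d(np.asarray(self.lam, dtype=float))
                lam = np.full(len(design.terms), lam_in[0]) if lam_in.size == 1 else lam_in
            for i, t in enumerate(design.terms):
                if t.spec.kind == "linear":
                    lam[i] = 0.0
            fit = fit_gam(y, off, design, lam)
        self.fit_ = fit
        self.coef_ = fit.coef
        self.lam_ = fit.lam
        self.edf_ = fit.edf_terms
        self.deviance_explained_ = fit.deviance_explained
        self.gcv_ = fit.gcv
        self.dispersion_ = fit.phi
        return self

    def predict(self, X: pd.DataFrame, offset=None) -> np.ndarray:
        return self.fit_.predict(X, offset=offset)

    def partial_effect(self, name: str, **kw) -> pd.DataFrame:
        return self.fit_.partial_effect(name, **kw)


# ---------------------------------------------------------------------------
# model building / reporting
# ---------------------------------------------------------------------------

def backward_delete(terms: list[TermSpec], covariates: pd.DataFrame, y, offset,
                    rel_tol: float | None = None):
    """Backward deletion on GCV from a full term list.

    At each step every single-term deletion is refitted (with GCV-selected
    smoothing); the deletion with the lowest GCV is accepted when that GCV
    is no worse than the current model's by more than ``rel_tol``
    (relative). The default tolerance 2/n translates the conventional
    "delta-AIC < 2" parsimony rule onto the GCV scale (treating AIC as
    roughly n log GCV), so terms whose contribution is within selection
    noise are deleted. Stops when every deletion worsens GCV beyond the
    tolerance. Returns (final GamFit, trace DataFrame with one row per
    evaluated model).
    """
    if len(terms) < 1:
        raise ValueError("need at least one candidate term")
    y = np.asarray(y, dtype=float)
    off = np.asarray(offset, dtype=float)
    if rel_tol is None:
        rel_tol = 2.0 / y.size

    def fitted(tl):
        design = build_design(covariates, tl)
        _, fit = select_smoothing(y, off, design)
        return fit

    current = list(terms)
    fit = fitted(current)
    trace = [{"step": 0, "action": "full", "terms": [t.label for t in current],
              "gcv": fit.gcv, "deviance_explained": fit.deviance_explained}]
    step = 0
    while len(current) > 1:
        step += 1
        best_drop, best_fit = None, None
        for i in range(len(current)):
            reduced = current[:i] + current[i + 1:]
            cand = fitted(reduced)
            trace.append({"step": step, "action": f"drop {current[i].label}",
                          "terms": [t.label for t in reduced], "gcv": cand.gcv,
                          "deviance_explained": cand.deviance_explained})
            if cand.gcv <= fit.gcv * (1.0 + rel_tol) and \
                    (best_fit is None or cand.gcv < best_fit.gcv):
                best_drop, best_fit = i, cand
        if best_drop is None:
            break
        current.pop(best_drop)
        fit = best_fit
    return fit, pd.DataFrame(trace)


def model_comparison_table(covariates: pd.DataFrame, y, offset,
                  univariate: list[TermSpec],
                  composite: dict[str, list[TermSpec]] | None = None) -> pd.DataFrame:
    """Model-comparison table: univariate fits ranked by deviance explained.

    One row per univariate term (ranked descending) followed by named
    composite models; columns are deviance explained (%), GCV score, and a
    significance star from the phi-scaled F-test against the null model.
    """
    y = np.asarray(y, dtype=float)
    off = np.asarray(offset, dtype=float)
    rows = []
    for spec in univariate:
        design = build_design(covariates, [spec])
        _, fit = select_smoothing(y, off, design)
        _, p = fit.significance_vs_null()
        rows.append({"model": spec.label, "kind": "univariate",
                     "deviance_explained_pct": round(fit.deviance_explained, 2),
                     "gcv_score": round(fit.gcv, 3),
                     "significant": p < 0.05})
    rows.sort(key=lambda r: -r["deviance_explained_pct"])
    for name, specs in (composite or {}).items():
        fit, _ = backward_delete(specs, covariates, y, off)
        _, p = fit.significance_vs_null()
        rows.append({"model": name, "kind": "composite",
                     "deviance_explained_pct": round(fit.deviance_explained, 2),
                     "gcv_score": round(fit.gcv, 3),
                     "significant": p < 0.05})
    return pd.DataFrame(rows)
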