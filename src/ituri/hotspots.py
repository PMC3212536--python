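"""Getis-Ord Gi* local hotspot statistics.

For each location i, the weighted sum of neighbourhood values (the starred
variant includes the location itself, w_ii = 1) is compared with what the
global mean would predict, standardized to a z-score:

    Gi*(i) = [sum_j w_ij x_j - Xbar sum_j w_ij]
             / (S * sqrt[(n sum_j w_ij^2 - (sum_j w_ij)^2) / (n - 1)])

with Xbar and S the global mean and (population) standard deviation.
Binary distance-band weights are used: w_ij = 1 iff d_ij <= band.
High positive z flags clustering of high values (hotspot, z > 1.96 at the
5% level), low negative z a coldspot.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["getis_ord_gistar", "GetisOrdGiStar", "default_band"]


def default_band(points) -> float:
    """Default distance band: twice the median nearest-neighbour distance."""
    pts = np.asarray(points, dtype=float)
    d = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1))
    np.fill_diagonal(d, np.inf)
    return 2.0 * float(np.median(d.min(axis=1)))


class GetisOrdGiStar:
    """Gi* estimator over planar points with a fixed distance band.

    Parameters
    ----------
    band_km : float, optional
        Binary-weight distance band; default: twice the median
        nearest-neighbour distance of the fitted points.
    crit_z : float
        Hot/cold flag threshold on \\|z\\| (default 1.96, i.e. 5% two-sided).
    """

    def __init__(self, band_km: float | None = None, crit_z: float = 1.96):
        self.band_km = band_km
        self.crit_z = crit_z

    def get_params(self, deep: bool = True) -> dict:
        return {"band_km": self.band_km, "crit_z": self.crit_z}

    def set_params(self, **kw) -> "GetisOrdGiStar":
        for k, v in kw.items():
            if k not in self.get_params():
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, X, y) -> "GetisOrdGiStar":
        pts = np.asarray(X, dtype=float)
        x = np.asarray(y, dtype=float)
        n = pts.shape[0]
        if n < 3:
            raise ValueError("need >= 3 points for Gi*")
        band = self.band_km if self.band_km is not None else default_band(pts)
        if not band > 0:
            raise ValueError("band must be > 0")
        d = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1))
        W = (d <= band).astype(float)  # includes self: d_ii = 0
        xbar = x.mean()
        S = np.sqrt((x**2).mean() - xbar**2)
        if S == 0:
            raise ValueError("constant field: Gi* undefined (zero variance)")
        wsum = W.sum(axis=1)
        wsq = (W**2).sum(axis=1)
        num = W @ x - xbar * wsum
        den = S * np.sqrt((n * wsq - wsum**2) / (n - 1))
        z = num / den
        self.band_ = float(band)
        self.z_ = z
        self.p_ = 2.0 * stats.norm.sf(np.abs(z))
        self.hot_ = z > self.crit_z
        self.cold_ = z < -self.crit_z
        return self

    def to_frame(self, location_ids=None) -> pd.DataFrame:
        ids = location_ids if location_ids is not None else np.arange(self.z_.size)
        return pd.DataFrame(
            {"location_id": ids, "z": self.z_, "p": self.p_,
             "hot": self.hot_, "cold": self.cold_}
        )


def getis_ord_gistar(points, values, band_km: float | None = None,
                     crit_z: float = 1.96, location_ids=None) -> pd.DataFrame:
    """Gi* z-scores, p-values and hot/cold flags as a DataFrame."""
    est = GetisOrdGiStar(band_km=band_km, crit_z=crit_z).fit(points, values)
    return est.to_frame(location_ids)
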