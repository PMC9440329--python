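"""Least-squares primitives shared by the search, evaluation and prediction
stages.

The exhaustive subset search evaluates millions of small regressions; it is
driven by one Gram matrix per district from which the normal equations of
every feature subset are gathered and solved in batch.  The trend column is
centred internally for conditioning; reported coefficients from
:func:`fit_regression` are in the original parametrisation (trend per
calendar year).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: a fit needs at least this many observations beyond the feature count
#: (intercept + trend + one residual degree of freedom)
FIT_MARGIN = 3

_CHUNK = 65536


@dataclass
class RegressionFit:
    """OLS fit of yield on intercept + linear trend + selected features."""

    intercept: float
    trend: float
    beta: np.ndarray
    residuals: np.ndarray
    r_squared: float
    n_obs: int
    degenerate: bool = False

    def predict(self, years: np.ndarray, features: np.ndarray) -> np.ndarray:
        years = np.asarray(years, dtype=float)
        features = np.atleast_2d(np.asarray(features, dtype=float))
        return self.intercept + self.trend * years + features @ self.beta


def fit_regression(
    years: np.ndarray, yields: np.ndarray, feature_values: np.ndarray | None = None
) -> RegressionFit:
    """Ordinary least squares of yield on intercept, trend and features.

    ``feature_values`` is (n_obs, d); pass ``None`` or an empty array for the
    trend-only model.  Rank-deficient designs are flagged degenerate and must
    be excluded from rankings.
    """
    years = np.asarray(years, dtype=float)
    y = np.asarray(yields, dtype=float)
    if feature_values is None:
        X = np.empty((len(y), 0))
    else:
        X = np.asarray(feature_values, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
    d = X.shape[1]
    n = len(y)
    Z = np.column_stack([np.ones(n), years, X])
    if n < d + FIT_MARGIN:
        raise ValueError(f"need at least {d + FIT_MARGIN} observations, got {n}")
    coef, _, rank, _ = np.linalg.lstsq(Z, y, rcond=None)
    degenerate = rank < Z.shape[1]
    resid = y - Z @ coef
    sst = float(np.sum((y - y.mean()) ** 2))
    sse = float(resid @ resid)
    r2 = 1.0 - sse / sst if sst > 0 else float("nan")
    return RegressionFit(
        intercept=float(coef[0]),
        trend=float(coef[1]),
        beta=coef[2:].copy(),
        residuals=resid,
        r_squared=min(r2, 1.0) if np.isfinite(r2) else r2,
        n_obs=n,
        degenerate=degenerate,
    )


class DistrictDesign:
    """Precomputed cross-products for one district's (trend, features, yield).

    Column 0 of the internal design is the intercept, column 1 the centred
    trend, columns ``2..`` the features in pool order.
    """

    def __init__(self, years: np.ndarray, y: np.ndarray, F: np.ndarray):
        years = np.asarray(years, dtype=float)
        self.years = years
        self.y = np.asarray(y, dtype=float)
        self.t_center = float(years.mean()) if len(years) else 0.0
        Z = np.column_stack([np.ones(len(years)), years - self.t_center, F])
        self.Z = Z
        self.G = Z.T @ Z
        self.c = Z.T @ self.y
        self.yty = float(self.y @ self.y)
        ybar = self.y.mean() if len(self.y) else 0.0
        self.sst = float(np.sum((self.y - ybar) ** 2))
        self.n = len(self.y)

    def _gather(self, combos: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        C, d = combos.shape
        base = np.tile(np.array([0, 1], dtype=np.intp), (C, 1))
        idx = np.concatenate([base, combos.astype(np.intp) + 2], axis=1)
        subG = self.G[idx[:, :, None], idx[:, None, :]]
        subc = self.c[idx]
        return idx, subG, subc

    def batch_r2(self, combos: np.ndarray) -> np.ndarray:
        """In-sample R-squared of every feature subset in *combos* (C, d).

        Singular subsets get ``-inf`` so they sort last.
        """
        combos = np.atleast_2d(combos)
        C = combos.shape[0]
        out = np.empty(C)
        if self.sst <= 0:
            out.fill(-np.inf)
            return out
        for lo in range(0, C, _CHUNK):
            hi = min(lo + _CHUNK, C)
            _, subG, subc = self._gather(combos[lo:hi])
            try:
                b = np.linalg.solve(subG, subc[..., None])[..., 0]
                sse = self.yty - np.einsum("ck,ck->c", b, subc)
                r2 = 1.0 - sse / self.sst
            except np.linalg.LinAlgError:
                r2 = self._r2_fallback(combos[lo:hi])
            r2 = np.where(np.isfinite(r2), np.minimum(r2, 1.0), -np.inf)
            out[lo:hi] = r2
        return out

    def _r2_fallback(self, combos: np.ndarray) -> np.ndarray:
        r2 = np.empty(combos.shape[0])
        for i, combo in enumerate(combos):
            cols = np.concatenate([[0, 1], combo + 2]).astype(np.intp)
            Zi = self.Z[:, cols]
            coef, _, rank, _ = np.linalg.lstsq(Zi, self.y, rcond=None)
            if rank < Zi.shape[1]:
                r2[i] = -np.inf
                continue
            resid = self.y - Zi @ coef
            r2[i] = 1.0 - float(resid @ resid) / self.sst
        return r2

    def batch_loo(self, combos: np.ndarray) -> np.ndarray:
        """Leave-one-out predictions for every subset, shape (C, n_obs).

        Uses the exact hat-matrix identity ``e_loo = e / (1 - h)``; points
        with leverage ~1 (interpolating fits) come back NaN.
        """
        combos = np.atleast_2d(combos)
        C, d = combos.shape
        k = d + 2
        preds = np.full((C, self.n), np.nan)
        if self.n < k + 1:
            return preds
        for lo in range(0, C, _CHUNK):
            hi = min(lo + _CHUNK, C)
            idx, subG, subc = self._gather(combos[lo:hi])
            try:
                S = np.linalg.inv(subG)
            except np.linalg.LinAlgError:
                for j in range(lo, hi):
                    preds[j] = self._loo_single(combos[j])
                continue
            b = np.einsum("cij,cj->ci", S, subc)
            Zg = self.Z[:, idx]  # (n, C_chunk, k)
            Zg = np.moveaxis(Zg, 0, 1)  # (C_chunk, n, k)
            fitted = np.einsum("cnk,ck->cn", Zg, b)
            h = np.einsum("cni,cij,cnj->cn", Zg, S, Zg)
            denom = 1.0 - h
            with np.errstate(divide="ignore", invalid="ignore"):
                loo = self.y[None, :] - (self.y[None, :] - fitted) / denom
            loo[denom < 1e-10] = np.nan
            preds[lo:hi] = loo
        return preds

    def _loo_single(self, combo: np.ndarray) -> np.ndarray:
        cols = np.concatenate([[0, 1], np.asarray(combo) + 2]).astype(np.intp)
        Zi = self.Z[:, cols]
        out = np.full(self.n, np.nan)
        for j in range(self.n):
            mask = np.ones(self.n, dtype=bool)
            mask[j] = False
            coef, _, rank, _ = np.linalg.lstsq(Zi[mask], self.y[mask], rcond=None)
            if rank == Zi.shape[1]:
                out[j] = Zi[j] @ coef
        return out


def masked_pearson(preds: np.ndarray, obs: np.ndarray, min_pairs: int = 3) -> np.ndarray:
    """Row-wise Pearson r of *preds* (C, n) against *obs* (n,), NaN-aware.

    Pairs where the prediction is NaN are dropped per row; rows with fewer
    than *min_pairs* pairs or zero variance in either series give NaN.
    """
    preds = np.atleast_2d(np.asarray(preds, dtype=float))
    obs = np.asarray(obs, dtype=float)
    valid = np.isfinite(preds) & np.isfinite(obs)[None, :]
    n = valid.sum(axis=1)
    p = np.where(valid, preds, 0.0)
    o = np.where(valid, obs[None, :], 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        pm = p.sum(axis=1) / n
        om = o.sum(axis=1) / n
        dp = np.where(valid, preds - pm[:, None], 0.0)
        do = np.where(valid, obs[None, :] - om[:, None], 0.0)
        cov = (dp * do).sum(axis=1)
        vp = (dp**2).sum(axis=1)
        vo = (do**2).sum(axis=1)
        r = cov / np.sqrt(vp * vo)
    bad = (n < min_pairs) | (vp <= 0) | (vo <= 0)
    r = np.where(bad, np.nan, r)
    return np.clip(r, -1.0, 1.0)
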