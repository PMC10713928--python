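"""Emax dose-response fitting with AICc model selection and CV maps.

Occupancy-vs-concentration curves are fitted with the hyperbolic Emax model
Occ = Occ_max * C / (C + EC50), either with Occ_max fixed (1-parameter
model) or with (Occ_max, EC50) estimated jointly (2-parameter model). The
two candidates are compared with the small-sample corrected Akaike
information criterion

    AICc = 2p + n ln(SSE/n) + (2p^2 + 2p)/(n - p - 1)

and the lower-AICc model is kept. Parameter precision comes from the
least-squares covariance, sigma_fit^2 = diag((J'J)^-1 * R'R/(n - p)), with
the coefficient of variation CV = sigma_fit / estimate as the per-curve
precision metric for EC50.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares
from sklearn.base import BaseEstimator, RegressorMixin

from .phantom import OccupancySeries
from .slic import ClusterLabeling, cluster_mean_curves

__all__ = [
    "EmaxFitResult",
    "ParametricMaps",
    "EmaxRegressor",
    "aicc",
    "fit_sigma",
    "fit_emax_1p",
    "fit_emax_2p",
    "select_model",
    "fit_curve_best",
    "fit_voxelwise",
    "fit_clusterwise",
]

SSE_FLOOR = 1e-12
_OCCMAX_LO = 1e-3
_EC50_LO = 1e-3


@dataclass
class EmaxFitResult:
    ec50_hat: float
    occmax_hat: float
    model: str  # "one_param" | "two_param"
    sse: float
    n_points: int
    aicc: float
    sigma_fit: np.ndarray  # per estimated parameter, EC50 last
    cv_ec50: float
    converged: bool
    aicc_1p: float = np.nan
    aicc_2p: float = np.nan


@dataclass
class ParametricMaps:
    ec50_image: np.ndarray
    cv_ec50_image: np.ndarray
    occmax_image: np.ndarray
    model_image: np.ndarray  # 1 or 2 inside mask where fitted, else 0
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))


def aicc(sse: float, n: int, p: int) -> float:
    """Corrected Akaike information criterion; SSE floored at 1e-12."""
    if n <= p + 1:
        raise ValueError("AICc requires n > p + 1")
    if sse < 0:
        raise ValueError("SSE must be nonnegative")
    sse = max(float(sse), SSE_FLOOR)
    return 2 * p + n * np.log(sse / n) + (2 * p**2 + 2 * p) / (n - p - 1)


def fit_sigma(jacobian: np.ndarray, residuals: np.ndarray, n: int, p: int) -> np.ndarray:
    """Per-parameter SD from the least-squares covariance.

    sigma_fit^2 = diag((J'J)^-1 * R'R/(n-p)); a rank-deficient Jacobian
    yields NaN entries.
    """
    J = np.asarray(jacobian, dtype=float).reshape(n, p)
    R = np.asarray(residuals, dtype=float).reshape(n)
    if n <= p:
        raise ValueError("need n > p")
    JTJ = J.T @ J
    if np.linalg.matrix_rank(J) < p:
        return np.full(p, np.nan)
    cov = np.linalg.inv(JTJ) * (R @ R / (n - p))
    return np.sqrt(np.diag(cov))


def _emax(c: np.ndarray, occmax: float, ec50: float) -> np.ndarray:
    return occmax * c / (c + ec50)


def _jac_2p(c: np.ndarray, occmax: float, ec50: float) -> np.ndarray:
    # d/dOccmax = C/(C+EC50); d/dEC50 = -Occmax*C/(C+EC50)^2
    denom = c + ec50
    return np.column_stack([c / denom, -occmax * c / denom**2])


def _failed(n: int) -> EmaxFitResult:
    return EmaxFitResult(
        ec50_hat=np.nan,
        occmax_hat=np.nan,
        model="two_param",
        sse=np.nan,
        n_points=n,
        aicc=np.nan,
        sigma_fit=np.array([np.nan]),
        cv_ec50=np.nan,
        converged=False,
    )


def _ec50_grid(conc: np.ndarray, n_grid: int = 20) -> np.ndarray:
    return np.geomspace(_EC50_LO * 10, 10 * conc.max(), n_grid)


def fit_emax_2p(occ: np.ndarray, conc: np.ndarray, n_grid: int = 20) -> EmaxFitResult:
    """Joint (Occ_max, EC50) least-squares fit of the Emax model.

    Deterministic initialization: a log-spaced EC50 grid scan with the
    amplitude profiled out in closed form, then a bounded trust-region
    refinement with the analytic Jacobian. Non-finite points are dropped.
    """
    occ = np.asarray(occ, dtype=float)
    conc = np.asarray(conc, dtype=float)
    ok = np.isfinite(occ) & np.isfinite(conc)
    occ, conc = occ[ok], conc[ok]
    n = occ.size
    if n < 3 or np.any(conc <= 0):
        return _failed(n)

    hi_ec50 = 10 * conc.max()
    # grid scan: for fixed EC50 the optimal amplitude is linear least squares
    grid = _ec50_grid(conc, n_grid)
    x = conc[None, :] / (conc[None, :] + grid[:, None])  # (G, n)
    denom = (x * x).sum(axis=1)
    a = np.clip((x * occ[None, :]).sum(axis=1) / denom, _OCCMAX_LO, 1.0)
    sse_grid = ((a[:, None] * x - occ[None, :]) ** 2).sum(axis=1)
    g = int(np.argmin(sse_grid))

    try:
        sol = least_squares(
            lambda th: _emax(conc, th[0], th[1]) - occ,
            x0=[float(a[g]), float(grid[g])],
            jac=lambda th: _jac_2p(conc, th[0], th[1]),
            bounds=([_OCCMAX_LO, _EC50_LO], [1.0, hi_ec50]),
            xtol=1e-14,
            ftol=1e-14,
            gtol=1e-14,
        )
    except Exception:
        return _failed(n)
    occmax_hat, ec50_hat = sol.x
    r = _emax(conc, occmax_hat, ec50_hat) - occ
    sse = float(r @ r)
    J = _jac_2p(conc, occmax_hat, ec50_hat)
    sigma = fit_sigma(J, r, n, 2)
    cv = float(sigma[1] / ec50_hat) if np.isfinite(sigma[1]) else np.nan
    a2 = aicc(sse, n, 2)
    return EmaxFitResult(
        ec50_hat=float(ec50_hat),
        occmax_hat=float(occmax_hat),
        model="two_param",
        sse=sse,
        n_points=n,
        aicc=a2,
        sigma_fit=sigma,
        cv_ec50=cv,
        converged=bool(sol.success),
        aicc_2p=a2,
    )


def fit_emax_1p(occ: np.ndarray, conc: np.ndarray, occmax_fixed: float = 1.0,
                n_grid: int = 20) -> EmaxFitResult:
    """EC50-only least-squares fit with Occ_max held fixed."""
    if not (0 < occmax_fixed <= 1):
        raise ValueError("occmax_fixed must lie in (0, 1]")
    occ = np.asarray(occ, dtype=float)
    conc = np.asarray(conc, dtype=float)
    ok = np.isfinite(occ) & np.isfinite(conc)
    occ, conc = occ[ok], conc[ok]
    n = occ.size
    if n < 3 or np.any(conc <= 0):
        res = _failed(n)
        res.model = "one_param"
        return res

    hi_ec50 = 10 * conc.max()
    grid = _ec50_grid(conc, n_grid)
    sse_grid = (
        (occmax_fixed * conc[None, :] / (conc[None, :] + grid[:, None]) - occ) ** 2
    ).sum(axis=1)
    g = int(np.argmin(sse_grid))
    try:
        sol = least_squares(
            lambda th: _emax(conc, occmax_fixed, th[0]) - occ,
            x0=[float(grid[g])],
            jac=lambda th: _jac_2p(conc, occmax_fixed, th[0])[:, 1:],
            bounds=([_EC50_LO], [hi_ec50]),
            xtol=1e-14,
            ftol=1e-14,
            gtol=1e-14,
        )
    except Exception:
        res = _failed(n)
        res.model = "one_param"
        return res
    ec50_hat = float(sol.x[0])
    r = _emax(conc, occmax_fixed, ec50_hat) - occ
    sse = float(r @ r)
    J = _jac_2p(conc, occmax_fixed, ec50_hat)[:, 1:]
    sigma = fit_sigma(J, r, n, 1)
    cv = float(sigma[0] / ec50_hat) if np.isfinite(sigma[0]) else np.nan
    a1 = aicc(sse, n, 1)
    return EmaxFitResult(
        ec50_hat=ec50_hat,
        occmax_hat=float(occmax_fixed),
        model="one_param",
        sse=sse,
        n_points=n,
        aicc=a1,
        sigma_fit=sigma,
        cv_ec50=cv,
        converged=bool(sol.success),
        aicc_1p=a1,
    )


def select_model(fit1: EmaxFitResult, fit2: EmaxFitResult) -> EmaxFitResult:
    """Keep the lower-AICc candidate; ties go to the 1-parameter model."""
    if not fit1.converged and not fit2.converged:
        out = fit1
        out.converged = False
        return out
    if not fit1.converged:
        chosen = fit2
    elif not fit2.converged:
        chosen = fit1
    else:
        chosen = fit1 if fit1.aicc <= fit2.aicc else fit2
    chosen.aicc_1p = fit1.aicc if fit1.converged else np.nan
    chosen.aicc_2p = fit2.aicc if fit2.converged else np.nan
    return chosen


def fit_curve_best(
    occ: np.ndarray, conc: np.ndarray, occmax_fixed: float = 1.0
) -> EmaxFitResult:
    """Fit both Emax variants to one curve and return the AICc-selected one."""
    f1 = fit_emax_1p(occ, conc, occmax_fixed)
    f2 = fit_emax_2p(occ, conc)
    return select_model(f1, f2)


class EmaxRegressor(BaseEstimator, RegressorMixin):
    """Single-curve Emax model estimator.

    With ``occmax=None`` (default) both the 1-parameter (Occ_max fixed at
    ``occmax_fixed``) and 2-parameter fits are computed and the AICc-selected
    model retained; ``occmax='free'`` forces the 2-parameter model and a
    float in (0, 1] forces the 1-parameter model with that fixed Occ_max.

    After ``fit(C, occ)``: ``ec50_``, ``occmax_``, ``model_``, ``sse_``,
    ``aicc_``, ``sigma_fit_``, ``cv_ec50_``, ``converged_``.
    """

    def __init__(self, occmax=None, occmax_fixed: float = 1.0):
        self.occmax = occmax
        self.occmax_fixed = occmax_fixed

    def fit(self, X, y):
        conc = np.asarray(X, dtype=float).reshape(-1)
        occ = np.asarray(y, dtype=float).reshape(-1)
        if conc.shape != occ.shape:
            raise ValueError("X and y must have equal length")
        if self.occmax is None:
            res = fit_curve_best(occ, conc, self.occmax_fixed)
        elif self.occmax == "free":
            res = fit_emax_2p(occ, conc)
        else:
            res = fit_emax_1p(occ, conc, float(self.occmax))
        self.result_ = res
        self.ec50_ = res.ec50_hat
        self.occmax_ = res.occmax_hat
        self.model_ = res.model
        self.sse_ = res.sse
        self.aicc_ = res.aicc
        self.sigma_fit_ = res.sigma_fit
        self.cv_ec50_ = res.cv_ec50
        self.converged_ = res.converged
        return self

    def predict(self, X):
        c = np.asarray(X, dtype=float).reshape(-1)
        return _emax(c, self.occmax_, self.ec50_)


def _empty_maps(shape, affine) -> ParametricMaps:
    return ParametricMaps(
        ec50_image=np.full(shape, np.nan),
        cv_ec50_image=np.full(shape, np.nan),
        occmax_image=np.full(shape, np.nan),
        model_image=np.zeros(shape, dtype=np.int8),
        affine=affine,
    )


def fit_voxelwise(
    series: OccupancySeries,
    occmax_fixed: float = 1.0,
    voxel_mask: np.ndarray | None = None,
) -> ParametricMaps:
    """Best-model Emax fit at every voxel (optionally a sub-mask of the brain).

    ``voxel_mask`` restricts fitting to a subset of in-mask voxels, which is
    how desk-scale runs keep the voxel-level stage tractable; unfitted voxels
    stay NaN (model code 0).
    """
    mask = series.brain_mask
    if voxel_mask is None:
        voxel_mask = mask
    else:
        voxel_mask = np.asarray(voxel_mask, dtype=bool) & mask
    maps = _empty_maps(mask.shape, series.affine)
    conc = series.concentrations
    coords = np.argwhere(voxel_mask)
    curves = series.data[:, voxel_mask].T
    for i, (x, y, z) in enumerate(coords):
        res = fit_curve_best(curves[i], conc, occmax_fixed)
        if not res.converged:
            continue
        maps.ec50_image[x, y, z] = res.ec50_hat
        maps.cv_ec50_image[x, y, z] = res.cv_ec50
        maps.occmax_image[x, y, z] = res.occmax_hat
        maps.model_image[x, y, z] = 1 if res.model == "one_param" else 2
    return maps


def fit_clusterwise(
    series: OccupancySeries,
    labeling: ClusterLabeling,
    occmax_fixed: float = 1.0,
) -> tuple[ParametricMaps, "pandas.DataFrame"]:
    """Best-model Emax fit on each cluster's mean curve, broadcast to voxels.

    Returns the piecewise-constant parametric maps and a per-cluster table
    (id, size, ec50, occmax, model, aicc_1p, aicc_2p, cv).
    """
    import pandas as pd

    curves, counts = cluster_mean_curves(labeling, series)
    conc = series.concentrations
    mask = series.brain_mask
    maps = _empty_maps(mask.shape, series.affine)
    rows = []
    Kf = curves.shape[0]
    ec50_by_label = np.full(Kf + 1, np.nan)
    cv_by_label = np.full(Kf + 1, np.nan)
    occmax_by_label = np.full(Kf + 1, np.nan)
    model_by_label = np.zeros(Kf + 1, dtype=np.int8)
    for k in range(Kf):
        res = fit_curve_best(curves[k], conc, occmax_fixed)
        rows.append(
            {
                "cluster": k + 1,
                "size": int(counts[k]),
                "ec50": res.ec50_hat,
                "occmax": res.occmax_hat,
                "model": 1 if res.model == "one_param" else 2,
                "aicc_1p": res.aicc_1p,
                "aicc_2p": res.aicc_2p,
                "cv_ec50": res.cv_ec50,
                "converged": res.converged,
            }
        )
        if res.converged:
            ec50_by_label[k + 1] = res.ec50_hat
            cv_by_label[k + 1] = res.cv_ec50
            occmax_by_label[k + 1] = res.occmax_hat
            model_by_label[k + 1] = 1 if res.model == "one_param" else 2
    lab = labeling.label_image
    inm = mask
    maps.ec50_image[inm] = ec50_by_label[lab[inm]]
    maps.cv_ec50_image[inm] = cv_by_label[lab[inm]]
    maps.occmax_image[inm] = occmax_by_label[lab[inm]]
    maps.model_image[inm] = model_by_label[lab[inm]]
    return maps, pd.DataFrame(rows)
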