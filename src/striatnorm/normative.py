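"""Warped Bayesian linear regression normative model of ROI uptake vs age.

The model is ``z = w^T phi(age) + eps`` with ``eps ~ N(0, 1/beta)``, where
``z = warp(y)`` maps the observed uptake ``y`` through a bijective
sinh-arcsinh transform

    warp(y; a, b) = sinh(b * arcsinh(y) - a),      b > 0,

so that skewed / heavy- or light-tailed response distributions become
Gaussian in the latent space while inference stays closed form.  ``phi`` is
a clamped cubic B-spline basis with five evenly spaced interior knots over
the training age range, plus an explicit intercept column.  For fixed
hyperparameters the posterior over weights is the standard Gaussian-prior
result

    S_w = (alpha*I + beta*Phi^T Phi)^-1,   m_w = beta * S_w Phi^T z,

and the hyperparameters (alpha, beta, a, b) are chosen by minimizing the
negative log marginal likelihood of the *warped* model: the Gaussian
evidence of z minus the Jacobian term ``sum_i log warp'(y_i)``.

Centile curves are back-transformed Gaussian quantiles of the latent
predictive distribution; deviation Z-scores are computed in the latent
space; explained variance (EV) is scored on back-transformed median
predictions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.interpolate import BSpline

__all__ = [
    "BasisSpec",
    "WarpParams",
    "NormativeModel",
    "DeviationReport",
    "design_matrix",
    "warp",
    "warp_inverse",
    "warp_deriv",
    "fit_fixed",
    "fit",
    "nlml",
    "predict",
    "centiles",
    "zscores",
    "explained_variance",
    "stratified_half_split",
    "run_normative",
    "RegionNormativeResult",
]

DEFAULT_QUANTILES = (0.01, 0.05, 0.25, 0.50, 0.75, 0.95, 0.99)


# ---------------------------------------------------------------------------
# basis expansion


@dataclass
class BasisSpec:
    """Clamped cubic B-spline basis over the training age range.

    ``n_interior_knots`` evenly spaced interior knots; boundary knots are
    repeated (clamped).  The expansion has ``n_interior_knots + order + 1``
    spline columns forming a partition of unity, to which a constant
    intercept column is appended.
    """

    order: int = 3
    n_interior_knots: int = 5
    age_min: float | None = None
    age_max: float | None = None

    @property
    def n_spline(self) -> int:
        return self.n_interior_knots + self.order + 1

    @property
    def knots(self) -> np.ndarray:
        if self.age_min is None or self.age_max is None:
            raise ValueError("basis age range not set; call with_range first")
        interior = np.linspace(self.age_min, self.age_max, self.n_interior_knots + 2)[1:-1]
        k = self.order
        return np.concatenate(
            [[self.age_min] * (k + 1), interior, [self.age_max] * (k + 1)]
        )

    def with_range(self, ages: np.ndarray) -> "BasisSpec":
        ages = np.asarray(ages, dtype=float)
        if len(np.unique(ages)) < 2:
            raise ValueError("need at least 2 distinct ages to set the basis range")
        return BasisSpec(
            order=self.order,
            n_interior_knots=self.n_interior_knots,
            age_min=float(ages.min()),
            age_max=float(ages.max()),
        )


def design_matrix(ages: np.ndarray, basis: BasisSpec) -> np.ndarray:
    """n x (n_spline + 1) basis expansion; last column is the intercept.

    Ages outside the training range are clamped to it (with a warning):
    clamped-spline extrapolation holds the boundary value.
    """
    ages = np.atleast_1d(np.asarray(ages, dtype=float))
    lo, hi = basis.age_min, basis.age_max
    if lo is None:
        raise ValueError("basis range unset; fit the model or call with_range")
    if (ages < lo).any() or (ages > hi).any():
        warnings.warn(
            f"ages outside training range [{lo:.1f}, {hi:.1f}] clamped for basis evaluation",
            stacklevel=2,
        )
        ages = np.clip(ages, lo, hi)
    Phi = BSpline.design_matrix(ages, basis.knots, basis.order).toarray()
    return np.column_stack([Phi, np.ones(len(ages))])


# ---------------------------------------------------------------------------
# sinh-arcsinh warp


@dataclass(frozen=True)
class WarpParams:
    """Sinh-arcsinh parameters: ``a`` skews, ``b`` reweights the tails;
    (a=0, b=1) is the identity."""

    a: float = 0.0
    b: float = 1.0

    def __post_init__(self) -> None:
        if self.b <= 0:
            raise ValueError("tail parameter b must be > 0")


def warp(y, p: WarpParams):
    """Latent-space transform z = sinh(b*arcsinh(y) - a)."""
    y = np.asarray(y, dtype=float)
    return np.sinh(p.b * np.arcsinh(y) - p.a)


def warp_inverse(z, p: WarpParams):
    """Response-space transform y = sinh((arcsinh(z) + a)/b)."""
    z = np.asarray(z, dtype=float)
    return np.sinh((np.arcsinh(z) + p.a) / p.b)


def warp_deriv(y, p: WarpParams):
    """dz/dy = b*cosh(b*arcsinh(y) - a)/sqrt(1 + y^2); strictly positive."""
    y = np.asarray(y, dtype=float)
    return p.b * np.cosh(p.b * np.arcsinh(y) - p.a) / np.sqrt(1.0 + y**2)


# ---------------------------------------------------------------------------
# model fitting


@dataclass
class NormativeModel:
    basis: BasisSpec
    m_w: np.ndarray
    S_w: np.ndarray
    alpha: float
    beta: float
    warp: WarpParams
    nlml: float = np.nan

    def __post_init__(self) -> None:
        if self.alpha <= 0 or self.beta <= 0:
            raise ValueError("precisions alpha and beta must be > 0")


def _posterior(Phi: np.ndarray, z: np.ndarray, alpha: float, beta: float):
    M = Phi.shape[1]
    A = alpha * np.eye(M) + beta * (Phi.T @ Phi)
    # lstsq rather than solve: as alpha -> 0 the spline + intercept columns
    # make A numerically singular and the minimum-norm limit is wanted
    m = beta * np.linalg.lstsq(A, Phi.T @ z, rcond=None)[0]
    return m, A


def nlml(ages, y, basis: BasisSpec, alpha: float, beta: float, wp: WarpParams,
         Phi: np.ndarray | None = None) -> float:
    """Negative log marginal likelihood of the warped model.

    Gaussian evidence of z = warp(y) under the weight prior N(0, 1/alpha),
    minus the change-of-variables Jacobian ``sum log warp'(y)``.
    """
    if Phi is None:
        Phi = design_matrix(ages, basis)
    n, M = Phi.shape
    z = warp(y, wp)
    m, A = _posterior(Phi, z, alpha, beta)
    sign, logdetA = np.linalg.slogdet(A)
    if sign <= 0:
        return np.inf
    E = 0.5 * beta * np.sum((z - Phi @ m) ** 2) + 0.5 * alpha * np.sum(m**2)
    log_ev = (
        0.5 * M * np.log(alpha)
        + 0.5 * n * np.log(beta)
        - E
        - 0.5 * logdetA
        - 0.5 * n * np.log(2 * np.pi)
    )
    log_jac = np.sum(np.log(warp_deriv(y, wp)))
    return float(-(log_ev + log_jac))


def fit_fixed(ages, y, basis: BasisSpec | None = None, alpha: float = 1e-3,
              beta: float | None = None, wp: WarpParams = WarpParams()) -> NormativeModel:
    """Closed-form posterior for fixed hyperparameters (no evidence search)."""
    ages = np.asarray(ages, dtype=float)
    y = np.asarray(y, dtype=float)
    basis = (basis or BasisSpec()).with_range(ages)
    Phi = design_matrix(ages, basis)
    z = warp(y, wp)
    if beta is None:
        beta = 1.0 / max(np.var(z), 1e-12)
    m, A = _posterior(Phi, z, alpha, beta)
    S = np.linalg.pinv(A, hermitian=True)
    return NormativeModel(
        basis=basis, m_w=m, S_w=S, alpha=alpha, beta=beta, warp=wp,
        nlml=nlml(ages, y, basis, alpha, beta, wp, Phi=Phi),
    )


def fit(
    ages,
    y,
    basis: BasisSpec | None = None,
    wp: WarpParams | None = None,
    n_restarts: int = 5,
    seed: int = 0,
    maxiter: int = 400,
    tol: float = 1e-6,
) -> NormativeModel:
    """Fit the warped-BLR normative model by evidence optimization.

    Hyperparameters are searched as (log alpha, log beta, a, log b) by
    Nelder-Mead from multiple seeded starts; the first start is the
    identity warp, so the optimized evidence never exceeds the identity
    initialization.  Passing ``wp`` fixes the warp and searches only the
    precisions.

    Requires ``n >= n_basis + 2`` observations.
    """
    ages = np.asarray(ages, dtype=float)
    y = np.asarray(y, dtype=float)
    basis = (basis or BasisSpec()).with_range(ages)
    if len(ages) < basis.n_spline + 3:
        raise ValueError(
            f"need at least {basis.n_spline + 3} observations, got {len(ages)}"
        )
    Phi = design_matrix(ages, basis)
    fixed_warp = wp is not None
    wp0 = wp or WarpParams()

    z0 = warp(y, wp0)
    beta0 = 1.0 / max(np.var(z0), 1e-12)
    theta0 = np.array([np.log(1e-2), np.log(beta0)])
    if not fixed_warp:
        theta0 = np.append(theta0, [wp0.a, np.log(wp0.b)])

    def unpack(theta):
        alpha = float(np.exp(np.clip(theta[0], -25, 25)))
        beta = float(np.exp(np.clip(theta[1], -25, 25)))
        if fixed_warp:
            return alpha, beta, wp0
        a = float(np.clip(theta[2], -5, 5))
        b = float(np.exp(np.clip(theta[3], -3, 3)))
        return alpha, beta, WarpParams(a, b)

    def objective(theta):
        alpha, beta, w = unpack(theta)
        val = nlml(ages, y, basis, alpha, beta, w, Phi=Phi)
        return val if np.isfinite(val) else 1e12

    if not np.isfinite(objective(theta0)):
        raise ValueError("non-finite evidence at initialization; check the response values")

    rng = np.random.default_rng(seed)
    scales = np.array([2.0, 1.0, 0.4, 0.25])[: len(theta0)]
    best = None
    for k in range(max(1, n_restarts)):
        start = theta0 if k == 0 else theta0 + scales * rng.standard_normal(len(theta0))
        res = optimize.minimize(
            objective, start, method="Nelder-Mead",
            options={"maxiter": maxiter, "fatol": tol, "xatol": 1e-5},
        )
        if best is None or res.fun < best.fun:
            best = res
    alpha, beta, w_opt = unpack(best.x)
    z = warp(y, w_opt)
    m, A = _posterior(Phi, z, alpha, beta)
    S = np.linalg.pinv(A, hermitian=True)
    return NormativeModel(
        basis=basis, m_w=m, S_w=S, alpha=alpha, beta=beta, warp=w_opt,
        nlml=float(best.fun),
    )


# ---------------------------------------------------------------------------
# prediction, centiles, deviations


def predict(model: NormativeModel, ages) -> tuple[np.ndarray, np.ndarray]:
    """Latent predictive mean and standard deviation at the given ages.

    ``m_* = phi^T m_w``; ``s_*^2 = 1/beta + phi^T S_w phi``.
    """
    Phi = design_matrix(ages, model.basis)
    m_star = Phi @ model.m_w
    s2 = 1.0 / model.beta + np.einsum("ij,jk,ik->i", Phi, model.S_w, Phi)
    return m_star, np.sqrt(s2)


def centiles(
    model: NormativeModel, ages, quantiles=DEFAULT_QUANTILES
) -> dict[float, np.ndarray]:
    """Centile curves in response units: back-transformed latent quantiles."""
    quantiles = tuple(quantiles)
    if any(not 0 < q < 1 for q in quantiles):
        raise ValueError("quantiles must lie strictly in (0, 1)")
    m_star, s_star = predict(model, ages)
    return {
        q: warp_inverse(m_star + stats.norm.ppf(q) * s_star, model.warp)
        for q in quantiles
    }


@dataclass
class DeviationReport:
    """Per-subject deviation scores with strict |Z| > 2 extreme flags."""

    z: np.ndarray
    subject_id: np.ndarray | None = None
    ev: float | None = None

    @property
    def extreme_positive(self) -> np.ndarray:
        return self.z > 2.0

    @property
    def extreme_negative(self) -> np.ndarray:
        return self.z < -2.0


def zscores(model: NormativeModel, ages, y, subject_id=None) -> DeviationReport:
    """Z = (warp(y) - m_*) / s_* ; extremes flagged by strict |Z| > 2."""
    m_star, s_star = predict(model, ages)
    z = (warp(y, model.warp) - m_star) / s_star
    return DeviationReport(z=z, subject_id=None if subject_id is None else np.asarray(subject_id))


def explained_variance(y_true, y_pred) -> float:
    """EV = 1 - Var(y_true - y_pred) / Var(y_true).

    1 means perfect mean fit, 0 matches a constant predictor, negative
    values mean the predictions are worse than a constant (no predictive
    power).
    """
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_true.size < 2:
        raise ValueError("need at least 2 observations")
    v = np.var(y_true)
    if v == 0:
        raise ValueError("zero variance in y_true")
    return float(1.0 - np.var(y_true - y_pred) / v)


# ---------------------------------------------------------------------------
# split and end-to-end per-region run


def stratified_half_split(cohort: pd.DataFrame, seed: int = 0):
    """Half split balanced on sex and age.

    Within each sex, subjects are sorted by age and assigned alternately to
    the two halves; the alternation phase of each stratum is randomized by
    the seed, subject to the constraint that the halves have equal total
    size (n/2 each; for odd n they differ by 1).  Per-sex counts between
    halves then differ by at most 1 and mean ages are closely matched.

    Returns (train_ids, test_ids) as lists of subject_id values.
    """
    rng = np.random.default_rng(seed)
    n = len(cohort)
    target = n // 2
    strata = []  # (sex, ids sorted by age)
    for sex, sub in cohort.groupby("sex", sort=True):
        ids = sub.sort_values("age")["subject_id"].tolist()
        strata.append((sex, ids))
    # phase 0 puts ceil(n_s/2) in train; choose how many odd strata use it
    n_phase0_needed = target - sum(len(ids) // 2 for _, ids in strata)
    odd = [i for i, (_, ids) in enumerate(strata) if len(ids) % 2 == 1]
    if not 0 <= n_phase0_needed <= len(odd):
        raise AssertionError("stratum sizes inconsistent with balanced halves")
    phases = {i: int(rng.integers(2)) for i in range(len(strata))}
    pick = rng.permutation(len(odd))
    for j, oi in enumerate(pick):
        phases[odd[oi]] = 0 if j < n_phase0_needed else 1
    train, test = [], []
    for i, (_, ids) in enumerate(strata):
        for rank, sid in enumerate(ids):
            (train if (rank + phases[i]) % 2 == 0 else test).append(sid)
    return train, test


@dataclass
class RegionNormativeResult:
    region: str
    model: NormativeModel
    train_ids: list
    test_ids: list
    ev_train: float
    ev_test: float
    test_report: DeviationReport
    centile_ages: np.ndarray
    centile_curves: dict[float, np.ndarray]


def run_normative(
    roi_table: pd.DataFrame,
    regions=("caudate_L", "caudate_R"),
    seed: int = 0,
    quantiles=DEFAULT_QUANTILES,
    age_grid: np.ndarray | None = None,
) -> dict[str, RegionNormativeResult]:
    """Split, fit per region on the training half, score the test half.

    ``roi_table`` must carry subject_id, age, sex and one column per
    region.  EV is computed on back-transformed median predictions;
    Z-scores are reported for the test half.
    """
    for region in regions:
        if region not in roi_table.columns:
            raise ValueError(f"region '{region}' not in table")
    train_ids, test_ids = stratified_half_split(roi_table, seed=seed)
    tr = roi_table.set_index("subject_id").loc[train_ids].reset_index()
    te = roi_table.set_index("subject_id").loc[test_ids].reset_index()
    results: dict[str, RegionNormativeResult] = {}
    for region in regions:
        model = fit(tr["age"].to_numpy(), tr[region].to_numpy(), seed=seed)
        grid = (
            np.arange(20.0, 81.5, 1.0) if age_grid is None else np.asarray(age_grid, float)
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # grid may exceed the training range
            curves = centiles(model, grid, quantiles)
            m_te, _ = predict(model, te["age"].to_numpy())
            rep = zscores(model, te["age"].to_numpy(), te[region].to_numpy(),
                          subject_id=te["subject_id"].to_numpy())
            m_tr, _ = predict(model, tr["age"].to_numpy())
        pred_te = warp_inverse(m_te, model.warp)
        pred_tr = warp_inverse(m_tr, model.warp)
        rep.ev = explained_variance(te[region].to_numpy(), pred_te)
        results[region] = RegionNormativeResult(
            region=region,
            model=model,
            train_ids=train_ids,
            test_ids=test_ids,
            ev_train=explained_variance(tr[region].to_numpy(), pred_tr),
            ev_test=rep.ev,
            test_report=rep,
            centile_ages=grid,
            centile_curves=curves,
        )
    return results
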