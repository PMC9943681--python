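"""Protection-kinetics models and bounded nonlinear least-squares fitting.

Digestion of an accessible RNA pool by a kinetically perfect RNase follows
pseudo-first-order kinetics, dR/dt = -k R A.  At a fixed digestion time t,
with a pool fraction P0 shielded from the enzyme (e.g. by organellar
membranes), the remaining fraction as a function of RNase concentration A is

    Model 1:  f(A) = (1 - P0) * exp(-k' A) + P0,     0 <= P0 <= 1, k' >= 0
    Model 2:  f(A) = exp(-k' A)                       (P0 = 0: pure contaminant)
    Model 3:  f(A) = 1                                (P0 = 1: fully protected;
                                                       implicit null, R^2 = 0)

P0 is the parameter of interest: the proportion of the transcript's pool
unavailable to digestion.  k' (per μg/ml) absorbs the bimolecular rate
constant and the fixed time, k' = k * c * t with c converting μg/ml of
enzyme into molarity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import optimize, stats

from .io import ColocError, DigestionProfile


def _lsq(*args, **kwargs):
    # scipy's TRF emits spurious divide/invalid warnings when polished to
    # machine tolerance; they carry no information here
    with np.errstate(divide="ignore", invalid="ignore"):
        return optimize.least_squares(*args, **kwargs)


EPS = 1e-12

#: RNase A molecular mass, g/mol (bovine pancreatic ribonuclease A, 13.7 kDa)
RNASE_A_MW = 13_700.0
#: digestion time used throughout, seconds (10 min)
DEFAULT_T = 600.0

MODEL1 = "model1"
MODEL2 = "model2"
MODEL3 = "model3_implicit"


@dataclass
class KineticsFit:
    """Result of fitting a digestion profile."""

    feature_id: str
    condition: str
    model: str
    P0: float
    k_prime: float
    r_squared: float
    dependency: float
    converged: bool
    n_points: int
    residual_ss: float
    P0_ci: tuple[float, float] = (np.nan, np.nan)
    k_ci: tuple[float, float] = (np.nan, np.nan)
    ci_at_bound: bool = False
    k_clamped: bool = False
    mean_f: float = np.nan

    def __post_init__(self) -> None:
        if not (0.0 <= self.P0 <= 1.0):
            raise ColocError(f"P0 out of [0,1]: {self.P0}")
        if self.k_prime < 0:
            raise ColocError(f"k_prime negative: {self.k_prime}")


@dataclass
class RateConstant:
    """Bimolecular digestion rate constant in absolute units."""

    k: float            # M^-1 s^-1
    enzyme_mw: float    # g/mol
    t: float            # s

    def __post_init__(self) -> None:
        if not math.isfinite(self.k) or self.k < 0:
            raise ColocError(f"rate constant must be finite and >= 0, got {self.k}")


def model1_eval(A, P0: float, k_prime: float):
    """Evaluate Model 1, f(A) = (1 - P0) exp(-k' A) + P0.

    Valid for A >= 0, P0 in [0, 1], k' >= 0; the value lies in [P0, 1] and is
    monotone non-increasing in A.
    """
    A = np.asarray(A, dtype=float)
    if np.any(A < 0):
        raise ColocError("RNase concentration A must be >= 0")
    if not (0.0 <= P0 <= 1.0):
        raise ColocError(f"P0 must lie in [0, 1], got {P0}")
    if k_prime < 0:
        raise ColocError(f"k_prime must be >= 0, got {k_prime}")
    out = (1.0 - P0) * np.exp(-k_prime * A) + P0
    return out if out.ndim else float(out)


def model2_eval(A, k_prime: float):
    """Evaluate Model 2, f(A) = exp(-k' A) (Model 1 with P0 = 0)."""
    return model1_eval(A, 0.0, k_prime)


def _check_profile(profile: DigestionProfile, min_points: int) -> tuple[np.ndarray, np.ndarray]:
    A, f = profile.conc, profile.f
    if not np.isfinite(f).all():
        raise ColocError(f"{profile.feature_id}: non-finite f values")
    if profile.n_points < min_points:
        raise ColocError(
            f"{profile.feature_id}/{profile.condition}: {profile.n_points} points, "
            f"need >= {min_points}")
    distinct = np.unique(A)
    if len(distinct) < 3 or 0.0 not in distinct:
        raise ColocError(
            f"{profile.feature_id}/{profile.condition}: need >= 3 distinct A values including 0")
    return A, f


def _ss(A, f, P0, k_prime) -> float:
    r = f - ((1.0 - P0) * np.exp(-k_prime * A) + P0)
    return float(r @ r)


def _r_squared(f, ss_res) -> float:
    ss_tot = float(np.sum((f - f.mean()) ** 2))
    if ss_tot <= 1e-300:  # constant data: the flat null explains everything
        return 0.0 if ss_res < 1e-12 else -np.inf
    return 1.0 - ss_res / ss_tot


def _initial_guesses(A, f) -> tuple[float, list[float]]:
    """Starting point per the fitting protocol: P0 starts at the lowest
    observed f; k' from inverting the model at the first clearly-decayed
    point, with scale-based fallbacks used as extra multistarts."""
    p0_init = float(np.clip(f.min(), 0.0, 1.0))
    pos = A > 0
    a_pos = A[pos]
    k_starts: list[float] = []
    half = (1.0 + p0_init) / 2.0
    order = np.argsort(A)
    for idx in order:
        if A[idx] > 0 and f[idx] < half:
            num = 1.0 - p0_init
            den = max(f[idx] - p0_init, EPS)
            k0 = math.log(max(num, EPS) / den) / A[idx]
            if k0 > 0 and math.isfinite(k0):
                k_starts.append(k0)
            break
    med = float(np.median(a_pos)) if len(a_pos) else 1.0
    k_starts.extend([1.0 / max(med, EPS), 0.1 / max(a_pos.min(), EPS) if len(a_pos) else 0.1,
                     5.0 / max(med, EPS)])
    # dedupe, keep order
    seen, uniq = set(), []
    for k in k_starts:
        key = round(math.log10(max(k, EPS)), 3)
        if key not in seen:
            seen.add(key)
            uniq.append(k)
    return p0_init, uniq


def fit_model1(profile: DigestionProfile, fix_p0: float | None = None,
               max_iter: int = 500, tol: float = 1e-9) -> KineticsFit:
    """Fit Model 1 by bounded least squares (trust-region damped Gauss-Newton).

    Box constraints 0 <= P0 <= 1, k' >= 0; the initial P0 is the lowest
    observed f(A); convergence tolerance 1e-9 within 500 iterations.  A small
    deterministic multistart over k' guards against the rare local minimum.
    ``fix_p0`` pins the protected fraction (fix_p0=0 reproduces Model 2).
    """
    A, f = _check_profile(profile, min_points=4)
    p0_init, k_starts = _initial_guesses(A, f)

    best = None
    for k0 in k_starts:
        if fix_p0 is None:
            def resid(theta):
                return ((1.0 - theta[0]) * np.exp(-theta[1] * A) + theta[0]) - f
            x0 = np.array([p0_init, max(k0, 1e-6)])
            res = _lsq(
                resid, x0, bounds=([0.0, 0.0], [1.0, np.inf]), method="trf",
                ftol=tol, xtol=tol, gtol=tol, max_nfev=max_iter)
            cand = (float(res.cost * 2), float(res.x[0]), float(res.x[1]), res.status > 0)
        else:
            p_fixed = float(fix_p0)
            def resid(theta):
                return ((1.0 - p_fixed) * np.exp(-theta[0] * A) + p_fixed) - f
            res = _lsq(
                resid, np.array([max(k0, 1e-6)]), bounds=([0.0], [np.inf]), method="trf",
                ftol=tol, xtol=tol, gtol=tol, max_nfev=max_iter)
            cand = (float(res.cost * 2), p_fixed, float(res.x[0]), res.status > 0)
        if best is None or cand[0] < best[0]:
            best = cand

    # polish the winning start to machine precision: the reported optimum is
    # contractually the SS minimiser, not wherever a 1e-9 step test stopped
    if fix_p0 is None:
        def resid_best(theta):
            return ((1.0 - theta[0]) * np.exp(-theta[1] * A) + theta[0]) - f
        res = _lsq(
            resid_best, np.array([best[1], max(best[2], 1e-12)]),
            bounds=([0.0, 0.0], [1.0, np.inf]), method="trf",
            ftol=None, xtol=2.3e-16, gtol=None, max_nfev=200)
        if float(res.cost * 2) <= best[0]:
            best = (float(res.cost * 2), float(res.x[0]), float(res.x[1]), best[3])

    ss, P0, k_prime, converged = best
    # also consider the flat (Model 3) corner which the optimizer may not reach
    if fix_p0 is None:
        ss_flat = _ss(A, f, 1.0, 0.0)
        p_flat = float(np.clip(f.mean(), 0.0, 1.0))  # best flat level within bounds
        ss_mean = _ss(A, f, p_flat, 0.0)
        if min(ss_flat, ss_mean) < ss:
            if ss_mean < ss_flat:
                P0, k_prime, ss = p_flat, 0.0, ss_mean
            else:
                P0, k_prime, ss = 1.0, 0.0, ss_flat

    dep = parameter_dependency_raw(A, f, P0, k_prime) if fix_p0 is None else 0.0
    return KineticsFit(
        feature_id=profile.feature_id, condition=profile.condition,
        model=MODEL1, P0=P0, k_prime=k_prime,
        r_squared=_r_squared(f, ss), dependency=dep, converged=converged,
        n_points=profile.n_points, residual_ss=ss, mean_f=float(f.mean()),
    )


def fit_model2(profile: DigestionProfile, max_iter: int = 500, tol: float = 1e-9) -> KineticsFit:
    """Fit Model 2 (pure pseudo-first-order decay), one free parameter k'.

    Fitted without constraints; a (rare) negative optimum on noisy flat data
    is clamped to k' = 0 and flagged via ``k_clamped``.
    """
    A, f = _check_profile(profile, min_points=3)
    _, k_starts = _initial_guesses(A, f)

    best = None
    for k0 in k_starts:
        def resid(theta):
            return np.exp(np.clip(-theta[0] * A, -700.0, 50.0)) - f
        res = _lsq(
            resid, np.array([max(k0, 1e-6)]), method="lm",
            ftol=tol, xtol=tol, max_nfev=max_iter)
        cand = (float(res.cost * 2), float(res.x[0]), res.status > 0)
        if best is None or cand[0] < best[0]:
            best = cand
    ss, k_prime, converged = best

    clamped = False
    if k_prime < 0:
        k_prime, clamped = 0.0, True
        ss = _ss(A, f, 0.0, 0.0)

    return KineticsFit(
        feature_id=profile.feature_id, condition=profile.condition,
        model=MODEL2, P0=0.0, k_prime=k_prime,
        r_squared=_r_squared(f, ss), dependency=0.0, converged=converged,
        n_points=profile.n_points, residual_ss=ss, P0_ci=(0.0, 0.0),
        k_clamped=clamped, mean_f=float(f.mean()),
    )


def parameter_dependency_raw(A: np.ndarray, f: np.ndarray,
                             P0: float, k_prime: float) -> float:
    """Parameter entanglement diagnostic at the Model-1 solution, in [0, 1].

    Defined as 1 - 1 / (C_ii * (C^-1)_ii) with C the Jacobian-based
    parameter covariance — the squared correlation between the P0 and k'
    estimates, identical for both parameters in a two-parameter fit.  0
    means orthogonal estimates; values near 1 mean plateau and rate cannot
    be separated (near-flat profiles).  With a parameter pinned at its box
    bound only one parameter is free and the dependency is 0 by convention;
    a singular curvature (k' = 0 makes the P0 column vanish) reports 1.
    """
    at_bound = P0 <= 1e-8 or P0 >= 1.0 - 1e-8
    if at_bound:
        return 0.0
    pos = A > 0
    a_pos = A[pos]
    if len(a_pos) and k_prime * a_pos.min() > 10.0:
        # Digestion complete before the first non-zero concentration: the
        # profile is a two-level step.  If the step height (1 - P0) clearly
        # exceeds the residual noise, P0 is pinned directly by the plateau
        # and k' is merely bounded below — one effective free parameter, not
        # an entangled pair.  An insignificant step is noise on a flat
        # profile: fully entangled.
        n_pos = int(pos.sum())
        dof = max(len(A) - 2, 1)
        sd = math.sqrt(max(float(np.sum((f - model1_eval(A, P0, k_prime)) ** 2)), EPS) / dof)
        t_step = (1.0 - P0) / (sd / math.sqrt(n_pos) + EPS)
        return 0.0 if t_step > 2.0 else 1.0
    e = np.exp(-k_prime * A)
    J = np.column_stack([1.0 - e, -(1.0 - P0) * A * e])
    JtJ = J.T @ J
    det = np.linalg.det(JtJ)
    if not np.isfinite(det) or det <= EPS * np.trace(JtJ) ** 2:
        return 1.0
    C = np.linalg.inv(JtJ)
    denom = C[0, 0] * C[1, 1]
    if denom <= 0 or not math.isfinite(denom):
        return 1.0
    return float(min(C[0, 1] ** 2 / denom, 1.0))


def parameter_dependency(fit: KineticsFit, profile: DigestionProfile) -> float:
    """Dependency diagnostic for a Model-1 fit on its profile."""
    if fit.model != MODEL1:
        return 0.0
    return parameter_dependency_raw(profile.conc, profile.f, fit.P0, fit.k_prime)


def select_model(profile: DigestionProfile, dependency_threshold: float = 0.3,
                 max_iter: int = 500, tol: float = 1e-9) -> KineticsFit:
    """Fit Model 1; fall back to Model 2 when the fit fails or is over-parameterised.

    A dependency above the threshold (default 0.3) means the plateau and the
    rate cannot be separately determined — the two-parameter model is
    unnecessarily complex for the data (typically flat profiles of fully
    protected transcripts) and the one-parameter decay is reported instead.
    """
    fit1 = err1 = None
    try:
        fit1 = fit_model1(profile, max_iter=max_iter, tol=tol)
    except ColocError as e:
        err1 = e
    if fit1 is not None and fit1.converged and fit1.dependency <= dependency_threshold:
        return fit1
    try:
        return fit_model2(profile, max_iter=max_iter, tol=tol)
    except ColocError as err2:
        if fit1 is not None:
            return fit1
        raise ColocError(
            f"{profile.feature_id}/{profile.condition}: both fits failed "
            f"(model1: {err1}; model2: {err2})") from err2


def _profile_ss(profile: DigestionProfile, param: str, value: float,
                fit: KineticsFit, max_iter: int, tol: float) -> float:
    """SS profiled over the other parameter at a pinned value of ``param``."""
    A, f = profile.conc, profile.f
    if fit.model == MODEL2:
        return _ss(A, f, 0.0, value)
    if param == "P0":
        def resid(theta):
            return ((1.0 - value) * np.exp(-theta[0] * A) + value) - f
        starts = [max(fit.k_prime, 1e-6)]
        _, extra = _initial_guesses(A, f)
        starts += extra
        best = np.inf
        for k0 in starts:
            res = _lsq(resid, [max(k0, 1e-6)], bounds=([0.0], [np.inf]),
                                         method="trf", ftol=tol, xtol=tol, max_nfev=max_iter)
            best = min(best, float(res.cost * 2))
        return best
    # pin k', profile over P0 (closed-form: linear least squares with bound)
    e = np.exp(-value * A)
    denom = float(np.sum((1.0 - e) ** 2))
    if denom == 0:
        p_hat = 0.0
    else:
        p_hat = float(np.sum((f - e) * (1.0 - e)) / denom)
    p_hat = min(max(p_hat, 0.0), 1.0)
    return _ss(A, f, p_hat, value)


def confidence_intervals(fit: KineticsFit, profile: DigestionProfile,
                         level: float = 0.95, max_iter: int = 500,
                         tol: float = 1e-9) -> KineticsFit:
    """Profile-likelihood (F-comparison) confidence intervals for P0 and k'.

    A parameter value θ lies inside the interval while

        SS(θ) <= SS_min * (1 + F(1, n - p; level) / (n - p))

    with SS(θ) minimised over the remaining parameter.  Bounds are clipped to
    the box constraints (``ci_at_bound`` set when an endpoint sits on a
    constraint or the search edge).  Zero-residual fits yield degenerate
    point intervals.
    """
    n, p = fit.n_points, (2 if fit.model == MODEL1 else 1)
    dof = n - p
    if dof <= 0:
        raise ColocError("not enough points for confidence intervals")
    ss_min = fit.residual_ss
    if ss_min <= 1e-18:  # noiseless: degenerate point interval
        return replace(fit, P0_ci=(fit.P0, fit.P0), k_ci=(fit.k_prime, fit.k_prime))
    f_crit = stats.f.ppf(level, 1, dof)
    ss_crit = ss_min * (1.0 + f_crit / dof)

    at_bound = False

    def bound(param: str, hat: float, lo_lim: float, hi_lim: float) -> tuple[float, float]:
        nonlocal at_bound

        def g(x):
            return _profile_ss(profile, param, x, fit, max_iter, tol) - ss_crit

        # lower
        if hat - lo_lim < 1e-12 or g(lo_lim) <= 0:
            lo = lo_lim
            if g(lo_lim) <= 0:
                at_bound = True
        else:
            lo = optimize.brentq(g, lo_lim, hat, xtol=1e-10)
        # upper
        if hi_lim - hat < 1e-12 or g(hi_lim) <= 0:
            hi = hi_lim
            if g(hi_lim) <= 0:
                at_bound = True
        else:
            hi = optimize.brentq(g, hat, hi_lim, xtol=1e-10)
        return lo, hi

    a_pos = profile.conc[profile.conc > 0]
    k_hi_lim = max(10.0 * max(fit.k_prime, 1.0), 50.0 / float(a_pos.min()))
    k_ci = bound("k", fit.k_prime, 0.0, k_hi_lim)
    if fit.model == MODEL1:
        p_ci = bound("P0", fit.P0, 0.0, 1.0)
    else:
        p_ci = (0.0, 0.0)
    return replace(fit, P0_ci=p_ci, k_ci=k_ci, ci_at_bound=at_bound)


def conc_to_molar(enzyme_mw: float = RNASE_A_MW) -> float:
    """mol/L of enzyme per (μg/ml): 1 μg/ml = 1e-3 g/L = 1e-3 / MW mol/L."""
    if enzyme_mw <= 0:
        raise ColocError("enzyme molecular weight must be positive")
    return 1e-3 / enzyme_mw


def convert_rate(k_prime: float, enzyme_mw: float = RNASE_A_MW,
                 t: float = DEFAULT_T) -> RateConstant:
    """Convert a fitted k' (per μg/ml at fixed time t) into a bimolecular
    rate constant k (M^-1 s^-1).

    The fitted exponent k' A equals k * A_molar * t, so k = k' / (c t) with
    c = 1e-3 / MW converting μg/ml to mol/L.  Defaults assume RNase A
    (13,700 g/mol) and t = 600 s; at k' = 1 this gives k ≈ 2.28e4 M^-1 s^-1,
    the scale of a slow RNase A substrate.
    """
    if k_prime < 0:
        raise ColocError("k_prime must be >= 0")
    if enzyme_mw <= 0 or t <= 0:
        raise ColocError("enzyme_mw and t must be positive")
    c = conc_to_molar(enzyme_mw)
    return RateConstant(k=k_prime / (c * t), enzyme_mw=enzyme_mw, t=t)


def k_to_k_prime(k: float, enzyme_mw: float = RNASE_A_MW, t: float = DEFAULT_T) -> float:
    """Inverse of :func:`convert_rate`: k' = k * c * t."""
    if k < 0 or enzyme_mw <= 0 or t <= 0:
        raise ColocError("inputs must be positive")
    return k * conc_to_molar(enzyme_mw) * t
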