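"""Weighted least-squares estimation of the disposition models.

Micro-rate models (S, U, N) and the independent biexponential macro model
are fitted by Levenberg-Marquardt least squares on log-transformed positive
parameters (positivity without explicit bounds).  Residuals are weighted by
the fractional-SD error model w_i = 1/(fsd * y_i)^2 — the SAAM-family
convention for concentration assays — and the basal lactate level carries a
Gaussian prior whose width is the standard error of the mean of the
pre-infusion replicates, appended to the residual vector as one extra row:

    SSR(theta) = sum_i [(y_i - yhat_i)/(fsd * y_i)]^2
               + [(P1 - prior.mean)/prior.sd]^2

Standard errors come from the inverse Gauss-Newton Hessian (J'J)^-1 of the
weighted problem at the optimum, mapped back to the natural scale by the
delta method; CVs are SE/estimate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .exceptions import InsufficientDataError, ParameterDomainError
from .infusion import InfusionProfile
from .model import (
    MacroParams,
    MicroParams,
    analytic_bolus_solution,
    rectangular_response,
    solve_micro,
)

_SD_FLOOR = 1e-6  # mmol/L; floor for a degenerate (zero-spread) prior


@dataclass
class KineticDataset:
    """Timed lactate observations from one infusion challenge.

    Times are minutes with the infusion starting at 0; phases are
    ``pre`` (baseline replicates, t < 0), ``infusion`` and ``post``.
    """

    times: np.ndarray
    concentrations: np.ndarray
    phase: np.ndarray
    body_weight: float
    protocol: InfusionProfile
    truth: MicroParams | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        self.phase = np.asarray(self.phase, dtype=object)
        if not (len(self.times) == len(self.concentrations) == len(self.phase)):
            raise ParameterDomainError("times/concentrations/phase lengths differ")
        bad = set(np.unique(self.phase)) - {"pre", "infusion", "post"}
        if bad:
            raise ParameterDomainError(f"unknown phase labels: {sorted(bad)}")
        if np.any(np.diff(self.times) <= 0):
            i = int(np.argmax(np.diff(self.times) <= 0)) + 1
            raise ParameterDomainError(f"times not strictly increasing at row {i}")
        order = {"pre": 0, "infusion": 1, "post": 2}
        codes = np.array([order[p] for p in self.phase])
        if np.any(np.diff(codes) < 0):
            raise ParameterDomainError("phases must be ordered pre < infusion < post")
        if np.any(self.concentrations <= 0):
            i = int(np.argmax(self.concentrations <= 0))
            raise ParameterDomainError(f"non-positive concentration at row {i}")
        if int(np.sum(self.phase == "pre")) < 3:
            raise ParameterDomainError("need >= 3 pre-infusion baseline samples")

    @property
    def pre_concentrations(self) -> np.ndarray:
        return self.concentrations[self.phase == "pre"]

    @property
    def fit_mask(self) -> np.ndarray:
        """Observations entering the kinetic fit (infusion + post phases)."""
        return self.phase != "pre"

    @property
    def infusion_end(self) -> float:
        """Nominal end of the infusion (min after start)."""
        return self.protocol.nominal_duration

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_min": self.times,
                "lactate_mmol_L": self.concentrations,
                "phase": self.phase,
            }
        )


@dataclass(frozen=True)
class BaselinePrior:
    """Gaussian prior on the basal lactate level.

    ``sd`` is the standard error of the mean of the replicates; a
    zero-spread replicate set is floored at a machine-scale width and
    flagged ``degenerate``.
    """

    mean: float
    sd: float
    n_obs: int
    degenerate: bool = False

    def __post_init__(self) -> None:
        if self.sd <= 0:
            raise ParameterDomainError("prior sd must be > 0")
        if self.n_obs < 2:
            raise ParameterDomainError("prior needs >= 2 observations")


def bayesian_baseline_prior(pre_samples: Sequence[float]) -> BaselinePrior:
    """Prior from pre-infusion replicates: mean and SEM of the samples."""
    y = np.asarray(pre_samples, dtype=float)
    if len(y) < 2:
        raise InsufficientDataError("need >= 2 pre-infusion samples for the prior")
    mean = float(np.mean(y))
    sem = float(np.std(y, ddof=1) / np.sqrt(len(y)))
    degenerate = sem < _SD_FLOOR
    return BaselinePrior(
        mean=mean, sd=max(sem, _SD_FLOOR), n_obs=len(y), degenerate=degenerate
    )


@dataclass
class FitResult:
    """Converged estimates with uncertainty and diagnostics.

    ``estimates``/``se``/``cv`` are keyed by parameter name (P1, P2 or K1,
    L01, L21, L12, DT for micro fits; A, alpha, B, beta for macro fits);
    ``cv`` is in percent.  ``objective`` is the weighted SSR including the
    prior term.
    """

    estimates: dict[str, float]
    se: dict[str, float]
    cv: dict[str, float]
    covariance: pd.DataFrame
    objective: float
    residuals: np.ndarray
    converged: bool
    n_iter: int
    model: str
    params: MicroParams | MacroParams | None = None
    prior: BaselinePrior | None = None
    baseline_fixed: float | None = None
    degenerate: bool = False
    predict: Callable[[np.ndarray], np.ndarray] | None = None

    def report_frame(self) -> pd.DataFrame:
        """Estimate / error / CV% table, one row per adjustable parameter."""
        names = list(self.estimates)
        return pd.DataFrame(
            {
                "parameter": names,
                "value": [self.estimates[n] for n in names],
                "error": [self.se[n] for n in names],
                "cv_percent": [self.cv[n] for n in names],
            }
        )


def _micro_param_names(variant: str) -> list[str]:
    scale = "K1" if variant == "S" else "P2"
    names = ["P1", scale, "L01", "L21", "L12"]
    if variant == "N":
        names = ["DT"] + names
    return names


def _micro_params_from_vector(
    x: np.ndarray, variant: str
) -> MicroParams:
    """Internal optimizer vector -> MicroParams.

    Layout: [P1 (linear), log scale, log L01, log L21, log L12, (log DT)].
    """
    p1 = x[0]
    scale = np.exp(x[1])
    l01, l21, l12 = np.exp(x[2:5])
    dt = np.exp(x[5]) if variant == "N" else None
    kw = dict(l01=l01, l21=l21, l12=l12, baseline=max(p1, 0.0), dt=dt, units_mode=variant)
    if variant == "S":
        return MicroParams(inverse_pool=scale, **kw)
    return MicroParams(pool_size=scale, **kw)


def _predict_micro(
    params: MicroParams, infusion: InfusionProfile, times: np.ndarray
) -> np.ndarray:
    """Model concentration at observation times (closed form where exact)."""
    if infusion.kind == "rectangular" and params.units_mode in ("S", "U"):
        duration = infusion.nominal_duration
    elif infusion.kind == "delay_chain" and infusion.delivery == "pump":
        duration = params.dt if params.dt is not None else infusion.nominal_duration
    else:
        traj = solve_micro(params, infusion, times=times)
        return traj.predicted_conc
    rate = infusion.dose / duration
    above = rectangular_response(params, rate, duration, times)
    return above + params.baseline


def weighted_objective(
    params: MicroParams,
    dataset: KineticDataset,
    prior: BaselinePrior | None = None,
    fsd: float = 0.05,
) -> float:
    """Weighted SSR (+ prior penalty) of a parameter set on a dataset."""
    r = _micro_residuals(params, dataset, prior, fsd)
    return float(np.sum(r * r))


def _micro_residuals(params, dataset, prior, fsd):
    mask = dataset.fit_mask
    t = dataset.times[mask]
    y = dataset.concentrations[mask]
    infusion = _protocol_for_variant(dataset, params.units_mode)
    yhat = _predict_micro(params, infusion, t)
    r = (y - yhat) / (fsd * y)
    if prior is not None:
        r = np.append(r, (params.baseline - prior.mean) / prior.sd)
    return r


def _protocol_for_variant(dataset: KineticDataset, variant: str) -> InfusionProfile:
    """What the fitting convention *assumes* the delivery was.

    Rigid models (S, U) trust the pump: rectangular delivery of the full
    dose over the intended duration.  The adjustable-duration model (N)
    assumes rectangular delivery over DT, with the delay chain sensing the
    end; DT is initialized at the intended duration and then estimated.
    True protocols that deviate (sensed or faulty pumps) are deliberately
    not handed to the rigid fits — that mismatch is the phenomenon under
    study.
    """
    proto = dataset.protocol
    dose_per_kg = (
        proto.dose if proto.mode != "S" else proto.dose / dataset.body_weight
    )
    intended = float(dataset.meta.get("intended_duration_min", proto.nominal_duration))
    if variant == "N":
        if proto.kind == "delay_chain" and proto.mode == "N":
            return proto
        return InfusionProfile(
            mode="N",
            dose=dose_per_kg,
            nominal_duration=intended,
            body_weight=dataset.body_weight,
            kind="delay_chain",
            n_cells=proto.n_cells,
            shutoff_fraction=proto.shutoff_fraction,
        )
    if proto.kind == "rectangular" and (proto.mode == "S") == (variant == "S"):
        return proto
    duration = proto.nominal_duration if proto.kind == "rectangular" else intended
    dose = dose_per_kg * dataset.body_weight if variant == "S" else dose_per_kg
    return InfusionProfile(
        mode=variant,
        dose=dose,
        nominal_duration=duration,
        body_weight=dataset.body_weight,
    )


def fit_micro(
    dataset: KineticDataset,
    variant: str = "U",
    init: dict[str, float] | None = None,
    prior: BaselinePrior | None = None,
    fsd: float = 0.05,
    use_prior: bool = True,
    optimizer_opts: dict | None = None,
) -> FitResult:
    """Fit a micro-rate model (S, U or N) to an infusion-challenge dataset.

    Pre-infusion replicates inform the basal level only through the
    Bayesian prior; the kinetic observations are the infusion and
    post-infusion phases.  Initialization is deterministic and neutral:
    rates 0.1 min^-1, pool 0.5 L/kg (K1 = 1/(0.5 * weight) in S mode),
    baseline at the prior mean, DT at the nominal duration.  If the first
    attempt fails to converge or leaves a grossly misfit objective, a small
    deterministic grid of rescaled starts is tried and the best kept.
    """
    if variant not in ("S", "U", "N"):
        raise ParameterDomainError(f"unknown model variant {variant!r}")
    if prior is None and use_prior:
        prior = bayesian_baseline_prior(dataset.pre_concentrations)
    infusion = _protocol_for_variant(dataset, variant)

    names = _micro_param_names(variant)
    init = dict(init or {})
    base0 = init.get("P1", prior.mean if prior is not None else float(np.mean(dataset.pre_concentrations)))
    if variant == "S":
        scale0 = init.get("K1", 1.0 / (0.5 * dataset.body_weight))
    else:
        scale0 = init.get("P2", 0.5)
    x0 = [base0, np.log(scale0)]
    x0 += [np.log(init.get(k, 0.1)) for k in ("L01", "L21", "L12")]
    if variant == "N":
        x0.append(np.log(init.get("DT", infusion.nominal_duration)))
    x0 = np.array(x0)

    # physiological envelope: rates 1e-4..5 min^-1, pool 0.01..5 L/kg
    # (K1 scaled by weight in S mode), DT 3..60 min, baseline 0..5 mmol/L
    if variant == "S":
        scale_lo, scale_hi = 1.0 / (5.0 * dataset.body_weight), 1.0 / (
            0.01 * dataset.body_weight
        )
    else:
        scale_lo, scale_hi = 0.01, 5.0
    lo = [0.0, np.log(scale_lo)] + [np.log(1e-4)] * 3
    hi = [5.0, np.log(scale_hi)] + [np.log(5.0)] * 3
    if variant == "N":
        lo.append(np.log(3.0))
        hi.append(np.log(60.0))
    bounds = (np.array(lo), np.array(hi))
    x0 = np.clip(x0, bounds[0] + 1e-9, bounds[1] - 1e-9)

    opts = dict(
        method="trf",
        bounds=bounds,
        x_scale="jac",
        xtol=1e-12,
        ftol=1e-12,
        gtol=1e-12,
        max_nfev=4000,
    )
    opts.update(optimizer_opts or {})

    def residual_vec(x):
        params = _micro_params_from_vector(x, variant)
        return _micro_residuals(params, dataset, prior if use_prior else None, fsd)

    n_obs = int(np.sum(dataset.fit_mask))
    best = None
    # deterministic multi-start: neutral start first, rescaled fallbacks after
    for scale_try in (1.0, 0.5, 2.0):
        x_try = x0.copy()
        x_try[2:] = x0[2:] + np.log(scale_try)
        res = least_squares(residual_vec, x_try, **opts)
        if best is None or res.cost < best.cost:
            best = res
        if best.cost < 0.5 * n_obs * 9.0:  # mean weighted residual^2 < 9
            break
    res = best

    params = _micro_params_from_vector(res.x, variant)
    est_vec = np.array(
        [res.x[0]] + list(np.exp(res.x[1:]))
    )  # natural-scale estimates in vector order
    jac = res.jac
    jtj = jac.T @ jac
    try:
        cov_int = np.linalg.inv(jtj)
        singular = False
    except np.linalg.LinAlgError:
        cov_int = np.linalg.pinv(jtj)
        singular = True
        warnings.warn(
            "singular Hessian: parameters weakly identifiable, SEs from "
            "pseudo-inverse",
            RuntimeWarning,
            stacklevel=2,
        )
    # delta method: d(natural)/d(internal) is 1 for P1, value for log params
    d = np.ones_like(est_vec)
    d[1:] = est_vec[1:]
    cov = cov_int * np.outer(d, d)

    order = _vector_to_report_order(variant)
    est = {name: float(est_vec[i]) for name, i in order.items()}
    se = {name: float(np.sqrt(max(cov[i, i], 0.0))) for name, i in order.items()}
    cv = {
        name: (100.0 * se[name] / abs(est[name]) if est[name] != 0 else np.nan)
        for name in est
    }
    cov_df = pd.DataFrame(
        cov[np.ix_(list(order.values()), list(order.values()))],
        index=list(order),
        columns=list(order),
    )
    converged = bool(res.success) and res.status > 0

    def predict(times):
        return _predict_micro(params, infusion, np.asarray(times, dtype=float))

    return FitResult(
        estimates={k: est[k] for k in names},
        se={k: se[k] for k in names},
        cv={k: cv[k] for k in names},
        covariance=cov_df,
        objective=float(2.0 * res.cost),
        residuals=res.fun,
        converged=converged,
        n_iter=int(res.nfev),
        model=variant,
        params=params,
        prior=prior if use_prior else None,
        degenerate=singular,
        predict=predict,
    )


def _vector_to_report_order(variant: str) -> dict[str, int]:
    scale = "K1" if variant == "S" else "P2"
    order = {"P1": 0, scale: 1, "L01": 2, "L21": 3, "L12": 4}
    if variant == "N":
        order["DT"] = 5
        order = {"DT": 5, **{k: v for k, v in order.items()}}
    return order


def fit_macro(
    dataset: KineticDataset,
    baseline: float | None = None,
    init: dict[str, float] | None = None,
    fsd: float = 0.05,
    optimizer_opts: dict | None = None,
) -> FitResult:
    """Biexponential fit to the post-infusion decay.

    Fits C(t') = A e^(-alpha t') + B e^(-beta t') + baseline with t' the
    time since the end of the infusion and the baseline *fixed* at the
    pre-infusion mean (the uniform-offset convention).  Labels are resolved
    by sorting alpha > beta at convergence.
    """
    mask = dataset.phase == "post"
    if int(mask.sum()) < 6:
        raise InsufficientDataError("macro fit needs >= 6 post-infusion points")
    t = dataset.times[mask] - dataset.infusion_end
    y = dataset.concentrations[mask]
    if baseline is None:
        baseline = float(np.mean(dataset.pre_concentrations))

    amp0 = max(float(np.max(y) - baseline), 1e-3)
    init = dict(init or {})
    x0 = np.log(
        [
            init.get("A", amp0 / 2.0),
            init.get("alpha", 0.1),
            init.get("B", amp0 / 2.0),
            init.get("beta", 0.01),
        ]
    )
    bounds = (np.log([1e-4, 1e-4, 1e-4, 1e-4]), np.log([50.0, 5.0, 50.0, 5.0]))
    x0 = np.clip(x0, bounds[0] + 1e-9, bounds[1] - 1e-9)
    opts = dict(
        method="trf",
        bounds=bounds,
        x_scale="jac",
        xtol=1e-12,
        ftol=1e-12,
        gtol=1e-12,
        max_nfev=4000,
    )
    opts.update(optimizer_opts or {})

    def residual_vec(x):
        a, al, b, be = np.exp(x)
        yhat = a * np.exp(-al * t) + b * np.exp(-be * t) + baseline
        return (y - yhat) / (fsd * y)

    best = None
    for al0, be0 in ((None, None), (0.05, 0.003), (0.3, 0.03)):
        x_try = x0.copy()
        if al0 is not None:
            x_try[1], x_try[3] = np.log(al0), np.log(be0)
        res = least_squares(residual_vec, x_try, **opts)
        if best is None or res.cost < best.cost:
            best = res
        if best.cost < 0.5 * len(t) * 9.0:
            break
    res = best

    vals = np.exp(res.x)
    jtj = res.jac.T @ res.jac
    try:
        cov_int = np.linalg.inv(jtj)
        singular = False
    except np.linalg.LinAlgError:
        cov_int = np.linalg.pinv(jtj)
        singular = True
    cov = cov_int * np.outer(vals, vals)

    names = ["A", "alpha", "B", "beta"]
    idx = list(range(4))
    degenerate = singular
    if vals[1] < vals[3]:  # enforce alpha > beta by label swap
        idx = [2, 3, 0, 1]
        vals = vals[idx]
        cov = cov[np.ix_(idx, idx)]
    if abs(vals[1] - vals[3]) < 1e-3 * vals[1] or vals[2] < 1e-6 * vals[0]:
        degenerate = True
        warnings.warn(
            "macro fit degenerate: phases indistinguishable or slow phase "
            "collapsed",
            RuntimeWarning,
            stacklevel=2,
        )

    est = dict(zip(names, map(float, vals)))
    se = {n: float(np.sqrt(max(cov[i, i], 0.0))) for i, n in enumerate(names)}
    cv = {n: 100.0 * se[n] / abs(est[n]) for n in names}
    macro = MacroParams(est["A"], est["alpha"], est["B"], est["beta"], validate=not degenerate)

    def predict(times):
        tt = np.asarray(times, dtype=float)
        return analytic_bolus_solution(macro, tt) + baseline

    return FitResult(
        estimates=est,
        se=se,
        cv=cv,
        covariance=pd.DataFrame(cov, index=names, columns=names),
        objective=float(2.0 * res.cost),
        residuals=res.fun,
        converged=bool(res.success),
        n_iter=int(res.nfev),
        model="macro",
        params=macro,
        baseline_fixed=baseline,
        degenerate=degenerate,
        predict=predict,
    )


def kinetic_impute(
    macro_fit: FitResult,
    extra_times: Sequence[float],
    span: tuple[float, float] | None = None,
) -> pd.DataFrame:
    """Pseudo-observations from a converged macro fit.

    Returns a frame of (time since infusion end, concentration, imputed)
    rows.  Imputed points are tagged so downstream fits can exclude them
    from standard errors by default or include them with an inflated
    fractional SD.  Extrapolation beyond 1.5x the fitted span is allowed
    but warned about.
    """
    if not macro_fit.converged:
        raise ParameterDomainError("kinetic imputation requires a converged macro fit")
    t = np.asarray(extra_times, dtype=float)
    if span is not None:
        lo, hi = span
        limit = lo + 1.5 * (hi - lo)
        if np.any(t > limit):
            warnings.warn(
                "imputing beyond 1.5x the observed span; predictions are "
                "extrapolations",
                RuntimeWarning,
                stacklevel=2,
            )
    conc = macro_fit.predict(t)
    return pd.DataFrame({"time_min": t, "lactate_mmol_L": conc, "imputed": True})
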