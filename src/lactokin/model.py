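"""Two-compartment lactate disposition model.

The central (sampled blood) pool F1 exchanges with a peripheral pool F2 and
loses lactate irreversibly from F1.  Fractional transfer rates follow the
``L(i, j)`` convention of the SAAM family of compartmental tools: ``L(i, j)``
is the fractional rate of flow *to* compartment ``i`` *from* compartment
``j`` (min^-1), so

    dF1/dt = L12*F2 - L21*F1 - L01*F1 + G1 + G2
    dF2/dt = L21*F1 - L12*F2

where G1 is the exogenous (infusion) input and G2 the endogenous (metabolic)
input.  States are *increments above the basal steady state*; the basal
level enters predictions as an additive offset and endogenous production is
recovered afterwards from the basal steady-state identity (see
:mod:`lactokin.dependencies`).

Amount units depend on the modeling convention:

``S`` (simple)
    amounts in mmol for the whole animal; the scale parameter is K1, the
    inverse pool size (L^-1).
``U`` (unit)
    amounts in mmol/kg; the scale parameter is the pool size P2 (L/kg).
``N`` (novel)
    same units as ``U``, with infusion delivery smoothed and sensed through
    an Erlang delay chain whose transit time DT is an adjustable parameter.

Because the system is linear and the inputs used in practice are piecewise
constant, solutions are available both in closed form (biexponential) and by
exact piecewise matrix-exponential propagation; an adaptive stiff integrator
(LSODA) is kept as a fully general path and as an independent cross-check.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import TYPE_CHECKING, Sequence

import numpy as np
from scipy.integrate import solve_ivp
from scipy.linalg import expm

from .exceptions import (
    DegenerateModelError,
    InconsistentMacroError,
    IntegrationError,
    ParameterDomainError,
)

if TYPE_CHECKING:  # pragma: no cover
    from .infusion import InfusionProfile

UNITS_MODES = ("S", "U", "N")


@dataclass(frozen=True)
class MicroParams:
    """Micro rate-constant parameterization of the two-compartment model.

    Parameters
    ----------
    l01, l21, l12 : float
        Fractional rates (min^-1): irreversible loss from the central pool,
        forward transfer central -> peripheral, and return transfer
        peripheral -> central.
    baseline : float
        Basal blood lactate concentration P1 (mmol/L), the uniform offset
        added to model predictions.
    pool_size : float, optional
        Central pool size P2 (L/kg); required in U and N modes.
    inverse_pool : float, optional
        Inverse pool size K1 (L^-1); required in S mode.
    dt : float, optional
        Delay-chain transit time DT (min); required in N mode.
    units_mode : {"S", "U", "N"}
        Modeling convention (see module docstring).
    """

    l01: float
    l21: float
    l12: float
    baseline: float
    pool_size: float | None = None
    inverse_pool: float | None = None
    dt: float | None = None
    units_mode: str = "U"

    def __post_init__(self) -> None:
        if self.units_mode not in UNITS_MODES:
            raise ParameterDomainError(
                f"units_mode must be one of {UNITS_MODES}, got {self.units_mode!r}"
            )
        for name in ("l01", "l21", "l12"):
            if not np.isfinite(getattr(self, name)) or getattr(self, name) <= 0:
                raise ParameterDomainError(f"{name} must be a positive rate (min^-1)")
        if self.baseline < 0:
            raise ParameterDomainError("baseline must be >= 0 mmol/L")
        if self.units_mode == "S":
            if self.inverse_pool is None or self.inverse_pool <= 0:
                raise ParameterDomainError("S mode requires inverse_pool K1 > 0")
        else:
            if self.pool_size is None or self.pool_size <= 0:
                raise ParameterDomainError("U/N modes require pool_size P2 > 0")
        if self.units_mode == "N" and (self.dt is None or self.dt <= 0):
            raise ParameterDomainError("N mode requires delay transit time DT > 0")

    @property
    def volume(self) -> float:
        """Apparent central volume V1 (L/kg in U/N mode, L in S mode)."""
        if self.units_mode == "S":
            return 1.0 / self.inverse_pool
        return self.pool_size

    @property
    def rate_matrix(self) -> np.ndarray:
        """2x2 compartmental rate matrix [[-(L01+L21), L12], [L21, -L12]]."""
        return np.array(
            [[-(self.l01 + self.l21), self.l12], [self.l21, -self.l12]]
        )


@dataclass(frozen=True)
class MacroParams:
    """Biexponential (macro constant) description C(t) = A e^-at + B e^-bt.

    ``alpha`` is the fast eigen-rate and ``beta`` the slow one; coefficients
    are above-baseline concentrations (mmol/L).
    """

    A: float
    alpha: float
    B: float
    beta: float
    validate: bool = True

    def __post_init__(self) -> None:
        if not self.validate:
            return
        for name in ("A", "alpha", "B", "beta"):
            if getattr(self, name) <= 0:
                raise ParameterDomainError(f"macro constant {name} must be > 0")
        if self.alpha <= self.beta:
            raise ParameterDomainError("requires alpha > beta (fast > slow phase)")

    def sorted(self) -> "MacroParams":
        """Return a copy with (A, alpha) holding the faster phase."""
        if self.alpha >= self.beta:
            return self
        return replace(self, A=self.B, alpha=self.beta, B=self.A, beta=self.alpha)


@dataclass
class StateTrajectory:
    """Solution of the state equations on a time grid.

    ``f1``/``f2`` are increments above basal (mmol/kg in U/N, mmol in S);
    ``cumulative_loss`` integrates the irreversible loss L01*F1;
    ``cumulative_input`` integrates all exogenous + endogenous input;
    ``chain`` holds delay-cell contents for N-mode solutions.
    """

    times: np.ndarray
    f1: np.ndarray
    f2: np.ndarray
    cumulative_loss: np.ndarray
    predicted_conc: np.ndarray
    cumulative_input: np.ndarray
    chain: np.ndarray | None = None

    def mass_balance_residual(self) -> np.ndarray:
        """F1 + F2 + chain + loss - input; zero for an exact solution."""
        total = self.f1 + self.f2 + self.cumulative_loss
        if self.chain is not None:
            total = total + self.chain.sum(axis=1)
        return total - self.cumulative_input


def micro_rhs(
    state: Sequence[float],
    params: MicroParams,
    exogenous_rate: float = 0.0,
    endogenous_rate: float = 0.0,
) -> tuple[float, float]:
    """Right-hand side of the two-compartment state equations.

    Returns (dF1/dt, dF2/dt) in the amount units of the inputs.
    """
    f1, f2 = state
    df1 = (
        params.l12 * f2
        - params.l21 * f1
        - params.l01 * f1
        + exogenous_rate
        + endogenous_rate
    )
    df2 = params.l21 * f1 - params.l12 * f2
    return df1, df2


def eigen_rates(l01: float, l21: float, l12: float) -> tuple[float, float]:
    """Exact eigen-rates (alpha, beta) of the two-compartment system.

    alpha + beta = L01 + L21 + L12 and alpha * beta = L01 * L12; the
    discriminant (L01 + L21 - L12)^2 + 4 L21 L12 is nonnegative for any
    positive rates, so both eigen-rates are real.
    """
    s = l01 + l21 + l12
    p = l01 * l12
    # cancellation-free discriminant: s^2 - 4p == (l01 + l21 - l12)^2 + 4 l21 l12
    disc = (l01 + l21 - l12) ** 2 + 4.0 * l21 * l12
    alpha = 0.5 * (s + np.sqrt(disc))
    beta = p / alpha  # stable for beta << alpha
    return alpha, beta


def macro_from_micro(params: MicroParams, dose: float = 1.0) -> MacroParams:
    """Macro constants equivalent to a micro-rate model, for a bolus ``dose``.

    The eigen-rates come from the rate matrix; the coefficients are the
    standard two-compartment bolus identities

        A = (D/V1) (alpha - L12) / (alpha - beta)
        B = (D/V1) (L12 - beta) / (alpha - beta)

    ``dose`` is in the amount units of ``params.units_mode`` (mmol/kg for
    U/N, mmol for S).  The one-compartment limit (L21 or L12 -> 0) is
    degenerate for this parameterization and is flagged with a warning.
    """
    alpha, beta = eigen_rates(params.l01, params.l21, params.l12)
    v1 = params.volume
    if beta < 1e-12 * alpha:
        warnings.warn(
            "beta ~ 0: system is effectively one-compartment (degenerate)",
            RuntimeWarning,
            stacklevel=2,
        )
        return MacroParams(dose / v1, alpha, 0.0, beta, validate=False)
    a_coef = (dose / v1) * (alpha - params.l12) / (alpha - beta)
    b_coef = (dose / v1) * (params.l12 - beta) / (alpha - beta)
    return MacroParams(a_coef, alpha, b_coef, beta)


def micro_from_macro(macro: MacroParams) -> dict[str, float]:
    """Micro rates implied by bolus macro constants.

    Uses the standard identities L12 = (A b + B a)/(A + B),
    L01 = a b / L12, L21 = a + b - L12 - L01.  Raises
    :class:`InconsistentMacroError` if any implied rate is non-positive and
    :class:`DegenerateModelError` when alpha == beta.
    """
    a, al, b, be = macro.A, macro.alpha, macro.B, macro.beta
    if abs(al - be) <= 1e-12 * al:
        raise DegenerateModelError("alpha == beta: micro rates are not identifiable")
    l12 = (a * be + b * al) / (a + b)
    l01 = al * be / l12
    l21 = al + be - l12 - l01
    rates = {"l01": l01, "l21": l21, "l12": l12}
    bad = [k for k, v in rates.items() if v <= 0]
    if bad:
        raise InconsistentMacroError(
            f"macro constants imply non-positive rates: {bad}"
        )
    return rates


def analytic_bolus_solution(macro: MacroParams, t: np.ndarray | float) -> np.ndarray:
    """Above-baseline concentration A e^-alpha.t + B e^-beta.t (mmol/L)."""
    t = np.asarray(t, dtype=float)
    return macro.A * np.exp(-macro.alpha * t) + macro.B * np.exp(-macro.beta * t)


def rectangular_response(
    params: MicroParams,
    rate: float,
    duration: float,
    times: np.ndarray,
) -> np.ndarray:
    """Closed-form above-baseline concentration for a rectangular infusion.

    ``rate`` is the constant delivery rate into the central compartment on
    [0, duration) in amount units per minute.  Times before zero return 0.
    This is the exact solution (convolution of the biexponential unit
    impulse response with the rectangle) and is the fast path used during
    fitting.
    """
    alpha, beta = eigen_rates(params.l01, params.l21, params.l12)
    v1 = params.volume
    denom = v1 * (alpha - beta)
    a_unit = (alpha - params.l12) / denom  # unit-bolus coefficients
    b_unit = (params.l12 - beta) / denom
    t = np.asarray(times, dtype=float)
    out = np.zeros_like(t)
    on = (t > 0) & (t <= duration)
    off = t > duration
    if np.any(on):
        tt = t[on]
        out[on] = rate * (
            a_unit * (1.0 - np.exp(-alpha * tt)) / alpha
            + b_unit * (1.0 - np.exp(-beta * tt)) / beta
        )
    if np.any(off):
        tp = t[off] - duration
        out[off] = rate * (
            a_unit * (1.0 - np.exp(-alpha * duration)) / alpha * np.exp(-alpha * tp)
            + b_unit * (1.0 - np.exp(-beta * duration)) / beta * np.exp(-beta * tp)
        )
    return out


def predict_concentration(
    f1: np.ndarray | float, params: MicroParams
) -> np.ndarray:
    """Blood concentration from the central-pool increment.

    U/N mode: C = F1/P2 + baseline; S mode: C = K1*F1 + baseline.  Both
    reduce to F1/V1 + baseline.
    """
    return np.asarray(f1, dtype=float) / params.volume + params.baseline


# ---------------------------------------------------------------------------
# piecewise-linear system assembly and propagation


def _system_matrices(
    params: MicroParams, infusion: "InfusionProfile", endogenous_rate: float
):
    """Assemble (M, segments, n_chain) for the piecewise-constant system.

    State layout: [chain cells...] + [F1, F2, cumulative_loss].  Segments
    are (t_start, t_end, input_vector) with constant input over each span.
    """
    n_chain = 0
    if infusion is None:
        # free decay from an initial state (e.g. a bolus), no pump
        n = 3
        m = np.zeros((n, n))
        i1, i2, il = 0, 1, 2
        pump_rate = 0.0
        pump_end = 0.0
    elif infusion.kind == "delay_chain" and infusion.delivery == "chain_exit":
        # smoothed-delivery variant: the chain sits in the mass path
        n_chain = infusion.n_cells
        dt_chain = params.dt if params.dt is not None else infusion.nominal_duration
        k = n_chain / dt_chain
        n = n_chain + 3
        m = np.zeros((n, n))
        for i in range(n_chain):
            m[i, i] = -k
            if i > 0:
                m[i, i - 1] = k
        i1, i2, il = n_chain, n_chain + 1, n_chain + 2
        m[i1, n_chain - 1] = k  # chain exit feeds the central pool
        pump_rate = infusion.dose / dt_chain
        pump_end = dt_chain
    elif infusion.kind == "delay_chain":
        # sensing configuration (default): delivery is the pump itself,
        # running at dose/DT for the adjustable duration DT; the chain is
        # an auxiliary monitor outside the mass path
        dt_chain = params.dt if params.dt is not None else infusion.nominal_duration
        n = 3
        m = np.zeros((n, n))
        i1, i2, il = 0, 1, 2
        pump_rate = infusion.dose / dt_chain
        pump_end = dt_chain
    elif infusion.kind == "rectangular":
        n = 3
        m = np.zeros((n, n))
        i1, i2, il = 0, 1, 2
        pump_rate = infusion.dose / infusion.nominal_duration
        pump_end = infusion.nominal_duration
    else:
        raise ValueError(
            f"piecewise-constant path does not support kind={infusion.kind!r}"
        )
    m[i1, i1] = -(params.l01 + params.l21)
    m[i1, i2] = params.l12
    m[i2, i1] = params.l21
    m[i2, i2] = -params.l12
    m[il, i1] = params.l01

    b_on = np.zeros(n)
    b_on[0] = pump_rate  # pump feeds cell 1 (chain) or F1 directly (n=3)
    b_on[i1] += endogenous_rate
    b_off = np.zeros(n)
    b_off[i1] = endogenous_rate
    segments = [(0.0, pump_end, b_on), (pump_end, np.inf, b_off)]
    return m, segments, n_chain


def _piecewise_expm_solve(
    m: np.ndarray, segments, times: np.ndarray, x0: np.ndarray | None = None
) -> np.ndarray:
    """Exact solution of x' = M x + b(t) with piecewise-constant b.

    Returns states at the requested (sorted, nonnegative) times using the
    augmented-matrix exponential exp([[M, b], [0, 0]] dt); matrix
    exponentials are batched over time points.
    """
    n = m.shape[0]
    out = np.zeros((len(times), n))
    x = np.zeros(n) if x0 is None else np.asarray(x0, dtype=float)
    out[times <= 0] = x
    for t0, t1, b in segments:
        maug = np.zeros((n + 1, n + 1))
        maug[:n, :n] = m
        maug[:n, n] = b
        mask = (times > t0) & (times <= t1)
        xaug = np.append(x, 1.0)
        if np.any(mask):
            dts = times[mask] - t0
            ph = expm(dts[:, None, None] * maug)
            out[mask] = (ph @ xaug)[:, :n]
        if not np.isfinite(t1):
            break
        x = (expm(maug * (t1 - t0)) @ xaug)[:n]
    return out


def solve_micro(
    params: MicroParams,
    infusion: "InfusionProfile | None",
    endogenous_rate: float = 0.0,
    times: np.ndarray | Sequence[float] | None = None,
    method: str = "auto",
    rtol: float = 1e-8,
    atol: float = 1e-10,
    initial: tuple[float, float] = (0.0, 0.0),
) -> StateTrajectory:
    """Solve the state equations under an infusion and return a trajectory.

    Parameters
    ----------
    params : MicroParams
    infusion : InfusionProfile or None
        Exogenous delivery G1.  Rectangular and delay-chain profiles admit
        the exact piecewise matrix-exponential path; arbitrary ``custom``
        profiles fall back to LSODA.  ``None`` means free decay from the
        ``initial`` state (e.g. a bolus placed in the central pool at t=0).
    endogenous_rate : float
        Constant extra input G2 into the central pool (amount/min).  Zero
        under the incremental-state convention.
    times : array-like
        Output grid (min); values at or before 0 return the initial state.
    method : {"auto", "expm", "lsoda"}
        "expm" is exact for piecewise-constant inputs; "lsoda" is the
        adaptive stiff integrator (also the only option for custom
        profiles), integrated segment-by-segment so the input discontinuity
        at the infusion switch is never smoothed over.
    initial : (float, float)
        Initial (F1, F2) increments above basal, amount units.
    """
    if times is None:
        raise ValueError("times grid is required")
    times = np.asarray(times, dtype=float)
    if np.any(np.diff(times) <= 0):
        raise ValueError("times must be strictly increasing")

    kind = "none" if infusion is None else infusion.kind
    if method == "auto":
        method = "lsoda" if kind == "custom" else "expm"
    if method == "expm" and kind == "custom":
        raise ValueError("custom infusion profiles require method='lsoda'")

    if method == "expm":
        m, segments, n_chain = _system_matrices(params, infusion, endogenous_rate)
        x0 = np.zeros(m.shape[0])
        x0[n_chain], x0[n_chain + 1] = initial
        states = _piecewise_expm_solve(m, segments, times, x0)
    elif method == "lsoda":
        states, n_chain = _lsoda_solve(
            params, infusion, endogenous_rate, times, rtol, atol, initial
        )
    else:
        raise ValueError(f"unknown method {method!r}")

    chain = states[:, :n_chain] if n_chain else None
    f1 = states[:, n_chain]
    f2 = states[:, n_chain + 1]
    loss = states[:, n_chain + 2]
    tpos = np.clip(times, 0.0, None)
    if kind == "none":
        cum_in = np.zeros_like(tpos)
    elif kind == "rectangular":
        cum_in = (infusion.dose / infusion.nominal_duration) * np.minimum(
            tpos, infusion.nominal_duration
        )
    elif kind == "delay_chain":
        dtc = params.dt if params.dt is not None else infusion.nominal_duration
        cum_in = (infusion.dose / dtc) * np.minimum(tpos, dtc)
    else:
        cum_in = infusion.delivered(times)
    cum_in = cum_in + endogenous_rate * tpos
    return StateTrajectory(
        times=times,
        f1=f1,
        f2=f2,
        cumulative_loss=loss,
        predicted_conc=predict_concentration(f1, params),
        cumulative_input=cum_in,
        chain=chain,
    )


def _lsoda_solve(params, infusion, endogenous_rate, times, rtol, atol, initial=(0.0, 0.0)):
    """Adaptive-integrator path; handles arbitrary rate functions."""
    if infusion is None or infusion.kind in ("rectangular", "delay_chain"):
        m, segments, n_chain = _system_matrices(params, infusion, endogenous_rate)
        breakpoints = sorted({t for t0, t1, _ in segments for t in (t0, t1) if np.isfinite(t)})

        def seg_input(t):
            for t0, t1, b in segments:
                if t0 <= t < t1:
                    return b
            return segments[-1][2]

        def rhs(t, x):
            return m @ x + seg_input(t)

        n = m.shape[0]
    else:
        n_chain = 0
        n = 3

        def rhs(t, x):
            g1 = infusion.rate(t)
            df1, df2 = micro_rhs(x[:2], params, g1, endogenous_rate)
            return [df1, df2, params.l01 * x[0]]

        breakpoints = list(infusion.breakpoints())

    x_init = np.zeros(n)
    x_init[n_chain], x_init[n_chain + 1] = initial
    t_pos = times[times > 0]
    out = np.zeros((len(times), n))
    out[times <= 0] = x_init
    if len(t_pos) == 0:
        return out, n_chain
    t_end = float(t_pos.max())
    edges = [0.0] + [b for b in breakpoints if 0.0 < b < t_end] + [t_end]
    x = x_init
    sols = {}
    for a, b in zip(edges[:-1], edges[1:]):
        t_eval = t_pos[(t_pos > a) & (t_pos <= b)]
        sol = solve_ivp(
            rhs,
            (a, b),
            x,
            method="LSODA",
            t_eval=np.unique(np.append(t_eval, b)),
            rtol=rtol,
            atol=atol,
        )
        if not sol.success:  # pragma: no cover - defensive
            raise IntegrationError(f"LSODA failed on [{a}, {b}]: {sol.message}")
        for tt, col in zip(sol.t, sol.y.T):
            sols[round(float(tt), 12)] = col
        x = sol.y[:, -1]
    for i, tt in enumerate(times):
        if tt <= 0:
            continue
        out[i] = sols[round(float(tt), 12)]
    return out, n_chain
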