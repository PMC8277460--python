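"""Infusion delivery representations.

Three ways of portraying an intravenous infusion of total dose D over a
nominal duration T:

* **rectangular** (S and U conventions): the pump is trusted — delivery runs
  at exactly D/T for exactly T minutes and then switches off.
* **delay chain** (N convention): the pump runs at dose/DT for an
  *adjustable* duration DT, and a parallel n-cell chain of first-order
  compartments (total transit time DT; impulse response Erlang(n, n/DT)
  with mean DT and variance DT^2/n) receives a copy of the pump signal and
  acts as a *sensor*: the end of the infusion is detected once the
  cumulative chain exit reaches a set fraction of the dose.  Because DT is
  estimated, a pump that ran slow or long is absorbed into the fit.  A
  smoothed-delivery variant (``delivery="chain_exit"``), in which the chain
  sits in the mass path and the blood receives the Erlang-smoothed exit
  rate, is available for exploring soft onset/offset delivery.
* **custom**: arbitrary nonnegative rate functions, used to emulate pump
  faults.

Fractional rates are per minute in every convention; amounts are mmol in S
mode and mmol/kg in U/N mode, so converting a profile between conventions
only rescales the dose by body weight.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Callable, Sequence

import numpy as np
from scipy.optimize import brentq
from scipy.special import gammainc

from .exceptions import ConversionError, DetectionError, ParameterDomainError

__all__ = [
    "InfusionProfile",
    "DelayChain",
    "rectangular_infusion",
    "delay_chain_rhs",
    "chain_exit_rate",
    "chain_cumulative_exit",
    "novel_infusion_profile",
    "detect_infusion_end",
    "sense_end_time",
    "convert_units",
]


@dataclass(frozen=True)
class InfusionProfile:
    """Time-varying exogenous lactate delivery.

    ``dose`` is the total amount in the units of ``mode`` (mmol in S,
    mmol/kg in U/N).  For ``kind="delay_chain"`` the pump runs at
    dose/DT for DT minutes into the chain; ``rate`` then reports the
    smoothed delivery into the central compartment.
    """

    mode: str  # S, U or N
    dose: float
    nominal_duration: float
    body_weight: float | None = None
    kind: str = "rectangular"  # rectangular | delay_chain | custom
    n_cells: int = 8
    shutoff_fraction: float = 0.99
    delivery: str = "pump"  # delay_chain only: "pump" | "chain_exit"
    rate_fn: Callable[[float], float] | None = None
    delivered_fn: Callable[[np.ndarray], np.ndarray] | None = None
    custom_breakpoints: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        if self.mode not in ("S", "U", "N"):
            raise ParameterDomainError(f"unknown units mode {self.mode!r}")
        if self.dose <= 0 or self.nominal_duration <= 0:
            raise ParameterDomainError("dose and duration must be positive")
        if self.kind == "delay_chain":
            if self.n_cells < 1:
                raise ParameterDomainError("delay chain needs n_cells >= 1")
            if not 0.0 < self.shutoff_fraction < 1.0:
                raise ParameterDomainError("shutoff_fraction must lie in (0, 1)")
        if self.kind == "custom" and self.rate_fn is None:
            raise ParameterDomainError("custom profiles require rate_fn")
        if self.delivery not in ("pump", "chain_exit"):
            raise ParameterDomainError(f"unknown delivery {self.delivery!r}")

    # -- delivery into the central compartment --------------------------------
    def rate(self, t: np.ndarray | float) -> np.ndarray:
        """Delivery rate into the central compartment at time t."""
        t = np.asarray(t, dtype=float)
        if self.kind == "rectangular" or (
            self.kind == "delay_chain" and self.delivery == "pump"
        ):
            r = self.dose / self.nominal_duration
            return np.where((t >= 0) & (t < self.nominal_duration), r, 0.0)
        if self.kind == "delay_chain":
            return chain_exit_rate(
                t, self.dose, self.nominal_duration, self.n_cells
            )
        return np.vectorize(self.rate_fn, otypes=[float])(t)

    def delivered(self, t: np.ndarray | float) -> np.ndarray:
        """Cumulative amount delivered into the central compartment by t."""
        t = np.asarray(t, dtype=float)
        if self.kind == "rectangular" or (
            self.kind == "delay_chain" and self.delivery == "pump"
        ):
            return (self.dose / self.nominal_duration) * np.clip(
                t, 0.0, self.nominal_duration
            )
        if self.kind == "delay_chain":
            return chain_cumulative_exit(
                t, self.dose, self.nominal_duration, self.n_cells
            )
        if self.delivered_fn is not None:
            return self.delivered_fn(t)
        # numeric fallback for custom rates
        scalar = t.ndim == 0
        tt = np.atleast_1d(t)
        out = np.empty_like(tt)
        for i, ti in enumerate(tt):
            if ti <= 0:
                out[i] = 0.0
                continue
            grid = np.linspace(0.0, ti, 2049)
            out[i] = np.trapezoid(self.rate(grid), grid)
        return out[0] if scalar else out

    def breakpoints(self) -> tuple[float, ...]:
        """Times where the delivery rate is non-smooth (for integrators)."""
        if self.kind in ("rectangular", "delay_chain"):
            return (0.0, self.nominal_duration)
        return self.custom_breakpoints


@dataclass
class DelayChain:
    """An n-cell first-order delay line with total transit time DT (min).

    Each cell drains at k = n/DT so an impulse exits as an Erlang(n, k)
    density: mean transit DT, variance DT^2/n.
    """

    n_cells: int = 8
    dt: float = 15.0
    cell_contents: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.n_cells < 1:
            raise ParameterDomainError("n_cells must be >= 1")
        if self.dt <= 0:
            raise ParameterDomainError("DT must be > 0")
        if self.cell_contents is None:
            self.cell_contents = np.zeros(self.n_cells)
        else:
            self.cell_contents = np.asarray(self.cell_contents, dtype=float)
            if self.cell_contents.shape != (self.n_cells,):
                raise ParameterDomainError("cell_contents length must equal n_cells")

    @property
    def k(self) -> float:
        """Per-cell drain rate n/DT (min^-1)."""
        return self.n_cells / self.dt


def delay_chain_rhs(
    chain: DelayChain, input_rate: float
) -> tuple[np.ndarray, float]:
    """Derivatives of the cell contents and the instantaneous exit rate."""
    k = chain.k
    c = chain.cell_contents
    dc = np.empty_like(c)
    dc[0] = input_rate - k * c[0]
    dc[1:] = k * c[:-1] - k * c[1:]
    return dc, k * c[-1]


def _erlang_cdf_sum(n: int, x: np.ndarray) -> np.ndarray:
    """Sum_{i=1..n} P(i, x) with P the regularized lower incomplete gamma."""
    x = np.asarray(x, dtype=float)
    total = np.zeros_like(x)
    for i in range(1, n + 1):
        total += gammainc(i, np.clip(x, 0.0, None))
    return total


def chain_exit_rate(
    t: np.ndarray | float, dose: float, dt: float, n_cells: int = 8
) -> np.ndarray:
    """Exit rate of an n-cell chain fed at dose/dt for dt minutes.

    Closed form: the exit of a step input is r * P(n, k t); superposing the
    switch-off at t = dt gives r * [P(n, k t) - P(n, k (t - dt))].
    """
    t = np.asarray(t, dtype=float)
    k = n_cells / dt
    r = dose / dt
    out = r * (
        gammainc(n_cells, np.clip(k * t, 0.0, None))
        - gammainc(n_cells, np.clip(k * (t - dt), 0.0, None))
    )
    return out


def chain_cumulative_exit(
    t: np.ndarray | float, dose: float, dt: float, n_cells: int = 8
) -> np.ndarray:
    """Cumulative chain exit = pump input so far minus chain content."""
    t = np.asarray(t, dtype=float)
    k = n_cells / dt
    r = dose / dt
    pumped = r * np.clip(t, 0.0, dt)
    content = (r / k) * (
        _erlang_cdf_sum(n_cells, k * t)
        - _erlang_cdf_sum(n_cells, k * (t - dt))
    )
    return pumped - content


def rectangular_infusion(
    dose: float,
    duration: float,
    mode: str = "U",
    body_weight: float | None = None,
) -> InfusionProfile:
    """Rigid rectangular delivery: dose/duration on [0, duration), 0 after.

    ``dose`` is in the units of ``mode`` (mmol for S, mmol/kg for U/N).
    """
    if dose <= 0 or duration <= 0:
        raise ParameterDomainError("dose and duration must be positive")
    return InfusionProfile(
        mode=mode, dose=dose, nominal_duration=duration, body_weight=body_weight
    )


def novel_infusion_profile(
    dose: float,
    dt: float,
    n_cells: int = 8,
    shutoff_fraction: float = 0.99,
    body_weight: float | None = None,
    delivery: str = "pump",
) -> InfusionProfile:
    """Sensed infusion delivery with an adjustable duration DT.

    The pump runs at dose/DT for DT minutes (so the whole dose is delivered,
    exactly); a parallel n-cell delay chain receives a copy of the pump
    signal and senses the end of the infusion as the time its cumulative
    exit reaches ``shutoff_fraction`` of the dose.  ``delivery="chain_exit"``
    instead routes the Erlang-smoothed chain exit into the blood.
    """
    if dt <= 0:
        raise ParameterDomainError("DT must be > 0")
    profile = InfusionProfile(
        mode="N",
        dose=dose,
        nominal_duration=dt,
        body_weight=body_weight,
        kind="delay_chain",
        n_cells=n_cells,
        shutoff_fraction=shutoff_fraction,
        delivery=delivery,
    )
    # validate that the sensing threshold is attainable
    sense_end_time(dose, dt, n_cells, shutoff_fraction)
    return profile


def sense_end_time(
    dose: float, dt: float, n_cells: int = 8, threshold: float = 0.99
) -> float:
    """Sensed end-of-infusion time: cumulative chain exit = threshold*dose.

    Solved by monotone root bracketing on the closed-form cumulative exit.
    """
    if threshold <= 0:
        return 0.0
    horizon = 10.0 * dt
    target = threshold * dose

    def shortfall(t):
        return chain_cumulative_exit(t, dose, dt, n_cells) - target

    if shortfall(horizon) < 0:
        raise DetectionError(
            f"threshold {threshold} of dose not attained within 10*DT"
        )
    return float(brentq(shortfall, 0.0, horizon, xtol=1e-10))


def detect_infusion_end(
    times: Sequence[float],
    cumulative_exit: Sequence[float],
    dose: float,
    threshold_fraction: float = 0.99,
) -> float:
    """First time a sampled cumulative-throughput curve crosses the threshold.

    The cumulative throughput is nondecreasing, so the crossing is unique;
    it is located by linear interpolation between the bracketing samples.
    """
    times = np.asarray(times, dtype=float)
    cum = np.asarray(cumulative_exit, dtype=float)
    target = threshold_fraction * dose
    if threshold_fraction <= 0:
        return 0.0
    idx = np.searchsorted(cum, target)
    if idx >= len(cum):
        raise DetectionError("threshold not attained within the trajectory")
    if idx == 0:
        return float(times[0])
    t0, t1 = times[idx - 1], times[idx]
    c0, c1 = cum[idx - 1], cum[idx]
    if c1 == c0:
        return float(t1)
    return float(t0 + (target - c0) * (t1 - t0) / (c1 - c0))


def convert_units(obj, to_mode: str, body_weight: float | None = None, dt: float | None = None):
    """Convert a MicroParams or InfusionProfile between unit conventions.

    Fractional rates (min^-1) and the concentration baseline are
    unit-invariant; amounts and the dose scale by body weight between S and
    U/N, and the scale parameter maps K1 <-> 1/(P2 * weight).
    """
    from .model import MicroParams  # local import avoids a cycle

    if to_mode not in ("S", "U", "N"):
        raise ConversionError(f"unknown target mode {to_mode!r}")

    if isinstance(obj, MicroParams):
        if obj.units_mode == to_mode:
            return obj
        w = body_weight
        if (obj.units_mode == "S") != (to_mode == "S"):
            if w is None or w <= 0:
                raise ConversionError("body weight required to convert S <-> U/N")
        if to_mode == "S":
            pool = obj.pool_size
            return MicroParams(
                l01=obj.l01,
                l21=obj.l21,
                l12=obj.l12,
                baseline=obj.baseline,
                inverse_pool=1.0 / (pool * w),
                units_mode="S",
            )
        pool = (
            obj.pool_size
            if obj.units_mode != "S"
            else 1.0 / (obj.inverse_pool * w)
        )
        new_dt = dt if dt is not None else obj.dt
        if to_mode == "N" and new_dt is None:
            raise ConversionError("converting to N mode requires a transit time DT")
        return MicroParams(
            l01=obj.l01,
            l21=obj.l21,
            l12=obj.l12,
            baseline=obj.baseline,
            pool_size=pool,
            dt=new_dt if to_mode == "N" else None,
            units_mode=to_mode,
        )

    if isinstance(obj, InfusionProfile):
        if obj.mode == to_mode:
            return obj
        w = body_weight if body_weight is not None else obj.body_weight
        if (obj.mode == "S") != (to_mode == "S"):
            if w is None or w <= 0:
                raise ConversionError("body weight required to convert S <-> U/N")
            factor = w if to_mode == "S" else 1.0 / w
        else:
            factor = 1.0
        return replace(obj, mode=to_mode, dose=obj.dose * factor, body_weight=w)

    raise ConversionError(f"cannot convert object of type {type(obj).__name__}")
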