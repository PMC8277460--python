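"""Synthetic infusion-challenge study generator.

Emulates the equine protocol: ~13 pre-infusion baseline replicates, a
nominal 15-minute infusion of 1 mmol/kg with sampling during the infusion,
rapid sampling for the first quarter hour afterwards, then geometrically
spaced samples until the predicted curve returns to within one noise SD of
baseline.  Observation noise is multiplicative Gaussian with a fixed CV,
matching the fractional-SD weighting used at fitting time.

Every generated dataset carries its ground-truth parameters so parameter-
recovery experiments need no external files.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
import numpy as np

from .estimation import KineticDataset
from .exceptions import ParameterDomainError
from .infusion import InfusionProfile, novel_infusion_profile, rectangular_infusion
from .model import MicroParams, eigen_rates, solve_micro
from .presets import (
    DOSE_MMOL_PER_KG,
    HORSE_WEIGHTS,
    N_PRE_SAMPLES,
    NOMINAL_DURATION_MIN,
    horse_micro_truth,
)

__all__ = ["StudyDesign", "generate_horse", "default_study", "pump_fault_injector"]


@dataclass(frozen=True)
class StudyDesign:
    """Sampling schedule and noise model for one synthetic infusion study."""

    n_pre_samples: int = N_PRE_SAMPLES
    infusion_duration: float = NOMINAL_DURATION_MIN
    dose: float = DOSE_MMOL_PER_KG  # mmol/kg
    infusion_sampling: tuple[float, ...] = (3.0, 6.0, 9.0, 12.0, 15.0)
    post_dense_interval: float = 2.0
    post_dense_span: float = 15.0
    post_growth: float = 1.3
    noise_cv: float = 0.05
    body_weight: float = 480.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.noise_cv < 0:
            raise ParameterDomainError("noise_cv must be >= 0")
        if self.n_pre_samples < 3:
            raise ParameterDomainError("need >= 3 pre-infusion samples")
        times = np.asarray(self.infusion_sampling)
        if np.any(np.diff(times) <= 0) or np.any(times <= 0):
            raise ParameterDomainError("infusion sampling must be increasing and > 0")
        if self.post_growth <= 1.0:
            raise ParameterDomainError("post_growth must exceed 1")

    @property
    def pre_times(self) -> np.ndarray:
        """Baseline replicate times: every 2 min ending 2 min before start."""
        n = self.n_pre_samples
        return -2.0 * np.arange(n, 0, -1)


def _post_schedule(
    design: StudyDesign, params: MicroParams, infusion: InfusionProfile
) -> np.ndarray:
    """Post-infusion times: dense early sampling then geometric spacing,
    stopping once the predicted curve is within one noise SD of baseline."""
    t_end = design.infusion_duration
    dense = np.arange(
        t_end + design.post_dense_interval,
        t_end + design.post_dense_span + 1e-9,
        design.post_dense_interval,
    )
    _, beta = eigen_rates(params.l01, params.l21, params.l12)
    horizon = 10.0 / beta
    # threshold: one noise SD of the baseline (floored so the zero-noise
    # schedule still terminates at a near-baseline return)
    thresh = max(design.noise_cv, 0.02) * params.baseline
    candidates = [dense[-1]]
    while candidates[-1] < horizon:
        candidates.append(candidates[-1] * design.post_growth)
    grid = np.concatenate([dense, np.asarray(candidates[1:])])
    traj = solve_micro(params, infusion, times=grid)
    above = traj.predicted_conc - params.baseline
    back = np.nonzero(above <= thresh)[0]
    if len(back) == 0:
        raise ParameterDomainError(
            "predicted curve never returns to baseline within 10/beta minutes"
        )
    return grid[: back[0] + 1]


def _profile_for(
    params: MicroParams, design: StudyDesign, infusion_mode: str
) -> InfusionProfile:
    if infusion_mode == "N":
        dt = params.dt if params.dt is not None else design.infusion_duration
        return novel_infusion_profile(
            design.dose, dt, body_weight=design.body_weight
        )
    if infusion_mode == "S":
        return rectangular_infusion(
            design.dose * design.body_weight,
            design.infusion_duration,
            mode="S",
            body_weight=design.body_weight,
        )
    return rectangular_infusion(
        design.dose, design.infusion_duration, mode="U", body_weight=design.body_weight
    )


def generate_horse(
    params: MicroParams,
    design: StudyDesign,
    infusion_mode: str = "U",
    profile: InfusionProfile | None = None,
    rng: np.random.Generator | None = None,
) -> KineticDataset:
    """Simulate one infusion challenge and sample it with assay noise.

    ``params`` must match ``infusion_mode`` conventions (S amounts are
    whole-animal; N requires a transit time DT).  A custom ``profile``
    (e.g. from :func:`pump_fault_injector`) overrides the default delivery.
    The returned dataset keeps the generating parameters in ``truth``.
    """
    if rng is None:
        rng = np.random.default_rng(design.seed)
    if profile is None:
        profile = _profile_for(params, design, infusion_mode)

    # schedule: pre replicates, infusion-phase samples, post until baseline
    sched_profile = profile
    post = _post_schedule(design, params, sched_profile)
    inf_times = np.asarray(design.infusion_sampling, dtype=float)
    times = np.concatenate([design.pre_times, inf_times, post])
    phase = np.array(
        ["pre"] * design.n_pre_samples
        + ["infusion"] * len(inf_times)
        + ["post"] * len(post),
        dtype=object,
    )

    kinetic_times = np.concatenate([inf_times, post])
    method = "lsoda" if profile.kind == "custom" else "auto"
    traj = solve_micro(params, profile, times=kinetic_times, method=method)
    clean = np.concatenate(
        [np.full(design.n_pre_samples, params.baseline), traj.predicted_conc]
    )
    noisy = clean * (1.0 + design.noise_cv * rng.standard_normal(len(clean)))
    noisy = np.maximum(noisy, 1e-3)  # assay floor: concentrations stay positive

    return KineticDataset(
        times=times,
        concentrations=noisy,
        phase=phase,
        body_weight=design.body_weight,
        protocol=profile,
        truth=params,
        meta={
            "noise_cv": design.noise_cv,
            "infusion_mode": infusion_mode,
            "intended_duration_min": design.infusion_duration,
        },
    )


def default_study(
    seed: int | None = None, noise_cv: float = 0.05
) -> list[KineticDataset]:
    """The five-horse synthetic study.

    One Unit-convention dataset per horse, with the published body weights
    and per-horse kinetic truths derived from the post-infusion macro
    constants.
    """
    rng = np.random.default_rng(seed)
    datasets = []
    for horse in sorted(HORSE_WEIGHTS):
        params = horse_micro_truth(horse)
        design = StudyDesign(
            body_weight=HORSE_WEIGHTS[horse], noise_cv=noise_cv
        )
        ds = generate_horse(params, design, infusion_mode="U", rng=rng)
        ds.meta["horse"] = horse
        datasets.append(ds)
    return datasets


def pump_fault_injector(
    profile: InfusionProfile, fault: str, fraction: float = 0.25
) -> InfusionProfile:
    """Emulate a misbehaving infusion pump.

    ``slowdown``: delivery runs at the nominal rate for the first
    (1 - fraction) of the dose, then declines linearly to zero; the full
    dose is still delivered, over a longer total duration.
    ``early_stop``: the pump halts after ``fraction`` of the dose (the only
    fault that does not conserve the dose, by construction).
    ``ramp``: trapezoidal delivery (ramp up, plateau, ramp down) within the
    nominal duration, conserving the dose.
    """
    if not 0.0 < fraction <= 1.0:
        raise ParameterDomainError("fault fraction must lie in (0, 1]")
    if profile.kind != "rectangular":
        raise ParameterDomainError("fault injection applies to rectangular profiles")
    dose, dur = profile.dose, profile.nominal_duration
    r0 = dose / dur

    if fault == "early_stop":
        if fraction == 1.0:
            return profile
        return replace(profile, dose=dose * fraction, nominal_duration=dur * fraction)

    if fault == "slowdown":
        t1 = (1.0 - fraction) * dur  # constant-rate span
        tail = 2.0 * fraction * dur  # linear decline delivering the rest
        total = t1 + tail

        def rate_fn(t):
            if 0 <= t < t1:
                return r0
            if t1 <= t < total:
                return r0 * (1.0 - (t - t1) / tail)
            return 0.0

        def delivered_fn(t):
            t = np.asarray(t, dtype=float)
            out = np.where(
                t < t1,
                r0 * np.clip(t, 0.0, None),
                r0 * t1
                + r0 * (np.clip(t - t1, 0.0, tail) - np.clip(t - t1, 0.0, tail) ** 2 / (2 * tail)),
            )
            return out

        return replace(
            profile,
            kind="custom",
            nominal_duration=total,
            rate_fn=rate_fn,
            delivered_fn=delivered_fn,
            custom_breakpoints=(0.0, t1, total),
        )

    if fault == "ramp":
        ramp = fraction * dur
        plateau = dur - 2.0 * ramp
        if plateau < 0:
            raise ParameterDomainError("ramp fraction too large for the duration")
        rp = dose / (dur - ramp)  # plateau rate conserving the dose

        def rate_fn(t):
            if 0 <= t < ramp:
                return rp * t / ramp
            if ramp <= t < ramp + plateau:
                return rp
            if ramp + plateau <= t < dur:
                return rp * (dur - t) / ramp
            return 0.0

        def delivered_fn(t):
            t = np.asarray(t, dtype=float)
            up = rp * np.clip(t, 0, ramp) ** 2 / (2 * ramp)
            mid = rp * np.clip(t - ramp, 0, plateau)
            tdn = np.clip(t - ramp - plateau, 0, ramp)
            down = rp * (tdn - tdn**2 / (2 * ramp))
            return up + mid + down

        return replace(
            profile,
            kind="custom",
            rate_fn=rate_fn,
            delivered_fn=delivered_fn,
            custom_breakpoints=(0.0, ramp, ramp + plateau, dur),
        )

    raise ParameterDomainError(f"unknown fault {fault!r}")
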