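"""Common pharmacokinetic dependencies of a fitted disposition model.

A panel of 15 standard two-compartment quantities, per kg of body weight,
plus the endogenous lactate production rate.  At the basal steady state the
state equations with no infusion give loss = production, so

    Ra = L01 * P1 * P2    (mmol kg^-1 min^-1)

— irreversible loss of the basal central-pool content equals the metabolic
input sustaining it.  This is how a lactate infusion challenge yields the
*production* of lactate, not just its clearance.
"""

from __future__ import annotations

import numpy as np

from .estimation import FitResult
from .exceptions import ParameterDomainError
from .infusion import InfusionProfile
from .model import MicroParams, macro_from_micro

__all__ = ["DEPENDENCY_NAMES", "compute_dependencies", "endogenous_production"]

#: The 15-quantity dependency panel, with units.
DEPENDENCY_NAMES: dict[str, str] = {
    "V1": "L/kg",
    "Vss": "L/kg",
    "V_area": "L/kg",
    "CL": "L/kg/min",
    "CL_distributional": "L/kg/min",
    "alpha": "1/min",
    "beta": "1/min",
    "t_half_alpha": "min",
    "t_half_beta": "min",
    "A": "mmol/L",
    "B": "mmol/L",
    "AUC": "mmol*min/L",
    "MRT": "min",
    "k_elim": "1/min",
    "Ra_endogenous": "mmol/kg/min",
}


def _as_unit_params(obj, body_weight: float | None) -> MicroParams:
    params = obj.params if isinstance(obj, FitResult) else obj
    if not isinstance(params, MicroParams):
        raise ParameterDomainError("dependencies require a micro-rate model")
    if params.units_mode == "S":
        from .infusion import convert_units

        if body_weight is None:
            raise ParameterDomainError(
                "body weight required to normalize an S-mode fit per kg"
            )
        params = convert_units(params, "U", body_weight=body_weight)
    return params


def endogenous_production(fit: FitResult | MicroParams, body_weight: float | None = None) -> float:
    """Basal endogenous lactate production Ra = L01 * P1 * P2 (mmol/kg/min)."""
    p = _as_unit_params(fit, body_weight)
    return p.l01 * p.baseline * p.pool_size


def compute_dependencies(
    fit: FitResult | MicroParams,
    protocol: InfusionProfile,
) -> dict[str, float]:
    """The 15-dependency panel from a converged micro-rate fit.

    All volumes and clearances are per kg; the macro coefficients A and B
    are those of a bolus of the protocol dose.  S-mode fits are normalized
    per kg using the protocol body weight first, which makes the panel
    invariant under the S <-> U unit conversion.
    """
    w = protocol.body_weight
    p = _as_unit_params(fit, w)
    dose = protocol.dose if protocol.mode != "S" else protocol.dose / w

    v1 = p.pool_size
    cl = p.l01 * v1
    cl_d = p.l21 * v1
    macro = macro_from_micro(p, dose=dose)
    vss = v1 * (1.0 + p.l21 / p.l12)
    deps = {
        "V1": v1,
        "Vss": vss,
        "V_area": cl / macro.beta,
        "CL": cl,
        "CL_distributional": cl_d,
        "alpha": macro.alpha,
        "beta": macro.beta,
        "t_half_alpha": np.log(2.0) / macro.alpha,
        "t_half_beta": np.log(2.0) / macro.beta,
        "A": macro.A,
        "B": macro.B,
        "AUC": dose / cl,
        "MRT": vss / cl,
        "k_elim": p.l01,
        "Ra_endogenous": endogenous_production(p),
    }
    bad = [k for k, v in deps.items() if not np.isfinite(v) or v <= 0]
    if bad:
        raise ParameterDomainError(f"non-positive dependencies from fit: {bad}")
    return deps
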