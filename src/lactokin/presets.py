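"""Reference parameter sets for the five-horse lactate infusion study.

Healthy adult horses received 1 mmol/kg body weight of L-lactate in 500 ml
saline over a nominal 15 minutes.  Two families of presets are provided:

* per-horse biexponential macro constants (A, alpha, B, beta) fitted
  independently to the post-infusion decay, with body weights; these seed
  the synthetic study generator, and
* the three full micro-rate parameter sets for horse 5 — one per modeling
  convention (Simple, Unit, Novel) — used as generating truths in
  parameter-recovery work.

The macro- and micro-based presets describe different data segments (the
macro constants come from the post-infusion decay alone), so they are not
interconvertible and are exposed as separate named presets.
"""

from __future__ import annotations

from .model import MacroParams, MicroParams, micro_from_macro

DOSE_MMOL_PER_KG = 1.0
NOMINAL_DURATION_MIN = 15.0
N_PRE_SAMPLES = 13

#: Body weight (kg) per horse.
HORSE_WEIGHTS: dict[int, float] = {1: 484.0, 2: 588.0, 3: 450.0, 4: 503.0, 5: 480.0}

#: Post-infusion macro constants per horse (A, B in mmol/L; rates in min^-1).
HORSE_MACRO: dict[int, MacroParams] = {
    1: MacroParams(A=0.694, alpha=0.247, B=1.492, beta=0.008),
    2: MacroParams(A=1.041, alpha=0.092, B=0.735, beta=0.002),
    3: MacroParams(A=0.738, alpha=0.101, B=1.104, beta=0.006),
    4: MacroParams(A=0.604, alpha=0.269, B=1.183, beta=0.007),
    5: MacroParams(A=0.698, alpha=0.202, B=1.337, beta=0.011),
}

#: Basal blood lactate (mmol/L) per horse.  Only horse 5's basal level is
#: published (0.357 under the Unit convention); the others are representative
#: values inside the published 0.356-0.419 range.
HORSE_BASELINES: dict[int, float] = {1: 0.40, 2: 0.38, 3: 0.41, 4: 0.39, 5: 0.357}

#: Horse-5 Unit-convention micro parameters.
HORSE5_UNIT = MicroParams(
    l01=0.070, l21=0.209, l12=0.137, baseline=0.357, pool_size=0.215, units_mode="U"
)

#: Horse-5 Novel-convention micro parameters (8-cell delay chain, DT 15.4).
HORSE5_NOVEL = MicroParams(
    l01=0.081,
    l21=0.266,
    l12=0.133,
    baseline=0.356,
    pool_size=0.181,
    dt=15.4,
    units_mode="N",
)

#: Horse-5 Simple-convention micro parameters (whole-animal mmol amounts).
HORSE5_SIMPLE = MicroParams(
    l01=0.072, l21=0.280, l12=0.189, baseline=0.419, inverse_pool=0.009, units_mode="S"
)


def horse_micro_truth(horse: int) -> MicroParams:
    """Unit-convention micro parameters for one horse, derived from its
    macro constants.

    Rates come from the exact bolus identities; the pool size is
    dose/(A + B), the bolus-equivalent central volume.
    """
    macro = HORSE_MACRO[horse]
    rates = micro_from_macro(macro)
    pool = DOSE_MMOL_PER_KG / (macro.A + macro.B)
    return MicroParams(
        baseline=HORSE_BASELINES[horse],
        pool_size=pool,
        units_mode="U",
        **rates,
    )
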