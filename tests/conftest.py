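import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from lactokin.estimation import KineticDataset
from lactokin.infusion import rectangular_infusion
from lactokin.model import MacroParams, MicroParams, analytic_bolus_solution
from lactokin.presets import HORSE5_NOVEL, HORSE5_SIMPLE, HORSE5_UNIT
from lactokin.synthetic import StudyDesign, generate_horse


@pytest.fixture(scope="session")
def horse5_unit() -> MicroParams:
    return HORSE5_UNIT


@pytest.fixture(scope="session")
def horse5_novel() -> MicroParams:
    return HORSE5_NOVEL


@pytest.fixture(scope="session")
def horse5_simple() -> MicroParams:
    return HORSE5_SIMPLE


@pytest.fixture(scope="session")
def horse5_macro() -> MacroParams:
    return MacroParams(A=0.698, alpha=0.202, B=1.337, beta=0.011)


@pytest.fixture(scope="session")
def clean_unit_dataset(horse5_unit) -> KineticDataset:
    """Noise-free Unit-convention challenge dataset for horse 5."""
    design = StudyDesign(noise_cv=0.0, body_weight=480.0, seed=1)
    return generate_horse(horse5_unit, design, infusion_mode="U")


@pytest.fixture(scope="session")
def clean_novel_dataset(horse5_novel) -> KineticDataset:
    """Noise-free Novel-convention dataset (true DT = 15.4 min)."""
    design = StudyDesign(noise_cv=0.0, body_weight=480.0, seed=1)
    return generate_horse(horse5_novel, design, infusion_mode="N")


@pytest.fixture(scope="session")
def noisy_unit_dataset(horse5_unit) -> KineticDataset:
    """One 5%-noise Unit dataset with a fixed seed."""
    design = StudyDesign(noise_cv=0.05, body_weight=480.0, seed=42)
    return generate_horse(horse5_unit, design, infusion_mode="U")


@pytest.fixture(scope="session")
def macro_decay_dataset(horse5_macro) -> KineticDataset:
    """Noise-free biexponential post-infusion decay at 25 times, with
    baseline replicates and placeholder infusion-phase samples."""
    baseline = 0.357
    t_post = 15.0 + np.linspace(1.0, 300.0, 25)
    times = np.concatenate([-2.0 * np.arange(13, 0, -1), [3, 6, 9, 12, 15], t_post])
    conc = np.concatenate(
        [
            np.full(13, baseline),
            np.full(5, 1.5),
            analytic_bolus_solution(horse5_macro, t_post - 15.0) + baseline,
        ]
    )
    phase = np.array(["pre"] * 13 + ["infusion"] * 5 + ["post"] * 25, dtype=object)
    return KineticDataset(
        times=times,
        concentrations=conc,
        phase=phase,
        body_weight=480.0,
        protocol=rectangular_infusion(1.0, 15.0, "U", body_weight=480.0),
    )
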