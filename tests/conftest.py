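import numpy as np
import pandas as pd
import pytest

from formantadapt.config import RunConfig
from formantadapt.pipeline import analyze_dataset
from formantadapt.simulate import StudyDesign, simulate_study


@pytest.fixture(scope="session")
def small_study():
    """A compact two-experiment dataset: 8 participants, defaults otherwise."""
    design = StudyDesign(n_participants=8, n_female=4)
    return simulate_study(design, seed=42)


@pytest.fixture(scope="session")
def small_analysis(small_study):
    return analyze_dataset(small_study.inventory, small_study.trials)


@pytest.fixture()
def config():
    return RunConfig(rng_seed=7)


@pytest.fixture()
def single_inventory():
    """One participant's mean formants covering all ten vowels."""
    rows = [
        ("iy", 270.0, 2290.0), ("ih", 390.0, 1990.0), ("ey", 450.0, 2150.0),
        ("eh", 530.0, 1840.0), ("ae", 660.0, 1720.0), ("aa", 730.0, 1090.0),
        ("ao", 570.0, 840.0), ("ow", 500.0, 910.0), ("uh", 440.0, 1020.0),
        ("uw", 300.0, 870.0),
    ]
    return pd.DataFrame(
        [{"participant_id": "S1", "vowel": v, "f1_hz": f1, "f2_hz": f2}
         for v, f1, f2 in rows]
    )


def make_case_trials(
    pid="S1", experiment=1, case="iy", f1_norm=0.5, f2_norm=1.8,
    good=None, delta_f=1000.0,
):
    """Build a 90-trial case table with constant normalised formants."""
    t = np.arange(1, 91)
    block = np.where(t <= 10, "baseline", np.where(t <= 60, "altered",
                                                   "washout"))
    good = np.ones(90, dtype=bool) if good is None else np.asarray(good)
    f1 = np.full(90, f1_norm)
    f2 = np.full(90, f2_norm)
    return pd.DataFrame(
        {
            "participant_id": pid,
            "experiment": experiment,
            "case": case,
            "trial_index": t,
            "block": block,
            "good": good,
            "f1_hz": f1 * delta_f,
            "f2_hz": f2 * delta_f,
            "f1_norm": f1,
            "f2_norm": f2,
        }
    )
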