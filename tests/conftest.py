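import numpy as np
import pandas as pd
import pytest

from moafit.synthetic import DEFAULT_PROBE, generate_panel


@pytest.fixture(scope="session")
def probe():
    return DEFAULT_PROBE


@pytest.fixture(scope="session")
def small_panel():
    return generate_panel(6, seed=11)


@pytest.fixture()
def example_plate():
    """Tiny endpoint plate with clean controls and one 8-dose compound."""
    rows = [
        {"well": "A1", "role": "neutral_control", "compound_id": "", "dose_M": np.nan,
         "signal": 10.0, "masked": 0},
        {"well": "A2", "role": "neutral_control", "compound_id": "", "dose_M": np.nan,
         "signal": 10.0, "masked": 0},
        {"well": "B1", "role": "inhibitor_control", "compound_id": "", "dose_M": np.nan,
         "signal": 2.0, "masked": 0},
        {"well": "B2", "role": "inhibitor_control", "compound_id": "", "dose_M": np.nan,
         "signal": 2.0, "masked": 0},
    ]
    doses = np.sort(1e-5 / 3.0 ** np.arange(8))
    for i, d in enumerate(doses):
        frac = 1.0 / (1.0 + 1e-7 / d)  # IC50 100 nM, Hill 1
        rows.append({"well": f"C{i + 1}", "role": "sample", "compound_id": "cmpd",
                     "dose_M": d, "signal": 10.0 - 8.0 * frac, "masked": 0})
    return pd.DataFrame(rows)
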