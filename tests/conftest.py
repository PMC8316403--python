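from __future__ import annotations

import pandas as pd
import pytest

from lipidshift import (
    NormalizedSample,
    default_panel,
    study_presets,
)


@pytest.fixture(scope="session")
def presets():
    return study_presets()


@pytest.fixture(scope="session")
def brain_panel():
    return default_panel(("brain",))


def make_sample(mouse_id, group, values, tissue="brain"):
    """Build a NormalizedSample directly from a {label: value} dict."""
    return NormalizedSample(mouse_id, tissue, group, pd.Series(values, dtype=float))
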