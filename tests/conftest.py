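import numpy as np
import pandas as pd
import pytest

import sedrisk as sr


@pytest.fixture(scope="session")
def wami() -> sr.ExposureTable:
    return sr.load_wami_exposure()


@pytest.fixture(scope="session")
def isqg() -> sr.GuidelineSet:
    return sr.load_isqg_guidelines()


def make_exposure(columns: dict, unit: str = "mg/kg") -> sr.ExposureTable:
    """Build an ExposureTable from {element: values} for tests."""
    mean = pd.DataFrame(columns)
    mean.index = pd.Index(range(1, len(mean) + 1), name="station")
    return sr.ExposureTable(mean=mean, unit=unit)


def make_toxicity(values, element: str = "Cd") -> sr.ToxicityDataset:
    return sr.ToxicityDataset(element=element, concentrations=np.asarray(values, float))
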