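import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from etqrs.preprocess import FilterSpec, FilteredSignal
from etqrs.signal_io import EcgRecord

FS = 360.0


@pytest.fixture
def fs() -> float:
    return FS


@pytest.fixture
def default_spec() -> FilterSpec:
    return FilterSpec(FS)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture
def sine_record() -> EcgRecord:
    t = np.arange(3600) / FS
    return EcgRecord(np.sin(2 * np.pi * 5.0 * t), FS, "sine5")


def make_filtered(values, fs=FS, group_delay=20) -> FilteredSignal:
    return FilteredSignal(np.asarray(values, dtype=float), group_delay, fs)
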