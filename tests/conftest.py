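import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles helper module

from abscan import (
    ANTIPARALLEL,
    SheetSpec,
    StrandSpec,
    build_ideal_sheet,
    build_library,
    load_iapp,
    load_template,
)


@pytest.fixture(scope="session")
def iapp():
    _, seq = load_iapp()
    return seq


@pytest.fixture()
def ap_sheet_8():
    """Ideal antiparallel two-strand sheet, 8+8, register 0."""
    spec = SheetSpec(
        strands=[
            StrandSpec("NFLVHSSN"),
            StrandSpec("AGKWTYQE", ANTIPARALLEL, 0),
        ],
        sheet_id="ap8",
    )
    return build_ideal_sheet(spec)


@pytest.fixture()
def nflvh_sheet():
    """Sheet whose target strand is the IAPP fragment NFLVH."""
    spec = SheetSpec(
        strands=[StrandSpec("NFLVH"), StrandSpec("WTYQE", ANTIPARALLEL, 0)],
        sheet_id="nflvh",
    )
    return build_ideal_sheet(spec)


@pytest.fixture()
def nflvh_library(nflvh_sheet):
    return build_library([nflvh_sheet], min_len=3, max_len=5)


@pytest.fixture(scope="session")
def sdab_template():
    return load_template("sdab")


@pytest.fixture(scope="session")
def monobody_template():
    return load_template("monobody")


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
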