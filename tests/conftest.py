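"""Shared fixtures.

The expensive artefacts (full R_19 MILP sweep, R_10 elementary-mode census)
are session-scoped so the acceptance-level tests that need them share one
computation.
"""

from __future__ import annotations

import pytest

from mbpkit.chemistry import build_network
from mbpkit.efm import degenerate_catalogue
from mbpkit.iterative import build_all_mbps_iterative
from mbpkit.milp import mbp_length_table


@pytest.fixture(scope="session")
def net10():
    return build_network(10)


@pytest.fixture(scope="session")
def net19():
    return build_network(19)


@pytest.fixture(scope="session")
def catalogue10(net10):
    """Degenerate MBP catalogue of R_10 from the elementary-mode pipeline."""
    return degenerate_catalogue(net10)


@pytest.fixture(scope="session")
def milp_table10(net10):
    L, sols = mbp_length_table(net10, collect_solutions=True)
    return L, sols


@pytest.fixture(scope="session")
def milp_table19(net19):
    """Full R_19 MILP sweep (the single most expensive fixture)."""
    L, sols = mbp_length_table(net19, collect_solutions=True)
    return L, sols


@pytest.fixture(scope="session")
def iterative10():
    return build_all_mbps_iterative(10)


@pytest.fixture(scope="session")
def iterative19():
    return build_all_mbps_iterative(19)
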