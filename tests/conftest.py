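"""Shared fixtures: toy structures, models and pre-run simulations.

Everything is generated programmatically; the heavier simulation fixtures
are session-scoped so several tests can share one run.
"""

from __future__ import annotations

import numpy as np
import pytest

from gofold import dmd
from gofold.synthetic import (
    ToySpec,
    build_toy_model,
    make_lock_key_pair,
    make_toy_native,
)


@pytest.fixture(scope="session")
def toy10():
    """The canonical 10-residue hairpin toy (2 pseudo-atoms per residue)."""
    return make_toy_native(ToySpec(n_residues=10, atoms_per_residue=2,
                                   topology="hairpin", seed=1))


@pytest.fixture(scope="session")
def model10(toy10):
    return build_toy_model(toy10)


@pytest.fixture(scope="session")
def toy12():
    """A 12-residue, 3-atom-per-residue hairpin with a 3-residue tail."""
    return make_toy_native(ToySpec(n_residues=12, atoms_per_residue=3,
                                   topology="hairpin", tail_residues=3,
                                   seed=2))


@pytest.fixture(scope="session")
def lock_key():
    """Verified lock-and-key pair with a unique planted docking optimum."""
    return make_lock_key_pair(patch_size=4, seed=0, verify=True)


@pytest.fixture(scope="session")
def re_run(model10):
    """Calibrated temperature grid plus a production RE-DMD run.

    Shared by the replica-exchange acceptance checks (swap acceptance,
    heat-capacity peak, melting curve).  The grid spans the toy's folding
    transition; the production run provides several hundred swap attempts
    per neighbour pair.
    """
    grid, pilot = dmd.calibrate_temperature_grid(
        model10, (0.5, 3.0), target_acceptance=0.9, seed=7
    )
    production = dmd.run_re_dmd(
        model10,
        grid,
        events_per_replica=400_000,
        swap_interval=600,
        seed=8,
    )
    return grid, pilot, production
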