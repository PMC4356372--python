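"""Shared fixtures: toy cells, planted crystals, maps, and a trained SVM.

Everything is generated programmatically; session-scoped fixtures cache
the expensive objects (structure factors, maps, classifier) across tests.
"""

from __future__ import annotations

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from nucleofit.cli_pipeline import (
    CrystalSpec,
    make_synthetic_crystal,
    train_suite_classifier,
)
from nucleofit.crystal_maps import (
    AtomicModel,
    ReflectionSet,
    SymmetryOps,
    UnitCell,
    bias_phases,
    compute_structure_factors,
    synthesize_map,
)
from nucleofit.fiber import HelixSpec, generate_helix
from nucleofit.phosphate_detect import PhosphateSet

# a toy two-fold screw-free P2-like operator set used in symmetry tests
P2_OPS = SymmetryOps(
    rotations=(tuple(map(tuple, np.eye(3, dtype=int))),
               ((-1, 0, 0), (0, 1, 0), (0, 0, -1))),
    translations=((0.0, 0.0, 0.0), (0.0, 0.0, 0.0)),
    label="P 1 2 1",
)


def blob_model(centers, element="P"):
    """Point-atom model: one Gaussian blob per centre."""
    return AtomicModel.from_rows(
        [(element, element, "BLB", i + 1, "X", tuple(c), 15.0, 1.0)
         for i, c in enumerate(centers)]
    )


def blob_map(centers, cell, d_min=2.5, element="P"):
    refl = compute_structure_factors(blob_model(centers, element), cell,
                                     d_min=d_min)
    return synthesize_map(refl)


def relaxed_recovery(built: AtomicModel, truth: AtomicModel) -> float:
    """Fraction of truth nucleotides with a built copy (P < 1.5, C1' < 1.0)."""
    hits = 0
    bres = built.residues()
    for ch, rs, idx in truth.residues():
        names = {str(truth.name[i]): truth.xyz[i] for i in idx}
        pref = names.get("P")
        c1ref = names["C1'"]
        found = False
        for ch2, rs2, idx2 in bres:
            n2 = {str(built.name[i]): built.xyz[i] for i in idx2}
            if "C1'" not in n2 or np.linalg.norm(n2["C1'"] - c1ref) >= 1.0:
                continue
            if pref is None or ("P" in n2 and
                                np.linalg.norm(n2["P"] - pref) < 1.5):
                found = True
                break
        hits += found
    return hits / len(truth.residues())


@pytest.fixture(scope="session")
def toy_cell():
    return UnitCell(30.0, 30.0, 30.0)


@pytest.fixture(scope="session")
def helix_crystal():
    """Planted 8-bp A-RNA duplex in a P1 cell (random orientation)."""
    hel = generate_helix(HelixSpec("A-RNA", 8, "GCAUGCAU"))
    R = Rotation.random(random_state=5).as_matrix()
    truth = hel.fragment.transformed(R, np.array([20.0, 20.0, 20.0]))
    cell = UnitCell(40.0, 42.0, 44.0)
    return truth, cell


@pytest.fixture(scope="session")
def helix_refl(helix_crystal):
    truth, cell = helix_crystal
    return compute_structure_factors(truth, cell, d_min=2.5)


@pytest.fixture(scope="session")
def helix_map_good(helix_refl):
    """2.5 Å map with 18 deg mean phase error (FOM ~0.92)."""
    return synthesize_map(bias_phases(helix_refl, 18.0, seed=3).reflections)


@pytest.fixture(scope="session")
def helix_map_4A(helix_refl):
    """4.0 Å map with 18 deg mean phase error."""
    return synthesize_map(bias_phases(helix_refl.trim(4.0), 18.0,
                                      seed=3).reflections)


@pytest.fixture(scope="session")
def helix_phosphates(helix_crystal):
    truth, _cell = helix_crystal
    return PhosphateSet(truth.atoms_named("P"), source="ground-truth")


@pytest.fixture(scope="session")
def stemloop_crystal():
    return make_synthetic_crystal(
        CrystalSpec("stem-loop", stem_seq="GCGAUC", loop_seq="GAAA"), seed=7)


@pytest.fixture(scope="session")
def suite_classifier():
    return train_suite_classifier(seed=1, n_crystals=3)


@pytest.fixture(scope="session")
def acentric_reflections():
    """20k synthetic acentric reflections for phase-statistics tests."""
    rng = np.random.default_rng(0)
    n = 20000
    cell = UnitCell(60.0, 70.0, 80.0)
    return ReflectionSet(rng.integers(1, 25, (n, 3)),
                         rng.uniform(10, 100, n),
                         rng.uniform(-180, 180, n),
                         np.zeros(n, bool), cell)
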