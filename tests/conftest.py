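"""Shared fixtures: a small four-helix bundle with its restraint sets."""

from __future__ import annotations

import numpy as np
import pytest

from vsdkit._geometry import dihedral
from vsdkit.anneal import _Topology
from vsdkit.model_io import Ensemble
from vsdkit.restraints import (DihedralRestraint, calibrate_noe,
                               hbond_restraints)
from vsdkit.synthetic import (BundleSpec, make_helical_bundle,
                              simulate_noe_peaks, vsd_like_bundle_spec)

HELIX_RANGES = [(1, 12), (17, 28), (33, 44), (49, 60)]


def small_bundle_spec(d: float = 8.8) -> BundleSpec:
    return BundleSpec(helices=(
        ((1, 12), (-d / 2, -d / 2, 0.0), (0.0, 0.0, 1.0)),
        ((17, 28), (d / 2, -d / 2, 0.0), (0.0, 0.0, -1.0)),
        ((33, 44), (d / 2, d / 2, 0.0), (0.0, 0.0, 1.0)),
        ((49, 60), (-d / 2, d / 2, 0.0), (0.0, 0.0, -1.0)),
    ))


def true_helical_dihedrals(model, helix_ranges) -> list[DihedralRestraint]:
    out = []
    for lo, hi in helix_ranges:
        for r in range(lo, hi + 1):
            try:
                phi = float(dihedral(model.coord(r - 1, "C"),
                                     model.coord(r, "N"),
                                     model.coord(r, "CA"),
                                     model.coord(r, "C")))
                out.append(DihedralRestraint(r, "phi", phi, 20.0))
            except KeyError:
                pass
            try:
                psi = float(dihedral(model.coord(r, "N"),
                                     model.coord(r, "CA"),
                                     model.coord(r, "C"),
                                     model.coord(r + 1, "N")))
                out.append(DihedralRestraint(r, "psi", psi, 20.0))
            except KeyError:
                pass
    return out


@pytest.fixture(scope="session")
def small_bundle():
    """60-residue four-helix bundle (truth structure for recovery tests)."""
    return make_helical_bundle(small_bundle_spec())


@pytest.fixture(scope="session")
def vsd_bundle():
    """VSD-numbered bundle (residues 120-239)."""
    return make_helical_bundle(vsd_like_bundle_spec())


@pytest.fixture(scope="session")
def bundle_sequence(small_bundle):
    return [(r, "ALA") for r in small_bundle.residue_numbers()]


@pytest.fixture(scope="session")
def bundle_backbone_index(bundle_sequence):
    topo = _Topology(bundle_sequence)
    return [i for i, (_, n) in enumerate(topo.atom_names)
            if n in ("N", "CA", "C", "O")]


@pytest.fixture(scope="session")
def bundle_restraints(small_bundle):
    """Calibrated NOE restraints plus helical hydrogen bonds."""
    peaks = simulate_noe_peaks(small_bundle, {}, cutoff=6.0)
    return calibrate_noe(peaks) + hbond_restraints(HELIX_RANGES)


@pytest.fixture(scope="session")
def bundle_dihedrals(small_bundle):
    return true_helical_dihedrals(small_bundle, HELIX_RANGES)


@pytest.fixture(scope="session")
def noisy_ensemble(vsd_bundle):
    """Five models jittered around the VSD bundle (0.3 A noise)."""
    models = []
    for i in range(5):
        rng = np.random.default_rng(100 + i)
        xyz = vsd_bundle.xyz + rng.normal(0.0, 0.3, vsd_bundle.xyz.shape)
        models.append(vsd_bundle.with_xyz(xyz, model_id=i + 1))
    return Ensemble(models)
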