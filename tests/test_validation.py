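"""Validation statistics: counts, violations, ensemble precision,
block clustering."""

import numpy as np
import pytest

from vsdkit.model_io import (DistanceRestraint, Ensemble,
                             ResidueRangeSelection)
from vsdkit.restraints import DihedralRestraint
from vsdkit.validation import (block_cluster_centroids, count_restraints,
                               dihedral_violation_rmsd,
                               distance_violation_rmsd, effective_distance,
                               ensemble_rmsd, table1_report,
                               ENSEMBLE_SELECTION)


def dr(res_a, res_b, lo=1.8, hi=5.5, klass="weak"):
    return DistanceRestraint(((res_a, "H"),), ((res_b, "H"),), lo, hi, klass)


class TestCounts:
    @pytest.mark.parametrize("a,b,key", [
        (160, 237, "noe_long_range"),
        (130, 133, "noe_medium_range"),
        (130, 131, "noe_sequential"),
        (130, 130, "noe_intra"),
    ])
    def test_sequence_separation_bins(self, a, b, key):
        counts = count_restraints([dr(a, b)])
        assert counts[key] == 1 and counts["noe_total"] == 1

    def test_totals_and_permutation_invariance(self, bundle_restraints):
        c1 = count_restraints(bundle_restraints)
        c2 = count_restraints(bundle_restraints[::-1])
        assert c1 == c2
        noe_sum = (c1["noe_intra"] + c1["noe_sequential"]
                   + c1["noe_medium_range"] + c1["noe_long_range"])
        assert noe_sum == c1["noe_total"]
        assert c1["noe_total"] + c1["hbond"] == len(bundle_restraints)

    def test_dihedrals_counted_by_angle(self):
        ds = [DihedralRestraint(5, "phi", -60, 20),
              DihedralRestraint(5, "psi", -45, 20),
              DihedralRestraint(6, "phi", -60, 20)]
        c = count_restraints([], ds)
        assert c["dihedral_phi"] == 2 and c["dihedral_psi"] == 1


class TestDistanceViolations:
    def test_zero_on_generating_structure(self, small_bundle,
                                          bundle_restraints):
        hbonds = [r for r in bundle_restraints if r.klass == "hbond"]
        mean, sd, ledger = distance_violation_rmsd(small_bundle, hbonds)
        assert mean == 0.0 and sd == 0.0
        assert not ledger["excluded"].any()

    def test_single_violation_among_satisfied(self, small_bundle):
        # 99 trivially satisfied + 1 violated by a known margin
        sat = [dr(2, 3, 0.1, 100.0) for _ in range(99)]
        d = float(np.linalg.norm(small_bundle.coord(2, "H")
                                 - small_bundle.coord(30, "H")))
        bad = [DistanceRestraint(((2, "H"),), ((30, "H"),), 0.1, d - 0.3,
                                 "weak")]
        mean, _, _ = distance_violation_rmsd(small_bundle, sat + bad)
        assert mean == pytest.approx(np.sqrt(0.3 ** 2 / 100), rel=1e-6)

    def test_ambiguous_effective_distance(self, small_bundle):
        # pairs at distances r1, r2 -> (r1^-6 + r2^-6)^(-1/6)
        sel_a = ((2, "H"), (3, "H"))
        sel_b = ((30, "H"),)
        d_eff = effective_distance(small_bundle, sel_a, sel_b)
        r1 = np.linalg.norm(small_bundle.coord(2, "H")
                            - small_bundle.coord(30, "H"))
        r2 = np.linalg.norm(small_bundle.coord(3, "H")
                            - small_bundle.coord(30, "H"))
        assert d_eff == pytest.approx((r1 ** -6 + r2 ** -6) ** (-1 / 6.0))
        assert d_eff <= min(r1, r2)

    def test_effective_distance_hand_value(self):
        # two pairs at 3 and 5 A -> about 2.98 A
        assert (3.0 ** -6 + 5.0 ** -6) ** (-1 / 6.0) == pytest.approx(
            2.98, abs=0.01)

    def test_missing_atom_excluded_with_flag(self, small_bundle):
        rs = [dr(2, 3, 0.1, 100.0),
              DistanceRestraint(((999, "H"),), ((2, "H"),), 1.0, 2.0)]
        _, _, ledger = distance_violation_rmsd(small_bundle, rs)
        assert list(ledger["excluded"]) == [False, True]

    def test_sidechain_falls_back_to_cb(self, small_bundle):
        r = DistanceRestraint(((5, "HB"),), ((40, "HB"),), 1.8, 60.0)
        _, _, ledger = distance_violation_rmsd(small_bundle, [r])
        assert not ledger["excluded"].any()


class TestDihedralViolations:
    def test_inside_well_zero(self, small_bundle, bundle_dihedrals):
        mean, sd = dihedral_violation_rmsd(small_bundle, bundle_dihedrals)
        assert mean == 0.0 and sd == 0.0

    def test_wraparound_arithmetic(self, small_bundle):
        # measure the true angle, then center the well across the branch
        from vsdkit._geometry import dihedral
        true = float(dihedral(small_bundle.coord(4, "C"),
                              small_bundle.coord(5, "N"),
                              small_bundle.coord(5, "CA"),
                              small_bundle.coord(5, "C")))
        shifted = ((true + 10.0 + 180.0) % 360.0) - 180.0
        d = DihedralRestraint(5, "phi", shifted, 5.0)
        mean, _ = dihedral_violation_rmsd(small_bundle, [d])
        assert mean == pytest.approx(5.0, abs=1e-6)

    def test_plus_minus_180_equivalent(self):
        from vsdkit._geometry import wrap_degrees
        assert wrap_degrees(180.0 - (-180.0)) == pytest.approx(0.0)


class TestEnsembleRmsd:
    def test_identical_models_zero(self, vsd_bundle):
        ens = Ensemble([vsd_bundle.with_xyz(vsd_bundle.xyz, 1),
                        vsd_bundle.with_xyz(vsd_bundle.xyz, 2)])
        assert ensemble_rmsd(ens, ENSEMBLE_SELECTION) == 0.0

    def test_rigid_transform_invariance(self, vsd_bundle):
        rng = np.random.default_rng(5)
        q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        if np.linalg.det(q) < 0:
            q[:, 0] = -q[:, 0]
        moved = vsd_bundle.with_xyz(vsd_bundle.xyz @ q.T + [3, -7, 11], 2)
        ens = Ensemble([vsd_bundle, moved])
        assert ensemble_rmsd(ens, ENSEMBLE_SELECTION) < 1e-9

    def test_modes_agree_in_scale(self, noisy_ensemble):
        mean_mode = ensemble_rmsd(noisy_ensemble, ENSEMBLE_SELECTION, "mean")
        pair_mode = ensemble_rmsd(noisy_ensemble, ENSEMBLE_SELECTION,
                                  "pairwise")
        assert 0.5 * pair_mode < mean_mode < pair_mode

    def test_requires_two_models(self, vsd_bundle):
        with pytest.raises(ValueError):
            ensemble_rmsd(Ensemble([vsd_bundle]), ENSEMBLE_SELECTION)


class TestBlockClustering:
    def test_identical_frames(self, vsd_bundle):
        frames = [vsd_bundle.with_xyz(vsd_bundle.xyz, i + 1)
                  for i in range(100)]
        traj = Ensemble(frames)
        sel = ResidueRangeSelection(((120, 239),), "calpha")
        centroids, flags = block_cluster_centroids(traj, 10, 1.0, 3, sel)
        assert len(centroids) == 10
        assert not any(flags)
        for c in centroids:
            assert np.array_equal(c.xyz, vsd_bundle.xyz)

    def test_majority_cluster_wins(self, vsd_bundle):
        # 7 frames near conformer A, 3 near well-separated conformer B
        rng = np.random.default_rng(0)
        shift = np.zeros_like(vsd_bundle.xyz)
        shift[:len(shift) // 2] += 20.0  # large internal rearrangement
        frames = []
        for i in range(10):
            base = vsd_bundle.xyz + (0 if i < 7 else shift)
            frames.append(vsd_bundle.with_xyz(
                base + rng.normal(0, 0.05, base.shape), i + 1))
        sel = ResidueRangeSelection(((120, 239),), "calpha")
        centroids, flags = block_cluster_centroids(
            Ensemble(frames), 10, 1.0, 2, sel)
        assert not flags[0]
        # centroid belongs to the 70 % conformer
        from vsdkit._geometry import aligned_rmsd
        idx = sel.atom_indices(vsd_bundle)
        assert aligned_rmsd(centroids[0].xyz[idx],
                            vsd_bundle.xyz[idx]) < 1.0

    def test_all_noise_falls_back_to_medoid(self, vsd_bundle):
        rng = np.random.default_rng(1)
        frames = [vsd_bundle.with_xyz(
            vsd_bundle.xyz + rng.normal(0, 3.0, vsd_bundle.xyz.shape),
            i + 1) for i in range(5)]
        sel = ResidueRangeSelection(((120, 239),), "calpha")
        centroids, flags = block_cluster_centroids(
            Ensemble(frames), 5, 1e-6, 2, sel)
        assert flags == [True]
        assert len(centroids) == 1


class TestReport:
    def test_full_report_assembles(self, noisy_ensemble, bundle_restraints):
        # restraints refer to 1-60 numbering; use hbond restraints for the
        # VSD numbering instead
        from vsdkit.restraints import hbond_restraints
        rs = hbond_restraints([(120, 142), (160, 179)])
        report = table1_report(noisy_ensemble, rs, [])
        text = report.summary()
        assert "Hydrogen bonds" in text
        assert report.ensemble_rmsd_backbone > 0
        assert report.counts["hbond"] == len(rs)
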