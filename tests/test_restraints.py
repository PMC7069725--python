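"""NOE calibration, PRE inversion, torsion filtering, hydrogen bonds."""

import numpy as np
import pandas as pd
import pytest

from vsdkit.restraints import (CalibrationError, DihedralRestraint,
                               NOE_CLASS_BOUNDS, TorsionPrediction,
                               calibrate_noe, filter_torsions,
                               hbond_restraints, invert_pre_ratio,
                               pre_to_restraints)
from vsdkit.synthetic import (pre_gamma2, pre_intensity_ratio, simulate_pre,
                              simulate_noe_peaks)


def peak_frame(intensities, residues=None, group=None):
    n = len(intensities)
    residues = residues or [(i + 1, i + 10) for i in range(n)]
    df = pd.DataFrame({
        "residue_a": [a for a, _ in residues],
        "atom_a": ["H"] * n,
        "residue_b": [b for _, b in residues],
        "atom_b": ["H"] * n,
        "intensity": intensities,
    })
    if group is not None:
        df["group"] = group
    return df


class TestNoeCalibration:
    def test_class_bounds_are_canonical(self):
        assert NOE_CLASS_BOUNDS == {
            "strong": (1.8, 2.8), "medium": (1.8, 3.5),
            "weak": (1.8, 4.5), "very_weak": (1.8, 5.5)}

    def test_top_quantile_is_strong(self):
        df = peak_frame([1.0, 2.0, 4.0, 8.0, 16.0, 32.0, 64.0, 128.0])
        rs = calibrate_noe(df)
        strongest = max(zip(df["intensity"], rs))[1]
        assert (strongest.d_low, strongest.d_high) == (1.8, 2.8)
        weakest = min(zip(df["intensity"], rs))[1]
        assert (weakest.d_low, weakest.d_high) == (1.8, 5.5)

    def test_per_group_calibration_is_scale_invariant(self):
        base = [1.0, 2.0, 4.0, 8.0, 16.0, 32.0, 64.0, 128.0]
        df = peak_frame(base + [0.5 * x for x in base],
                        residues=[(i + 1, i + 10) for i in range(16)],
                        group=["periphery"] * 8 + ["core"] * 8)
        rs = calibrate_noe(df)
        classes_p = [r.klass for r in rs if "periphery" in r.provenance]
        classes_c = [r.klass for r in rs if "core" in r.provenance]
        assert classes_p == classes_c

    def test_strong_closer_than_very_weak_on_noise_free_peaks(
            self, small_bundle):
        peaks = simulate_noe_peaks(small_bundle, {}, noise_sd=0.0)
        rs = calibrate_noe(peaks)
        by_class = {}
        for r, true_r in zip(rs, peaks["r_true"]):
            by_class.setdefault(r.klass, []).append(true_r)
        assert max(by_class["strong"]) <= min(by_class["very_weak"])

    def test_small_group_raises(self):
        df = peak_frame([1.0, 2.0, 3.0])
        with pytest.raises(CalibrationError):
            calibrate_noe(df)

    def test_all_noe_bounds_canonical(self, bundle_restraints):
        noe = [r for r in bundle_restraints if r.klass in NOE_CLASS_BOUNDS]
        assert all(r.d_low == 1.8 for r in noe)
        assert all(r.d_high in (2.8, 3.5, 4.5, 5.5) for r in noe)


PRE_KW = dict(tau_c_s=20e-9, t_inept_s=10e-3, field_mhz=900.0)


def pre_frame(rows):
    return pd.DataFrame(rows, columns=["label_residue", "target_residue",
                                       "i_para", "i_dia", "fwhm_dia"])


class TestPreBinning:
    @pytest.mark.parametrize("ratio,expected", [
        (0.10, (2.0, 18.0)),
        (0.19999, (2.0, 18.0)),
        (0.95, (19.0, 100.0)),
        (0.80001, (19.0, 100.0)),
    ])
    def test_outer_bins(self, ratio, expected):
        (r,) = pre_to_restraints(pre_frame([(10, 50, ratio, 1.0, 20.0)]),
                                 **PRE_KW)
        assert (r.d_low, r.d_high) == expected

    def test_boundary_ratios_fall_in_explicit_regime(self):
        for ratio in (0.2, 0.8):
            (r,) = pre_to_restraints(pre_frame([(10, 50, ratio, 1.0, 20.0)]),
                                     **PRE_KW)
            assert r.klass == "pre_mid"

    def test_explicit_distance_example(self):
        # ratio 0.69, 20 Hz diamagnetic line, 10 ms, tau_c 20 ns, 900 MHz
        (r,) = pre_to_restraints(pre_frame([(10, 50, 0.69, 1.0, 20.0)]),
                                 **PRE_KW)
        r_star = 0.5 * (r.d_low + r.d_high)
        assert r_star == pytest.approx(20.0, abs=0.1)
        assert r.d_high - r.d_low == pytest.approx(12.0)

    def test_selections_span_label_cb_to_amide(self):
        (r,) = pre_to_restraints(pre_frame([(10, 50, 0.5, 1.0, 20.0)]),
                                 **PRE_KW)
        assert r.sel_a == ((10, "CB"),)
        assert r.sel_b == ((50, "H"),)

    def test_unphysical_records_rejected(self):
        rs = pre_to_restraints(pre_frame([(10, 50, -0.1, 1.0, 20.0),
                                          (10, 51, 1.5, 1.0, 20.0),
                                          (10, 52, 0.5, 1.0, 20.0)]),
                               **PRE_KW)
        assert len(rs) == 1

    def test_s0_exclusion_filter(self):
        rs = pre_to_restraints(pre_frame([(10, 50, 0.5, 1.0, 20.0),
                                          (10, 105, 0.5, 1.0, 20.0)]),
                               exclude_residues=[(100, 110)], **PRE_KW)
        assert [r.sel_b[0][0] for r in rs] == [50]

    def test_monotone_inversion(self):
        r2 = np.pi * 20.0
        rs = [invert_pre_ratio(x, r2, 20e-9, 10e-3, 900.0)
              for x in np.linspace(0.21, 0.79, 15)]
        assert (np.diff(rs) > 0).all()

    def test_bisection_residual(self):
        r2 = np.pi * 20.0
        for ratio in (0.25, 0.5, 0.75):
            r_star = invert_pre_ratio(ratio, r2, 20e-9, 10e-3, 900.0)
            g2 = pre_gamma2(r_star, 20e-9, 900.0)
            assert abs(pre_intensity_ratio(g2, r2, 10e-3) - ratio) < 1e-9

    def test_roundtrip_bounds_contain_truth(self, small_bundle):
        """Noise-free forward PRE -> restraints: every true distance lies
        inside the emitted bounds."""
        df = simulate_pre(small_bundle, [5, 40], noise_sd=0.0)
        df = df[(df.i_para / df.i_dia) > 0]
        rs = pre_to_restraints(df, **PRE_KW)
        kept = df.reset_index(drop=True)
        assert len(rs) == len(kept)
        for r, true_r in zip(rs, kept["r_true"]):
            assert r.d_low <= true_r <= r.d_high

    def test_midrange_recovery_within_tolerance(self, small_bundle):
        df = simulate_pre(small_bundle, [5, 40], noise_sd=0.0)
        mid = df[(df.i_para / df.i_dia).between(0.2, 0.8)]
        rs = pre_to_restraints(mid, **PRE_KW)
        for r, true_r in zip(rs, mid["r_true"]):
            assert 0.5 * (r.d_low + r.d_high) == pytest.approx(true_r,
                                                               abs=1e-3)


class TestTorsionFilter:
    def test_strong_high_confidence_kept(self):
        preds = [TorsionPrediction(5, -60.0, -45.0, 5.0, 5.0, "Strong", 9)]
        out = filter_torsions(preds)
        assert len(out) == 2
        phi = next(d for d in out if d.angle == "phi")
        assert (phi.center, phi.half_width) == (-60.0, 20.0)

    @pytest.mark.parametrize("klass,conf", [
        ("strong", 6), ("Generous", 10), ("dyn", 9)])
    def test_filtered_out(self, klass, conf):
        preds = [TorsionPrediction(5, -60.0, -45.0, 5.0, 5.0, klass, conf)]
        assert filter_torsions(preds) == []

    def test_confidence_validation(self):
        with pytest.raises(ValueError):
            TorsionPrediction(5, -60.0, -45.0, 5.0, 5.0, "strong", 11)


class TestHbondRestraints:
    def test_nine_residue_helix_counts(self):
        rs = hbond_restraints([(1, 9)])
        assert len(rs) == 10  # 5 donor/acceptor pairs x 2 restraints
        oh = [r for r in rs if r.sel_b[0][1] == "H"]
        assert all((r.d_low, r.d_high) == (1.8, 2.3) for r in oh)
        on = [r for r in rs if r.sel_b[0][1] == "N"]
        assert all((r.d_low, r.d_high) == (2.8, 3.3) for r in on)

    def test_no_cross_range_pairs(self):
        rs = hbond_restraints([(120, 142), (160, 179)])
        for r in rs:
            i, j = r.sel_a[0][0], r.sel_b[0][0]
            assert (120 <= i <= 142 and 120 <= j <= 142) or \
                   (160 <= i <= 179 and 160 <= j <= 179)

    def test_short_range_skipped(self):
        assert hbond_restraints([(1, 4)]) == []

    def test_vsd_helix_ranges_can_yield_55_pairs(self):
        # 5 helical segments sized to give 55 O(i)-H(i+4) hydrogen bonds
        ranges = [(104, 109), (120, 142), (160, 179), (198, 215),
                  (219, 226)]
        rs = hbond_restraints(ranges)
        oh_pairs = [r for r in rs if r.sel_b[0][1] == "H"]
        assert len(oh_pairs) == 55
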