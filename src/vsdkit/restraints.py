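"""Conversion of raw NMR observables into flat-well structural restraints.

Implements the calibration rules used for the voltage-sensor structure
determination: NOE cross-peaks are split into two amplitude groups and
binned by intensity into strong / medium / weak / very-weak classes with
bounds 1.8-2.8, 1.8-3.5, 1.8-4.5 and 1.8-5.5 A; PRE intensity ratios are
binned at 0.2 and 0.8 (below 0.2 -> 2-18 A, above 0.8 -> 19-100 A, the
middle regime inverted through the Solomon-Bloembergen model to an
explicit distance +- 6 A); TALOS-style torsion predictions are kept only
when classified 'strong' with confidence >= 7, with a 20 degree error;
and alpha-helical hydrogen bonds contribute O(i)-H(i+4) / O(i)-N(i+4)
distance pairs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .model_io import DistanceRestraint
from .synthetic import pre_intensity_ratio

logger = logging.getLogger(__name__)

__all__ = [
    "PRERecord", "DihedralRestraint", "TorsionPrediction",
    "calibrate_noe", "pre_to_restraints", "filter_torsions",
    "hbond_restraints", "invert_pre_ratio", "CalibrationError",
    "NOE_CLASS_BOUNDS",
]

NOE_CLASS_BOUNDS = {
    "strong": (1.8, 2.8),
    "medium": (1.8, 3.5),
    "weak": (1.8, 4.5),
    "very_weak": (1.8, 5.5),
}


class CalibrationError(ValueError):
    pass


@dataclass(frozen=True)
class PRERecord:
    label_residue: int
    target_residue: int
    i_para: float
    i_dia: float
    fwhm_dia: float  # Hz

    def __post_init__(self):
        if self.i_dia <= 0:
            raise ValueError("diamagnetic intensity must be positive")
        if self.fwhm_dia <= 0:
            raise ValueError("diamagnetic linewidth must be positive")


@dataclass(frozen=True)
class DihedralRestraint:
    residue: int
    angle: str  # phi | psi
    center: float  # degrees, in (-180, 180]
    half_width: float  # degrees

    def __post_init__(self):
        if self.angle not in ("phi", "psi"):
            raise ValueError("angle must be 'phi' or 'psi'")
        if not (-180.0 < self.center <= 180.0):
            raise ValueError("center must lie in (-180, 180]")
        if self.half_width <= 0:
            raise ValueError("half width must be positive")


@dataclass(frozen=True)
class TorsionPrediction:
    residue: int
    phi: float
    psi: float
    dphi: float
    dpsi: float
    klass: str
    confidence: int

    def __post_init__(self):
        if not (0 <= self.confidence <= 10):
            raise ValueError("confidence must lie in [0, 10]")


# -- NOE calibration -------------------------------------------------------

def calibrate_noe(peaks: pd.DataFrame,
                  group_map: Mapping[int, str] | None = None,
                  bin_quantiles: Sequence[float] = (0.25, 0.5, 0.75),
                  ) -> list[DistanceRestraint]:
    """Classify NOE peaks by intensity within each calibration group and
    assign class distance bounds.

    Within a group, log-intensities are cut at ``bin_quantiles`` (ascending);
    the highest-intensity bin is 'strong'. The per-group calibration makes
    the classification invariant to a uniform intensity scale within a
    group. A peak belongs to the 'core' group when both of its residues
    map to 'core' (else 'periphery'); a precomputed ``group`` column takes
    precedence.
    """
    q = tuple(bin_quantiles)
    if len(q) != 3 or any(b <= a for a, b in zip(q, q[1:])):
        raise ValueError("bin_quantiles must be 3 ascending fractions")
    peaks = peaks.copy()
    if "group" not in peaks.columns:
        if group_map is None:
            peaks["group"] = "periphery"
        else:
            both_core = (peaks["residue_a"].map(group_map).eq("core")
                         & peaks["residue_b"].map(group_map).eq("core"))
            peaks["group"] = np.where(both_core, "core", "periphery")

    restraints: list[DistanceRestraint] = []
    for group, sub in peaks.groupby("group", sort=True):
        if len(sub) < 4:
            raise CalibrationError(
                f"group {group!r} has {len(sub)} peaks; need >= 4 "
                "for quantile calibration")
        logi = np.log(sub["intensity"].to_numpy(dtype=float))
        cuts = np.quantile(logi, q)
        classes = np.select(
            [logi >= cuts[2], logi >= cuts[1], logi >= cuts[0]],
            ["strong", "medium", "weak"], default="very_weak")
        for (_, row), klass in zip(sub.iterrows(), classes):
            lo, hi = NOE_CLASS_BOUNDS[klass]
            restraints.append(DistanceRestraint(
                sel_a=((int(row["residue_a"]), str(row["atom_a"])),),
                sel_b=((int(row["residue_b"]), str(row["atom_b"])),),
                d_low=lo, d_high=hi, klass=klass,
                provenance=f"noe:{group}:{row['residue_a']}-{row['residue_b']}",
            ))
    return restraints


# -- PRE inversion ---------------------------------------------------------

def invert_pre_ratio(ratio: float, r2_dia: float, tau_c_s: float,
                     t_inept_s: float, field_mhz: float,
                     tol: float = 1e-12) -> float:
    """Distance (A) whose Solomon-Bloembergen PRE reproduces ``ratio``.

    Gamma_2 is found by bisection on [0, 1e6] s^-1 (the forward ratio is
    strictly decreasing in Gamma_2), then inverted through the r^-6 law.
    """
    lo, hi = 0.0, 1.0e6
    f_lo = pre_intensity_ratio(lo, r2_dia, t_inept_s) - ratio
    f_hi = pre_intensity_ratio(hi, r2_dia, t_inept_s) - ratio
    if f_lo < 0 or f_hi > 0:
        raise ValueError(f"ratio {ratio} outside the invertible range")
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        f_mid = pre_intensity_ratio(mid, r2_dia, t_inept_s) - ratio
        if abs(f_mid) < tol:
            break
        if f_mid > 0:
            lo = mid
        else:
            hi = mid
    gamma2 = 0.5 * (lo + hi)
    # invert Gamma_2 = K/r^6 * j(tau_c): r^6 = K j / Gamma_2
    omega = 2 * np.pi * field_mhz * 1e6
    spectral = 4 * tau_c_s + 3 * tau_c_s / (1 + (omega * tau_c_s) ** 2)
    from .synthetic import SB_CONSTANT_CM6_S2
    r_cm = (SB_CONSTANT_CM6_S2 * spectral / gamma2) ** (1.0 / 6.0)
    return float(r_cm * 1e8)


def pre_to_restraints(records, tau_c_s: float, t_inept_s: float,
                      field_mhz: float,
                      exclude_residues: Sequence[tuple[int, int]] = (),
                      ) -> list[DistanceRestraint]:
    """Bin PRE intensity ratios into distance restraints.

    ratio < 0.2 -> bounds (2, 18); 0.2 <= ratio <= 0.8 -> explicit distance
    r* +- 6 A (clipped to [2, 100]); ratio > 0.8 -> bounds (19, 100). The
    restraint spans the CB of the label residue to the target amide H.
    ``exclude_residues`` drops targets inside the given inclusive ranges
    (used for mobile elements such as the S0 helix). Records with
    non-positive or unphysical (> 1.2) ratios are rejected with a logged
    diagnostic.
    """
    if isinstance(records, pd.DataFrame):
        records = [PRERecord(int(r.label_residue), int(r.target_residue),
                             float(r.i_para), float(r.i_dia),
                             float(r.fwhm_dia))
                   for r in records.itertuples()]
    out: list[DistanceRestraint] = []
    for rec in records:
        if any(a <= rec.target_residue <= b for a, b in exclude_residues):
            continue
        ratio = rec.i_para / rec.i_dia
        if not np.isfinite(ratio) or ratio <= 0:
            logger.warning("PRE record %s-%s rejected: ratio %.3g <= 0",
                           rec.label_residue, rec.target_residue, ratio)
            continue
        if ratio > 1.2:
            logger.warning("PRE record %s-%s rejected: ratio %.3g "
                           "unphysical (> 1.2)",
                           rec.label_residue, rec.target_residue, ratio)
            continue
        if ratio < 0.2:
            lo, hi, klass = 2.0, 18.0, "pre_short"
        elif ratio <= 0.8:
            r2 = np.pi * rec.fwhm_dia  # Lorentzian line: R2 = pi * FWHM
            r_star = invert_pre_ratio(ratio, r2, tau_c_s, t_inept_s,
                                      field_mhz)
            lo = max(2.0, r_star - 6.0)
            hi = min(100.0, r_star + 6.0)
            klass = "pre_mid"
        else:
            lo, hi, klass = 19.0, 100.0, "pre_long"
        out.append(DistanceRestraint(
            sel_a=((rec.label_residue, "CB"),),
            sel_b=((rec.target_residue, "H"),),
            d_low=lo, d_high=hi, klass=klass,
            provenance=f"pre:{rec.label_residue}->{rec.target_residue}",
        ))
    return out


# -- torsion filtering -----------------------------------------------------

def filter_torsions(preds: Iterable[TorsionPrediction] | pd.DataFrame,
                    ) -> list[DihedralRestraint]:
    """Keep predictions classified 'strong' (case-insensitive) with
    confidence >= 7; emit phi and psi restraints with a 20 degree half
    width."""
    if isinstance(preds, pd.DataFrame):
        preds = [TorsionPrediction(int(r.residue), float(r.phi), float(r.psi),
                                   float(r.dphi), float(r.dpsi),
                                   str(r.klass), int(r.confidence))
                 for r in preds.itertuples()]
    out: list[DihedralRestraint] = []
    for p in preds:
        if p.klass.lower() != "strong" or p.confidence < 7:
            continue
        out.append(DihedralRestraint(p.residue, "phi", p.phi, 20.0))
        out.append(DihedralRestraint(p.residue, "psi", p.psi, 20.0))
    return out


# -- helical hydrogen bonds ------------------------------------------------

def hbond_restraints(helix_ranges: Sequence[tuple[int, int]],
                     ) -> list[DistanceRestraint]:
    """Alpha-helical i -> i+4 hydrogen-bond restraints.

    For every i with both i and i+4 inside a range: O(i)-H(i+4) bounded
    (1.8, 2.3) and O(i)-N(i+4) bounded (2.8, 3.3). Ranges shorter than 5
    residues are skipped with a warning.
    """
    out: list[DistanceRestraint] = []
    for start, end in helix_ranges:
        if end - start + 1 < 5:
            logger.warning("helix range %s-%s shorter than 5 residues; "
                           "skipped", start, end)
            continue
        for i in range(start, end - 3):
            for name, (lo, hi) in (("H", (1.8, 2.3)), ("N", (2.8, 3.3))):
                out.append(DistanceRestraint(
                    sel_a=((i, "O"),), sel_b=((i + 4, name),),
                    d_low=lo, d_high=hi, klass="hbond",
                    provenance=f"hbond:{i}->{i + 4}:{name}",
                ))
    return out
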