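"""Comparison of voltage-sensor conformations.

Quantifies the intermediate-to-activated transition: helix axes by
principal-component analysis of the CA trace, the signed translation of
the S4 helix along the membrane normal after superposition on the static
S1-S3 core, salt-bridge registry between S4 basic residues and S2/S3
acidic residues, and the helical span of a segment from backbone
torsions.

Residue numbering between orthologs is handled by a fixed offset map
(human G229 corresponds to Xenopus G219, offset 10).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from ._geometry import dihedral, kabsch_rotation
from .model_io import StructureModel

logger = logging.getLogger(__name__)

__all__ = [
    "HelixAxis", "IonPair", "ResidueMap", "helix_axis", "s4_displacement",
    "detect_ion_pairs", "helical_span",
    "CORE_RANGES", "S4_RANGE",
]

# S1-S3 core and S4 presets (human voltage-sensor numbering)
CORE_RANGES = ((120, 142), (160, 179), (198, 215))
S4_RANGE = (219, 239)

BASIC_SIDECHAIN_N = {
    "ARG": ("NE", "NH1", "NH2"),
    "LYS": ("NZ",),
    "HIS": ("ND1", "NE2"),  # both ring nitrogens regardless of protonation
}
ACIDIC_SIDECHAIN_O = {
    "ASP": ("OD1", "OD2"),
    "GLU": ("OE1", "OE2"),
}


@dataclass(frozen=True)
class HelixAxis:
    origin: tuple[float, float, float]   # CA centroid, A
    direction: tuple[float, float, float]  # unit, toward increasing residue
    residue_range: tuple[int, int]

    def as_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        return np.asarray(self.origin), np.asarray(self.direction)


@dataclass(frozen=True)
class IonPair:
    basic_residue: tuple[int, str]
    acidic_residue: tuple[int, str]
    min_no_distance: float  # A


@dataclass(frozen=True)
class ResidueMap:
    """Fixed numbering offset: residue r in the reference numbering maps
    to r - offset in the other model."""

    offset: int = 0

    def map(self, residue: int) -> int:
        return residue - self.offset


def _ca_coords(model: StructureModel, start: int, end: int) -> np.ndarray:
    pts = [model.coord(r, "CA") for r in range(start, end + 1)
           if model.has_atom(r, "CA")]
    return np.array(pts)


def helix_axis(model: StructureModel,
               residue_range: tuple[int, int]) -> HelixAxis:
    """Helix axis as the first principal component of the centered CA
    coordinates, oriented toward the C-terminal end."""
    ca = _ca_coords(model, *residue_range)
    if len(ca) < 4:
        raise ValueError(
            f"need >= 4 CA atoms in range {residue_range}, got {len(ca)}")
    centroid = ca.mean(axis=0)
    centered = ca - centroid
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    direction = vt[0]
    # orient toward increasing residue number
    if np.dot(ca[-1] - ca[0], direction) < 0:
        direction = -direction
    return HelixAxis(tuple(centroid), tuple(direction), tuple(residue_range))


def membrane_normal(model: StructureModel,
                    core_ranges=CORE_RANGES) -> np.ndarray:
    """Membrane normal: normalized mean of the core (S1-S3) helix axes,
    consistently oriented, with the extracellular side fixed by requiring
    a positive projection of the S3 C-terminus -> N-terminus vector."""
    axes = [helix_axis(model, r) for r in core_ranges]
    s3 = axes[-1]
    s3_start, s3_end = s3.residue_range
    ref = model.coord(s3_start, "CA") - model.coord(s3_end, "CA")
    dirs = []
    for ax in axes:
        _, d = ax.as_arrays()
        dirs.append(d if np.dot(d, ref) > 0 else -d)
    normal = np.mean(dirs, axis=0)
    return normal / np.linalg.norm(normal)


def s4_displacement(model_a: StructureModel, model_b: StructureModel,
                    core_ranges=CORE_RANGES,
                    s4_range: tuple[int, int] = S4_RANGE,
                    residue_map: ResidueMap = ResidueMap(0)) -> float:
    """Signed S4 translation along the membrane normal (A), model_b
    relative to model_a.

    model_b is superposed onto model_a on the shared core CA atoms
    (numbering in model_b mapped through ``residue_map``); the
    displacement is the difference of S4 CA centroids projected on the
    membrane normal of model_a. Positive values point extracellularly
    under the S3-based orientation convention.
    """
    core_a, core_b, missing = [], [], []
    for start, end in core_ranges:
        for r in range(start, end + 1):
            rb = residue_map.map(r)
            if model_a.has_atom(r, "CA") and model_b.has_atom(rb, "CA"):
                core_a.append(model_a.coord(r, "CA"))
                core_b.append(model_b.coord(rb, "CA"))
    s4_a, s4_b = [], []
    for r in range(s4_range[0], s4_range[1] + 1):
        rb = residue_map.map(r)
        if model_a.has_atom(r, "CA") and model_b.has_atom(rb, "CA"):
            s4_a.append(model_a.coord(r, "CA"))
            s4_b.append(model_b.coord(rb, "CA"))
        else:
            missing.append(r)
    if len(core_a) < 3 or not s4_a:
        raise ValueError(
            f"insufficient shared CA atoms after mapping; missing S4 "
            f"residues: {missing}")
    core_a = np.array(core_a)
    core_b = np.array(core_b)
    ca_mean, cb_mean = core_a.mean(axis=0), core_b.mean(axis=0)
    rot = kabsch_rotation(core_b - cb_mean, core_a - ca_mean)
    s4_b_sup = (np.array(s4_b) - cb_mean) @ rot.T + ca_mean
    normal = membrane_normal(model_a, core_ranges)
    delta = s4_b_sup.mean(axis=0) - np.array(s4_a).mean(axis=0)
    return float(np.dot(delta, normal))


def detect_ion_pairs(model: StructureModel,
                     cutoff: float = 4.0) -> list[IonPair]:
    """Salt bridges: basic side-chain N to acidic side-chain O pairs with
    minimum distance <= cutoff, sorted by distance. Residues with missing
    side chains are skipped."""
    basics, acidics = [], []
    for res in model.residue_numbers():
        name = model.residue_name(res)
        if name in BASIC_SIDECHAIN_N:
            atoms = [model.coord(res, a) for a in BASIC_SIDECHAIN_N[name]
                     if model.has_atom(res, a)]
            if atoms:
                basics.append((res, name, np.array(atoms)))
            else:
                logger.debug("residue %s %s lacks side-chain N; skipped",
                             name, res)
        elif name in ACIDIC_SIDECHAIN_O:
            atoms = [model.coord(res, a) for a in ACIDIC_SIDECHAIN_O[name]
                     if model.has_atom(res, a)]
            if atoms:
                acidics.append((res, name, np.array(atoms)))
    pairs = []
    for bres, bname, bxyz in basics:
        for ares, aname, axyz in acidics:
            diff = bxyz[:, None, :] - axyz[None, :, :]
            dmin = float(np.sqrt(np.sum(diff ** 2, axis=-1)).min())
            if dmin <= cutoff:
                pairs.append(IonPair((bres, bname), (ares, aname), dmin))
    pairs.sort(key=lambda p: p.min_no_distance)
    return pairs


def helical_span(model: StructureModel,
                 candidate_range: tuple[int, int],
                 phi_range: tuple[float, float] = (-100.0, -30.0),
                 psi_range: tuple[float, float] = (-80.0, -5.0),
                 min_run: int = 4) -> tuple[int, int] | None:
    """Longest contiguous alpha-helical stretch within a residue range.

    A residue is helical when its (phi, psi) fall inside the alpha
    region; runs shorter than ``min_run`` are discarded. Chain breaks
    (C-N distance > 2.5 A) truncate a run. Returns (start, end) or None.
    """
    start, end = candidate_range
    helical = {}
    for res in range(start, end + 1):
        try:
            phi = dihedral(model.coord(res - 1, "C"), model.coord(res, "N"),
                           model.coord(res, "CA"), model.coord(res, "C"))
            psi = dihedral(model.coord(res, "N"), model.coord(res, "CA"),
                           model.coord(res, "C"), model.coord(res + 1, "N"))
        except KeyError:
            helical[res] = False
            continue
        broken = False
        if model.has_atom(res - 1, "C") and model.has_atom(res, "N"):
            if np.linalg.norm(model.coord(res - 1, "C")
                              - model.coord(res, "N")) > 2.5:
                broken = True
        helical[res] = (not broken
                        and phi_range[0] <= phi <= phi_range[1]
                        and psi_range[0] <= psi <= psi_range[1])
    best = None
    run_start = None
    for res in range(start, end + 2):
        if helical.get(res, False):
            if run_start is None:
                run_start = res
        else:
            if run_start is not None:
                length = res - run_start
                if length >= min_run and (
                        best is None or length > best[1] - best[0] + 1):
                    best = (run_start, res - 1)
                run_start = None
    return best
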