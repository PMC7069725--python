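"""Ensemble-versus-restraint validation statistics.

Computes the statistics reported for NMR ensembles: restraint tallies by
class and sequence separation, violation r.m.s.d.s against distance and
dihedral restraints, coordinate r.m.s.d. of the ensemble about its mean
structure, and trajectory block clustering (DBSCAN on pairwise r.m.s.d.)
for centroid extraction.

The violation statistic is the r.m.s.d. of zero-floored flat-well
violations (a fully satisfied restraint contributes 0), reported as
mean +- sd over the models of the ensemble.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import DBSCAN

from ._geometry import aligned_rmsd, dihedral, superpose, wrap_degrees
from .model_io import (DistanceRestraint, Ensemble, ResidueRangeSelection,
                       StructureModel)
from .restraints import DihedralRestraint

logger = logging.getLogger(__name__)

__all__ = [
    "ValidationReport", "count_restraints", "distance_violation_rmsd",
    "dihedral_violation_rmsd", "ensemble_rmsd", "block_cluster_centroids",
    "effective_distance", "table1_report",
    "ENSEMBLE_SELECTION", "TM_SELECTION",
]

# ordered-region and transmembrane presets for the voltage-sensor construct
ENSEMBLE_SELECTION = ResidueRangeSelection(((120, 152), (160, 239)))
TM_SELECTION = ResidueRangeSelection(
    ((120, 142), (160, 179), (198, 215), (219, 239)))


# -- restraint tallies -----------------------------------------------------

NOE_CLASSES = ("strong", "medium", "weak", "very_weak")


def count_restraints(restraints: list[DistanceRestraint],
                     dihedrals: list[DihedralRestraint] | None = None,
                     ) -> dict[str, int]:
    """Tally restraints: NOE classes partitioned by sequence separation
    |i-j| (0 intra, 1 sequential, 2-4 medium-range, >= 5 long-range);
    other distance classes counted by klass; dihedrals by angle."""
    counts = {
        "noe_total": 0, "noe_intra": 0, "noe_sequential": 0,
        "noe_medium_range": 0, "noe_long_range": 0,
    }
    for r in restraints:
        if r.klass in NOE_CLASSES:
            counts["noe_total"] += 1
            sep = r.sequence_separation()
            if sep == 0:
                counts["noe_intra"] += 1
            elif sep == 1:
                counts["noe_sequential"] += 1
            elif sep < 5:
                counts["noe_medium_range"] += 1
            else:
                counts["noe_long_range"] += 1
        else:
            counts[r.klass] = counts.get(r.klass, 0) + 1
    if dihedrals:
        for d in dihedrals:
            key = f"dihedral_{d.angle}"
            counts[key] = counts.get(key, 0) + 1
    return counts


# -- distance violations ---------------------------------------------------

def effective_distance(model: StructureModel, sel_a, sel_b) -> float:
    """r^-6-summed effective distance over an ambiguous selection pair:
    (sum_pairs r^-6)^(-1/6); always <= the minimum pairwise distance."""
    pa = np.array([model.coord(res, name) for res, name in sel_a])
    pb = np.array([model.coord(res, name) for res, name in sel_b])
    diff = pa[:, None, :] - pb[None, :, :]
    r = np.sqrt(np.sum(diff ** 2, axis=-1)).ravel()
    return float(np.sum(r ** -6.0) ** (-1.0 / 6.0))


def _resolve_selection(model: StructureModel, sel,
                       cb_fallback: bool) -> tuple[tuple, float]:
    """Map a selection onto atoms present in the model.

    Missing side-chain atoms fall back to the residue CB with a +1.0 A
    upper-bound correction (reduced-representation convention); returns
    (resolved selection, bound correction)."""
    resolved = []
    correction = 0.0
    for res, name in sel:
        if model.has_atom(res, name):
            resolved.append((res, name))
        elif cb_fallback and name not in ("N", "CA", "C", "O", "H") \
                and model.has_atom(res, "CB"):
            resolved.append((res, "CB"))
            correction = 1.0
    return tuple(dict.fromkeys(resolved)), correction


def distance_violation_rmsd(ensemble: Ensemble | StructureModel,
                            restraints: list[DistanceRestraint],
                            cb_fallback: bool = True,
                            ) -> tuple[float, float, pd.DataFrame]:
    """Flat-well violation r.m.s.d. (mean, sd over models, per-restraint
    ledger).

    Per model, violation_k = max(0, d_k - d_high, d_low - d_k) with
    r^-6-sum averaging over ambiguous selections; the model statistic is
    sqrt(mean_k violation_k^2). Restraints with unresolvable atoms are
    excluded and flagged in the ledger.
    """
    if isinstance(ensemble, StructureModel):
        ensemble = Ensemble([ensemble])
    ledger_rows = []
    model_rmsds = []
    per_restraint_viol = np.zeros((len(ensemble), len(restraints)))
    usable = np.ones(len(restraints), dtype=bool)
    resolved_cache = []
    ref = ensemble[0]
    for k, r in enumerate(restraints):
        sel_a, corr_a = _resolve_selection(ref, r.sel_a, cb_fallback)
        sel_b, corr_b = _resolve_selection(ref, r.sel_b, cb_fallback)
        if not sel_a or not sel_b:
            usable[k] = False
            logger.warning("restraint %s references missing atoms; excluded",
                           r.provenance or k)
        resolved_cache.append((sel_a, sel_b, corr_a + corr_b))
    for mi, model in enumerate(ensemble):
        viol2 = []
        for k, r in enumerate(restraints):
            if not usable[k]:
                continue
            sel_a, sel_b, corr = resolved_cache[k]
            d = effective_distance(model, sel_a, sel_b)
            v = max(0.0, d - (r.d_high + corr), r.d_low - d)
            per_restraint_viol[mi, k] = v
            viol2.append(v * v)
        model_rmsds.append(np.sqrt(np.mean(viol2)) if viol2 else 0.0)
    for k, r in enumerate(restraints):
        ledger_rows.append({
            "provenance": r.provenance, "klass": r.klass,
            "d_low": r.d_low, "d_high": r.d_high,
            "mean_violation": (per_restraint_viol[:, k].mean()
                               if usable[k] else np.nan),
            "max_violation": (per_restraint_viol[:, k].max()
                              if usable[k] else np.nan),
            "excluded": not usable[k],
        })
    return (float(np.mean(model_rmsds)), float(np.std(model_rmsds)),
            pd.DataFrame(ledger_rows))


# -- dihedral violations ---------------------------------------------------

def _measure_dihedral(model: StructureModel, res: int,
                      angle: str) -> float | None:
    try:
        if angle == "phi":
            pts = [model.coord(res - 1, "C"), model.coord(res, "N"),
                   model.coord(res, "CA"), model.coord(res, "C")]
        else:
            pts = [model.coord(res, "N"), model.coord(res, "CA"),
                   model.coord(res, "C"), model.coord(res + 1, "N")]
    except KeyError:
        return None
    return float(dihedral(*pts))


def dihedral_violation_rmsd(ensemble: Ensemble | StructureModel,
                            dihedrals: list[DihedralRestraint],
                            ) -> tuple[float, float]:
    """Wrapped angular violation r.m.s.d. (degrees): mean +- sd over
    models. Restraints whose atoms are missing (chain breaks) are skipped
    and logged."""
    if isinstance(ensemble, StructureModel):
        ensemble = Ensemble([ensemble])
    model_rmsds = []
    warned = set()
    for model in ensemble:
        viol2 = []
        for d in dihedrals:
            measured = _measure_dihedral(model, d.residue, d.angle)
            if measured is None:
                if (d.residue, d.angle) not in warned:
                    logger.warning("dihedral %s of residue %s not "
                                   "computable; skipped", d.angle, d.residue)
                    warned.add((d.residue, d.angle))
                continue
            delta = abs(float(wrap_degrees(measured - d.center)))
            viol2.append(max(0.0, delta - d.half_width) ** 2)
        model_rmsds.append(np.sqrt(np.mean(viol2)) if viol2 else 0.0)
    return float(np.mean(model_rmsds)), float(np.std(model_rmsds))


# -- coordinate precision --------------------------------------------------

def ensemble_rmsd(ensemble: Ensemble, selection: ResidueRangeSelection,
                  mode: str = "mean", max_iter: int = 100) -> float:
    """Coordinate r.m.s.d. of the ensemble on a residue selection.

    ``mode='mean'`` (default): iterative least-squares superposition of
    every model onto the evolving mean structure until the mean shifts by
    < 1e-6 A, then the average over models of the r.m.s.d. to the mean.
    ``mode='pairwise'``: mean over all model pairs of the pairwise aligned
    r.m.s.d.
    """
    if len(ensemble) < 2:
        raise ValueError("ensemble r.m.s.d. requires at least 2 models")
    idx = selection.atom_indices(ensemble[0])
    if len(idx) == 0:
        raise ValueError("selection matches no atoms")
    coords = np.array([m.xyz[idx] for m in ensemble])
    if mode == "pairwise":
        vals = [aligned_rmsd(coords[i], coords[j])
                for i in range(len(coords))
                for j in range(i + 1, len(coords))]
        return float(np.mean(vals))
    if mode != "mean":
        raise ValueError(f"unknown mode {mode!r}")
    mean = coords[0].copy()
    for _ in range(max_iter):
        coords = np.array([superpose(c, mean) for c in coords])
        new_mean = coords.mean(axis=0)
        shift = np.sqrt(np.mean(np.sum((new_mean - mean) ** 2, axis=1)))
        mean = new_mean
        if shift < 1e-6:
            break
    return float(np.mean([np.sqrt(np.mean(np.sum((c - mean) ** 2, axis=1)))
                          for c in coords]))


# -- trajectory block clustering ------------------------------------------

def block_cluster_centroids(trajectory: Ensemble, block_size: int,
                            eps: float, min_pts: int,
                            selection: ResidueRangeSelection,
                            ) -> tuple[Ensemble, list[bool]]:
    """Per-block DBSCAN clustering on the pairwise-r.m.s.d. matrix.

    Each block of ``block_size`` consecutive frames contributes one
    centroid: the member of the most populated cluster minimizing the
    summed r.m.s.d. to the rest of that cluster. A block with no core
    points falls back to the medoid of the whole block and is flagged.
    Returns (centroid ensemble, per-block fallback flags).
    """
    n = len(trajectory)
    if block_size < 1 or n < block_size:
        raise ValueError("trajectory shorter than one block")
    idx = selection.atom_indices(trajectory[0])
    centroids = []
    flags = []
    for b0 in range(0, n - block_size + 1, block_size):
        frames = trajectory.models[b0:b0 + block_size]
        coords = [m.xyz[idx] for m in frames]
        k = len(frames)
        dmat = np.zeros((k, k))
        for i in range(k):
            for j in range(i + 1, k):
                d = aligned_rmsd(coords[i], coords[j])
                dmat[i, j] = dmat[j, i] = d
        labels = DBSCAN(eps=eps, min_samples=min_pts,
                        metric="precomputed").fit_predict(dmat)
        clustered = labels >= 0
        if not clustered.any():
            members = np.arange(k)  # all noise: fall back to block medoid
            flags.append(True)
        else:
            top = np.bincount(labels[clustered]).argmax()
            members = np.nonzero(labels == top)[0]
            flags.append(False)
        sums = dmat[np.ix_(members, members)].sum(axis=1)
        centroid_local = members[int(np.argmin(sums))]
        centroids.append(frames[centroid_local])
    return Ensemble([m.with_xyz(m.xyz, model_id=i + 1)
                     for i, m in enumerate(centroids)]), flags


# -- aggregate report ------------------------------------------------------

@dataclass
class ValidationReport:
    """Restraint tallies plus violation and coordinate statistics."""

    counts: dict[str, int]
    dist_rmsd: tuple[float, float]
    dihedral_rmsd: tuple[float, float]
    rdc_rmsd: tuple[float, float] | None
    ensemble_rmsd_backbone: float
    ensemble_rmsd_heavy: float
    tm_rmsd_backbone: float

    def summary(self) -> str:
        c = self.counts
        lines = ["Restraint counts",
                 f"  Total NOE                    {c.get('noe_total', 0)}",
                 f"    Sequential (|i-j| = 1)     {c.get('noe_sequential', 0)}",
                 f"    Medium-range (1<|i-j|<5)   {c.get('noe_medium_range', 0)}",
                 f"    Long-range (|i-j| >= 5)    {c.get('noe_long_range', 0)}",
                 f"  Hydrogen bonds               {c.get('hbond', 0)}",
                 f"  PRE                          "
                 f"{sum(v for k, v in c.items() if k.startswith('pre_'))}",
                 f"  Dihedral (phi/psi)           "
                 f"{c.get('dihedral_phi', 0)}/{c.get('dihedral_psi', 0)}",
                 "r.m.s.d. from experimental restraints",
                 f"  Distances (A)       {self.dist_rmsd[0]:.3f} "
                 f"+- {self.dist_rmsd[1]:.3f}",
                 f"  Dihedral angles (deg) {self.dihedral_rmsd[0]:.1f} "
                 f"+- {self.dihedral_rmsd[1]:.1f}"]
        if self.rdc_rmsd is not None:
            lines.append(f"  RDC (Hz)            {self.rdc_rmsd[0]:.2f} "
                         f"+- {self.rdc_rmsd[1]:.2f}")
        lines += ["Ensemble r.m.s.d. (A)",
                  f"  Backbone heavy atoms  {self.ensemble_rmsd_backbone:.2f}",
                  f"  All heavy atoms       {self.ensemble_rmsd_heavy:.2f}",
                  f"  Transmembrane backbone {self.tm_rmsd_backbone:.2f}"]
        return "\n".join(lines)


def table1_report(ensemble: Ensemble,
                  restraints: list[DistanceRestraint],
                  dihedrals: list[DihedralRestraint],
                  couplings=None,
                  ordered_selection: ResidueRangeSelection = None,
                  tm_selection: ResidueRangeSelection = None,
                  ) -> ValidationReport:
    """Assemble the full validation report for an ensemble."""
    from .rdc import ensemble_rdc_stats
    ordered = ordered_selection or ENSEMBLE_SELECTION
    tm = tm_selection or TM_SELECTION
    mean_d, sd_d, _ = distance_violation_rmsd(ensemble, restraints)
    dihedral_stats = dihedral_violation_rmsd(ensemble, dihedrals)
    rdc_stats = None
    if couplings is not None:
        rdc_stats = ensemble_rdc_stats(ensemble, couplings)
    heavy = ResidueRangeSelection(ordered.ranges, "all_heavy")
    return ValidationReport(
        counts=count_restraints(restraints, dihedrals),
        dist_rmsd=(mean_d, sd_d),
        dihedral_rmsd=dihedral_stats,
        rdc_rmsd=rdc_stats,
        ensemble_rmsd_backbone=ensemble_rmsd(ensemble, ordered),
        ensemble_rmsd_heavy=ensemble_rmsd(ensemble, heavy),
        tm_rmsd_backbone=ensemble_rmsd(ensemble, tm),
    )
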