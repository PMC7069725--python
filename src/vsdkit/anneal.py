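"""Restraint-driven structure embedding on a reduced backbone
representation.

The embedder turns flat-well distance restraints plus phi/psi dihedral
restraints into 3D backbone models (atoms N, H, CA, C, O and a CB
pseudo-atom per non-glycine residue). Each run starts from a randomized
distance-geometry embedding (distances sampled within triangle-smoothed
bounds, classical multidimensional scaling, better-scoring mirror image
kept) and is refined by noisy gradient annealing over a linear
temperature schedule with ramped restraint weights, followed by an
L-BFGS minimization. The energy is

    E = sum_k k_geom (d - d0)^2                 ideal-geometry pairs
      + sum_r k_r  max(0, d_eff - hi, lo - d_eff)^2   flat wells
      + sum_t k_dih max(0, |wrap(chi - center)| - halfwidth)^2
      + k_chir (V - V0)^2                        CA-centered chirality
      + k_rep  max(0, r_min - d)^2               soft sterics

with r^-6-sum effective distances over ambiguous selections. E is
non-negative and vanishes exactly when every well and geometry target is
satisfied.

This is a desk-scale embedder for restraint-recovery and jackknife
experiments, not a molecular dynamics engine: there is no torsion-angle
dynamics stage and no force-field refinement.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.spatial.distance import cdist

from ._geometry import ANGLE, BOND, OMEGA, nerf
from .model_io import AtomRecord, DistanceRestraint, Ensemble, StructureModel
from .restraints import DihedralRestraint

logger = logging.getLogger(__name__)

__all__ = ["AnnealSchedule", "EmbedResult", "embed", "jackknife_longrange",
           "select_top_fraction", "RestraintValidationError"]


class RestraintValidationError(ValueError):
    pass


@dataclass(frozen=True)
class AnnealSchedule:
    """Annealing schedule: temperatures in K, weights in energy units.

    Defaults mirror a standard simulated-annealing protocol (3500 K cooled
    to 100 K in 25 K steps with the NOE weight ramped 20 -> 30 and the PRE
    weight 2 -> 3); the energy function itself is the reduced flat-well
    form above.
    """

    t_start: float = 3500.0
    t_end: float = 100.0
    t_step: float = 25.0
    k_noe: tuple[float, float] = (20.0, 30.0)
    k_pre: tuple[float, float] = (2.0, 3.0)
    k_dihedral: float = 200.0
    steps_per_temperature: int = 15
    seed: int = 0

    def __post_init__(self):
        if not (self.t_start > self.t_end > 0):
            raise ValueError("require t_start > t_end > 0")
        if self.t_step <= 0:
            raise ValueError("t_step must be positive")

    def temperatures(self) -> np.ndarray:
        return np.arange(self.t_start, self.t_end - 1e-9, -self.t_step)


@dataclass
class EmbedResult:
    """Models ranked by ascending energy plus a violation ledger."""

    models: Ensemble
    per_model_energy: list[float]
    acceptance_ledger: pd.DataFrame

    @property
    def best(self) -> StructureModel:
        return self.models[0]


def select_top_fraction(result: EmbedResult,
                        fraction: float = 0.10) -> Ensemble:
    """Lowest-energy ``fraction`` of the calculated models (at least one);
    mirrors the usual keep-the-top-10% refinement workflow."""
    n = max(1, int(round(fraction * len(result.models))))
    return Ensemble(result.models.models[:n])


# -- topology --------------------------------------------------------------

_BACKBONE_ORDER = ("N", "H", "CA", "C", "O", "CB")

# weights of the hard geometry terms; these dominate the restraint weights
# so the covalent skeleton stays intact through annealing
_K_GEOM = 300.0
_K_CHIR = 50.0
_K_REP = 5.0
_R_MIN_HEAVY = 2.7
_R_MIN_H = 1.7


class _Topology:
    """Atom bookkeeping plus precompiled energy-term index arrays."""

    def __init__(self, sequence: Sequence[tuple[int, str]]):
        self.sequence = [(int(r), str(n).upper()) for r, n in sequence]
        self.atom_names: list[tuple[int, str]] = []
        self.res_names: dict[int, str] = {}
        index: dict[tuple[int, str], int] = {}
        res_numbers = [r for r, _ in self.sequence]
        if len(set(res_numbers)) != len(res_numbers):
            raise RestraintValidationError("duplicate residue in sequence")
        first = res_numbers[0]
        for res, name in self.sequence:
            self.res_names[res] = name
            for atom in _BACKBONE_ORDER:
                if atom == "H" and res == first:
                    continue
                if atom == "CB" and name == "GLY":
                    continue
                index[(res, atom)] = len(self.atom_names)
                self.atom_names.append((res, atom))
        self.index = index
        self.n_atoms = len(self.atom_names)
        self.residues = res_numbers
        self._template = _template_geometry()

    def has(self, res: int, atom: str) -> bool:
        return (res, atom) in self.index

    def geometry_pairs(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(i, j, d0) arrays for the ideal-geometry distance terms."""
        tpl = self._template
        ii, jj, dd = [], [], []

        def add(res_a, at_a, res_b, at_b, d0):
            if self.has(res_a, at_a) and self.has(res_b, at_b):
                ii.append(self.index[(res_a, at_a)])
                jj.append(self.index[(res_b, at_b)])
                dd.append(d0)

        for k, res in enumerate(self.residues):
            for (a, b), d0 in tpl["intra"].items():
                add(res, a, res, b, d0)
            if k + 1 < len(self.residues):
                nxt = self.residues[k + 1]
                if nxt == res + 1:  # only across unbroken chain
                    for (a, b), d0 in tpl["inter"].items():
                        add(res, a, nxt, b, d0)
        return (np.array(ii, dtype=int), np.array(jj, dtype=int),
                np.array(dd, dtype=float))

    def chirality_quads(self) -> tuple[np.ndarray, float]:
        quads = []
        for res, name in self.sequence:
            if name == "GLY" or not self.has(res, "CB"):
                continue
            quads.append([self.index[(res, "CA")], self.index[(res, "N")],
                          self.index[(res, "C")], self.index[(res, "CB")]])
        return np.array(quads, dtype=int), self._template["chirality"]


def _template_geometry() -> dict:
    """Distances (and the chiral volume) measured on one ideally built
    residue pair; cached module-wide."""
    global _TEMPLATE_CACHE
    if _TEMPLATE_CACHE is not None:
        return _TEMPLATE_CACHE
    # build a two-residue trans peptide with helical phi/psi
    phi, psi = -60.0, -45.0
    N0 = np.zeros(3)
    CA0 = np.array([BOND[("N", "CA")], 0.0, 0.0])
    ang = np.radians(ANGLE[("N", "CA", "C")])
    C0 = CA0 + BOND[("CA", "C")] * np.array([-np.cos(ang), np.sin(ang), 0.0])
    O0 = nerf(N0, CA0, C0, BOND[("C", "O")], ANGLE[("CA", "C", "O")],
              psi + 180.0)
    CB0 = nerf(C0, N0, CA0, BOND[("CA", "CB")], ANGLE[("N", "CA", "CB")],
               122.6)
    N1 = nerf(N0, CA0, C0, BOND[("C", "N")], ANGLE[("CA", "C", "N")], psi)
    CA1 = nerf(CA0, C0, N1, BOND[("N", "CA")], ANGLE[("C", "N", "CA")], OMEGA)
    H1 = nerf(CA0, C0, N1, BOND[("N", "H")], ANGLE[("C", "N", "H")], 0.0)
    def d(p, q):
        return float(np.linalg.norm(p - q))

    intra = {
        ("N", "CA"): d(N0, CA0), ("CA", "C"): d(CA0, C0),
        ("C", "O"): d(C0, O0), ("CA", "CB"): d(CA0, CB0),
        ("N", "C"): d(N0, C0), ("CA", "O"): d(CA0, O0),
        ("N", "CB"): d(N0, CB0), ("C", "CB"): d(C0, CB0),
    }
    # N-H and H-CA within a residue use the H built from the previous one
    inter = {
        ("C", "N"): d(C0, N1), ("CA", "N"): d(CA0, N1),
        ("C", "CA"): d(C0, CA1), ("O", "N"): d(O0, N1),
        ("C", "H"): d(C0, H1), ("CA", "CA"): d(CA0, CA1),
    }
    intra.update({("N", "H"): d(N1, H1), ("CA", "H"): d(CA1, H1)})
    u, v, w = N0 - CA0, C0 - CA0, CB0 - CA0
    chirality = float(np.dot(np.cross(u, v), w))
    tpl = {"intra": intra, "inter": inter, "chirality": chirality}
    _TEMPLATE_CACHE = tpl
    return tpl


_TEMPLATE_CACHE: dict | None = None


# -- energy function -------------------------------------------------------

class _Energy:
    def __init__(self, topo: _Topology,
                 restraints: list[DistanceRestraint],
                 dihedrals: list[DihedralRestraint],
                 k_noe: float, k_pre: float, k_dihedral: float):
        self.topo = topo
        gi, gj, gd = topo.geometry_pairs()
        self.geom_i, self.geom_j, self.geom_d = gi, gj, gd

        # flat-well pair terms (unambiguous) and ambiguous terms
        pi, pj, lo, hi, kk = [], [], [], [], []
        self.ambiguous = []  # (idx_a, idx_b, lo, hi, k)
        for r in restraints:
            sel_a = self._resolve(r.sel_a)
            sel_b = self._resolve(r.sel_b)
            if sel_a is None or sel_b is None:
                raise RestraintValidationError(
                    f"restraint {r.provenance or r.klass} references atoms "
                    "not constructible from the sequence")
            k = k_pre if r.klass.startswith("pre") else k_noe
            corr = 1.0 if (sel_a[1] + sel_b[1]) > 0 else 0.0
            lo_r, hi_r = r.d_low, r.d_high + corr
            if len(sel_a[0]) == 1 and len(sel_b[0]) == 1:
                pi.append(sel_a[0][0])
                pj.append(sel_b[0][0])
                lo.append(lo_r)
                hi.append(hi_r)
                kk.append(k)
            else:
                self.ambiguous.append((np.array(sel_a[0]), np.array(sel_b[0]),
                                       lo_r, hi_r, k))
        self.pair_i = np.array(pi, dtype=int)
        self.pair_j = np.array(pj, dtype=int)
        self.pair_lo = np.array(lo, dtype=float)
        self.pair_hi = np.array(hi, dtype=float)
        self.pair_k = np.array(kk, dtype=float)

        # dihedral terms
        quads, centers, widths = [], [], []
        first, last = topo.residues[0], topo.residues[-1]
        for d in dihedrals:
            res = d.residue
            if res not in topo.res_names:
                raise RestraintValidationError(
                    f"dihedral restraint references unknown residue {res}")
            if d.angle == "phi":
                if res - 1 not in topo.res_names:
                    continue
                atoms = [(res - 1, "C"), (res, "N"), (res, "CA"), (res, "C")]
            else:
                if res + 1 not in topo.res_names:
                    continue
                atoms = [(res, "N"), (res, "CA"), (res, "C"), (res + 1, "N")]
            if not all(topo.has(*a) for a in atoms):
                continue
            quads.append([topo.index[a] for a in atoms])
            centers.append(d.center)
            widths.append(d.half_width)
        self.dih_quads = np.array(quads, dtype=int).reshape(-1, 4)
        self.dih_center = np.array(centers, dtype=float)
        self.dih_width = np.array(widths, dtype=float)
        self.k_dihedral = k_dihedral

        self.chir_quads, self.chir_v0 = topo.chirality_quads()

        # steric exclusion: same or adjacent residue
        res_of = np.array([r for r, _ in topo.atom_names])
        self.res_of = res_of
        is_h = np.array([n == "H" for _, n in topo.atom_names])
        rmin = np.where(is_h[:, None] | is_h[None, :], _R_MIN_H,
                        _R_MIN_HEAVY)
        excl = np.abs(res_of[:, None] - res_of[None, :]) <= 1
        rmin[excl] = 0.0
        np.fill_diagonal(rmin, 0.0)
        self.rep_rmin = rmin

    def _resolve(self, sel):
        """Map a selection to atom indices; unknown side-chain atoms fall
        back to the residue CB (reduced representation, +1 A correction)."""
        idx, fallbacks = [], 0
        for res, name in sel:
            if self.topo.has(res, name):
                idx.append(self.topo.index[(res, name)])
            elif res in self.topo.res_names and self.topo.has(res, "CB"):
                idx.append(self.topo.index[(res, "CB")])
                fallbacks += 1
            else:
                return None
        return (list(dict.fromkeys(idx)), fallbacks)

    # -- evaluation --------------------------------------------------------
    def __call__(self, x: np.ndarray,
                 with_grad: bool = True) -> tuple[float, np.ndarray]:
        xyz = x.reshape(-1, 3)
        grad = np.zeros_like(xyz)
        energy = 0.0

        # geometry harmonics
        dvec = xyz[self.geom_i] - xyz[self.geom_j]
        d = np.linalg.norm(dvec, axis=1)
        delta = d - self.geom_d
        energy += _K_GEOM * float(np.sum(delta ** 2))
        if with_grad:
            f = (2.0 * _K_GEOM * delta / np.maximum(d, 1e-9))[:, None] * dvec
            np.add.at(grad, self.geom_i, f)
            np.add.at(grad, self.geom_j, -f)

        # flat-well pair restraints
        if len(self.pair_i):
            dvec = xyz[self.pair_i] - xyz[self.pair_j]
            d = np.linalg.norm(dvec, axis=1)
            over = np.maximum(d - self.pair_hi, 0.0)
            under = np.maximum(self.pair_lo - d, 0.0)
            v = over - under  # signed violation
            energy += float(np.sum(self.pair_k * v ** 2))
            if with_grad:
                f = (2.0 * self.pair_k * v / np.maximum(d, 1e-9))[:, None] * dvec
                np.add.at(grad, self.pair_i, f)
                np.add.at(grad, self.pair_j, -f)

        # ambiguous flat wells (r^-6 sum)
        for ia, ib, lo_r, hi_r, k in self.ambiguous:
            diff = xyz[ia][:, None, :] - xyz[ib][None, :, :]
            r = np.sqrt(np.sum(diff ** 2, axis=-1))
            s = np.sum(r ** -6.0)
            d_eff = s ** (-1.0 / 6.0)
            v = max(d_eff - hi_r, 0.0) - max(lo_r - d_eff, 0.0)
            energy += k * v ** 2
            if with_grad and v != 0.0:
                # d d_eff / d r_p = d_eff^7 r_p^-7
                coeff = 2.0 * k * v * d_eff ** 7 * r ** -7.0
                pair_f = (coeff / np.maximum(r, 1e-9))[..., None] * diff
                np.add.at(grad, ia, pair_f.sum(axis=1))
                np.add.at(grad, ib, -pair_f.sum(axis=0))

        # dihedral flat wells (degrees)
        if len(self.dih_quads):
            a = xyz[self.dih_quads[:, 0]]
            b = xyz[self.dih_quads[:, 1]]
            c = xyz[self.dih_quads[:, 2]]
            dd = xyz[self.dih_quads[:, 3]]
            b1, b2, b3 = b - a, c - b, dd - c
            n1 = np.cross(b1, b2)
            n2 = np.cross(b2, b3)
            b2n = np.linalg.norm(b2, axis=1)
            m1 = np.cross(n1, b2 / b2n[:, None])
            xcomp = np.sum(n1 * n2, axis=1)
            ycomp = np.sum(m1 * n2, axis=1)
            chi = np.degrees(np.arctan2(-ycomp, xcomp))
            delta = chi - self.dih_center
            delta = -((-delta + 180.0) % 360.0 - 180.0)
            excess = np.abs(delta) - self.dih_width
            active = excess > 0
            v = np.where(active, np.sign(delta) * excess, 0.0)
            energy += self.k_dihedral * float(np.sum(v ** 2)) * (
                np.pi / 180.0) ** 2
            if with_grad and active.any():
                # d chi / d atoms (radians), scaled into degree-based well
                n1sq = np.sum(n1 * n1, axis=1)
                n2sq = np.sum(n2 * n2, axis=1)
                dchi_da = -(b2n / np.maximum(n1sq, 1e-12))[:, None] * n1
                dchi_dd = (b2n / np.maximum(n2sq, 1e-12))[:, None] * n2
                s12 = (np.sum(b1 * b2, axis=1) / b2n ** 2)[:, None]
                s32 = (np.sum(b3 * b2, axis=1) / b2n ** 2)[:, None]
                dchi_db = (-1.0 - s12) * dchi_da + s32 * dchi_dd
                dchi_dc = s12 * dchi_da - (1.0 + s32) * dchi_dd
                coeff = (2.0 * self.k_dihedral * v * (np.pi / 180.0)
                         )[:, None]
                np.add.at(grad, self.dih_quads[:, 0], coeff * dchi_da)
                np.add.at(grad, self.dih_quads[:, 1], coeff * dchi_db)
                np.add.at(grad, self.dih_quads[:, 2], coeff * dchi_dc)
                np.add.at(grad, self.dih_quads[:, 3], coeff * dchi_dd)

        # chirality
        if len(self.chir_quads):
            ca = xyz[self.chir_quads[:, 0]]
            u = xyz[self.chir_quads[:, 1]] - ca
            v_ = xyz[self.chir_quads[:, 2]] - ca
            w = xyz[self.chir_quads[:, 3]] - ca
            vol = np.sum(np.cross(u, v_) * w, axis=1)
            dv = vol - self.chir_v0
            energy += _K_CHIR * float(np.sum(dv ** 2))
            if with_grad:
                coeff = (2.0 * _K_CHIR * dv)[:, None]
                g_u = coeff * np.cross(v_, w)
                g_v = coeff * np.cross(w, u)
                g_w = coeff * np.cross(u, v_)
                np.add.at(grad, self.chir_quads[:, 1], g_u)
                np.add.at(grad, self.chir_quads[:, 2], g_v)
                np.add.at(grad, self.chir_quads[:, 3], g_w)
                np.add.at(grad, self.chir_quads[:, 0], -(g_u + g_v + g_w))

        # soft sterics
        dmat = cdist(xyz, xyz)
        pen = np.maximum(self.rep_rmin - dmat, 0.0)
        np.fill_diagonal(pen, 0.0)
        energy += 0.5 * _K_REP * float(np.sum(pen ** 2))
        if with_grad:
            active = pen > 0
            if active.any():
                ii, jj = np.nonzero(active)
                dvec = xyz[ii] - xyz[jj]
                d = np.maximum(dmat[ii, jj], 1e-9)
                f = (-2.0 * 0.5 * _K_REP * pen[ii, jj] / d)[:, None] * dvec
                np.add.at(grad, ii, f)

        return energy, grad.ravel()


# -- distance-geometry initialization -------------------------------------

def _dg_start(energy: _Energy, rng: np.random.Generator) -> np.ndarray:
    topo = energy.topo
    n = topo.n_atoms
    big = 3.8 * len(topo.residues) + 20.0
    lo = np.full((n, n), 2.0)
    hi = np.full((n, n), big)
    np.fill_diagonal(lo, 0.0)
    np.fill_diagonal(hi, 0.0)

    def set_pair(i, j, lo_v, hi_v):
        lo[i, j] = lo[j, i] = max(lo[i, j], lo_v) if lo_v > 0 else 0.0
        hi[i, j] = hi[j, i] = min(hi[i, j], hi_v)

    for i, j, d0 in zip(energy.geom_i, energy.geom_j, energy.geom_d):
        lo[i, j] = lo[j, i] = d0
        hi[i, j] = hi[j, i] = d0
    for i, j, lo_r, hi_r in zip(energy.pair_i, energy.pair_j,
                                energy.pair_lo, energy.pair_hi):
        set_pair(i, j, lo_r, min(hi_r, big))
    # triangle smoothing of upper bounds (min-plus transitive closure)
    for k in range(n):
        np.minimum(hi, hi[:, k, None] + hi[None, k, :], out=hi)
    hi = np.maximum(hi, lo)
    d = lo + rng.random((n, n)) * (hi - lo)
    d = 0.5 * (d + d.T)
    np.fill_diagonal(d, 0.0)
    # classical MDS
    d2 = d ** 2
    j = np.eye(n) - np.ones((n, n)) / n
    gram = -0.5 * j @ d2 @ j
    vals, vecs = np.linalg.eigh(gram)
    top = np.argsort(vals)[::-1][:3]
    coords = vecs[:, top] * np.sqrt(np.maximum(vals[top], 1e-9))
    # keep the mirror image with the better chirality energy
    mirrored = coords * np.array([1.0, 1.0, -1.0])
    e_a, _ = energy(coords.ravel(), with_grad=False)
    e_b, _ = energy(mirrored.ravel(), with_grad=False)
    return (coords if e_a <= e_b else mirrored).ravel()


# -- annealing driver ------------------------------------------------------

_N_LEVELS = 10  # temperature levels actually visited (ladder subsampled)


def _anneal_one(energy_start: _Energy, energy_end: _Energy,
                schedule: AnnealSchedule,
                rng: np.random.Generator) -> tuple[np.ndarray, float]:
    """One embedding run: distance-geometry start, then basin-hopping down
    the temperature ladder (thermal perturbation + noisy gradient steps +
    local minimization, Metropolis-accepted), then a final minimization at
    the end-point restraint weights."""
    level_iters = 20 * schedule.steps_per_temperature
    x = _dg_start(energy_start, rng)
    res = minimize(lambda xx: energy_start(xx), x, jac=True,
                   method="L-BFGS-B", options={"maxiter": level_iters})
    x, e_cur = res.x, float(res.fun)
    temps = schedule.temperatures()
    levels = temps[np.unique(np.linspace(0, len(temps) - 1,
                                         min(_N_LEVELS, len(temps)),
                                         dtype=int))]
    step_len = 0.12  # A, max per-atom displacement per gradient move
    for ti, temp in enumerate(levels):
        energy = energy_start if ti < len(levels) / 2 else energy_end
        sigma = 0.8 * np.sqrt(temp / schedule.t_start)
        trial = x + rng.normal(0.0, sigma, x.shape)
        for _ in range(schedule.steps_per_temperature):
            _, g = energy(trial)
            trial = trial - step_len * g / (np.max(np.abs(g)) + 1e-9)
        res = minimize(lambda xx: energy(xx), trial, jac=True,
                       method="L-BFGS-B", options={"maxiter": level_iters})
        e_trial = float(res.fun)
        if (e_trial < e_cur
                or rng.random() < np.exp(-(e_trial - e_cur) / max(temp, 1e-9))):
            x, e_cur = res.x, e_trial
    res = minimize(lambda xx: energy_end(xx), x, jac=True, method="L-BFGS-B",
                   options={"maxiter": 5 * level_iters})
    return res.x, float(res.fun)


def _build_model(topo: _Topology, x: np.ndarray,
                 model_id: int) -> StructureModel:
    xyz = x.reshape(-1, 3)
    atoms = []
    for (res, name), pos in zip(topo.atom_names, xyz):
        atoms.append(AtomRecord("A", res, topo.res_names[res], name,
                                name[0], tuple(pos)))
    return StructureModel(atoms, model_id=model_id)


def embed(restraints: list[DistanceRestraint],
          dihedrals: list[DihedralRestraint],
          sequence: Sequence[tuple[int, str]],
          schedule: AnnealSchedule = AnnealSchedule(),
          n_structures: int = 20) -> EmbedResult:
    """Calculate ``n_structures`` independent models and rank them by
    energy.

    Every restraint must reference atoms constructible from the sequence
    (N, H, CA, C, O, CB); this is validated before any sampling. Runs are
    reproducible given (schedule.seed, n_structures).
    """
    from .validation import distance_violation_rmsd

    topo = _Topology(sequence)
    k_noe0, k_noe1 = schedule.k_noe
    k_pre0, k_pre1 = schedule.k_pre
    e_start = _Energy(topo, restraints, dihedrals, k_noe0, k_pre0,
                      schedule.k_dihedral)
    e_end = _Energy(topo, restraints, dihedrals, k_noe1, k_pre1,
                    schedule.k_dihedral)
    seeds = np.random.SeedSequence(schedule.seed).spawn(n_structures)
    runs = []
    for i, ss in enumerate(seeds):
        rng = np.random.default_rng(ss)
        x, e = _anneal_one(e_start, e_end, schedule, rng)
        runs.append((e, i, x))
    runs.sort(key=lambda t: (t[0], t[1]))
    models = [_build_model(topo, x, mid + 1)
              for mid, (_, _, x) in enumerate(runs)]
    ensemble = Ensemble(models)
    _, _, ledger = distance_violation_rmsd(ensemble, restraints)
    return EmbedResult(models=ensemble,
                       per_model_energy=[e for e, _, _ in runs],
                       acceptance_ledger=ledger)


# -- jackknife -------------------------------------------------------------

def jackknife_longrange(restraints: list[DistanceRestraint],
                        dihedrals: list[DihedralRestraint],
                        sequence: Sequence[tuple[int, str]],
                        schedule: AnnealSchedule = AnnealSchedule(),
                        fraction: float = 0.10,
                        repeats: int = 10,
                        seed: int = 0,
                        n_structures: int = 5,
                        ) -> tuple[list[EmbedResult], pd.DataFrame]:
    """Robustness of the fold to long-range NOE exclusion.

    Each repeat drops a disjoint-as-possible random ``fraction`` of the
    long-range (|i-j| >= 5) NOE restraints and re-embeds; the report
    lists the backbone (CA) r.m.s.d. of each repeat's best model to the
    all-data best model. When ``repeats * floor(fraction * n)`` covers
    the long-range set, every long-range restraint is excluded at least
    once.
    """
    from ._geometry import aligned_rmsd
    from .validation import NOE_CLASSES

    if not (0.0 < fraction <= 0.5):
        raise ValueError("fraction must lie in (0, 0.5]")
    long_idx = [i for i, r in enumerate(restraints)
                if r.klass in NOE_CLASSES and r.sequence_separation() >= 5]
    if len(long_idx) < 10:
        raise ValueError(
            f"only {len(long_idx)} long-range NOE restraints; need >= 10")
    n_excl = max(1, int(np.floor(fraction * len(long_idx))))
    rng = np.random.default_rng(seed)
    perm = rng.permutation(long_idx)
    # cyclic chunks: disjoint until the permutation is exhausted, so every
    # long-range restraint is excluded at least once when coverage allows
    excl_sets = []
    for rep in range(repeats):
        sel = [perm[(rep * n_excl + k) % len(perm)] for k in range(n_excl)]
        excl_sets.append(set(sel))

    full = embed(restraints, dihedrals, sequence, schedule, n_structures)
    ca_idx = [i for i, (r, n) in enumerate(
        _Topology(sequence).atom_names) if n == "CA"]
    ref = full.best.xyz[ca_idx]

    results, rows = [], []
    for rep, excl in enumerate(excl_sets):
        sub = [r for i, r in enumerate(restraints) if i not in excl]
        sub_schedule = AnnealSchedule(
            t_start=schedule.t_start, t_end=schedule.t_end,
            t_step=schedule.t_step, k_noe=schedule.k_noe,
            k_pre=schedule.k_pre, k_dihedral=schedule.k_dihedral,
            steps_per_temperature=schedule.steps_per_temperature,
            seed=schedule.seed + rep + 1)
        res = embed(sub, dihedrals, sequence, sub_schedule, n_structures)
        results.append(res)
        rows.append({
            "repeat": rep,
            "n_excluded": len(excl),
            "rmsd_to_full_A": aligned_rmsd(res.best.xyz[ca_idx], ref),
            "best_energy": res.per_model_energy[0],
        })
    covered = set().union(*excl_sets)
    report = pd.DataFrame(rows)
    report.attrs["coverage"] = len(covered) / len(long_idx)
    return results, report
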