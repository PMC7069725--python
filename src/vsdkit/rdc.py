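"""Residual dipolar coupling extraction, alignment-tensor fitting and
structure scoring.

Couplings are extracted from 15N-dimension HSQC/TROSY peak-position pairs
by the doubling rule (the peak pair is split by half the coupling), the
alignment tensor is fit by linear least squares on the five independent
Saupe elements, and agreement is scored by Q-factor and r.m.s.d.

The dipolar coupling for an N-H bond at polar angles (theta, phi) in the
tensor principal frame is

    D = Da [ (3 cos^2 theta - 1) + (3/2) R sin^2 theta cos 2 phi ]

with axial component Da (Hz) and rhombicity R in [0, 2/3].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model_io import Ensemble, StructureModel

__all__ = [
    "RdcRecord", "AlignmentTensor", "extract_couplings",
    "estimate_tensor_extrema", "fit_tensor_svd", "q_factor", "rdc_rmsd",
    "ensemble_rdc_stats", "TensorFitError",
]


class TensorFitError(ValueError):
    pass


@dataclass(frozen=True)
class RdcRecord:
    """Peak positions (Hz, 15N dimension) for one residue."""

    residue: int
    n15_hsqc_iso: float
    n15_trosy_iso: float
    n15_hsqc_ali: float
    n15_trosy_ali: float


@dataclass(frozen=True)
class AlignmentTensor:
    """Alignment tensor in its (Da, R, orientation) representation.

    ``rotation`` columns are the principal axes (x, y, z) expressed in the
    laboratory frame. The equivalent traceless symmetric 3x3 matrix in Hz
    units has principal values (Txx, Tyy, Tzz) =
    (-Da(1 - 1.5 R), -Da(1 + 1.5 R), 2 Da).
    """

    da: float
    rhombicity: float = 0.0
    rotation: tuple = ((1.0, 0.0, 0.0), (0.0, 1.0, 0.0), (0.0, 0.0, 1.0))

    def __post_init__(self):
        if not (0.0 <= self.rhombicity <= 2.0 / 3.0 + 1e-9):
            raise ValueError("rhombicity must lie in [0, 2/3]")

    def matrix(self) -> np.ndarray:
        rot = np.asarray(self.rotation, dtype=float)
        principal = np.diag([
            -self.da * (1.0 - 1.5 * self.rhombicity),
            -self.da * (1.0 + 1.5 * self.rhombicity),
            2.0 * self.da,
        ])
        return rot @ principal @ rot.T

    @classmethod
    def from_matrix(cls, t: np.ndarray) -> "AlignmentTensor":
        """Principal-axis decomposition with |Tzz| >= |Tyy| >= |Txx|."""
        t = np.asarray(t, dtype=float)
        t = 0.5 * (t + t.T)
        vals, vecs = np.linalg.eigh(t)
        order = np.argsort(np.abs(vals))  # ascending |.|: x, y, z
        vals = vals[order]
        vecs = vecs[:, order]
        if np.linalg.det(vecs) < 0:
            vecs[:, 0] = -vecs[:, 0]
        tzz = vals[2]
        da = tzz / 2.0
        if abs(da) < 1e-15:
            raise TensorFitError("degenerate (zero) alignment tensor")
        rhomb = (vals[0] - vals[1]) / (3.0 * da)
        rhomb = float(np.clip(rhomb, 0.0, 2.0 / 3.0))
        return cls(da=float(da), rhombicity=rhomb,
                   rotation=tuple(map(tuple, vecs)))

    def summary(self) -> str:
        return (f"AlignmentTensor: Da = {self.da:.3f} Hz, "
                f"R = {self.rhombicity:.3f}")


# -- coupling extraction ---------------------------------------------------

def extract_couplings(records: pd.DataFrame) -> pd.DataFrame:
    """Apply the doubling rule to peak-position pairs.

    J = 2 |iso HSQC - iso TROSY|, J + D = 2 |aligned HSQC - aligned TROSY|,
    D = (J + D) - J. Splittings are treated as magnitudes (the physical
    one-bond J_NH is negative; only frequency differences are observed),
    so the sign of D follows the change in splitting. Residues with any
    missing peak are skipped.
    """
    cols = ["n15_hsqc_iso", "n15_trosy_iso", "n15_hsqc_ali", "n15_trosy_ali"]
    df = records.dropna(subset=cols).copy()
    j_iso = 2.0 * (df["n15_hsqc_iso"] - df["n15_trosy_iso"]).abs()
    j_plus_d = 2.0 * (df["n15_hsqc_ali"] - df["n15_trosy_ali"]).abs()
    out = pd.DataFrame({
        "residue": df["residue"].astype(int),
        "j_iso": j_iso,
        "d_nh": j_plus_d - j_iso,
    })
    return out.reset_index(drop=True)


def estimate_tensor_extrema(d_values) -> tuple[float, float]:
    """Initial (Da, R) estimates from the coupling extrema.

    The coupling along the tensor z-axis is 2 Da, so Da ~ max|D| / 2; the
    opposite extreme D_min = -Da (1 + 1.5 R) yields R. Both are initial
    estimates only; the SVD fit refines them.
    """
    d = np.asarray(list(d_values), dtype=float)
    if len(d) < 5:
        raise ValueError("need at least 5 couplings for tensor estimation")
    if np.allclose(d, 0.0):
        raise TensorFitError("all couplings zero; tensor degenerate")
    extreme = d[np.argmax(np.abs(d))]
    da_est = extreme / 2.0
    opposite = d[np.argmin(np.sign(extreme) * d)]
    if np.sign(opposite) == np.sign(extreme) or opposite == 0.0:
        r_est = 0.0
    else:
        r_est = max(0.0, (abs(opposite) / abs(da_est) - 1.0) / 1.5)
    return float(da_est), float(min(r_est, 2.0 / 3.0))


# -- SVD tensor fit --------------------------------------------------------

def _nh_vector(model: StructureModel, residue: int) -> np.ndarray | None:
    if not model.has_atom(residue, "N"):
        return None
    n = model.coord(residue, "N")
    if model.has_atom(residue, "H"):
        h = model.coord(residue, "H")
    else:
        # idealized amide geometry: H on the bisector of CA-N and C'(i-1)-N,
        # pointing away, at 1.02 A
        if not (model.has_atom(residue, "CA")
                and model.has_atom(residue - 1, "C")):
            return None
        u = model.coord(residue, "CA") - n
        v = model.coord(residue - 1, "C") - n
        u /= np.linalg.norm(u)
        v /= np.linalg.norm(v)
        d = -(u + v)
        h = n + 1.02 * d / np.linalg.norm(d)
    nh = h - n
    return nh / np.linalg.norm(nh)


def fit_tensor_svd(model: StructureModel, couplings: pd.DataFrame,
                   residues=None) -> tuple[AlignmentTensor, pd.DataFrame]:
    """Least-squares Saupe-element fit of the alignment tensor.

    ``couplings`` needs columns ``residue`` and ``d_nh``. Returns the
    principal-axis tensor and a per-residue observed/back-calculated
    table. Unweighted least squares (no error weighting of couplings).
    """
    rows = []
    for _, rec in couplings.iterrows():
        res = int(rec["residue"])
        if residues is not None and res not in residues:
            continue
        nh = _nh_vector(model, res)
        if nh is None:
            continue
        rows.append((res, float(rec["d_nh"]), nh))
    if len(rows) < 5:
        raise TensorFitError(
            f"only {len(rows)} usable couplings; need at least 5")
    nvec = np.array([r[2] for r in rows])
    d_obs = np.array([r[1] for r in rows])
    x, y, z = nvec[:, 0], nvec[:, 1], nvec[:, 2]
    design = np.column_stack([
        x ** 2 - z ** 2, y ** 2 - z ** 2, 2 * x * y, 2 * x * z, 2 * y * z])
    if np.linalg.matrix_rank(design) < 5:
        raise TensorFitError(
            "rank-deficient design matrix: fewer than 5 effective "
            "bond orientations")
    s, *_ = np.linalg.lstsq(design, d_obs, rcond=None)
    txx, tyy, txy, txz, tyz = s
    t = np.array([[txx, txy, txz],
                  [txy, tyy, tyz],
                  [txz, tyz, -txx - tyy]])
    tensor = AlignmentTensor.from_matrix(t)
    d_calc = np.einsum("ni,ij,nj->n", nvec, t, nvec)
    table = pd.DataFrame({
        "residue": [r[0] for r in rows],
        "d_obs": d_obs,
        "d_calc": d_calc,
    })
    return tensor, table


# -- agreement scores ------------------------------------------------------

def q_factor(d_obs, d_calc) -> float:
    """sqrt( sum (obs - calc)^2 / sum obs^2 )."""
    d_obs = np.asarray(list(d_obs), dtype=float)
    d_calc = np.asarray(list(d_calc), dtype=float)
    if len(d_obs) != len(d_calc) or len(d_obs) == 0:
        raise ValueError("observed and calculated sets must match in length")
    denom = np.sum(d_obs ** 2)
    if denom == 0:
        raise ValueError("all observed couplings zero; Q undefined")
    return float(np.sqrt(np.sum((d_obs - d_calc) ** 2) / denom))


def rdc_rmsd(d_obs, d_calc) -> float:
    d_obs = np.asarray(list(d_obs), dtype=float)
    d_calc = np.asarray(list(d_calc), dtype=float)
    return float(np.sqrt(np.mean((d_obs - d_calc) ** 2)))


def ensemble_rdc_stats(ensemble: Ensemble, couplings: pd.DataFrame,
                       shared_tensor: bool = False,
                       residues=None) -> tuple[float, float]:
    """RDC r.m.s.d. (mean, sd over models).

    ``shared_tensor=False`` (default) fits one tensor per model;
    ``shared_tensor=True`` fits a single tensor to the first model and
    back-calculates every model with it.
    """
    rmsds = []
    shared = None
    if shared_tensor:
        shared, _ = fit_tensor_svd(ensemble[0], couplings, residues)
    for model in ensemble:
        if shared_tensor:
            tmat = shared.matrix()
            vals = []
            for _, rec in couplings.iterrows():
                nh = _nh_vector(model, int(rec["residue"]))
                if nh is None:
                    continue
                vals.append((float(rec["d_nh"]), float(nh @ tmat @ nh)))
            obs, calc = zip(*vals)
            rmsds.append(rdc_rmsd(obs, calc))
        else:
            _, table = fit_tensor_svd(model, couplings, residues)
            rmsds.append(rdc_rmsd(table["d_obs"], table["d_calc"]))
    return float(np.mean(rmsds)), float(np.std(rmsds))
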