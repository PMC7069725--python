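"""Synthetic structures, NMR observables and voltage-clamp sweeps.

Everything downstream of raw data collection is testable against these
generators: a parametric four-helix bundle standing in for the
voltage-sensor fold, NOE cross-peak intensities following the r^-6 law
with two calibration groups, nitroxide-label PRE intensity ratios under
the Solomon-Bloembergen model, residual dipolar couplings from a chosen
alignment tensor, and TEVC/VCF sweeps from a sequential two-transition
(resting -> intermediate -> activated) gating model with separate
intermediate-open (IO) and activated-open (AO) conductances,
photobleaching, and state-dependent block.

All generators are deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.spatial.distance import cdist

from ._geometry import ANGLE, BOND, OMEGA, nerf
from .model_io import AtomRecord, StructureModel
from .rdc import AlignmentTensor
from .ephys import (FARADAY, GAS_CONSTANT, ROOM_TEMPERATURE, Sweep, SweepSet,
                    VoltageProtocol)

__all__ = [
    "BundleSpec", "GatingModelSpec", "make_helical_bundle",
    "simulate_noe_peaks", "simulate_pre", "simulate_rdc", "simulate_sweeps",
    "vsd_like_bundle_spec", "pre_gamma2", "pre_intensity_ratio",
    "SB_CONSTANT_CM6_S2", "apply_kcne_preset",
]

# Solomon-Bloembergen prefactor for a nitroxide-proton pair, cm^6 s^-2
SB_CONSTANT_CM6_S2 = 1.23e-32


# -- parametric helical bundle --------------------------------------------

@dataclass(frozen=True)
class BundleSpec:
    """Parametric helical-bundle geometry.

    Each helix is ((start_res, end_res), axis_origin, axis_direction); CA
    atoms lie on an ideal cylinder (radius, rise and twist per residue) and
    loops between consecutive helices are smooth circular-arc connectors
    with ~3.8 A CA spacing.
    """

    helices: tuple
    rise_per_residue: float = 1.5
    twist_per_residue: float = 100.0
    radius: float = 2.3
    residue_name: str = "ALA"
    chain: str = "A"

    def __post_init__(self):
        spans = sorted(h[0] for h in self.helices)
        for (_, e1), (s2, _) in zip(spans, spans[1:]):
            if s2 <= e1:
                raise ValueError("overlapping helix ranges")


def _reference_helix_offsets() -> dict[str, np.ndarray]:
    """Per-atom offsets (in the local CA-trace frame) measured on an ideal
    NeRF-built alpha-helix; applied to the parametric CA trace."""
    phi, psi = -57.8, -47.0
    n_res = 12
    N = [np.array([0.0, 0.0, 0.0])]
    CA = [np.array([BOND[("N", "CA")], 0.0, 0.0])]
    ang = np.radians(ANGLE[("N", "CA", "C")])
    C = [CA[0] + BOND[("CA", "C")] * np.array([-np.cos(ang), np.sin(ang), 0.0])]
    for _ in range(1, n_res):
        N.append(nerf(N[-1], CA[-1], C[-1], BOND[("C", "N")],
                      ANGLE[("CA", "C", "N")], psi))
        CA.append(nerf(CA[-1], C[-1], N[-1],
                       BOND[("N", "CA")], ANGLE[("C", "N", "CA")], OMEGA))
        C.append(nerf(C[-1], N[-1], CA[-1],
                      BOND[("CA", "C")], ANGLE[("N", "CA", "C")], phi))
    N, CA, C = np.array(N), np.array(CA), np.array(C)
    O = np.array([nerf(N[i], CA[i], C[i], BOND[("C", "O")],
                       ANGLE[("CA", "C", "O")], psi + 180.0)
                  for i in range(n_res)])
    H = np.array([nerf(CA[i - 1], C[i - 1], N[i], BOND[("N", "H")],
                       ANGLE[("C", "N", "H")], 0.0)
                  for i in range(1, n_res)])
    H = np.vstack([[np.full(3, np.nan)], H])
    CB = np.array([nerf(C[i], N[i], CA[i], BOND[("CA", "CB")],
                        ANGLE[("N", "CA", "CB")], _CB_TORSION)
                   for i in range(n_res)])
    offsets: dict[str, list[np.ndarray]] = {k: [] for k in
                                            ("N", "H", "C", "O", "CB")}
    for i in range(3, n_res - 3):  # interior residues only
        t = CA[i + 1] - CA[i - 1]
        t /= np.linalg.norm(t)
        r = CA[i - 1] + CA[i + 1] - 2 * CA[i]
        n = r - np.dot(r, t) * t
        n /= np.linalg.norm(n)
        b = np.cross(t, n)
        frame = np.column_stack([t, n, b])
        for name, arr in (("N", N), ("H", H), ("C", C), ("O", O), ("CB", CB)):
            offsets[name].append(frame.T @ (arr[i] - CA[i]))
    return {k: np.mean(v, axis=0) for k, v in offsets.items()}


# L-amino-acid branch torsion C-N-CA-CB; sign checked by the chirality test
_CB_TORSION = 122.6

_OFFSET_CACHE: dict[str, np.ndarray] | None = None


def _offsets() -> dict[str, np.ndarray]:
    global _OFFSET_CACHE
    if _OFFSET_CACHE is None:
        _OFFSET_CACHE = _reference_helix_offsets()
    return _OFFSET_CACHE


def _arc_connector(p0: np.ndarray, p1: np.ndarray, n_points: int,
                   spacing: float, out_of_plane: np.ndarray) -> np.ndarray:
    """Circular-arc loop connector: ``n_points`` interior points between the
    anchors with total arc length ``spacing * (n_points + 1)``."""
    chord = np.linalg.norm(p1 - p0)
    target = spacing * (n_points + 1)
    if target <= chord * 1.0001:
        frac = np.linspace(0, 1, n_points + 2)[1:-1]
        return p0 + np.outer(frac, p1 - p0)
    # arc half-angle a solves sin(a)/a = chord/target
    a = brentq(lambda x: np.sin(x) / x - chord / target, 1e-9, np.pi - 1e-9)
    radius = target / (2 * a)
    u = (p1 - p0) / chord
    w = out_of_plane - np.dot(out_of_plane, u) * u
    nw = np.linalg.norm(w)
    if nw < 1e-9:
        w = np.array([1.0, 0.0, 0.0])
        w = w - np.dot(w, u) * u
        nw = np.linalg.norm(w)
    w /= nw
    center = 0.5 * (p0 + p1) - w * radius * np.cos(a)
    angles = np.linspace(-a, a, n_points + 2)[1:-1]
    return (center[None, :] + radius *
            (np.outer(np.cos(angles), w) + np.outer(np.sin(angles), u)))


def make_helical_bundle(spec: BundleSpec, seed: int = 0,
                        jitter_sd: float = 0.0) -> StructureModel:
    """Build a backbone model (N, H, CA, C, O + CB pseudo-atom) from a
    parametric bundle spec; deterministic given ``seed``."""
    rng = np.random.default_rng(seed)
    helices = sorted(spec.helices, key=lambda h: h[0][0])
    ca: dict[int, np.ndarray] = {}
    # frame neighbors for helix termini come from the helix parametrization
    # itself (virtual k = -1 / k = n points), keeping terminal residue
    # geometry ideal instead of loop-contaminated
    virtual_prev: dict[int, np.ndarray] = {}
    virtual_next: dict[int, np.ndarray] = {}
    helix_axes = []
    for (start, end), origin, direction in helices:
        origin = np.asarray(origin, dtype=float)
        u = np.asarray(direction, dtype=float)
        u = u / np.linalg.norm(u)
        helix_axes.append(u)
        ref = np.array([0.0, 0.0, 1.0])
        if abs(np.dot(ref, u)) > 0.9:
            ref = np.array([1.0, 0.0, 0.0])
        v = np.cross(u, ref)
        v /= np.linalg.norm(v)
        w = np.cross(u, v)
        n = end - start + 1

        def point(k, origin=origin, u=u, v=v, w=w, n=n):
            theta = np.radians(spec.twist_per_residue * k)
            z = (k - (n - 1) / 2) * spec.rise_per_residue
            return (origin + z * u
                    + spec.radius * (np.cos(theta) * v + np.sin(theta) * w))

        for k in range(n):
            ca[start + k] = point(k)
        virtual_prev[start] = point(-1)
        virtual_next[end] = point(n)
    # loops between consecutive helices
    for i in range(len(helices) - 1):
        (s1, e1), _, _ = helices[i]
        (s2, e2), _, _ = helices[i + 1]
        n_loop = s2 - e1 - 1
        if n_loop <= 0:
            continue
        plane_normal = np.cross(helix_axes[i], helix_axes[i + 1])
        if np.linalg.norm(plane_normal) < 1e-6:
            plane_normal = np.array([0.0, 0.0, 1.0])
        pts = _arc_connector(ca[e1], ca[s2], n_loop, 3.8, plane_normal)
        for j, res in enumerate(range(e1 + 1, s2)):
            ca[res] = pts[j]

    residues = sorted(ca)
    trace = np.array([ca[r] for r in residues])
    if jitter_sd > 0:
        trace = trace + rng.normal(0.0, jitter_sd, trace.shape)

    off = _offsets()
    atoms: list[AtomRecord] = []
    n_res = len(residues)
    for i, res in enumerate(residues):
        if res in virtual_prev:
            prev_ca = virtual_prev[res]
        elif i > 0:
            prev_ca = trace[i - 1]
        else:
            prev_ca = 2 * trace[0] - trace[1]
        if res in virtual_next:
            next_ca = virtual_next[res]
        elif i < n_res - 1:
            next_ca = trace[i + 1]
        else:
            next_ca = 2 * trace[-1] - trace[-2]
        t = next_ca - prev_ca
        t /= np.linalg.norm(t)
        r = prev_ca + next_ca - 2 * trace[i]
        nvec = r - np.dot(r, t) * t
        norm = np.linalg.norm(nvec)
        if norm < 1e-8:  # straight segment: pick any perpendicular
            nvec = np.cross(t, [0.0, 0.0, 1.0])
            if np.linalg.norm(nvec) < 1e-8:
                nvec = np.cross(t, [1.0, 0.0, 0.0])
            norm = np.linalg.norm(nvec)
        nvec /= norm
        b = np.cross(t, nvec)
        frame = np.column_stack([t, nvec, b])
        res_name = spec.residue_name
        for atom_name in ("N", "H", "CA", "C", "O", "CB"):
            if atom_name == "CA":
                pos = trace[i]
            elif atom_name == "H" and i == 0:
                continue  # N-terminal amide proton undefined
            elif atom_name == "CB" and res_name == "GLY":
                continue
            else:
                pos = trace[i] + frame @ off[atom_name]
            element = atom_name[0]
            atoms.append(AtomRecord(spec.chain, res, res_name, atom_name,
                                    element, tuple(pos)))
    return StructureModel(atoms, model_id=1)


def vsd_like_bundle_spec(scale: float = 1.0) -> BundleSpec:
    """Four antiparallel transmembrane helices arranged on a square,
    with residue spans mirroring a voltage-sensor construct
    (S1 120-142, S2 160-179, S3 198-215, S4 219-239)."""
    d = 8.8 * scale  # center-to-center spacing of adjacent helices
    up = (0.0, 0.0, 1.0)
    down = (0.0, 0.0, -1.0)
    return BundleSpec(helices=(
        ((120, 142), (-d / 2, -d / 2, 0.0), up),
        ((160, 179), (d / 2, -d / 2, 0.0), down),
        ((198, 215), (d / 2, d / 2, 0.0), up),
        ((219, 239), (-d / 2, d / 2, 0.0), down),
    ))


# -- NOE cross-peak intensities -------------------------------------------

def simulate_noe_peaks(model: StructureModel,
                       group_map: Mapping[int, str],
                       scale_core: float = 0.5,
                       noise_sd: float = 0.0,
                       cutoff: float = 6.0,
                       seed: int = 0,
                       base_amplitude: float = 1.0e6,
                       include_sidechain_sites: bool = True) -> pd.DataFrame:
    """NOE peak table: one row per proton pair within ``cutoff``.

    Intensity = A * r^-6 * exp(eps), eps ~ N(0, noise_sd); A is scaled by
    ``scale_core`` for pairs whose residues are both in the 'core' group
    (emulating reduced peak amplitudes in the core transmembrane helices).
    With ``include_sidechain_sites`` a pseudo side-chain proton named
    ``HB`` is placed at each CB, standing in for the side-chain NOE
    network that dominates inter-helix contacts in real spectra.
    """
    rng = np.random.default_rng(seed)
    protons = [(i, a) for i, a in enumerate(model.atoms) if a.element == "H"]
    if include_sidechain_sites:
        for i, a in enumerate(model.atoms):
            if a.atom_name == "CB":
                protons.append(
                    (i, AtomRecord(a.chain, a.residue_number, a.residue_name,
                                   "HB", "H", a.xyz)))
    idx = np.array([i for i, _ in protons])
    coords = model.xyz[idx]
    dist = cdist(coords, coords)
    rows = []
    for i in range(len(protons)):
        for j in range(i + 1, len(protons)):
            r = dist[i, j]
            if r > cutoff or r <= 0:
                continue
            a_i, a_j = protons[i][1], protons[j][1]
            both_core = (group_map.get(a_i.residue_number) == "core"
                         and group_map.get(a_j.residue_number) == "core")
            amp = base_amplitude * (scale_core if both_core else 1.0)
            eps = rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0
            rows.append({
                "residue_a": a_i.residue_number, "atom_a": a_i.atom_name,
                "residue_b": a_j.residue_number, "atom_b": a_j.atom_name,
                "intensity": amp * r ** -6 * np.exp(eps),
                "group": "core" if both_core else "periphery",
                "r_true": r,
            })
    return pd.DataFrame(rows)


# -- PRE intensity ratios --------------------------------------------------

def pre_gamma2(r_angstrom, tau_c_s: float, field_mhz: float) -> np.ndarray:
    """Solomon-Bloembergen transverse PRE rate for a nitroxide-amide pair:

    Gamma_2 = (K / r^6) (4 tau_c + 3 tau_c / (1 + omega_H^2 tau_c^2)),
    K = 1.23e-32 cm^6 s^-2.
    """
    r_cm = np.asarray(r_angstrom, dtype=float) * 1e-8
    omega = 2 * np.pi * field_mhz * 1e6
    spectral = 4 * tau_c_s + 3 * tau_c_s / (1 + (omega * tau_c_s) ** 2)
    return SB_CONSTANT_CM6_S2 / r_cm ** 6 * spectral


def pre_intensity_ratio(gamma2, r2_dia: float, t_inept_s: float) -> np.ndarray:
    """Paramagnetic/diamagnetic peak-intensity ratio:
    R2 exp(-Gamma_2 t) / (R2 + Gamma_2)."""
    g = np.asarray(gamma2, dtype=float)
    return r2_dia * np.exp(-g * t_inept_s) / (r2_dia + g)


def simulate_pre(model: StructureModel,
                 label_residues: Sequence[int],
                 tau_c_s: float = 20e-9,
                 t_inept_s: float = 10e-3,
                 r2_dia: float = 62.83,
                 field_mhz: float = 900.0,
                 noise_sd: float = 0.0,
                 seed: int = 0) -> pd.DataFrame:
    """PRE table: per (label site, amide) intensity ratio.

    The unpaired electron sits at the CB of each label residue (matching
    the restraint convention); ratios are clipped to [0, 1.2].
    """
    if tau_c_s <= 0 or t_inept_s <= 0:
        raise ValueError("tau_c and INEPT time must be positive")
    rng = np.random.default_rng(seed)
    rows = []
    for label in label_residues:
        if not model.has_atom(label, "CB"):
            raise ValueError(f"label residue {label} has no CB atom")
        cb = model.coord(label, "CB")
        for res in model.residue_numbers():
            if res == label or not model.has_atom(res, "H"):
                continue
            r = float(np.linalg.norm(model.coord(res, "H") - cb))
            g2 = float(pre_gamma2(r, tau_c_s, field_mhz))
            ratio = float(pre_intensity_ratio(g2, r2_dia, t_inept_s))
            if noise_sd > 0:
                ratio += rng.normal(0.0, noise_sd)
            ratio = float(np.clip(ratio, 0.0, 1.2))
            i_dia = 1.0
            rows.append({
                "label_residue": label, "target_residue": res,
                "i_para": ratio * i_dia, "i_dia": i_dia,
                "fwhm_dia": r2_dia / np.pi,
                "r_true": r, "gamma2_true": g2,
            })
    return pd.DataFrame(rows)


# -- residual dipolar couplings -------------------------------------------

def simulate_rdc(model: StructureModel, tensor: AlignmentTensor,
                 j_nh: float = 93.0, noise_sd: float = 0.0,
                 seed: int = 0) -> pd.DataFrame:
    """Isotropic/aligned 15N peak-position table encoding J and J+D.

    The 15N-dimension HSQC/TROSY peak pair is split by half the coupling,
    so doubling the position difference recovers J (isotropic) or J+D
    (aligned). Splittings are handled as magnitudes; the physical J_NH is
    negative but only frequency differences are observable here.
    """
    rng = np.random.default_rng(seed)
    tmat = tensor.matrix()
    rows = []
    for res in model.residue_numbers():
        if not (model.has_atom(res, "N") and model.has_atom(res, "H")):
            continue
        nh = model.coord(res, "H") - model.coord(res, "N")
        nh /= np.linalg.norm(nh)
        d = float(nh @ tmat @ nh)
        center = float(rng.uniform(-500.0, 500.0))
        noise = (rng.normal(0.0, noise_sd, 4) if noise_sd > 0
                 else np.zeros(4))
        rows.append({
            "residue": res,
            "n15_hsqc_iso": center + noise[0],
            "n15_trosy_iso": center + j_nh / 2 + noise[1],
            "n15_hsqc_ali": center + noise[2],
            "n15_trosy_ali": center + (j_nh + d) / 2 + noise[3],
            "d_true": d,
        })
    return pd.DataFrame(rows)


# -- gating-model sweep generator -----------------------------------------

@dataclass(frozen=True)
class GatingModelSpec:
    """Sequential two-transition gating model, resting -> intermediate ->
    activated, with separate IO/AO conductances.

    Numeric defaults are generator choices for a plausible KCNQ1-like
    oocyte recording, not measured channel parameters: valences ~2 and
    ~1.2, half-activation voltages -50 and +10 mV, whole-oocyte
    conductances of order 10 uS, K+ reversal near -80 mV, a ~50 s
    photobleaching time and the 0.8/0.2 IO/AO block asymmetry of 5 uM
    XE991.
    """

    z1: float = 2.0
    z2: float = 1.2
    v1_mV: float = -50.0
    v2_mV: float = 10.0
    tau1_s: float = 0.3
    tau2_s: float = 1.0
    g_io_uS: float = 10.0
    g_ao_uS: float = 10.0
    e_rev_mV: float = -80.0
    f1_amp: float = 0.7
    f2_amp: float = 0.3
    bleach_tau_s: float = 50.0
    block_io: float = 0.8
    block_ao: float = 0.2
    block_tau_s: float = 10.0
    noise_sd: float = 0.0
    temperature_K: float = ROOM_TEMPERATURE

    def __post_init__(self):
        if self.g_io_uS < 0 or self.g_ao_uS < 0:
            raise ValueError("conductances must be non-negative")
        if not (0 <= self.block_io <= 1 and 0 <= self.block_ao <= 1):
            raise ValueError("block fractions must lie in [0, 1]")

    def equilibrium(self, v_mV: float) -> tuple[float, float]:
        """(q, a): steady-state occupancy of intermediate-or-beyond and of
        the activated state."""
        rt = GAS_CONSTANT * self.temperature_K
        k1 = np.exp(self.z1 * FARADAY * (v_mV - self.v1_mV) * 1e-3 / rt)
        k2 = np.exp(self.z2 * FARADAY * (v_mV - self.v2_mV) * 1e-3 / rt)
        total = 1 + k1 + k1 * k2
        return (k1 + k1 * k2) / total, (k1 * k2) / total


def apply_kcne_preset(spec: GatingModelSpec, kcne: str) -> GatingModelSpec:
    """Auxiliary-subunit phenotypes: KCNE1 suppresses the IO conductance and
    amplifies AO; KCNE3 left-shifts the first VSD transition so the channel
    is constitutively conductive at physiological voltages."""
    if kcne == "none":
        return spec
    if kcne == "kcne1":
        return replace(spec, g_io_uS=0.0, g_ao_uS=spec.g_ao_uS * 2.0,
                       v1_mV=spec.v1_mV - 40.0, tau2_s=spec.tau2_s * 2.0)
    if kcne == "kcne3":
        return replace(spec, v1_mV=spec.v1_mV - 90.0)
    raise ValueError(f"unknown KCNE preset {kcne!r}")


def simulate_sweeps(spec: GatingModelSpec,
                    protocol: VoltageProtocol,
                    test_voltages: Sequence[float],
                    kcne: str = "none",
                    drug: str = "control",
                    seed: int = 0,
                    with_fluorescence: bool = True,
                    drug_equilibrated: bool = True,
                    time_in_drug_s: float = 0.0) -> SweepSet:
    """Simulate a sweep set under a step protocol.

    ``drug`` is one of ``control``, ``xe991`` (state-dependent partial
    block, fully developed when ``drug_equilibrated``), or ``chromanol``
    (zeroes both conductances). Occupancies relax mono-exponentially
    toward the two sequential Boltzmann equilibria and always sum to one.
    """
    if any(abs(v) > 200 for v in test_voltages):
        raise ValueError("protocol voltages outside +-200 mV")
    spec = apply_kcne_preset(spec, kcne)
    rng = np.random.default_rng(seed)

    g_io, g_ao = spec.g_io_uS, spec.g_ao_uS
    if drug == "xe991":
        onset = 1.0 if drug_equilibrated else (
            1.0 - np.exp(-time_in_drug_s / spec.block_tau_s))
        g_io = g_io * (1.0 - spec.block_io * onset)
        g_ao = g_ao * (1.0 - spec.block_ao * onset)
    elif drug == "chromanol":
        g_io = g_ao = 0.0
    elif drug != "control":
        raise ValueError(f"unknown drug preset {drug!r}")

    sweeps = []
    for v_test in test_voltages:
        t = np.arange(0.0, protocol.total_duration, protocol.dt_s)
        volt = np.where(
            t < protocol.test_start, protocol.holding_mV,
            np.where(t < protocol.tail_start, v_test,
                     protocol.tail_voltage_mV))
        q = np.empty_like(t)
        a = np.empty_like(t)
        q0, a0 = spec.equilibrium(protocol.holding_mV)
        seg_bounds = [0.0, protocol.test_start, protocol.tail_start,
                      protocol.total_duration]
        seg_v = [protocol.holding_mV, v_test, protocol.tail_voltage_mV]
        for lo, hi, vv in zip(seg_bounds[:-1], seg_bounds[1:], seg_v):
            mask = (t >= lo) & (t < hi)
            tt = t[mask] - lo
            q_inf, a_inf = spec.equilibrium(vv)
            q[mask] = q_inf + (q0 - q_inf) * np.exp(-tt / spec.tau1_s)
            a[mask] = a_inf + (a0 - a_inf) * np.exp(-tt / spec.tau2_s)
            if mask.any():
                last = np.nonzero(mask)[0][-1]
                q0, a0 = q[last], a[last]
        p_a = np.minimum(a, q)
        p_i = q - p_a
        current = (g_io * p_i + g_ao * p_a) * (volt - spec.e_rev_mV) * 1e-3
        if spec.noise_sd > 0:
            scale = max(np.max(np.abs(current)), 1e-9)
            current = current + rng.normal(0.0, spec.noise_sd * scale,
                                           current.shape)
        fluo = None
        if with_fluorescence:
            fluo = ((1.0 + spec.f1_amp * q + spec.f2_amp * p_a)
                    * np.exp(-t / spec.bleach_tau_s))
            if spec.noise_sd > 0:
                fluo = fluo + rng.normal(0.0, spec.noise_sd, fluo.shape)
        sweeps.append(Sweep(v_test, t, current, fluo))
    return SweepSet(sweeps, protocol, spec.temperature_K)
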