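# vsdkit

Analysis toolkit for voltage-sensor-domain (VSD) structure and function:
the computational chain behind a combined solution-NMR and
electrophysiology study of the KCNQ1 potassium-channel voltage sensor in
its intermediate conformation.

The package is for structural biologists and channel physiologists who
need, in one place:

- **NMR restraint derivation** — NOE cross-peak calibration into
  strong/medium/weak/very-weak distance classes (1.8–2.8, 1.8–3.5,
  1.8–4.5, 1.8–5.5 Å), paramagnetic relaxation enhancement (PRE)
  intensity ratios inverted through the Solomon–Bloembergen model
  (Γ₂ = K r⁻⁶ (4τ_c + 3τ_c/(1+ω²τ_c²)), K = 1.23×10⁻³² cm⁶s⁻²) into
  distance bounds, TALOS-style torsion filtering (class "strong",
  confidence ≥ 7, ±20°) and α-helical hydrogen-bond restraints.
- **RDC analysis** — coupling extraction from HSQC/TROSY ¹⁵N peak pairs
  (the doubling rule), alignment-tensor estimation from coupling extrema
  and exact SVD least-squares fitting of the Saupe matrix, Q-factor and
  r.m.s.d. agreement scores.
- **A restraint-driven embedder** — a desk-scale simulated-annealing
  embedder on a reduced backbone representation (N, H, CA, C, O + CB)
  with flat-well distance wells, wrapped dihedral wells, chirality and
  ideal-geometry terms, used for parameter-recovery and long-range-NOE
  jackknife experiments.
- **Ensemble validation** — restraint tallies by sequence separation,
  violation r.m.s.d.s (distance and dihedral), iterative mean-structure
  ensemble r.m.s.d., and DBSCAN block clustering of trajectories.
- **Conformation comparison** — helix axes by PCA, the signed S4
  translation along the membrane normal, salt-bridge (gating charge)
  registry detection, helical-span measurement.
- **Electrophysiology/VCF quantification** — tail-current G-V and
  bleach-corrected ΔF/F F-V relations, single/double Boltzmann fits of
  the form 1/(1+exp(−zF(V−V₁/₂)/RT)), and the chromanol-subtracted XE991
  inhibition fraction f = (I_control − I_XE991)/(I_control − I_chromanol).
- **Synthetic generators** for all of the above, so the entire chain is
  testable without any deposited data: a parametric four-helix bundle,
  r⁻⁶ NOE intensities with two amplitude groups, Solomon–Bloembergen PRE
  ratios, tensor-derived RDC peak tables, and TEVC/VCF sweeps from a
  sequential two-transition (resting → intermediate → activated) gating
  model with separate intermediate-open (IO) and activated-open (AO)
  conductances and state-dependent block.

## Worked example

Simulate a channel whose current is carried purely by the IO state,
apply the drug protocol (hold −20 mV, +40 mV for 4 s, −40 mV for 2 s),
and quantify XE991 block with chromanol subtraction:

```python
from vsdkit import GatingModelSpec, VoltageProtocol, xe991_inhibition
from vsdkit.ephys import steady_state_current
from vsdkit.synthetic import simulate_sweeps

spec = GatingModelSpec(g_io_uS=10.0, g_ao_uS=0.0,
                       block_io=0.8, block_ao=0.2,
                       tau1_s=0.05, tau2_s=0.2)
proto = VoltageProtocol(holding_mV=-20.0, pre_duration_s=1.0)

def steady(drug):
    sweeps = simulate_sweeps(spec, proto, [40.0], drug=drug)
    return steady_state_current(sweeps.sweeps[0], proto)

res = xe991_inhibition(steady("control"), steady("xe991"),
                       steady("chromanol"))
print(res.summary())
```

```
XE991 inhibition fraction = 0.800
  I_control = 0.234 uA, I_XE991 = 0.047 uA, I_chromanol = 0.000 uA (n = 1)
```

An IO-only channel under an 80 %/20 % IO/AO block shows 80 % inhibition;
rerunning with `g_io_uS=0, g_ao_uS=10` gives 0.200 — the signature used
to assign intermediate-open versus activated-open conductances.

A structural round trip in a few lines:

```python
from vsdkit.synthetic import make_helical_bundle, vsd_like_bundle_spec, simulate_pre
from vsdkit.restraints import pre_to_restraints

bundle = make_helical_bundle(vsd_like_bundle_spec())
table = simulate_pre(bundle, [121, 238])            # nitroxide labels
restraints = pre_to_restraints(table, tau_c_s=20e-9,
                               t_inept_s=10e-3, field_mhz=900.0)
mid = [r for r in restraints if r.klass == "pre_mid"][0]
print(len(restraints), mid.provenance, mid.d_low, mid.d_high)
```

prints `232 pre:121->133 10.02... 22.02...`: 232 restraints, and the
mid-regime restraint from the label at residue 121 to the amide of
residue 133 brackets the true label–amide distance (16.02 Å) with the
±6 Å well. On noise-free input the well midpoint reproduces the true
distance to better than 10⁻³ Å.

A CLI mirrors the common workflows: `vsdkit info/convert`,
`vsdkit simulate {bundle,pre,sweeps}`, `vsdkit restraints {pre,hbond}`,
`vsdkit validate`, `vsdkit compare`, `vsdkit inhibition`.

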