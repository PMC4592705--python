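# ribomech

Anisotropic-network mechanics and center-of-mass analysis for
ribonucleoprotein assemblies, built around the bacterial ribosome use case:
how do peripheral ribosomal proteins — L9 on one side, the L12 stalk on the
other — shape the mass distribution and intrinsic dynamics of the 50S
subunit, and how rigid is the peptidyl transferase center (PTC) where
catalysis happens?

`ribomech` is a library for structural bioinformaticians who want these
analyses as composable Python functions (plus a thin `ribomech` CLI for
batch runs on PDB files).

## The model

A structure is coarse-grained to the residue level: one node at Cα per
amino acid; three nodes per nucleotide at P (backbone), C2 (base) and C4′
(pentose). Since an amino acid averages ~110 Da and a nucleotide ~330 Da,
every node represents a nominal 110 Da, and the **center of mass of any node
subset is simply its geometric center**.

Nodes within a cutoff R_c (default 15 Å) are connected by identical
harmonic springs — the anisotropic network model (ANM):

    E = γ/2 Σ_{i<j} (R_ij − R⁰_ij)²  Θ(R_c − R⁰_ij)

The 3N×3N Hessian **H** of this energy has six zero eigenvalues for a
connected network (rigid translations and rotations); the remaining
eigenpairs (λ_k, **V**_k) are the normal modes, with frequencies √λ_k.
Thermal fluctuations follow from the pseudo-inverse,

    ⟨ΔR ΔRᵀ⟩ = k_B T H⁻¹ = (k_B T/γ) Σ_{k>6} λ̃_k⁻¹ V_k V_kᵀ,   λ̃_k = λ_k/γ,

from which per-node mean-square fluctuations, predicted B-factors
(B = 8π²/3 ⟨Δr²⟩) and normalized cross-correlation maps are derived.

On top of this sit the mass-balance operations: apply named deletions
(e.g. "L9", "outermost L12 dimer + bound L10 CTD segment", both), recompute
the CM of the retained nodes, and report shift magnitudes, directions, and
distances to the PTC centroid — plus a PTC rigidity summary comparing PTC
B-factors (experimental or ANM-predicted) against the whole assembly.

## Worked example

```sh
python examples/04_cm_deletion_report.py
```

```
   variant  n_nodes      cm_x      cm_y      cm_z  shift_from_wt  distance_to_ptc  direction_dot
 wild_type      240  0.792688 -1.031980 -0.885900       0.000000         1.954571            NaN
  delta_L9      210 -4.811876 -1.186316 -1.017700       5.608237         3.826389    -220.166245
 delta_L12      210  6.618312 -1.179101 -1.006214       5.828724         7.688787    -237.818151
delta_both      180  1.050592 -1.383680 -1.180033       0.526044         2.214499      -0.830167
```

The fixture is a 240-node assembly: a globular RNA-like core with two equal
protein appendages (L9-like and L12-like) on opposite sides, and a planted
low-B "PTC" at the core center. Deleting either appendage alone moves the
CM ~5.6–5.8 Å *away* from the deleted component (`direction_dot < 0`) and
away from the PTC; deleting both nearly cancels (0.53 Å) — the compensation
logic by which L9 counterbalances the mass of the L12 stalk. The other
examples (`examples/01–05`) cover coarse-graining, normal modes, B-factor
prediction and the PTC rigidity summary.

The same pipeline runs from a shell:

```sh
ribomech generate --preset balanced --seed 4 --outdir fx
ribomech modes    --config fx/config.yaml     # reports n_zero=6
ribomech cmreport --config fx/config.yaml
ribomech ptc      --config fx/config.yaml --source predicted
```

To analyse a real ribosome structure, point `input:` at a PDB file and
supply the chain mapping for L9/L10/L12 in the config — chain identifiers
differ between depositions, so they are never hard-coded.

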