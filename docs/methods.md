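# Methods

## Coarse-grained representation

Structures are reduced to point nodes at the residue level: the Cα atom for
each amino acid, and three atoms — P (backbone), C2 (nitrogenous base),
C4′ (pentose) — for each nucleotide. The 3:1 node ratio mirrors the ~330 Da
vs ~110 Da average residue weights, so each node carries a uniform nominal
110 Da and the geometric center of any node subset equals its center of
mass. A mass-weighted centroid option exists (`center_of_mass(...,
masses=)`) but is off by default; the uniform convention is the model.

Node order is deterministic: chains in file order, residues in chain order,
P < C4′ < C2 within a nucleotide. Residues missing a mapped atom (a
5′-terminal nucleotide without P, a disordered Cα) contribute only the nodes
that exist; coordinates are never synthesized, and each omission is warned.
Residues that classify as neither amino acid nor nucleotide are skipped and
counted. Classification is by residue name against standard dictionaries,
with an atom-content fallback (P + C2 + C4′ present ⇒ nucleotide) so
modified nucleosides map like standard ones. Altloc conformers collapse to
the highest-occupancy copy; waters and non-polymer HETATM records (ions,
ligands) are excluded from the node model; multi-model files use the first
model, since the elastic network needs a single equilibrium geometry.

## Elastic network

The anisotropic network model connects node pairs whose equilibrium
separation is **strictly** below the cutoff (the Heaviside factor is zero at
and beyond R_c) with identical springs:

E = γ/2 Σ_{i<j} (R_ij − R⁰_ij)², summed over unordered contact pairs. The
Hessian's off-diagonal 3×3 blocks are −γ û ûᵀ with û the unit inter-node
vector; diagonal blocks enforce zero block-row sums, which makes the six
rigid-body motions exact null vectors of a connected network. A two-body
system therefore has five zero modes and one stretching mode at exactly 2γ —
a useful analytic anchor.

Parameters and units: γ defaults to 1 (energy Å⁻², nominally
kcal mol⁻¹ Å⁻²), R_c to 15 Å — appropriate for the mixed Cα/P-C2-C4′ node
density — and T to 300 K with k_B in kcal mol⁻¹ K⁻¹, giving the covariance
prefactor k_B T/γ ≈ 0.596 Å². Mode shapes and *relative* fluctuations are
independent of γ; only absolute magnitudes carry the prefactor. One
convention deserves note: the assembled Hessian contains γ, while the
textbook covariance prefactor k_B T/γ belongs with the γ-free
contact-topology matrix. `covariance()` therefore divides stored
eigenvalues by γ, so that C = k_B T · pinv(H) holds identically and
fluctuations scale as 1/γ (doubling γ halves ⟨Δr²⟩), with both readings
coinciding at the default γ = 1.

Numerics: the Hessian is stored sparse (CSR). Below 3 000 nodes the full
spectrum comes from a dense symmetric eigensolver; above, the lowest m modes
come from ARPACK in shift-invert mode about σ = −10⁻⁶ (H − σI is positive
definite despite the null space). Eigenvalues below
max(10⁻⁸ · λ_max, 10⁻¹⁰) count as zero, with λ_max Gershgorin-bounded when
the spectrum is partial. More than six zero modes triggers a
disconnected-network warning carrying the component count of the contact
graph. Coincident nodes (pair distance ≤ 10⁻⁶ Å) are rejected outright.
Degenerate eigenvalues may return any orthonormal basis; tests compare
subspaces, not individual vectors.

Observables: per-node mean-square fluctuation is the trace of the node's
diagonal 3×3 covariance block, converted to B-factors by the standard
crystallographic B = 8π²/3 ⟨Δr²⟩; cross-correlations are
tr C_ij / √(tr C_ii · tr C_jj), clipped to [−1, 1] against round-off.
Truncating the mode sum to the lowest non-zero modes under-approximates
every variance monotonically. `mode_fluctuations` computes fluctuations
without materializing the dense 3N×3N covariance.

## Center-of-mass analysis

Deletion variants remove labeled components (and/or explicit residue
selections) from the node set; the PTC nodes are protected and any deletion
touching them is refused, since every variant must report its distance to
the PTC centroid (geometric center of all nodes of the PTC nucleotides, in
wild-type geometry). For each variant the report records the CM, its shift
from wild type, its distance to the PTC centroid, and the diagnostic dot
product (CM_mut − CM_wt)·(c_removed − CM_wt), which centroid arithmetic
forces negative: the CM moves strictly away from deleted material. Two
equal components on opposite sides compensate — double deletion shifts the
CM less than either single deletion.

The PTC rigidity summary reports the mean B over PTC nodes, the median B
over all nodes, and the PTC nodes' percentile rank using mid-rank ties
(uniform B ⇒ exactly 50 %). B-factors come either from the input's B-factor
column or from the ANM prediction; per-node values can be exported clamped
to a fixed 0–70 Å² window for color mapping.

The component boundaries themselves (which chains are L9, which L12 dimer
is outermost, which L10 residues form its bound CTD segment) are deliberately
config-supplied selections: they vary between depositions and are not
derivable from coordinates.

## Synthetic fixtures

The generators emulate the features the pipeline assumes: helical Cα traces
(~3.8 Å steps), helical P/C4′/C2 single strands (P–P ≈ 6 Å, connected at
15 Å), and a balanced assembly — a jittered globular RNA-like core
(default 60 nucleotides in a 22 Å ball) with two 30-residue protein
appendages on opposite sides at 40 Å offset, standing in for L9 and the
outermost L12 dimer, plus a planted low-B island (B = 8 Å² vs 40 Å² core,
60 Å² appendages) at the five center-most core nucleotides standing in for
the PTC. Geometry is idealized, not physical: no sequence realism, base
pairing or sterics, and B-factor "experiments" are planted constants. Tests
passing on these fixtures validate the bookkeeping, the algebra and the
directional laws — they do not validate biological realism of any particular
deposition.

Ground truth accompanies every balanced fixture: component centroids and
per-deletion CMs computed by closed-form centroid arithmetic
((N·CM − n_c·c_c)/(N − n_c)), independent of the analysis pipeline, which
must agree to 10⁻⁶ Å. All generators are pure functions of their seed
(byte-identical re-runs), and the seed is recorded in the PDB header and the
sidecar JSON.

Problem sizes throughout the tests and the acceptance script are small by
design — tens to a few hundred nodes — because every asserted quantity
(null-space dimension, finite-difference agreement, centroid laws) is
size-independent; the sparse/iterative code path exists for assemblies of
tens of thousands of nodes.

## Known limitations

- Uniform γ for all contact types; no distance-weighted or
  chemistry-specific springs, and no Gaussian (isotropic) network variant.
- No modeling of missing residues or subunits: what is absent from the
  input is absent from the network, warned but not repaired.
- mmCIF input is not supported; PDB only.
- Predicted B-factors are in k_B T/γ-scaled units; absolute comparison to
  experimental B requires calibrating γ, which the package leaves to the
  user (relative profiles and percentile ranks do not).
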