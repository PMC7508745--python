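# Methods

## Forward model

A paramagnetic center with an anisotropic magnetic susceptibility shifts
every nucleus by the pseudocontact shift (point-dipole approximation)

    σ = (1/12π) [ Δχ_ax (2z² − x² − y²)/r⁵ + (3/2) Δχ_rh (x² − y²)/r⁵ ],

evaluated in the tensor frame (origin at the metal, axes along the tensor
principal axes).  Contributions of several centers add linearly.  The model
neglects Fermi-contact terms, the temperature dependence of Δχ, and
nucleus-specific residual anisotropic chemical shifts; for amide ¹H/¹⁵N
data from strongly shifting lanthanides these are small compared to the
PCS itself, and a proton-only fit option is provided to check this on any
dataset (on unbiased synthetic data it reproduces the all-nuclei tensor
within noise).

**Units.** Coordinates Å, Δχ in 10⁻³² m³, PCS in ppm.  The prefactor is
then K = 10⁴/(12π) ≈ 265.26: Δχ·10⁻³²/r³·10⁻³⁰ leaves 10⁻², and ppm
contributes 10⁶.  K is frozen in `symmpcs.model.K_PCS` and exercised by
hand-evaluated spot values (−1.460 ppm for Δχ_ax = −43, spin 25 Å on-axis;
+0.531 ppm for Δχ_ax = −43, Δχ_rh = −7.8, spin 25 Å equatorial).

**Rotations.** Euler angles are intrinsic ZYZ, active:
R = Rz(α)·Ry(β)·Rz(γ); the columns of R are the tensor principal axes in
molecular coordinates.  Worked example: (α, β, γ) = (30°, 40°, 50°) gives

    R = [[ 0.0434, -0.8296,  0.5567],
         [ 0.9096,  0.2633,  0.3214],
         [-0.4132,  0.4924,  0.7660]]

(first column = image of x̂).  The inverse conversion returns β ∈ [0, 180),
α, γ ∈ [0, 360), with γ = 0 at the gimbal degeneracies (β ≈ 0 or 180).  A
symmetric traceless tensor is invariant under 180° flips about its
principal axes, so four ZYZ triples describe each orientation;
`ChiTensor.canonicalized()` resolves this (β ≤ 90° when possible, then
smallest α, then smallest γ) and also re-labels principal axes so that
|Δχ_rh| ≤ (2/3)|Δχ_ax| with z on the largest-magnitude principal value.
Canonicalization never changes the PCS field; it exists so fitted tensors
can be compared.

**Singularity guard.** The r⁻⁵ pole is guarded at 10⁻⁶ Å; the point-dipole
model is meaningless at the metal anyway.  Inside the fit the guard is a
large finite penalty rather than an exception so the optimizer can retreat.

## Symmetry reduction

For one tag per protomer of a Cₙ assembly, the total PCS at spin j equals
the PCS of a single tensor summed over the n symmetry-equivalent copies of
j (exactly, for ideal symmetry; verified to <10⁻¹⁰ ppm over random
configurations).  This reduces 8n parameters to 8.  Symmetry operators are
rotations by k·360/n about the axis; the axis is either supplied or
detected from two chains by least-squares (Kabsch) superposition of shared
Cα atoms, reading order and axis off the resulting rotation (order
tolerance 5°).  For real, slightly asymmetric crystal structures the
detected axis is used as-is and the residual asymmetry flows into the fit
residuals.  Chains sorted by identifier define the operator indices;
Euler-angle reports depend on that convention.

## Fitting

The cost f = Σⱼ wⱼ [PCSⱼ^exp − Σ_chains PCS^calc]² is minimized with
L-BFGS-B (SciPy) using central finite differences.  Internally Δχ and
coordinates are scaled by 1/10 and angles converted to radians so the
Hessian approximation is well conditioned; bounds are |Δχ| ≤ 200 ×10⁻³² m³
and the structure bounding box padded by 30 Å for the metal.  Convergence:
projected-gradient tolerance 10⁻⁸ on the scaled problem, at most 2000
iterations.  Weights default to 1 (no down-weighting of mobile regions).

**Staged starts.**  Because the PCS is linear in (Δχ_ax, Δχ_rh), those two
are seeded by closed-form least squares at any candidate geometry.  Each
start position first runs an **axial-only** stage (Δχ_rh = 0, six
parameters) over a coarse orientation grid (α ∈ {0..300°} step 60, β ∈
{30, 90, 150}); the winner seeds the full eight-parameter refinement.  With
fewer than 20 data points the full model is refined only from the axial
basin: eight parameters against ~10 noisy values can carve spurious minima
whose cost undercuts the true one, and comparing full-model minima by cost
is then misleading.  With more data, additional full-model starts (a small
orientation-seed set, plus a warm start from the previous round during
assignment) compete by final cost.

**Multi-start over chains.**  One staged fit per chain, started 6 Å outward
from the tag residue's Cβ along Cα→Cβ (the typical tag-arm length).  The n
results are the n symmetry-related minima; starts that collapse onto the
same minimum (metal positions within 1 Å) are flagged as duplicates.

**Reporting frame.**  Fitted tensors are reported in the standard frame
for symmetric multimers: origin at the centroid of the n metal positions,
z along the best-fit metal-plane normal (aligned with the symmetry axis),
x such that a chosen reference metal has θ = 0.  Each metal is given as
(r_metal, θ_metal) polar coordinates; orientations as ZYZ angles in this
frame.  The report includes the metal's distance to both the tag residue's
Cα and Cβ.  The reference metal (θ = 0) is configurable; the default is
the first fitted chain.

**Diagnostics.**  Per-residue total deviation (Σ over that residue's
nuclei of |exp − calc|) is classified ok (< 0.2 ppm), warn ([0.2, 0.4)) or
bad (≥ 0.4) — half-open intervals, lower bound inclusive — plus Pearson r
and RMSD between experimental and back-calculated values.

## Iterative assignment

PCS = paramagnetic − diamagnetic peak position.  From ~10 unambiguous seed
PCSs the loop is: fit tensor → back-predict paramagnetic peaks from the
assigned diamagnetic spectrum (¹H PCS at the H coordinate, ¹⁵N PCS at the
N coordinate) → match predictions to observed peaks → convert new matches
to PCS values → repeat until no new assignments (max 20 rounds).
Assignments only accumulate; existing matches are never revoked, so the
PCS set grows monotonically to a fixed point.

Matching is one-to-one in tolerance-scaled shift space,
d² = (Δh/tol_h)² + (Δn/tol_n)², accepting d ≤ 1 under mutual
nearest-neighborhood; if a second candidate lies within 10% of the best
distance on either side, both peaks stay unassigned.  Defaults
tol_h = 0.05 ppm, tol_n = 0.5 ppm (typical TROSY linewidths).  Emitted PCS
values are taken from the ¹H dimension by default (smallest relative
error); ¹⁵N differences can be added as separate entries.  Spurious
observed peaks fail the ambiguity/mutual-nearest rules and remain
unassigned.

## Field maps

`evaluate_grid` sums all expanded tensors at every node of a regular grid
(default: structure bounding box + 30 Å padding, 2 Å spacing — enough to
resolve the ±0.2 ppm surface without excessive file size).  Cells within
1 Å of a metal are clamped to ±10⁶ ppm as a documented sentinel so files
stay loadable.  Output is an OpenDX scalar field (last index fastest, the
convention molecular-graphics programs parse) plus a companion file with
the recommended contour levels −1.0, −0.2, +0.2, +1.0 ppm.  For
tensors of the magnitude fitted here the summed field at ≥ 100 Å from the
tags falls below the 0.2 ppm outer contour — only the widest isosurface
survives at remote distances, which is what makes long-range studies
possible.

## Synthetic study conditions

The fixture generator builds one backbone-like protomer (N/CA/C per
residue along a gentle helical curve, radius 12 Å, rise 1.5 Å/residue,
20°/residue, protomer axis 18 Å from the symmetry axis), replicates it by
the Cₙ operators, adds amide protons geometrically, and designates a tag
residue (default 30) with a Cβ.  Defaults define the standard study:

| parameter | default | rationale |
|---|---|---|
| order n | 3 | trimeric demonstration system |
| spins per chain | 60 | typical assigned-amide count per protomer |
| Δχ_ax, Δχ_rh | −43.0, −7.8 ×10⁻³² m³ | strongly shifting Tm-DOTA-scale tag |
| truth metal | tag Cβ + 6 Å along Cα→Cβ | tag-arm geometry |
| PCS noise σ | 0.02 ppm | read-off precision of well-resolved amide peaks |
| PRE censoring | < 13 Å to any metal | peaks near the tag broaden beyond detection |
| jitter σ | 0 (option) | controlled symmetry breaking for asymmetry tests |

Diamagnetic shifts are drawn uniformly (¹H 7–10 ppm, ¹⁵N 105–130 ppm);
paramagnetic peaks add the per-dimension PCS and noise.  All randomness
comes from one explicit seeded generator per call (bitwise reproducible).

**What the generator does not emulate:** a real protein fold and its
packing, chemical-shift physics, differential line widths, backbone
dynamics (the main source of real fit deviations), or tag-linker
flexibility.  Passing tests therefore demonstrate the correctness of the
mathematics and the robustness of the estimation/assignment machinery
under realistic noise and censoring — not chemical-shift prediction
accuracy on real spectra.

## Problem sizes and numerical choices

The standard study yields ~107 PCS values (¹H+¹⁵N after censoring) and
~53 observable paramagnetic peaks; a multi-start fit takes a few seconds,
a full assignment run ~15 s.  Replicate-based checks use 10 seeds.
Degenerate inputs: empty datasets give f = 0 with a degeneracy warning;
fewer than 8 points refuse to fit; fewer than 3 Cα pairs refuse to
superpose; collinear point sets and collinear metals raise geometry
errors; gimbal orientations fall back to the γ = 0 convention.

## Known limitations

- No uncertainty estimates on fitted parameters (no bootstrap/jackknife).
- Single-lanthanide fits only; no joint multi-dataset fitting.
- Cyclic groups only (no dihedral or higher point groups), no screw axes.
- PDB input only (no mmCIF); insertion codes rejected; backbone amide
  protons only (no side-chain protons).
- PRE is modeled only as censoring in the generator, not quantitatively.
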