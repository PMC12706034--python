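# Methods

This note documents the models, conventions, and numerical choices behind
`g3k`, and what the synthetic validation does and does not demonstrate.

## Structures and topology

A glycan is represented as a rooted tree of monosaccharide residues: each
linkage records the donor (the residue contributing its anomeric carbon,
C1 for aldoses, C2 for sialic acids), the acceptor, and the acceptor
position x, so `Galb1-4GlcNAc` is the edge Gal→GlcNAc with x = 4. The
root is the reducing-end residue — the one whose anomeric carbon is free
or bonded to a protein side chain.

**Bond detection.** Glycosidic bonds are inferred geometrically: an
anomeric carbon within 1.8 Å of an exocyclic oxygen of another sugar (or
of a side-chain N/O of an amino acid) is treated as covalent. C–O bonds
are ~1.4 Å; the 1.8 Å cutoff (configurable) tolerates model strain
without bridging packing contacts. A cyclic bond graph is an error; a
bonded residue with an unrecognized code is kept unassigned with a
warning.

**Residue codes and anomers.** A curated table maps common PDB
carbohydrate codes to canonical names (NAG/NDG→GlcNAc, MAN/BMA→Man,
GAL/GLA→Gal, GLC/BGC→Glc, FUC/FUL→Fuc, XYS/XYP→Xyl, A2G/NGA→GalNAc,
SIA/SLB→Neu5Ac, NGC→Neu5Gc, AHR/BXX→Araf). Where the code pins the
anomer it wins; otherwise the sign of the improper dihedral C2–C1–O5–O1
decides (calibrated on ideal ⁴C₁ D-pyranose geometry: negative improper
= axial O1 = α for D-sugars). Alternative locations keep the
highest-occupancy copy (tie → 'A'); hydrogens are ignored throughout
(all analyses are heavy-atom).

**Canonical IUPAC emission.** At each acceptor the main chain continues
through the donor with the deepest subtree; ties go to the lower linkage
position, then the name; remaining donors are parenthesized branches in
ascending-position order. This makes emission a deterministic canonical
form: `emit(parse(s))` is idempotent, and the generator round-trips any
canonical sequence. Note the tie-break differs from some conventional
spellings (Lewis-type branches print as `Fuca1-3(Galb1-4)GlcNAc`); only
canonical-form equality is ever asserted.

**Glycan classes.** Conformer selection between anomeric groups uses the
physiological reducing-end rule: α for O-glycans and glycolipids, β for
N-glycans, with a warned fallback when the requested group is absent.
Class inference from topology is a deliberately small heuristic (root
GalNAc → O; root GlcNAc with ≥2 Man → N; root Glc/Gal → lipid); an
explicit class argument always wins.

## Torsions

φ = ringO–Canomeric–Ox–Cx where the donor ring oxygen is O5 (pyranose),
O4 (furanose) or O6 (sialic acids, whose ring is C2–C6 + O6);
ψ = Canomeric–Ox–Cx–Cy with Cy the ring carbon following Cx (wrapping to
the previous ring carbon when C(x+1) is exocyclic, e.g. Cy = C5 for x = 6);
ω = O6–C6–C5–O5 of the acceptor, reported exactly for x = 6 linkages.
Glycoprotein linkers report φ/ψ through the side-chain site
(N-linked: O5–C1–ND2–CG and C1–ND2–CG–CB; O-linked through OG/OG1).
Dihedrals use the atan2 formulation on bond-vector normals; angles live
in (−180°, 180°] (−180 mapped to +180) and are reported to two decimals.

## Ring puckering and conformation labels

Cremer–Pople parameters are computed about the geometric ring center
with the standard √(2/n) normalization:
q_m cos φ_m = √(2/n) Σ z_j cos(2πmj/n), q_m sin φ_m = −√(2/n) Σ z_j sin(2πmj/n),
q₃ = n^(−1/2) Σ (−1)^j z_j (6-rings), Q² = Σ q_m², θ = atan2(q₂, q₃) ∈ [0°, 180°].
The mean-plane normal is oriented so that a counterclockwise-ordered flat
ring has a +z normal; with ring atoms ordered from the anomeric carbon
(C1…C5,O5; C1…C4,O4; C2…C6,O6) this makes the analysis the exact inverse
of the generator's synthesis formula, so round trips are machine-exact.

Labels partition the (θ, φ₂) space totally. Six-rings: θ < 45° and
θ > 135° are chairs (⁴C₁/¹C₄ for D-sugars, inverted for L; ²C₅/⁵C₂ for
sialic acids); in the equatorial band, boats sit within ±15° of φ₂
multiples of 60° and skew-boats fill the gaps (windows are half the
anchor spacing so every cell is covered). Five-rings: envelopes within
±18° of multiples of 72°, twists in between. The anchor→label tables are
derived from the m = 2 cosine displacement pattern under our ring
indexing, with "6" denoting the ring oxygen:
boats {0°: ¹,⁴B, 60°: B₂,₅, 120°: ³,⁶B, 180°: B₁,₄, 240°: ²,⁵B, 300°: B₃,₆},
skews {30°: ¹S₅, 90°: ⁶S₂, 150°: ³S₁, 210°: ⁵S₁, 270°: ²S₆, 330°: ¹S₃};
envelopes are named by the single endo atom (C1/C3/O4/C2/C4-endo), twists
by the dominant up/down pair. L-monosaccharide inversion applies to the
chair labels; boat/skew names are reported as computed. A ring with
Q < 10⁻⁶ Å is "planar" (θ/φ₂ undefined).

Hydroxyl orientation is defined only for chair-like rings: an exocyclic
O/N whose C–X vector makes < 45° with the mean-plane normal is axial,
otherwise equatorial; non-chair rings return "undetermined".

## Surface accessibility

Shrake–Rupley with a 1.4 Å probe (water) at the atom level: for each
atom, the fraction of quasi-uniform points on its expanded sphere
(vdW + probe) outside all neighbor spheres, times the sphere area. The
point set is a fixed 960-point golden spiral, so results are
deterministic; the count is configurable and recorded in the profile.
vdW radii (Å): C 1.70, N 1.55, O 1.52, S 1.80, P 1.80. Residue SASA sums
constituent atoms; covalent modification groups (sulfate, acetyl,
phosphocholine, …) are attributed to their bonded parent sugar, and a
glycoprotein's linker amino acid is reported as its own entry. Ensemble
profiles are weighted means over conformers using cluster proportions.
Validation compares totals against an independent random-direction
Monte-Carlo surface sampler (agreement within 2% on random clusters) and
the closed-form isolated-sphere area.

## Flexibility

Three measures, all conformer-weight aware and non-negative:

* **B-factor RMSF** = √(3B/8π²) — exact closed form; only comparable
  within one crystal structure (combining across files warns).
* **Distance flexibility**: per-atom MAD = weighted mean over conformers
  of the per-axis absolute deviation from the weighted-mean structure,
  averaged over the three axes; RMSF = MAD·√(π/2). The per-axis
  convention is chosen because the half-normal identity E|X| = σ√(2/π)
  makes the conversion exact for Gaussian displacements per axis (a
  radial MAD would need a different constant); it is recorded in the
  profile. Requires pre-aligned conformers; the generator emulates the
  aligned-leading-residues convention via its anchor mechanism.
* **Torsion flexibility**: weighted circular standard deviation
  s = √(−2 ln R̄) of φ, ψ, ω separately, averaged over the angles a
  linkage has, then over the linkages a residue participates in.
  Rotation-invariant by construction. Fully dispersed angles (R̄ ≈ 0) are
  capped at the spread corresponding to R̄ = 0.2 (≈102.8°) and flagged,
  so single degenerate linkages cannot poison residue averages.

## Contacts and alignment

Distance maps are all-pairs matrices per conformer (residue level:
heavy-atom centroid distance by default; minimum atom distance as an
option — the notion of "contact" is left to the user as a threshold on
raw distances). Variability maps are the conformer-weighted standard
deviation (optionally MAD) of each pairwise distance; like distance
flexibility they presuppose pre-aligned conformers.

Superposition is SVD-Kabsch with reflection correction (the smallest
singular direction is sign-flipped whenever the raw determinant is
negative, so rotations are always proper). For unequal point sets, ICP
alternates k-d-tree nearest-neighbor correspondences with Kabsch steps,
accepting only non-increasing RMSD, until improvement < 10⁻⁴ Å or 50
iterations; initialization tries the centroid shift plus four
principal-axis alignments and starts from the best. The reported RMSD is
asymmetric (mobile points → nearest reference points), with a symmetric
average as an option; a fast mode runs a single correspondence + Kabsch
pass. Nelder–Mead refinement searches the 6 rigid-motion parameters and
never returns a worse result than its start. Best-conformer-pair search
is exhaustive with lexicographic tie-breaking; pairwise matrices compute
each unordered pair once.

## Motif statistics

Motifs are IUPAC-condensed subtrees with optional `?` wildcards for
anomer/position and an optional terminal constraint (motif leaves must be
unsubstituted). A motif ending in a dangling linkage (`Fuca1-6`)
describes a pendant subtree plus its attachment position; twin detection
deletes one such occurrence, canonicalizes, and matches the result
against the other sequences. The compared property excludes the motif
residues and the attachment-site residue (on both sides of the pair, via
the canonical-order correspondence between the deleted tree and the
partner). Paired comparisons use the paired two-tailed t-test with
Cohen's d_z = mean(diff)/sd(diff) (zero-variance differences are flagged
degenerate with a signed-infinite d_z rather than an exception); unpaired
comparisons use Mann–Whitney U; families of p-values use
Benjamini–Hochberg. Motif properties average monosaccharide values
within a motif occurrence and then across occurrences (a sum-within-motif
mode exists for total-exposure questions); when a wildcard motif matches
several linkage isoforms in one glycan, all matches are averaged.
Binding analysis regresses z-scored binding on the motif property
(ordinary least squares, Pearson r, two-sided p), requiring ≥3 glycans
and a non-constant predictor.

## Von Mises mixtures

Densities are Σ wᵢ exp(κᵢ cos(θ−μᵢ))/(2π I₀(κᵢ)) per radian with up to 5
components; the NLL is the weighted mean −log density with a 10⁻¹²
density floor against underflow (warned). The constrained
parameterization maps raw streams through softmax (weights), 180·tanh
(means; the bound is inclusive at float precision since tanh saturates),
and softplus clamped at κ = 10 (concentrations). Sampling draws a
component by weight, then a von Mises variate via numpy's generator
(Best–Fisher rejection sampling internally; exact uniform at κ = 0), and
is reproducible under a seed. Angles are degrees at the API surface and
radians internally. Mean/median baselines keyed by mono- or disaccharide
use circular statistics for angular targets (the circular median is the
observed angle minimizing summed circular distance) and fall back,
flagged, to the global statistic for unseen keys. Mixture fitting and
any neural parameter prediction are out of scope: this module supplies
the loss, constraints, and evaluation a trainer would plug into.

## Synthetic generator

The generator is the package's ground-truth instrument, not a physical
simulator. Geometry is idealized — C–C 1.53 Å, C–O 1.43 Å, C–N 1.45 Å,
tetrahedral substituents, rings as regular polygons plus exact
Cremer–Pople displacements — so every prescribed quantity is imposed
analytically: ring targets (Q, θ, φ₂) by CP synthesis, glycosidic
(φ, ψ, ω) by rotating donor subtrees about the glycosidic bonds, contact
distances by exact placement, binding tables as z = slope·property + ε.
Ensembles perturb torsions with von Mises noise (per-linkage κ) and add
Gaussian positional jitter, holding the first k residues fixed (default
k = 5 when the glycan has ≥5 residues, emulating conformers aligned along
their leading residues; ω of a linkage onto an anchored acceptor is also
held, since it rotates the acceptor's own arm). Identical spec + seed
gives byte-identical PDB output.

What this validates: the analysis conventions are exactly
self-consistent, invariant where they should be, and agree with
independent oracles (closed forms, Monte-Carlo sampling, brute-force
enumeration, permutation nulls). What it does not validate: behavior on
real crystallographic data — distorted rings, missing atoms, alternate
nomenclature, solvent, and force-field-relaxed geometry are absent, and
default torsions/puckering are idealized rather than ensemble-typical.

## Validation problem sizes

The test suite and `scripts/acceptance.py` use desk-scale problems chosen
to make each check sharp: 50 random build specs for torsion round trips,
100 random puckering targets, a full 1°-grid label sweep, 200-conformer
Gaussian ensembles for the MAD conversion (σ = 0.3 Å), 20 random
10-atom clusters against the Monte-Carlo SASA oracle, 100 random
mixtures for density normalization with 10⁵-draw goodness-of-fit, a
40-pair planted twin corpus (offset −0.5, noise 0.2 → population
d_z = −2.5), and 1000-rep permutation nulls for the binding regression.

## Known limitations

* The monosaccharide registry covers the common cores (Glc/Gal/Man ±
  NAc, Fuc, Xyl, Neu5Ac/Gc, Araf); rarer sugars parse as unassigned
  residues rather than failing.
* Puckering sign conventions (hence θ = 0 vs 180 and φ₂ phases) are
  internally consistent but, as with any CP implementation, depend on
  ring-atom ordering; comparisons across tools must align conventions.
* ICP is a local optimizer; the principal-axis multi-start makes
  self-alignments robust but pathological decoys can still converge to
  local minima (the Nelder–Mead refiner mitigates, never fixes,
  this).
* The sialic-acid φ convention takes O6 as the ring oxygen under sialic
  numbering; files using O7-as-ring-oxygen nomenclature would need
  renaming on input.
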