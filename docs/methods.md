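# Methods

## The torsion model

Each side-chain torsion correction is a cosine series in the Amber
convention,

    V(θ) = Σₘ kₘ [1 + cos(m·θ − θ₀)],

with the phase θ₀ fixed to 0° and distinct positive integer multiplicities
m. Force constants kₘ (kcal/mol) may be negative; the "1 +" offsets add a
constant per term that never affects forces, barrier heights or relative
populations. All angles are degrees in the API and on disk, wrapped
internally to (−180°, 180°]. The packaged ILDN parameter set modifies χ₁ of
Ile (M = 2 terms), Leu (M = 3), Asp and Asn (M = 6), and χ₂ of Asp and Asn
(M = 6); the Asp χ₂ correction, applied to both carboxylate oxygens, has
zero odd-multiplicity constants because the carboxylate makes χ₂ two-fold
symmetric.

Because θ₀ is pinned at 0°, dihedral quadruples that would be equivalent
under an ideal-geometry rotation (N–Cα–Cβ–Cγ vs C′–Cα–Cβ–Cγ) produce
genuinely different corrections. `select_dihedral_definition` fits every
candidate quadruple and keeps the one with the lowest weighted residual;
ties go to the first-listed candidate so results are deterministic.

## Scan grids

"Varied between −180° and 180° in s° increments" is implemented as 360/s
unique angles: −180° and +180° label the same conformation and are counted
once. Only this reading reproduces the canonical point counts, 24 × 3 = 72
for the 1D χ₁ scans (15° steps at χ₂ ∈ {−60°, 60°, 180°}) and 12 × 12 = 144
for the 2D 30° χ₁/χ₂ grids. For a two-fold symmetric χ₂ the 2D grid is
folded into χ₂ ∈ [0°, 180°), halving it to 72 points; the half-range choice
is arbitrary but fixed and invertible (every folded value has the pre-image
pair {χ₂, χ₂ ± 180°}). The backbone is held at the extended conformation
(φ = −135°, ψ = 135°) by default, recorded in the scan-table header.

## The fitting objective

The fit minimizes

    J = Σᵢ wᵢ (E_mm_base,i + Σ_angles V(θᵢ) + k₀ − E_qm,i)²

where `E_mm_base` is the force-field energy with the torsion under refit
already removed (a helper subtracts a supplied old series when callers hold
full MM energies), and k₀ absorbs the arbitrary energy-zero offset between
the QM and MM scales. Weights are normalized Boltzmann factors of the QM
energies, wᵢ ∝ exp(−β (E_qm,i − min E_qm)); the shift to minimum 0 cancels
in the normalization and prevents overflow, and the normalization itself
does not move the minimizer — it is done purely for conditioning. β
defaults to 1.0 mol kcal⁻¹, i.e. a weighting temperature of ≈503 K
(1/(Rβ) with R = 1.9872 × 10⁻³ kcal mol⁻¹ K⁻¹); β = 0 gives an ordinary
unweighted fit and β ≈ 1.7 mol kcal⁻¹ corresponds to room temperature
(298 K). k₀ is a free parameter by default and can be fixed at 0.

The model is linear in {kₘ, k₀}, so the solution is closed-form weighted
linear least squares. Rows of the design matrix (columns 1 + cos(m·θ) per
fitted angle, plus a ones column for k₀) are scaled by √wᵢ and solved by
SVD. Singular values below s₁·max(n, p)·ε are treated as zero; if the
numerical rank is below the parameter count the fit aborts with an error
naming the degenerate columns rather than returning a minimum-norm
solution, because a silently pinned parameter would masquerade as a fitted
force constant.

A consequence worth noting: on the *folded* half-grid of a symmetric χ₂
(six unique χ₂ values at 30° steps), the six χ₂ cosine columns together
with the offset column are linearly dependent — the folded grid simply
cannot determine odd and even χ₂ multiplicities separately. The end-to-end
recipe therefore fits only the even χ₂ multiplicities {2, 4, 6} on the
folded Asp grid, which is exactly the subspace the symmetry leaves
non-zero. On the full 144-point grid with symmetric data, fitting all six
multiplicities returns odd constants of 0 to machine precision, which the
tests assert.

## Helical backbone restraint

The restraint used to keep model helical peptides helical is the
single-term cosine well

    U(θ) = k_θ [1 + cos(θ − θ_ref)],

with θ_ref = 122° (φ), 133° (ψ) and k_θ = 1 kcal/mol. The minimum of this
form sits at θ_ref − 180°, i.e. −58°/−47° — squarely in the α-helical
basin — which is why reference values outside the helical region still hold
the peptide helical. The functional form is configurable; any single-minimum
periodic restraint with the same minima behaves equivalently for this
purpose.

## Rotamer statistics

χ₁ values are classified into the three canonical wells with half-open
±120°-wide bins centred on the well modes: p for χ₁ ∈ (0°, 120°], m for
(−120°, 0°], t otherwise. Half-open edges make boundary angles
deterministic. Distributions are compared by the RMSD over the three-state
population vector, √((1/3) Σ_s (a_s − b_s)²). Dihedrals from coordinates
use the standard atan2 formulation and follow the IUPAC sign convention
(cis = 0°), cross-checked against Biopython, MDAnalysis and mdtraj; χ₁
quadruples are N–Cα–Cβ–X with the residue-specific fourth atom (Cγ2 for
Ile, matching the packaged parameter table, Cγ1 for Val, Oγ1 for Thr, Oγ
for Ser, Sγ for Cys). PDB input uses the first model and Bio.PDB's default
altloc preference. Reference rotamer tables (e.g. helix survey statistics)
are user-supplied delimited text; the packaged table used by the recipe and
tests is synthetic (invented, plausible helix-like populations) and exists
only to exercise the machinery.

## NMR back-calculation

Scalar couplings use the Karplus relation J(θ) = A cos²(θ+δ) + B cos(θ+δ)
+ C. Coefficients are not part of the method; they live in an editable YAML
registry of named presets covering four coupling classes (Hα–Hβ, N–Cγ,
C′–Cγ, C′–Hβ), and every computation records the preset used. The phase
offset δ maps a reported heavy-atom χ₁ onto the coupling's own dihedral
(e.g. −120° for an Hβ proton) so couplings can be computed from χ₁ series
without explicit hydrogens. Ensemble averages are always taken over the
coupling evaluated per frame, never over the angle.

RDCs use a symmetric traceless alignment (Saupe) tensor S, stored as its
five independent components (Sxx, Syy, Sxy, Sxz, Syz). For a unit bond
vector u, D = Dmax·uᵀSu is linear in those components, so the tensor is fit
to ≥5 measured couplings by SVD least squares and aborts on rank-deficient
bond geometry. Dmax scale factors depend on gyromagnetic ratios and bond
lengths; they sit in the same registry (conventional magnitudes), and all
predictions scale linearly in Dmax, so any other choice is a rescaling.
Predicted RDCs are per-frame tensor contractions averaged over the
ensemble; for primary amides where experiment resolves only the sum of the
two N–H couplings, the same sum is predicted. Agreement is reported as RMSD
between calculated and experimental values, groupable by residue type or
coupling class.

## frcmod export

Fitted series are emitted as Amber DIHE records. A negative force constant
maps to PK = |k| with PHASE = 180° via k(1 + cos mθ) = |k|(1 + cos(mθ −
180°)) + 2k; the additive constant 2k only shifts the energy zero, which
the file header notes. Zero-k terms are dropped (logged), multi-term
torsions use negative PN continuation lines on all but the last record, and
IDIVF is 1. PK is written with 10 decimals so a parse → evaluate round trip
reproduces the energy function to better than 1e−9 kcal/mol (up to the
additive constant) on a dense grid; the emitter is column-stable, so
re-emitting a parsed file is byte-identical. On input, phases other than
0°/180° are retained as an explicit series phase.

## Synthetic data

The scan generator produces E_qm = background(χ) + Σ V_generating(χ) +
offset + N(0, σ²) and E_mm_base = background(χ). The background is a
low-order cosine surface with an optional cos(χ₁ − χ₂) coupling term, so a
fit must genuinely separate the torsion signal from a structured,
non-constant baseline; an even-in-χ₂ variant emulates a carboxylate-like
symmetric residue. σ defaults to 0.2 kcal/mol, mimicking sub-kcal/mol
QM-vs-fit discrepancies; it is Gaussian, not Boltzmann-consistent, by
deliberate simplification. Trajectories are von Mises mixtures centred at
+60°/−60°/180°; RDC datasets pair uniformly random unit bond vectors with
tensor-derived couplings plus Gaussian noise. All generators are
bit-reproducible under a fixed integer seed.

What the generators do **not** emulate: real QM scans have geometry
relaxation coupling all internal coordinates (the background here depends
only on χ₁/χ₂); real χ₁ time series are autocorrelated with rare rotameric
transitions (samples here are i.i.d.); real bond-vector ensembles librate
around structured orientations rather than being uniformly random. Passing
tests therefore demonstrate correctness of the estimators and
transformations under known truth, not force-field accuracy against
experiment — the latter requires long explicit-solvent MD and measured NMR
tables, which are outside this package's scope.

## The end-to-end recipe

`run_ildn_recipe` chains identify → refit → validate at desk scale:
10 residue types × 20,000-frame synthetic trajectories (von Mises κ = 8)
ranked by rotamer-distribution RMSD against the synthetic reference table;
refits of all four target residues on their canonical grids (72/72/72/144
points, σ = 0.2 kcal/mol, β = 1.0); and validation via ensemble ³J averages
against delta-mixture ground truth plus a noise-free alignment-tensor round
trip. These problem sizes keep the whole recipe under a second while
leaving sampling noise visible in the reported recovery errors. The summary
carries tool version, a SHA-256 config hash and the seed; identical
configurations and seeds yield byte-identical summaries. Stage failures
abort with a stage-labeled error and the summary status stays INCOMPLETE
until all stages finish.

## Known limitations

* The toolkit consumes precomputed QM and base-MM energies; it performs no
  QM, no MD and no topology editing, and nonbonded errors cannot be
  compensated by a torsion-only refit.
* Stereospecific assignment ambiguity (Hβ2/Hβ3) is resolved upstream by the
  caller; the registry's δ offsets assume a chosen assignment.
* frcmod export covers the DIHE section only.
* The packaged reference rotamer table is synthetic; quantitative
  comparisons against real helix statistics require a user-supplied table.
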