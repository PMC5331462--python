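# Methods

This note documents the models and procedures `tyrgate` implements, the
parameters that matter, what the synthetic-data generators emulate (and
what they deliberately do not), and the numerical choices made where
the design was open.

## Structures, trajectories, selections

Coordinates are Å and times ps throughout. A `Trajectory` is an ordered
list of frames over one shared atom table with a nominal spacing
`dt_ps`; the package reads and writes multi-model PDB through
MDAnalysis, with a thin fixed-column validation pass so malformed
records are reported with their line number. The PDB format carries no
time metadata, so `dt_ps` is caller-supplied (default 2 ps, the usual
spacing of dihedral-extraction streams; clustering streams are
typically thinned to 10 ps). Residue numbers are taken verbatim from
the file — FimH crystallographic numbering (Phe1…Thr158) is preserved,
so Tyr48, Ile52 and Tyr137 mean the same thing in every module. When
alternate-location indicators appear, only the highest-occupancy
conformer is kept: alternate crystallographic conformers are a
refinement detail the trajectory statistics should not double-count.

Selections are declarative (chain, residue set/range, atom-name set,
heavy-atoms-only, backbone/side-chain) and resolve to ordered,
frame-independent index lists; an empty result is always an error at
the point of use, naming the predicate. `sidechain` removes N, CA, C, O
plus OXT and backbone hydrogens; `heavy` removes hydrogens — centres of
mass of "side-chain heavy atoms" compose the two flags. Masses come
from a built-in standard table keyed by element, with elements inferred
from atom names when the element column is absent.

## Geometry

Torsions follow the IUPAC convention — degrees in (−180, 180], positive
clockwise looking from the second toward the third atom — computed with
the standard atan2 construction and cross-checked in the test suite
against an independent implementation. φ(r) is C(r−1)–N–CA–C and ψ(r)
is N–CA–C–N(r+1); chain-terminal residues simply lack the outer torsion
and produce no series.

Superposition is Kabsch least squares via SVD with reflection
correction (determinant sign), delegated to
`scipy.spatial.transform.Rotation.align_vectors`, plus a batched SVD
path used by RMSD series, fluctuation profiles and the pairwise RMSD
matrix. Fewer than three points, or a collinear point set, is an error
rather than a silent degenerate fit.

`rotate_dihedral` turns a torsion by exactly δ by rigidly rotating an
explicit *moving* set about the j→k bond axis; the moving set must
contain the fourth atom and exclude the first two, and rigidity is an
invariant (internal distances of moving and fixed sets are preserved to
machine precision). `scan_grid` stacks such rotations into the
2·n+1-frame geometry grid of a rigid potential-energy-surface scan
(default ten steps of 2.0° in both directions); energies are explicitly
someone else's job — the frames are input geometry for any QM engine.
Which side of the bond moves is a caller decision, not a guess: for
the linear toy peptides the generator derives the moving set from the
builder's chain-ordered atom layout (everything stored after the third
torsion atom).

## Dihedral distributions and mode shifts

Angle histograms are periodic over (−180, 180] with probabilities =
counts/n. The default bin width is 5°: at the 10³–10⁵-sample sizes of
interest this resolves well positions without empty-bin noise. The
shift statistic between two states is the signed minimal circular
difference of the *modal bin centres* — several gate distributions are
multimodal, so the mode, not the circular mean, is what moves when a
ligand binds; a wrap across ±180° always takes the short arc and an
exact 180° tie reports +180. `compare_states` tabulates each bound
state against the ligand-free reference and flags torsions with
|shift| above a threshold (default 20°, recorded in the table
attributes). The threshold is an implementation choice: it cleanly
separates the ~35° ligand-induced displacement of a responding torsion
from the ≤ one-bin jitter of a non-responding one, and the mode-shift
quantization is at most one bin width.

## GROMOS (Daura) clustering

The pairwise frame RMSD matrix is computed over the clustering
selection; the greedy rule then iterates: the frame with the most
neighbours within the cutoff becomes a representative, it and its
neighbours form a cluster and leave the pool. Conventions made
explicit: a frame is its own neighbour (singletons form one-member
clusters, as in the original implementation); neighbour-count ties go
to the lowest frame index, making the partition deterministic; clusters
are reported by descending population in % of all frames. The default
selection is the side-chain heavy atoms of the two gate residues with
frames pre-aligned on the protein backbone (no per-pair refit), the
standard treatment after whole-protein superposition; per-pair fitting
is available (batched Kabsch when the fit and report selections
coincide, pairwise otherwise). The 1.5 Å cutoff is the conventional
choice for side-chain-scale conformers. Correctness is pinned by an
exhaustive brute-force re-implementation on hundreds of random small
instances and by exact recovery of generated conformer mixtures.

## Fluctuation profiles

r.m.s.f._i = sqrt((1/N) Σ_n |p_{n,i} − ⟨p_i⟩|²) after a stated
superposition: frames are aligned to the first frame over the alignment
selection, the average structure is the per-atom mean of aligned
coordinates, and fluctuations are measured about it. A single alignment
pass is used; iterating alignment to the evolving mean changes results
far below test tolerances at these fluctuation scales. Ligand profiles
are computed over heavy atoms after aligning the pyranose ring — the
mannose moiety stays anchored in the binding site, so ring alignment
isolates aglycon mobility — and Δr.m.s.f. = bound − free, negative
where binding restricts an atom. When replicate trajectories exist,
replicate r.m.s.f. profiles are averaged before subtraction (and kept
individually); for isotropic per-coordinate jitter of amplitude σ the
analytic expectation r.m.s.f. = σ√3 anchors the tests.

## Thermodynamics

State functions: ΔG = RT ln K_d (kJ mol⁻¹, K_d molar), TΔS = ΔH − ΔG,
rK_d = K_d/K_d(reference), c = M_t(0)/K_d flagged reliable in the
conventional 10–600 window. R = 8.314 J mol⁻¹ K⁻¹. The default
temperature is 298.15 K (25 °C): the source measurements were performed
at 25 °C, and 298.15 K reproduces the published ΔG cells that are
arithmetically derivable from the published K_d; the value is
overridable everywhere. Report tables round at 1 decimal place, half
away from zero, always computed on unrounded intermediates. Four of the
nine published ΔG cells are *not* reproducible from the published K_d
at 1 d.p. (the originals were evidently derived from unrounded K_d
estimates before rounding); tests and the acceptance report therefore
assert the five consistent ΔG cells, all nine TΔS cells (from the
published ΔH/ΔG pairs) and all six rK_d ratios. The rK_d/rIC₅₀
reference is an explicit caller choice, defaulting to each ligand's
wild-type measurement (the published table's convention).

ITC: the exact single-site (Wiseman) total-heat expression
Q(X_r) = n·M_t·ΔH·V₀/2 · [1 + X_r/n + 1/(n·c) − √((1 + X_r/n + 1/(n·c))² − 4X_r/n)]
is differenced per injection and normalised per mole of injectant; an
optional constant offset absorbs residual dilution heat (the dominant
dilution enthalpy is assumed subtracted upstream, as in practice).
Fitting is bounded least squares over (n, log₁₀K_d, ΔH); initial values
come from the first-plateau height (ΔH), the half-height crossing of
the molar ratio (n) and c = 100. Flat curves raise an error; a solution
with c outside a generous 1–5000 window warns that K_d is weakly
constrained.

IC₅₀: four-parameter logistic, bottom + (top−bottom)/(1+(x/IC₅₀)^h),
decreasing for h > 0; replicate wells are averaged before fitting, a
response that rises with concentration triggers a quality warning, and
a fit whose plateaus invert is rejected. rIC₅₀ = IC₅₀/IC₅₀(reference).

Unfolding (linear extrapolation method): observed signal =
(1−f_U)(a_N + b_N·D) + f_U(a_U + b_U·D) with
f_U = K/(1+K), K = exp(−ΔG_unf(D)/RT), ΔG_unf(D) = −ΔG_fold − m·D.
ΔG_fold is reported in the folding convention (negative for a stable
protein), m > 0 is the cooperativity slope, and D₁/₂ = |ΔG_fold|/m
holds exactly for every fit by construction. Initialisation is
data-driven: straight lines through the first/last sixth of the curve
seed the baselines, and a logit-linear regression of the empirical
unfolded fraction seeds (ΔG_fold, m). Sparse transition coverage warns
rather than fails.

## Synthetic data

The generators emulate, with known ground truth, exactly the inputs the
analyses need: (i) idealized peptides built from standard bond
lengths/angles by NeRF placement, all φ/ψ set to requested values,
side chains from per-residue internal-coordinate templates with the
l-chirality-fixing C–N–CA–CB = −120° placement — no hydrogens, no
energy minimisation, since every analysis here is geometric or
statistical; (ii) trajectories sampling per-torsion von Mises wells
(the canonical circular analogue of a harmonic well; κ plays the role
of well stiffness) or discrete conformer mixtures, plus per-atom
isotropic Gaussian jitter; (iii) schematic mannoside-like ligands (a
pyranose-like ring with a heptyl or biphenyl aglycon) with per-atom
fluctuation amplitudes — by default a quiet ring (0.05 Å), a tail
ramping 0.1→0.5 Å in water and halved when bound, emulating an aglycon
clamped by the gate; (iv) thermodynamic curves from the same model
functions the fitters use. The default ITC design titrates to molar
ratio 2 in 52 equal injections (the experiments used 38–66 injections
to complete saturation) with Gaussian noise scaled to the curve span;
the unfolding grid spans 0–6 M denaturant in 25 points; dose–response
tables use 11 log-spaced concentrations in duplicate.

Conformer mixtures assign labels by largest-remainder apportionment and
a seeded shuffle, so requested populations are met *exactly* when
weights × frames is integral — cluster-recovery checks are then exact
rather than statistical. Every generator is a pure function of
(spec, seed), bit-for-bit reproducible, and returns its ground truth
record alongside the data; analyses only meet the truth at the
comparison step.

What the generators do **not** emulate: force-field energetics,
solvent, correlated backbone motion, anharmonic wells, instrument
baseline drift. Passing tests therefore demonstrate the correctness of
the statistics and fits on data with known structure — not the physics
of real trajectories, whose distribution shapes and populations require
actual MD input through the same interfaces.

## Problem sizes and numerics

Test and acceptance runs use 10³ frames for clustering (three-conformer
mixture), 5·10³ frames for mode-shift detection, 10⁴ frames for
fluctuation analytics, 20 seeds for fit-recovery ensembles and 200
random instances for the clustering brute-force oracle — sizes at which
every statistical tolerance asserted is comfortably inside its sampling
noise. K_d from a 2%-noise isotherm is the one weakly-determined
quantity (relative-error spread ≈ 9% at c ≈ 333), so its recovery is
asserted as a 20-seed median; n and ΔH are asserted per seed. All fits
use bounded least squares with tight (1e−14) convergence tolerances;
zero-noise self-consistency recovers generator truth to ~1e−8 or
better. Degenerate inputs (coincident/collinear torsion points, < 3
superposition points, flat curves, empty selections) raise typed errors
rather than returning NaN.

## Known limitations

PDB-format precision bounds round trips at 5·10⁻⁴ Å; binary trajectory
formats (DCD/XTC) and mmCIF are unsupported. The toy-peptide builder
uses generic side-chain rotamers and approximate ring closure for
proline, adequate for selection/COM/clustering logic but not for
Ramachandran-accurate modelling of real proteins. The ITC model is a
single-site 1:1 isotherm without the cell-displacement volume
correction; multi-site or global multi-experiment regression is out of
scope. The mode-shift statistic inherits a ±one-bin quantization from
the histogram; callers needing finer shifts can reduce the bin width at
the cost of noisier modes.
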