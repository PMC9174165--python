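# Methods

This note documents the models and procedures `vardyn` implements, the
defaults it ships, the numerical choices behind them, and what the
synthetic-data generators do and do not emulate.

## Scope and data model

The package analyses single-solute protein trajectories: a fixed topology,
`T × N × 3` coordinates in Å, and a strictly increasing time axis in ns.
Coordinates are assumed pre-imaged (no periodic box, no solvent); residue
numbers are taken verbatim from the input so that region definitions in
crystal-structure numbering — CDR1 = 40–47, CDR2 = 67–78, CDR3 = 115–120 of
the TREM2 Ig domain, anchors His43/Leu72/Ser116 — apply without re-indexing.
When a file carries no time information, frames are spaced at dt = 0.1 ns,
the common 100 ps trajectory save interval. Replica trimming defaults to
keeping the final 60% of each run (the usual "last 300 of 500 ns" rule) as a
config constant rather than an automatic plateau detector: equilibration
points are judgement calls, and automating one would invent a criterion the
workflow does not need.

Concatenated replicas are re-indexed onto one strictly increasing axis with
one frame-interval gap between replicas (so 3 × 300 ns at 1 ns spacing ends
at 902 ns); the original (replica, time) of every frame is kept as metadata.

## Consensus variant voting

Per-tool binary calls are aggregated into per-SNP vote counts; missing calls
are excluded from the count (never imputed) and reported separately. The
high-risk filter keeps SNPs with at least 15 of 17 votes by default,
descending by count with lexicographic tie-breaks. Tool agreement is the phi
coefficient (Pearson on binary vectors) over jointly scored SNPs; a constant
call vector makes the coefficient undefined and is reported as missing, not
as zero, because "no variance" is not "no agreement". When raw scores are
available a plain Pearson matrix can be produced alongside; the package does
not assert which convention any given published heatmap used.

## Descriptors

**Superposition.** Weighted Kabsch fit via SVD with reflection correction;
near-collinear references are rejected (second singular value < 1e-8).
RMSD is measured against the first frame of a run (the conventional
"deviation from the initial structure" usage); RMSF and the covariance
analyses use the iteratively converged mean structure (re-fit and re-average
until the mean moves < 1e-8 Å RMS, ≤ 10 iterations) so fluctuation
statistics are well defined.

A practical caveat that shaped the API: least-squares fitting of frames that
*already share* a reference frame absorbs ~6/(3N) of the variance into the
rigid-body fit (fitting to noise). For a 10-atom ensemble this turns a
planted correlation of +1.0 into ≈ 0.80. All fluctuation routines therefore
take `superpose=False` for pre-aligned input; superposition stays the
default because real MD frames are never pre-aligned.

**Rg** is the (optionally mass-weighted) RMS distance from the centre of
mass. **SASA** uses Shrake–Rupley counting on a deterministic golden-ratio
spiral lattice (default 960 points, floor 32), probe 1.4 Å, with per-element
van der Waals radii C 1.70 / N 1.55 / O 1.52 / S 1.80 / H 1.20 Å — community
defaults, since published figures rarely state them. Results are Å²; nm²
is a trivial rescale left to the caller. **B-factors** use the isotropic
crystallographic relation B = (8π²/3)·RMSF². Series summaries carry a
Gaussian-KDE density (Silverman bandwidth, 512-point grid) normalised to 1
within 1e-3.

## Correlated motion and essential dynamics

The DCCM normalises the displacement covariance per residue pair:
C_ij = ⟨Δr_i·Δr_j⟩ / √(⟨Δr_i²⟩⟨Δr_j²⟩), averaged over frames, on Cα atoms
by default. Zero-variance atoms (variance ≤ 1e-12 Å², i.e. numerically
rigid) get NaN rows rather than a fabricated 0. PCA diagonalises the 3N×3N
covariance (denominator T−1) of the superposed coordinates with a full
symmetric solver — adequate for 3N up to ~1000 — and fixes each
eigenvector's sign by making its largest-magnitude component positive, so
porcupine orientations are reproducible across runs. The trace (sum of all
eigenvalues, Å²) is the total positional variance. A warning (not an error)
is emitted when T ≤ 3N, where the covariance is rank-deficient.

RMSIP over the first n modes is √((1/n)ΣΣ(aᵢ·bⱼ)²); n = 10 by default with
n = 3 also reported by the pipeline, since both conventions are common.
Cosine content uses the discrete form of Hess's diagnostic,
c_i = (2/T)(Σ_t cos(iπt/T)p(t))² / Σ_t p(t)², on the first three PCs of each
replica; values < 0.1 are flagged convergent, and the pipeline warns (rather
than aborts) above that, treating it as a diagnostic, not a gate.

## Secondary structure

The Kabsch–Sander electrostatic model is implemented directly:
E = 0.084·332·(1/r_ON + 1/r_CH − 1/r_OH − 1/r_CN) kcal/mol, hydrogen bond at
E < −0.5, energies capped at −9.9 for clashes (< 0.5 Å). Amide hydrogens are
reconstructed 1.0 Å from N opposite the C(i−1)/CA bisector when absent, so
heavy-atom-only trajectories are fully supported. Patterns follow the
standard rules: two consecutive 4-turns → H, two consecutive 3-turns → G,
parallel/antiparallel bridge patterns → E (isolated bridges folded into E),
turn residues → T, priority H > E > G > T > C; chains split at C–N > 2.5 Å
or missing backbone atoms; π-helix turns fold into "other". Occupancy
reports per-residue and per-region fractions (and percentages) of H, G, E
and other; fractions sum to 1 by construction.

## Loop geometry

Anchor distances are per-frame Cα–Cα Euclidean distances with density and
quartile summaries. Contacts: a residue pair is in contact in a frame when
its minimum heavy-atom distance is ≤ 4.5 Å — the common persistent-contact
convention; no published criterion was available, so the cutoff is a config
knob and outputs are labelled with it. Occupancies are exact rationals k/T,
and the persistence filter is strictly greater-than (a pair at exactly 10%
is dropped), matching the "exceeded 10%" phrasing it implements.

## Free-energy landscapes

G_i = −k_B·T·ln(N_i/N_max) over a 2-D histogram of (RMSD, Rg) by default —
any two per-frame series, e.g. PC1/PC2, can be substituted without a
separate code path. T = 300 K; output in kT or kcal/mol
(k_B·T = 0.5961 kcal/mol at 300 K). Bin ranges are data-driven with 1%
padding; a constant descriptor gets a nominal ±0.5 Å window so the single
occupied bin stays well defined. Empty bins are +inf sentinels, never a
finite cap, so minima are unambiguous. The representative conformer is the
frame in the most populated bin nearest the bin centre (normalised bin
units), earliest-time tie-break — "lowest-energy conformer" alone does not
pick a unique frame, so the rule is fixed for determinism.

## Synthetic generators: what they emulate, and what they don't

Each generator produces data whose analysis outcome is known in closed form:

- Gaussian ensembles (prescribed 3N×3N covariance) → planted correlations
  and principal modes; isotropic σ gives per-atom RMSF √3·σ.
- Drift ensembles (frame k = ref + k·drift + noise) → the slow relaxation of
  an unequilibrated run; a linear drift's PC1 projection has cosine content
  96/π⁴ ≈ 0.986, i.e. flagged unconverged.
- Two-state ensembles (Bernoulli switching, jitter) → two-basin landscapes
  with ΔG = ln(p/(1−p)) kT; the state labels are kept as metadata so basin
  statistics can be checked against the generating truth.
- Ideal-torsion peptides (H −57/−47, G −49/−26, E −119/113, irregular coil)
  built by natural-extension chain growth with standard bond geometry
  (N–CA 1.458, CA–C 1.525, C–N 1.329, C=O 1.231 Å). An all-E pattern adds an
  antiparallel partner chain placed by a deterministic grid search that
  maximises inter-chain Kabsch–Sander bonds — per-residue torsions alone do
  not fix the inter-strand registry, so the search is part of the ideal
  construction. Lone strands are deliberately never assigned E (bridges need
  partners).
- Call tables: seeded Bernoulli calls with per-SNP probabilities; the
  TREM2-like stand-in plants three known high-risk variants at 17/16/15
  votes among 228 SNPs and caps all others at ≤ 14.

All generators draw from a single `numpy.random.default_rng(seed)` stream
per call and are bit-reproducible.

What passing these tests shows — and what it doesn't: the analyses recover
planted statistical structure exactly or within stated sampling error, which
validates the *estimators*. The generators do not emulate force-field
physics, solvent, anharmonic couplings, or realistic secondary-structure
kinetics, so agreement here says nothing about whether a particular
simulation was long enough or its force field adequate; for real data the
cosine-content and RMSIP diagnostics exist precisely to assess that.

## Problem sizes and tolerances used in verification

Stage-level checks use the smallest sizes at which the relevant sampling
error is comfortably below the assertion tolerance: 10,000 frames for DCCM
block recovery (null pairs |C| < 0.05; two-pass oracle agreement 1e-10),
50,000 frames for planted-eigenvector recovery (|dot| > 0.99), 20,000 for
isotropic RMSF (√3σ within 2%), 10 seeds × 10,000 frames for the two-basin
ΔG (within 3 binomial SE), 50 frames with an exact 40% helix fraction for
occupancy, and 100 frames for exact contact counting. The end-to-end
pipeline test uses 2 variants × 2 replicas × 30 frames of a jittered
8-residue helix, chosen to exercise every stage rather than to be
statistically meaningful.

## Known limitations

- PDB I/O only (fixed-column, one MODEL per frame); no DCD/XTC/TRR.
- The selection grammar is minimal (name / backbone / resid, `and` only).
- SASA has no per-residue sidechain/backbone split beyond what selections
  express.
- DSSP ladder/sheet topology (sheet labels, bulges) is not reconstructed;
  bridges simply mark E.
- The full-matrix eigensolver makes PCA impractical beyond a few hundred
  selected atoms.
- Published trace values from the original 1.5 μs trajectories are treated
  as descriptive; they cannot be recomputed without the (undeposited) data.
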