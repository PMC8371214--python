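# Methods

## The model

The conformer unit is a coarse-grained bead model at one bead per
residue (Cα-like), coordinates in nm, partitioned into five rigid
regions: two Fabs, one Fc, the hinge, and (optionally) two N-glycan
chains on the Fc. Beads carry unit scattering length by default; at the
momentum transfers treated here (Q ≤ 1.5 nm⁻¹, Q = 4π sinθ/λ) all the
observables the pipeline consumes — R_G, P(r), I(Q), the convex hull —
are shape-dominated, so per-element form factors and a hydration shell
are deliberately not modeled (the neutron contrast barely sees the
hydration layer, and for X-rays the omission affects the absolute scale
far more than the shape, which the R-factor's η absorbs).

Fab and Fc regions are ellipsoidal bead clouds (defaults: Fab semi-axes
3.9 × 1.9 × 1.9 nm with 200 beads, Fc 2.8 × 2.2 × 2.2 nm with 230
beads, minimum bead spacing 0.30 nm). The hinge is an explicit chain of
70 beads, one per residue of the expanded pattern
`ELKTPLGDTTHTCPRCP(EPKSCDTPPPCPRCP)3APELLGGP` (continuous numbering
216–285; the 11 cysteines land at 228…276). An 8-bead anchor segment
(`SVFLFPPK`, residues 286–293, tagged FC) continues the hinge chain and
rigidly carries the Fc — the anchor is the superposition handle that
ties Fc placement to the hinge C-terminus. Continuous numbering is
canonical; an offset of −47 maps the hinge/Fc span to EU numbering
(Asn344 continuous = Asn297 EU). Bead masses reproduce the composition
masses: ≈158.1 kDa glycosylated and ≈153.7 kDa after glycan removal,
with each 11-residue biantennary glycan (Gal₂Man₃GlcNAc₄ + 2 NeuNAc)
carried as a linear chain stand-in of 2.2 kDa.

Default geometry (chosen once to emulate an extended long-hinge
antibody): Fab centres 9.0 nm apart, 3.2 nm above the hinge N-terminus,
long axes tilted 70° outwards; hinge end-to-end ≈ 9.6–10.8 nm; Fc hung
below the anchor. These defaults give a maximum dimension of 25–28 nm, a
triple-peaked P(r) whose middle peak tracks the Fab–Fab centre distance,
and a coordinate R_G near 10 nm. Note the coordinate R_G of this
synthetic stand-in is larger than the Guinier R_G of a real IgG3
(6.95 nm): with three homogeneous bodies the mass sits farther from the
centre than in the real molecule. All recovery tests are therefore
against the generator's own truth, never against published values.

## Torsion-angle Monte Carlo

Moves are discrete: 24 states of 15°, φ about the virtual bond entering
the pivot bead, ψ about the bond leaving it. Pivot peptides sit at the
hinge termini — for glycosylated models residues 217–220 plus 285–286
(hinge A) and 217–222 (hinge B); for deglycosylated models 217–219 plus
283–284 and 217–220. One hinge chain is explicit (hinge A): its
N-terminal pivots rotate FAB1 together with the hinge stub N-terminal of
the axis, and its C-terminal pivots rotate the Fc side (anchor, Fc,
glycans, hinge tail). The second heavy chain's hinge is implicit: its
pivots (`fab2`) swivel FAB2 alone about axes through the hinge junction
bead with the direction of the local virtual bond at the pivot, which
preserves every FAB2-to-junction distance exactly — a ball joint whose
axis set follows the hinge conformation. Rotations about axes through
beads keep those beads fixed, so chain bond lengths and intra-region
distance matrices are preserved to machine precision.

Acceptance is clash-only (no energy, no Metropolis): a conformer is kept
iff no inter-region or non-bonded intra-hinge bead pair approaches below
0.35 nm (a standard Cα excluded-volume scale; pairs within ±2 residues
on one chain are bonded and exempt, as are pairs inside one non-hinge
rigid region, whose packing is fixed at construction). Clash search uses
a k-d tree; a 50-bead brute-force O(N²) oracle checks it in the tests.
The chain updates only on acceptance, and each accepted conformer is
appended to the library; pivot and step are drawn uniformly; the seed
fully determines the library.

## Hinge starting structures

The all-atom molecular-dynamics step that produced representative hinge
conformations in experimental workflows is replaced by a constrained
sampler: correlated random walks at fixed 0.365 nm virtual bond length
(persistence tuned to give end-to-end lengths centred near 9 nm for 70
residues), self-avoiding at 0.36 nm, with the implicit partner strand's
11 Cys–Cys bridge distances held inside 0.4–0.75 nm. PCA of the
flattened conformer coordinates followed by k-means gives five clusters;
each cluster's centroid (the member minimizing summed in-cluster
distance in PC1–3) becomes a starting hinge.

Start selection for the recovery study enforces two same-molecule
constraints. First, every trial model reuses the ground truth's
rigid-body bead fills: the study's premise is that the trial library and
the measured molecule share the same domain structures, and independent
fills add a model-mismatch floor to the R-factor. Second, start hinges
are restricted to the extended end-to-end band of the truth ensemble
(9.6–10.8 nm): the pivots never alter the disulfide-locked hinge core,
so a start's hinge length is frozen into every conformer derived from
it, and a library built on shorter hinges systematically compensates by
splaying the Fabs — a bias this restriction removes.

## Scattering and real space

The Debye sum is exact; for throughput the pair distances may be
histogrammed first (bin 0.02 nm; the per-pair error is O((QΔr)²) and
stays below 0.3% at Q ≤ 1.5 nm⁻¹). The orientational-average route uses
a golden-ratio (Fibonacci) spherical lattice, 1000 directions by
default; the two routes agree to 0.5% on 150-bead models and converge as
directions increase — the standing cross-check on both implementations.

Guinier fits are unweighted least squares of ln I on Q² with the fixed
default window 0.10–0.22 nm⁻¹ and the achieved Q·R_G limits reported; a
positive slope is returned flagged rather than as a silent NaN. The two
cross-sectional windows are 0.22–0.28 and 0.50–1.10 nm⁻¹. Two numerical
facts uncovered by the closed-form oracles are worth recording: (i) for
a solid sphere the fitted Guinier R_G is biased high by the curvature of
ln I — about +1.1% fitting to Q·R_G ≤ 1.0 and +1.9% at ≤ 1.3 — so
sphere validations fit to Q·R_G ≤ 1.0; (ii) a finite rod (L = 30 nm)
reaches the infinite-cylinder ln(IQ) asymptote only beyond Q ≈ 0.8 nm⁻¹,
where the fitted R_XS matches R/√2 to ~2%.

P(r) from a model is the f-weighted pair-distance histogram; from a
curve it is a regularized indirect transform: P on a uniform r grid with
P(0) = P(Dmax) = 0, non-negativity via NNLS, and a second-difference
roughness penalty whose weight (0.05 after an L-curve scan on the
synthetic suite) is scale-normalized against the design matrix. The
forward model is I(Q) = 4π∫P(r)·sinc(Qr)dr; the fit residual is reported
as the RMS misfit normalized by the RMS intensity, and a residual above
0.1 raises a warning that Dmax is smaller than the data's support —
undersizing is flagged, never silently truncated. L is read where P
falls below 1% of its maximum for good; peaks are the up-to-three most
prominent maxima (SciPy peak finding plus a local parabola, which
removes the histogram-bin discretization of the peak position), labelled
M1 < M2 < M3.

## Fitting and screening

Experimental-style curves are preprocessed to uniform grids on
[0, 1.5] nm⁻¹ — 825 points for X-ray, 146 for neutron — by monotone
piecewise-cubic (PCHIP) interpolation, with the region below the first
measured Q filled by the Guinier model fitted in the low-Q window and
rescaled to join the data continuously. The R-factor's scale factor η is
found by golden-section search on the L1 objective (refined to 1e-6
relative), then snapped to the best nearby intensity ratio — the L1
optimum lies at such a kink, which makes perfect self-fits return
exactly R = 0 and resolves plateau ties toward smaller η. χ² is
deliberately not offered: interpolated curves carry no usable per-point
errors. The flat neutron background (2.0% of the experimental I(0)) is
added to the model curve before comparison; consistent backgrounds on
both sides leave rankings unchanged (tested). Screening shares one sinc
quadrature matrix across the library, so ranking ~9000 conformers
against an 825-point curve takes well under a minute.

## Ensembles and hydrodynamics

Best-fit sets are glycan-stripped (so glycosylated and deglycosylated
ensembles are comparable), superposed by Kabsch SVD on a chosen region,
and decomposed by PCA of the flattened coordinates; k-means on PC1–3
(k = 5 for X-ray-style sets, 3 for neutron-style, always explicit) gives
groups whose centroids are the members minimizing summed in-group
distance. Eigenvector signs follow the largest-magnitude loading.

The sedimentation predictor is a documented simplified hull method, not
a reimplementation of any published tool: convex hull of the bead
centres (glycan beads included) → equivalent-sphere radius → +0.28 nm
hydration increment → Stokes radius; a prolate-equivalent axial ratio
from the coordinate covariance gives a Perrin friction factor; then
s = M(1−v̄ρ)/(N_A·6πη·R_s·F). It is validated against analytic Stokes
cases (compact spheres to within a few percent; s ∝ 1/R at fixed mass)
and used only as a relative cross-check: extended three-body models
sediment at roughly half the rate of an equal-mass compact sphere, with
f/f₀ ≈ 2.3. The f/f₀ of a bead model smaller than the molecule's
anhydrous volume can fall below 1; the ratio is meaningful only when the
model carries realistic volume, as the antibody builds do. Standard
water at 20 °C is fixed at ρ = 0.99823 g/ml, η = 0.010019 P.

## Synthetic data

Noise is multiplicative Gaussian — reduced solution-scattering data are
background-subtracted averages, so counting statistics are already
Gaussianized — with σ(Q) = σ₀·(1 + (Q/Qmax)²)·I(Q), σ₀ = 1% for
X-ray-like and 4% for neutron-like curves, and the neutron channel adds
the flat 2%-of-I(0) background. A "concentration series" is emulated as
a noise-level series (σ₀ 0.8–1.5% for SAXS, 3–6% for SANS); no real
concentration dependence is simulated. What the generator does **not**
emulate: atomic detail and sequence-specific domain shapes, the hydration
shell, interparticle interference, radiation damage, aggregation,
O-linked hinge glycans, and real instrument smearing. Passing tests
therefore demonstrate the correctness and self-consistency of the
machinery on a known three-body truth, not agreement with any measured
antibody dataset.

## Recovery study and its limits

The end-to-end study (workflows.recovery_study) uses five starts × 2000
proposals (~9000 accepted conformers; the published analogue used
5 × 50 000 — the reduction keeps a desk-scale run at minutes on one
CPU), screens against one simulated noisy SAXS curve, and keeps the 100
lowest-R models. Across independent study seeds the R-factor minimum
falls at the true R_G, the top-100 mean R_G stays inside ±2% of truth,
and the ensemble M2 stays inside 10% of the truth-model M2. The Fab-tip
separation is different in kind: a Fab spinning about its own anchor
axis moves its tip by ~1 nm per 15° step while changing I(Q) by about
the noise floor, so the statistic is weakly identified by a single
curve and its ensemble mean shrinks toward the library average
(deviations of up to ~20% from truth were observed). The package
reports the tip-separation distribution (broad, unimodal) rather than
claiming point recovery; the corresponding acceptance test asserts the
strict 10% tolerance and is expected to fail, documenting the limit.
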