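# Methods

This note documents the models, conventions and numerical choices behind
each analysis stage, what the synthetic-data generators do and do not
emulate, and the known limitations.

## Units and coordinate model

All lengths are nanometres internally; PDB files (ångström) are converted
by a factor of 10 on read and write, so round trips preserve coordinates to
the format's printed precision (10⁻³ Å = 10⁻⁴ nm). Energies are kJ/mol
internally and kcal/mol (1 kcal = 4.184 kJ) in free-energy outputs.
Residue numbering is taken verbatim from the source file — author-style
numbering such as "residues 112–116" is never renumbered. Nanoparticle
atoms are identified by element Au by default; frames with non-increasing
timestamps are rejected because every time-series stage assumes strict
ordering. No periodic-boundary minimum-image correction is applied:
analysis frames are assumed whole/unwrapped, which is how per-frame
structures destined for contact and H-bond analysis are normally exported.

## Contact ratios (interface mapping)

A residue contacts the surface in a frame when its minimum atom–Au distance
is **strictly** below the 0.45 nm cutoff; the boundary case (exactly 0.45)
is deliberately excluded and covered by a test, since "within" is otherwise
ambiguous. All residue atoms, hydrogens included, are eligible. The
conditional ratio divides by the number of frames with at least one residue
in contact, which makes it invariant to prepending any amount of
pre-adsorption diffusion — the property that lets replicates with different
approach times be averaged. Replicates in which the protein never adsorbs
have no contact frames and are excluded from the cross-replicate mean
rather than averaged as zeros; a pooled-frames averaging mode is available
as an alternative and the mode used is recorded in the output. Distance
queries run through a KD-tree but are exact, and a test asserts whole-table
equality with the O(frames × residues × atoms × Au) brute force on
~1000-atom frames.

Motif ranking reports maximal runs of consecutive residue ids (never
spanning chains or numbering gaps) whose mean ratio clears a threshold;
runs shorter than `min_len` are listed separately as single-residue-scale
sites. A threshold above 1 is legal and yields an empty, valid report.

## Hydrogen bonds

Gates: d(D,A) < 0.30 nm and deviation angle < 20°, both strict. The
20° criterion is only satisfiable by near-linear bonds when read as a
deviation from linearity, so the default convention measures the angle
between D→H and D→A at the donor; the literal 180° − ∠(D-H-A) alternative
is a config switch (identical for ideal geometries, slightly different off
axis). Donors are N/O/S with a covalent hydrogen, acceptors are N/O/S;
with no bond table supplied, a hydrogen is assigned to the nearest N/O/S
within 0.12 nm (hydrogens on carbon are simply not donor hydrogens).
Occupancy tables report replicate values at two significant figures and
averages at the nearest integer, halves away from zero. With that rule a
replicate set (0, 0, 0, 58) averages to 15, not 14 — one published table
cell disagrees with its own replicate values at this precision, so that
cell is not reproduced and the discrepancy is noted here rather than
special-cased in code. Count-distribution error bars are the SD over
bootstrap resamples of the pooled per-frame counts (frames, not
replicates, are the resampling unit), 1000 resamples by default,
deterministic under a fixed seed.

## Conformational metrics

Superposition is Kabsch via SVD with reflection correction (det = +1),
geometric (unweighted) unless mass weighting is requested. RMSF and PCA
align to the mean structure using one iterative-fit pass (fit to the first
frame, average, re-fit to the average); the PCA covariance is over the
flattened aligned coordinates, heavy atoms by default. SASA is
Shrake–Rupley on a golden-spiral point lattice, 960 points and a 0.14 nm
probe by default, with a Bondi-style radius table (gold included) supplied
through configuration; per-residue values sum exactly to the total by
construction. The moving average is a centred window in *time* (±w/2),
length-preserving, with truncated windows at the edges. Phase statistics
pool samples across replicates and report the population SD (divide by n);
the default phase boundaries 0–750/750–2000 ns are user input, never
inferred — the package treats state boundaries as a modelling decision made
by the analyst. Contact counts exclude intra-residue pairs, which only
matters for overlapping selections.

## Pulling

Traces are aligned on pull distance (rate × time) rather than wall time so
replicates at one rate share a grid (default step 0.05 nm); per bin, each
trace contributes its within-bin mean and the profile reports the mean and
population SD across traces, with per-bin replicate coverage flagged.
Detachment is threshold-after-last-peak: the largest distance at which the
(optionally distance-smoothed) mean force still reaches `drop_fraction`
(default 0.1) of its global maximum; a profile that never drops below
threshold returns the last grid point flagged "unruptured". Negative
(compressive) force samples stay in profiles but are ignored by the
detachment logic. Work is the trapezoidal integral of force over pull
distance. Published detachment values for such systems are read off
visually ("∼6 nm"), so the rule, threshold and smoothing window here are
explicit outputs, not reproductions; a contact-loss estimator via the
contact module offers an independent read-out.

## WHAM

Standard self-consistent iteration in log space (logsumexp throughout), bin
probabilities from pooled histograms, window free energies gauge-fixed to
f₁ = 0, convergence when max |Δf| < 10⁻⁶ kJ/mol (default), at most 10⁵
iterations. Defaults: 200 uniform bins over the pooled sample range padded
by 1%, T = 310 K, k_B = 0.0083144621 kJ·mol⁻¹·K⁻¹. Empty bins are masked,
never zero-filled or interpolated. Window sets whose histogram supports
form disconnected clusters raise an error instead of silently stitching
across a gap. The residual history is attached to every profile; a residual
that grows after burn-in triggers a warning pointing at it.

Two bias conventions are supported because write-ups print u = k(r − r₀)²
while most MD engines implement u = ½k(r − r₀)²: the "full" convention is
the default and the choice is stamped into every output. Solving
half-convention data with doubled k must (and does, bit-for-bit) equal the
full-convention solution.

Binding energy: bound minimum = global-minimum bin; unbound plateau = the
largest-separation contiguous run of bins whose finite-difference slope
(computed over a half-plateau-width baseline after smoothing, so
bin-level sampling noise does not masquerade as curvature) stays below
0.5 kcal·mol⁻¹·nm⁻¹ for at least 0.4 nm. The far-most bins are typically
sampled only by the tail of the last window and are not required to belong
to the plateau. A fixed-separation read-out is available as an
alternative. ΔG = plateau mean − minimum; a rising profile with no
qualifying plateau raises an error suggesting longer coverage.

Bootstrap bands resample each window's samples with replacement (window
sizes preserved), re-solve, re-anchor, and take the per-bin SD;
block-convergence re-solves on nested time prefixes and reports the max
bin-wise change between successive profiles.

## Synthetic data: what it emulates, and what it does not

Each generator produces inputs with the statistical structure one stage
assumes, with ground truth computed by construction or enumeration — never
by calling the analysis modules — so fixture comparisons are genuine
oracles. All generators are deterministic under a fixed seed.

- **Interface fixtures**: a CA-bead chain against a spherical-cap gold
  shell; scheduled residues sit 0.35 nm from their surface atom, others at
  0.9 nm. True conditional ratios are enumerated from the schedule.
- **H-bond fixtures**: D/H/A triplets placed at 0.28 nm/5° in exactly
  ⌊occupancy·n/100⌋ frames, at 0.45 nm otherwise; pairs are 5 nm apart so
  they cannot interfere.
- **Two-state fixtures**: two bead arms converging linearly after a
  transition frame, with inter-arm H-bond triplets whose geometry closes
  exactly at the compact separation.
- **Umbrella fixtures**: overdamped Langevin dynamics,
  ξ' = ξ − βD∇(V+u)dt + √(2Ddt)·η, on analytic PMFs (harmonic well,
  well-plus-plateau built from a cosine ramp with a harmonic near wall, or
  quartic double well). Defaults: D = 10⁻³ nm²/ps, dt = 0.05 ps, 310 K,
  first 10% discarded, stride 10 (≥1000 effectively independent samples
  per window at the default relaxation time of a few ps). The drift-step
  bound βD·dt·max|∇(V+u)| < 0.1 is checked on a domain grid before
  integration. The reaction coordinate is one-dimensional because the
  physical coordinate (core-COM to nearest surface atom distance) is
  scalar, so WHAM correctness is fully exercisable in 1-D.
- **Pulling fixtures**: the measured force is the series-spring response
  k·κ/(k+κ)·(d − e) of the pulling spring against a bond of stiffness κ
  engaged at e, peaking at the prescribed rupture distance, then decaying
  exponentially (0.1 nm width), plus Gaussian noise; peak forces and
  rupture points are exported analytically.

What passing these tests shows: the estimators are correct on inputs that
satisfy their assumptions exactly. What it does not show: robustness to
force-field artefacts, solvent effects, periodic-image contacts,
ill-converged sampling, or correlated noise in real MD output — none of
which the bead models contain. The study-scale conditions (20 windows ×
~5000 samples for the free-energy recovery; 100-fixture exactness sweeps)
were chosen as the smallest sizes at which the statistical recovery
criteria are meaningful.

## Workflow layer

Three report bundles (conformation, interface, free-energy) orchestrate the
stages behind YAML configs; every effective parameter — including
untouched defaults — is echoed into a run manifest together with the
package version, input/output SHA-256 checksums, seeds and warnings, so a
deterministic report can be regenerated byte-identically and a stochastic
one seed-identically. Failure policy is fail-fast with the stage name
prefixed to the error. The CLI is a thin click wrapper over the same
functions (exit codes: 2 config, 3 data, 4 convergence).

## Known limitations

- PDB/XYZ/XVG only; binary trajectory formats (XTC/DCD/TRR) and topology
  formats (PSF/TOP) are out of scope.
- Covalent-hydrogen assignment is geometric (0.12 nm), not bond-table
  driven; exotic protonation states may need an explicit bond table.
- WHAM uses direct iteration; pathological window ladders (very poor
  overlap) converge slowly and, physically, should be re-sampled rather
  than forced.
- The binding-energy plateau rule needs ≥0.4 nm of genuinely flat coverage;
  reaction coordinates truncated right after the barrier will (correctly)
  refuse to report a ΔG.
- Published binding free energies from atomistic simulations of the real
  protein–nanoparticle system are far larger than any bead-model fixture
  here; this package reproduces the *method*, and its tests validate
  estimator correctness, not the published magnitudes.
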