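# nptraj

Trajectory analysis and free-energy toolkit for protein–nanoparticle
binding studies, built around the workflow used to localise a
nanoparticle-binding motif on a flexible protein: per-residue contact
statistics against a gold surface, geometric hydrogen-bond occupancy,
conformational-state metrics, steered-pulling force analysis, and
umbrella-sampling PMF reconstruction by WHAM.

## Who it is for

Researchers analysing molecular-dynamics trajectories of a protein
adsorbing to a nanoparticle surface (here: a VEGF-like homodimer against a
fixed gold shell) who need reproducible, scriptable answers to: *which
residues form the binding interface, how strong is the binding, and how do
conformational states modulate it* — without re-running the MD engine.
Everything operates on plain-text inputs (multi-model PDB, XYZ,
XVG-style series) and is exercised end-to-end by a synthetic-data module,
so the full pipeline is testable on a laptop.

## The statistics at the core

**Conditional contact ratio.** A residue is in contact in a frame when any
of its atoms lies within 4.5 Å of any Au atom. To make replicates with
different adsorption times comparable, the per-residue ratio conditions on
the protein touching the surface at all:

    ratio_i = |frames where residue i contacts| / |frames with ≥1 contact|

Ratios are averaged across replicates (replicates that never adsorb are
excluded, not zero-filled), and contiguous high-ratio runs are ranked as
candidate binding motifs.

**Geometric H-bond occupancy.** A donor–hydrogen–acceptor triplet counts as
bonded when d(D,A) < 3.0 Å and the deviation-from-linearity angle is below
20°. Pair occupancy is the percentage of frames with at least one bonded
triplet between two residues, averaged across replicates.

**WHAM.** Umbrella windows with harmonic biases u_i(ξ) = k_i (ξ − r_i)²
are combined through the self-consistent equations

    P(b) = Σ_i n_i(b) / Σ_j N_j exp(−β(u_j(b) − f_j))
    f_j  = −kT ln Σ_b P(b) exp(−β u_j(b))

to give G(ξ) = −kT ln P(ξ), anchored at zero; the binding free energy is
the plateau level minus the bound minimum. Overlap histograms,
block-convergence profiles and bootstrap bands diagnose the estimate. The
bias convention (with or without the ½) is configurable and stamped into
every output.

**Pulling analysis.** Constant-velocity pulling traces are aligned on pull
distance, binned into a mean ± SD force profile, and the detachment
distance is read as the last distance at which the smoothed force still
reaches a fraction (default 10%) of its global peak.

## Worked example

`examples/pmf_wham.py` samples 20 umbrella windows by overdamped Langevin
dynamics over an analytic PMF with a 5 kcal/mol bound well and reconstructs
it:

```
windows: 20, samples/window: 5400
WHAM converged in 1230 iterations (full bias convention, 310 K)
minimum adjacent-window histogram overlap: 0.34 (1 = identical sampling)
bound minimum at 0.52 nm; plateau 1.49-2.42 nm
binding free energy dG = 4.99 kcal/mol (programmed depth: 5.00 kcal/mol)
mean bootstrap band: 0.050 kcal/mol
```

The recovered 4.99 kcal/mol against a programmed 5.00 kcal/mol shows the
window ladder, the solver and the plateau read-out working together; the
overlap line confirms adjacent windows sample overlapping regions, which
WHAM requires.

Other example scripts, one per capability:

- `examples/contact_mapping.py` — motif discovery from contact ratios
  (recovers a programmed 5-residue block at positions 112–116),
- `examples/hbond_occupancy.py` — a four-replicate occupancy table,
- `examples/conformational_metrics.py` — extended/compact phase statistics,
- `examples/pulling_analysis.py` — force profile and detachment distance,
- `examples/assay_statistics.py` — binding rate, viability, percent
  inhibition.

A thin CLI (`nptraj conformation|interface|free-energy|synth`) wraps the
same library workflows behind YAML configs and writes TSV report bundles
with a run manifest (config snapshot, checksums, seeds).

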