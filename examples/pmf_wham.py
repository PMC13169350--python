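"""Umbrella sampling + WHAM: recover a programmed binding free energy.

Samples 20 harmonic windows along a 1-D reaction coordinate by overdamped
Langevin dynamics on an analytic PMF (a 5 kcal/mol bound well flattening to
a plateau, mimicking a protein-surface separation coordinate), reconstructs
the profile with WHAM, checks window overlap, and reads off the binding
free energy as plateau minus minimum.
"""

import numpy as np

from nptraj.synthetic import LangevinParams, PmfSpec, langevin_umbrella_samples
from nptraj.wham import (WhamConfig, bootstrap_pmf, extract_binding_energy,
                         overlap_histograms, wham_solve)

spec = PmfSpec(kind="well_plateau", depth_kcal=5.0, minimum_nm=0.5,
               plateau_onset_nm=1.5)
refs = np.linspace(0.3, 2.2, 20)
windows = langevin_umbrella_samples(
    spec, [(float(r), 400.0) for r in refs],
    LangevinParams(n_steps=60000, stride=10, seed=1))

cfg = WhamConfig(n_bins=100, tolerance_kj=1e-5)
pmf = wham_solve(windows, cfg)
pmf.bootstrap_sd = bootstrap_pmf(windows, cfg, n_boot=10, seed=1)

_, overlaps = overlap_histograms(windows, np.linspace(0.25, 2.35, 120))
est = extract_binding_energy(pmf)

print(f"windows: {len(windows)}, samples/window: {windows[0].samples.size}")
print(f"WHAM converged in {pmf.iterations} iterations "
      f"({pmf.bias_convention} bias convention, {pmf.temperature_k:.0f} K)")
print(f"minimum adjacent-window histogram overlap: "
      f"{overlaps['overlap'].min():.2f} (1 = identical sampling)")
print(f"bound minimum at {est.minimum_nm:.2f} nm; plateau "
      f"{est.plateau_interval_nm[0]:.2f}-{est.plateau_interval_nm[1]:.2f} nm")
print(f"binding free energy dG = {est.delta_g:.2f} {est.unit} "
      f"(programmed depth: {spec.depth_kcal:.2f} kcal/mol)")
print(f"mean bootstrap band: {np.nanmean(pmf.bootstrap_sd):.3f} kcal/mol")
print("\ndG is the free-energy cost of moving the system from its bound "
      "minimum to the flat unbound region of the reaction coordinate.")
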