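"""Estimate fibril vs oligomer stability from steered pulling work.

Simulates overdamped pulling of a particle out of two prescribed
free-energy landscapes (a deep "fibril" well and a shallower "oligomer"
well at a 3:1 depth ratio), reconstructs the PMFs with the Jarzynski
equality and compares the dissociation energies.
"""

import numpy as np

from oligofib.pmf import accumulate_work, dissociation_energy, jarzynski_pmf, stability_ratio
from oligofib.synthetic import LANDSCAPE_PRESETS, generate_pull_traces

energies = {}
for name in ("fibril_like", "oligomer_like"):
    spec = LANDSCAPE_PRESETS[name]
    traces = generate_pull_traces(spec, n=25, rate=0.002, dt=0.02, seed=3)
    r_grid = np.linspace(0.0, 1.98, 150)
    works = [accumulate_work(trace, r_grid) for trace in traces]
    profile = jarzynski_pmf(works, temperature=spec.temperature)
    energies[name] = dissociation_energy(profile)
    print(
        f"{name}: dGd = {energies[name]:.1f} kJ/mol "
        f"(prescribed depth {spec.depth:.0f}) from {profile.n_trajectories} trajectories"
    )

ratio = stability_ratio(energies["fibril_like"], energies["oligomer_like"])
print(
    f"\nstability ratio dGd / dGd' = {ratio:.2f}\n"
    "-> pulling one peptide out of the fibril costs ~3x more free energy than"
    " out of the micellar oligomer, marking the fibril as the far more stable state."
)
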