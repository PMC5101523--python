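"""Vibronic optical spectra with a localised discrete mode.

Couples one discrete vibrational mode (ω = 100 or 180 cm⁻¹, S = 0.3) to
a 7-site exciton system — either to the three "core" pigments that the
breather dynamics single out, or to all pigments equally — and computes
disorder-averaged linear absorption, linear dichroism and circular
dichroism spectra.  The localised placement red-shifts the lowest
exciton and redistributes intensity differently from the uniform
placement.
"""

from pathlib import Path

import numpy as np
import pandas as pd

import nnmfmo as nm
from nnmfmo.vibronic import first_moment

OUT = Path("results/spectra")
OUT.mkdir(parents=True, exist_ok=True)
SEED = 1

# --- single pigment: Franck-Condon ladder ------------------------------
mono = nm.make_vibronic_fixture("monomer", site_energy=12300.0,
                                mode_frequency=100.0, huang_rhys=0.3)
sticks = nm.stick_transitions(mono)
order = np.argsort(sticks.energies)
rel = sticks.intensities[order] / sticks.intensities.sum()
print("single pigment, S = 0.3: vibronic progression "
      f"{np.round(rel[:4], 4)} (Poisson e^-S Sⁿ/n!), "
      f"0-0 line at {sticks.energies[order][0]:.0f} cm⁻¹ "
      f"(polaron shift Sω = {12300 - sticks.energies[order][0]:.0f} cm⁻¹)")

# --- heptamer with mode on {3,4,7} vs all sites ------------------------
hept = nm.make_vibronic_fixture("heptamer", seed=5, huang_rhys=0.3)
grid = np.linspace(11300.0, 13300.0, 1200)
line = nm.LineshapeSpec(hwhm=30.0)
disorder = nm.DisorderSpec(n_realisations=1000, fwhm=100.0, seed=SEED)

for omega in (100.0, 180.0):
    from dataclasses import replace

    system = replace(hept, mode_frequency=omega)
    out = nm.compare_mode_placement(system, grid, coupled_subset=[2, 3, 6],
                                    lineshape=line, disorder=disorder)
    table = pd.DataFrame({"frequency_cm1": grid})
    for name, ss in out.items():
        table[f"la_{name}"] = ss.la
        table[f"ld_{name}"] = ss.ld
        table[f"cd_{name}"] = ss.cd
    table.iloc[::2].to_csv(OUT / f"heptamer_omega{omega:.0f}.csv", index=False,
                           float_format="%.5g")

    m_no = first_moment(grid, out["no_mode"].la)
    m_sub = first_moment(grid, out["subset"].la)
    low_no = np.min(nm.stick_transitions(
        replace(system, huang_rhys=0.0, n_levels=1)).energies)
    low_sub = np.min(nm.stick_transitions(system).energies)
    print(f"ω = {omega:.0f} cm⁻¹: lowest exciton red-shifts "
          f"{low_no - low_sub:.1f} cm⁻¹ with the mode on pigments 3/4/7; "
          f"LA first moment {m_no:.0f} → {m_sub:.0f} cm⁻¹ "
          f"({disorder.n_realisations} disorder realisations, "
          f"FWHM {disorder.fwhm:.0f} cm⁻¹)")

print(f"tables in {OUT}")
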