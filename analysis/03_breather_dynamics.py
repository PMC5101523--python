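"""Anharmonic dynamics: discrete breathers and energy localisation.

Excites the band-edge mode and integrates the quartic network dynamics:

* 64-node periodic chain at high vs low energy — the high-energy run
  develops a localised oscillation above the harmonic band (a discrete
  breather), the low-energy run stays delocalised in the band;
* the C3 toy trimer — an initially symmetric band-edge excitation
  spontaneously concentrates most of the energy on one monomer, and the
  local energy oscillates at twice the breather frequency plus a slow
  sub-10 cm⁻¹ envelope.
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

import nnmfmo as nm
from nnmfmo.breathers import breather_experiment

OUT = Path("results/breathers")
OUT.mkdir(parents=True, exist_ok=True)
SEED = 1


def save(tag, exp):
    # keep the physically relevant band; the full grid runs to 16700 cm⁻¹
    sel = exp.spectrum.frequencies_cm1 <= 250.0
    pd.DataFrame({
        "frequency_cm1": exp.spectrum.frequencies_cm1[sel],
        "power": exp.spectrum.power[sel],
    }).to_csv(OUT / f"{tag}_power_spectrum.csv", index=False, float_format="%.6g")
    r = exp.report
    payload = {
        "main_peak_cm1": r.main_peak_cm1, "band_edge_cm1": r.band_edge_cm1,
        "gap_cm1": r.gap_cm1, "is_breather": r.is_breather,
        "participation": r.participation,
        "dominant_group_fraction": r.dominant_group_fraction,
        "energy_peaks": exp.energy_peaks, "probe": list(exp.probe),
    }
    (OUT / f"{tag}_report.json").write_text(json.dumps(payload, indent=2,
                                                       default=float))
    return r


# --- chain: breather needs enough energy -------------------------------
spec = nm.FpuChainSpec(n_nodes=64, boundary="periodic", k2=10.0, k4=10.0)
chain = nm.make_fpu_chain(spec)
chain_modes = nm.normal_modes(chain)
for tag, e0 in (("chain_high", 60.0), ("chain_low", 0.5)):
    exc = nm.ExcitationSpec(mode_from_top=0, e0=e0, seed=SEED, perturbation=0.05)
    exp = breather_experiment(chain, chain_modes, exc, t_transient_fs=100_000,
                              t_window_fs=300_000, stride=100)
    r = save(tag, exp)
    print(f"{tag}: E0={e0} kcal/mol → peak {r.main_peak_cm1:.2f} cm⁻¹ "
          f"({r.gap_cm1:+.2f} vs band edge {r.band_edge_cm1:.2f}), "
          f"breather={r.is_breather}, participation {r.participation:.2f}")

# --- trimer: spontaneous symmetry breaking -----------------------------
trimer = nm.make_c3_trimer(nm.ToyTrimerSpec(seed=1))
net = nm.build_network(trimer, 10.0, 10.0, 10.0)
modes = nm.normal_modes(net)
k = nm.highest_nondegenerate_mode(modes)
gi = trimer.monomer_index()
exc = nm.ExcitationSpec(mode_from_top=modes.n_modes - 1 - k, e0=120.0,
                        seed=SEED, perturbation=0.02)
exp = breather_experiment(net, modes, exc, t_transient_fs=50_000,
                          t_window_fs=150_000, stride=20, group_index=gi)
r = save("trimer", exp)
g = exp.energies.group_totals(gi)
frac = g.mean(axis=0)[:3] / g.mean(axis=0).sum()
print(f"trimer: peak {r.main_peak_cm1:.2f} cm⁻¹ ({r.gap_cm1:+.2f} above band), "
      f"monomer energy fractions {np.round(100 * frac, 1)} % — "
      f"C3 symmetry broken, dominant monomer {100 * frac.max():.1f} %")
print(f"trimer energy trace: high peak {exp.energy_peaks['high_peak_cm1']:.1f} "
      f"cm⁻¹ ≈ 2 × displacement peak; slow envelope "
      f"{exp.energy_peaks['low_peak_cm1']:.1f} cm⁻¹")

dmap = nm.displacement_map(exp.trajectory)
pd.DataFrame({
    "node": np.arange(len(trimer)),
    "label": [n.source_label for n in trimer.nodes],
    "monomer": [n.monomer for n in trimer.nodes],
    "mean_disp_A": dmap,
}).to_csv(OUT / "trimer_displacement_map.csv", index=False)
top = int(np.argmax(dmap))
print(f"largest mean displacement on node {top} "
      f"({trimer.nodes[top].monomer}/{trimer.nodes[top].source_label}): "
      f"{dmap[top]:.2f} Å")
print(f"tables in {OUT}")
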