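"""Harmonic normal modes: band structure, localisation, degree profile.

Diagonalises the mass-weighted Hessian of the chain and the toy trimer,
verifies the chain band structure against the analytic dispersion,
and examines where the high-frequency modes live: equally split across
the three monomers (exact C3 symmetry) with a bias toward highly
connected nodes.
"""

from pathlib import Path

import numpy as np
import pandas as pd

import nnmfmo as nm

OUT = Path("results/modes")
OUT.mkdir(parents=True, exist_ok=True)

# --- chain dispersion ---------------------------------------------------
spec = nm.FpuChainSpec(n_nodes=64, boundary="periodic")
chain_modes = nm.normal_modes(nm.make_fpu_chain(spec))
analytic = nm.chain_dispersion_cm1(spec)
rel = np.abs(chain_modes.frequencies_cm1[1:] - analytic[1:]) / analytic[1:]
print(f"chain band edge {chain_modes.band_edge_cm1:.3f} cm⁻¹ "
      f"(analytic {nm.chain_band_edge_cm1(spec):.3f}); "
      f"max dispersion error {rel.max():.1e} relative")

# --- trimer modes -------------------------------------------------------
trimer = nm.make_c3_trimer(nm.ToyTrimerSpec(seed=1))
net = nm.build_network(trimer, 10.0, 10.0, 10.0)
modes = nm.normal_modes(net)
print(f"trimer: {modes.n_modes} modes, {modes.n_rigid} rigid-body, "
      f"band edge {modes.band_edge_cm1:.2f} cm⁻¹")
pd.DataFrame({"frequency_cm1": modes.frequencies_cm1}).to_csv(
    OUT / "trimer_frequencies.csv", index=False
)

k = nm.highest_nondegenerate_mode(modes)
shares = nm.mode_node_shares(modes, k)
gi = trimer.monomer_index()
per_monomer = nm.group_shares(shares, gi)
print(f"highest non-degenerate mode (#{modes.n_modes - 1 - k} from top, "
      f"{modes.frequencies_cm1[k]:.2f} cm⁻¹): per-monomer shares "
      f"{np.round(per_monomer[:3] * 100, 4)} % (core {per_monomer[3]*100:.2f} %)"
      f" — equal to {np.ptp(per_monomer[:3]):.1e}")
pd.DataFrame({
    "node": np.arange(len(trimer)),
    "label": [n.source_label for n in trimer.nodes],
    "monomer": [n.monomer for n in trimer.nodes],
    "share": shares,
}).to_csv(OUT / "trimer_top_mode_shares.csv", index=False)

# --- degree vs share ----------------------------------------------------
profile = nm.degree_share_profile(net, modes, top_k=20)
corr = np.corrcoef(profile["degree"], profile["mean_share"])[0, 1]
print(f"degree vs mean share over top 20 modes: Pearson r = {corr:.3f} "
      "(high-frequency modes concentrate on highly connected nodes)")
profile.to_csv(OUT / "trimer_degree_share_profile.csv", index=False)
print(f"tables in {OUT}")
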