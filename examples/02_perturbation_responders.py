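"""Stimulate single units in a critical lattice and classify responders.

Runs a reduced single-experiment protocol (100x100 lattice, 5 target cells,
60 trials each), bins spikes into 22-ms frames, classifies every
(target, cell) pair as positive/negative/non-responder with the one-tailed
z test, and fits the power law of responder spike count versus target spike
count."""

import numpy as np

import critperturb as cp
from critperturb import response
from critperturb.workflows import PAPER_TRUNCATION_UM

net = cp.build_lattice(side=100, max_radius_um=PAPER_TRUNCATION_UM, seed=0)
net = cp.set_branching(net, 1.02)  # near-critical
p_poiss = cp.calibrate_poisson_drive(net, target_rate=0.02, seed=1)
tcs = cp.choose_tc_indices(net, n_tc=5, seed=2)
p_stim = cp.calibrate_stim_drive(net, p_poiss, tcs, target_count=5.0, seed=3)
proto = cp.StimProtocol(tc_indices=tcs, iti_steps=500, trials_per_tc=60,
                        p_stim=p_stim)
rec = cp.run_protocol(net, proto, p_poiss=p_poiss, seed=4).to_recording()
print(f"recording: {rec.n_cells} cells x {rec.n_frames} frames, "
      f"{len(rec.trials)} trials")

counts = response.extract_trial_counts(rec)
response.remove_outlier_trials(counts)
table = response.classify_responders(counts, alpha=0.025)
frac = table["cls"].value_counts(normalize=True)
print("responder fractions:", {k: round(v, 3) for k, v in frac.items()})

fit = response.scaling_fit(counts, table, mode="population", phase="stim")
print(f"PosR response ~ (TC count)^h with h = {fit.exponent:.2f} "
      f"(95% CI {fit.ci95[0]:.2f}..{fit.ci95[1]:.2f})")
print("sublinear h means each added target spike yields a diminishing — "
      "but still large — increment of the population response; pooled "
      "multi-experiment runs tighten this estimate considerably.")
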