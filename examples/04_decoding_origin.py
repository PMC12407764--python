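"""Decode which target cell was stimulated from non-target activity.

Uses a synthetic recording where each of 5 pseudo-targets drives its own
small signature population.  A gradient-boosted classifier decodes the
stimulation origin from non-target spike counts; Shapley-ranked feature
elimination shows how performance collapses once the informative neurons
are removed, and the drop-probability curve shows those neurons are the
planted positive responders."""

import numpy as np

from critperturb import decoding, fixtures

rec, gt = fixtures.decoding_recording(seed=0)
ds = decoding.build_dataset(rec)
res = decoding.train_eval(ds, model="gbt", n_splits=10, seed=1,
                          n_estimators=60, max_depth=4)
print(f"decoding accuracy {res.accuracy_mean:.2f} +- {res.accuracy_se:.2f} "
      f"(chance {ds.chance:.2f}) over {ds.X.shape[1]} feature cells")

curve = decoding.shapley_drop(ds, repeats=2, seed=2, drop_per_iter=5,
                              n_estimators=60, max_depth=4)
acc = np.nanmean(curve.accuracy, axis=0)
print("accuracy after removing top-ranked cells (5 per step):",
      np.round(acc[:8], 2))

table = fixtures.ground_truth_table(rec, gt)
L = decoding.posr_drop_probability(curve, table)
print("P(removed cell is a positive responder), first ranks:",
      np.round(L['L'].to_numpy()[:6], 2))
print("accuracy collapses to chance once the planted responders are gone; "
      "early removals are responders of one target each.")
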