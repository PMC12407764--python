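"""Avalanche statistics of a near-critical population trace.

Generates a branching-process population trace (offspring mean 0.95),
selects the soft-threshold from the log-normal shape of the epoch-count
curve, applies temporal coarse-graining at several factors k, extracts
avalanches, and fits the mean-size-versus-duration curve with the double
power law (initial slope chi_sh, asymptotic slope chi_lg)."""

from critperturb import avalanches, fixtures

trace = fixtures.make_branching_trace(60000, offspring_mean=0.95,
                                      immigration=0.3, seed=0)
catalog = avalanches.build_catalog(trace, ks=(1, 2, 4, 8), theta="auto")
print(f"{len(catalog)} avalanches pooled over k and phases; thresholds "
      f"per k: {catalog.groupby('k')['theta'].first().round(2).to_dict()}")

curve = avalanches.mean_size_vs_duration(catalog)
fit = avalanches.fit_scaling_curve(curve)
print(f"mean size vs duration: initial slope chi_sh = {fit.chi_sh:.2f}, "
      f"asymptotic slope chi_lg = {fit.chi_lg:.2f}, "
      f"crossover at d = {fit.phi:.1f} bins")

summary = avalanches.parabolic_summary(catalog, d_max_frames=32)
print(f"{100*summary['event_frac']:.0f}% of avalanches (holding "
      f"{100*summary['spike_frac']:.0f}% of spikes) last under "
      f"{summary['d_max_s']:.2f} s")
print("chi_sh near 2 indicates parabolic avalanche growth at short "
      "durations.")
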