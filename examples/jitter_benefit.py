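"""Why the parallel 6-channel maps help: robustness to spectral-range jitter.

Raw band powers carry each trial's absolute power scale, which varies
between trials and subjects. Here every trial's raw powers are multiplied
by a random gain before mapping; the enhanced channels are nearly
invariant to such per-trial scaling (the min-max rescale sees only the
within-trial structure), so 6-channel PMSFE maps should hold up better
than 3-channel spectral maps. Three seeds keep this demo quick; the
acceptance script runs ten.
"""

from pmsfe import ClassifierSpec, SimulationConfig, run_jitter_benchmark

table = run_jitter_benchmark(
    SimulationConfig(n_subjects=6, trials_per_level_per_subject=10,
                     effect_size=0.5, seed=500),
    seeds=range(3),
    classifier=ClassifierSpec(epochs=150),
    jitter_sd=0.5,
)
print(table.to_string(index=False))
print("\nincreased_rate_pp is the PMSFE-minus-spectral accuracy gain in "
      "percentage points under per-trial scale jitter.")
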