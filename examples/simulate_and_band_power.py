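"""Generate a small synthetic EEG dataset and extract band powers.

Builds 2 subjects x 4 workload levels x 6 trials of 64-electrode EEG,
computes the per-electrode theta/alpha/beta band powers of every trial and
prints how mean frontal theta power grows with workload level - the
spectral signature the generator plants and the classifier later decodes.
"""

import numpy as np

from pmsfe import SimulationConfig, THETA, compute_band_power, generate_trials
from pmsfe.simulate import FRONTAL_ELECTRODES

cfg = SimulationConfig(n_subjects=2, trials_per_level_per_subject=6, seed=1)
ds = generate_trials(cfg)
print(f"generated {len(ds)} trials "
      f"({ds.manifest.subject_id.nunique()} subjects, "
      f"{ds.trials[0].n_electrodes} electrodes, "
      f"{ds.trials[0].duration_s:.1f} s at {ds.trials[0].fs:.0f} Hz)")

frontal = np.array([e - 1 for e in FRONTAL_ELECTRODES])
theta = np.array([compute_band_power(t, THETA)[frontal].mean() for t in ds.trials])
levels = ds.labels

print("\nmean frontal theta power by workload level (arbitrary units):")
for lv in (1, 2, 3, 4):
    print(f"  level {lv}: {theta[levels == lv].mean():8.2f}")
print("\nhigher workload -> more frontal oscillatory power; the effect is "
      "strongest in higher bands by design.")
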