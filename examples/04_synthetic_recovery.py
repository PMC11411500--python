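"""Recovery study on synthetic instances.

Generates seeded synthetic datasets on the quinoline template (hidden
true shifts, biased priors, incomplete correlation sets), runs the full
assignment engine, and scores the fraction of sites whose assignment
recovers the hidden truth.  Recovery should be near one while the prior
bias stays below the inter-peak spacing, and degrade as bias or the
missing-peak rate grow.
"""

import numpy as np

from xtalshift.pipeline import AssignOptions, assign_dataset
from xtalshift.synthetic import generate, recovery_score

print("prior sd scale   missing   mean recovery (10 seeds)")
for scale in (0.5, 1.5, 4.0):
    for missing in (0.0, 0.3):
        scores = []
        for seed in range(10):
            inst = generate(
                "quinoline", seed=seed,
                prior_sd_c=3.0 * scale, prior_sd_h=0.3 * scale,
                missing_rate=missing,
            )
            res = assign_dataset(
                inst.sites, inst.bdm, inst.peaklists, inst.correlations,
                inst.priors, AssignOptions(max_enum=12, seed=seed),
            )
            scores.append(recovery_score(inst, res))
        print(f"{scale:>13.1f} {missing:>9.1f} {np.mean(scores):>14.3f}")
print("\nrecovery of 1.0 means every site was assigned to its true peak")
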