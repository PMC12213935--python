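"""Generate a synthetic cohort and look at its statistical structure.

Builds participants, daily sleepiness self-reports (EMA), and a session
plan of recorded test attempts whose planted verbal reaction times follow
a lognormal link to sleepiness.
"""

import numpy as np

from sleepvoice import CohortConfig, generate_cohort

config = CohortConfig(seed=42)  # 16 participants, 4 weekly sessions
participants, ema, sessions = generate_cohort(config)

print(f"participants: {len(participants)}  ema records: {len(ema)}  "
      f"attempts: {len(sessions)}")
print(f"female share: {(participants['sex'] == 'female').mean():.1%}")

present = ema["sleepiness"].dropna()
shares = present.value_counts(normalize=True).sort_index()
print("sleepiness level shares:",
      {int(k): round(v, 3) for k, v in shares.items()})

lat = sessions["true_latency"].dropna()
print(f"planted VRT: median {lat.median():.2f} s, mean {lat.mean():.2f} s, "
      f"sd {lat.std():.2f} s")
# The generator encodes level probabilities 23.7/39.5/17.1/19.8% and a VRT
# marginal with median 1.68 s / mean 2.19 s.  One EMA record per test day
# means only 64 independent sleepiness draws here, so the observed shares
# are noisy; they converge to the targets as the cohort grows.
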