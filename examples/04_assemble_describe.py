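"""Assemble the analysis dataset and describe the cohort.

Joins onset results with EMA, session and participant tables, applies the
exclusion cascade (non-speech, invalid strategy, missing sleepiness - in
that order), and prints the flow ledger, cohort descriptives and the
sex-difference tests on VRT.
"""

from sleepvoice import (account_flow, assemble, fig1_preset, generate_cohort,
                        sex_difference_tests, summarize)
from sleepvoice.speechvalidation import render_flow_text
from sleepvoice.syncohort import attempt_flags, onsets_from_truth

# the preset reproduces the flow composition exactly: 2,230 attempts,
# 136 non-speech, 295 invalid-strategy, 286 missing sleepiness
participants, ema, sessions = generate_cohort(fig1_preset(seed=0))
ledger, _ = account_flow(attempt_flags(sessions, ema))
print(render_flow_text(ledger))

obs, log = assemble(onsets_from_truth(sessions), ema, sessions, participants)
print(f"\nanalysis rows: {len(obs)}  excluded rows: {len(log)}")

s = summarize(obs)
print(f"cohort: {s.n_participants} participants, "
      f"{s.sex_percent.get('female', 0)}% female")
print(f"VRT median {s.vrt['median']:.2f} s "
      f"(IQR {s.vrt['iqr'][0]:.2f}-{s.vrt['iqr'][1]:.2f}), "
      f"mean {s.vrt['mean']:.2f} +/- {s.vrt['sd']:.2f} s")
print("sex-difference p-values:",
      {k: round(v, 2) for k, v in sex_difference_tests(obs).items()})
# With no planted sex effect all three tests should be non-significant.
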