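"""Audit the speech/non-speech classifier against manual labels.

Draws a random subsample for manual validation, builds the confusion
matrix with speech as the positive class, derives PPV/NPV/accuracy, and
relabels discovered false negatives.  The worked example reproduces the
arithmetic of a validation pass with TP=35, FP=0, FN=14, TN=136.
"""

from sleepvoice import ConfusionMatrix, apply_corrections, confusion_metrics
from sleepvoice.speechvalidation import percent_nonspeech
from sleepvoice.util import percent

import pandas as pd

cm = ConfusionMatrix(tp=35, fp=0, fn=14, tn=136)
m = confusion_metrics(cm)
print(f"PPV {percent(m['ppv'], 0):.0f}%  NPV {percent(m['npv'], 0):.0f}%  "
      f"accuracy {percent(m['accuracy'])}%")
# PPV 100%: everything the threshold called speech really was speech.
# NPV 91%: 14 of 150 predicted non-speech actually contained speech.
# Accuracy recomputes to 171/185 = 92.4%.

table = pd.DataFrame({
    "source_id": [f"s{i}" for i in range(2080)]
    + [f"n{i}" for i in range(150)],
    "is_speech": [True] * 2080 + [False] * 150})
corrected, speech, nonspeech = apply_corrections(
    table, {f"n{i}" for i in range(14)})
print(f"after correcting the 14 false negatives: {speech} speech / "
      f"{nonspeech} non-speech ({percent_nonspeech(nonspeech, 2230)}% "
      f"non-speech)")
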