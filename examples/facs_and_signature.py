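"""Small closed-form assay quantities: the FACS competition fold change and
the AR-selective signature score."""

import pandas as pd

from plscreen import ar_signature_score, competition_fold_change

# A marked (GFP+) population rises from 20% to 50% of a mixed culture:
# the odds ratio (0.5/0.5) / (0.2/0.8) = 4 means the marked cells
# outgrew the unmarked ones four-fold.
fold = competition_fold_change(0.2, 0.5)
print(f"competition fold change (X=20% -> Y=50%): {fold:.1f}")

# Androgen-receptor signature: the per-sample sum of RPKM over a defined
# AR-responsive gene list; a drop signals loss of AR signaling output.
expression = pd.DataFrame(
    {"parental": [120.0, 45.0, 80.0, 300.0],
     "resistant": [15.0, 4.0, 11.0, 310.0]},
    index=["KLK3", "NKX3-1", "TMPRSS2", "HOUSEKEEPER"])
score = ar_signature_score(expression, ["KLK3", "NKX3-1", "TMPRSS2"])
print("AR signature score per sample:")
print(score.to_string(float_format="%.1f"))
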