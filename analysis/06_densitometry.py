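"""Western-blot densitometry of the gel phantoms against designed truth.

The pipeline's blot stage quantifies each band with the inversion-difference
formula and normalizes to beta-actin and the untreated lane; this script
joins those readouts to the generator's designed signals and reports the
recovery error of the normalized expression ratios.
"""

import json

import pandas as pd

from common import FIXTURES, RESULTS, ensure_run

run_dir = ensure_run()
blots = pd.read_csv(run_dir / "blots.csv")

rows = []
for blot_id, grp in blots.groupby("blot_id"):
    truth = json.loads((FIXTURES / f"gels/{blot_id}_truth.json").read_text())
    for _, q in grp.iterrows():
        t = truth[q.lane_id]
        expected = (t[q.protein] / t["beta_actin"]) / (
            truth["NT"][q.protein] / truth["NT"]["beta_actin"])
        rows.append(dict(blot_id=blot_id, lane=q.lane_id, protein=q.protein,
                         signal=q.signal, designed_signal=t[q.protein],
                         normalized_expression=q.normalized_expression,
                         expected_expression=expected,
                         rel_error=abs(q.normalized_expression - expected) / expected))

df = pd.DataFrame(rows)
df.to_csv(RESULTS / "densitometry_recovery.csv", index=False)
print(f"{len(df)} bands over {df.blot_id.nunique()} blots: "
      f"max |relative error| of normalized expression {df.rel_error.max():.3f}")
print(df.groupby("protein").rel_error.max().round(4).to_string())
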