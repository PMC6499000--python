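"""Build the synthetic three-model PDT/RT study with ground truth.

Generates bright-field/calcein/PI/NADH/FAD image sets for 3 spheroid models x
3 days x 7 treatment groups x 4 replicates, plus western-blot phantoms and
DNA-content event lists, all with truth sidecars.  The design table (the
designed area factor and necrotic fraction per spheroid) is copied into
results/ as the reference for every downstream recovery check.
"""

import shutil

import pandas as pd

from common import FIXTURES, RESULTS, ensure_fixtures

manifest = ensure_fixtures()
shutil.copy(FIXTURES / "design.csv", RESULTS / "design.csv")
design = pd.read_csv(FIXTURES / "design.csv")
print(f"fixture study at {FIXTURES}")
print(f"  {len(design)} spheroids: {design.model.nunique()} models x "
      f"{design.day.nunique()} days x {design.treatment.nunique()} groups x "
      f"{design.groupby(['model', 'day', 'treatment']).size().iloc[0]} replicates")
print(design.groupby('treatment')[['designed_area_factor',
                                   'designed_necrotic_fraction']].mean().round(3))
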