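"""Score cancellation sheets into CoC values and a neglect classification.

Builds two synthetic response sheets for one patient — a letter cancellation
sheet marked completely and a bells sheet where only the right half was
found — and scores them.
"""

import numpy as np

from disconnectomics import CancellationSheet, coc, record_from_sheets

x_letters = np.linspace(-90, 90, 60)     # 60 'A' targets across the sheet, mm
x_bells = np.linspace(-88, 88, 35)       # 35 bell icons

letter = CancellationSheet(
    "letter", x_letters, np.zeros(60), np.ones(60, dtype=bool)
)
bells = CancellationSheet(
    "bells", x_bells, np.zeros(35), x_bells > 0  # only right-sided bells marked
)

print(f"letter CoC: {coc(letter):+.3f}   (all targets found -> exactly 0)")
print(f"bells CoC:  {coc(bells):+.3f}   (right-sided search -> strongly positive)")

record = record_from_sheets("patient_001", [letter, bells])
print(f"compound CoC: {record.coc_compound:+.3f}  (mean of the two task scores)")
print(f"neglect: {record.neglect}  (bells CoC exceeds its 0.081 cut-off)")
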