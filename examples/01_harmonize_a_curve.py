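"""Harmonize one monotherapy dose-response curve.

Takes the five-dose MK-5108 / ES2 example, shows the raw padded baseline
encoding, then interpolates the curve onto the common 10-point log10-dose
grid with the three operators (linear, Lagrange, anchored log-logistic)
and prints the summary metrics (IC50 and relative inhibition).
"""

import numpy as np

from drcbridge import (
    DoseResponseCurve,
    HarmonizationConfig,
    compute_ri,
    encode_drc_baseline,
    encode_drc_imputation,
    estimate_ic50,
)
from drcbridge.harmonize import log10_grid

curve = DoseResponseCurve(
    drug_id="MK-5108",
    cell_line_id="ES2",
    study_id="DEMO",
    doses=(0.0, 0.075, 0.225, 0.675, 2.0),
    responses=(0.0, -0.48, -0.47, 4.32, 20.72),
)

np.set_printoptions(precision=3, suppress=True)
print("doses (uM):     ", curve.doses)
print("responses (%):  ", curve.responses)

print("\nbaseline encoding (doses + responses, right-padded with -1):")
print(encode_drc_baseline(curve))

config = HarmonizationConfig()
print("\ncommon log10-dose grid (zero dose -> pseudo-dose):")
print(log10_grid(curve, config))

print("\nimputation encoding (linear | lagrange | ll4, 10 points each):")
encoded = encode_drc_imputation(curve, config=config)
for method, chunk in zip(config.methods, encoded.reshape(3, 10)):
    print(f"  {method:8s} {chunk}")

print(f"\nIC50 = {estimate_ic50(curve):.3f} uM "
      f"(first crossing of half the maximal response)")
print(f"RI   = {compute_ri(curve):.4f} "
      f"(normalized area under the log10-dose curve)")
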