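"""Total and incremental AUC of an OGTT curve, by the trapezoid rule."""

import numpy as np

from metabologenome import OGTTCurve, incremental_auc, total_auc

curve = OGTTCurve(
    subject="S01",
    timepoint="T1",
    analyte="glucose",
    times=np.array([0.0, 30.0, 60.0, 90.0, 120.0]),
    values=np.array([100.0, 150.0, 130.0, 110.0, 100.0]),
)

print(f"glucose AUC  (0-120 min): {total_auc(curve, (0, 120)):8.0f} mg/dL*min")
print(f"glucose AUC  (0-90 min):  {total_auc(curve, (0, 90)):8.0f} mg/dL*min")
print(f"glucose iAUC (0-120 min): {incremental_auc(curve, (0, 120)):8.0f} mg/dL*min")
print(f"net iAUC     (0-120 min): {incremental_auc(curve, (0, 120), 'net'):8.0f} mg/dL*min")
# iAUC counts only the area above the fasting value (100 mg/dL here); the
# net convention subtracts baseline x 120 min and can go negative.
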