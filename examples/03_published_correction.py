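"""Apply the published measured-astigmatism -> recCP prediction models.

For toric IOL planning, measured corneal astigmatism must be corrected
toward the astigmatism the pseudophakic eye will actually show.  The
published bivariate regressions do this per modality; the constant
centroid correction is the simpler baseline that only shifts the mean.
"""

import numpy as np

from reccp import (
    Laterality,
    MeridionalPower,
    PseudophakicRecord,
    SpheroCylinder,
    apply_published_correction,
    published_models,
)

# the five published models: y = A x + b, x = measured (C0, C45)
for name, model in published_models().items():
    print(f"REG_{name}: A diag ({model.A[0,0]:.3f}, {model.A[1,1]:.3f}), "
          f"b = ({model.b[0]:+.3f}, {model.b[1]:+.3f}) dpt, logL {model.logL:.0f}")
print("diagonals < 1: large measured astigmatism is shrunk toward recCP\n")

# one eye with 2 dpt of with-the-rule keratometric astigmatism
eye = PseudophakicRecord(
    laterality=Laterality.OD,
    AL=24.0, ACD=3.3, LT=4.6, CD=12.0, IOLP=20.0,
    refraction=SpheroCylinder(0, 0, 0),
    modality_readings={"IOLMK": MeridionalPower(42.0, 5.0, 44.0)},
)
df = apply_published_correction([eye], "IOLMK")
row = df.iloc[0]
print("measured IOLMK: flat 42.0 @ 5 deg, steep 44.0 (2 dpt with-the-rule)")
print(f"predicted recCP astigmatism: C0 {row.pred_C0_dpt:+.4f}, C45 {row.pred_C45_dpt:+.4f}")
print(f"  -> cylinder {row.pred_cyl_D:+.3f} dpt x {row.pred_axis_deg:.1f} deg "
      f"(magnitude {np.hypot(row.pred_C0_dpt, row.pred_C45_dpt):.3f} dpt)")
print("the prediction is smaller than the measurement: part of the")
print("keratometric astigmatism never reaches the pseudophakic refraction")
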