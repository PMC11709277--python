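"""Back-calculate corneal power from pseudophakic refraction and biometry.

After cataract surgery the cornea's spherocylindrical power can be
reconstructed (recCP) by running a paraxial vergence chain from both ends:
from the retina through the IOL to the corneal plane, and from the
spectacle refraction through the vertex distance to the same plane.  The
difference of the two vergences, meridian by meridian, is the corneal
power — including any surgically induced astigmatism.
"""

from reccp import (
    PseudophakicRecord,
    SpheroCylinder,
    forward_refraction,
    haigis_elp,
    reconstruct_corneal_power,
    vector_to_sphero,
)

# the cohort-mean eye: AL 24.03 mm, ACD 3.32 mm, a 20.5 dpt IOL, and a
# post-operative refraction of -0.25 -0.75 x 10
eye = PseudophakicRecord(
    laterality="OD",
    AL=24.03, ACD=3.32, LT=4.58, CD=12.02,
    IOLP=20.5,
    refraction=SpheroCylinder(-0.25, -0.75, 10.0),
)

elp = haigis_elp(eye.ACD, eye.AL)
print(f"Haigis effective lens position: {elp:.4f} mm")

reccp = reconstruct_corneal_power(eye)
print(f"reconstructed corneal power: EQ {reccp.EQ:.3f} dpt, "
      f"C0 {reccp.C0:+.3f}, C45 {reccp.C45:+.3f}")
sc = vector_to_sphero(reccp, form="plus")
print(f"  in keratometric notation: {sc.sphere:.2f} / {sc.sphere + sc.cylinder:.2f} "
      f"dpt, flat meridian @ {sc.axis:.1f} deg")

# the forward model is the exact inverse: feeding recCP back returns the
# measured refraction to numerical precision
ref = forward_refraction(reccp, eye.AL, elp, eye.IOLP)
print(f"forward model round trip: {ref.sphere:+.4f} {ref.cylinder:+.4f} x {ref.axis:.1f}")
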