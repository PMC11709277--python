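"""Decompose clinical astigmatism notation into double-angle power vectors.

A refraction or keratometry reading in sphere/cylinder/axis (or flat/steep)
notation maps to the (EQ, C0, C45) power vector: the spherical equivalent
plus the astigmatism projected onto the 0/90 and 45/135 degree meridians.
Positive C0 is with-the-rule (steep corneal meridian near vertical).
"""

from reccp import (
    Laterality,
    MeridionalPower,
    SpheroCylinder,
    defocus_equivalent,
    meridional_to_vector,
    mirror_to_right_eye,
    sphero_to_vector,
    vector_to_sphero,
)

# a typical post-operative subjective refraction, minus-cylinder form
refraction = SpheroCylinder(sphere=-0.25, cylinder=-0.75, axis=10.0)
rv = sphero_to_vector(refraction)
print(f"refraction {refraction.sphere:+.2f} {refraction.cylinder:+.2f} x {refraction.axis:.0f}")
print(f"  -> EQ {rv.EQ:+.4f} dpt, C0 {rv.C0:+.4f}, C45 {rv.C45:+.4f}")
print(f"  defocus equivalent DEQ = {defocus_equivalent(rv):.4f} dpt (scalar blur)")

# with-the-rule keratometry: steep meridian at 100 deg -> C0 > 0
kerato = MeridionalPower(power_flat=42.0, axis_flat=10.0, power_steep=44.0)
kv = meridional_to_vector(kerato)
print(f"\nkeratometry flat {kerato.power_flat} @ {kerato.axis_flat} deg, steep {kerato.power_steep}")
print(f"  -> EQ {kv.EQ:.4f} dpt, C0 {kv.C0:+.4f} (with-the-rule), C45 {kv.C45:+.4f}")

# left eyes are mirrored (C45 sign flip) so one model serves both sides
left = mirror_to_right_eye(kv, Laterality.OS)
print(f"  as a right eye (OS mirrored): C45 {left.C45:+.4f}")

# the conversion is exactly invertible
back = vector_to_sphero(kv, form="plus")
print(f"\nback to plus-cyl notation: {back.sphere:.2f} {back.cylinder:+.2f} x {back.axis:.0f}")
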