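"""Astigmatism representations and conversions.

Three equivalent descriptions of a spherocylindrical power are used
throughout tIOL work:

* standard (clinical) notation — sphere, cylinder and cylinder axis;
* meridional notation — the power in the flat principal meridian, the axis
  of that meridian, and the power in the steep meridian (keratometry style);
* the double-angle power vector (EQ, C0, C45) — spherical equivalent plus
  the astigmatism projected onto the 0/90 deg and 45/135 deg meridians.

The power vector is the lingua franca of the analysis: centroids, error
ellipses and the prediction models all operate on (C0, C45).

Convention (full-cylinder projections)
--------------------------------------
``C0 = C * cos(2*axis)`` and ``C45 = C * sin(2*axis)`` where ``C`` is the
full cylinder power, NOT the half-magnitude Jackson-crossed-cylinder
J0/J45.  This is the convention under which the defocus equivalent
``DEQ = sqrt(EQ^2 + C0^2/4 + C45^2/4)`` reduces to the familiar
``sqrt(M^2 + (C/2)^2)``.  With-the-rule astigmatism (steep corneal meridian
near 90 deg) has C0 > 0.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass

__all__ = [
    "Laterality",
    "SpheroCylinder",
    "MeridionalPower",
    "PowerVector",
    "sphero_to_vector",
    "meridional_to_vector",
    "vector_to_sphero",
    "vector_to_meridional",
    "defocus_equivalent",
    "mirror_to_right_eye",
    "meridional_power",
    "normalize_axis",
]


def normalize_axis(axis_deg: float) -> float:
    """Normalize a meridian/axis angle to [0, 180) degrees."""
    a = float(axis_deg) % 180.0
    # -1e-9 % 180 == 180 - 1e-9; fold the boundary back to 0
    return 0.0 if a == 180.0 else a


def _require_finite(**kwargs: float) -> None:
    for name, value in kwargs.items():
        if not math.isfinite(value):
            raise ValueError(f"{name} must be finite, got {value!r}")


class Laterality(str, enum.Enum):
    """Eye side: OD (right) or OS (left)."""

    OD = "OD"
    OS = "OS"


@dataclass(frozen=True)
class SpheroCylinder:
    """Refraction or corneal power in standard sphere/cylinder/axis notation.

    The cylinder may be given in plus or minus form; both describe the same
    power profile.  ``axis`` is the standard ophthalmic cylinder axis in
    degrees, stored normalized to [0, 180).  The cylinder's power acts in
    the meridian perpendicular to its axis.
    """

    sphere: float
    cylinder: float
    axis: float

    def __post_init__(self) -> None:
        _require_finite(sphere=self.sphere, cylinder=self.cylinder, axis=self.axis)
        object.__setattr__(self, "axis", normalize_axis(self.axis))

    def transposed(self) -> "SpheroCylinder":
        """The same power in the opposite cylinder form (plus <-> minus)."""
        return SpheroCylinder(
            sphere=self.sphere + self.cylinder,
            cylinder=-self.cylinder,
            axis=self.axis + 90.0,
        )


@dataclass(frozen=True)
class MeridionalPower:
    """Keratometry-style notation: flat-meridian power/axis and steep power.

    The steep meridian is implicitly at ``axis_flat + 90`` (mod 180).
    """

    power_flat: float
    axis_flat: float
    power_steep: float

    def __post_init__(self) -> None:
        _require_finite(
            power_flat=self.power_flat,
            axis_flat=self.axis_flat,
            power_steep=self.power_steep,
        )
        if self.power_steep < self.power_flat:
            raise ValueError(
                f"power_steep ({self.power_steep}) must be >= power_flat "
                f"({self.power_flat})"
            )
        object.__setattr__(self, "axis_flat", normalize_axis(self.axis_flat))


@dataclass(frozen=True)
class PowerVector:
    """Double-angle power vector (EQ, C0, C45), all in dioptres."""

    EQ: float
    C0: float
    C45: float

    def __post_init__(self) -> None:
        _require_finite(EQ=self.EQ, C0=self.C0, C45=self.C45)

    @property
    def astigmatism(self) -> float:
        """Full cylinder magnitude ``sqrt(C0^2 + C45^2)`` (>= 0)."""
        return math.hypot(self.C0, self.C45)


def sphero_to_vector(sc: SpheroCylinder) -> PowerVector:
    """Decompose standard notation into power-vector components.

    EQ = sphere + cylinder/2; C0 = C cos(2 axis); C45 = C sin(2 axis).
    Plus- and minus-cylinder forms of the same power map to the same vector.
    """
    two_axis = math.radians(2.0 * sc.axis)
    return PowerVector(
        EQ=sc.sphere + sc.cylinder / 2.0,
        C0=sc.cylinder * math.cos(two_axis),
        C45=sc.cylinder * math.sin(two_axis),
    )


def meridional_to_vector(mp: MeridionalPower) -> PowerVector:
    """Decompose flat/steep keratometry into power-vector components.

    Equivalent to the plus-cylinder form (sphere = flat power,
    cylinder = steep - flat, axis = flat meridian), so with-the-rule
    corneas (steep meridian near 90 deg) get C0 > 0.
    """
    return sphero_to_vector(
        SpheroCylinder(
            sphere=mp.power_flat,
            cylinder=mp.power_steep - mp.power_flat,
            axis=mp.axis_flat,
        )
    )


def vector_to_sphero(pv: PowerVector, form: str = "minus") -> SpheroCylinder:
    """Convert a power vector back to standard notation.

    ``form='plus'`` puts the cylinder axis at the flat meridian
    (cylinder = +A); ``form='minus'`` at the steep meridian (cylinder = -A).
    A zero-astigmatism vector reports axis 0 by convention.
    """
    if form not in ("plus", "minus"):
        raise ValueError(f"form must be 'plus' or 'minus', got {form!r}")
    a = pv.astigmatism
    if a == 0.0:
        return SpheroCylinder(sphere=pv.EQ, cylinder=0.0, axis=0.0)
    plus_axis = normalize_axis(math.degrees(math.atan2(pv.C45, pv.C0)) / 2.0)
    if form == "plus":
        return SpheroCylinder(sphere=pv.EQ - a / 2.0, cylinder=a, axis=plus_axis)
    return SpheroCylinder(sphere=pv.EQ + a / 2.0, cylinder=-a, axis=plus_axis + 90.0)


def vector_to_meridional(pv: PowerVector) -> MeridionalPower:
    """Express a power vector as flat/steep meridional powers."""
    sc = vector_to_sphero(pv, form="plus")
    return MeridionalPower(
        power_flat=sc.sphere,
        axis_flat=sc.axis,
        power_steep=sc.sphere + sc.cylinder,
    )


def defocus_equivalent(pv: PowerVector) -> float:
    """Scalar blur metric DEQ = sqrt(EQ^2 + C0^2/4 + C45^2/4), in dioptres."""
    return math.sqrt(pv.EQ**2 + pv.C0**2 / 4.0 + pv.C45**2 / 4.0)


def mirror_to_right_eye(pv: PowerVector, lat: Laterality) -> PowerVector:
    """Flip the oblique component's sign for left eyes.

    Left and right eyes are mirror-symmetric about the vertical; treating
    all eyes as right eyes means negating C45 for OS.  The map is an
    involution: applying it twice restores the input.
    """
    if Laterality(lat) is Laterality.OS:
        return PowerVector(EQ=pv.EQ, C0=pv.C0, C45=-pv.C45)
    return pv


def meridional_power(pv: PowerVector, meridian_deg: float) -> float:
    """Power acting in a given meridian.

    ``P(theta) = EQ - (C0 cos 2theta + C45 sin 2theta)/2`` — the flat
    meridian (minimum power) lies at half the double angle of (C0, C45).
    """
    t = math.radians(2.0 * meridian_deg)
    return pv.EQ - 0.5 * (pv.C0 * math.cos(t) + pv.C45 * math.sin(t))
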