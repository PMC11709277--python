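"""Paraxial pseudophakic eye model and corneal-power reconstruction.

The eye is modelled with three refracting thin elements on a common axis:
the spectacle correction at a vertex distance in front of the cornea, a
thin-lens (spherocylindrical) cornea, and a thin-lens IOL at the effective
lens position (ELP) behind the cornea, with the retina at the axial length
AL.  Between any two of these planes only rotationally symmetric media lie,
so an astigmatic pencil can be propagated meridian by meridian along its
(preserved) principal axes.

Reconstruction runs the chain from both ends and meets at the cornea:

* image side — assume the retina is conjugate to the object, so the
  vergence leaving the IOL is ``n_V / (AL - ELP)``; subtract the IOL power
  and transfer backwards by ELP through aqueous to the corneal plane (V2_);
* object side — start from the lane vergence (-1/6 dpt for a 6 m lane),
  add the spectacle refraction per principal meridian, and transfer through
  the vertex distance in air to the corneal plane (V2).

The reconstructed corneal power recCP is V2_ - V2 per meridian.  All
vergence arithmetic is done with distances in metres; vergences are in
dioptres.  ``forward_refraction`` is the exact algebraic inverse and serves
as the generator/oracle counterpart of the reconstruction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

from .vectors import (
    Laterality,
    MeridionalPower,
    PowerVector,
    SpheroCylinder,
    meridional_power,
    mirror_to_right_eye,
    sphero_to_vector,
    vector_to_sphero,
)

__all__ = [
    "EyeConstants",
    "HaigisConstants",
    "PseudophakicRecord",
    "MeridionalVergence",
    "GeometryError",
    "FocusAtPlaneError",
    "haigis_elp",
    "retinal_vergence",
    "transfer_vergence",
    "transfer_vergence_scalar",
    "spectacle_vergence_at_cornea",
    "reconstruct_corneal_power",
    "forward_refraction",
]


class GeometryError(ValueError):
    """Raised when the eye geometry is non-physical (e.g. ELP >= AL)."""


class FocusAtPlaneError(ZeroDivisionError):
    """Raised when a vergence transfer would pass through its own focus."""


@dataclass(frozen=True)
class EyeConstants:
    """Optical constants of the simplified pseudophakic eye.

    ``lane_vergence`` is the vergence directly in front of the spectacle
    plane for a 6 m refraction lane (-1/6 dpt).
    """

    n_air: float = 1.0
    n_aqueous: float = 1.336
    n_vitreous: float = 1.336
    vertex_distance: float = 0.012  # m
    lane_vergence: float = -1.0 / 6.0  # dpt


@dataclass(frozen=True)
class HaigisConstants:
    """Haigis ELP regression constants (defaults: MX60P, IOLCon-optimised)."""

    a0: float = 0.1835
    a1: float = 0.3153
    a2: float = 0.1725


@dataclass(frozen=True)
class PseudophakicRecord:
    """One pseudophakic eye: biometry, implanted IOL power, refraction and
    per-modality corneal astigmatism readings (stored in the eye's own
    frame, i.e. not mirrored)."""

    laterality: Laterality
    AL: float  # axial length, mm
    ACD: float  # anterior chamber depth, mm
    LT: float  # lens thickness, mm (descriptive)
    CD: float  # corneal diameter, mm (descriptive)
    IOLP: float  # implanted IOL power, dpt
    refraction: SpheroCylinder
    modality_readings: Mapping[str, MeridionalPower] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 15.0 <= self.AL <= 40.0:
            raise ValueError(f"AL {self.AL} mm outside [15, 40]")
        if not 1.5 <= self.ACD <= 6.0:
            raise ValueError(f"ACD {self.ACD} mm outside [1.5, 6]")
        if not -5.0 <= self.IOLP <= 40.0:
            raise ValueError(f"IOLP {self.IOLP} dpt outside [-5, 40]")
        object.__setattr__(self, "laterality", Laterality(self.laterality))


@dataclass(frozen=True)
class MeridionalVergence:
    """A (possibly astigmatic) vergence along two orthogonal principal
    meridians; ``axis_m1`` is the meridian of ``v_m1`` in degrees."""

    v_m1: float
    v_m2: float
    axis_m1: float = 0.0

    @classmethod
    def spherical(cls, v: float) -> "MeridionalVergence":
        return cls(v_m1=v, v_m2=v, axis_m1=0.0)

    @property
    def is_spherical(self) -> bool:
        return self.v_m1 == self.v_m2


def haigis_elp(ACD: float, AL: float, hc: HaigisConstants = HaigisConstants()) -> float:
    """Effective lens position in mm: ELP = a0 + a1*ACD + a2*AL."""
    if not (math.isfinite(ACD) and math.isfinite(AL)) or ACD < 0 or AL <= 0:
        raise ValueError(f"ACD/AL must be finite and positive, got {ACD}, {AL}")
    return hc.a0 + hc.a1 * ACD + hc.a2 * AL


def retinal_vergence(AL: float, ELP: float, ec: EyeConstants = EyeConstants()) -> float:
    """Vergence at the IOL plane of a pencil focusing on the retina.

    ``n_V`` divided by the IOL-to-retina distance (AL - ELP, converted to
    metres).  Requires AL > ELP.
    """
    if AL <= ELP:
        raise GeometryError(f"AL ({AL} mm) must exceed ELP ({ELP} mm)")
    return ec.n_vitreous / ((AL - ELP) / 1000.0)


def transfer_vergence_scalar(v: float, distance: float, index: float) -> float:
    """Propagate a single-meridian vergence: v' = v / (1 - v*d/n).

    ``distance`` is in metres and signed: positive propagates with the
    light, negative transfers backwards (the exact inverse of the forward
    step).
    """
    denom = 1.0 - v * distance / index
    if denom == 0.0:
        raise FocusAtPlaneError(
            f"vergence {v} dpt focuses exactly at the target plane ({distance} m)"
        )
    return v / denom


def transfer_vergence(
    v: MeridionalVergence, distance: float, index: float
) -> MeridionalVergence:
    """Propagate both principal meridians through a homogeneous gap.

    Principal axes are preserved (the gap is rotationally symmetric).
    """
    return MeridionalVergence(
        v_m1=transfer_vergence_scalar(v.v_m1, distance, index),
        v_m2=transfer_vergence_scalar(v.v_m2, distance, index),
        axis_m1=v.axis_m1,
    )


def spectacle_vergence_at_cornea(
    ref: SpheroCylinder, ec: EyeConstants = EyeConstants()
) -> MeridionalVergence:
    """Vergence V2 just in front of the cornea implied by the refraction.

    Per principal meridian of the refraction: lane vergence plus the
    meridional refractive power, then a vertex-distance transfer in air.
    ``axis_m1`` is the flat principal meridian of the refraction vector.
    """
    rv = sphero_to_vector(ref)
    flat = vector_to_sphero(rv, form="plus").axis  # flat meridian angle
    p1 = meridional_power(rv, flat)
    p2 = meridional_power(rv, flat + 90.0)
    behind_spectacle = MeridionalVergence(
        v_m1=ec.lane_vergence + p1, v_m2=ec.lane_vergence + p2, axis_m1=flat
    )
    return transfer_vergence(behind_spectacle, ec.vertex_distance, ec.n_air)


def reconstruct_corneal_power(
    rec: PseudophakicRecord,
    hc: HaigisConstants = HaigisConstants(),
    ec: EyeConstants = EyeConstants(),
) -> PowerVector:
    """Back-calculate the corneal power vector recCP for one eye.

    Image-side chain: ELP (Haigis) -> retinal vergence V3_ -> subtract IOLP
    (V3) -> backward transfer by ELP through aqueous (V2_, spherical since
    the IOL is non-toric).  Object-side chain: spectacle refraction ->
    vergence V2 at the cornea.  recCP = V2_ - V2 per principal meridian of
    the refraction, re-composed into a power vector; for left eyes the C45
    component is mirrored so all eyes are expressed as right eyes.
    """
    elp_mm = haigis_elp(rec.ACD, rec.AL, hc)
    v3_ = retinal_vergence(rec.AL, elp_mm, ec)
    v3 = v3_ - rec.IOLP
    v2_ = transfer_vergence_scalar(v3, -elp_mm / 1000.0, ec.n_aqueous)
    v2 = spectacle_vergence_at_cornea(rec.refraction, ec)
    # corneal power per meridian, on the refraction's principal axes
    k1 = v2_ - v2.v_m1
    k2 = v2_ - v2.v_m2
    cornea = sphero_to_vector(
        SpheroCylinder(sphere=k1, cylinder=k2 - k1, axis=v2.axis_m1)
    )
    return mirror_to_right_eye(cornea, rec.laterality)


def forward_refraction(
    cornea: PowerVector,
    AL: float,
    ELP: float,
    IOLP: float,
    ec: EyeConstants = EyeConstants(),
) -> SpheroCylinder:
    """Spectacle refraction produced by a given corneal power (eye frame).

    Exact inverse of the reconstruction chain: per principal meridian of
    the cornea, subtract the corneal power from the image-side vergence at
    the corneal plane, invert the vertex transfer analytically, and remove
    the lane vergence.  Returns the refraction in minus-cylinder form.
    """
    if not 30.0 <= cornea.EQ <= 60.0:
        raise ValueError(f"corneal EQ {cornea.EQ} dpt outside physiologic [30, 60]")
    v3_ = retinal_vergence(AL, ELP, ec)
    v3 = v3_ - IOLP
    v2_ = transfer_vergence_scalar(v3, -ELP / 1000.0, ec.n_aqueous)
    flat = vector_to_sphero(cornea, form="plus").axis
    powers = []
    for meridian in (flat, flat + 90.0):
        k = meridional_power(cornea, meridian)
        v2 = v2_ - k
        v1_ = transfer_vergence_scalar(v2, -ec.vertex_distance, ec.n_air)
        powers.append(v1_ - ec.lane_vergence)
    p1, p2 = powers
    ref = sphero_to_vector(SpheroCylinder(sphere=p1, cylinder=p2 - p1, axis=flat))
    return vector_to_sphero(ref, form="minus")
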