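"""Visual-field <-> collicular-surface coordinate mapping.

The superior colliculus contains a retinotopically organised motor map with a
strong foveal over-representation.  The classical description (van Gisbergen,
van Opstal & Tax; Ottes et al.) is a complex-logarithmic mapping: a visual
location at eccentricity ``R`` (deg) and polar angle ``phi`` (deg, measured
from the horizontal meridian, upper field positive) maps to the point

.. math::

    u = B_u \\ln\\frac{\\sqrt{R^2 + 2AR\\cos\\phi + A^2}}{A}, \\qquad
    v = B_v \\arctan\\frac{R\\sin\\phi}{R\\cos\\phi + A}

on the collicular surface, where ``u`` (mm) runs along the rostro-caudal axis
(amplitude) and ``v`` (mm) along the medio-lateral axis (direction).  ``A``
sets the foveal scale and ``B_u``, ``B_v`` the millimetres of tissue per log
unit of eccentricity and per radian of direction.  The standard constants are
``A = 3.0 deg``, ``B_u = 1.4 mm``, ``B_v = 1.8 mm``.

Writing ``z = R e^{i phi}`` the mapping is ``w = B ln((z + A)/A)`` for the
isotropic case; the anisotropic (Bu, Bv) variant used here applies the two
scale factors to the real and imaginary parts separately, which keeps the
closed-form inverse (see :func:`collicular_to_visual`).

This module also implements the eccentricity-matched design computation used
when comparing distractor effects across stimulus eccentricities: the polar
separation at a new eccentricity whose *collicular* distance equals that of a
reference pair (:func:`matched_separation`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import bisect

__all__ = [
    "VisualLocation", "CollicularPoint", "MappingParams", "ChordGeometry",
    "visual_to_collicular", "collicular_to_visual", "collicular_distance",
    "matched_separation", "scaled_stimulus_size", "InvalidPointError",
    "NoSolutionError",
]


class InvalidPointError(ValueError):
    """A collicular point outside the image of the forward mapping."""


class NoSolutionError(ValueError):
    """No polar separation in (0, 180) deg matches the requested distance."""


@dataclass(frozen=True)
class VisualLocation:
    """A location in the visual field.

    Parameters
    ----------
    eccentricity_deg : float
        Visual eccentricity (>= 0).
    polar_angle_deg : float
        Direction measured from the horizontal meridian, upper field
        positive, in (-180, 180].
    """

    eccentricity_deg: float
    polar_angle_deg: float = 0.0

    def __post_init__(self) -> None:
        if self.eccentricity_deg < 0:
            raise ValueError("eccentricity_deg must be >= 0")
        if not (-180.0 < self.polar_angle_deg <= 180.0):
            raise ValueError("polar_angle_deg must lie in (-180, 180]")


@dataclass(frozen=True)
class CollicularPoint:
    """A point on the collicular surface, in mm.

    ``u_mm`` is the distance along the rostro-caudal axis (>= 0 for real
    eccentricities), ``v_mm`` along the medio-lateral axis (positive for the
    upper visual field).
    """

    u_mm: float
    v_mm: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.u_mm) and math.isfinite(self.v_mm)):
            raise ValueError("collicular coordinates must be finite")


@dataclass(frozen=True)
class MappingParams:
    """Constants of the logarithmic motor-map model."""

    A_deg: float = 3.0
    Bu_mm: float = 1.4
    Bv_mm_per_rad: float = 1.8

    def __post_init__(self) -> None:
        if min(self.A_deg, self.Bu_mm, self.Bv_mm_per_rad) <= 0:
            raise ValueError("mapping constants must be strictly positive")


DEFAULT_MAPPING = MappingParams()


def visual_to_collicular(
    loc: VisualLocation, p: MappingParams = DEFAULT_MAPPING
) -> CollicularPoint:
    """Map a visual-field location onto the collicular surface."""
    R = loc.eccentricity_deg
    phi = math.radians(loc.polar_angle_deg)
    u = p.Bu_mm * math.log(
        math.sqrt(R * R + 2 * p.A_deg * R * math.cos(phi) + p.A_deg**2) / p.A_deg
    )
    v = p.Bv_mm_per_rad * math.atan2(R * math.sin(phi), R * math.cos(phi) + p.A_deg)
    return CollicularPoint(u, v)


def collicular_to_visual(
    pt: CollicularPoint, p: MappingParams = DEFAULT_MAPPING
) -> VisualLocation:
    """Invert the motor-map mapping (closed form).

    With ``zeta = exp(u/Bu) * exp(i v/Bv)`` the visual location is
    ``z = A (zeta - 1)``; eccentricity and polar angle are modulus and
    argument of ``z``.  Points with ``|v| >= pi * Bv`` lie outside the image
    of the forward mapping and raise :class:`InvalidPointError`.

    The origin maps back to the fovea; its polar angle is reported as 0 by
    convention.
    """
    if abs(pt.v_mm) >= math.pi * p.Bv_mm_per_rad:
        raise InvalidPointError(
            f"v = {pt.v_mm} mm outside the map image (|v| < pi*Bv = "
            f"{math.pi * p.Bv_mm_per_rad:.4f} mm)"
        )
    zeta = complex(
        math.exp(pt.u_mm / p.Bu_mm) * math.cos(pt.v_mm / p.Bv_mm_per_rad),
        math.exp(pt.u_mm / p.Bu_mm) * math.sin(pt.v_mm / p.Bv_mm_per_rad),
    )
    z = p.A_deg * (zeta - 1)
    R = abs(z)
    phi = math.degrees(math.atan2(z.imag, z.real)) if R > 0 else 0.0
    if phi == -180.0:
        phi = 180.0
    return VisualLocation(R, phi)


def collicular_distance(
    a: VisualLocation, b: VisualLocation, p: MappingParams = DEFAULT_MAPPING
) -> float:
    """Euclidean distance (mm) between two visual locations on the motor map."""
    pa = visual_to_collicular(a, p)
    pb = visual_to_collicular(b, p)
    return math.hypot(pa.u_mm - pb.u_mm, pa.v_mm - pb.v_mm)


def _mirrored_pair_distance(ecc: float, sep_deg: float, p: MappingParams) -> float:
    """Collicular distance of a target/distractor pair mirrored across the
    horizontal meridian at polar angles +- sep/2."""
    return collicular_distance(
        VisualLocation(ecc, +sep_deg / 2.0),
        VisualLocation(ecc, -sep_deg / 2.0),
        p,
    )


def matched_separation(
    ecc_ref_deg: float,
    sep_ref_deg: float,
    ecc_new_deg: float,
    p: MappingParams = DEFAULT_MAPPING,
    xtol_deg: float = 1e-4,
) -> float:
    """Polar separation at ``ecc_new`` matching a reference pair's collicular
    distance.

    Target and distractor are assumed to mirror the horizontal meridian at
    polar angles of plus/minus half the separation.  The matching separation
    is found by bisection on (0.1, 179) deg; the bracketing interval not
    containing a sign change raises :class:`NoSolutionError`.
    """
    d_ref = _mirrored_pair_distance(ecc_ref_deg, sep_ref_deg, p)

    def residual(s: float) -> float:
        return _mirrored_pair_distance(ecc_new_deg, s, p) - d_ref

    lo, hi = 0.1, 179.0
    if residual(lo) * residual(hi) > 0:
        raise NoSolutionError(
            f"no separation in (0, 180) deg at eccentricity {ecc_new_deg} deg "
            f"matches a collicular distance of {d_ref:.4f} mm"
        )
    return float(bisect(residual, lo, hi, xtol=xtol_deg))


def scaled_stimulus_size(
    ecc_ref_deg: float,
    size_ref_deg: float,
    ecc_new_deg: float,
    p: MappingParams = DEFAULT_MAPPING,
) -> float:
    """Stimulus size at a new eccentricity with comparable collicular footprint.

    Convenience only: scales by the inverse of the local rostro-caudal
    magnification ``M(R) = Bu / (R + A)`` along the horizontal meridian, i.e.
    ``size_new = size_ref * (R_new + A) / (R_ref + A)``.  The criterion the
    original experiments used to pick their printed sizes is not fully
    determined by magnification alone, so this helper is informational and not
    part of the tested design chain.
    """
    return size_ref_deg * (ecc_new_deg + p.A_deg) / (ecc_ref_deg + p.A_deg)


class ChordGeometry:
    """The 1-D tissue chord through a mirrored target/distractor pair.

    The simulated field is the straight line segment, in collicular
    coordinates, through the mapped target and distractor.  The pair sits at
    polar angles ``-sep/2`` (target) and ``+sep/2`` (distractor) at a common
    eccentricity, mirroring the horizontal meridian, and is placed
    symmetrically about the field centre.  The chord supplies the conversion
    between a field position (mm) and the visual direction (deg of polar
    angle) it encodes, via the inverse mapping.

    Parameters
    ----------
    eccentricity_deg : stimulus eccentricity.
    separation_deg : polar target-distractor separation, in (0, 180).
    field_extent_mm : length of the simulated field.
    distractor_side : +1 if the distractor occupies the positive-angle /
        high-x end of the field (default), -1 for the mirrored layout.
    """

    def __init__(
        self,
        eccentricity_deg: float,
        separation_deg: float,
        field_extent_mm: float = 5.0,
        distractor_side: int = +1,
        params: MappingParams = DEFAULT_MAPPING,
    ) -> None:
        if not (0.0 < separation_deg < 180.0):
            raise ValueError("separation_deg must lie in (0, 180)")
        if distractor_side not in (+1, -1):
            raise ValueError("distractor_side must be +1 or -1")
        self.eccentricity_deg = float(eccentricity_deg)
        self.separation_deg = float(separation_deg)
        self.field_extent_mm = float(field_extent_mm)
        self.distractor_side = int(distractor_side)
        self.params = params

        half = separation_deg / 2.0
        lo = visual_to_collicular(VisualLocation(eccentricity_deg, -half), params)
        hi = visual_to_collicular(VisualLocation(eccentricity_deg, +half), params)
        p_lo = np.array([lo.u_mm, lo.v_mm])
        p_hi = np.array([hi.u_mm, hi.v_mm])
        self.chord_length_mm = float(np.hypot(*(p_hi - p_lo)))
        if self.chord_length_mm > self.field_extent_mm:
            raise ValueError(
                "target-distractor collicular distance exceeds the field extent"
            )
        # field x always increases with polar angle; the side only decides
        # which endpoint holds the target
        self._mid = (p_lo + p_hi) / 2.0
        self._unit = (p_hi - p_lo) / self.chord_length_mm
        self.center_mm = self.field_extent_mm / 2.0
        lo_pos = self.center_mm - self.chord_length_mm / 2.0
        hi_pos = self.center_mm + self.chord_length_mm / 2.0
        if distractor_side > 0:
            self.target_pos_mm, self.distractor_pos_mm = lo_pos, hi_pos
            self.target_angle_deg = -half
        else:
            self.target_pos_mm, self.distractor_pos_mm = hi_pos, lo_pos
            self.target_angle_deg = +half

    def point_at(self, pos_mm: float) -> CollicularPoint:
        """Collicular point corresponding to a field position."""
        uv = self._mid + (pos_mm - self.center_mm) * self._unit
        return CollicularPoint(float(uv[0]), float(uv[1]))

    def angle_at(self, pos_mm: float) -> float:
        """Visual polar angle (deg) encoded at a field position."""
        return collicular_to_visual(self.point_at(pos_mm), self.params).polar_angle_deg

    def toward_sign(self, delta_angle_deg: float) -> float:
        """Convert an angle difference into the toward-distractor-positive
        convention."""
        return float(self.distractor_side) * delta_angle_deg
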