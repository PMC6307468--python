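"""Closed-form geometric estimators for filament cross-sections.

Filamentous bacteria imaged after drying or embedding are rarely perfect
cylinders: sample preparation flattens them.  The estimators here recover a
cross-sectional perimeter ``P`` from what the images actually show — a
flattened ellipse (SEM/FIB-SEM), a half-ellipse adhering to the substrate
(AFM of air-dried filaments), or a partially visible arc — and derive from
``P`` the quantities used to characterize the envelope:

* ridge width ``delta_R = P / N_R`` (perimeter length per ridge compartment),
* equivalent spherical diameter ``d_ESD = P / pi``,
* bulb area ``A_B = pi (delta_B / 2)^2`` at cell junctions.

The ellipse perimeter uses Ramanujan's second approximation, whose relative
error is below 1e-5 over the full flattening range needed here.

All functions are scalar, pure, and operate in nanometers internally; every
public entry point takes an explicit unit tag (see :mod:`cablemorph.units`).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional

from cablemorph.units import to_nm

logger = logging.getLogger(__name__)

__all__ = [
    "EllipseSpec",
    "HalfEllipseSpec",
    "ArcObservation",
    "DerivedMorphometrics",
    "auxiliary_h",
    "ellipse_perimeter_ramanujan",
    "half_ellipse_perimeter",
    "total_ridge_count",
    "ridge_width",
    "equivalent_spherical_diameter",
    "perimeter_from_arc",
    "bulb_area",
]


@dataclass(frozen=True)
class EllipseSpec:
    """A flattened elliptical cross-section.

    Parameters
    ----------
    W : float
        Transverse width of the filament (major-axis length).
    epsilon : float, optional
        Flattening: the minor axis is ``epsilon * W``.  Ranges from 0
        (perfectly flat) to 1 (perfectly round).  When not supplied the
        filament is assumed round (``epsilon = 1``) and a warning is logged,
        since the flattening of an embedded filament must be judged from
        image context and no automatic estimator is provided.
    unit : str
        Length unit of ``W`` (``"nm"`` or ``"um"``).
    """

    W: float
    epsilon: Optional[float] = None
    unit: str = "nm"

    #: width in canonical nm, set on construction
    W_nm: float = field(init=False, repr=False)

    def __post_init__(self) -> None:
        w_nm = to_nm(self.W, self.unit)
        if w_nm <= 0:
            raise ValueError(f"width W must be positive, got {self.W} {self.unit}")
        eps = self.epsilon
        if eps is None:
            logger.warning(
                "EllipseSpec: no flattening supplied; assuming a round "
                "cross-section (epsilon = 1)"
            )
            eps = 1.0
        if not 0.0 <= eps <= 1.0:
            raise ValueError(f"flattening epsilon must lie in [0, 1], got {eps}")
        object.__setattr__(self, "epsilon", float(eps))
        object.__setattr__(self, "W_nm", w_nm)


@dataclass(frozen=True)
class HalfEllipseSpec:
    """A half-elliptical cross-section of an air-dried, substrate-adhered filament.

    The filament collapses onto the substrate with width ``W`` and apex
    height ``H`` measured at the middle of a cell; the flattening is
    ``epsilon = 2H / W``, so ``H`` may not exceed ``W / 2``.
    """

    W: float
    H: float
    unit: str = "nm"

    W_nm: float = field(init=False, repr=False)
    H_nm: float = field(init=False, repr=False)

    def __post_init__(self) -> None:
        w_nm = to_nm(self.W, self.unit)
        h_nm = to_nm(self.H, self.unit)
        if w_nm <= 0:
            raise ValueError(f"width W must be positive, got {self.W} {self.unit}")
        if h_nm < 0:
            raise ValueError(f"height H must be non-negative, got {self.H} {self.unit}")
        if 2.0 * h_nm > w_nm * (1.0 + 1e-12):
            raise ValueError(
                f"H = {self.H} exceeds W/2 = {self.W / 2} ({self.unit}): "
                "flattening 2H/W would exceed 1"
            )
        object.__setattr__(self, "W_nm", w_nm)
        object.__setattr__(self, "H_nm", h_nm)

    @property
    def epsilon(self) -> float:
        """Flattening ``2H / W`` of the collapsed cross-section."""
        return min(2.0 * self.H_nm / self.W_nm, 1.0)


@dataclass(frozen=True)
class ArcObservation:
    """A partially visible cross-section outline.

    ``L_arc`` is the measured arc length and ``theta`` the angle (radians)
    it subtends at the section center; the full perimeter follows by
    circular extrapolation.
    """

    L_arc: float
    theta: float
    unit: str = "nm"

    L_nm: float = field(init=False, repr=False)

    def __post_init__(self) -> None:
        l_nm = to_nm(self.L_arc, self.unit)
        if l_nm <= 0:
            raise ValueError(f"arc length must be positive, got {self.L_arc}")
        if not 0.0 < self.theta <= 2.0 * math.pi + 1e-12:
            raise ValueError(
                f"subtended angle must lie in (0, 2*pi], got {self.theta}"
            )
        object.__setattr__(self, "L_nm", l_nm)


@dataclass
class DerivedMorphometrics:
    """Derived per-filament quantities, all in nanometers (areas in nm^2).

    Fields left as ``None`` were not measurable for that filament.  The
    stored values must be mutually consistent: ``P = pi * d_ESD`` exactly,
    and ``delta_R = P / N_R`` whenever both are present.
    """

    P: Optional[float] = None
    d_ESD: Optional[float] = None
    N_obs: Optional[int] = None
    N_R: Optional[int] = None
    delta_R: Optional[float] = None
    A_R: Optional[float] = None
    delta_B: Optional[float] = None
    A_B: Optional[float] = None
    delta_C: Optional[float] = None
    delta_S: Optional[float] = None

    def __post_init__(self) -> None:
        for name in ("P", "d_ESD", "delta_R", "A_R", "delta_B", "A_B",
                     "delta_C", "delta_S"):
            v = getattr(self, name)
            if v is not None and v <= 0:
                raise ValueError(f"{name} must be positive when present, got {v}")
        if self.P is not None and self.d_ESD is not None:
            if not math.isclose(self.P, math.pi * self.d_ESD, rel_tol=1e-9):
                raise ValueError(
                    f"inconsistent record: P = {self.P} but "
                    f"pi * d_ESD = {math.pi * self.d_ESD}"
                )
        if (self.P is not None and self.N_R is not None
                and self.delta_R is not None):
            if not math.isclose(self.delta_R, self.P / self.N_R, rel_tol=1e-9):
                raise ValueError(
                    f"inconsistent record: delta_R = {self.delta_R} but "
                    f"P / N_R = {self.P / self.N_R}"
                )


def auxiliary_h(epsilon: float) -> float:
    """Auxiliary parameter ``h = (1 - eps)^2 / (1 + eps)^2`` of the Ramanujan formula.

    For an ellipse with major axis ``W`` and minor axis ``eps * W`` this is
    the standard Ramanujan ``h = ((a - b) / (a + b))^2``.  Monotonically
    decreasing from 1 (flat) to 0 (round).
    """
    if not 0.0 <= epsilon <= 1.0:
        raise ValueError(f"flattening epsilon must lie in [0, 1], got {epsilon}")
    return ((1.0 - epsilon) / (1.0 + epsilon)) ** 2


def _ramanujan_factor(epsilon: float) -> float:
    """The factor ``(1 + eps) * (1 + 3h / (10 + sqrt(4 - 3h)))``."""
    h = auxiliary_h(epsilon)
    return (1.0 + epsilon) * (1.0 + 3.0 * h / (10.0 + math.sqrt(4.0 - 3.0 * h)))


def ellipse_perimeter_ramanujan(spec: EllipseSpec) -> float:
    """Perimeter of a flattened elliptical cross-section, in nm.

    ``P = (pi/2) * W * (1 + eps) * (1 + 3h / (10 + sqrt(4 - 3h)))``.

    Exact limits: a round filament (``eps = 1``) gives ``P = pi * W``; a
    perfectly flat one (``eps = 0``) gives ``P ~ 2 W`` (the Ramanujan value
    is ``(pi/2) * (14/11) * W = 1.99926 W``, 0.04 % below the true ribbon
    perimeter ``2W``).
    """
    return 0.5 * math.pi * spec.W_nm * _ramanujan_factor(spec.epsilon)


def half_ellipse_perimeter(spec: HalfEllipseSpec) -> float:
    """Perimeter of a collapsed (half-ellipse) cross-section, in nm.

    Half the Ramanujan perimeter of the ellipse with semi-axes ``W/2`` and
    ``H`` (the curved top), plus the flat base ``W`` where the envelope
    adheres to the substrate:

    ``P = (pi/2) * (W/2) * (1 + eps) * (1 + 3h / (10 + sqrt(4 - 3h))) + W``

    with ``eps = 2H / W``.  For ``H = W/2`` this is exactly the semicircle
    ``(pi/2 + 1) * W``.
    """
    return 0.25 * math.pi * spec.W_nm * _ramanujan_factor(spec.epsilon) + spec.W_nm


def total_ridge_count(N_obs: int) -> int:
    """Total ridge count from a one-sided (surface-view) ridge count.

    Only one side of a filament is visible in a surface SEM image, so the
    total number of ridge compartments is estimated as ``N_R = 2 * N_obs``.
    """
    if not isinstance(N_obs, (int,)) or isinstance(N_obs, bool):
        raise TypeError(f"N_obs must be an integer, got {N_obs!r}")
    if N_obs <= 0:
        raise ValueError(f"N_obs must be positive, got {N_obs}")
    return 2 * N_obs


def ridge_width(P: float, N_R: int, unit: str = "nm") -> float:
    """Mean ridge width ``delta_R = P / N_R``, in nm.

    The perimeter length attributed to a single ridge compartment of the
    cell envelope.
    """
    p_nm = to_nm(P, unit)
    if p_nm <= 0:
        raise ValueError(f"perimeter must be positive, got {P} {unit}")
    if N_R < 1:
        raise ValueError(f"ridge count must be >= 1, got {N_R}")
    return p_nm / N_R


def equivalent_spherical_diameter(P: float, unit: str = "nm") -> float:
    """Equivalent spherical diameter ``d_ESD = P / pi``, in nm.

    The diameter of the circle having the measured cross-sectional
    perimeter; the natural diameter scale for a filament whose actual
    cross-section has been deformed by sample preparation.
    """
    p_nm = to_nm(P, unit)
    if p_nm <= 0:
        raise ValueError(f"perimeter must be positive, got {P} {unit}")
    return p_nm / math.pi


def perimeter_from_arc(obs: ArcObservation) -> float:
    """Full perimeter extrapolated from a partial outline: ``P = L * 2*pi / theta``."""
    return obs.L_nm * 2.0 * math.pi / obs.theta


def bulb_area(delta_B: float, unit: str = "nm") -> float:
    """Cross-sectional area of a circular junction bulb: ``A_B = pi (delta_B/2)^2``.

    Returns nm^2.
    """
    d_nm = to_nm(delta_B, unit)
    if d_nm < 0:
        raise ValueError(f"bulb diameter must be non-negative, got {delta_B}")
    return math.pi * (0.5 * d_nm) ** 2
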