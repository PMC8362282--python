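"""Reduced-order motion-segment mechanics.

A lumbar motion segment is modelled as a composite Euler-Bernoulli section:
the disc cross-section is discretised into thin strips along the
anteroposterior axis, each strip carrying the annulus and (optionally)
nucleus material found there.  The annulus is *bilinear* — it takes a
different modulus in tension and in compression — which is what makes the
bending stiffness sensitive to where the soft (or void) nucleus region sits.
Moving the nucleus posteriorly swaps annulus material between the tension
and compression zones of the two bending directions, so flexion and
extension range of motion move in opposite directions: the mechanism that a
nucleus-position calibration exploits.

Under a pure moment M the section bends with curvature
``kappa = M / sum(E_i * (x_i - x0)^2 * A_i)`` about the neutral axis x0 at
which the net axial force vanishes; the segment's range of motion is the
rotation accumulated over the disc height, ``RoM = degrees(kappa * h)``.
Axial compression uses the uniform-strain composite-rod analogue.

This surrogate deliberately contains no ligaments, facet joints or 3D
effects; it exists to give the calibration loop a live, monotone,
mechanically grounded evaluator, not to reproduce a full finite-element
model's absolute numbers.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Callable

import numpy as np
import shapely

from .exceptions import SingularSectionError
from .geometry import Contour, place_nucleus

__all__ = [
    "MaterialSet",
    "LoadCase",
    "SectionModel",
    "DEFAULT_MATERIALS",
    "CANONICAL_LOAD_CASES",
    "neutral_axis",
    "bending_rom",
    "compression_response",
    "rom_evaluator",
    "SurrogateRomEvaluator",
]

_X0_TOL_MM = 1e-9


@dataclass(frozen=True)
class MaterialSet:
    """Section material constants.

    Parameters
    ----------
    annulus_tension_modulus, annulus_compression_modulus : float
        Effective annulus moduli (MPa) on the tension and compression side
        of the neutral axis.  They may differ (bilinear annulus).
    nucleus_modulus : float
        Effective nucleus modulus (MPa); must not exceed either annulus
        modulus, reflecting that the gel-like nucleus is softer than the
        fibrous annulus (equality is the degenerate homogeneous limit, in
        which nucleus position and size stop affecting stiffness).
    disc_height : float
        Disc height h (mm) over which section curvature accumulates.
    """

    annulus_tension_modulus: float
    annulus_compression_modulus: float
    nucleus_modulus: float
    disc_height: float

    def __post_init__(self) -> None:
        e = (
            self.annulus_tension_modulus,
            self.annulus_compression_modulus,
            self.nucleus_modulus,
        )
        if any(v < 0 for v in e):
            raise ValueError("moduli must be nonnegative")
        if self.nucleus_modulus > min(e[0], e[1]):
            raise ValueError("nucleus modulus must not exceed the annulus moduli")
        if self.disc_height <= 0:
            raise ValueError("disc height must be positive")

    @classmethod
    def from_dict(cls, d: dict) -> "MaterialSet":
        return cls(
            annulus_tension_modulus=float(d["annulus_tension_modulus"]),
            annulus_compression_modulus=float(d["annulus_compression_modulus"]),
            nucleus_modulus=float(d["nucleus_modulus"]),
            disc_height=float(d["disc_height"]),
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "MaterialSet":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


#: Default material set: annulus much stiffer in compression than tension,
#: tuned so the surrogate's flexion/extension RoM at 10 Nm falls in the
#: 15-18 degree band reported for cadaveric L4-L5 segments, with the
#: flexion-up / extension-down trend in P1.
DEFAULT_MATERIALS = MaterialSet(
    annulus_tension_modulus=1.0,
    annulus_compression_modulus=8.0,
    nucleus_modulus=0.5,
    disc_height=10.0,
)


@dataclass(frozen=True)
class LoadCase:
    """Applied loads: sagittal moment (Nm, flexion positive) and axial
    compressive force (N, compression positive)."""

    moment_nm: float = 0.0
    axial_force_n: float = 0.0
    label: str = ""

    def __post_init__(self) -> None:
        if self.moment_nm == 0.0 and self.axial_force_n == 0.0:
            raise ValueError("a load case needs a nonzero moment or axial force")


#: The study's canonical load cases: RoM under 10 Nm with a 100 N preload,
#: pressure/facet-force comparisons under 7.5 Nm, compression under 1200 N.
CANONICAL_LOAD_CASES = {
    "rom_10Nm_100N": LoadCase(moment_nm=10.0, axial_force_n=100.0, label="rom_10Nm_100N"),
    "idp_fcf_7.5Nm": LoadCase(moment_nm=7.5, axial_force_n=0.0, label="idp_fcf_7.5Nm"),
    "dc_1200N": LoadCase(moment_nm=0.0, axial_force_n=1200.0, label="dc_1200N"),
}


class SectionModel:
    """Strip discretisation of a disc cross-section with an optional nucleus.

    The disc polygon is sliced into ``n_strips`` equal-width strips along the
    anteroposterior (x) axis; each strip records its annulus area and nucleus
    area.  ``nucleus_suppressed=True`` keeps the nucleus geometry but assigns
    it zero modulus (a void), the configuration used during calibration.
    """

    def __init__(
        self,
        disc: Contour,
        nucleus: Contour | None = None,
        n_strips: int = 2000,
        nucleus_suppressed: bool = False,
    ) -> None:
        if n_strips < 100:
            raise ValueError("need at least 100 strips")
        self.disc = disc
        self.nucleus = nucleus
        self.n_strips = n_strips
        self.nucleus_suppressed = nucleus_suppressed

        minx, miny, maxx, maxy = disc.polygon.bounds
        edges = np.linspace(minx, maxx, n_strips + 1)
        boxes = shapely.box(edges[:-1], miny - 1.0, edges[1:], maxy + 1.0)
        disc_areas = shapely.area(shapely.intersection(disc.polygon, boxes))
        if nucleus is not None:
            nucleus_areas = shapely.area(shapely.intersection(nucleus.polygon, boxes))
        else:
            nucleus_areas = np.zeros(n_strips)
        self.x = 0.5 * (edges[:-1] + edges[1:])
        self.annulus_area = np.maximum(disc_areas - nucleus_areas, 0.0)
        self.nucleus_area = nucleus_areas

    def moduli(self, materials: MaterialSet, tension_mask: np.ndarray) -> np.ndarray:
        """Per-strip axial stiffness density E*A given a tension/compression
        split of the annulus; a suppressed nucleus contributes nothing."""
        e_annulus = np.where(
            tension_mask,
            materials.annulus_tension_modulus,
            materials.annulus_compression_modulus,
        )
        e_nucleus = 0.0 if self.nucleus_suppressed else materials.nucleus_modulus
        return e_annulus * self.annulus_area + e_nucleus * self.nucleus_area


def _axial_stiffness(section: SectionModel, materials: MaterialSet, x0: float, sign: float) -> np.ndarray:
    # flexion (sign > 0): posterior fibres (x > x0) in tension
    tension = (section.x - x0) * sign > 0
    return section.moduli(materials, tension)


def neutral_axis(section: SectionModel, materials: MaterialSet, moment_sign: float) -> float:
    """Neutral-axis position x0 (mm) under pure bending.

    x0 is the unique root of the net axial force
    ``sum(E(x, strain sign) * (x - x0) * A)``, with each strip's annulus
    modulus chosen by whether it lies on the tension or compression side for
    the given moment sign; solved by bisection to 1e-9 mm.
    """
    if moment_sign == 0:
        raise ValueError("moment sign must be nonzero")
    sign = float(np.sign(moment_sign))

    def residual(x0: float) -> float:
        ea = _axial_stiffness(section, materials, x0, sign)
        return float(np.sum(ea * (section.x - x0)))

    lo, hi = float(section.x[0]), float(section.x[-1])
    r_lo, r_hi = residual(lo), residual(hi)
    if r_lo == 0.0 and r_hi == 0.0:
        raise SingularSectionError("section carries no load (all-void)")
    # residual is strictly decreasing in x0
    while hi - lo > _X0_TOL_MM:
        mid = 0.5 * (lo + hi)
        if residual(mid) > 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def bending_rom(section: SectionModel, materials: MaterialSet, load: LoadCase) -> float:
    """Range of motion (degrees, signed by moment direction) under bending.

    curvature kappa = |M| / EI_eff with EI_eff = sum(E * (x - x0)^2 * A);
    RoM = degrees(kappa * h).  Linear in |M|; the axial preload of the load
    case does not enter the bending stiffness (linear model).
    """
    if load.moment_nm == 0.0:
        raise ValueError("bending_rom needs a nonzero moment")
    sign = float(np.sign(load.moment_nm))
    x0 = neutral_axis(section, materials, sign)
    ea = _axial_stiffness(section, materials, x0, sign)
    ei = float(np.sum(ea * (section.x - x0) ** 2))  # MPa*mm^4 == N*mm^2
    if ei <= 0:
        raise SingularSectionError("zero bending stiffness")
    kappa = abs(load.moment_nm) * 1000.0 / ei  # 1/mm
    return float(np.degrees(kappa * materials.disc_height)) * sign


def compression_response(
    section: SectionModel, materials: MaterialSet, load: LoadCase
) -> tuple[float, float]:
    """Disc compression (mm) and nucleus-stress proxy for intradiscal
    pressure (MPa) under axial force.

    Uniform-strain composite rod: DC = F*h / sum(E*A) with the annulus at its
    compression modulus; the pressure proxy is the axial stress carried by
    the nucleus, E_n * DC / h.
    """
    if load.axial_force_n <= 0.0:
        raise ValueError("compression_response needs a positive axial force")
    ea = section.moduli(materials, tension_mask=np.zeros(section.n_strips, dtype=bool))
    total = float(np.sum(ea))  # N
    if total <= 0:
        raise SingularSectionError("section carries no axial load (all-void)")
    dc = load.axial_force_n * materials.disc_height / total
    e_nucleus = 0.0 if section.nucleus_suppressed else materials.nucleus_modulus
    idp_proxy = e_nucleus * dc / materials.disc_height
    return (dc, idp_proxy)


class SurrogateRomEvaluator:
    """Callable P1 -> (flexion RoM, extension RoM) backed by the strip model.

    Each evaluation places a nucleus at (P1, P2) inside the fixed disc
    contour, builds the section (with the nucleus as a zero-modulus void
    when suppressed), and computes RoM for +M and -M.  Deterministic: equal
    inputs give identical outputs.
    """

    def __init__(
        self,
        disc: Contour,
        p2: float,
        materials: MaterialSet = DEFAULT_MATERIALS,
        load: LoadCase = CANONICAL_LOAD_CASES["rom_10Nm_100N"],
        nucleus_suppressed: bool = True,
        n_strips: int = 2000,
    ) -> None:
        if load.moment_nm == 0.0:
            raise ValueError("RoM evaluation needs a nonzero moment")
        self.disc = disc
        self.p2 = p2
        self.materials = materials
        self.load = load
        self.nucleus_suppressed = nucleus_suppressed
        self.n_strips = n_strips

    def __call__(self, p1: float) -> tuple[float, float]:
        nucleus = place_nucleus(self.disc, p1, self.p2)
        section = SectionModel(
            self.disc,
            nucleus,
            n_strips=self.n_strips,
            nucleus_suppressed=self.nucleus_suppressed,
        )
        m = abs(self.load.moment_nm)
        flex = bending_rom(section, self.materials, replace(self.load, moment_nm=m))
        ext = bending_rom(section, self.materials, replace(self.load, moment_nm=-m))
        return (flex, ext)


def rom_evaluator(
    disc: Contour,
    p2: float,
    materials: MaterialSet = DEFAULT_MATERIALS,
    load: LoadCase = CANONICAL_LOAD_CASES["rom_10Nm_100N"],
    nucleus_suppressed: bool = True,
    n_strips: int = 2000,
) -> Callable[[float], tuple[float, float]]:
    """Build the P1 -> (flexion, extension) contract used by calibration."""
    return SurrogateRomEvaluator(
        disc, p2, materials=materials, load=load,
        nucleus_suppressed=nucleus_suppressed, n_strips=n_strips,
    )
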