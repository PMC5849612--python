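"""Beam-theory cross-sectional geometry of long-bone sections.

Transverse bone sections arrive as binary cortical-bone profiles (true =
cortical bone) with a known physical pixel size.  From such a profile the
module computes the quantities classically used to characterise the
mechanical build of a wing bone at mid-diaphysis:

* ``CA`` — cortical area (mm²), the amount of bone in the section;
* ``TA`` — total subperiosteal area (mm²), everything enclosed by the outer
  (periosteal) surface, medullary cavity included;
* ``CA/TA`` — relative cortical thickness, the hollowness of the element;
* ``Ixx, Iyy, Ixy`` and principal moments ``Imax ≥ Imin`` (mm⁴) — second
  moments of area governing bending resistance;
* ``J = Imax + Imin`` (mm⁴) — polar moment, resistance against torsion
  about the bone's long axis; normalised by body mass (``J/M``) it can be
  compared across taxa spanning several orders of magnitude in size;
* section ellipticity ``Imax/Imin``, flagged when above 1.50 because polar
  moments of strongly elliptical sections are overestimated by the
  circular-torsion assumption.

A separate path counts vascular canals in grayscale images of the cortex
and expresses them as canals per mm² of bone area.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
from PIL import Image
from scipy import ndimage
from skimage import measure

__all__ = [
    "SectionMask",
    "SectionProperties",
    "VascularReport",
    "load_section",
    "compute_section_properties",
    "principal_moments",
    "mass_normalised_torsion",
    "aggregate_element",
    "vascular_density",
    "properties_to_frame",
    "ELLIPTICITY_FLAG_THRESHOLD",
]

#: Sections with Imax/Imin above this ratio get ``ellipticity_flag`` set:
#: their polar moment J is typically overestimated and should be used
#: proportionally rather than quantitatively.
ELLIPTICITY_FLAG_THRESHOLD = 1.50


class EmptySectionError(ValueError):
    """Raised when a raster contains no cortical-bone pixels."""


@dataclass(frozen=True)
class SectionMask:
    """Binary cortical-bone profile of one transverse section.

    ``pixels`` is a 2-D boolean grid, true where cortical bone is present;
    ``pixel_size`` is the physical edge length of one pixel in mm.
    """

    pixels: np.ndarray
    pixel_size: float
    element: Literal["humerus", "ulna"] = "humerus"
    side: Literal["left", "right", "unknown"] = "unknown"
    specimen_id: str = ""
    section_label: str = ""

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=bool)
        if px.ndim != 2 or px.size == 0:
            raise ValueError("section raster must be a non-empty 2-D grid")
        if not self.pixel_size > 0:
            raise ValueError(f"pixel_size must be positive, got {self.pixel_size}")
        object.__setattr__(self, "pixels", px)

    @property
    def n_true(self) -> int:
        return int(self.pixels.sum())


@dataclass(frozen=True)
class SectionProperties:
    """All beam-theory quantities for one section (units mm, mm², mm⁴)."""

    CA: float
    TA: float
    centroid: tuple[float, float]
    Ixx: float
    Iyy: float
    Ixy: float
    Imax: float
    Imin: float
    theta: float  # orientation of the Imax principal axis, degrees in (-90, 90]
    J: float
    ca_ta: float
    ellipticity: float
    ellipticity_flag: bool
    element: str = "humerus"
    side: str = "unknown"
    specimen_id: str = ""
    section_label: str = ""


@dataclass(frozen=True)
class VascularReport:
    """Vascular canal census for one cortical cross section."""

    canal_count: int
    cortical_area: float  # mm²
    density: float  # canals per mm²
    threshold_used: float
    size_range: tuple[float, float]  # pixel-area interval, inclusive


def load_section(
    path: str | Path,
    pixel_size: float,
    *,
    element: str = "humerus",
    side: str = "unknown",
    specimen_id: str = "",
    section_label: str = "",
    threshold: float | None = None,
) -> SectionMask:
    """Read a single-channel raster and binarise it into a cortical mask.

    Binary inputs (two grey levels) map directly: the higher level is bone.
    Grayscale inputs are thresholded at ``threshold`` if given, otherwise at
    the midpoint between the extreme grey levels (an Otsu-style default for
    clean two-phase profiles).
    """
    img = Image.open(path)
    if img.mode not in ("1", "L", "I", "I;16", "F"):
        img = img.convert("L")
    arr = np.asarray(img, dtype=float)
    if arr.ndim != 2:
        raise ValueError(f"expected a single-channel raster, got shape {arr.shape}")

    levels = np.unique(arr)
    if levels.size == 1:
        pixels = arr > 0
    else:
        if threshold is None:
            if levels.size == 2:
                threshold = float(levels.mean())
            else:
                threshold = float((levels.min() + levels.max()) / 2.0)
        pixels = arr > threshold

    if not pixels.any():
        raise EmptySectionError(f"empty section: no cortical pixels in {path}")
    return SectionMask(
        pixels=pixels,
        pixel_size=pixel_size,
        element=element,  # type: ignore[arg-type]
        side=side,  # type: ignore[arg-type]
        specimen_id=specimen_id,
        section_label=section_label,
    )


def principal_moments(Ixx: float, Iyy: float, Ixy: float) -> tuple[float, float, float]:
    """Principal second moments and Imax-axis orientation.

    Eigen-decomposition of the 2x2 area-moment tensor [[Ixx, Ixy], [Ixy, Iyy]].
    Returns ``(Imax, Imin, theta)`` with ``Imax >= Imin`` and theta in degrees
    in (-90, 90]; a circular section (Imax == Imin) reports theta = 0 by
    convention.
    """
    if Ixx < 0 or Iyy < 0:
        raise ValueError("diagonal second moments must be non-negative")
    mean = 0.5 * (Ixx + Iyy)
    half_diff = 0.5 * (Ixx - Iyy)
    radius = float(np.hypot(half_diff, Ixy))
    imax, imin = mean + radius, mean - radius
    if radius <= 1e-12 * max(mean, 1.0):
        return imax, imin, 0.0
    # eigenvector of [[Ixx, Ixy], [Ixy, Iyy]] for the larger eigenvalue
    theta = 0.5 * np.degrees(np.arctan2(2.0 * Ixy, Ixx - Iyy))
    if theta <= -90.0:
        theta += 180.0
    elif theta > 90.0:
        theta -= 180.0
    return imax, imin, float(theta)


def _fill_intracortical_voids(pixels: np.ndarray) -> np.ndarray:
    """Fill enclosed holes except the largest (the medullary cavity).

    Binary profiles are expected to show solid cortex; residual small
    enclosed voids (vascular canals, erosion bays) are counted as bone,
    while the single largest enclosed space is retained as the medullary
    cavity and contributes only to TA.
    """
    filled = ndimage.binary_fill_holes(pixels)
    holes = filled & ~pixels
    if not holes.any():
        return pixels
    labels, n = ndimage.label(holes)
    if n <= 1:
        return pixels
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
    keep = int(np.argmax(sizes)) + 1  # medullary cavity stays a hole
    return pixels | (holes & (labels != keep))


def compute_section_properties(
    mask: SectionMask, *, fill_canals: bool = True
) -> SectionProperties:
    """Compute all beam-theory section properties of a cortical profile.

    Each true pixel contributes as a solid unit square about its own centre,
    including its own px⁴/12 self-moment, matching the convention of the
    standard ImageJ section-moment macros. TA is obtained by flood-fill:
    every false pixel not reachable from the grid border is enclosed by the
    periosteal surface and counts toward the total subperiosteal area.
    """
    px = mask.pixel_size
    pixels = mask.pixels
    if not pixels.any():
        raise EmptySectionError("empty section mask")
    if pixels.sum() < 2:
        raise ValueError("degenerate single-pixel section: moments undefined")

    if fill_canals:
        pixels = _fill_intracortical_voids(pixels)

    _, n_components = ndimage.label(pixels)
    if n_components > 1:
        warnings.warn(
            f"cortical region has {n_components} connected components; "
            "properties assume one dominant component",
            stacklevel=2,
        )

    rows, cols = np.nonzero(pixels)
    # physical pixel-centre coordinates: x along columns, y along rows
    x = (cols + 0.5) * px
    y = (rows + 0.5) * px
    n = x.size
    area_px = px * px
    ca = n * area_px

    filled = ndimage.binary_fill_holes(pixels)
    ta = float(filled.sum()) * area_px

    cx, cy = float(x.mean()), float(y.mean())
    dx, dy = x - cx, y - cy
    self_moment = n * px**4 / 12.0
    ixx = float(np.sum(dy * dy)) * area_px + self_moment
    iyy = float(np.sum(dx * dx)) * area_px + self_moment
    ixy = float(np.sum(dx * dy)) * area_px

    imax, imin, theta = principal_moments(ixx, iyy, ixy)
    j = imax + imin
    ellipticity = imax / imin if imin > 0 else np.inf

    return SectionProperties(
        CA=ca,
        TA=ta,
        centroid=(cx, cy),
        Ixx=ixx,
        Iyy=iyy,
        Ixy=ixy,
        Imax=imax,
        Imin=imin,
        theta=theta,
        J=j,
        ca_ta=ca / ta,
        ellipticity=float(ellipticity),
        ellipticity_flag=bool(ellipticity > ELLIPTICITY_FLAG_THRESHOLD),
        element=mask.element,
        side=mask.side,
        specimen_id=mask.specimen_id,
        section_label=mask.section_label,
    )


def mass_normalised_torsion(J: float, mass: float) -> float:
    """Polar moment normalised by body mass, J/M in mm⁴ g⁻¹."""
    if not mass > 0:
        raise ValueError(f"body mass must be positive, got {mass}")
    return J / mass


def aggregate_element(
    sections: Sequence[SectionProperties],
    policy: Literal["mean", "single"] = "mean",
) -> SectionProperties:
    """Combine per-section properties into one per-element value.

    Specimens represented by two circa mid-diaphyseal sections contribute
    the arithmetic mean of each scalar property (policy ``"mean"``); single
    best-preserved sections pass through unchanged (policy ``"single"``).
    J is recomputed from the averaged principal moments so the identity
    J = Imax + Imin holds exactly for the aggregate.
    """
    if len(sections) == 0:
        raise ValueError("need at least one section")
    elements = {s.element for s in sections}
    if len(elements) > 1:
        raise ValueError(f"cannot aggregate across elements: {sorted(elements)}")
    if policy == "single":
        if len(sections) != 1:
            raise ValueError('policy "single" requires exactly one section')
        return sections[0]
    if policy != "mean":
        raise ValueError(f"unknown aggregation policy {policy!r}")

    def m(attr: str) -> float:
        return float(np.mean([getattr(s, attr) for s in sections]))

    imax, imin = m("Imax"), m("Imin")
    ellipticity = imax / imin
    ref = sections[0]
    return replace(
        ref,
        CA=m("CA"),
        TA=m("TA"),
        centroid=(
            float(np.mean([s.centroid[0] for s in sections])),
            float(np.mean([s.centroid[1] for s in sections])),
        ),
        Ixx=m("Ixx"),
        Iyy=m("Iyy"),
        Ixy=m("Ixy"),
        Imax=imax,
        Imin=imin,
        theta=m("theta"),
        J=imax + imin,
        ca_ta=m("ca_ta"),
        ellipticity=float(ellipticity),
        ellipticity_flag=bool(ellipticity > ELLIPTICITY_FLAG_THRESHOLD),
        section_label="+".join(s.section_label for s in sections if s.section_label),
    )


def vascular_density(
    gray: np.ndarray,
    cortex: SectionMask,
    threshold: float,
    size_range: tuple[float, float],
) -> VascularReport:
    """Count vascular canals inside the cortex of a grayscale section.

    Canals image darker than bone: connected components of sub-threshold
    pixels lying inside the cortical mask whose pixel area falls within
    ``size_range`` (inclusive) are counted, and the count is expressed per
    mm² of cortical bone area.
    """
    gray = np.asarray(gray, dtype=float)
    if gray.shape != cortex.pixels.shape:
        raise ValueError(
            f"gray raster {gray.shape} and cortex mask {cortex.pixels.shape} differ"
        )
    lo, hi = size_range
    if not lo < hi:
        raise ValueError(f"inverted canal size range {size_range}")
    if not cortex.pixels.any():
        raise EmptySectionError("no cortical pixels in mask")

    ca = cortex.n_true * cortex.pixel_size**2
    candidates = (gray < threshold) & cortex.pixels
    labels = measure.label(candidates, connectivity=2)
    count = 0
    if labels.max() > 0:
        sizes = np.bincount(labels.ravel())[1:]
        count = int(np.sum((sizes >= lo) & (sizes <= hi)))
    return VascularReport(
        canal_count=count,
        cortical_area=ca,
        density=count / ca,
        threshold_used=float(threshold),
        size_range=(float(lo), float(hi)),
    )


def properties_to_frame(props: Iterable[SectionProperties]):
    """Tabulate section properties, one row per section (CSV-ready)."""
    import pandas as pd

    rows = []
    for p in props:
        rows.append(
            {
                "specimen": p.specimen_id,
                "element": p.element,
                "side": p.side,
                "CA": p.CA,
                "TA": p.TA,
                "Ixx": p.Ixx,
                "Iyy": p.Iyy,
                "Ixy": p.Ixy,
                "Imax": p.Imax,
                "Imin": p.Imin,
                "theta_deg": p.theta,
                "J": p.J,
                "CA_TA": p.ca_ta,
                "ellipticity": p.ellipticity,
                "ellipticity_flag": p.ellipticity_flag,
            }
        )
    return pd.DataFrame(rows)
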