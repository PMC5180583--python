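"""Polygonal regions of interest on specimen photographs.

A region of interest (RoI) is a closed polygon drawn over one body region of a
pinned insect (face, thorax dorsal, ...). Regions are persisted as JSON
sidecar files next to the image (``<image_id>.rois.json``) and rasterized to
boolean masks for the entropy measurement.

Coordinate convention: origin at the top-left corner of the image, ``x`` is
the column axis, ``y`` the row axis, vertices in continuous pixel units. A
pixel (row ``i``, column ``j``) belongs to a polygon iff its center
``(j + 0.5, i + 0.5)`` lies strictly inside under the even-odd rule; centers
exactly on the boundary count as outside.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "CANONICAL_LABELS",
    "PolygonRoI",
    "RoISet",
    "RoiValidationError",
    "load_roiset",
    "save_roiset",
    "rasterize",
    "validate_roiset",
]

#: The eight body regions marked in the original protocol, in reporting order.
CANONICAL_LABELS: tuple[str, ...] = (
    "face",
    "head_dorsal",
    "head_ventral",
    "front_leg",
    "thorax_dorsal",
    "thorax_ventral",
    "abdomen_dorsal",
    "abdomen_ventral",
)

#: Vertex positions may exceed the image bounds by up to this much (px)
#: before a warning is raised.
BOUNDS_TOL = 0.5

#: The original tool's UI allowed at most this many regions per image; more
#: are accepted here with a warning.
SOFT_MAX_REGIONS = 4


class RoiValidationError(ValueError):
    """An RoI definition violates a structural invariant."""


def normalize_label(label: str) -> str:
    """Normalize a region label to ``lower_snake_case``."""
    return re.sub(r"[\s\-]+", "_", label.strip().lower())


@dataclass
class PolygonRoI:
    """One labeled polygonal region.

    Parameters
    ----------
    label:
        Region name; one of :data:`CANONICAL_LABELS` or free text.
    vertices:
        ``(n, 2)`` float array of ``(x, y)`` pixel coordinates, ``n >= 3``.
    """

    label: str
    vertices: np.ndarray

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 2:
            raise RoiValidationError(
                f"region {self.label!r}: vertices must be an (n, 2) array"
            )
        if len(self.vertices) < 3:
            raise RoiValidationError(
                f"region {self.label!r}: a polygon needs at least 3 vertices, "
                f"got {len(self.vertices)}"
            )
        closed = np.vstack([self.vertices, self.vertices[:1]])
        if np.any(np.all(closed[:-1] == closed[1:], axis=1)):
            raise RoiValidationError(
                f"region {self.label!r}: consecutive duplicate vertices"
            )
        if self.area() <= 0.0:
            raise RoiValidationError(f"region {self.label!r}: polygon area is zero")

    def area(self) -> float:
        """Unsigned continuum (shoelace) area in px^2."""
        x = self.vertices[:, 0]
        y = self.vertices[:, 1]
        return 0.5 * abs(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))

    def perimeter(self) -> float:
        """Continuum perimeter (sum of edge lengths) in px."""
        d = np.diff(np.vstack([self.vertices, self.vertices[:1]]), axis=0)
        return float(np.hypot(d[:, 0], d[:, 1]).sum())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PolygonRoI):
            return NotImplemented
        return self.label == other.label and np.array_equal(
            self.vertices, other.vertices
        )


@dataclass
class RoISet:
    """All regions marked on one image."""

    image_id: str
    image_width: int
    image_height: int
    regions: list[PolygonRoI] = field(default_factory=list)

    def get(self, label: str) -> PolygonRoI:
        for r in self.regions:
            if r.label == label:
                return r
        raise KeyError(label)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, RoISet):
            return NotImplemented
        return (
            self.image_id == other.image_id
            and self.image_width == other.image_width
            and self.image_height == other.image_height
            and self.regions == other.regions
        )


def load_roiset(path: str | Path) -> RoISet:
    """Load and validate an RoI JSON sidecar file.

    Labels are normalized to ``lower_snake_case``. Raises
    :class:`RoiValidationError` for structural problems (naming the offending
    key or region) and ``json.JSONDecodeError`` for malformed JSON.
    """
    path = Path(path)
    with open(path) as fh:
        doc = json.load(fh)
    for key in ("image_id", "image_width", "image_height", "regions"):
        if key not in doc:
            raise RoiValidationError(f"{path.name}: missing key {key!r}")
    regions = []
    for entry in doc["regions"]:
        if "label" not in entry or "vertices" not in entry:
            raise RoiValidationError(
                f"{path.name}: region entry missing 'label' or 'vertices'"
            )
        regions.append(
            PolygonRoI(normalize_label(entry["label"]), np.asarray(entry["vertices"]))
        )
    return RoISet(
        image_id=str(doc["image_id"]),
        image_width=int(doc["image_width"]),
        image_height=int(doc["image_height"]),
        regions=regions,
    )


def save_roiset(rs: RoISet, path: str | Path) -> None:
    """Write an RoI set to JSON.

    Emits a warning (via :func:`validate_roiset`) if the set has more than
    four regions; the file is still written.
    """
    import logging

    for w in validate_roiset(rs, rs.image_width, rs.image_height):
        logging.getLogger(__name__).warning("%s: %s", rs.image_id, w)
    doc = {
        "image_id": rs.image_id,
        "image_width": rs.image_width,
        "image_height": rs.image_height,
        "regions": [
            {"label": r.label, "vertices": r.vertices.tolist()} for r in rs.regions
        ],
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)
        fh.write("\n")


def _centers_in_polygon(px: np.ndarray, py: np.ndarray, verts: np.ndarray) -> np.ndarray:
    """Even-odd test for points against a polygon; boundary points are outside.

    ``px``/``py`` are broadcastable arrays of point coordinates.
    """
    inside = np.zeros(np.broadcast(px, py).shape, dtype=bool)
    on_edge = np.zeros_like(inside)
    n = len(verts)
    for k in range(n):
        x1, y1 = verts[k]
        x2, y2 = verts[(k + 1) % n]
        # crossing-number update for the horizontal ray towards +x
        cond = (y1 > py) != (y2 > py)
        if np.any(cond):
            xi = x1 + (py - y1) * (x2 - x1) / (y2 - y1)
            inside ^= cond & (px < xi)
        # exact/near-exact boundary detection
        ex, ey = x2 - x1, y2 - y1
        seg_len2 = ex * ex + ey * ey
        t = ((px - x1) * ex + (py - y1) * ey) / seg_len2
        t = np.clip(t, 0.0, 1.0)
        dx = px - (x1 + t * ex)
        dy = py - (y1 + t * ey)
        on_edge |= dx * dx + dy * dy <= 1e-18
    return inside & ~on_edge


def rasterize(roi: PolygonRoI, width: int, height: int) -> np.ndarray:
    """Rasterize a polygon to a boolean mask of shape ``(height, width)``.

    A pixel is set iff its center lies strictly inside the polygon (even-odd
    rule); centers on the boundary are outside. Deterministic and equivariant
    under integer translation of polygon and window together.
    """
    mask = np.zeros((height, width), dtype=bool)
    xmin = int(np.floor(roi.vertices[:, 0].min()))
    xmax = int(np.ceil(roi.vertices[:, 0].max()))
    ymin = int(np.floor(roi.vertices[:, 1].min()))
    ymax = int(np.ceil(roi.vertices[:, 1].max()))
    c0, c1 = max(0, xmin), min(width, xmax + 1)
    r0, r1 = max(0, ymin), min(height, ymax + 1)
    if c0 >= c1 or r0 >= r1:
        return mask
    cols = np.arange(c0, c1) + 0.5
    rows = np.arange(r0, r1) + 0.5
    px, py = np.meshgrid(cols, rows)
    mask[r0:r1, c0:c1] = _centers_in_polygon(px, py, roi.vertices)
    return mask


def validate_roiset(
    rs: RoISet, image_width: int, image_height: int
) -> list[str]:
    """Return human-readable warnings for an RoI set; never mutates it.

    Checks: vertices within image bounds (0.5 px tolerance), at most four
    regions, unique labels.
    """
    warnings: list[str] = []
    if len(rs.regions) > SOFT_MAX_REGIONS:
        warnings.append(
            f"{len(rs.regions)} regions defined; the original protocol marks "
            f"at most {SOFT_MAX_REGIONS} per image"
        )
    seen: set[str] = set()
    for r in rs.regions:
        if r.label in seen:
            warnings.append(f"duplicate region label {r.label!r}")
        seen.add(r.label)
        v = r.vertices
        oob = (
            (v[:, 0] < -BOUNDS_TOL)
            | (v[:, 0] > image_width + BOUNDS_TOL)
            | (v[:, 1] < -BOUNDS_TOL)
            | (v[:, 1] > image_height + BOUNDS_TOL)
        )
        for x, y in v[oob]:
            warnings.append(
                f"region {r.label!r}: vertex ({x:g}, {y:g}) outside "
                f"{image_width}x{image_height} image"
            )
    return warnings
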