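"""Width profiles along spine skeletons and the ten shape descriptors.

The width of a spine at a given arc position is the length of the chord
obtained by intersecting its plane's segmentation outline with the in-plane
line through the skeleton point, perpendicular to the local in-plane
skeleton direction.  Profiles are sampled at a nominal 20 nm arc step
(3D arc length, so the 300 nm plane pitch contributes along z); samples
that land on purely axial stretches of the skeleton, where no in-plane
direction exists, are linearly interpolated from their neighbours.
"""

from __future__ import annotations

from dataclasses import dataclass, fields

import numpy as np
from shapely.geometry import LineString, Point, Polygon

from spinemorph.io import (
    REGION_HEAD,
    REGION_NECK,
    SpineAnnotation,
    SpineSkeleton,
)

__all__ = [
    "WidthProfile",
    "SpineDescriptors",
    "MorphometryError",
    "arc_length_3d",
    "polyline_samples",
    "compute_width_profile",
    "compute_descriptors",
    "chord_length",
    "DESCRIPTOR_NAMES",
]

REGION_OTHER = "other"

#: Column order of the descriptor table.
DESCRIPTOR_NAMES = (
    "head_diameter",
    "neck_diameter",
    "head_neck_ratio",
    "spine_length",
    "spine_area",
    "neck_area",
    "head_area",
    "cv_spine",
    "cv_neck",
    "cv_head",
)


class MorphometryError(ValueError):
    pass


@dataclass
class WidthProfile:
    """Sampled diameter profile of one spine.

    ``s``: arc positions in nm (strictly increasing, starting at 0);
    ``d``: in-plane diameters in nm; ``region``: per-sample tag
    (``neck``/``head``/``other``); ``measured``: False where the diameter
    was interpolated rather than measured from an outline chord.
    """

    s: np.ndarray
    d: np.ndarray
    region: np.ndarray
    spine_id: str
    measured: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.s = np.asarray(self.s, dtype=float)
        self.d = np.asarray(self.d, dtype=float)
        self.region = np.asarray(self.region, dtype=object)
        if not (len(self.s) == len(self.d) == len(self.region)):
            raise MorphometryError(f"spine {self.spine_id}: ragged profile arrays")
        if len(self.s) and (self.s[0] != 0.0 or np.any(np.diff(self.s) <= 0)):
            raise MorphometryError(
                f"spine {self.spine_id}: arc positions must increase from 0"
            )
        if np.any(self.d <= 0):
            raise MorphometryError(f"spine {self.spine_id}: non-positive diameter")

    @property
    def length(self) -> float:
        return float(self.s[-1])


@dataclass
class SpineDescriptors:
    """The ten scalar shape measures for one spine (NaN where undefined)."""

    spine_id: str
    head_diameter: float
    neck_diameter: float
    head_neck_ratio: float
    spine_length: float
    spine_area: float
    neck_area: float
    head_area: float
    cv_spine: float
    cv_neck: float
    cv_head: float

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


def arc_length_3d(skeleton: SpineSkeleton | np.ndarray) -> float:
    """3D arc length (nm) of a skeleton polyline from attachment to tip."""
    nodes = skeleton.nodes if isinstance(skeleton, SpineSkeleton) else np.asarray(skeleton)
    if len(nodes) < 2:
        raise MorphometryError("arc length needs >= 2 nodes")
    return float(np.linalg.norm(np.diff(nodes, axis=0), axis=1).sum())


def chord_length(
    polygon: Polygon,
    point_xy: np.ndarray,
    normal_xy: np.ndarray,
    tol: float = 1e-6,
) -> float | None:
    """Length of the chord of ``polygon`` through ``point_xy`` along ``normal_xy``.

    Returns the length of the intersection component containing the point,
    or None when the point lies on no chord (i.e. outside the polygon).
    For concave outlines producing several chords, only the one next to the
    skeleton point is used.
    """
    minx, miny, maxx, maxy = polygon.bounds
    reach = np.hypot(maxx - minx, maxy - miny) + 1.0
    n = np.asarray(normal_xy, dtype=float)
    n = n / np.linalg.norm(n)
    p = np.asarray(point_xy, dtype=float)
    line = LineString([p - reach * n, p + reach * n])
    inter = polygon.intersection(line)
    if inter.is_empty:
        return None
    pt = Point(p)
    parts = getattr(inter, "geoms", [inter])
    best = None
    best_dist = np.inf
    for part in parts:
        if part.geom_type != "LineString" or part.length == 0:
            continue
        dist = part.distance(pt)
        if dist < best_dist:
            best_dist = dist
            best = part
    if best is None or best_dist > tol:
        return None
    return float(best.length)


def polyline_samples(
    nodes: np.ndarray, step_nm: float = 20.0
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Arc-step samples along a 3D polyline.

    Returns ``(s, points, tangents_xy)``: arc positions (nominal step,
    final sample exactly at the total length), 3D sample points, and unit
    in-plane tangents (NaN rows where the local segment is purely axial).
    """
    nodes = np.asarray(nodes, dtype=float)
    seg = np.diff(nodes, axis=0)
    seg_len = np.linalg.norm(seg, axis=1)
    keep = seg_len > 1e-9
    if not np.all(keep):  # collapse duplicate nodes
        nodes = np.concatenate([nodes[:1], nodes[1:][keep]])
        seg = np.diff(nodes, axis=0)
        seg_len = np.linalg.norm(seg, axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg_len)])
    total = cum[-1]

    s = np.arange(0.0, total, step_nm)
    if total - s[-1] > 1e-6:
        s = np.append(s, total)
    else:
        s[-1] = total

    seg_idx = np.clip(np.searchsorted(cum, s, side="right") - 1, 0, len(seg) - 1)
    t = (s - cum[seg_idx]) / seg_len[seg_idx]
    points = nodes[seg_idx] + t[:, None] * seg[seg_idx]
    dxy = seg[seg_idx, :2]
    lxy = np.linalg.norm(dxy, axis=1)
    tangents = np.full((len(s), 2), np.nan)
    ok = lxy > 1e-9
    tangents[ok] = dxy[ok] / lxy[ok, None]
    return s, points, tangents


def compute_width_profile(
    annotation: SpineAnnotation,
    step_nm: float = 20.0,
    plane_tol_nm: float = 160.0,
) -> WidthProfile:
    """Sample the in-plane width of a spine every ~``step_nm`` of 3D arc.

    The skeleton polyline is walked from attachment to tip; at every step
    the chord through the current point, perpendicular to the in-plane
    skeleton direction, is measured in that plane's outline.  Steps landing
    on axial (plane-to-plane) stretches are interpolated linearly in arc
    position.  Region tags are inherited from the nearest labelled node.
    """
    if not annotation.complete:
        raise MorphometryError(
            f"spine {annotation.spine_id}: incomplete spines are excluded"
        )
    if not annotation.outlines:
        raise MorphometryError(f"spine {annotation.spine_id}: no outlines")

    skel = annotation.skeleton
    s, points, tangents = polyline_samples(skel.nodes, step_nm)
    seg_len = np.linalg.norm(np.diff(skel.nodes, axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg_len)])

    outline_z = np.array([o.z for o in annotation.outlines])
    polygons = [o.polygon() for o in annotation.outlines]

    d = np.full(len(s), np.nan)
    measured = np.zeros(len(s), dtype=bool)
    for k, (sk, point, tangent) in enumerate(zip(s, points, tangents)):
        if not np.isfinite(tangent[0]):
            continue  # axial stretch: no in-plane direction, interpolate later
        iz = int(np.argmin(np.abs(outline_z - point[2])))
        if abs(outline_z[iz] - point[2]) > plane_tol_nm:
            raise MorphometryError(
                f"spine {annotation.spine_id}: no outline for skeleton plane "
                f"z={point[2]:.1f} nm (s={sk:.1f})"
            )
        normal = np.array([-tangent[1], tangent[0]])
        chord = chord_length(polygons[iz], point[:2], normal)
        if chord is None:
            raise MorphometryError(
                f"spine {annotation.spine_id}: skeleton point outside its outline "
                f"at s={sk:.1f} nm"
            )
        d[k] = chord
        measured[k] = True

    if not measured.any():
        raise MorphometryError(
            f"spine {annotation.spine_id}: no measurable sample (skeleton axial?)"
        )
    if not measured.all():
        d = np.interp(s, s[measured], d[measured])

    region = _sample_regions(s, cum, skel.region_labels)
    return WidthProfile(s=s, d=d, region=region, spine_id=annotation.spine_id,
                        measured=measured)


def _sample_regions(
    s: np.ndarray, node_arc: np.ndarray, labels: list[str]
) -> np.ndarray:
    """Tag each sample with the label of the nearest labelled node."""
    labelled = [
        (arc, lab)
        for arc, lab in zip(node_arc, labels)
        if lab in (REGION_NECK, REGION_HEAD)
    ]
    if not labelled:
        return np.array([REGION_OTHER] * len(s), dtype=object)
    arcs = np.array([a for a, _ in labelled])
    labs = [lab for _, lab in labelled]
    nearest = np.argmin(np.abs(s[:, None] - arcs[None, :]), axis=1)
    return np.array([labs[i] for i in nearest], dtype=object)


def _cv(values: np.ndarray) -> float:
    return float(np.std(values) / np.mean(values))


def compute_descriptors(profile: WidthProfile) -> SpineDescriptors:
    """Reduce a width profile to the ten scalar descriptors.

    Areas are Riemann sums of diameter over the actual sampling intervals
    (trapezoid weights, so a constant profile of diameter d and length L
    yields exactly d*L).  Head/neck descriptors are NaN when the profile
    carries no samples of that region; the spine is kept for the
    whole-spine measures.
    """
    s, d, region = profile.s, profile.d, profile.region
    w = np.empty_like(s)
    w[1:-1] = (s[2:] - s[:-2]) / 2.0
    w[0] = (s[1] - s[0]) / 2.0
    w[-1] = (s[-1] - s[-2]) / 2.0

    neck = region == REGION_NECK
    head = region == REGION_HEAD

    spine_area = float(np.sum(d * w))
    neck_area = float(np.sum(d[neck] * w[neck])) if neck.any() else float("nan")
    head_area = float(np.sum(d[head] * w[head])) if head.any() else float("nan")
    neck_diameter = float(np.min(d[neck])) if neck.any() else float("nan")
    head_diameter = float(np.max(d[head])) if head.any() else float("nan")

    return SpineDescriptors(
        spine_id=profile.spine_id,
        head_diameter=head_diameter,
        neck_diameter=neck_diameter,
        head_neck_ratio=head_diameter / neck_diameter,
        spine_length=profile.length,
        spine_area=spine_area,
        neck_area=neck_area,
        head_area=head_area,
        cv_spine=_cv(d),
        cv_neck=_cv(d[neck]) if neck.any() else float("nan"),
        cv_head=_cv(d[head]) if head.any() else float("nan"),
    )
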