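"""Synthetic spines, dendrites and image stacks with known class ground truth.

Four archetype diameter templates stand in for the morphological classes
seen in real data (stubby-like, mushroom-like, thin, filopodia-like).  Each
sampled spine gets a randomly oriented, gently bent 3D skeleton spanning
one or more 300 nm imaging planes, and per-plane "ribbon" outlines whose
local width perpendicular to the skeleton equals the (noise-perturbed)
template diameter — so measuring a noise-free spine returns its template.

Template shapes are package constants, not fitted to any dataset; they are
chosen to be qualitatively plausible and pairwise well separated.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import PchipInterpolator
from scipy.signal import fftconvolve

from spinemorph.io import (
    REGION_HEAD,
    REGION_NECK,
    REGION_UNLABELED,
    Dendrite,
    Neuron,
    NeuronDataset,
    PlaneOutline,
    SpineAnnotation,
    SpineSkeleton,
)

__all__ = [
    "ClassArchetype",
    "DendriteSpec",
    "SyntheticConfig",
    "default_archetypes",
    "sample_spine",
    "sample_dataset",
    "render_stack",
]

TEMPLATE_POINTS = 100
MIN_LENGTH_NM = 200.0


@dataclass
class ClassArchetype:
    """Ground-truth template for one morphological class.

    ``template_profile`` holds 100 diameters (nm) on the normalized arc
    coordinate u in [0, 1] (0 = dendrite attachment, 1 = tip).
    ``neck_span``/``head_span`` give the normalized arc intervals used to
    set skeleton region labels.
    """

    class_id: int
    name: str
    template_profile: np.ndarray
    neck_span: tuple[float, float]
    head_span: tuple[float, float]
    length_mean: float
    length_sd: float
    diameter_noise_cv: float = 0.15

    def __post_init__(self) -> None:
        self.template_profile = np.asarray(self.template_profile, dtype=float)
        if self.template_profile.shape != (TEMPLATE_POINTS,):
            raise ValueError("template must have 100 points")
        if np.any(self.template_profile <= 0):
            raise ValueError("template diameters must be positive")

    def diameter_at(self, u: np.ndarray | float) -> np.ndarray:
        grid = np.linspace(0.0, 1.0, TEMPLATE_POINTS)
        return np.interp(u, grid, self.template_profile)


@dataclass
class DendriteSpec:
    """Mixture recipe for one synthetic dendrite."""

    neuron_id: str
    dendrite_id: str
    mixture: tuple[float, float, float, float]
    n_spines: int

    def __post_init__(self) -> None:
        mix = np.asarray(self.mixture, dtype=float)
        if np.any(mix < 0) or abs(mix.sum() - 1.0) > 1e-9:
            raise ValueError(
                f"dendrite {self.dendrite_id}: mixture must be >= 0 and sum to 1"
            )


@dataclass
class SyntheticConfig:
    """Configuration for :func:`sample_dataset`."""

    dendrites: list[DendriteSpec]
    seed: int = 0
    scale_nm: tuple[float, float, float] = (20.0, 20.0, 300.0)
    noise_cv: float | None = None  # None: use each archetype's default
    bend_sd_rad: float = 0.05
    z_fraction_max: float = 0.35
    metadata: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Archetypes
# ---------------------------------------------------------------------------

def _template(controls: list[tuple[float, float]]) -> np.ndarray:
    u, v = zip(*controls)
    return PchipInterpolator(np.array(u), np.array(v))(
        np.linspace(0.0, 1.0, TEMPLATE_POINTS)
    )


def default_archetypes() -> list[ClassArchetype]:
    """The four built-in class archetypes.

    1. stubby-like: short, wide, with a shallow but resolvable neck;
    2. mushroom-like: large head over a narrow neck (head/neck > 2);
    3. thin: long thin neck carrying a small head;
    4. filopodia-like: long, near-uniform, monotonically tapering.
    """
    return [
        ClassArchetype(
            class_id=1,
            name="stubby-like",
            template_profile=_template(
                [(0.0, 440.0), (0.25, 360.0), (0.5, 400.0), (0.75, 490.0), (1.0, 340.0)]
            ),
            neck_span=(0.05, 0.45),
            head_span=(0.55, 1.0),
            length_mean=550.0,
            length_sd=80.0,
        ),
        ClassArchetype(
            class_id=2,
            name="mushroom-like",
            template_profile=_template(
                [(0.0, 270.0), (0.3, 120.0), (0.55, 240.0), (0.8, 750.0), (1.0, 400.0)]
            ),
            neck_span=(0.05, 0.5),
            head_span=(0.6, 1.0),
            length_mean=1150.0,
            length_sd=130.0,
        ),
        ClassArchetype(
            class_id=3,
            name="thin",
            template_profile=_template(
                [(0.0, 240.0), (0.35, 105.0), (0.65, 115.0), (0.85, 330.0), (1.0, 160.0)]
            ),
            neck_span=(0.05, 0.65),
            head_span=(0.75, 1.0),
            length_mean=1650.0,
            length_sd=170.0,
        ),
        ClassArchetype(
            class_id=4,
            name="filopodia-like",
            template_profile=_template([(0.0, 190.0), (0.5, 120.0), (1.0, 50.0)]),
            neck_span=(0.05, 0.7),
            head_span=(0.7, 1.0),
            length_mean=2500.0,
            length_sd=230.0,
        ),
    ]


# ---------------------------------------------------------------------------
# Spine sampling
# ---------------------------------------------------------------------------

def _lognormal_factors(
    rng: np.random.Generator, cv: float, n: int
) -> np.ndarray:
    """Unit-mean multiplicative lognormal noise with coefficient of variation cv."""
    if cv <= 0:
        return np.ones(n)
    sigma2 = np.log1p(cv * cv)
    sigma = np.sqrt(sigma2)
    return rng.lognormal(mean=-sigma2 / 2.0, sigma=sigma, size=n)


def sample_spine(
    archetype: ClassArchetype,
    rng: np.random.Generator,
    *,
    spine_id: str = "spine",
    plane_pitch_nm: float = 300.0,
    node_step_nm: float = 100.0,
    outline_step_nm: float = 25.0,
    bend_sd_rad: float = 0.05,
    noise_cv: float | None = None,
    z_fraction_max: float = 0.35,
    straight: bool = False,
    origin_xy: tuple[float, float] | None = None,
) -> SpineAnnotation:
    """Draw one spine from an archetype.

    Length ~ Normal(length_mean, length_sd) truncated above ``MIN_LENGTH_NM``;
    diameters are the template perturbed by unit-mean multiplicative
    lognormal noise of coefficient of variation ``noise_cv`` (archetype
    default when None).  With ``straight=True`` the skeleton is a single
    straight in-plane segment (useful for exact generator/measurer checks).
    """
    cv = archetype.diameter_noise_cv if noise_cv is None else noise_cv
    length = rng.normal(archetype.length_mean, archetype.length_sd)
    while length <= MIN_LENGTH_NM:
        length = rng.normal(archetype.length_mean, archetype.length_sd)

    noisy = archetype.template_profile * _lognormal_factors(rng, cv, TEMPLATE_POINTS)
    grid = np.linspace(0.0, 1.0, TEMPLATE_POINTS)
    # cap the per-step turn so the inner ribbon boundary cannot fold back
    max_turn = min(0.12, 0.6 * outline_step_nm / (noisy.max() / 2.0))

    def diam(u: np.ndarray | float) -> np.ndarray:
        return np.interp(u, grid, noisy)

    # --- plane layout -----------------------------------------------------
    if straight:
        n_jumps = 0
        bend_sd_rad = 0.0
    else:
        f_z = rng.uniform(0.0, z_fraction_max)
        n_jumps = int(round(length * f_z / plane_pitch_nm))
        # keep at least half the arc (and 100 nm per plane) in-plane
        while n_jumps > 0 and (
            length - n_jumps * plane_pitch_nm < max(0.5 * length, 100.0 * (n_jumps + 1))
        ):
            n_jumps -= 1
    n_planes = n_jumps + 1
    inplane_total = length - n_jumps * plane_pitch_nm
    if n_planes > 1:
        props = rng.dirichlet(np.full(n_planes, 8.0))
        props = 0.5 / n_planes + 0.5 * props  # keep every plane segment sizeable
        props /= props.sum()
    else:
        props = np.ones(1)
    plane_lengths = inplane_total * props

    z0 = float(rng.integers(0, 8)) * plane_pitch_nm
    dz = plane_pitch_nm if rng.random() < 0.5 else -plane_pitch_nm
    if dz < 0:
        z0 += n_jumps * plane_pitch_nm
    theta = rng.uniform(0.0, 2.0 * np.pi)
    if origin_xy is None:
        origin_xy = tuple(rng.uniform(0.0, 2000.0, size=2))
    pos = np.array(origin_xy, dtype=float)
    z = z0

    nodes: list[np.ndarray] = [np.array([pos[0], pos[1], z])]
    s_nodes: list[float] = [0.0]
    # per plane: list of (s, x, y) centerline samples for the outline ribbon
    plane_center: list[tuple[float, list[tuple[float, float, float]]]] = []
    s = 0.0
    for p in range(n_planes):
        seg_total = plane_lengths[p]
        m = max(1, int(np.ceil(seg_total / node_step_nm)))
        sub = seg_total / m
        center: list[tuple[float, float, float]] = [(s, pos[0], pos[1])]
        for _ in range(m):
            theta += float(np.clip(rng.normal(0.0, bend_sd_rad), -max_turn, max_turn))
            direction = np.array([np.cos(theta), np.sin(theta)])
            n_fine = max(1, int(np.ceil(sub / outline_step_nm)))
            for j in range(1, n_fine + 1):
                q = pos + direction * (sub * j / n_fine)
                center.append((s + sub * j / n_fine, q[0], q[1]))
            pos = pos + direction * sub
            s += sub
            nodes.append(np.array([pos[0], pos[1], z]))
            s_nodes.append(s)
        plane_center.append((z, center))
        if p < n_planes - 1:
            z += dz
            s += plane_pitch_nm
            nodes.append(np.array([pos[0], pos[1], z]))
            s_nodes.append(s)

    node_arr = np.array(nodes)
    s_arr = np.array(s_nodes)
    u_nodes = s_arr / length
    labels = []
    for u in u_nodes:
        if archetype.head_span[0] <= u <= archetype.head_span[1]:
            labels.append(REGION_HEAD)
        elif archetype.neck_span[0] <= u <= archetype.neck_span[1]:
            labels.append(REGION_NECK)
        else:
            labels.append(REGION_UNLABELED)
    labels[-1] = REGION_HEAD  # tip is always part of the head suffix

    outlines = [
        PlaneOutline(z=pz, vertices=_ribbon_polygon(center, diam, length))
        for pz, center in plane_center
    ]

    skeleton = SpineSkeleton(
        nodes=node_arr, region_labels=labels, spine_id=spine_id
    )
    return SpineAnnotation(
        skeleton=skeleton,
        outlines=outlines,
        complete=True,
        notes={"true_class": archetype.class_id, "true_length_nm": float(length)},
    )


def _ribbon_polygon(
    center: list[tuple[float, float, float]],
    diam,
    total_length: float,
    end_pad_nm: float = 2.0,
) -> np.ndarray:
    """Build a ribbon polygon around an in-plane centerline polyline.

    The polygon's width perpendicular to the centerline equals the target
    diameter at each arc position; ends are extended by ``end_pad_nm`` so
    skeleton endpoints lie strictly inside.
    """
    pts = np.array([(x, y) for _, x, y in center])
    arcs = np.array([a for a, _, _ in center])
    # drop duplicate consecutive points
    keep = np.concatenate([[True], np.linalg.norm(np.diff(pts, axis=0), axis=1) > 1e-9])
    pts, arcs = pts[keep], arcs[keep]
    tang = np.diff(pts, axis=0)
    tang = tang / np.linalg.norm(tang, axis=1, keepdims=True)
    # per-vertex tangent: average of adjacent segment tangents
    vt = np.empty_like(pts)
    vt[0] = tang[0]
    vt[-1] = tang[-1]
    if len(pts) > 2:
        mid = tang[:-1] + tang[1:]
        mid = mid / np.linalg.norm(mid, axis=1, keepdims=True)
        vt[1:-1] = mid
    normals = np.stack([-vt[:, 1], vt[:, 0]], axis=1)
    half = np.asarray(diam(arcs / total_length)) / 2.0

    # extend ends along the tangent so skeleton end nodes are interior
    first = pts[0] - vt[0] * end_pad_nm
    last = pts[-1] + vt[-1] * end_pad_nm
    pts = np.vstack([first, pts, last])
    normals = np.vstack([normals[0], normals, normals[-1]])
    half = np.concatenate([[half[0]], half, [half[-1]]])

    left = pts + normals * half[:, None]
    right = pts - normals * half[:, None]
    verts = np.vstack([left, right[::-1]])
    from shapely.geometry import Polygon
    from shapely.validation import make_valid

    if not Polygon(verts).is_valid:
        # sharp bends can fold the inner boundary into a sliver loop;
        # keep the dominant part of the repaired geometry
        repaired = make_valid(Polygon(verts))
        polys = (
            list(repaired.geoms) if hasattr(repaired, "geoms") else [repaired]
        )
        polys = [g for g in polys if g.geom_type == "Polygon"]
        best = max(polys, key=lambda g: g.area)
        verts = np.asarray(best.exterior.coords)[:-1]
    return verts


# ---------------------------------------------------------------------------
# Dataset sampling
# ---------------------------------------------------------------------------

def sample_dataset(
    config: SyntheticConfig,
    archetypes: list[ClassArchetype] | None = None,
) -> NeuronDataset:
    """Generate a full dataset; class per spine is a draw from its
    dendrite's mixture, and the ground-truth class is kept in the notes."""
    if archetypes is None:
        archetypes = default_archetypes()
    by_id = {a.class_id: a for a in archetypes}
    rng = np.random.default_rng(config.seed)

    neurons: dict[str, Neuron] = {}
    for spec in config.dendrites:
        neuron = neurons.setdefault(spec.neuron_id, Neuron(neuron_id=spec.neuron_id))
        dendrite = Dendrite(dendrite_id=spec.dendrite_id)
        classes = rng.choice(
            [a.class_id for a in archetypes],
            size=spec.n_spines,
            p=np.asarray(spec.mixture, dtype=float),
        )
        for i, cid in enumerate(classes):
            spine_id = f"{spec.neuron_id}_{spec.dendrite_id}_s{i:04d}"
            dendrite.spines.append(
                sample_spine(
                    by_id[int(cid)],
                    rng,
                    spine_id=spine_id,
                    bend_sd_rad=config.bend_sd_rad,
                    noise_cv=config.noise_cv,
                    z_fraction_max=config.z_fraction_max,
                    plane_pitch_nm=config.scale_nm[2],
                )
            )
        neuron.dendrites.append(dendrite)

    dataset = NeuronDataset(
        neurons=list(neurons.values()),
        scale_nm=config.scale_nm,
        metadata={"seed": config.seed, "generator": "spinemorph.synth",
                  **config.metadata},
    )
    dataset.validate()
    return dataset


def ground_truth_classes(dataset: NeuronDataset) -> dict[str, int]:
    """Map spine_id -> generator class for datasets made by this module."""
    return {
        ann.spine_id: int(ann.notes["true_class"])
        for _, _, ann in dataset.iter_spines()
        if "true_class" in ann.notes
    }


# ---------------------------------------------------------------------------
# Stack rendering
# ---------------------------------------------------------------------------

def render_stack(
    dataset: NeuronDataset,
    psf_fwhm: float = 50.0,
    photon_scale: float | None = 100.0,
    rng: np.random.Generator | None = None,
    pixel_nm: float | None = None,
    margin_nm: float = 500.0,
    shape: tuple[int, int, int] | None = None,
    origin_nm: tuple[float, float] = (0.0, 0.0),
) -> tuple[np.ndarray, np.ndarray]:
    """Rasterize outlines plane-wise, blur with a Lorentzian PSF and add
    Poisson noise.

    Returns ``(stack, ground_truth)`` as (nz, ny, nx) float arrays; the
    ground truth is the unblurred, noise-free rasterization.  With
    ``psf_fwhm <= 0`` and ``photon_scale=None`` (noise off) the stack
    equals the ground truth.
    """
    from skimage.draw import polygon as draw_polygon

    from spinemorph.deconv import lorentzian_psf

    if pixel_nm is None:
        pixel_nm = dataset.scale_nm[0]
    pitch = dataset.scale_nm[2]

    all_outlines = [
        (ann.spine_id, o) for _, _, ann in dataset.iter_spines() for o in ann.outlines
    ]
    if not all_outlines:
        raise ValueError("dataset has no outlines to render")
    zs = np.array([o.z for _, o in all_outlines])
    if shape is None:
        xy = np.vstack([o.vertices for _, o in all_outlines])
        x0 = xy[:, 0].min() - margin_nm
        y0 = xy[:, 1].min() - margin_nm
        nx = int(np.ceil((xy[:, 0].max() + margin_nm - x0) / pixel_nm))
        ny = int(np.ceil((xy[:, 1].max() + margin_nm - y0) / pixel_nm))
        z_lo = zs.min()
        nz = int(round((zs.max() - z_lo) / pitch)) + 1
        origin_nm = (x0, y0)
    else:
        nz, ny, nx = shape
        x0, y0 = origin_nm
        z_lo = zs.min()

    truth = np.zeros((nz, ny, nx), dtype=float)
    for spine_id, outline in all_outlines:
        iz = int(round((outline.z - z_lo) / pitch))
        cols = (outline.vertices[:, 0] - x0) / pixel_nm
        rows = (outline.vertices[:, 1] - y0) / pixel_nm
        if (
            iz < 0 or iz >= nz
            or cols.min() < 0 or cols.max() >= nx
            or rows.min() < 0 or rows.max() >= ny
        ):
            raise ValueError(f"spine {spine_id}: outline outside stack bounds")
        rr, cc = draw_polygon(rows, cols, shape=(ny, nx))
        truth[iz, rr, cc] += 1.0

    if psf_fwhm > 0:
        support = int(2 * np.ceil(3.0 * psf_fwhm / pixel_nm) + 1)
        kernel = lorentzian_psf(psf_fwhm, pixel_nm, support).kernel
        stack = np.stack(
            [fftconvolve(plane, kernel, mode="same") for plane in truth]
        )
    else:
        stack = truth.copy()
    if photon_scale is not None:
        if rng is None:
            raise ValueError("photon noise requested but no rng given")
        stack = rng.poisson(np.clip(stack, 0, None) * photon_scale) / photon_scale
    return stack, truth
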