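"""Domain types and readers/writers for spine annotation data.

Coordinate conventions
----------------------
All physical coordinates are in nanometres.  Voxel coordinates in NML files
are 0-based indices; a ``scale`` element gives the nm-per-voxel pitch and
physical positions refer to voxel centres.  ``x``/``y`` are lateral (in the
imaging plane), ``z`` is axial; with the default pitch of 300 nm along z,
skeleton nodes derived from a stack sit on discrete imaging planes.

Two on-disk formats are supported:

* a minimal webKnossos-style NML dialect (XML ``<things>`` with ``<thing>``
  trees of ``<node>``/``<edge>`` elements, a ``<scale>`` element and node
  comments carrying the ``neck``/``head`` region labels);
* an annotation JSON schema that bundles skeletons with per-plane
  segmentation outlines into a neuron → dendrite → spine hierarchy.
"""

from __future__ import annotations

import json
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
from shapely.geometry import Polygon

__all__ = [
    "Point3D",
    "SpineSkeleton",
    "PlaneOutline",
    "SpineAnnotation",
    "Dendrite",
    "Neuron",
    "NeuronDataset",
    "AnnotationError",
    "REGION_NECK",
    "REGION_HEAD",
    "REGION_UNLABELED",
    "read_skeleton_nml",
    "write_skeleton_nml",
    "read_annotations_json",
    "write_annotations_json",
    "write_results_tables",
]

REGION_NECK = "neck"
REGION_HEAD = "head"
REGION_UNLABELED = "unlabeled"
_VALID_REGIONS = (REGION_NECK, REGION_HEAD, REGION_UNLABELED)


class AnnotationError(ValueError):
    """Raised when an annotation file violates the data-model invariants."""


class Point3D(NamedTuple):
    """A 3D position in nanometres (x/y lateral, z axial)."""

    x: float
    y: float
    z: float


@dataclass
class SpineSkeleton:
    """Ordered centerline of one spine, from dendrite attachment to tip.

    ``nodes`` is an (n, 3) float array in nm; node 0 is the attachment
    point.  ``region_labels`` carries one of ``neck``/``head``/``unlabeled``
    per node; head nodes, when present, form a contiguous suffix and neck
    nodes a contiguous run between attachment and head.
    """

    nodes: np.ndarray
    region_labels: list[str]
    spine_id: str
    dendrite_id: str | None = None
    neuron_id: str | None = None

    def __post_init__(self) -> None:
        self.nodes = np.asarray(self.nodes, dtype=float)
        if self.nodes.ndim != 2 or self.nodes.shape[1] != 3:
            raise AnnotationError(
                f"spine {self.spine_id}: nodes must be an (n, 3) array"
            )
        if len(self.nodes) < 2:
            raise AnnotationError(f"spine {self.spine_id}: needs >= 2 nodes")
        if not np.all(np.isfinite(self.nodes)):
            raise AnnotationError(f"spine {self.spine_id}: non-finite node coordinate")
        if len(self.region_labels) != len(self.nodes):
            raise AnnotationError(
                f"spine {self.spine_id}: {len(self.region_labels)} labels for "
                f"{len(self.nodes)} nodes"
            )
        _check_region_labels(self.region_labels, self.spine_id)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)


def _check_region_labels(labels: Sequence[str], spine_id: str) -> None:
    for lab in labels:
        if lab not in _VALID_REGIONS:
            raise AnnotationError(f"spine {spine_id}: unknown region label {lab!r}")
    neck_idx = [i for i, lab in enumerate(labels) if lab == REGION_NECK]
    head_idx = [i for i, lab in enumerate(labels) if lab == REGION_HEAD]
    if neck_idx and neck_idx != list(range(neck_idx[0], neck_idx[-1] + 1)):
        raise AnnotationError(f"spine {spine_id}: neck nodes are not contiguous")
    if head_idx:
        if head_idx != list(range(head_idx[0], head_idx[-1] + 1)):
            raise AnnotationError(f"spine {spine_id}: head nodes are not contiguous")
        if head_idx[-1] != len(labels) - 1:
            raise AnnotationError(
                f"spine {spine_id}: head nodes must form a suffix ending at the tip"
            )
    if neck_idx and head_idx and neck_idx[-1] >= head_idx[0]:
        raise AnnotationError(f"spine {spine_id}: neck run must precede the head run")


@dataclass
class PlaneOutline:
    """A simple polygon outlining the spine in one imaging plane (nm)."""

    z: float
    vertices: np.ndarray

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 2:
            raise AnnotationError("outline vertices must form an (m, 2) array")
        if len(self.vertices) < 3:
            raise AnnotationError(f"outline at z={self.z}: needs >= 3 vertices")
        if not np.all(np.isfinite(self.vertices)):
            raise AnnotationError(f"outline at z={self.z}: non-finite vertex")

    def polygon(self) -> Polygon:
        return Polygon(self.vertices)


@dataclass
class SpineAnnotation:
    """One spine: skeleton + per-plane outlines + completeness flag.

    Spines with ``complete=False`` are carried through I/O but excluded
    from morphometry.  ``notes`` holds free-form metadata (e.g. a
    ground-truth class from the synthetic generator, spinule flags).
    """

    skeleton: SpineSkeleton
    outlines: list[PlaneOutline]
    complete: bool = True
    notes: dict = field(default_factory=dict)

    @property
    def spine_id(self) -> str:
        return self.skeleton.spine_id

    def validate(self, plane_tol_nm: float = 1e-3) -> None:
        """Check outline invariants: simple polygons, each on a skeleton plane."""
        node_z = self.skeleton.nodes[:, 2]
        for outline in self.outlines:
            poly = outline.polygon()
            if not poly.is_valid or poly.area <= 0:
                raise AnnotationError(
                    f"spine {self.spine_id}: outline at z={outline.z} is not a "
                    "simple polygon"
                )
            if np.min(np.abs(node_z - outline.z)) > plane_tol_nm:
                raise AnnotationError(
                    f"spine {self.spine_id}: outline at z={outline.z} has no "
                    "skeleton node in its plane"
                )


@dataclass
class Dendrite:
    dendrite_id: str
    spines: list[SpineAnnotation] = field(default_factory=list)


@dataclass
class Neuron:
    neuron_id: str
    dendrites: list[Dendrite] = field(default_factory=list)


@dataclass
class NeuronDataset:
    """Neuron → dendrite → spine hierarchy plus acquisition metadata."""

    neurons: list[Neuron] = field(default_factory=list)
    scale_nm: tuple[float, float, float] = (20.0, 20.0, 300.0)
    metadata: dict = field(default_factory=dict)

    def iter_spines(self) -> Iterator[tuple[str, str, SpineAnnotation]]:
        """Yield (neuron_id, dendrite_id, annotation) in stored order."""
        for neuron in self.neurons:
            for dendrite in neuron.dendrites:
                for spine in dendrite.spines:
                    yield neuron.neuron_id, dendrite.dendrite_id, spine

    def spine_ids(self) -> list[str]:
        return [ann.spine_id for _, _, ann in self.iter_spines()]

    def validate(self) -> None:
        seen: set[str] = set()
        for neuron_id, dendrite_id, ann in self.iter_spines():
            if ann.spine_id in seen:
                raise AnnotationError(f"duplicate spine id {ann.spine_id!r}")
            seen.add(ann.spine_id)
            ann.skeleton.dendrite_id = dendrite_id
            ann.skeleton.neuron_id = neuron_id
            ann.validate()


# ---------------------------------------------------------------------------
# NML (webKnossos-style XML)
# ---------------------------------------------------------------------------

def read_skeleton_nml(path: str | Path) -> list[SpineSkeleton]:
    """Read skeletons from a minimal webKnossos-style NML file.

    Each ``<thing>`` tree becomes one :class:`SpineSkeleton`, ordered from
    its root (the attachment point, taken as the first node listed that has
    degree <= 1).  Voxel coordinates are converted to nm using the
    ``<scale>`` element; region labels are read from node comments.
    Unknown elements are ignored.
    """
    path = Path(path)
    root = ET.parse(path).getroot()

    scale_el = root.find("./parameters/scale")
    if scale_el is None:
        scale_el = root.find("scale")
    if scale_el is None:
        raise AnnotationError(f"{path}: no <scale> element (nm per voxel) found")
    scale = np.array(
        [float(scale_el.get(ax)) for ax in ("x", "y", "z")], dtype=float
    )

    comments: dict[int, str] = {}
    for cblock in root.iter("comments"):
        for c in cblock.findall("comment"):
            comments[int(c.get("node"))] = (c.get("content") or "").strip()

    skeletons: list[SpineSkeleton] = []
    for thing in root.iter("thing"):
        thing_id = thing.get("name") or thing.get("id") or f"tree{len(skeletons)}"
        node_order: list[int] = []
        coords: dict[int, np.ndarray] = {}
        nodes_el = thing.find("nodes")
        if nodes_el is not None:
            for n in nodes_el.findall("node"):
                nid = int(n.get("id"))
                node_order.append(nid)
                coords[nid] = np.array(
                    [float(n.get("x")), float(n.get("y")), float(n.get("z"))]
                )
        adjacency: dict[int, list[int]] = {nid: [] for nid in node_order}
        edges_el = thing.find("edges")
        if edges_el is not None:
            for e in edges_el.findall("edge"):
                a, b = int(e.get("source")), int(e.get("target"))
                adjacency[a].append(b)
                adjacency[b].append(a)

        ordered = _order_path(node_order, adjacency, path, thing_id)
        nodes_nm = np.array([coords[nid] * scale for nid in ordered])
        labels = [
            comments[nid].lower() if comments.get(nid, "").lower() in
            (REGION_NECK, REGION_HEAD) else REGION_UNLABELED
            for nid in ordered
        ]
        skeletons.append(
            SpineSkeleton(nodes=nodes_nm, region_labels=labels, spine_id=str(thing_id))
        )
    return skeletons


def _order_path(
    node_order: list[int],
    adjacency: Mapping[int, list[int]],
    path: Path,
    thing_id: str,
) -> list[int]:
    """Order the nodes of a tree that must be a simple path, root first."""
    if len(node_order) == 1:
        return list(node_order)
    # connectivity check: BFS from the first node
    seen = {node_order[0]}
    frontier = [node_order[0]]
    while frontier:
        nxt = []
        for nid in frontier:
            for nb in adjacency[nid]:
                if nb not in seen:
                    seen.add(nb)
                    nxt.append(nb)
        frontier = nxt
    orphans = [nid for nid in node_order if nid not in seen]
    if orphans:
        raise AnnotationError(
            f"{path}: tree {thing_id} is disconnected; orphan nodes {orphans}"
        )
    degrees = {nid: len(adjacency[nid]) for nid in node_order}
    if any(d > 2 for d in degrees.values()):
        raise AnnotationError(
            f"{path}: tree {thing_id} branches; skeletons must be simple paths"
        )
    # root = first listed endpoint (the attachment node by convention)
    root = next(nid for nid in node_order if degrees[nid] <= 1)
    ordered = [root]
    prev = None
    cur = root
    while len(ordered) < len(node_order):
        nxt = [nb for nb in adjacency[cur] if nb != prev]
        if not nxt:
            raise AnnotationError(f"{path}: tree {thing_id} path truncated at {cur}")
        prev, cur = cur, nxt[0]
        ordered.append(cur)
    return ordered


def write_skeleton_nml(
    skeletons: Sequence[SpineSkeleton],
    path: str | Path,
    scale_nm: tuple[float, float, float] = (20.0, 20.0, 300.0),
) -> None:
    """Write skeletons to the NML dialect read by :func:`read_skeleton_nml`."""
    scale = np.asarray(scale_nm, dtype=float)
    root = ET.Element("things")
    params = ET.SubElement(root, "parameters")
    ET.SubElement(
        params,
        "scale",
        {"x": repr(float(scale[0])), "y": repr(float(scale[1])), "z": repr(float(scale[2]))},
    )
    comments = ET.Element("comments")
    next_node_id = 1
    for ti, skel in enumerate(skeletons, start=1):
        thing = ET.SubElement(root, "thing", {"id": str(ti), "name": skel.spine_id})
        nodes_el = ET.SubElement(thing, "nodes")
        edges_el = ET.SubElement(thing, "edges")
        ids = []
        for point, label in zip(skel.nodes, skel.region_labels):
            vox = point / scale
            ET.SubElement(
                nodes_el,
                "node",
                {
                    "id": str(next_node_id),
                    "x": repr(float(vox[0])),
                    "y": repr(float(vox[1])),
                    "z": repr(float(vox[2])),
                },
            )
            if label in (REGION_NECK, REGION_HEAD):
                ET.SubElement(
                    comments, "comment", {"node": str(next_node_id), "content": label}
                )
            ids.append(next_node_id)
            next_node_id += 1
        for a, b in zip(ids[:-1], ids[1:]):
            ET.SubElement(edges_el, "edge", {"source": str(a), "target": str(b)})
    root.append(comments)
    ET.ElementTree(root).write(path, xml_declaration=True, encoding="unicode")


# ---------------------------------------------------------------------------
# Annotation JSON
# ---------------------------------------------------------------------------

def read_annotations_json(path: str | Path) -> NeuronDataset:
    """Read and fully validate a :class:`NeuronDataset` from annotation JSON."""
    path = Path(path)
    with open(path) as fh:
        doc = json.load(fh)
    try:
        scale = tuple(float(v) for v in doc["scale_nm"])
    except KeyError as exc:
        raise AnnotationError(f"{path}: missing scale_nm") from exc
    dataset = NeuronDataset(scale_nm=scale, metadata=doc.get("metadata", {}))
    for neuron_doc in doc.get("neurons", []):
        neuron = Neuron(neuron_id=str(neuron_doc["id"]))
        for dend_doc in neuron_doc.get("dendrites", []):
            dendrite = Dendrite(dendrite_id=str(dend_doc["id"]))
            for spine_doc in dend_doc.get("spines", []):
                skeleton = SpineSkeleton(
                    nodes=np.asarray(spine_doc["nodes"], dtype=float),
                    region_labels=list(spine_doc["region_labels"]),
                    spine_id=str(spine_doc["id"]),
                    dendrite_id=dendrite.dendrite_id,
                    neuron_id=neuron.neuron_id,
                )
                outlines = [
                    PlaneOutline(
                        z=float(o["z"]),
                        vertices=np.asarray(o["vertices"], dtype=float),
                    )
                    for o in spine_doc.get("outlines", [])
                ]
                dendrite.spines.append(
                    SpineAnnotation(
                        skeleton=skeleton,
                        outlines=outlines,
                        complete=bool(spine_doc.get("complete", True)),
                        notes=dict(spine_doc.get("notes", {})),
                    )
                )
            neuron.dendrites.append(dendrite)
        dataset.neurons.append(neuron)
    dataset.validate()
    return dataset


def write_annotations_json(dataset: NeuronDataset, path: str | Path) -> None:
    doc = {
        "scale_nm": list(dataset.scale_nm),
        "metadata": dataset.metadata,
        "neurons": [
            {
                "id": neuron.neuron_id,
                "dendrites": [
                    {
                        "id": dendrite.dendrite_id,
                        "spines": [
                            {
                                "id": ann.spine_id,
                                "complete": ann.complete,
                                "nodes": ann.skeleton.nodes.tolist(),
                                "region_labels": list(ann.skeleton.region_labels),
                                "outlines": [
                                    {"z": o.z, "vertices": o.vertices.tolist()}
                                    for o in ann.outlines
                                ],
                                "notes": ann.notes,
                            }
                            for ann in dendrite.spines
                        ],
                    }
                    for dendrite in neuron.dendrites
                ],
            }
            for neuron in dataset.neurons
        ],
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)


# ---------------------------------------------------------------------------
# Result tables
# ---------------------------------------------------------------------------

def write_results_tables(
    dataset: NeuronDataset,
    descriptors: pd.DataFrame,
    labels: Mapping[str, int],
    stats: pd.DataFrame,
    out_dir: str | Path,
) -> dict[str, Path]:
    """Write the CSV result bundle; returns the paths written.

    ``descriptors`` must be indexed (or keyed by a ``spine_id`` column) by
    spine id; ``labels`` maps spine id to class label.  Row order is
    deterministic: dataset order (neuron, dendrite, spine).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    desc = descriptors.copy()
    if "spine_id" in desc.columns:
        desc = desc.set_index("spine_id")

    rows = []
    counts: dict[tuple[str, str], dict[int, int]] = {}
    for neuron_id, dendrite_id, ann in dataset.iter_spines():
        if not ann.complete:  # excluded from morphometry, so not tabulated
            continue
        sid = ann.spine_id
        if sid not in desc.index or sid not in labels:
            raise AnnotationError(
                f"spine {sid}: missing from descriptor table or label map"
            )
        row = {"neuron_id": neuron_id, "dendrite_id": dendrite_id, "spine_id": sid}
        row.update(desc.loc[sid].to_dict())
        row["class"] = int(labels[sid])
        rows.append(row)
        key = (neuron_id, dendrite_id)
        counts.setdefault(key, {})[row["class"]] = (
            counts.setdefault(key, {}).get(row["class"], 0) + 1
        )

    desc_path = out_dir / "descriptors.csv"
    pd.DataFrame(rows).to_csv(desc_path, index=False)

    classes = sorted({int(v) for v in labels.values()})
    count_rows = [
        {
            "neuron_id": nid,
            "dendrite_id": did,
            **{f"class_{c}": counts[(nid, did)].get(c, 0) for c in classes},
        }
        for (nid, did) in counts
    ]
    counts_path = out_dir / "class_counts.csv"
    pd.DataFrame(count_rows).to_csv(counts_path, index=False)

    stats_path = out_dir / "stats.csv"
    stats_cols = ["test", "comparison", "statistic", "df", "p", "p_adjusted"]
    stats_out = stats if len(stats) else pd.DataFrame(columns=stats_cols)
    stats_out.to_csv(stats_path, index=False)

    return {"descriptors": desc_path, "class_counts": counts_path, "stats": stats_path}
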