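"""From dense per-class confidence grids to discrete pharmacophore features.

Pipeline: grid the binding-site box at 0.5 Å and evaluate the predictor at
every point; binarize each class at 0.5 and label 26-connected components;
for each component, emit its top-confidence voxel for every complementary
protein group within the class's distance cutoff; merge nearby points by
average-linkage agglomerative clustering with a 1.5 Å criterion and take
cluster centroids as the final features.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.cluster.hierarchy import fcluster, linkage

from .errors import ContractError
from .features import N_CLASSES, FeatureClass, PharmFeature
from .protein import COMPLEMENTARY_GROUP, DEFAULT_COMP_DIST, ProteinStructure


@dataclass
class ConfidenceGrid:
    """Per-class confidences on a regular grid over an axis-aligned box."""

    values: np.ndarray  # (6, nx, ny, nz) in [0, 1]
    origin: np.ndarray
    spacing: float = 0.5

    def __post_init__(self):
        self.origin = np.asarray(self.origin, dtype=float)
        if self.spacing <= 0:
            raise ValueError("spacing must be > 0")

    def voxel_coords(self, idx: np.ndarray) -> np.ndarray:
        return self.origin + self.spacing * np.asarray(idx, dtype=float)


@dataclass
class GridComponent:
    cls: FeatureClass
    voxel_indices: np.ndarray  # (n, 3) int
    confidences: np.ndarray  # (n,)


@dataclass
class ExtractionConfig:
    binarize_threshold: float = 0.5
    cluster_merge_dist: float = 1.5
    comp_group_dist: dict = field(
        default_factory=lambda: dict(DEFAULT_COMP_DIST))

    def __post_init__(self):
        if not 0.0 < self.binarize_threshold < 1.0:
            raise ValueError("binarize_threshold must lie in (0, 1)")
        if self.cluster_merge_dist <= 0:
            raise ValueError("cluster_merge_dist must be > 0")


# 26-connectivity: any of the 3x3x3 neighbours counts as adjacent; at
# 0.5 Å spacing even a diagonal contact is well below bond length.
_STRUCTURE_26 = np.ones((3, 3, 3), dtype=int)


def evaluate_grid(model, protein: ProteinStructure, box,
                  spacing: float = 0.5) -> ConfidenceGrid:
    """Evaluate the predictor on every grid point of ``box``.

    ``box`` is a pair of corner coordinates (lower, upper); a box spanning
    L Å along an axis yields L/spacing + 1 evaluation points on that axis.
    """
    lo = np.asarray(box[0], dtype=float)
    hi = np.asarray(box[1], dtype=float)
    ns = [int(round((hi[d] - lo[d]) / spacing)) + 1 for d in range(3)]
    if any(n < 1 for n in ns) or np.any(hi < lo):
        raise ContractError("box must have positive extent")
    axes = [lo[d] + spacing * np.arange(ns[d]) for d in range(3)]
    pts = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, 3)
    conf, _ = model.predict_points(protein, pts)
    values = np.transpose(conf.reshape(ns[0], ns[1], ns[2], N_CLASSES),
                          (3, 0, 1, 2))
    return ConfidenceGrid(values, lo, spacing)


def find_components(grid: ConfidenceGrid,
                    config: ExtractionConfig | None = None) -> list[GridComponent]:
    """Per class: binarize (strict >) and label 26-connected components.

    Components are ordered by (class code, lexicographically smallest
    voxel index).
    """
    config = config or ExtractionConfig()
    out = []
    for cls in FeatureClass:
        mask = grid.values[cls] > config.binarize_threshold
        labels, n = ndimage.label(mask, structure=_STRUCTURE_26)
        comps = []
        for lab in range(1, n + 1):
            idx = np.argwhere(labels == lab)
            idx = idx[np.lexsort((idx[:, 2], idx[:, 1], idx[:, 0]))]
            conf = grid.values[cls][idx[:, 0], idx[:, 1], idx[:, 2]]
            comps.append(GridComponent(cls, idx, conf))
        comps.sort(key=lambda c: tuple(c.voxel_indices[0]))
        out.extend(comps)
    return out


def select_component_points(component: GridComponent, grid: ConfidenceGrid,
                            protein: ProteinStructure,
                            config: ExtractionConfig | None = None
                            ) -> list[np.ndarray]:
    """Top-confidence component voxels supported by complementary groups.

    For each complementary protein group within the class's distance cutoff
    of any voxel of the component, the component voxel with the highest
    confidence among those within the cutoff of that group is emitted.
    Duplicates collapse; ties break toward the lexicographically smallest
    voxel index.
    """
    config = config or ExtractionConfig()
    cutoff = config.comp_group_dist[component.cls]
    kind = COMPLEMENTARY_GROUP[component.cls]
    sites = protein.group_positions(kind)
    if sites.size == 0:
        return []
    coords = grid.voxel_coords(component.voxel_indices)
    picked: list[tuple] = []
    out: list[np.ndarray] = []
    for site in sites:
        d = np.linalg.norm(coords - site, axis=1)
        in_range = d <= cutoff
        if not in_range.any():
            continue
        conf = np.where(in_range, component.confidences, -np.inf)
        # voxel_indices are lexicographically sorted, so the first argmax
        # is the smallest-index tie-break
        best = int(np.argmax(conf))
        key = tuple(component.voxel_indices[best])
        if key not in picked:
            picked.append(key)
            out.append(coords[best])
    return out


def cluster_points(points: list[PharmFeature],
                   config: ExtractionConfig | None = None) -> list[PharmFeature]:
    """Average-linkage agglomerative clustering, merged while linkage <= 1.5 Å.

    Clustering is per class (classes never merge).  Each cluster becomes one
    feature at the unweighted centroid, carrying the maximum member
    confidence.  Points are canonically sorted first, so the result is
    invariant under input permutation.
    """
    config = config or ExtractionConfig()
    out: list[PharmFeature] = []
    for cls in FeatureClass:
        members = [p for p in points if p.cls == cls]
        if not members:
            continue
        members.sort(key=lambda p: (p.position[0], p.position[1], p.position[2]))
        X = np.array([p.position for p in members])
        if len(members) == 1:
            assignment = np.array([1])
        else:
            Z = linkage(X, method="average")
            assignment = fcluster(Z, t=config.cluster_merge_dist,
                                  criterion="distance")
        for lab in np.unique(assignment):
            grp = [m for m, a in zip(members, assignment) if a == lab]
            centroid = np.mean([m.position for m in grp], axis=0)
            confs = [m.confidence for m in grp if m.confidence is not None]
            out.append(PharmFeature(centroid, cls,
                                    confidence=max(confs) if confs else None))
    out.sort(key=lambda f: (int(f.cls), f.position[0], f.position[1],
                            f.position[2]))
    return out


def extract_features(model, protein: ProteinStructure, box,
                     config: ExtractionConfig | None = None,
                     spacing: float = 0.5) -> list[PharmFeature]:
    """Full extraction pipeline; features carry class, centroid position,
    confidence, and the predictor embedding evaluated at the centroid."""
    config = config or ExtractionConfig()
    grid = evaluate_grid(model, protein, box, spacing)
    components = find_components(grid, config)
    raw: list[PharmFeature] = []
    for comp in components:
        for pos in select_component_points(comp, grid, protein, config):
            idx = np.round((pos - grid.origin) / grid.spacing).astype(int)
            conf = float(grid.values[comp.cls][idx[0], idx[1], idx[2]])
            raw.append(PharmFeature(pos, comp.cls, confidence=conf))
    feats = cluster_points(raw, config)
    if feats:
        centroids = np.array([f.position for f in feats])
        conf, emb = model.predict_points(protein, centroids)
        for i, f in enumerate(feats):
            f.embedding = emb[i]
    return feats


def box_from_points(points: np.ndarray, pad: float = 4.0):
    """Axis-aligned bounding box of ``points`` expanded by ``pad`` Å."""
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    return pts.min(axis=0) - pad, pts.max(axis=0) + pad
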