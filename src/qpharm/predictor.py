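"""Voxel encoding of local protein environments and the point predictor.

The predictor answers, for any query point in a binding site: which of the
six feature classes are plausible at this point (independent multilabel
confidences), and what does the local environment look like (a latent
embedding, 32-dimensional by default, taken from the final hidden layer)?

The input encoding is a cubic box of edge 9.5 Å sampled at 0.5 Å
resolution (20 grid points per edge), centered at the query point, with
one channel per atom type.  Each heavy atom contributes a truncated
Gaussian density scaled to its van der Waals radius.

The reference trainable model is a compact fully-connected network over a
block-averaged voxel grid; the architecture is configurable and
deliberately small so it trains on a CPU at synthetic-fixture scale.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .errors import ContractError
from .features import N_CLASSES, FeatureClass
from .nn import MLP
from .protein import (COMPLEMENTARY_GROUP, DEFAULT_COMP_DIST,
                      CHANNEL_NAMES, ProteinStructure, atom_channel, vdw_radius)


@dataclass
class PredictorConfig:
    """Geometry and shape of the point-predictor input/output."""

    box_edge: float = 9.5
    resolution: float = 0.5
    channels: tuple[str, ...] = CHANNEL_NAMES
    embedding_size: int = 32
    gaussian_width_scale: float = 1.0
    hidden_size: int = 64
    pool: int = 4  # block-averaging factor applied to the voxel grid

    def __post_init__(self):
        n = self.box_edge / self.resolution + 1
        if abs(n - round(n)) > 1e-9:
            raise ValueError("box_edge/resolution must give an integer point count")
        if self.embedding_size < 1:
            raise ValueError("embedding_size must be >= 1")

    @property
    def points_per_edge(self) -> int:
        # grid points at 0, res, ..., box_edge  ->  edge/res + 1 points
        return int(round(self.box_edge / self.resolution)) + 1

    @property
    def n_channels(self) -> int:
        return len(self.channels)


@dataclass
class VoxelGrid:
    values: np.ndarray  # (channel, i, j, k), all >= 0
    origin: np.ndarray
    resolution: float


@dataclass
class PointPrediction:
    confidences: np.ndarray  # (6,) in [0, 1], multilabel
    embedding: np.ndarray


@dataclass
class TrainingSample:
    protein_ref: ProteinStructure
    point: np.ndarray
    labels: np.ndarray  # (6,) of {0, 1}
    is_adversarial: bool = False

    def __post_init__(self):
        self.point = np.asarray(self.point, dtype=float)
        self.labels = np.asarray(self.labels, dtype=float)
        if self.is_adversarial and self.labels.any():
            raise ValueError("adversarial samples must have all-zero labels")


#: Gaussian truncation radius in units of the vdW radius.  At 3 r the kernel
#: value is e^-18, so the discrete grid mass matches the closed-form integral
#: of the truncated kernel to high accuracy.
TRUNCATION_FACTOR = 3.0


def _kernel_sigma(r_vdw: float, scale: float) -> float:
    # density exp(-2 d^2 / r^2)  <=>  Gaussian with sigma = r/2
    return 0.5 * r_vdw * scale


def analytic_kernel_mass(r_vdw: float, scale: float = 1.0) -> float:
    """Closed-form integral of one atom's truncated Gaussian density (Å³)."""
    from scipy.special import erf

    s = _kernel_sigma(r_vdw, scale)
    R = TRUNCATION_FACTOR * r_vdw * scale
    u = R / (np.sqrt(2.0) * s)
    return float((2 * np.pi * s * s) ** 1.5
                 * (erf(u) - np.sqrt(2.0 / np.pi) * (R / s) * np.exp(-u * u)))


def voxelize(protein: ProteinStructure, center, config: PredictorConfig) -> VoxelGrid:
    """Typed Gaussian atom densities on a cubic grid centered at ``center``.

    Additive over atoms; atoms outside the box contribute nothing; exactly
    translation-covariant because densities are evaluated at grid-point
    coordinates relative to each atom.
    """
    center = np.asarray(center, dtype=float)
    n = config.points_per_edge
    res = config.resolution
    origin = center - config.box_edge / 2.0
    values = np.zeros((config.n_channels, n, n, n))
    axis = origin[:, None] + res * np.arange(n)[None, :]  # (3, n)

    for atom in protein.atoms:
        ch = atom_channel(atom)
        if ch is None:
            continue
        r = vdw_radius(atom)
        sigma = _kernel_sigma(r, config.gaussian_width_scale)
        trunc = TRUNCATION_FACTOR * r * config.gaussian_width_scale
        lo = atom.position - trunc
        hi = atom.position + trunc
        sl = []
        ok = True
        for d in range(3):
            i0 = max(0, int(np.ceil((lo[d] - origin[d]) / res)))
            i1 = min(n - 1, int(np.floor((hi[d] - origin[d]) / res)))
            if i0 > i1:
                ok = False
                break
            sl.append((i0, i1))
        if not ok:
            continue
        dx = axis[0, sl[0][0]:sl[0][1] + 1] - atom.position[0]
        dy = axis[1, sl[1][0]:sl[1][1] + 1] - atom.position[1]
        dz = axis[2, sl[2][0]:sl[2][1] + 1] - atom.position[2]
        d2 = (dx[:, None, None] ** 2 + dy[None, :, None] ** 2
              + dz[None, None, :] ** 2)
        g = np.exp(-d2 / (2.0 * sigma * sigma))
        g[d2 > trunc * trunc] = 0.0
        values[ch, sl[0][0]:sl[0][1] + 1, sl[1][0]:sl[1][1] + 1,
               sl[2][0]:sl[2][1] + 1] += g
    return VoxelGrid(values, origin, res)


def _pooled_features(values: np.ndarray, pool: int) -> np.ndarray:
    """Block-average each channel by ``pool`` and flatten to one vector."""
    c, n = values.shape[0], values.shape[1]
    m = n // pool
    v = values[:, :m * pool, :m * pool, :m * pool]
    v = v.reshape(c, m, pool, m, pool, m, pool).mean(axis=(2, 4, 6))
    return v.reshape(-1)


class ReferencePredictor:
    """Trainable point predictor: pooled voxel grid -> MLP -> 6 confidences.

    The final hidden layer (width ``embedding_size``) is exposed as the
    per-point embedding.  A zero-initialized model outputs confidence 0.5
    everywhere (sigmoid of zero logits).
    """

    def __init__(self, config: PredictorConfig | None = None, seed: int = 0,
                 zero_init: bool = False):
        self.config = config or PredictorConfig()
        m = self.config.points_per_edge // self.config.pool
        in_dim = self.config.n_channels * m ** 3
        self.net = MLP([in_dim, self.config.hidden_size,
                        self.config.embedding_size, N_CLASSES],
                       activation="relu", out="sigmoid", seed=seed,
                       zero_init=zero_init)
        self.loss_trace: list[float] = []

    # -- point-model protocol ------------------------------------------
    @property
    def embedding_size(self) -> int:
        return self.config.embedding_size

    def featurize(self, protein: ProteinStructure, points: np.ndarray) -> np.ndarray:
        points = np.atleast_2d(np.asarray(points, dtype=float))
        rows = [
            _pooled_features(voxelize(protein, p, self.config).values,
                             self.config.pool)
            for p in points
        ]
        return np.array(rows)

    def predict_points(self, protein: ProteinStructure,
                       points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Confidences (n, 6) and embeddings (n, embedding_size)."""
        X = self.featurize(protein, points)
        conf = self.net.predict(X)
        emb = self.net.hidden(X)
        if conf.shape[1] != N_CLASSES or emb.shape[1] != self.config.embedding_size:
            raise ContractError("model output shapes do not match the config")
        return conf, emb

    # -- persistence ---------------------------------------------------
    def save(self, path) -> None:
        doc = {
            "config": {
                "box_edge": self.config.box_edge,
                "resolution": self.config.resolution,
                "channels": list(self.config.channels),
                "embedding_size": self.config.embedding_size,
                "gaussian_width_scale": self.config.gaussian_width_scale,
                "hidden_size": self.config.hidden_size,
                "pool": self.config.pool,
            },
            "net": self.net.state_dict(),
            "loss_trace": self.loss_trace,
        }
        Path(path).write_text(json.dumps(doc))

    @classmethod
    def load(cls, path) -> "ReferencePredictor":
        doc = json.loads(Path(path).read_text())
        cfg = doc["config"]
        cfg["channels"] = tuple(cfg["channels"])
        model = cls(PredictorConfig(**cfg))
        model.net = MLP.from_state_dict(doc["net"])
        model.loss_trace = list(doc.get("loss_trace", []))
        return model


def predict_point(model, protein: ProteinStructure, point,
                  config: PredictorConfig | None = None) -> PointPrediction:
    """Evaluate the predictor at one point.

    ``model`` is anything implementing ``predict_points(protein, points)``
    (the trainable reference model or a synthetic oracle).
    """
    conf, emb = model.predict_points(protein, np.atleast_2d(point))
    return PointPrediction(conf[0], emb[0])


# ---------------------------------------------------------------------
# adversarial-negative mining
# ---------------------------------------------------------------------

#: A prediction closer than this to any protein heavy atom is implausible
#: (steric clash) and mined as a negative.
DEFAULT_CLASH_DIST = 2.0
#: Multilabel logistic midpoint: a class "fires" above this confidence.
FIRE_THRESHOLD = 0.5


def _box_grid(box, spacing: float) -> np.ndarray:
    lo = np.asarray(box[0], dtype=float)
    hi = np.asarray(box[1], dtype=float)
    axes = [lo[d] + spacing * np.arange(int(round((hi[d] - lo[d]) / spacing)) + 1)
            for d in range(3)]
    pts = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, 3)
    return pts


def _min_dist(points: np.ndarray, targets: np.ndarray) -> np.ndarray:
    if targets.size == 0:
        return np.full(len(points), np.inf)
    from scipy.spatial import cKDTree

    return cKDTree(targets).query(points)[0]


def generate_adversarial_negatives(model, protein: ProteinStructure, box,
                                   config: PredictorConfig | None = None,
                                   clash_dist: float = DEFAULT_CLASH_DIST,
                                   comp_dist: dict | None = None,
                                   spacing: float = 0.5) -> list[TrainingSample]:
    """Mine physically implausible firing predictions as all-negative samples.

    A grid point (0.5 Å spacing over ``box``) where some class fires above
    0.5 becomes an adversarial negative if it clashes with the protein
    (distance to the nearest heavy atom < ``clash_dist``) or if the fired
    class has no complementary protein group within its distance cutoff
    (e.g. a hydrogen-acceptor prediction more than 4 Å from every donor
    group).  Deterministic and idempotent.
    """
    comp_dist = dict(DEFAULT_COMP_DIST) if comp_dist is None else comp_dist
    pts = _box_grid(box, spacing)
    conf, _ = model.predict_points(protein, pts)
    heavy = protein.heavy_coords
    d_heavy = _min_dist(pts, heavy)
    samples = []
    d_group = {}
    for cls in FeatureClass:
        kind = COMPLEMENTARY_GROUP[cls]
        d_group[cls] = _min_dist(pts, protein.group_positions(kind))
    flagged = np.zeros(len(pts), dtype=bool)
    for cls in FeatureClass:
        fired = conf[:, cls] > FIRE_THRESHOLD
        bad = fired & ((d_heavy < clash_dist) | (d_group[cls] > comp_dist[cls]))
        flagged |= bad
    for i in np.nonzero(flagged)[0]:
        samples.append(TrainingSample(protein, pts[i], np.zeros(N_CLASSES),
                                      is_adversarial=True))
    return samples


def train_predictor(samples: list[TrainingSample],
                    config: PredictorConfig | None = None, seed: int = 0,
                    epochs: int = 150, lr: float = 3e-3,
                    batch_size: int = 32) -> ReferencePredictor:
    """Fit the reference predictor by per-class binary cross-entropy.

    Reproducible under ``seed``; the per-epoch loss trace is stored on the
    returned model.  A dataset without both positives and negatives trains
    with a warning (every class degenerate).
    """
    if not samples:
        raise ValueError("no training samples")
    config = config or PredictorConfig()
    Y = np.array([s.labels for s in samples], dtype=float)
    if np.all(Y == Y[0]):
        warnings.warn("degenerate training set: every sample carries the "
                      "same label vector", stacklevel=2)
    model = ReferencePredictor(config, seed=seed)
    X = np.vstack([
        model.featurize(s.protein_ref, s.point[None, :]) for s in samples
    ])
    model.loss_trace = model.net.fit(X, Y, loss="bce", epochs=epochs,
                                     batch_size=batch_size, lr=lr, seed=seed)
    return model
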