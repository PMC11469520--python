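"""Pharmacophore feature types and Pharmit-compatible JSON I/O.

A pharmacophore is a set of typed 3D interaction points.  Each point has a
Cartesian position (Å), one of six chemical feature classes, and a match
tolerance radius.  Points may additionally carry a unit direction vector
(stored but not used by the matcher), a prediction confidence, and a latent
embedding of the local protein environment.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import FormatError


class FeatureClass(enum.IntEnum):
    """The six pharmacophore feature classes, with stable integer codes."""

    HydrogenAcceptor = 0
    HydrogenDonor = 1
    Hydrophobic = 2
    Aromatic = 3
    NegativeIon = 4
    PositiveIon = 5


N_CLASSES = len(FeatureClass)

#: Pharmit point names map 1:1 onto FeatureClass member names.
PHARMIT_NAMES = {cls.name: cls for cls in FeatureClass}


def _as_vec3(x) -> np.ndarray:
    v = np.asarray(x, dtype=float)
    if v.shape != (3,):
        raise ValueError(f"expected a 3-vector, got shape {v.shape}")
    if not np.all(np.isfinite(v)):
        raise ValueError("coordinates must be finite")
    return v


@dataclass
class PharmFeature:
    """One typed interaction point.

    Parameters
    ----------
    position : (3,) array-like, Å
    cls : FeatureClass
    radius : float, Å
        Match tolerance used by the screener (default 1.0 Å).
    direction : optional unit 3-vector
        Orientation for directional classes; stored and round-tripped,
        ignored by the matcher.
    confidence : optional float in [0, 1]
    embedding : optional 1-D array
        Latent descriptor of the local protein environment (length 32 under
        the default predictor configuration).
    """

    position: np.ndarray
    cls: FeatureClass
    radius: float = 1.0
    direction: np.ndarray | None = None
    confidence: float | None = None
    embedding: np.ndarray | None = None

    def __post_init__(self):
        self.position = _as_vec3(self.position)
        self.cls = FeatureClass(self.cls)
        if not self.radius > 0:
            raise ValueError("radius must be > 0")
        if self.direction is not None:
            self.direction = _as_vec3(self.direction)
            if abs(float(np.linalg.norm(self.direction)) - 1.0) > 1e-6:
                raise ValueError("direction must have unit norm")
        if self.confidence is not None:
            self.confidence = float(self.confidence)
            if not 0.0 <= self.confidence <= 1.0:
                raise ValueError("confidence must lie in [0, 1]")
        if self.embedding is not None:
            self.embedding = np.asarray(self.embedding, dtype=float).ravel()

    def translated(self, dv) -> "PharmFeature":
        return PharmFeature(
            self.position + _as_vec3(dv), self.cls, self.radius,
            None if self.direction is None else self.direction.copy(),
            self.confidence,
            None if self.embedding is None else self.embedding.copy(),
        )


@dataclass
class Pharmacophore:
    """An ordered set of pharmacophore features.

    Two features of the same class closer than 0.1 Å are considered
    duplicates and rejected, which keeps downstream graphs simple.
    """

    features: list[PharmFeature] = field(default_factory=list)
    name: str = "pharmacophore"

    def __post_init__(self):
        for i, a in enumerate(self.features):
            for b in self.features[i + 1:]:
                if a.cls == b.cls and np.linalg.norm(a.position - b.position) < 0.1:
                    raise ValueError(
                        f"duplicate {a.cls.name} features closer than 0.1 Å"
                    )

    def __len__(self) -> int:
        return len(self.features)

    @property
    def positions(self) -> np.ndarray:
        return np.array([f.position for f in self.features], dtype=float)

    @property
    def classes(self) -> list[FeatureClass]:
        return [f.cls for f in self.features]


def _feature_to_point(feat: PharmFeature) -> dict:
    pt = {
        "name": feat.cls.name,
        "x": float(feat.position[0]),
        "y": float(feat.position[1]),
        "z": float(feat.position[2]),
        "radius": float(feat.radius),
        "enabled": True,
    }
    if feat.direction is not None:
        pt["svector"] = {
            "x": float(feat.direction[0]),
            "y": float(feat.direction[1]),
            "z": float(feat.direction[2]),
        }
    if feat.confidence is not None:
        pt["confidence"] = float(feat.confidence)
    if feat.embedding is not None:
        pt["embedding"] = [float(v) for v in feat.embedding]
    return pt


def _point_to_feature(pt: dict) -> PharmFeature | None:
    if not pt.get("enabled", True):
        return None
    name = pt.get("name")
    if name not in PHARMIT_NAMES:
        raise FormatError(
            f"unknown pharmacophore point name {name!r}; accepted names: "
            + ", ".join(sorted(PHARMIT_NAMES))
        )
    direction = None
    sv = pt.get("svector")
    if sv is not None:
        d = np.array([sv["x"], sv["y"], sv["z"]], dtype=float)
        n = np.linalg.norm(d)
        if n > 0:
            direction = d / n
    return PharmFeature(
        position=[pt["x"], pt["y"], pt["z"]],
        cls=PHARMIT_NAMES[name],
        radius=float(pt.get("radius", 1.0)),
        direction=direction,
        confidence=pt.get("confidence"),
        embedding=pt.get("embedding"),
    )


def write_pharmacophore(pharm: Pharmacophore, path) -> None:
    """Serialize to Pharmit-style JSON with a ``points`` array."""
    doc = {"points": [_feature_to_point(f) for f in pharm.features]}
    Path(path).write_text(json.dumps(doc, indent=1))


def read_pharmacophore(path) -> Pharmacophore:
    """Read a Pharmit-style JSON pharmacophore; disabled points are skipped."""
    try:
        doc = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise FormatError(f"malformed pharmacophore JSON in {path}: {exc}") from exc
    if not isinstance(doc, dict) or "points" not in doc:
        raise FormatError(f"pharmacophore JSON in {path} lacks a 'points' array")
    feats = []
    for pt in doc["points"]:
        f = _point_to_feature(pt)
        if f is not None:
            feats.append(f)
    return Pharmacophore(features=feats, name=str(Path(path).stem))
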