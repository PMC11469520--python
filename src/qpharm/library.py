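"""Molecule feature libraries: per-molecule typed 3D feature points.

A library is a JSON Lines file with one molecule per line::

    {"id": "mol1", "is_active": true,
     "features": [{"name": "HydrogenDonor", "x": 1.0, "y": 0.0, "z": 0.0}, ...],
     "atoms": [[1.0, 0.0, 0.0], ...]}

Multi-conformer molecules are represented as multiple records sharing an
``id``; a molecule counts as matched if any of its records matches.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np

from .errors import FormatError
from .features import PHARMIT_NAMES, PharmFeature


@dataclass
class MoleculeRecord:
    id: str
    features: list[PharmFeature]
    atoms: np.ndarray | None = None  # (n, 3) heavy-atom coordinates
    is_active: bool = False

    def __post_init__(self):
        if not self.features:
            raise ValueError("a molecule record needs at least one feature")
        if self.atoms is not None:
            self.atoms = np.asarray(self.atoms, dtype=float).reshape(-1, 3)

    @property
    def positions(self) -> np.ndarray:
        return np.array([f.position for f in self.features], dtype=float)


def write_library(records: Iterable[MoleculeRecord], path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            doc = {
                "id": rec.id,
                "is_active": bool(rec.is_active),
                "features": [
                    {"name": f.cls.name,
                     "x": float(f.position[0]), "y": float(f.position[1]),
                     "z": float(f.position[2]), "radius": float(f.radius)}
                    for f in rec.features
                ],
            }
            if rec.atoms is not None:
                doc["atoms"] = [[float(v) for v in row] for row in rec.atoms]
            fh.write(json.dumps(doc) + "\n")


def read_library(path) -> list[MoleculeRecord]:
    records = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        try:
            doc = json.loads(line)
        except json.JSONDecodeError as exc:
            raise FormatError(f"{path}:{lineno}: malformed JSON: {exc}") from exc
        feats = []
        for pt in doc.get("features", []):
            name = pt.get("name")
            if name not in PHARMIT_NAMES:
                raise FormatError(
                    f"{path}:{lineno}: unknown feature name {name!r}")
            feats.append(PharmFeature([pt["x"], pt["y"], pt["z"]],
                                      PHARMIT_NAMES[name],
                                      radius=float(pt.get("radius", 1.0))))
        records.append(MoleculeRecord(
            id=str(doc["id"]),
            features=feats,
            atoms=doc.get("atoms"),
            is_active=bool(doc.get("is_active", False)),
        ))
    return records
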