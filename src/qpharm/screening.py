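"""Pharmacophore matching and library screening.

A molecule matches a pharmacophore if there is an injective,
class-consistent assignment of pharmacophore features to molecule features
and a proper rigid transform (rotation + translation, no reflection)
placing every assigned molecule feature within the corresponding feature's
tolerance radius.  The search prunes candidate assignments with pairwise
distance compatibility and verifies survivors by least-squares
superposition.  Pharmacophores with fewer than 3 features are refused,
mirroring the screening tools this emulates.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

from .errors import MinimumSizeError
from .features import PharmFeature, Pharmacophore
from .library import MoleculeRecord
from .metrics import ScreenCounts, ScreenMetrics, compute_metrics
from .protein import ProteinStructure

logger = logging.getLogger(__name__)

MIN_PHARMACOPHORE_SIZE = 3


@dataclass
class RigidTransform:
    """x -> R (x - center_from) + center_to, with R a proper rotation."""

    rotation: Rotation
    center_from: np.ndarray
    center_to: np.ndarray

    def apply(self, pts: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(pts, dtype=float))
        return self.rotation.apply(pts - self.center_from) + self.center_to


@dataclass
class MatchOptions:
    default_radius: float = 1.0
    exclusion: bool = False
    exclusion_dist: float = 1.5
    protein: ProteinStructure | None = None


@dataclass
class MatchResult:
    matched: bool
    correspondence: dict[int, int] = field(default_factory=dict)
    rmsd: float = float("nan")
    excluded: bool = False
    transform: RigidTransform | None = None


def _superpose(pharm_pts: np.ndarray, mol_pts: np.ndarray
               ) -> tuple[RigidTransform, np.ndarray]:
    """Least-squares proper superposition of mol points onto pharm points.

    Returns the transform and the per-point residual distances.
    """
    cp = pharm_pts.mean(axis=0)
    cm = mol_pts.mean(axis=0)
    rot, _ = Rotation.align_vectors(pharm_pts - cp, mol_pts - cm)
    tf = RigidTransform(rot, cm, cp)
    resid = np.linalg.norm(tf.apply(mol_pts) - pharm_pts, axis=1)
    return tf, resid


def match_molecule(pharm: Pharmacophore, mol: MoleculeRecord,
                   options: MatchOptions | None = None) -> MatchResult:
    """Search for a class-consistent rigid match of ``mol`` onto ``pharm``.

    All pharmacophore features must be satisfied (hard filter, no partial
    matching).  The first satisfying assignment in lexicographic order is
    returned.  Directions on features are ignored.
    """
    options = options or MatchOptions()
    k = len(pharm.features)
    if k < MIN_PHARMACOPHORE_SIZE:
        raise MinimumSizeError(
            f"matcher requires at least {MIN_PHARMACOPHORE_SIZE} features, "
            f"got {k}")

    p_pos = pharm.positions
    radii = np.array([f.radius for f in pharm.features])
    m_pos = mol.positions
    m_cls = [f.cls for f in mol.features]
    # candidate molecule features per pharmacophore feature, by class
    cands = [[a for a, c in enumerate(m_cls) if c == f.cls]
             for f in pharm.features]
    if any(not c for c in cands):
        return MatchResult(False)

    pd = np.linalg.norm(p_pos[:, None, :] - p_pos[None, :, :], axis=-1)
    md = np.linalg.norm(m_pos[:, None, :] - m_pos[None, :, :], axis=-1)

    assign = [-1] * k
    used = set()

    def backtrack(i: int) -> MatchResult | None:
        if i == k:
            mol_pts = m_pos[assign]
            tf, resid = _superpose(p_pos, mol_pts)
            if np.all(resid <= radii + 1e-9):
                rmsd = float(np.sqrt(np.mean(resid ** 2)))
                res = MatchResult(True, {j: assign[j] for j in range(k)},
                                  rmsd, False, tf)
                return res
            return None
        for a in cands[i]:
            if a in used:
                continue
            ok = True
            for j in range(i):
                if abs(pd[i, j] - md[a, assign[j]]) > radii[i] + radii[j]:
                    ok = False
                    break
            if not ok:
                continue
            assign[i] = a
            used.add(a)
            res = backtrack(i + 1)
            used.discard(a)
            assign[i] = -1
            if res is not None:
                return res
        return None

    result = backtrack(0)
    if result is None:
        return MatchResult(False)
    if options.exclusion:
        excluded = exclusion_check(result.transform, mol, options.protein,
                                   options.exclusion_dist)
        if excluded:
            return MatchResult(False, result.correspondence, result.rmsd,
                               True, result.transform)
    return result


def exclusion_check(transform: RigidTransform, mol: MoleculeRecord,
                    protein: ProteinStructure | None,
                    r_excl: float = 1.5) -> bool:
    """True iff any transformed molecule atom lies strictly within
    ``r_excl`` of a protein heavy atom (steric clash with the receptor)."""
    if mol.atoms is None:
        logger.warning("molecule %s has no atom coordinates; "
                       "receptor exclusion skipped", mol.id)
        return False
    if protein is None:
        logger.warning("no protein supplied; receptor exclusion skipped")
        return False
    heavy = protein.heavy_coords
    if heavy.size == 0:
        return False
    moved = transform.apply(mol.atoms)
    from scipy.spatial import cKDTree

    d = cKDTree(heavy).query(moved)[0]
    # strict inequality: an atom at exactly r_excl is not excluded (a tiny
    # slack absorbs rotation round-off from the match transform)
    return bool(np.any(d < r_excl - 1e-9))


@dataclass
class ScreenResult:
    counts: ScreenCounts
    metrics: ScreenMetrics
    per_molecule: list[tuple[str, bool]]


def screen_library(pharm: Pharmacophore, library: list[MoleculeRecord],
                   options: MatchOptions | None = None,
                   max_reference_f1: float | None = None) -> ScreenResult:
    """Screen a labelled library; conformers sharing an id are pooled
    (matched if any conformer matches)."""
    if not library:
        raise ValueError("library is empty")
    options = options or MatchOptions()
    matched: dict[str, bool] = {}
    active: dict[str, bool] = {}
    order: list[str] = []
    for rec in library:
        if rec.id not in matched:
            matched[rec.id] = False
            active[rec.id] = rec.is_active
            order.append(rec.id)
        if not matched[rec.id]:
            matched[rec.id] = match_molecule(pharm, rec, options).matched
    tp = sum(1 for m in order if matched[m] and active[m])
    fp = sum(1 for m in order if matched[m] and not active[m])
    fn = sum(1 for m in order if not matched[m] and active[m])
    tn = sum(1 for m in order if not matched[m] and not active[m])
    counts = ScreenCounts(tp, fp, fn, tn)
    return ScreenResult(counts, compute_metrics(counts, max_reference_f1),
                        [(m, matched[m]) for m in order])


@dataclass
class BaselineResult:
    best_f1: float
    mean_f1: float
    best_pharm: Pharmacophore
    n_evaluated: int
    evaluations: list[tuple[tuple[int, ...], float]]


def enumerate_baseline(features: list[PharmFeature],
                       library: list[MoleculeRecord],
                       sizes: tuple[int, ...] = (3, 4, 5),
                       cap: int = 10_000, seed: int = 0,
                       options: MatchOptions | None = None) -> BaselineResult:
    """Best and mean F1 over feature subsets of the given sizes.

    Exhaustive when the total combination count is within ``cap``;
    otherwise ``cap`` distinct subsets are sampled uniformly with a fixed
    seed.  This is the ligand-feature enumeration baseline against which
    learned pharmacophores are normalized.
    """
    n = len(features)
    if n < MIN_PHARMACOPHORE_SIZE:
        raise MinimumSizeError(
            f"need at least {MIN_PHARMACOPHORE_SIZE} features to enumerate")
    sizes = tuple(s for s in sizes if s <= n)
    from math import comb

    total = sum(comb(n, s) for s in sizes)
    subsets: list[tuple[int, ...]]
    if total <= cap:
        subsets = [c for s in sizes for c in itertools.combinations(range(n), s)]
    else:
        rng = np.random.default_rng(seed)
        weights = np.array([comb(n, s) for s in sizes], dtype=float)
        weights /= weights.sum()
        chosen: set[tuple[int, ...]] = set()
        while len(chosen) < cap:
            s = sizes[rng.choice(len(sizes), p=weights)]
            chosen.add(tuple(sorted(rng.choice(n, size=s, replace=False))))
        subsets = sorted(chosen)

    evals = []
    best_f1, best_subset = -1.0, None
    for sub in subsets:
        pharm = Pharmacophore([features[i] for i in sub],
                              name="-".join(map(str, sub)))
        f1 = screen_library(pharm, library, options).metrics.f1
        evals.append((sub, f1))
        if f1 > best_f1:
            best_f1, best_subset = f1, sub
    mean_f1 = float(np.mean([e[1] for e in evals]))
    best = Pharmacophore([features[i] for i in best_subset],
                         name="baseline_best")
    return BaselineResult(best_f1, mean_f1, best, len(subsets), evals)
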