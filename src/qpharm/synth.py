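"""Synthetic pockets, confidence fields and libraries with planted truth.

Every other module is testable against these generators without external
data.  A synthetic pocket consists of typed protein atoms carrying the
complementary functional group for each planted interaction site, plus a
closed-form per-class confidence oracle (a Gaussian bump of width
``blob_sigma`` at each planted site over a smooth low-amplitude background
field).  Libraries are built by jittering a planted pharmacophore under
random rigid motions for actives and breaking it (class shuffling,
geometry perturbation, or full randomization) for decoys; every generated
record is verified against the matcher at generation time, which makes the
matcher the single source of truth for separability.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

from .errors import GenerationError
from .features import FeatureClass, N_CLASSES, PharmFeature, Pharmacophore
from .library import MoleculeRecord
from .protein import (COMPLEMENTARY_GROUP, DEFAULT_COMP_DIST, ProteinAtom,
                      ProteinStructure, annotate_groups)


@dataclass
class SyntheticPocketSpec:
    n_sites: int = 4
    classes: list[FeatureClass] | None = None
    box: tuple = ((0.0, 0.0, 0.0), (12.0, 12.0, 12.0))
    min_site_separation: float = 4.0
    blob_sigma: float = 0.8
    noise_level: float = 0.05
    group_distance: tuple[float, float] = (2.5, 3.2)
    n_filler_atoms: int = 10
    seed: int = 0


@dataclass
class SyntheticLibrarySpec:
    planted: Pharmacophore
    n_actives: int = 20
    n_decoys: int = 80
    jitter_sigma: float = 0.3
    decoy_mode: str = "perturb_geometry"  # shuffle_classes | perturb_geometry | random
    seed: int = 0


class OraclePredictor:
    """Closed-form point predictor with planted per-class maxima.

    Confidence of class c at point x is a Gaussian bump of width
    ``blob_sigma`` around each planted site of that class, over a smooth
    deterministic background of amplitude ``noise_level``, clipped to
    [0, 1].  The embedding is a smooth sinusoidal function of position.
    Everything is expressed in coordinates relative to ``origin`` so the
    oracle can be rigidly translated alongside its pocket.
    """

    def __init__(self, sites: np.ndarray, classes: list[FeatureClass],
                 blob_sigma: float = 0.8, noise_level: float = 0.05,
                 seed: int = 0, embedding_size: int = 32,
                 origin=np.zeros(3)):
        self.sites = np.atleast_2d(np.asarray(sites, dtype=float))
        self.classes = [FeatureClass(c) for c in classes]
        self.blob_sigma = blob_sigma
        self.noise_level = noise_level
        self.seed = seed
        self.embedding_size = embedding_size
        self.origin = np.asarray(origin, dtype=float)
        rng = np.random.default_rng(seed)
        self._noise_k = rng.normal(0, 1.8, size=(N_CLASSES, 3))
        self._noise_phase = rng.uniform(0, 2 * np.pi, size=N_CLASSES)
        self._emb_w = rng.normal(0, 0.7, size=(3, embedding_size))
        self._emb_phase = rng.uniform(0, 2 * np.pi, size=embedding_size)

    def predict_points(self, protein, points) -> tuple[np.ndarray, np.ndarray]:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        local = pts - self.origin
        conf = np.zeros((len(pts), N_CLASSES))
        if self.noise_level > 0:
            phase = local @ self._noise_k.T + self._noise_phase
            conf += 0.5 * self.noise_level * (1.0 + np.sin(phase))
        for site, cls in zip(self.sites, self.classes):
            d2 = np.sum((pts - site) ** 2, axis=1)
            conf[:, cls] += np.exp(-d2 / (2.0 * self.blob_sigma ** 2))
        conf = np.clip(conf, 0.0, 1.0)
        emb = np.sin(local @ self._emb_w + self._emb_phase)
        return conf, emb

    def translated(self, dv) -> "OraclePredictor":
        dv = np.asarray(dv, dtype=float)
        out = OraclePredictor(self.sites + dv, self.classes, self.blob_sigma,
                              self.noise_level, self.seed,
                              self.embedding_size, self.origin + dv)
        return out


# one residue template per group kind; each yields atoms whose annotation
# produces the wanted group (possibly with benign extra kinds, listed so
# that placement can keep them away from foreign planted sites)
_TEMPLATE_KINDS = {
    "donor_group": ("donor_group",),
    "acceptor_group": ("acceptor_group",),
    "cationic_group": ("cationic_group", "donor_group"),
    "anionic_group": ("anionic_group", "acceptor_group"),
    "aromatic_ring": ("aromatic_ring",),
    "hydrophobic_patch": ("hydrophobic_patch",),
}


def _random_unit(rng) -> np.ndarray:
    v = rng.normal(size=3)
    return v / np.linalg.norm(v)


def _template_atoms(kind: str, center: np.ndarray, res_id: int,
                    rng) -> list[ProteinAtom]:
    if kind == "donor_group":
        return [ProteinAtom(center, "N", "GLY", "N", res_id=res_id)]
    if kind == "acceptor_group":
        return [ProteinAtom(center, "O", "GLY", "O", res_id=res_id)]
    if kind == "cationic_group":
        return [ProteinAtom(center, "N", "LYS", "NZ", res_id=res_id)]
    if kind == "anionic_group":
        a = 0.55 * _random_unit(rng)
        return [ProteinAtom(center + a, "O", "ASP", "OD1", res_id=res_id),
                ProteinAtom(center - a, "O", "ASP", "OD2", res_id=res_id)]
    if kind == "hydrophobic_patch":
        return [ProteinAtom(center, "C", "ALA", "CB", res_id=res_id)]
    if kind == "aromatic_ring":
        rot = Rotation.random(rng=rng)
        names = ("CG", "CD1", "CE1", "CZ", "CE2", "CD2")
        atoms = []
        for i, name in enumerate(names):
            ang = np.pi * i / 3.0
            p = rot.apply([1.39 * np.cos(ang), 1.39 * np.sin(ang), 0.0])
            atoms.append(ProteinAtom(center + p, "C", "PHE", name,
                                     res_id=res_id))
        return atoms
    raise ValueError(f"unknown group kind {kind!r}")


@dataclass
class SyntheticPocket:
    protein: ProteinStructure
    features: list[PharmFeature]  # ground truth, one per planted site
    oracle: OraclePredictor
    spec: SyntheticPocketSpec

    def translated(self, dv) -> "SyntheticPocket":
        dv = np.asarray(dv, dtype=float)
        lo, hi = np.asarray(self.spec.box[0]) + dv, np.asarray(self.spec.box[1]) + dv
        spec = SyntheticPocketSpec(
            self.spec.n_sites, self.spec.classes, (tuple(lo), tuple(hi)),
            self.spec.min_site_separation, self.spec.blob_sigma,
            self.spec.noise_level, self.spec.group_distance,
            self.spec.n_filler_atoms, self.spec.seed)
        return SyntheticPocket(self.protein.translated(dv),
                               [f.translated(dv) for f in self.features],
                               self.oracle.translated(dv), spec)


def make_pocket(spec: SyntheticPocketSpec) -> SyntheticPocket:
    """Generate a pocket with planted sites and a confidence oracle.

    Each planted site is paired with a complementary functional group
    placed ``group_distance`` away, oriented so that none of the group's
    kinds falls within the support cutoff of a foreign planted site (which
    would otherwise leak extra extraction points).  Rejection sampling is
    bounded; an infeasible packing raises.
    """
    rng = np.random.default_rng(spec.seed)
    lo = np.asarray(spec.box[0], dtype=float)
    hi = np.asarray(spec.box[1], dtype=float)
    margin = 1.5
    if np.any(hi - lo < 2 * margin):
        raise GenerationError("box too small for the placement margin")

    classes = spec.classes or [FeatureClass(i % N_CLASSES)
                               for i in range(spec.n_sites)]
    classes = [FeatureClass(classes[i % len(classes)])
               for i in range(spec.n_sites)]

    sites = []
    for _ in range(spec.n_sites):
        for attempt in range(10_000):
            p = rng.uniform(lo + margin, hi - margin)
            if all(np.linalg.norm(p - q) >= spec.min_site_separation
                   for q in sites):
                sites.append(p)
                break
        else:
            raise GenerationError(
                f"could not place {spec.n_sites} sites at "
                f"{spec.min_site_separation} Å separation in the box")
    sites = np.array(sites).reshape(-1, 3)

    atoms: list[ProteinAtom] = []
    res_id = 1
    for i, (site, cls) in enumerate(zip(sites, classes)):
        kind = COMPLEMENTARY_GROUP[cls]
        kinds = _TEMPLATE_KINDS[kind]
        placed = False
        for attempt in range(10_000):
            d = rng.uniform(*spec.group_distance)
            center = site + d * _random_unit(rng)
            ok = True
            for j, (other, ocls) in enumerate(zip(sites, classes)):
                if j == i:
                    continue
                if COMPLEMENTARY_GROUP[ocls] in kinds and \
                        np.linalg.norm(center - other) <= \
                        DEFAULT_COMP_DIST[ocls] + 0.75:
                    ok = False
                    break
            if ok:
                atoms.extend(_template_atoms(kind, center, res_id, rng))
                res_id += 1
                placed = True
                break
        if not placed:
            raise GenerationError("could not place a complementary group "
                                  "clear of foreign sites")

    # filler carbons: structural context with no functional groups
    occupied = [a.position for a in atoms] + list(sites)
    for _ in range(spec.n_filler_atoms):
        for attempt in range(10_000):
            p = rng.uniform(lo + margin, hi - margin)
            if all(np.linalg.norm(p - q) >= 2.5 for q in occupied):
                atoms.append(ProteinAtom(p, "C", "GLY", "CA", res_id=res_id))
                res_id += 1
                occupied.append(p)
                break
        else:
            break  # box is full; filler is best-effort

    protein = ProteinStructure(atoms, annotate_groups(atoms))
    oracle = OraclePredictor(sites, classes, spec.blob_sigma,
                             spec.noise_level, spec.seed, origin=lo)
    truth = [PharmFeature(site, cls, confidence=1.0)
             for site, cls in zip(sites, classes)]
    # sanity: every planted site is supported by a complementary group
    for site, cls in zip(sites, classes):
        pos = protein.group_positions(COMPLEMENTARY_GROUP[cls])
        assert pos.size and np.min(np.linalg.norm(pos - site, axis=1)) \
            <= DEFAULT_COMP_DIST[cls], "planted site lacks its group"
    return SyntheticPocket(protein, truth, oracle, spec)


# ---------------------------------------------------------------------
# libraries
# ---------------------------------------------------------------------

def _rigid(rng) -> tuple[Rotation, np.ndarray]:
    return Rotation.random(rng=rng), rng.uniform(-10.0, 10.0, size=3)


def _apply(rot: Rotation, shift: np.ndarray, pts: np.ndarray) -> np.ndarray:
    return rot.apply(pts) + shift


def make_library(spec: SyntheticLibrarySpec) -> list[MoleculeRecord]:
    """Actives that verifiably match the planted pharmacophore, decoys that
    verifiably do not."""
    from .screening import match_molecule

    planted = spec.planted
    if len(planted) < 3:
        raise GenerationError("planted pharmacophore needs >= 3 features")
    rng = np.random.default_rng(spec.seed)
    base = planted.positions
    classes = planted.classes
    records: list[MoleculeRecord] = []

    for i in range(spec.n_actives):
        for attempt in range(100):
            rot, shift = _rigid(rng)
            pts = _apply(rot, shift,
                         base + rng.normal(0, spec.jitter_sigma, base.shape))
            rec = MoleculeRecord(
                f"active_{i:03d}",
                [PharmFeature(p, c) for p, c in zip(pts, classes)],
                atoms=pts, is_active=True)
            if match_molecule(planted, rec).matched:
                records.append(rec)
                break
        else:
            raise GenerationError(
                "could not generate a matching active in 100 tries; "
                "use a smaller jitter_sigma")

    for i in range(spec.n_decoys):
        for attempt in range(100):
            mode = spec.decoy_mode
            if mode == "shuffle_classes":
                perm = rng.permutation(len(classes))
                dec_classes = [classes[k] for k in perm]
                if [int(c) for c in dec_classes] == [int(c) for c in classes]:
                    continue
                pts = base + rng.normal(0, spec.jitter_sigma, base.shape)
            elif mode == "perturb_geometry":
                dec_classes = classes
                disp = np.array([rng.uniform(2.0, 4.0) * _random_unit(rng)
                                 for _ in base])
                pts = base + disp
            elif mode == "random":
                dec_classes = [FeatureClass(int(k))
                               for k in rng.integers(0, N_CLASSES,
                                                     size=len(classes))]
                lo = base.min(axis=0) - 3.0
                hi = base.max(axis=0) + 3.0
                pts = rng.uniform(lo, hi, size=base.shape)
            else:
                raise GenerationError(f"unknown decoy_mode {mode!r}")
            rot, shift = _rigid(rng)
            pts = _apply(rot, shift, pts)
            try:
                rec = MoleculeRecord(
                    f"decoy_{i:03d}",
                    [PharmFeature(p, c) for p, c in zip(pts, dec_classes)],
                    atoms=pts, is_active=False)
            except ValueError:  # coincident same-class points; resample
                continue
            if not match_molecule(planted, rec).matched:
                records.append(rec)
                break
        else:
            raise GenerationError("could not generate a non-matching decoy")
    return records


# ---------------------------------------------------------------------
# the unique-optimum RL task
# ---------------------------------------------------------------------

@dataclass
class UniqueOptimumTask:
    features: list[PharmFeature]
    protein: ProteinStructure
    library: list[MoleculeRecord]
    optimal_indices: tuple[int, ...]
    seed: int


def make_unique_optimum_task(n_features: int = 8, seed: int = 0,
                             n_actives: int = 12, n_decoys: int = 28,
                             jitter_sigma: float = 0.25,
                             max_attempts: int = 50) -> UniqueOptimumTask:
    """A compact feature cloud in which exactly one 3-subset screens
    perfectly (F1 = 1) and every other subset of size 3-5 scores <= 0.5,
    verified by exhaustive enumeration at generation time.

    All features lie within the feature-feature graph threshold of each
    other, so the optimum is reachable from any of its own features.  The
    optimal triple carries the highest predictor confidences, mirroring a
    site where the point predictor strongly supports the true features.
    """
    from .screening import enumerate_baseline

    if n_features < 4:
        raise GenerationError("the task needs at least 4 candidate features")

    for attempt in range(max_attempts):
        rng = np.random.default_rng(seed + 1000 * attempt)
        positions = []
        while len(positions) < n_features:
            p = rng.uniform(-3.2, 3.2, size=3)
            if np.linalg.norm(p) > 3.4:
                continue
            if all(np.linalg.norm(p - q) >= 2.2 for q in positions):
                positions.append(p)
        positions = np.array(positions)
        classes = [FeatureClass(int(k)) for k in
                   rng.permuted(np.arange(n_features) % N_CLASSES)]
        optimal = tuple(sorted(rng.choice(n_features, 3, replace=False).tolist()))

        emb_oracle = OraclePredictor(np.zeros((0, 3)), [], seed=seed + attempt)
        _, embs = emb_oracle.predict_points(None, positions)
        features = []
        for i in range(n_features):
            conf = rng.uniform(0.85, 0.99) if i in optimal \
                else rng.uniform(0.55, 0.80)
            features.append(PharmFeature(positions[i], classes[i],
                                         confidence=conf, embedding=embs[i]))

        planted = Pharmacophore([features[i] for i in optimal], "planted")
        # Actives carry the planted triple plus one rotating extra candidate
        # feature.  Subsets overlapping the optimum then earn partial F1
        # (verified <= 0.5 below), which grades the reward landscape the way
        # real actives sharing additional interactions would.
        rng_lib = np.random.default_rng(seed + 1000 * attempt + 1)
        non_triple = [i for i in range(n_features) if i not in optimal]
        # cap each extra feature's share of actives at 1/3 so that any
        # subset relying on it has recall <= 1/3, hence F1 <= 0.5
        quota = n_actives // 3
        extras: list[int | None] = []
        for k, x in enumerate(non_triple):
            extras.extend([x] * quota)
        extras = extras[:n_actives]
        extras += [None] * (n_actives - len(extras))
        tri_pos = planted.positions
        tri_cls = planted.classes
        library = []
        feasible = True
        for i in range(n_actives):
            extra = extras[i]
            for _ in range(100):
                if extra is None:
                    pts = tri_pos.copy()
                    cls_list = list(tri_cls)
                else:
                    pts = np.vstack([tri_pos, positions[extra][None, :]])
                    cls_list = list(tri_cls) + [classes[extra]]
                pts = pts + rng_lib.normal(0, jitter_sigma, pts.shape)
                rot, shift = _rigid(rng_lib)
                pts = _apply(rot, shift, pts)
                rec = MoleculeRecord(
                    f"active_{i:03d}",
                    [PharmFeature(p, c) for p, c in zip(pts, cls_list)],
                    atoms=pts, is_active=True)
                from .screening import match_molecule
                if match_molecule(planted, rec).matched:
                    library.append(rec)
                    break
            else:
                feasible = False
                break
        if not feasible:
            continue
        try:
            library += make_library(SyntheticLibrarySpec(
                planted, 0, n_decoys, jitter_sigma,
                decoy_mode="random", seed=seed + 1000 * attempt + 2))
        except GenerationError:
            continue

        base = enumerate_baseline(features, library, sizes=(3, 4, 5),
                                  cap=100_000)
        perfect = [sub for sub, f1 in base.evaluations if f1 >= 1.0 - 1e-12]
        others_ok = all(f1 <= 0.5 for sub, f1 in base.evaluations
                        if sub != optimal)
        if perfect == [optimal] and others_ok:
            atoms = []
            res_id = 1
            for i, f in enumerate(features):
                kind = COMPLEMENTARY_GROUP[f.cls]
                center = f.position + 2.8 * _dir_away(f.position, positions, rng)
                atoms.extend(_template_atoms(kind, center, res_id, rng))
                res_id += 1
            protein = ProteinStructure(atoms, annotate_groups(atoms))
            return UniqueOptimumTask(features, protein, library, optimal,
                                     seed + 1000 * attempt)
    raise GenerationError(
        f"could not build a verified unique-optimum task in {max_attempts} tries")


def _dir_away(p: np.ndarray, all_pos: np.ndarray, rng) -> np.ndarray:
    v = p - all_pos.mean(axis=0)
    n = np.linalg.norm(v)
    if n < 1e-9:
        return _random_unit(rng)
    return v / n
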