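"""Independent brute-force oracles used to validate the implementation.

These deliberately avoid the package's own search/labelling code paths:
the matcher oracle enumerates every injective class-consistent assignment
and checks feasibility with its own SVD-based Kabsch superposition; the
component oracle is a plain flood fill; the proposal oracle recomputes
candidate neighborhoods by direct distance checks.
"""

from __future__ import annotations

import itertools

import numpy as np


def kabsch_proper(P: np.ndarray, Q: np.ndarray) -> np.ndarray:
    """Proper rotation (det +1) minimizing ||P_c - R Q_c||, via SVD."""
    Pc = P - P.mean(axis=0)
    Qc = Q - Q.mean(axis=0)
    H = Qc.T @ Pc
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    return Vt.T @ np.diag([1.0, 1.0, d]) @ U.T


def oracle_match(pharm, mol) -> bool:
    """Exhaustive assignment enumeration + closed-form superposition check."""
    k = len(pharm.features)
    p_pos = pharm.positions
    radii = np.array([f.radius for f in pharm.features])
    m_pos = mol.positions
    m_cls = [f.cls for f in mol.features]
    m = len(m_cls)
    for assign in itertools.permutations(range(m), k):
        if any(m_cls[a] != pharm.features[i].cls
               for i, a in enumerate(assign)):
            continue
        Q = m_pos[list(assign)]
        R = kabsch_proper(p_pos, Q)
        moved = (Q - Q.mean(axis=0)) @ R.T + p_pos.mean(axis=0)
        if np.all(np.linalg.norm(moved - p_pos, axis=1) <= radii + 1e-9):
            return True
    return False


def flood_fill_components(mask: np.ndarray) -> list[set[tuple[int, int, int]]]:
    """26-connected components of a 3D boolean grid by explicit flood fill."""
    visited = np.zeros_like(mask, dtype=bool)
    comps = []
    nbrs = [(di, dj, dk)
            for di in (-1, 0, 1) for dj in (-1, 0, 1) for dk in (-1, 0, 1)
            if (di, dj, dk) != (0, 0, 0)]
    for start in zip(*np.nonzero(mask)):
        if visited[start]:
            continue
        comp = set()
        stack = [start]
        visited[start] = True
        while stack:
            cur = stack.pop()
            comp.add(cur)
            for d in nbrs:
                nxt = (cur[0] + d[0], cur[1] + d[1], cur[2] + d[2])
                if all(0 <= nxt[a] < mask.shape[a] for a in range(3)) \
                        and mask[nxt] and not visited[nxt]:
                    visited[nxt] = True
                    stack.append(nxt)
        comps.append(comp)
    return comps


def brute_force_proposals(selected: tuple[int, ...], positions: np.ndarray,
                          delta_ff: float) -> set[int]:
    """Admissible new features: absent and within delta_ff of the subset."""
    out = set()
    for i in range(len(positions)):
        if i in selected:
            continue
        if any(np.linalg.norm(positions[i] - positions[j]) <= delta_ff
               for j in selected):
            out.add(i)
    return out


def random_match_instance(rng: np.random.Generator):
    """One random matcher test case: (pharmacophore, molecule record)."""
    from qpharm.features import FeatureClass, PharmFeature, Pharmacophore
    from qpharm.library import MoleculeRecord
    from scipy.spatial.transform import Rotation

    while True:
        k = int(rng.integers(3, 6))
        pts = rng.uniform(0, 6, size=(k, 3))
        cls = [FeatureClass(int(c)) for c in rng.integers(0, 6, size=k)]
        try:
            pharm = Pharmacophore(
                [PharmFeature(p, c) for p, c in zip(pts, cls)])
            break
        except ValueError:
            continue
    m = int(rng.integers(k, 9))
    if rng.random() < 0.5:
        # embed a (possibly jittered) transformed copy among distractors
        jitter = rng.uniform(0, 0.8) * rng.normal(0, 0.4, size=(k, 3))
        mpts = pts + jitter
        mcls = list(cls)
        for _ in range(m - k):
            mpts = np.vstack([mpts, rng.uniform(-2, 8, size=3)])
            mcls.append(FeatureClass(int(rng.integers(0, 6))))
        rot = Rotation.random(rng=rng)
        mpts = rot.apply(mpts) + rng.uniform(-5, 5, size=3)
    else:
        mpts = rng.uniform(0, 7, size=(m, 3))
        mcls = [FeatureClass(int(c)) for c in rng.integers(0, 6, size=m)]
    mol = MoleculeRecord("m", [PharmFeature(p, c)
                               for p, c in zip(mpts, mcls)],
                         atoms=mpts, is_active=False)
    return pharm, mol
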