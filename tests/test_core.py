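"""Domain types, screening metrics, PDB annotation and pharmacophore I/O."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from qpharm.errors import (ContractError, EmptyStructureError, FormatError)
from qpharm.features import (FeatureClass, PharmFeature, Pharmacophore,
                             read_pharmacophore, write_pharmacophore)
from qpharm.metrics import ScreenCounts, compute_metrics
from qpharm.protein import (ProteinAtom, annotate_groups, load_protein,
                            write_protein_pdb, ProteinStructure)


# ---------------------------------------------------------------- metrics

def test_metrics_worked_example():
    m = compute_metrics(ScreenCounts(tp=6, fp=2, fn=4, tn=88))
    assert m.precision == pytest.approx(0.75)
    assert m.recall == pytest.approx(0.6)
    assert m.f1 == pytest.approx(2 / 3, abs=1e-4)
    assert m.enrichment_factor == pytest.approx(7.5)


def test_metrics_degenerate_and_normalized():
    m = compute_metrics(ScreenCounts(0, 0, 10, 90))
    assert (m.precision, m.recall, m.f1) == (0.0, 0.0, 0.0)
    m = compute_metrics(ScreenCounts(3, 7, 7, 83), max_reference_f1=0.6)
    assert m.normalized_f1 == pytest.approx(m.f1 / 0.6)
    with pytest.raises(ContractError):
        compute_metrics(ScreenCounts(1, 1, 1, 1), max_reference_f1=0.0)


@settings(max_examples=100, deadline=None)
@given(tp=st.integers(0, 50), fp=st.integers(0, 50),
       fn=st.integers(0, 50), tn=st.integers(0, 200))
def test_metrics_match_hand_formulas(tp, fp, fn, tn):
    m = compute_metrics(ScreenCounts(tp, fp, fn, tn))
    prec = tp / (tp + fp) if tp + fp else 0.0
    rec = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * prec * rec / (prec + rec) if prec + rec else 0.0
    assert m.precision == pytest.approx(prec)
    assert m.recall == pytest.approx(rec)
    assert m.f1 == pytest.approx(f1)
    if tp + fn > 0 and tp + fp + fn + tn > 0:
        assert m.enrichment_factor == pytest.approx(
            prec / ((tp + fn) / (tp + fp + fn + tn)))


def test_random_classifier_enrichment_is_one():
    # precision equals the active fraction exactly -> EF = 1
    m = compute_metrics(ScreenCounts(tp=5, fp=20, fn=15, tn=60))
    assert m.enrichment_factor == pytest.approx(1.0)


def test_counts_identities_and_validation():
    c = ScreenCounts(2, 3, 4, 5)
    assert c.n_total == 14 and c.n_active == 6
    with pytest.raises(ValueError):
        ScreenCounts(-1, 0, 0, 0)


# --------------------------------------------------------------- features

def test_feature_validation():
    with pytest.raises(ValueError):
        PharmFeature([0, 0, 0], FeatureClass.Aromatic, radius=0.0)
    with pytest.raises(ValueError):
        PharmFeature([0, 0, 0], FeatureClass.Aromatic, direction=[1, 1, 0])
    f = PharmFeature([1, 2, 3], FeatureClass.HydrogenDonor,
                     direction=[0, 0, 1], confidence=0.7)
    assert f.cls is FeatureClass.HydrogenDonor


def test_duplicate_feature_guard():
    with pytest.raises(ValueError):
        Pharmacophore([
            PharmFeature([0, 0, 0], FeatureClass.Aromatic),
            PharmFeature([0.05, 0, 0], FeatureClass.Aromatic)])
    # different classes may coincide
    Pharmacophore([PharmFeature([0, 0, 0], FeatureClass.Aromatic),
                   PharmFeature([0.05, 0, 0], FeatureClass.Hydrophobic)])


@pytest.mark.parametrize("with_direction", [False, True])
def test_pharmacophore_roundtrip_all_classes(tmp_path, with_direction):
    feats = []
    for i, cls in enumerate(FeatureClass):
        direction = None
        if with_direction:
            v = np.array([1.0, float(i), 0.5])
            direction = v / np.linalg.norm(v)
        feats.append(PharmFeature([i * 2.0, -i, 0.5 * i], cls, radius=1.0 + i / 10,
                                  direction=direction, confidence=0.5,
                                  embedding=np.arange(32.0)))
    pharm = Pharmacophore(feats, "rt")
    path = tmp_path / "p.json"
    write_pharmacophore(pharm, path)
    back = read_pharmacophore(path)
    assert len(back) == len(pharm)
    for a, b in zip(pharm.features, back.features):
        assert a.cls == b.cls
        assert np.allclose(a.position, b.position, atol=1e-6)
        assert a.radius == pytest.approx(b.radius)
        if with_direction:
            assert np.allclose(a.direction, b.direction, atol=1e-6)
        assert np.allclose(a.embedding, b.embedding)


def test_disabled_points_skipped_and_errors(tmp_path):
    path = tmp_path / "p.json"
    path.write_text('{"points": [{"name": "Aromatic", "x": 0, "y": 0, "z": 0,'
                    ' "radius": 1.0, "enabled": false},'
                    '{"name": "Hydrophobic", "x": 1, "y": 0, "z": 0}]}')
    pharm = read_pharmacophore(path)
    assert [f.cls for f in pharm.features] == [FeatureClass.Hydrophobic]

    path.write_text('{"points": [{"name": "Banana", "x": 0, "y": 0, "z": 0}]}')
    with pytest.raises(FormatError, match="HydrogenAcceptor"):
        read_pharmacophore(path)

    path.write_text("{not json")
    with pytest.raises(FormatError):
        read_pharmacophore(path)


# ---------------------------------------------------------------- protein

def _atom(pos, element, res, name, res_id=1):
    return ProteinAtom(pos, element, res, name, res_id=res_id)


def test_annotate_three_residue_toy():
    """Ser OG is donor+acceptor; Asp carboxylate merges to one anion plus
    two acceptor annotations; the Phe ring gives one aromatic site."""
    atoms = [
        _atom([0, 0, 0], "O", "SER", "OG", 1),
        _atom([5, 0, 0], "O", "ASP", "OD1", 2),
        _atom([5, 1.1, 0], "O", "ASP", "OD2", 2),
    ]
    ring = [([10 + 1.39 * np.cos(np.pi * i / 3),
              1.39 * np.sin(np.pi * i / 3), 0], n)
            for i, n in enumerate(("CG", "CD1", "CE1", "CZ", "CE2", "CD2"))]
    atoms += [_atom(p, "C", "PHE", n, 3) for p, n in ring]
    sites = annotate_groups(atoms)
    kinds = sorted(s.group_kind for s in sites)
    assert kinds == ["acceptor_group", "acceptor_group", "acceptor_group",
                     "anionic_group", "aromatic_ring", "donor_group"]
    anion = next(s for s in sites if s.group_kind == "anionic_group")
    assert np.allclose(anion.position, [5, 0.55, 0])
    arom = next(s for s in sites if s.group_kind == "aromatic_ring")
    assert np.allclose(arom.position, [10, 0, 0], atol=1e-9)


def test_annotate_glycine_backbone_only():
    atoms = [_atom([0, 0, 0], "N", "GLY", "N", 1),
             _atom([1.5, 0, 0], "C", "GLY", "CA", 1),
             _atom([2.5, 1, 0], "C", "GLY", "C", 1),
             _atom([3.5, 1, 0], "O", "GLY", "O", 1)]
    kinds = sorted(s.group_kind for s in annotate_groups(atoms))
    assert kinds == ["acceptor_group", "donor_group"]


def test_annotate_lysine_trp_ala():
    nz = annotate_groups([_atom([1, 2, 3], "N", "LYS", "NZ")])
    assert sorted(s.group_kind for s in nz) == ["cationic_group", "donor_group"]
    assert all(np.allclose(s.position, [1, 2, 3]) for s in nz)

    rng = np.random.default_rng(0)
    trp_names = ("CG", "CD1", "CD2", "NE1", "CE2", "CE3", "CZ2", "CZ3", "CH2")
    pos = rng.uniform(0, 3, size=(9, 3))
    atoms = [_atom(p, "N" if n.startswith("N") else "C", "TRP", n)
             for p, n in zip(pos, trp_names)]
    sites = annotate_groups(atoms)
    rings = [s for s in sites if s.group_kind == "aromatic_ring"]
    assert len(rings) == 1  # single fused-ring site
    assert np.allclose(rings[0].position, pos.mean(axis=0))

    ala = annotate_groups([_atom([0, 0, 1], "C", "ALA", "CB")])
    assert [s.group_kind for s in ala] == ["hydrophobic_patch"]
    assert np.allclose(ala[0].position, [0, 0, 1])


def test_annotate_permutation_invariant():
    rng = np.random.default_rng(4)
    atoms = [
        _atom([0, 0, 0], "N", "GLY", "N", 1),
        _atom([3, 0, 0], "O", "SER", "OG", 2),
        _atom([6, 0, 0], "N", "LYS", "NZ", 3),
        _atom([9, 0, 0], "O", "ASP", "OD1", 4),
        _atom([9, 1, 0], "O", "ASP", "OD2", 4),
    ]
    ref = {(s.group_kind, tuple(np.round(s.position, 6)))
           for s in annotate_groups(atoms)}
    for _ in range(5):
        perm = [atoms[i] for i in rng.permutation(len(atoms))]
        got = {(s.group_kind, tuple(np.round(s.position, 6)))
               for s in annotate_groups(perm)}
        assert got == ref


def test_load_protein_roundtrip_and_errors(tmp_path):
    atoms = [_atom([0, 0, 0], "O", "SER", "OG", 1),
             _atom([4, 0, 0], "C", "ALA", "CB", 2)]
    struct = ProteinStructure(atoms, annotate_groups(atoms))
    path = tmp_path / "toy.pdb"
    write_protein_pdb(struct, path)
    back = load_protein(path)
    assert len(back.atoms) == 2
    assert sorted(s.group_kind for s in back.groups) == \
        ["acceptor_group", "donor_group", "hydrophobic_patch"]
    assert np.allclose(back.atoms[0].position, [0, 0, 0], atol=1e-3)

    empty = tmp_path / "empty.pdb"
    empty.write_text("")
    with pytest.raises(EmptyStructureError):
        load_protein(empty)
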