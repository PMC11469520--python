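"""Voxel encoding, the reference point predictor, adversarial mining."""

import numpy as np
import pytest

from qpharm.features import N_CLASSES, FeatureClass
from qpharm.predictor import (PredictorConfig, ReferencePredictor,
                              TrainingSample, analytic_kernel_mass,
                              generate_adversarial_negatives, predict_point,
                              train_predictor, voxelize)
from qpharm.protein import ProteinAtom, ProteinStructure, annotate_groups

CFG = PredictorConfig()


def _carbon(pos):
    return ProteinAtom(pos, "C", "GLY", "CA")


def test_grid_dimensions_and_empty_box():
    grid = voxelize(ProteinStructure([_carbon([100, 100, 100])], []),
                    [0, 0, 0], CFG)
    assert grid.values.shape == (8, 20, 20, 20)
    assert np.all(grid.values == 0)  # distant atom contributes nothing


def test_translation_covariance_exact():
    atoms = [_carbon([1.0, 2.0, 3.0]),
             ProteinAtom([3.5, 2.0, 1.0], "O", "GLY", "O")]
    protein = ProteinStructure(atoms, [])
    dv = np.array([7.3, -2.1, 0.9])
    g0 = voxelize(protein, [2.0, 2.0, 2.0], CFG)
    g1 = voxelize(protein.translated(dv), np.array([2.0, 2.0, 2.0]) + dv, CFG)
    assert np.allclose(g0.values, g1.values, atol=1e-9)
    # an integer translation is exactly representable -> bitwise identical
    g2 = voxelize(protein.translated([4.0, -2.0, 8.0]),
                  np.array([6.0, 0.0, 10.0]), CFG)
    assert np.array_equal(g0.values, g2.values)


def test_single_atom_kernel_shape_and_mass():
    center = np.array([4.75, 4.75, 4.75])
    protein = ProteinStructure([_carbon(center)], [])
    grid = voxelize(protein, center, CFG)
    ch = grid.values[0]  # aliphatic carbon channel
    assert grid.values[1:].sum() == 0
    # maximum at the 8 central voxels, symmetric under axis permutation
    peak = np.unravel_index(np.argmax(ch), ch.shape)
    assert peak in {(i, j, k) for i in (9, 10) for j in (9, 10)
                    for k in (9, 10)}
    assert np.allclose(ch, np.transpose(ch, (1, 2, 0)))
    assert np.allclose(ch, ch[::-1, :, :])  # mirror symmetry of the grid
    mass = ch.sum() * CFG.resolution ** 3
    assert mass == pytest.approx(analytic_kernel_mass(1.70), abs=1e-3)


def test_zero_init_model_outputs_half_and_embedding_length():
    protein = ProteinStructure([_carbon([0, 0, 0])], [])
    model = ReferencePredictor(CFG, zero_init=True)
    pred = predict_point(model, protein, [0.5, 0.5, 0.5])
    assert np.allclose(pred.confidences, 0.5)
    assert pred.embedding.shape == (32,)


def test_predictions_deterministic_for_fixed_weights():
    protein = ProteinStructure([_carbon([0, 0, 0]), _carbon([2, 1, 0])], [])
    model = ReferencePredictor(CFG, seed=5)
    a = predict_point(model, protein, [1, 0, 0])
    b = predict_point(model, protein, [1, 0, 0])
    assert np.array_equal(a.confidences, b.confidences)
    assert np.array_equal(a.embedding, b.embedding)


def test_checkpoint_roundtrip(tmp_path):
    protein = ProteinStructure([_carbon([0, 0, 0])], [])
    model = ReferencePredictor(CFG, seed=3)
    model.save(tmp_path / "m.json")
    back = ReferencePredictor.load(tmp_path / "m.json")
    pt = [0.3, -0.2, 0.6]
    assert np.allclose(predict_point(model, protein, pt).confidences,
                       predict_point(back, protein, pt).confidences)


class _ConstantModel:
    """Fires one class everywhere with a fixed confidence."""

    def __init__(self, cls, confidence=0.9, embedding_size=32):
        self.cls = cls
        self.confidence = confidence
        self.embedding_size = embedding_size

    def predict_points(self, protein, points):
        pts = np.atleast_2d(points)
        conf = np.full((len(pts), N_CLASSES), 0.1)
        conf[:, self.cls] = self.confidence
        return conf, np.zeros((len(pts), self.embedding_size))


def _donor_protein():
    """One backbone-N donor group at the origin (also the only heavy atom)."""
    atoms = [ProteinAtom([0, 0, 0], "N", "GLY", "N")]
    return ProteinStructure(atoms, annotate_groups(atoms))


def test_adversarial_rules():
    protein = _donor_protein()
    model = _ConstantModel(FeatureClass.HydrogenAcceptor)

    def flagged_points(box):
        samples = generate_adversarial_negatives(model, protein, box,
                                                 spacing=1.0)
        return {tuple(s.point) for s in samples}

    # 5 Å from the only donor group -> beyond the 4 Å cutoff -> negative
    assert (5.0, 0.0, 0.0) in flagged_points(([5, 0, 0], [5, 0, 0]))
    # 3 Å away: inside the cutoff and clash-free -> not flagged
    assert flagged_points(([3, 0, 0], [3, 0, 0])) == set()
    # 1 Å from a heavy atom -> clash -> negative despite the nearby donor
    assert (1.0, 0.0, 0.0) in flagged_points(([1, 0, 0], [1, 0, 0]))


def test_adversarial_idempotent_and_all_negative():
    protein = _donor_protein()
    model = _ConstantModel(FeatureClass.HydrogenAcceptor)
    box = ([-2, -2, -2], [6, 6, 6])
    s1 = generate_adversarial_negatives(model, protein, box, spacing=1.0)
    s2 = generate_adversarial_negatives(model, protein, box, spacing=1.0)
    assert len(s1) == len(s2) > 0
    assert all(not s.labels.any() and s.is_adversarial for s in s1)
    assert [tuple(a.point) for a in s1] == [tuple(b.point) for b in s2]


def _pocket_samples(pocket, per_site=18, n_neg=70, seed=0):
    rng = np.random.default_rng(seed)
    samples = []
    for f in pocket.features:
        labels = np.zeros(N_CLASSES)
        labels[int(f.cls)] = 1.0
        for _ in range(per_site):
            samples.append(TrainingSample(
                pocket.protein, f.position + rng.normal(0, 0.3, 3), labels))
    sites = np.array([f.position for f in pocket.features])
    lo = np.asarray(pocket.spec.box[0])
    hi = np.asarray(pocket.spec.box[1])
    while n_neg > 0:
        p = rng.uniform(lo, hi)
        if np.min(np.linalg.norm(sites - p, axis=1)) > 2.5:
            samples.append(TrainingSample(pocket.protein, p,
                                          np.zeros(N_CLASSES)))
            n_neg -= 1
    return samples


@pytest.fixture(scope="module")
def separable_fixture(pocket):
    samples = _pocket_samples(pocket)
    rng = np.random.default_rng(1)
    idx = rng.permutation(len(samples))
    split = int(0.7 * len(samples))
    train = [samples[i] for i in idx[:split]]
    test = [samples[i] for i in idx[split:]]
    model = train_predictor(train, seed=0, epochs=120)
    return pocket, model, train, test


def test_training_separates_classes(separable_fixture):
    """Held-out per-class AUC > 0.95 on the linearly separable pocket."""
    from sklearn.metrics import roc_auc_score

    pocket, model, _, test = separable_fixture
    X = model.featurize(pocket.protein, np.array([s.point for s in test]))
    conf = model.net.predict(X)
    Y = np.array([s.labels for s in test])
    for c in range(N_CLASSES):
        if len(np.unique(Y[:, c])) > 1:
            assert roc_auc_score(Y[:, c], conf[:, c]) > 0.95


def test_training_deterministic(pocket):
    samples = _pocket_samples(pocket, per_site=4, n_neg=16)
    m1 = train_predictor(samples, seed=9, epochs=20)
    m2 = train_predictor(samples, seed=9, epochs=20)
    assert m1.loss_trace[-1] == m2.loss_trace[-1]


def test_degenerate_dataset_warns(pocket):
    feat = pocket.features[0]
    labels = np.zeros(N_CLASSES)
    labels[int(feat.cls)] = 1.0
    rng = np.random.default_rng(2)
    ones = [TrainingSample(pocket.protein,
                           feat.position + rng.normal(0, 0.3, 3), labels)
            for _ in range(6)]
    with pytest.warns(UserWarning):
        train_predictor(ones, seed=0, epochs=2)


def test_retraining_with_adversarial_negatives(separable_fixture):
    """Appending mined negatives suppresses them without hurting recall."""
    pocket, base_model, train, test = separable_fixture
    box = pocket.spec.box
    mined = generate_adversarial_negatives(pocket.oracle, pocket.protein,
                                           box, spacing=1.0)
    assert mined  # the oracle fires at sites whose class lacks support nearby

    retrained = train_predictor(train + mined, seed=0, epochs=120)

    def recall(model):
        pos = [s for s in test if s.labels.any()]
        X = model.featurize(pocket.protein, np.array([s.point for s in pos]))
        conf = model.net.predict(X)
        Y = np.array([s.labels for s in pos])
        hits = ((conf > 0.5) & (Y > 0.5)).sum()
        return hits / Y.sum()

    assert recall(base_model) - recall(retrained) < 0.05
    Xm = retrained.featurize(pocket.protein,
                             np.array([s.point for s in mined]))
    assert retrained.net.predict(Xm).max(axis=1).mean() < 0.5
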