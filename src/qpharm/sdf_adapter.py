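"""Optional adapter: derive molecule feature records from SDF files.

Types pharmacophore features on molecules with RDKit's chemical feature
factory (its standard donor/acceptor/aromatic/hydrophobe/ionizable
definitions) and converts each conformer into a MoleculeRecord.  Isolated
behind a lazy import so the rest of the package has no RDKit dependency;
install the ``sdf`` extra to use it.
"""

from __future__ import annotations

import numpy as np

from .errors import FormatError
from .features import FeatureClass, PharmFeature
from .library import MoleculeRecord

#: RDKit feature-family names mapped onto the six classes.
FAMILY_TO_CLASS = {
    "Donor": FeatureClass.HydrogenDonor,
    "Acceptor": FeatureClass.HydrogenAcceptor,
    "NegIonizable": FeatureClass.NegativeIon,
    "PosIonizable": FeatureClass.PositiveIon,
    "Aromatic": FeatureClass.Aromatic,
    "Hydrophobe": FeatureClass.Hydrophobic,
    "LumpedHydrophobe": FeatureClass.Hydrophobic,
}


def _feature_factory():
    import os

    from rdkit import RDConfig
    from rdkit.Chem import ChemicalFeatures

    return ChemicalFeatures.BuildFeatureFactory(
        os.path.join(RDConfig.RDDataDir, "BaseFeatures.fdef"))


def mol_to_record(mol, mol_id: str, is_active: bool = False,
                  radius: float = 1.0, factory=None) -> MoleculeRecord | None:
    """One RDKit molecule (with a 3D conformer) -> MoleculeRecord.

    Returns None when no feature family maps onto a pharmacophore class.
    """
    factory = factory or _feature_factory()
    conf = mol.GetConformer()
    feats = []
    for f in factory.GetFeaturesForMol(mol):
        cls = FAMILY_TO_CLASS.get(f.GetFamily())
        if cls is None:
            continue
        pos = f.GetPos()
        feats.append(PharmFeature([pos.x, pos.y, pos.z], cls, radius=radius))
    if not feats:
        return None
    atoms = np.array([[conf.GetAtomPosition(i).x, conf.GetAtomPosition(i).y,
                       conf.GetAtomPosition(i).z]
                      for i in range(mol.GetNumAtoms())
                      if mol.GetAtomWithIdx(i).GetAtomicNum() > 1])
    return MoleculeRecord(mol_id, feats, atoms=atoms, is_active=is_active)


def read_sdf_library(path, is_active: bool = False,
                     radius: float = 1.0) -> list[MoleculeRecord]:
    """Read an SDF file into molecule feature records.

    Molecules that fail to parse or carry no typed features are skipped.
    All records receive the same activity label; screen-ready libraries
    are usually assembled from one actives SDF and one decoys SDF.
    """
    from rdkit import Chem

    supplier = Chem.SDMolSupplier(str(path), removeHs=False)
    factory = _feature_factory()
    records = []
    for i, mol in enumerate(supplier):
        if mol is None or mol.GetNumConformers() == 0:
            continue
        name = mol.GetProp("_Name") if mol.HasProp("_Name") else ""
        rec = mol_to_record(mol, name or f"mol_{i}", is_active, radius,
                            factory)
        if rec is not None:
            records.append(rec)
    if not records:
        raise FormatError(f"no usable molecules with 3D coordinates in {path}")
    return records
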