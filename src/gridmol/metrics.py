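"""Molecule-level evaluation metrics for generated structures.

Definitions:

* **valid** — a single connected fragment that passes an independent
  sanitization (valence check plus kekulization attempt).
* **novel** — canonical SMILES not present in a reference (training) set.
* **unique** — canonical SMILES not generated earlier in the evaluation.
* **Tanimoto similarity** — bit-set intersection over union of two
  molecular fingerprints (default: RDKit 2048-bit path fingerprint).
* **per-target diversity** — inverse of the mean pairwise Tanimoto
  similarity among molecules generated for one receptor.
* **UFF relaxation** — Universal Force Field minimization of the internal
  degrees of freedom (receptor, when given, held rigid); reported as the
  energy change and heavy-atom RMSD between pre- and post-minimization
  poses.  Downstream analyses typically gate on RMSD < 2 Å.

Novelty and uniqueness are computed over valid molecules (canonical SMILES
is undefined otherwise); percentages over all samples are also reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from rdkit import Chem, DataStructs
from rdkit.Chem import AllChem, Descriptors

__all__ = [
    "is_valid", "canonical_smiles", "is_novel", "is_unique", "fingerprint",
    "tanimoto", "per_target_diversity", "relax_and_rmsd", "molecular_weight",
    "evaluate_molecules", "tabulate_internal_coordinates",
]


def _as_rdkit(mol) -> Chem.Mol | None:
    if mol is None:
        return None
    if isinstance(mol, Chem.Mol):
        return mol
    return mol.to_rdkit()  # InferredMolecule


def _sanitized_copy(mol) -> Chem.Mol | None:
    rd = _as_rdkit(mol)
    if rd is None:
        return None
    rd = Chem.Mol(rd)
    try:
        Chem.SanitizeMol(rd)
        return rd
    except Exception:
        return None


def is_valid(mol) -> bool:
    """Single connected fragment and sanitizable."""
    rd = _as_rdkit(mol)
    if rd is None or rd.GetNumAtoms() == 0:
        return False
    if len(Chem.GetMolFrags(rd)) != 1:
        return False
    return _sanitized_copy(rd) is not None


def canonical_smiles(mol) -> str | None:
    rd = _sanitized_copy(mol)
    return None if rd is None else Chem.MolToSmiles(rd)


def is_novel(mol, reference_smiles: set) -> bool:
    smi = canonical_smiles(mol)
    if smi is None:
        raise ValueError("novelty is undefined for invalid molecules")
    return smi not in reference_smiles


def is_unique(mol, generated: set):
    """Membership test against the running set; returns (bool, updated set)."""
    smi = canonical_smiles(mol)
    if smi is None:
        raise ValueError("uniqueness is undefined for invalid molecules")
    unique = smi not in generated
    return unique, generated | {smi}


def fingerprint(mol, kind: str = "path", n_bits: int = 2048):
    rd = _sanitized_copy(mol)
    if rd is None:
        raise ValueError("cannot fingerprint an invalid molecule")
    if kind == "path":
        return Chem.RDKFingerprint(rd, fpSize=n_bits)
    if kind == "morgan":
        return AllChem.GetMorganFingerprintAsBitVect(rd, 2, nBits=n_bits)
    raise ValueError(f"unknown fingerprint kind {kind!r}")


def tanimoto(mol_a, mol_b, kind: str = "path") -> float:
    """|bits_a ∩ bits_b| / |bits_a ∪ bits_b|; empty∪empty is 1 for identical
    canonical SMILES, else 0."""
    fa, fb = fingerprint(mol_a, kind), fingerprint(mol_b, kind)
    if fa.GetNumOnBits() == 0 and fb.GetNumOnBits() == 0:
        return 1.0 if canonical_smiles(mol_a) == canonical_smiles(mol_b) else 0.0
    return float(DataStructs.TanimotoSimilarity(fa, fb))


def diversity_from_similarities(sims) -> float:
    """Inverse of the mean pairwise similarity."""
    mean = float(np.mean(np.asarray(sims, dtype=float)))
    return float("inf") if mean == 0 else 1.0 / mean


def per_target_diversity(mols, kind: str = "path") -> float | None:
    """1 / mean pairwise Tanimoto over unordered distinct pairs; None if < 2."""
    mols = list(mols)
    if len(mols) < 2:
        return None
    fps = [fingerprint(m, kind) for m in mols]
    sims = []
    for i in range(len(fps)):
        for j in range(i + 1, len(fps)):
            fa, fb = fps[i], fps[j]
            if fa.GetNumOnBits() == 0 and fb.GetNumOnBits() == 0:
                sims.append(1.0 if canonical_smiles(mols[i]) == canonical_smiles(mols[j]) else 0.0)
            else:
                sims.append(float(DataStructs.TanimotoSimilarity(fa, fb)))
    return diversity_from_similarities(sims)


def relax_and_rmsd(mol, receptor: Chem.Mol | None = None, max_iters: int = 500):
    """UFF relaxation; returns (delta_E kcal/mol, heavy-atom RMSD Å).

    With a receptor, the combined system is minimized with every receptor
    atom held fixed.  Returns (None, None, reason) on force-field setup
    failure; otherwise (delta_E, rmsd, None).
    """
    rd = _sanitized_copy(mol)
    if rd is None or rd.GetNumConformers() == 0:
        return None, None, "invalid molecule or missing 3D coordinates"
    try:
        n_lig = rd.GetNumAtoms()
        if receptor is not None:
            combined = Chem.CombineMols(rd, receptor)
            ff = AllChem.UFFGetMoleculeForceField(combined)
            for idx in range(n_lig, combined.GetNumAtoms()):
                ff.AddFixedPoint(idx)
            work = combined
        else:
            work = Chem.Mol(rd)
            ff = AllChem.UFFGetMoleculeForceField(work)
        if ff is None:
            return None, None, "UFF setup failed"
        e0 = ff.CalcEnergy()
        ff.Minimize(maxIts=max_iters)
        e1 = ff.CalcEnergy()
        conf0 = rd.GetConformer()
        conf1 = work.GetConformer()
        heavy = [a.GetIdx() for a in rd.GetAtoms() if a.GetAtomicNum() > 1]
        before = np.array([list(conf0.GetAtomPosition(i)) for i in heavy])
        after = np.array([list(conf1.GetAtomPosition(i)) for i in heavy])
        rmsd = float(np.sqrt(np.mean(np.sum((before - after) ** 2, axis=1))))
        return float(e1 - e0), rmsd, None
    except Exception as exc:
        return None, None, f"UFF failure: {exc}"


def molecular_weight(mol) -> float:
    """Average molecular weight in Da, including implicit hydrogens."""
    rd = _sanitized_copy(mol)
    if rd is None:
        rd = _as_rdkit(mol)
        if rd is None or rd.GetNumAtoms() == 0:
            return 0.0
    return float(Descriptors.MolWt(rd))


def evaluate_molecules(mols, reference_smiles=(), reference_mol=None,
                       fingerprint_kind: str = "path", relax: bool = False,
                       receptor: Chem.Mol | None = None):
    """Per-molecule metric table plus aggregate report.

    Returns (DataFrame, dict).  Novelty/uniqueness percentages are reported
    both over valid molecules (default convention) and over all samples.
    """
    reference_smiles = set(reference_smiles)
    rows = []
    seen: set = set()
    for k, mol in enumerate(mols):
        valid = is_valid(mol)
        smi = canonical_smiles(mol) if valid else None
        novel = (smi not in reference_smiles) if valid else None
        unique = (smi not in seen) if valid else None
        if valid:
            seen.add(smi)
        row = {
            "index": k, "valid": valid, "canonical_smiles": smi,
            "novel": novel, "unique": unique,
            "mol_weight": molecular_weight(mol) if valid else None,
            "tanimoto_to_reference": (
                tanimoto(mol, reference_mol, fingerprint_kind)
                if valid and reference_mol is not None else None
            ),
        }
        if relax and valid:
            de, rmsd, reason = relax_and_rmsd(mol, receptor)
            row.update(delta_e_minimization=de, minimized_rmsd=rmsd,
                       relax_failure=reason)
        rows.append(row)
    df = pd.DataFrame(rows)
    n = len(df)
    valid_df = df[df["valid"]] if n else df
    n_valid = len(valid_df)
    report = {
        "n_molecules": n,
        "percent_valid": 100.0 * n_valid / n if n else 0.0,
        "percent_novel_of_valid": (
            100.0 * valid_df["novel"].mean() if n_valid else None
        ),
        "percent_unique_of_valid": (
            100.0 * valid_df["unique"].mean() if n_valid else None
        ),
        "percent_novel_of_all": 100.0 * valid_df["novel"].sum() / n if n else 0.0,
        "percent_unique_of_all": 100.0 * valid_df["unique"].sum() / n if n else 0.0,
        "diversity": per_target_diversity(
            [m for m, v in zip(mols, df["valid"]) if v], fingerprint_kind
        ) if n_valid >= 2 else None,
    }
    if relax and "minimized_rmsd" in df:
        rmsds = df["minimized_rmsd"].dropna()
        report["percent_rmsd_lt_2A"] = (
            100.0 * float((rmsds < 2.0).mean()) if len(rmsds) else None
        )
    return df, report


def tabulate_internal_coordinates(mols):
    """Bond-length / angle / torsion tables keyed by typed element tuples.

    Bonds are keyed by (element_i, element_j, order) with the element pair
    sorted; angles and torsions by their element paths (canonical direction).
    Returns three DataFrames (bonds, angles, torsions).
    """
    bond_rows, angle_rows, torsion_rows = [], [], []
    for mol in mols:
        rd = _sanitized_copy(mol)
        if rd is None or rd.GetNumConformers() == 0:
            continue
        conf = rd.GetConformer()
        pos = np.array([list(conf.GetAtomPosition(i)) for i in range(rd.GetNumAtoms())])
        sym = [a.GetSymbol() for a in rd.GetAtoms()]
        for b in rd.GetBonds():
            i, j = b.GetBeginAtomIdx(), b.GetEndAtomIdx()
            key = tuple(sorted((sym[i], sym[j]))) + (str(b.GetBondType()),)
            bond_rows.append({"type": key, "length": float(np.linalg.norm(pos[i] - pos[j]))})
        from rdkit.Chem import rdMolTransforms

        for a in rd.GetAtoms():
            j = a.GetIdx()
            nbrs = [x.GetIdx() for x in a.GetNeighbors()]
            for ii in range(len(nbrs)):
                for kk in range(ii + 1, len(nbrs)):
                    i, k = nbrs[ii], nbrs[kk]
                    path = (sym[i], sym[j], sym[k])
                    if path[::-1] < path:
                        path = path[::-1]
                        i, k = k, i
                    angle_rows.append({
                        "type": path,
                        "angle_deg": float(rdMolTransforms.GetAngleDeg(conf, i, j, k)),
                    })
        for b in rd.GetBonds():
            j, k = b.GetBeginAtomIdx(), b.GetEndAtomIdx()
            for i in [x.GetIdx() for x in rd.GetAtomWithIdx(j).GetNeighbors() if x.GetIdx() != k]:
                for l in [x.GetIdx() for x in rd.GetAtomWithIdx(k).GetNeighbors() if x.GetIdx() != j]:
                    path = (sym[i], sym[j], sym[k], sym[l])
                    if path[::-1] < path:
                        continue
                    torsion_rows.append({
                        "type": path,
                        "torsion_deg": float(rdMolTransforms.GetDihedralDeg(conf, i, j, k, l)),
                    })
    return (pd.DataFrame(bond_rows), pd.DataFrame(angle_rows), pd.DataFrame(torsion_rows))
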