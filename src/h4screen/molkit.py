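"""Molecule ingestion, 2D descriptors, fingerprints and rule-based filters.

This module owns everything that touches chemical structures directly:
reading SMILES/SDF inputs, computing the eleven-descriptor panel used by
the range-filter learner, ECFP4-style fingerprints with Tanimoto
similarity, greedy diversity filtering, drug-/lead-likeness rules
(Lipinski, Oprea) plus the charge/nitrogen/surface-area rule triple that
characterises H4-receptor antagonists, and stratified train/test
splitting.

All descriptors are 2D (computable from the molecular graph alone); no
conformers are ever generated. Molecules are used as written in the input
SMILES — protonation states are the caller's responsibility.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
from rdkit import Chem
from rdkit.Chem import Crippen, Descriptors, rdFingerprintGenerator, rdMolDescriptors
from rdkit.Chem.AllChem import ComputeGasteigerCharges

__all__ = [
    "DESCRIPTOR_PANEL",
    "RULES",
    "Fingerprint",
    "LabelledMolecule",
    "MoleculeParseWarning",
    "compute_descriptors",
    "diversity_filter",
    "fingerprint",
    "read_molecules",
    "rule_filter",
    "split_train_test",
    "tanimoto",
]

#: Ordered 2D descriptor panel (name -> unit). Every descriptor is
#: computable from the parsed structure alone.
DESCRIPTOR_PANEL: dict[str, str] = {
    "molecular_weight": "Da",
    "total_charge": "e",
    "n_nitrogen": "count",
    "n_oxygen": "count",
    "n_aromatic_atoms": "count",
    "hbd": "count",
    "hba": "count",
    "logp": "",
    "n_rings": "count",
    "n_rot_bonds": "count",
    "fasa_neg": "fraction",
}

INF = math.inf

#: Rule filters as conjunctions of closed descriptor intervals.
#: ``three_rules`` is the published charge/nitrogen/negative-surface rule
#: triple for H4 antagonists; all bounds are inclusive as printed.
RULES: dict[str, dict[str, tuple[float, float]]] = {
    "lipinski": {
        "hbd": (-INF, 5),
        "hba": (-INF, 10),
        "molecular_weight": (-INF, 500),
        "logp": (-INF, 5),
    },
    "oprea": {
        "molecular_weight": (-INF, 450),
        "logp": (-3.5, 4.5),
        "n_rings": (-INF, 4),
        "n_rot_bonds": (-INF, 10),
        "hbd": (-INF, 5),
        "hba": (-INF, 8),
    },
    "three_rules": {
        "total_charge": (1, 1),
        "n_nitrogen": (3, 7),
        "fasa_neg": (-INF, 0.42),
    },
}


class MoleculeParseWarning(UserWarning):
    """A record in an input file could not be parsed and was skipped."""


@dataclass
class LabelledMolecule:
    """A molecule with an activity label and (optionally) its descriptor panel.

    The label is fixed at ingestion; descriptor computation returns a new
    instance rather than mutating in place.
    """

    id: str
    smiles: str
    label: str = "unknown"
    descriptors: dict[str, float] = field(default_factory=dict)
    flagged: bool = False

    def __post_init__(self) -> None:
        if self.label not in ("active", "inactive", "unknown"):
            raise ValueError(f"invalid label {self.label!r}")

    def mol(self) -> Chem.Mol:
        m = Chem.MolFromSmiles(self.smiles)
        if m is None:
            raise ValueError(f"unparseable SMILES for {self.id!r}: {self.smiles!r}")
        return m


def read_molecules(
    path: str | Path,
    format: str | None = None,
    label: str = "unknown",
) -> list[LabelledMolecule]:
    """Read molecules from a .smi or SDF file, skipping unparseable records.

    The .smi dialect is one record per line, ``SMILES<whitespace>id``;
    lines beginning with ``#`` are ignored and a missing id becomes
    ``mol{k}`` (1-based record number). Per-record parse failures emit a
    :class:`MoleculeParseWarning` with the offending line number; a file
    with zero parseable records is an error.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        format = "sdf" if path.suffix.lower() in (".sdf", ".mol", ".sd") else "smi"
    if format not in ("smi", "sdf"):
        raise ValueError(f"unknown format {format!r}")

    out: list[LabelledMolecule] = []
    if format == "smi":
        k = 0
        for lineno, line in enumerate(path.read_text().splitlines(), start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            k += 1
            parts = line.split(None, 1)
            smiles = parts[0]
            mol_id = parts[1].strip() if len(parts) > 1 else f"mol{k}"
            if Chem.MolFromSmiles(smiles) is None:
                warnings.warn(
                    f"{path.name}:{lineno}: unparseable SMILES {smiles!r}, skipped",
                    MoleculeParseWarning,
                    stacklevel=2,
                )
                continue
            out.append(LabelledMolecule(id=mol_id, smiles=smiles, label=label))
    else:
        supplier = Chem.SDMolSupplier(str(path), sanitize=True)
        for k, mol in enumerate(supplier, start=1):
            if mol is None:
                warnings.warn(
                    f"{path.name}: SDF record {k} unparseable, skipped",
                    MoleculeParseWarning,
                    stacklevel=2,
                )
                continue
            name = mol.GetProp("_Name") if mol.HasProp("_Name") else ""
            out.append(
                LabelledMolecule(
                    id=name.strip() or f"mol{k}",
                    smiles=Chem.MolToSmiles(mol),
                    label=label,
                )
            )
    if not out:
        raise ValueError(f"{path}: no parseable records")
    return out


def _fasa_neg(mol: Chem.Mol) -> float:
    """Fraction of the Labute VdW surface area on negatively charged atoms.

    Approximates MOE's fractional negative VdW surface area using
    Gasteiger partial charges and per-heavy-atom Labute ASA
    contributions; implicit-hydrogen area counts as non-negative.
    """
    ComputeGasteigerCharges(mol)
    contribs, h_contrib = rdMolDescriptors._CalcLabuteASAContribs(mol)
    total = float(sum(contribs)) + float(h_contrib)
    if total <= 0:
        raise ValueError("zero VdW surface area")
    neg = 0.0
    for atom, area in zip(mol.GetAtoms(), contribs):
        q = atom.GetDoubleProp("_GasteigerCharge")
        if not math.isfinite(q):
            raise ValueError("Gasteiger charge assignment failed")
        if q < 0:
            neg += float(area)
    return neg / total


def compute_descriptors(mol: LabelledMolecule) -> LabelledMolecule:
    """Return a copy of *mol* with the full descriptor panel attached.

    If charge assignment fails (exotic atoms), the returned record is
    flagged and should be excluded downstream.
    """
    m = mol.mol()
    d: dict[str, float] = {
        "molecular_weight": Descriptors.MolWt(m),
        "total_charge": float(Chem.GetFormalCharge(m)),
        "n_nitrogen": float(sum(1 for a in m.GetAtoms() if a.GetAtomicNum() == 7)),
        "n_oxygen": float(sum(1 for a in m.GetAtoms() if a.GetAtomicNum() == 8)),
        "n_aromatic_atoms": float(sum(1 for a in m.GetAtoms() if a.GetIsAromatic())),
        "hbd": float(rdMolDescriptors.CalcNumHBD(m)),
        "hba": float(rdMolDescriptors.CalcNumHBA(m)),
        "logp": Crippen.MolLogP(m),
        "n_rings": float(rdMolDescriptors.CalcNumRings(m)),
        "n_rot_bonds": float(rdMolDescriptors.CalcNumRotatableBonds(m)),
    }
    flagged = False
    try:
        d["fasa_neg"] = _fasa_neg(m)
    except ValueError:
        d["fasa_neg"] = float("nan")
        flagged = True
    return replace(mol, descriptors=d, flagged=flagged)


# ---------------------------------------------------------------------------
# Fingerprints and similarity


@dataclass(frozen=True)
class Fingerprint:
    """Sparse circular fingerprint: set of on-bit indices in [0, bit_width)."""

    on_bits: frozenset[int]
    bit_width: int = 2048

    def __post_init__(self) -> None:
        if self.on_bits and not all(0 <= b < self.bit_width for b in self.on_bits):
            raise ValueError("bit index out of range")


_MORGAN = rdFingerprintGenerator.GetMorganGenerator(radius=2, fpSize=2048)


def fingerprint(mol: LabelledMolecule | Chem.Mol) -> Fingerprint:
    """ECFP4-equivalent fingerprint: Morgan radius 2 hashed to 2048 bits."""
    m = mol.mol() if isinstance(mol, LabelledMolecule) else mol
    bv = _MORGAN.GetFingerprint(m)
    return Fingerprint(on_bits=frozenset(bv.GetOnBits()), bit_width=bv.GetNumBits())


def tanimoto(a: Fingerprint, b: Fingerprint) -> float:
    """Tanimoto coefficient |a∩b| / |a∪b|; 0.0 when both sets are empty."""
    if a.bit_width != b.bit_width:
        raise ValueError(f"bit_width mismatch: {a.bit_width} != {b.bit_width}")
    union = len(a.on_bits | b.on_bits)
    if union == 0:
        return 0.0
    return len(a.on_bits & b.on_bits) / union


def diversity_filter(
    mols: Sequence[LabelledMolecule],
    threshold: float,
    sim: Callable[[LabelledMolecule, LabelledMolecule], float] | None = None,
) -> list[LabelledMolecule]:
    """Greedy leader diversity selection in input order.

    The first molecule is always retained; each subsequent molecule is
    retained iff its similarity to every already-retained leader is
    strictly below *threshold*. By default similarity is Tanimoto on
    ECFP4 fingerprints; *sim* can replace it (e.g. a precomputed matrix
    lookup).
    """
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    if sim is None:
        fps = {id(m): fingerprint(m) for m in mols}

        def sim(a: LabelledMolecule, b: LabelledMolecule) -> float:  # noqa: F811
            return tanimoto(fps[id(a)], fps[id(b)])

    leaders: list[LabelledMolecule] = []
    for m in mols:
        if all(sim(m, lead) < threshold for lead in leaders):
            leaders.append(m)
    return leaders


# ---------------------------------------------------------------------------
# Rule filters and splitting


def rule_filter(mol: LabelledMolecule | Mapping[str, float], rule: str) -> bool:
    """Evaluate a named rule set (lipinski / oprea / three_rules) on a molecule.

    All bounds are inclusive. Raises ``KeyError`` if a required
    descriptor is missing.
    """
    try:
        constraints = RULES[rule]
    except KeyError:
        raise ValueError(f"unknown rule {rule!r}") from None
    desc = mol.descriptors if isinstance(mol, LabelledMolecule) else mol
    for name, (low, high) in constraints.items():
        v = desc[name]
        if not (low <= v <= high):
            return False
    return True


def split_train_test(
    mols: Sequence[LabelledMolecule],
    fraction_train: float,
    seed: int,
) -> tuple[list[LabelledMolecule], list[LabelledMolecule]]:
    """Random stratified split: per class, round(fraction·n) go to train.

    Rounding is half-up so 78 actives at 2/3 give 52/26 and 9000 decoys
    give 6000/3000. Reproducible for a fixed seed; a class with fewer
    than two members cannot be split.
    """
    if not 0 < fraction_train < 1:
        raise ValueError("fraction_train must be in (0, 1)")
    rng = np.random.default_rng(seed)
    by_class: dict[str, list[LabelledMolecule]] = {}
    for m in mols:
        by_class.setdefault(m.label, []).append(m)
    train: list[LabelledMolecule] = []
    test: list[LabelledMolecule] = []
    for label in sorted(by_class):
        members = by_class[label]
        n = len(members)
        if n < 2:
            raise ValueError(f"class {label!r} has {n} member(s); cannot split")
        n_train = int(math.floor(fraction_train * n + 0.5))
        n_train = min(max(n_train, 1), n - 1)
        order = rng.permutation(n)
        chosen = set(order[:n_train].tolist())
        train.extend(m for i, m in enumerate(members) if i in chosen)
        test.extend(m for i, m in enumerate(members) if i not in chosen)
    return train, test


def descriptor_table(mols: Iterable[LabelledMolecule]):
    """Descriptor table as a DataFrame: id first column, then label, panel."""
    import pandas as pd

    rows = []
    for m in mols:
        row: dict[str, object] = {"id": m.id, "label": m.label}
        row.update({k: m.descriptors.get(k, float("nan")) for k in DESCRIPTOR_PANEL})
        rows.append(row)
    return pd.DataFrame(rows)
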