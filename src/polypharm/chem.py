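"""Small-molecule structure handling: parsing, identity, fingerprints, descriptors.

Everything downstream (rubric scoring, similarity networks, ADMET rules)
goes through this module, so fingerprint dialects and descriptor flavors
are pinned here once.

Fingerprint dialects
--------------------
``path1024``
    Linear atom-bond paths up to depth 7 (bonds), hashed onto 1024 bits
    (RDKit's Daylight-style ``RDKFingerprint``).  This is the classic
    "standard" path-based hashed fingerprint used for similarity heatmaps
    and networks.
``ecfp4_2048`` / ``ecfp6_2048``
    Extended-connectivity (Morgan) fingerprints of radius 2 / 3 folded to
    2048 bits.  ECFP6 is the dialect used for novelty checks against
    reference-active sets.

All fingerprints are binary bit-sets and ignore stereochemistry; canonical
identity (:func:`canonical_key`) preserves stereochemistry.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from rdkit import Chem, RDLogger
from rdkit.Chem import Crippen, Descriptors, Lipinski, rdMolDescriptors
from rdkit import DataStructs

RDLogger.DisableLog("rdApp.*")

__all__ = [
    "Molecule",
    "Fingerprint",
    "DescriptorSet",
    "SmilesParseError",
    "parse_smiles",
    "canonical_key",
    "fingerprint",
    "tanimoto",
    "similarity_matrix",
    "descriptors",
    "substructure_match",
    "FP_DIALECTS",
]

#: dialect -> (nbits, radius_or_depth)
FP_DIALECTS = {
    "path1024": (1024, 7),
    "ecfp4_2048": (2048, 2),
    "ecfp6_2048": (2048, 3),
}


class SmilesParseError(ValueError):
    """Raised when a SMILES or SMARTS string cannot be parsed."""


def _check_balanced(text: str) -> None:
    """Cheap pre-check so syntax errors can name an offending position."""
    depth = 0
    for pos, ch in enumerate(text):
        if ch == "(":
            depth += 1
        elif ch == ")":
            depth -= 1
            if depth < 0:
                raise SmilesParseError(
                    f"unbalanced ')' at position {pos} in {text!r}"
                )
    if depth != 0:
        raise SmilesParseError(f"unclosed '(' in {text!r}")
    digits: dict[str, int] = {}
    in_bracket = False
    for pos, ch in enumerate(text):
        if ch == "[":
            in_bracket = True
        elif ch == "]":
            in_bracket = False
        elif ch.isdigit() and not in_bracket:
            digits[ch] = digits.get(ch, 0) + 1
    for digit, count in digits.items():
        if count % 2 != 0:
            raise SmilesParseError(
                f"unclosed ring bond {digit!r} in {text!r}"
            )


class Molecule:
    """A parsed small molecule: atom/bond graph with perceived aromaticity.

    Thin value wrapper around an RDKit ``Mol``; ``atoms`` and ``bonds``
    expose the graph in plain tuples for oracle-style inspection.
    """

    __slots__ = ("rdmol", "source_text")

    def __init__(self, rdmol: Chem.Mol, source_text: str):
        self.rdmol = rdmol
        self.source_text = source_text

    @property
    def atoms(self) -> list[tuple[str, int, bool, int]]:
        """(element symbol, formal charge, aromatic flag, attached-H count)."""
        return [
            (a.GetSymbol(), a.GetFormalCharge(), a.GetIsAromatic(), a.GetTotalNumHs())
            for a in self.rdmol.GetAtoms()
        ]

    @property
    def bonds(self) -> list[tuple[tuple[int, int], float, bool]]:
        """((atom i, atom j), bond order, aromatic flag)."""
        return [
            (
                (b.GetBeginAtomIdx(), b.GetEndAtomIdx()),
                b.GetBondTypeAsDouble(),
                b.GetIsAromatic(),
            )
            for b in self.rdmol.GetBonds()
        ]

    @property
    def num_heavy_atoms(self) -> int:
        return self.rdmol.GetNumAtoms()

    def __repr__(self) -> str:  # pragma: no cover
        return f"Molecule({self.source_text!r})"


def parse_smiles(text: str) -> Molecule:
    """Parse a SMILES string into a :class:`Molecule`.

    Raises :class:`SmilesParseError` on syntax or valence problems; ring and
    branch imbalance is reported with the offending position.
    """
    if not isinstance(text, str) or not text.strip():
        raise SmilesParseError("empty SMILES string")
    text = text.strip()
    _check_balanced(text)
    mol = Chem.MolFromSmiles(text, sanitize=True)
    if mol is None:
        raise SmilesParseError(f"cannot parse SMILES {text!r} (syntax or valence)")
    return Molecule(mol, text)


def canonical_key(mol: Molecule | str) -> str:
    """Canonical identity string, equal for chemically identical structures.

    Invariant under input atom ordering and aromatic vs. kekulized writing;
    stereochemistry is preserved (distinct stereoisomers get distinct keys).
    """
    if isinstance(mol, str):
        mol = parse_smiles(mol)
    return Chem.MolToSmiles(mol.rdmol, isomericSmiles=True, canonical=True)


@dataclass(frozen=True)
class Fingerprint:
    """Binary molecular fingerprint of a fixed dialect."""

    bits: frozenset[int]
    nbits: int
    dialect: str
    radius_or_depth: int

    @property
    def popcount(self) -> int:
        return len(self.bits)

    def to_numpy(self) -> np.ndarray:
        arr = np.zeros(self.nbits, dtype=bool)
        arr[list(self.bits)] = True
        return arr


def _rdkit_bitvect(mol: Molecule, dialect: str, nbits: int, radius_or_depth: int):
    rd = mol.rdmol
    if dialect == "path1024" or dialect.startswith("path"):
        return Chem.RDKFingerprint(rd, maxPath=radius_or_depth, fpSize=nbits)
    if dialect.startswith("ecfp"):
        return rdMolDescriptors.GetMorganFingerprintAsBitVect(
            rd, radius=radius_or_depth, nBits=nbits, useChirality=False
        )
    raise ValueError(f"unknown fingerprint dialect {dialect!r}")


def fingerprint(
    mol: Molecule | str,
    dialect: str = "path1024",
    nbits: int | None = None,
    radius_or_depth: int | None = None,
) -> Fingerprint:
    """Compute a binary fingerprint in one of the registered dialects.

    Deterministic across runs and platforms (RDKit's fixed hashing); empty
    molecules yield an all-zero bitset rather than an error.
    """
    if isinstance(mol, str):
        mol = parse_smiles(mol)
    if dialect not in FP_DIALECTS:
        raise ValueError(
            f"unknown fingerprint dialect {dialect!r}; expected one of {sorted(FP_DIALECTS)}"
        )
    default_nbits, default_rd = FP_DIALECTS[dialect]
    nbits = default_nbits if nbits is None else nbits
    radius_or_depth = default_rd if radius_or_depth is None else radius_or_depth
    if nbits <= 0 or (nbits & (nbits - 1)) != 0:
        raise ValueError(f"nbits must be a positive power of two, got {nbits}")
    if mol.rdmol.GetNumAtoms() == 0:
        bits: frozenset[int] = frozenset()
    else:
        bv = _rdkit_bitvect(mol, dialect, nbits, radius_or_depth)
        bits = frozenset(bv.GetOnBits())
    return Fingerprint(bits=bits, nbits=nbits, dialect=dialect, radius_or_depth=radius_or_depth)


def tanimoto(a: Fingerprint, b: Fingerprint, empty_value: float = 1.0) -> float:
    """Tanimoto coefficient |a∧b| / |a∨b| in [0, 1].

    Two all-zero fingerprints compare as ``empty_value`` (default 1.0:
    identical objects); set ``empty_value=0.0`` for the stricter convention.
    """
    if a.nbits != b.nbits or a.dialect != b.dialect:
        raise ValueError(
            f"fingerprint mismatch: {a.dialect}/{a.nbits} vs {b.dialect}/{b.nbits}"
        )
    union = len(a.bits | b.bits)
    if union == 0:
        return empty_value
    return len(a.bits & b.bits) / union


def similarity_matrix(
    set_a: Sequence[Molecule | str],
    set_b: Sequence[Molecule | str] | None = None,
    dialect: str = "path1024",
    nbits: int | None = None,
    radius_or_depth: int | None = None,
    empty_value: float = 1.0,
) -> np.ndarray:
    """Pairwise Tanimoto matrix between two molecule sets.

    With ``set_b=None`` the matrix is square, symmetric, unit-diagonal.
    """
    fps_a = [fingerprint(m, dialect, nbits, radius_or_depth) for m in set_a]
    if set_b is None:
        fps_b = fps_a
    else:
        fps_b = [fingerprint(m, dialect, nbits, radius_or_depth) for m in set_b]
    out = np.empty((len(fps_a), len(fps_b)), dtype=float)
    for i, fa in enumerate(fps_a):
        for j, fb in enumerate(fps_b):
            out[i, j] = tanimoto(fa, fb, empty_value=empty_value)
    return out


@dataclass(frozen=True)
class DescriptorSet:
    """Physicochemical descriptors feeding the rubric and ADMET rule sets.

    ``clogp`` is RDKit's Crippen atom-contribution logP (a Wildman–Crippen
    scheme); HBD/HBA use the Lipinski convention (HBD = N/O bearing >= 1 H,
    HBA = count of N and O atoms); ``tpsa`` is the Ertl fragment-contribution
    topological polar surface area in Å².
    """

    mw: float
    clogp: float
    hbd: int
    hba: int
    tpsa: float
    rotatable_bonds: int
    heavy_atoms: int
    molar_refractivity: float
    ring_count: int
    carbon_count: int
    heteroatom_count: int


def descriptors(mol: Molecule | str) -> DescriptorSet:
    """Compute the full descriptor set for one molecule."""
    if isinstance(mol, str):
        mol = parse_smiles(mol)
    rd = mol.rdmol
    carbons = sum(1 for a in rd.GetAtoms() if a.GetSymbol() == "C")
    hetero = sum(1 for a in rd.GetAtoms() if a.GetAtomicNum() not in (1, 6))
    return DescriptorSet(
        mw=Descriptors.MolWt(rd),
        clogp=Crippen.MolLogP(rd),
        hbd=Lipinski.NumHDonors(rd),
        hba=Lipinski.NOCount(rd),
        tpsa=rdMolDescriptors.CalcTPSA(rd),
        rotatable_bonds=Lipinski.NumRotatableBonds(rd),
        heavy_atoms=rd.GetNumHeavyAtoms(),
        molar_refractivity=Crippen.MolMR(rd),
        ring_count=rdMolDescriptors.CalcNumRings(rd),
        carbon_count=carbons,
        heteroatom_count=hetero,
    )


def substructure_match(mol: Molecule | str, pattern: str) -> list[tuple[int, ...]]:
    """All distinct atom-index matches of a SMARTS pattern in a molecule.

    Matches are uniquified over atom sets (symmetry-equivalent mappings of
    the same atoms count once) and returned in deterministic order.
    """
    if isinstance(mol, str):
        mol = parse_smiles(mol)
    query = Chem.MolFromSmarts(pattern)
    if query is None:
        raise SmilesParseError(f"invalid SMARTS pattern {pattern!r}")
    matches = mol.rdmol.GetSubstructMatches(query, uniquify=True)
    return sorted(matches)
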