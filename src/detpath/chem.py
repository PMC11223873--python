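"""Chemical identity, canonicalisation, fingerprinting and similarity.

Every other module treats molecules through the :class:`Compound` wrapper
defined here.  Identity is canonical-SMILES equality (optionally ignoring
stereochemistry for metabolome membership tests), and similarity is the
Tanimoto coefficient over Morgan fingerprints.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Optional

from rdkit import Chem, RDLogger
from rdkit.Chem import DataStructs, inchi, rdFingerprintGenerator

RDLogger.DisableLog("rdApp.*")

__all__ = [
    "ChemConfig",
    "Compound",
    "StructureParseError",
    "canonicalize",
    "configure",
    "get_config",
    "tanimoto",
]


class StructureParseError(ValueError):
    """Raised when a SMILES/InChI string cannot be parsed."""

    def __init__(self, structure: str, reason: str = "unparsable structure"):
        self.structure = structure
        super().__init__(f"{reason}: {structure!r}")


@dataclass(frozen=True)
class ChemConfig:
    """Session-wide fingerprint settings.

    The similarity guidance score is a tunable: fingerprint family, radius
    and length are fixed per session so that all fingerprints compared in
    one run have identical shape.
    """

    fp_radius: int = 2
    fp_bits: int = 2048


_config = ChemConfig()


def configure(fp_radius: int = 2, fp_bits: int = 2048) -> ChemConfig:
    """Replace the session fingerprint configuration."""
    global _config
    _config = ChemConfig(fp_radius=fp_radius, fp_bits=fp_bits)
    return _config


def get_config() -> ChemConfig:
    return _config


@lru_cache(maxsize=8)
def _fp_generator(radius: int, bits: int):
    return rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=bits)


def _parse_mol(structure: str) -> Chem.Mol:
    if not isinstance(structure, str) or not structure.strip():
        raise StructureParseError(str(structure), "empty structure")
    s = structure.strip()
    if s.startswith("InChI="):
        mol = inchi.MolFromInchi(s, treatWarningAsError=False)
    else:
        mol = Chem.MolFromSmiles(s)
    if mol is None:
        raise StructureParseError(s)
    return mol


def canonicalize(structure: str, ignore_stereo: bool = False) -> str:
    """Return the canonical structure key for a SMILES or InChI string.

    Idempotent: canonicalizing a canonical key returns the key itself.
    With ``ignore_stereo`` the key drops stereochemical annotation, which
    is used for chassis-metabolome membership where stereo labelling is
    inconsistent across sources.
    """
    mol = _parse_mol(structure)
    return Chem.MolToSmiles(mol, isomericSmiles=not ignore_stereo)


class Compound:
    """A molecule with canonical identity and a lazily computed fingerprint.

    Construction fails (``StructureParseError``) for unparsable input, so a
    ``Compound`` instance is always chemically valid.  Equality and hashing
    are on ``canonical_key``.
    """

    __slots__ = ("id", "structure", "mol", "canonical_key", "_fp", "_key_nostereo")

    def __init__(self, structure: str, id: Optional[str] = None):
        self.structure = structure
        self.mol = _parse_mol(structure)
        self.canonical_key = Chem.MolToSmiles(self.mol)
        self.id = id if id is not None else self.canonical_key
        self._fp = None
        self._key_nostereo: Optional[str] = None

    @property
    def key_nostereo(self) -> str:
        """Canonical key with stereochemistry stripped."""
        if self._key_nostereo is None:
            self._key_nostereo = Chem.MolToSmiles(self.mol, isomericSmiles=False)
        return self._key_nostereo

    @property
    def fingerprint(self):
        if self._fp is None:
            cfg = get_config()
            gen = _fp_generator(cfg.fp_radius, cfg.fp_bits)
            self._fp = gen.GetFingerprint(self.mol)
        return self._fp

    @property
    def inchi(self) -> str:
        return inchi.MolToInchi(self.mol) or ""

    @property
    def inchikey(self) -> str:
        return inchi.MolToInchiKey(self.mol) or ""

    def __eq__(self, other) -> bool:
        if not isinstance(other, Compound):
            return NotImplemented
        return self.canonical_key == other.canonical_key

    def __hash__(self) -> int:
        return hash(self.canonical_key)

    def __repr__(self) -> str:
        return f"Compound({self.canonical_key!r}, id={self.id!r})"


def tanimoto(a: Compound, b: Compound) -> float:
    """Tanimoto similarity |A∩B| / |A∪B| over binary fingerprints.

    Identical canonical keys score 1.0 without touching fingerprints; two
    all-zero fingerprints (degenerate toy molecules) also score 1.0 so the
    coefficient stays defined.
    """
    if a.canonical_key == b.canonical_key:
        return 1.0
    fa, fb = a.fingerprint, b.fingerprint
    if fa.GetNumOnBits() == 0 and fb.GetNumOnBits() == 0:
        return 1.0
    return DataStructs.TanimotoSimilarity(fa, fb)
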