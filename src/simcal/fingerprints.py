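"""2D fingerprints and Tanimoto similarity for molecule pairs.

Five open fingerprint families are provided, chosen to span the main
classes of 2D fingerprint used in regulatory similarity assessment:

``circular-binary-r2``
    Morgan (extended-connectivity) fingerprint of radius 2, i.e. atom
    environments up to diameter 4, folded to a binary vector (ECFP4-like).
``circular-count-r2``
    The same circular environments with occurrence counts (ECFC4-like).
``path-hashed-binary``
    RDKit's hashed linear-path fingerprint (Daylight-like).
``structural-keys-166``
    The 166 public MACCS structural keys (MDL-like).
``generic-keys``
    Hashed atom-pair keys, standing in for generic key-based fingerprints
    such as BCI or Unity.

Similarity between two fingerprints is the Tanimoto coefficient
|A∩B| / |A∪B|, generalised to count vectors as Σmin / Σmax, which reduces
exactly to the binary form on 0/1 vectors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem, DataStructs, RDLogger
from rdkit.Chem import Crippen, Descriptors, Lipinski, MACCSkeys, rdFingerprintGenerator

# RDKit logs every rejected SMILES at error level; parse failures are
# reported through MoleculeParseError instead.
RDLogger.DisableLog("rdApp.error")

CIRCULAR_BINARY = "circular-binary-r2"
CIRCULAR_COUNT = "circular-count-r2"
PATH_BINARY = "path-hashed-binary"
STRUCTURAL_KEYS = "structural-keys-166"
GENERIC_KEYS = "generic-keys"

ALL_SCHEMES = (CIRCULAR_BINARY, CIRCULAR_COUNT, PATH_BINARY, STRUCTURAL_KEYS, GENERIC_KEYS)

#: default folded lengths per scheme
DEFAULT_LENGTHS = {
    CIRCULAR_BINARY: 1024,
    CIRCULAR_COUNT: 1024,
    PATH_BINARY: 2048,
    STRUCTURAL_KEYS: 166,
    GENERIC_KEYS: 1024,
}

#: schemes whose vectors are 0/1 valued
BINARY_SCHEMES = frozenset({CIRCULAR_BINARY, PATH_BINARY, STRUCTURAL_KEYS, GENERIC_KEYS})

#: scheme used by default when a single reference similarity is needed
REFERENCE_SCHEME = CIRCULAR_BINARY


class MoleculeParseError(ValueError):
    """Raised when a SMILES string cannot be parsed; carries the offending id."""

    def __init__(self, molecule_id: str, smiles: str):
        self.molecule_id = molecule_id
        self.smiles = smiles
        super().__init__(f"unparseable SMILES for molecule {molecule_id!r}: {smiles!r}")


class SchemeError(ValueError):
    """Raised for an unknown fingerprint scheme or an invalid scheme/length combination."""


@dataclass(frozen=True)
class MoleculeRecord:
    """A parsed structure with the descriptors used for drug-likeness filtering."""

    id: str
    smiles: str  # canonical SMILES of the largest covalent fragment
    mol_weight: float  # Daltons
    n_hba: int  # hydrogen-bond acceptors (Lipinski N/O count convention not used; RDKit definition)
    n_hbd: int  # hydrogen-bond donors
    logp: float  # Crippen octanol-water logP estimate
    n_carbon: int


@dataclass
class FingerprintVector:
    scheme: str
    length: int
    values: np.ndarray  # non-negative ints; 0/1 for binary schemes

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.int64)
        if self.values.shape != (self.length,):
            raise ValueError(f"values must have shape ({self.length},)")
        if (self.values < 0).any():
            raise ValueError("fingerprint values must be non-negative")
        if self.scheme in BINARY_SCHEMES and (self.values > 1).any():
            raise ValueError(f"scheme {self.scheme} is binary but values exceed 1")


@dataclass
class SimilarityProfile:
    """Per-pair Tanimoto values under each scheme, plus optional panel response."""

    pair_id: str
    molecule_a_id: str
    molecule_b_id: str
    similarities: dict[str, float] = field(default_factory=dict)
    yes_fraction: float | None = None
    majority_label: bool | None = None  # True = similar


def parse_molecule(smiles: str, molecule_id: str) -> MoleculeRecord:
    """Parse a SMILES string into a :class:`MoleculeRecord`.

    Salts are stripped by retaining the largest covalent fragment (by heavy
    atom count) before canonicalisation, since expert similarity judgments
    concern the active moiety.
    """
    if not smiles or not smiles.strip():
        raise MoleculeParseError(molecule_id, smiles)
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise MoleculeParseError(molecule_id, smiles)
    frags = Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=True)
    if len(frags) > 1:
        mol = max(frags, key=lambda f: f.GetNumHeavyAtoms())
    return MoleculeRecord(
        id=molecule_id,
        smiles=Chem.MolToSmiles(mol),
        mol_weight=float(Descriptors.MolWt(mol)),
        n_hba=int(Lipinski.NumHAcceptors(mol)),
        n_hbd=int(Lipinski.NumHDonors(mol)),
        logp=float(Crippen.MolLogP(mol)),
        n_carbon=sum(1 for a in mol.GetAtoms() if a.GetSymbol() == "C"),
    )


def _mol(record: MoleculeRecord) -> Chem.Mol:
    mol = Chem.MolFromSmiles(record.smiles)
    if mol is None:  # cannot happen for records built by parse_molecule
        raise MoleculeParseError(record.id, record.smiles)
    return mol


def compute_fingerprint(
    mol: MoleculeRecord, scheme: str, length: int | None = None
) -> FingerprintVector:
    """Compute the fingerprint of ``mol`` under ``scheme``.

    Deterministic for a given (canonical SMILES, scheme, length): records are
    canonicalised at parse time, so input SMILES variants of one structure
    yield identical vectors.
    """
    if scheme not in ALL_SCHEMES:
        raise SchemeError(f"unsupported fingerprint scheme {scheme!r}; known: {list(ALL_SCHEMES)}")
    if length is None:
        length = DEFAULT_LENGTHS[scheme]
    rdmol = _mol(mol)
    arr = np.zeros(length, dtype=np.int64)
    if scheme == STRUCTURAL_KEYS:
        if length != 166:
            raise SchemeError("structural-keys-166 has a fixed length of 166")
        keys = MACCSkeys.GenMACCSKeys(rdmol)  # 167 bits, bit 0 unused
        tmp = np.zeros(167, dtype=np.int64)
        DataStructs.ConvertToNumpyArray(keys, tmp)
        arr = tmp[1:]
    elif scheme == CIRCULAR_BINARY:
        gen = rdFingerprintGenerator.GetMorganGenerator(radius=2, fpSize=length)
        DataStructs.ConvertToNumpyArray(gen.GetFingerprint(rdmol), arr)
    elif scheme == CIRCULAR_COUNT:
        gen = rdFingerprintGenerator.GetMorganGenerator(radius=2, fpSize=length)
        for idx, count in gen.GetCountFingerprint(rdmol).GetNonzeroElements().items():
            arr[idx] = count
    elif scheme == PATH_BINARY:
        gen = rdFingerprintGenerator.GetRDKitFPGenerator(fpSize=length)
        DataStructs.ConvertToNumpyArray(gen.GetFingerprint(rdmol), arr)
    elif scheme == GENERIC_KEYS:
        gen = rdFingerprintGenerator.GetAtomPairGenerator(fpSize=length)
        DataStructs.ConvertToNumpyArray(gen.GetFingerprint(rdmol), arr)
    return FingerprintVector(scheme=scheme, length=length, values=arr)


def tanimoto(a: FingerprintVector, b: FingerprintVector) -> float:
    """Tanimoto similarity of two fingerprints of the same scheme and length.

    Binary vectors: |A∩B| / |A∪B|.  Count vectors: Σmin / Σmax.  A pair of
    all-zero vectors has no features to compare; it is assigned similarity
    0.0 with a warning — the conservative choice for a dissimilarity-sensitive
    regulatory use.
    """
    if a.scheme != b.scheme or a.length != b.length:
        raise ValueError(
            f"fingerprint mismatch: ({a.scheme}, {a.length}) vs ({b.scheme}, {b.length})"
        )
    union = int(np.maximum(a.values, b.values).sum())
    if union == 0:
        warnings.warn(
            "Tanimoto of two empty fingerprints is undefined; returning 0.0", stacklevel=2
        )
        return 0.0
    inter = int(np.minimum(a.values, b.values).sum())
    return inter / union


def pair_similarity_table(
    pairs: list[tuple[MoleculeRecord, MoleculeRecord]],
    schemes: list[str] | tuple[str, ...] = ALL_SCHEMES,
    pair_ids: list[str] | None = None,
    lengths: dict[str, int] | None = None,
) -> list[SimilarityProfile]:
    """Compute one :class:`SimilarityProfile` per molecule pair, order preserved."""
    if not pairs:
        raise ValueError("pair list must be non-empty")
    if pair_ids is None:
        pair_ids = [f"{a.id}__{b.id}" for a, b in pairs]
    if len(pair_ids) != len(pairs):
        raise ValueError("pair_ids must match pairs in length")
    lengths = lengths or {}
    # fingerprint each distinct molecule once per scheme
    cache: dict[tuple[str, str], FingerprintVector] = {}

    def fp(rec: MoleculeRecord, scheme: str) -> FingerprintVector:
        key = (rec.smiles, scheme)
        if key not in cache:
            cache[key] = compute_fingerprint(rec, scheme, lengths.get(scheme))
        return cache[key]

    profiles = []
    for pid, (a, b) in zip(pair_ids, pairs):
        try:
            sims = {s: tanimoto(fp(a, s), fp(b, s)) for s in schemes}
        except (MoleculeParseError, SchemeError, ValueError) as exc:
            exc.args = (f"pair {pid!r}: {exc}",)
            raise
        profiles.append(
            SimilarityProfile(
                pair_id=pid, molecule_a_id=a.id, molecule_b_id=b.id, similarities=sims
            )
        )
    return profiles
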