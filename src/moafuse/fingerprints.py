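"""SMILES to fingerprint featurization: RDK, ECFP, PubChem-style, MACCS.

RDK (topological path), ECFP (Morgan, radius 2 by default) and MACCS keys come
from RDKit. The 881-slot PubChem/CACTVS fingerprint has no implementation in
the open-source toolkits, so this module ships a documented approximation
(:func:`pubchem_like_fingerprint`): element-count thresholds, ring-size
counts, a bank of common substructure SMARTS, and hashed atom-pair features
fill the 881 slots. The approximation is deterministic and binary but is NOT
the authoritative CACTVS bit layout; when real PubChem bits are available,
supply them through the override table of :func:`featurize_table` (override
rows always win).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from rdkit import Chem, RDLogger
from rdkit.Chem import MACCSkeys, rdFingerprintGenerator, rdmolops

from .datamodel import FeaturizationError, FingerprintSet, ValidationError

RDLogger.DisableLog("rdApp.error")

__all__ = ["FingerprintConfig", "featurize", "featurize_table", "pubchem_like_fingerprint"]


@dataclass(frozen=True)
class FingerprintConfig:
    """Bit lengths and ECFP radius; defaults are the community conventions."""

    rdk_bits: int = 2048
    ecfp_bits: int = 2048
    ecfp_radius: int = 2
    pubchem_bits: int = 881
    maccs_bits: int = 167  # fixed by the MACCS definition; kept for symmetry


# Element-count thresholds: (atomic number, count threshold), one slot each.
_ELEMENT_THRESHOLDS = [
    (6, 2), (6, 4), (6, 8), (6, 16), (6, 32),
    (7, 1), (7, 2), (7, 4), (7, 8),
    (8, 1), (8, 2), (8, 4), (8, 8), (8, 16),
    (9, 1), (9, 2), (9, 4),
    (15, 1), (15, 2),
    (16, 1), (16, 2), (16, 4),
    (17, 1), (17, 2),
    (35, 1), (53, 1), (5, 1), (14, 1),
    (3, 1), (11, 1), (19, 1), (12, 1), (20, 1), (26, 1), (30, 1),
]

# Common substructure patterns (presence bits).
_SMARTS_BANK = [
    "[CX4]", "[CX3]=[CX3]", "[CX2]#C", "c1ccccc1", "[cX3]", "[$([NX3])]",
    "[NX3;H2]", "[NX3;H1]", "[NX2]=[CX3]", "[NX1]#[CX2]", "[OX2H]", "[OX2]",
    "[CX3]=[OX1]", "[CX3](=O)[OX2H1]", "[CX3](=O)[OX2][CX4]", "[CX3](=O)[NX3]",
    "[SX2]", "[SX2H]", "[#16X4](=[OX1])(=[OX1])", "[F]", "[Cl]", "[Br]", "[I]",
    "[NX3][CX3]=[OX1]", "[OX2][CX4][OX2]", "c1ccncc1", "c1cc[nH]c1", "c1ccoc1",
    "c1ccsc1", "c1cnc2ncccc2c1", "[nX2]", "[nX3]", "[#7]1[#6][#6][#7][#6][#6]1",
    "[CX4][OX2H]", "[cX3][OX2H]", "[NX3+]", "[O-]", "[CX4]([F])([F])[F]",
    "[#6]=[#7]", "[#6]=[#16]", "[#7]-[#7]", "[#7]=[#7]", "[#8]-[#8]",
    "[#16]-[#16]", "[CX3H1]=[OX1]", "[CX4H2]", "[CX4H3]", "[R]", "[R2]",
    "[r5]", "[r6]", "[r7]", "a", "[A;!#1]", "[#6]~[#7]~[#6]",
    "[#6]~[#8]~[#6]", "[#7]~[#6]~[#8]", "[#6](~[#8])~[#8]", "[!#6;!#1]",
    "[CX3](=O)[Cl,Br,I,F]",
]

_N_RING_SLOTS = 16  # rings of size 3..10, thresholds >=1 and >=2


def pubchem_like_fingerprint(mol, n_bits: int = 881) -> np.ndarray:
    """Deterministic 881-slot substructure/count fingerprint (approximation).

    Layout: element-count thresholds, ring-size counts, SMARTS presence bank,
    then hashed (element, element, topological distance) atom pairs over the
    remaining slots.
    """
    bits = np.zeros(n_bits, dtype=np.uint8)
    pos = 0
    counts = {}
    for atom in mol.GetAtoms():
        counts[atom.GetAtomicNum()] = counts.get(atom.GetAtomicNum(), 0) + 1
    for z, thr in _ELEMENT_THRESHOLDS:
        if pos < n_bits and counts.get(z, 0) >= thr:
            bits[pos] = 1
        pos += 1
    ring_info = mol.GetRingInfo()
    ring_sizes = [len(r) for r in ring_info.AtomRings()]
    for size in range(3, 11):
        for thr in (1, 2):
            if pos < n_bits and sum(1 for s in ring_sizes if s == size) >= thr:
                bits[pos] = 1
            pos += 1
    for smarts in _SMARTS_BANK:
        patt = Chem.MolFromSmarts(smarts)
        if pos < n_bits and patt is not None and mol.HasSubstructMatch(patt):
            bits[pos] = 1
        pos += 1
    # hashed atom pairs over the remaining slots
    lo = pos
    span = n_bits - lo
    if span > 0 and mol.GetNumAtoms() > 1:
        dmat = rdmolops.GetDistanceMatrix(mol)
        nums = [a.GetAtomicNum() for a in mol.GetAtoms()]
        n = len(nums)
        for i in range(n):
            for j in range(i + 1, n):
                d = int(dmat[i, j])
                if d <= 0 or d > 10:
                    continue
                zi, zj = sorted((nums[i], nums[j]))
                h = (zi * 9176 + zj * 541 + d * 89) % span
                bits[lo + h] = 1
    return bits


def _bitvect_to_array(bv, length: int) -> np.ndarray:
    arr = np.zeros(length, dtype=np.uint8)
    arr[list(bv.GetOnBits())] = 1
    return arr


def featurize(smiles: str, config: FingerprintConfig = FingerprintConfig()) -> FingerprintSet:
    """Convert one SMILES string to the four binary fingerprint vectors.

    Pure function of (smiles, config): repeated calls return identical bits.
    Raises :class:`FeaturizationError` for unparseable SMILES.
    """
    mol = Chem.MolFromSmiles(smiles) if smiles else None
    if mol is None:
        raise FeaturizationError(f"cannot parse SMILES {smiles!r}")
    rdk_gen = rdFingerprintGenerator.GetRDKitFPGenerator(fpSize=config.rdk_bits)
    ecfp_gen = rdFingerprintGenerator.GetMorganGenerator(
        radius=config.ecfp_radius, fpSize=config.ecfp_bits
    )
    return FingerprintSet(
        rdk=_bitvect_to_array(rdk_gen.GetFingerprint(mol), config.rdk_bits),
        ecfp=_bitvect_to_array(ecfp_gen.GetFingerprint(mol), config.ecfp_bits),
        pubchem=pubchem_like_fingerprint(mol, config.pubchem_bits),
        maccs=_bitvect_to_array(MACCSkeys.GenMACCSKeys(mol), config.maccs_bits),
    )


def featurize_table(
    compounds,
    config: FingerprintConfig = FingerprintConfig(),
    overrides: dict | None = None,
) -> dict:
    """Featurize a list of CompoundRecord; returns compound_id -> FingerprintSet.

    ``overrides`` (compound_id -> FingerprintSet, e.g. from a precomputed
    table with authoritative PubChem bits) take precedence over computed
    values; compounds with neither a parseable SMILES nor an override are a
    validation error, reported together.
    """
    overrides = overrides or {}
    out, missing = {}, []
    for rec in compounds:
        if rec.compound_id in overrides:
            out[rec.compound_id] = overrides[rec.compound_id]
        elif rec.smiles:
            out[rec.compound_id] = featurize(rec.smiles, config)
        else:
            missing.append(rec.compound_id)
    if missing:
        raise ValidationError(
            f"compounds with neither SMILES nor a fingerprint override: {missing}"
        )
    return out
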