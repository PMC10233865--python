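"""Optional cheminformatics convenience: SMILES -> set-bit fingerprints.

The pipeline itself is chemistry-toolkit-agnostic and consumes precomputed
bitsets; this helper converts SMILES strings via a hashed atom-pair
fingerprint when rdkit is available.
"""

from __future__ import annotations

from typing import Optional

from .errors import InputError
from .network import Fingerprint


def smiles_to_fingerprint(
    chemical_id: str, smiles: str, n_bits: int = 2048
) -> Fingerprint:
    """Hashed atom-pair fingerprint of a SMILES string (requires rdkit)."""
    try:
        from rdkit import Chem
        from rdkit.Chem.rdFingerprintGenerator import GetAtomPairGenerator
    except ImportError as exc:  # pragma: no cover
        raise ImportError(
            "rdkit is required for SMILES conversion; install herblink[chem]"
        ) from exc
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise InputError(f"cannot parse SMILES {smiles!r} for {chemical_id}")
    gen = GetAtomPairGenerator(fpSize=n_bits)
    fp = gen.GetFingerprint(mol)
    return Fingerprint(chemical_id, frozenset(fp.GetOnBits()))
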