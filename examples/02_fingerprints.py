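"""Featurize a few SMILES strings into the four fingerprint types.

Prints the number of set bits per type and shows that two SMILES spellings
of the same molecule produce identical fingerprints.
"""

import numpy as np

from moafuse.fingerprints import featurize

for name, smiles in [
    ("ethanol", "CCO"),
    ("benzene", "c1ccccc1"),
    ("caffeine", "CN1C=NC2=C1C(=O)N(C(=O)N2C)C"),
]:
    fps = featurize(smiles)
    on = {t: int(v.sum()) for t, v in zip(("rdk", "ecfp", "pubchem", "maccs"), fps.as_tuple())}
    print(f"{name:10s} {smiles:30s} on-bits: {on}")

assert featurize("OCC") == featurize("CCO")
print("OCC and CCO (same molecule) give identical fingerprints.")
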