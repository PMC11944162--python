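"""Tanimoto drug-drug similarity with row standardization.

Builds the pairwise Tanimoto matrix for five small molecules, symmetrizes
it by triangle averaging and Z-scores each row (zero mean, unit variance).
The standardized row of a drug is the fourth input block of the fusion
model.
"""

import numpy as np

from adrfusion.chem_io import compute_ecfp
from adrfusion.similarity import similarity_matrix

drugs = {
    "aspirin": "CC(=O)Oc1ccccc1C(=O)O",
    "salicylic_acid": "O=C(O)c1ccccc1O",
    "paracetamol": "CC(=O)Nc1ccc(O)cc1",
    "caffeine": "Cn1cnc2c1c(=O)n(C)c(=O)n2C",
    "ethanol": "CCO",
}

fps = [compute_ecfp(smi, 2, 2048) for smi in drugs.values()]
sim = similarity_matrix(fps, list(drugs))
raw, std = sim.to_frames()

print("raw Tanimoto coefficients (symmetric, diagonal = 1):")
print(raw.round(3), "\n")
print("row-standardized matrix (each row: mean 0, sd 1):")
print(std.round(2))

# aspirin vs salicylic acid shares the salicylate scaffold -> the largest
# off-diagonal coefficient; ethanol shares almost nothing with the rest.
i, j = 0, 1
print(f"\nTC(aspirin, salicylic_acid) = {sim.S_raw[i, j]:.3f}")
print(f"TC(aspirin, ethanol)        = {sim.S_raw[0, 4]:.3f}")
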