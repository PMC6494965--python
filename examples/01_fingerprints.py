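"""Compute MACCS substructure profiles and Tanimoto similarities.

Builds fingerprints for a handful of drugs, filters uninformative keys and
finds each query's nearest neighbor in a small reference panel.
"""

from abcscreen import (
    CompoundRecord,
    build_matrix,
    compute_maccs,
    filter_constant_keys,
    nearest_training_neighbor,
    tanimoto,
)

panel = [
    CompoundRecord("aspirin", "CC(=O)Oc1ccccc1C(=O)O"),
    CompoundRecord("salicylic_acid", "OC(=O)c1ccccc1O"),
    CompoundRecord("caffeine", "Cn1cnc2c1c(=O)n(C)c(=O)n2C"),
    CompoundRecord("ibuprofen", "CC(C)Cc1ccc(cc1)C(C)C(=O)O"),
    CompoundRecord("fluconazole", "OC(Cn1cncn1)(Cn1cncn1)c1ccc(F)cc1F"),
]
profiles = [compute_maccs(r) for r in panel]
matrix = build_matrix(profiles)
print(f"{matrix.n_drugs} drugs x {len(matrix.key_ids)} MACCS keys")

informative = filter_constant_keys(matrix)
print(f"{len(informative.key_ids)} keys vary across this panel "
      "(constant keys carry no signal and are dropped for modeling)")

t = tanimoto(profiles[0], profiles[1])
print(f"Tanimoto(aspirin, salicylic acid) = {t:.4f}  "
      "(shared substructure bits / union; 1.0 means identical key profiles)")

query = build_matrix([compute_maccs(CompoundRecord("paracetamol", "CC(=O)Nc1ccc(O)cc1"))])
edges = nearest_training_neighbor(query, matrix)
e = edges[0]
print(f"nearest panel neighbor of {e.query_id}: {e.neighbor_id} "
      f"(Tanimoto {e.tanimoto:.4f}) — how close the new drug sits to known chemistry")
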