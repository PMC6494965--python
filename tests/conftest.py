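"""Shared fixtures: planted synthetic datasets and a small molecule panel."""

from __future__ import annotations

import numpy as np
import pytest

from abcscreen.simulate import (
    DrugGrowthSpec,
    FingerprintSimConfig,
    GrowthSimConfig,
    generate_fingerprint_dataset,
    simulate_growth_curves,
)

# Six planted keys spread over the key range, alternating sign, |effect| >= 1.2.
PLANTED_KEYS = ((5, 1.5), (36, -1.5), (67, 1.3), (98, -1.3), (129, 1.2), (160, -1.2))

# Literature structures of common small molecules (drawn as canonical SMILES);
# used to pin fingerprint behavior against the reference MACCS implementation.
MOLECULES = [
    ("water", "O"),
    ("ethanol", "CCO"),
    ("benzene", "c1ccccc1"),
    ("toluene", "Cc1ccccc1"),
    ("phenol", "Oc1ccccc1"),
    ("aniline", "Nc1ccccc1"),
    ("pyridine", "c1ccncc1"),
    ("acetic_acid", "CC(=O)O"),
    ("aspirin", "CC(=O)Oc1ccccc1C(=O)O"),
    ("paracetamol", "CC(=O)Nc1ccc(O)cc1"),
    ("caffeine", "Cn1cnc2c1c(=O)n(C)c(=O)n2C"),
    ("ibuprofen", "CC(C)Cc1ccc(cc1)C(C)C(=O)O"),
    ("naproxen", "COc1ccc2cc(ccc2c1)C(C)C(=O)O"),
    ("nicotine", "CN1CCC[C@H]1c1cccnc1"),
    ("glucose", "OC[C@H]1OC(O)[C@H](O)[C@@H](O)[C@@H]1O"),
    ("glycine", "NCC(=O)O"),
    ("l_glutamic_acid", "N[C@@H](CCC(=O)O)C(=O)O"),
    ("urea", "NC(N)=O"),
    ("imidazole", "c1c[nH]cn1"),
    ("cyclohexane", "C1CCCCC1"),
    ("naphthalene", "c1ccc2ccccc2c1"),
    ("benzoic_acid", "OC(=O)c1ccccc1"),
    ("fluconazole", "OC(Cn1cncn1)(Cn1cncn1)c1ccc(F)cc1F"),
    ("salicylic_acid", "OC(=O)c1ccccc1O"),
]


@pytest.fixture(scope="session")
def planted_dataset():
    """n=400 drugs, six planted keys, ~1/3 positives: the standard test signal."""
    cfg = FingerprintSimConfig(n_drugs=400, planted_keys=PLANTED_KEYS, seed=11)
    return generate_fingerprint_dataset(cfg)


@pytest.fixture(scope="session")
def zero_noise_plate():
    """Noise-free two-strain growth curves: one substrate, one neutral, one reversed drug."""
    cfg = GrowthSimConfig(
        drugs=(
            DrugGrowthSpec("substrate", True, 4.0, 0.25),
            DrugGrowthSpec("neutral", False, 1.5, 1.5),
            DrugGrowthSpec("reversed", False, 0.5, 2.0),
        ),
        noise_sd=0.0,
        seed=1,
    )
    return simulate_growth_curves(cfg)


@pytest.fixture(scope="session")
def molecule_smiles():
    return MOLECULES


@pytest.fixture()
def smi_file(tmp_path, molecule_smiles):
    path = tmp_path / "molecules.smi"
    path.write_text("".join(f"{smi} {name}\n" for name, smi in molecule_smiles))
    return path
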