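"""166-key MACCS substructure profiles and Tanimoto similarity.

Converts compound structures (SMILES / CSV / SDF) into binary MACCS-key
profiles, assembles drugs-by-keys matrices, removes zero-variance keys from
modeling matrices, and maps validation compounds to their nearest training
neighbors by Tanimoto similarity.

MACCS keys are indexed 1..166 throughout, matching the standard key
dictionary. RDKit's MACCS arrays carry an unused leading bit 0, which is
dropped on conversion.
"""

from __future__ import annotations

import csv
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

N_MACCS_KEYS = 166

__all__ = [
    "CompoundRecord",
    "FingerprintProfile",
    "FingerprintMatrix",
    "SimilarityEdge",
    "InvalidSmilesError",
    "read_structures",
    "compute_maccs",
    "compute_maccs_many",
    "build_matrix",
    "filter_constant_keys",
    "tanimoto",
    "nearest_training_neighbor",
    "write_similarity_edges",
]


class InvalidSmilesError(ValueError):
    """Raised when a SMILES string cannot be parsed into a molecule."""

    def __init__(self, drug_id: str, smiles: str):
        self.drug_id = drug_id
        self.smiles = smiles
        super().__init__(f"invalid SMILES for drug {drug_id!r}: {smiles!r}")


@dataclass(frozen=True)
class CompoundRecord:
    """A compound identifier with its SMILES structure."""

    drug_id: str
    smiles: str
    pubchem_id: int | None = None
    display_abbreviation: str | None = None

    def __post_init__(self):
        if not self.smiles:
            raise InvalidSmilesError(self.drug_id, self.smiles)


@dataclass(frozen=True)
class FingerprintProfile:
    """Binary MACCS profile for one compound, bit i stored at index i-1."""

    drug_id: str
    bits: np.ndarray  # shape (166,), dtype uint8

    def __post_init__(self):
        bits = np.asarray(self.bits, dtype=np.uint8)
        if bits.shape != (N_MACCS_KEYS,):
            raise ValueError(
                f"profile for {self.drug_id!r} has {bits.shape} bits, expected ({N_MACCS_KEYS},)"
            )
        if not np.isin(bits, (0, 1)).all():
            raise ValueError(f"profile for {self.drug_id!r} has non-binary entries")
        object.__setattr__(self, "bits", bits)


@dataclass
class FingerprintMatrix:
    """Drugs-by-keys binary matrix with explicit key identifiers.

    ``key_ids`` are the retained MACCS key numbers (strictly increasing,
    subset of 1..166); the full matrix has ``key_ids == [1, ..., 166]``.
    """

    drug_ids: list[str]
    key_ids: list[int]
    bits: np.ndarray  # shape (n_drugs, n_keys), dtype uint8

    def __post_init__(self):
        self.bits = np.asarray(self.bits, dtype=np.uint8)
        if self.bits.shape != (len(self.drug_ids), len(self.key_ids)):
            raise ValueError(
                f"bits shape {self.bits.shape} does not match "
                f"{len(self.drug_ids)} drugs x {len(self.key_ids)} keys"
            )
        ks = list(self.key_ids)
        if ks != sorted(set(ks)) or (ks and (ks[0] < 1 or ks[-1] > N_MACCS_KEYS)):
            raise ValueError("key_ids must be strictly increasing within 1..166")

    @property
    def n_drugs(self) -> int:
        return len(self.drug_ids)

    def row(self, drug_id: str) -> np.ndarray:
        return self.bits[self.drug_ids.index(drug_id)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.bits,
            index=pd.Index(self.drug_ids, name="drug_id"),
            columns=[f"MACCS_{k}" for k in self.key_ids],
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "FingerprintMatrix":
        key_ids = [int(c.split("_", 1)[1]) for c in frame.columns]
        return cls(
            drug_ids=[str(i) for i in frame.index],
            key_ids=key_ids,
            bits=frame.to_numpy(dtype=np.uint8),
        )

    @classmethod
    def read_csv(cls, path: str | Path) -> "FingerprintMatrix":
        return cls.from_frame(pd.read_csv(path, index_col="drug_id"))


@dataclass(frozen=True)
class SimilarityEdge:
    """Nearest-neighbor assignment of a query drug to a reference drug."""

    query_id: str
    neighbor_id: str
    tanimoto: float

    def __post_init__(self):
        if not 0.0 <= self.tanimoto <= 1.0:
            raise ValueError(f"tanimoto {self.tanimoto} outside [0, 1]")


# ---------------------------------------------------------------------------
# structure input


def _records_from_smi(path: Path) -> list[CompoundRecord]:
    from rdkit import Chem

    records = []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split(None, 1)
        smiles = parts[0]
        drug_id = parts[1].strip() if len(parts) > 1 else f"line{lineno}"
        if Chem.MolFromSmiles(smiles) is None:
            logger.warning("dropping unparseable SMILES at %s:%d (%s)", path, lineno, drug_id)
            continue
        records.append(CompoundRecord(drug_id=drug_id, smiles=smiles))
    return records


def _records_from_csv(path: Path) -> list[CompoundRecord]:
    from rdkit import Chem

    frame = pd.read_csv(path)
    cols = {c.lower(): c for c in frame.columns}
    if "drug_id" not in cols or "smiles" not in cols:
        raise ValueError(f"{path}: CSV must have drug_id and smiles columns")
    records = []
    for _, row in frame.iterrows():
        drug_id, smiles = str(row[cols["drug_id"]]), str(row[cols["smiles"]])
        if Chem.MolFromSmiles(smiles) is None:
            logger.warning("dropping unparseable SMILES for %r in %s", drug_id, path)
            continue
        pubchem = None
        if "pubchem_id" in cols and not pd.isna(row[cols["pubchem_id"]]):
            pubchem = int(row[cols["pubchem_id"]])
        records.append(CompoundRecord(drug_id=drug_id, smiles=smiles, pubchem_id=pubchem))
    return records


def _records_from_sdf(path: Path) -> list[CompoundRecord]:
    from rdkit import Chem

    records = []
    supplier = Chem.SDMolSupplier(str(path), sanitize=True)
    for i, mol in enumerate(supplier):
        if mol is None:
            logger.warning("dropping unparseable SDF entry %d in %s", i, path)
            continue
        if mol.HasProp("drug_id"):
            drug_id = mol.GetProp("drug_id")
        elif mol.HasProp("_Name") and mol.GetProp("_Name"):
            drug_id = mol.GetProp("_Name")
        else:
            drug_id = f"entry{i}"
        records.append(CompoundRecord(drug_id=drug_id, smiles=Chem.MolToSmiles(mol)))
    return records


def read_structures(path: str | Path, format: str | None = None) -> list[CompoundRecord]:
    """Read compound structures from a .smi, CSV or SDF file.

    Unparseable entries are dropped with a logged warning naming the entry;
    an unreadable file or unknown format raises ``ValueError``.
    """
    path = Path(path)
    if not path.exists():
        raise ValueError(f"structure file not found: {path}")
    fmt = (format or path.suffix.lstrip(".")).lower()
    readers = {"smi": _records_from_smi, "csv": _records_from_csv, "sdf": _records_from_sdf}
    if fmt not in readers:
        raise ValueError(f"unknown structure format {fmt!r} for {path} (expected smi/csv/sdf)")
    return readers[fmt](path)


# ---------------------------------------------------------------------------
# fingerprints


def compute_maccs(record: CompoundRecord) -> FingerprintProfile:
    """Compute the 166-key MACCS profile of a compound.

    Bit k is 1 iff MACCS key k's substructure pattern matches the molecule.
    RDKit's 167-bit array (dummy bit 0) is sliced down to keys 1..166.
    """
    from rdkit import Chem
    from rdkit.Chem import MACCSkeys

    mol = Chem.MolFromSmiles(record.smiles)
    if mol is None:
        raise InvalidSmilesError(record.drug_id, record.smiles)
    fp = MACCSkeys.GenMACCSKeys(mol)  # 167 bits, bit 0 unused
    bits = np.zeros(N_MACCS_KEYS, dtype=np.uint8)
    for b in fp.GetOnBits():
        if b >= 1:
            bits[b - 1] = 1
    return FingerprintProfile(drug_id=record.drug_id, bits=bits)


def compute_maccs_many(records: Iterable[CompoundRecord]) -> list[FingerprintProfile]:
    return [compute_maccs(r) for r in records]


def build_matrix(profiles: Sequence[FingerprintProfile]) -> FingerprintMatrix:
    """Stack profiles into a drugs x 166 matrix, preserving input order."""
    if len(profiles) == 0:
        raise ValueError("cannot build a fingerprint matrix from an empty profile list")
    ids = [p.drug_id for p in profiles]
    seen, dupes = set(), []
    for d in ids:
        if d in seen:
            dupes.append(d)
        seen.add(d)
    if dupes:
        raise ValueError(f"duplicate drug_ids: {sorted(set(dupes))}")
    return FingerprintMatrix(
        drug_ids=ids,
        key_ids=list(range(1, N_MACCS_KEYS + 1)),
        bits=np.vstack([p.bits for p in profiles]),
    )


def filter_constant_keys(matrix: FingerprintMatrix) -> FingerprintMatrix:
    """Drop keys whose column is all-0 or all-1 across drugs.

    Constant keys carry no information for enrichment or modeling; filtering
    is a training-set property, so similarity computations keep all 166 keys.
    """
    if matrix.n_drugs == 0:
        raise ValueError("cannot filter an empty matrix")
    colsum = matrix.bits.sum(axis=0)
    keep = (colsum > 0) & (colsum < matrix.n_drugs)
    return FingerprintMatrix(
        drug_ids=list(matrix.drug_ids),
        key_ids=[k for k, m in zip(matrix.key_ids, keep) if m],
        bits=matrix.bits[:, keep],
    )


def tanimoto(a: FingerprintProfile | np.ndarray, b: FingerprintProfile | np.ndarray) -> float:
    """Tanimoto coefficient |a AND b| / |a OR b| of two binary profiles.

    Two all-zero profiles have an undefined ratio; by convention this returns
    0.0 with a warning.
    """
    va = a.bits if isinstance(a, FingerprintProfile) else np.asarray(a, dtype=np.uint8)
    vb = b.bits if isinstance(b, FingerprintProfile) else np.asarray(b, dtype=np.uint8)
    if va.shape != vb.shape:
        raise ValueError(f"profile length mismatch: {va.shape} vs {vb.shape}")
    union = int(np.count_nonzero(va | vb))
    if union == 0:
        warnings.warn("Tanimoto of two all-zero profiles defined as 0.0", stacklevel=2)
        return 0.0
    return int(np.count_nonzero(va & vb)) / union


def nearest_training_neighbor(
    validation: FingerprintMatrix, training: FingerprintMatrix
) -> list[SimilarityEdge]:
    """Closest training compound for each validation compound, by Tanimoto.

    Ties are broken by training-set order and logged. Both matrices must
    share the same key set (use the full 166-key profiles).
    """
    if validation.key_ids != training.key_ids:
        raise ValueError("validation and training matrices have different key_ids")
    v = validation.bits.astype(np.int32)
    t = training.bits.astype(np.int32)
    inter = v @ t.T
    union = v.sum(axis=1)[:, None] + t.sum(axis=1)[None, :] - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        sim = np.where(union > 0, inter / np.maximum(union, 1), 0.0)
    edges = []
    for i, qid in enumerate(validation.drug_ids):
        best = float(sim[i].max())
        hits = np.flatnonzero(sim[i] == best)
        if hits.size > 1:
            logger.warning(
                "nearest-neighbor tie for %r among %s; keeping first by training order",
                qid,
                [training.drug_ids[j] for j in hits],
            )
        edges.append(SimilarityEdge(qid, training.drug_ids[int(hits[0])], best))
    return edges


def write_similarity_edges(edges: Sequence[SimilarityEdge], path: str | Path) -> None:
    """Write edges as TSV: query_id, neighbor_id, tanimoto (4 decimals)."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(["query_id", "neighbor_id", "tanimoto"])
        for e in edges:
            w.writerow([e.query_id, e.neighbor_id, f"{e.tanimoto:.4f}"])
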