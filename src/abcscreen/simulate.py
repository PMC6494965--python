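"""Synthetic fingerprint datasets and two-strain plate-reader growth curves.

Every downstream stage of the pipeline (enrichment, substrate-likeness
modeling, growth-curve efficacy scoring) is testable against planted ground
truth generated here:

* ``generate_fingerprint_dataset`` draws a drugs x 166 binary key matrix with
  per-key prevalences and a binary sensitivity label from a logistic model
  with a sparse set of planted log-odds effects. The logistic intercept is
  calibrated (closed-form expectation + bisection) so the positive-class
  fraction matches a target, by default the ~1/3 sensitive fraction typical
  of ABC-transporter-null screens.
* ``simulate_growth_curves`` emulates a 15 h plate-reader run sampled every
  15 min for two strains (parental, abc16) across a two-fold dose ladder
  plus a no-drug control, in duplicate. Growth follows a logistic curve whose
  gap above the initial OD is scaled by a Hill inhibition factor; designated
  substrate drugs have a lower IC50 in the transporter-null strain.

The growth model is a test harness, not transporter biology.
"""

from __future__ import annotations

import itertools
import json
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from ._util import require, spawn_rng
from .fingerprints import N_MACCS_KEYS, FingerprintMatrix

__all__ = [
    "FingerprintSimConfig",
    "GrowthSimConfig",
    "DrugGrowthSpec",
    "TruthRecord",
    "generate_fingerprint_dataset",
    "simulate_growth_curves",
    "calibrate_intercept",
    "labels_to_csv",
    "labels_from_csv",
]

LABEL_POSITIVE = "sensitive"
LABEL_NEGATIVE = "resistant"


@dataclass(frozen=True)
class FingerprintSimConfig:
    """Design of a synthetic fingerprint/label dataset.

    ``planted_keys`` lists ``(key_index, log_odds_effect)`` pairs (1-based key
    indices); all other keys are label-independent. If ``intercept`` is None
    it is calibrated so the expected positive fraction equals
    ``target_positive_fraction``.
    """

    n_drugs: int
    n_keys: int = N_MACCS_KEYS
    key_prevalence_range: tuple[float, float] = (0.05, 0.6)
    planted_keys: tuple[tuple[int, float], ...] = ()
    intercept: float | None = None
    target_positive_fraction: float = 1.0 / 3.0
    seed: int = 0

    def __post_init__(self):
        require(self.n_drugs >= 2, "n_drugs", f"must be >= 2, got {self.n_drugs}")
        require(self.n_keys >= 1, "n_keys", f"must be >= 1, got {self.n_keys}")
        lo, hi = self.key_prevalence_range
        require(
            0.0 < lo <= hi < 1.0,
            "key_prevalence_range",
            f"must lie within (0, 1) with lo <= hi, got {self.key_prevalence_range}",
        )
        object.__setattr__(self, "planted_keys", tuple((int(k), float(e)) for k, e in self.planted_keys))
        idx = [k for k, _ in self.planted_keys]
        require(len(idx) == len(set(idx)), "planted_keys", "key indices must be distinct")
        require(
            all(1 <= k <= self.n_keys for k in idx),
            "planted_keys",
            f"key indices must lie in [1, {self.n_keys}]",
        )
        require(
            0.0 < self.target_positive_fraction < 1.0,
            "target_positive_fraction",
            "must lie in (0, 1)",
        )


@dataclass(frozen=True)
class TruthRecord:
    """Ground truth of a generated dataset: prevalences, effects, realized class balance."""

    prevalences: tuple[float, ...]
    planted_keys: tuple[tuple[int, float], ...]
    intercept: float
    positive_fraction: float
    seed: int

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2))


def _sigmoid(x: np.ndarray | float) -> np.ndarray | float:
    return 1.0 / (1.0 + np.exp(-np.asarray(x)))


def _expected_positive_fraction(
    intercept: float, effects: Sequence[float], prevalences: Sequence[float]
) -> float:
    """Exact E[sigmoid(b + sum e_k x_k)] over independent Bernoulli planted bits."""
    total = 0.0
    for bits in itertools.product((0, 1), repeat=len(effects)):
        prob = 1.0
        lin = intercept
        for x, e, p in zip(bits, effects, prevalences):
            prob *= p if x else (1.0 - p)
            lin += e * x
        total += prob * float(_sigmoid(lin))
    return total


def calibrate_intercept(
    target: float,
    effects: Sequence[float],
    prevalences: Sequence[float],
    tol: float = 1e-10,
) -> float:
    """Bisection for the logistic intercept hitting a target positive fraction.

    The expectation over planted-bit configurations is evaluated in closed
    form (the 2^m enumeration is exact), so calibration does not consume
    random numbers and is independent of n_drugs.
    """
    lo, hi = -30.0, 30.0
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if _expected_positive_fraction(mid, effects, prevalences) < target:
            lo = mid
        else:
            hi = mid
        if hi - lo < tol:
            break
    return 0.5 * (lo + hi)


def generate_fingerprint_dataset(
    config: FingerprintSimConfig,
) -> tuple[FingerprintMatrix, pd.Series, TruthRecord]:
    """Draw a binary fingerprint matrix and logistic-model labels.

    Returns the matrix, a 0/1 label Series indexed by drug_id (1 = sensitive),
    and the ground-truth record. Bitwise reproducible for a fixed config.
    """
    rng = spawn_rng(config.seed, 0)
    prevalences = rng.uniform(*config.key_prevalence_range, size=config.n_keys)
    bits = (rng.random((config.n_drugs, config.n_keys)) < prevalences[None, :]).astype(np.uint8)

    planted_idx = np.array([k - 1 for k, _ in config.planted_keys], dtype=int)
    effects = np.array([e for _, e in config.planted_keys], dtype=float)
    intercept = config.intercept
    if intercept is None:
        intercept = calibrate_intercept(
            config.target_positive_fraction, effects, prevalences[planted_idx]
        )

    lin = np.full(config.n_drugs, intercept, dtype=float)
    if planted_idx.size:
        lin += bits[:, planted_idx].astype(float) @ effects
    labels = (rng.random(config.n_drugs) < _sigmoid(lin)).astype(np.int8)

    drug_ids = [f"drug{i:04d}" for i in range(config.n_drugs)]
    matrix = FingerprintMatrix(
        drug_ids=drug_ids, key_ids=list(range(1, config.n_keys + 1)), bits=bits
    )
    label_series = pd.Series(labels, index=pd.Index(drug_ids, name="drug_id"), name="label")
    truth = TruthRecord(
        prevalences=tuple(float(p) for p in prevalences),
        planted_keys=config.planted_keys,
        intercept=float(intercept),
        positive_fraction=float(labels.mean()),
        seed=config.seed,
    )
    return matrix, label_series, truth


def labels_to_csv(labels: pd.Series, path: str | Path) -> None:
    """Write labels as CSV drug_id,label with sensitive/resistant strings."""
    out = labels.map({1: LABEL_POSITIVE, 0: LABEL_NEGATIVE})
    out.rename("label").to_csv(path)


def labels_from_csv(path: str | Path) -> pd.Series:
    frame = pd.read_csv(path, index_col="drug_id")
    mapping = {LABEL_POSITIVE: 1, LABEL_NEGATIVE: 0}
    bad = set(frame["label"]) - set(mapping)
    if bad:
        raise ValueError(f"unknown label values {sorted(bad)} in {path}")
    return frame["label"].map(mapping).astype(np.int8)


# ---------------------------------------------------------------------------
# growth curves


@dataclass(frozen=True)
class DrugGrowthSpec:
    """Per-drug dose-response parameters in relative-dose units (top dose = 1)."""

    drug_id: str
    is_substrate: bool
    ic50_parental: float
    ic50_abc16: float
    hill: float = 4.0

    def __post_init__(self):
        require(self.ic50_parental > 0, "ic50_parental", "must be positive")
        require(self.ic50_abc16 > 0, "ic50_abc16", "must be positive")
        require(self.hill > 0, "hill", "must be positive")
        if self.is_substrate:
            require(
                self.ic50_abc16 < self.ic50_parental,
                "ic50_abc16",
                f"substrate {self.drug_id!r} needs ic50_abc16 < ic50_parental",
            )


@dataclass(frozen=True)
class GrowthSimConfig:
    """Design of a two-strain plate-reader experiment.

    Defaults follow the standard screen layout: 15 h runs sampled every
    15 min, a two-fold dose ladder {0.25, 0.5, 1.0} of each drug's top dose
    plus a no-drug control, duplicate wells.
    """

    drugs: tuple[DrugGrowthSpec, ...]
    carrying_capacity: float = 1.0
    growth_rate: float = 0.8  # per hour
    midpoint_time: float = 7.0  # hours
    od_initial: float = 0.02
    duration: float = 15.0
    sampling_interval: float = 0.25
    relative_doses: tuple[float, ...] = (0.25, 0.5, 1.0)
    n_replicates: int = 2
    noise_sd: float = 0.01
    seed: int = 0

    def __post_init__(self):
        object.__setattr__(self, "drugs", tuple(self.drugs))
        object.__setattr__(self, "relative_doses", tuple(float(d) for d in self.relative_doses))
        require(len(self.drugs) >= 1, "drugs", "need at least one drug")
        require(self.duration > 0, "duration", "must be positive")
        n_points = int(round(self.duration / self.sampling_interval)) + 1
        require(
            self.sampling_interval > 0 and n_points >= 2,
            "sampling_interval",
            "must divide duration into at least 2 time points",
        )
        doses = self.relative_doses
        require(
            all(d > 0 for d in doses) and all(a < b for a, b in zip(doses, doses[1:])),
            "relative_doses",
            "must be strictly increasing and positive",
        )
        require(self.n_replicates >= 1, "n_replicates", "must be >= 1")
        require(self.noise_sd >= 0, "noise_sd", "must be non-negative")
        require(self.carrying_capacity > self.od_initial, "carrying_capacity", "must exceed od_initial")
        require(self.od_initial >= 0, "od_initial", "must be non-negative")


def _hill_growth_factor(dose: float, ic50: float, hill: float) -> float:
    """Fraction of the logistic growth gap realized at a relative dose.

    1 at dose 0 (uninhibited), 0.5 at dose == IC50, -> 0 at saturating dose.
    """
    if dose == 0:
        return 1.0
    dh = dose**hill
    return 1.0 - dh / (dh + ic50**hill)


def simulate_growth_curves(config: GrowthSimConfig) -> pd.DataFrame:
    """Simulate OD600 time series for every (drug, strain, dose, replicate) well.

    Returns a long-format frame with columns drug_id, strain, relative_dose,
    replicate, time_h, od600. Inhibition scales the logistic gap above the
    initial OD, so zero-dose curves are exactly logistic and a saturating
    dose leaves a flat curve at the initial OD. Additive Gaussian noise is
    truncated at 0.
    """
    times = np.round(
        np.arange(0.0, config.duration + config.sampling_interval / 2, config.sampling_interval),
        10,
    )
    logistic = 1.0 / (1.0 + np.exp(-config.growth_rate * (times - config.midpoint_time)))
    gap = config.carrying_capacity - config.od_initial
    doses = (0.0,) + config.relative_doses

    rows = []
    for drug in config.drugs:
        for strain in ("parental", "abc16"):
            ic50 = drug.ic50_parental if strain == "parental" else drug.ic50_abc16
            for dose in doses:
                factor = _hill_growth_factor(dose, ic50, drug.hill)
                clean = config.od_initial + factor * gap * logistic
                for rep in range(1, config.n_replicates + 1):
                    well_tag = zlib.crc32(f"{drug.drug_id}|{strain}".encode())
                    rng = spawn_rng(config.seed, well_tag, int(dose * 10**6), rep)
                    noise = (
                        rng.normal(0.0, config.noise_sd, size=times.size)
                        if config.noise_sd > 0
                        else np.zeros(times.size)
                    )
                    od = np.maximum(clean + noise, 0.0)
                    rows.append(
                        pd.DataFrame(
                            {
                                "drug_id": drug.drug_id,
                                "strain": strain,
                                "relative_dose": dose,
                                "replicate": rep,
                                "time_h": times,
                                "od600": od,
                            }
                        )
                    )
    return pd.concat(rows, ignore_index=True)
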