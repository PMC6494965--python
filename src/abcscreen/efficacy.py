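"""Reduce OD600 growth curves to relative-efficacy scores.

The reduction follows the screen's growth metric chain: trapezoidal area
under each growth curve, normalization to the no-drug control well to get a
growth fraction per dose, trapezoidal area under the dose-response curve
(including the control anchor at (0, 1)), and finally

    relative efficacy = -log2( ABC-16 growth metric / parental growth metric )

per replicate. Scores of replicate experiments are averaged and the drug is
categorized as sensitive (score > eps), resistant (score < -eps) or equal.
A positive score means the transporter-null strain grows less, i.e. the
drug is a candidate ABC-transporter substrate.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GrowthCurve",
    "DoseResponse",
    "EfficacyRecord",
    "growth_auc",
    "make_dose_response",
    "dose_response_auc",
    "relative_efficacy",
    "summarize_efficacy",
    "replicate_concordance",
    "compute_efficacy_table",
    "read_plate_reads",
    "write_efficacy_tsv",
]

#: treated growth AUCs at or below 0 are floored at this fraction of the control AUC
_AUC_FLOOR_FRACTION = 1e-6

STRAINS = ("parental", "abc16")
CATEGORIES = ("resistant", "equal", "sensitive")


@dataclass(frozen=True)
class GrowthCurve:
    """One well's OD600 time series."""

    drug_id: str
    strain: str
    relative_dose: float
    replicate: int
    times: np.ndarray  # hours, strictly increasing
    od: np.ndarray  # >= 0, same length

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        o = np.asarray(self.od, dtype=float)
        if self.strain not in STRAINS:
            raise ValueError(f"unknown strain {self.strain!r}, expected one of {STRAINS}")
        if t.size < 2 or o.size != t.size:
            raise ValueError(
                f"curve for {self.drug_id!r} needs >= 2 matched (time, od) points, "
                f"got {t.size} times / {o.size} ods"
            )
        if np.any(np.diff(t) <= 0):
            raise ValueError(f"times for {self.drug_id!r} must be strictly increasing")
        if np.any(o < 0):
            raise ValueError(f"negative OD values for {self.drug_id!r}")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "od", o)


@dataclass(frozen=True)
class DoseResponse:
    """Growth fractions (AUC relative to control) over the dose ladder."""

    drug_id: str
    strain: str
    replicate: int
    doses: np.ndarray  # strictly increasing, starting at 0
    growth_fraction: np.ndarray  # >= 0; exactly 1 at dose 0

    def __post_init__(self):
        d = np.asarray(self.doses, dtype=float)
        g = np.asarray(self.growth_fraction, dtype=float)
        if d.size != g.size or d.size < 2:
            raise ValueError("dose-response needs matched doses/fractions with >= 2 points")
        if d[0] != 0 or np.any(np.diff(d) <= 0):
            raise ValueError("doses must start at 0 and increase strictly")
        if np.any(g < 0):
            raise ValueError("growth fractions must be non-negative")
        object.__setattr__(self, "doses", d)
        object.__setattr__(self, "growth_fraction", g)


@dataclass(frozen=True)
class EfficacyRecord:
    """Per-drug relative-efficacy summary across replicates."""

    drug_id: str
    replicate_scores: tuple[float, ...]
    mean_score: float
    category: str


def growth_auc(curve: GrowthCurve) -> float:
    """Trapezoidal area under the growth curve, in OD * hours."""
    return float(np.trapezoid(curve.od, curve.times))


def make_dose_response(curves: Sequence[GrowthCurve]) -> DoseResponse:
    """Normalize one (drug, strain, replicate)'s curves to its no-drug control.

    growth_fraction(d) = AUC(d) / AUC(0); the control fraction is exactly 1.
    A treated AUC <= 0 is floored at 1e-6 x control AUC with a warning so the
    downstream log-ratio stays finite for fully lethal doses.
    """
    if not curves:
        raise ValueError("no curves given")
    ids = {(c.drug_id, c.strain, c.replicate) for c in curves}
    if len(ids) != 1:
        raise ValueError(f"curves span multiple (drug, strain, replicate) groups: {sorted(ids)}")
    drug_id, strain, replicate = next(iter(ids))
    by_dose = {c.relative_dose: c for c in sorted(curves, key=lambda c: c.relative_dose)}
    if 0.0 not in by_dose:
        raise ValueError(f"missing dose-0 control for {drug_id!r} ({strain}, rep {replicate})")
    if len(by_dose) < 2:
        raise ValueError(f"need at least one treated dose for {drug_id!r}")
    control_auc = growth_auc(by_dose[0.0])
    if control_auc <= 0:
        raise ValueError(f"control AUC is non-positive for {drug_id!r} ({strain}, rep {replicate})")
    doses, fractions = [], []
    for dose, curve in by_dose.items():
        auc = growth_auc(curve)
        if dose > 0 and auc <= 0:
            warnings.warn(
                f"treated AUC <= 0 at dose {dose} for {drug_id!r}; "
                f"floored at {_AUC_FLOOR_FRACTION} x control",
                stacklevel=2,
            )
            auc = _AUC_FLOOR_FRACTION * control_auc
        doses.append(dose)
        fractions.append(1.0 if dose == 0 else auc / control_auc)
    return DoseResponse(drug_id, strain, replicate, np.array(doses), np.array(fractions))


def dose_response_auc(dr: DoseResponse) -> float:
    """Trapezoidal area under growth fraction vs relative dose, control included."""
    return float(np.trapezoid(dr.growth_fraction, dr.doses))


def relative_efficacy(abc16_auc: float, parental_auc: float) -> float:
    """-log2(ABC-16 growth metric / parental growth metric).

    Zero when the strains are equally sensitive, positive when the
    transporter-null strain is more sensitive (substrate-like), negative when
    it is more resistant.
    """
    if abc16_auc <= 0 or parental_auc <= 0:
        raise ValueError(
            f"growth metrics must be positive, got abc16={abc16_auc}, parental={parental_auc}"
        )
    return -math.log2(abc16_auc / parental_auc)


def summarize_efficacy(
    drug_id: str, replicate_scores: Sequence[float], epsilon: float = 0.1
) -> EfficacyRecord:
    """Average replicate scores and assign the ternary efficacy category.

    sensitive if mean > eps, resistant if mean < -eps, else equal; eps is in
    log2 units.
    """
    scores = tuple(float(s) for s in replicate_scores)
    if not scores:
        raise ValueError(f"no replicate scores for {drug_id!r}")
    mean = float(np.mean(scores))
    if mean > epsilon:
        category = "sensitive"
    elif mean < -epsilon:
        category = "resistant"
    else:
        category = "equal"
    return EfficacyRecord(drug_id, scores, mean, category)


def replicate_concordance(records: Sequence[EfficacyRecord]) -> dict[str, float]:
    """Pearson and Spearman correlation between replicate-1 and replicate-2 scores."""
    pairs = [r.replicate_scores[:2] for r in records if len(r.replicate_scores) >= 2]
    if len(pairs) < 3:
        raise ValueError(f"need >= 3 drugs with two replicates, got {len(pairs)}")
    x = np.array([p[0] for p in pairs])
    y = np.array([p[1] for p in pairs])
    if np.allclose(x, y):
        # identical replicates: correlation is 1 by definition but scipy warns
        return {"pearson": 1.0, "spearman": 1.0, "n": float(len(pairs))}
    pearson = float(stats.pearsonr(x, y).statistic)
    spearman = float(stats.spearmanr(x, y).statistic)
    return {"pearson": pearson, "spearman": spearman, "n": float(len(pairs))}


# ---------------------------------------------------------------------------
# long-format plate reads -> per-drug efficacy table

_PLATE_COLUMNS = ["drug_id", "strain", "relative_dose", "replicate", "time_h", "od600"]


def read_plate_reads(path: str | Path) -> pd.DataFrame:
    frame = pd.read_csv(path)
    missing = [c for c in _PLATE_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"plate-reads CSV {path} missing columns: {missing}")
    return frame


def _curves_from_frame(frame: pd.DataFrame) -> dict[tuple, list[GrowthCurve]]:
    groups: dict[tuple, list[GrowthCurve]] = {}
    for (drug, strain, dose, rep), g in frame.groupby(
        ["drug_id", "strain", "relative_dose", "replicate"], sort=True
    ):
        g = g.sort_values("time_h")
        curve = GrowthCurve(
            drug_id=str(drug),
            strain=str(strain),
            relative_dose=float(dose),
            replicate=int(rep),
            times=g["time_h"].to_numpy(),
            od=g["od600"].to_numpy(),
        )
        groups.setdefault((str(drug), str(strain), int(rep)), []).append(curve)
    return groups


def compute_efficacy_table(
    plate_reads: pd.DataFrame, epsilon: float = 0.1
) -> tuple[pd.DataFrame, list[EfficacyRecord]]:
    """Full reduction of a long-format plate-read table to per-drug efficacy.

    For every (drug, replicate): dose-response AUC per strain, then the
    -log2 strain ratio; replicates are averaged into the drug's score and
    ternary category. Returns (tidy table, records).
    """
    groups = _curves_from_frame(plate_reads)
    per_drug: dict[str, dict[int, dict[str, float]]] = {}
    for (drug, strain, rep), curves in groups.items():
        dr = make_dose_response(curves)
        per_drug.setdefault(drug, {}).setdefault(rep, {})[strain] = dose_response_auc(dr)
    records = []
    for drug in sorted(per_drug):
        scores = []
        for rep in sorted(per_drug[drug]):
            aucs = per_drug[drug][rep]
            missing = [s for s in STRAINS if s not in aucs]
            if missing:
                raise ValueError(f"drug {drug!r} replicate {rep} missing strains: {missing}")
            scores.append(relative_efficacy(aucs["abc16"], aucs["parental"]))
        records.append(summarize_efficacy(drug, scores, epsilon=epsilon))
    table = pd.DataFrame(
        {
            "drug_id": [r.drug_id for r in records],
            **{
                f"score_rep{i + 1}": [
                    r.replicate_scores[i] if i < len(r.replicate_scores) else np.nan
                    for r in records
                ]
                for i in range(max(len(r.replicate_scores) for r in records))
            },
            "mean_score": [r.mean_score for r in records],
            "category": [r.category for r in records],
        }
    )
    return table, records


def write_efficacy_tsv(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False, float_format="%.6f")
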