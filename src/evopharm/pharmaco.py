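"""Paired longitudinal drug-response analysis per evolution group.

For each drug and patient group, the shift in drug AUC between paired
timepoints is summarised as the mean of per-patient paired log2 ratios
log2(AUC_late / AUC_early); candidate drugs are called at p < 0.1 and
|log2FC| > 0.2, with the sign giving direction (negative = sensitization,
positive = acquired resistance). Both the paired t-test and the Wilcoxon
signed-rank test are offered; the default is the paired t-test.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from evopharm.io import ValidationError

METHODS = ("paired_t", "wilcoxon_signed_rank")


@dataclass
class DrugResponseTable:
    """Samples x drugs AUC matrix with a sample -> (patient, timepoint) map.

    AUC values lie in [0, 1]; higher means more resistant. NaN marks a
    drug not screened for a sample.
    """

    values: pd.DataFrame  # index sample_id, columns drugs
    sample_meta: pd.DataFrame  # index sample_id, columns patient_id, timepoint

    def __post_init__(self) -> None:
        for col in ("patient_id", "timepoint"):
            if col not in self.sample_meta.columns:
                raise ValidationError(f"sample_meta missing column {col!r}")
        if not self.values.index.equals(self.sample_meta.index):
            raise ValidationError("values and sample_meta indices differ")
        arr = self.values.to_numpy(dtype=float)
        finite = arr[~np.isnan(arr)]
        if ((finite < 0) | (finite > 1)).any():
            raise ValidationError("AUC values must lie in [0, 1]")
        dup = self.sample_meta.duplicated(subset=["patient_id", "timepoint"])
        if dup.any():
            raise ValidationError("a patient contributes >1 sample per timepoint")

    @property
    def drugs(self) -> list[str]:
        return list(self.values.columns)

    def patients(self) -> list[str]:
        return sorted(self.sample_meta["patient_id"].unique())

    def sample_at(self, patient: str, timepoint: int) -> str | None:
        meta = self.sample_meta
        hit = meta[(meta["patient_id"] == patient) & (meta["timepoint"] == timepoint)]
        return None if hit.empty else str(hit.index[0])

    def to_tsv(self, path: str | Path) -> None:
        joined = self.sample_meta.join(self.values)
        joined.index.name = "sample_id"
        joined.to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "DrugResponseTable":
        df = pd.read_csv(path, sep="\t", index_col="sample_id")
        for col in ("patient_id", "timepoint"):
            if col not in df.columns:
                raise ValidationError(f"missing column(s): ['{col}']")
        meta = df[["patient_id", "timepoint"]].copy()
        meta["timepoint"] = meta["timepoint"].astype(int)
        values = df.drop(columns=["patient_id", "timepoint"]).astype(float)
        return cls(values, meta)


@dataclass
class DrugShiftResult:
    drug: str
    group: str
    n: int
    log2fc: float
    p: float
    direction: str  # sensitive | resistant | none
    testable: bool


def _paired_auc(
    auc: DrugResponseTable,
    group: Iterable[str],
    drug: str,
    t_from: int | None,
    t_to: int | None,
) -> tuple[np.ndarray, np.ndarray]:
    """Complete (early, late) AUC pairs for the group; missing pairs dropped."""
    early, late = [], []
    meta = auc.sample_meta
    for patient in sorted(set(group)):
        tps = sorted(meta.loc[meta["patient_id"] == patient, "timepoint"])
        if t_from is None or t_to is None:
            if len(tps) < 2:
                continue
            tf, tt = tps[0], tps[1]
        else:
            tf, tt = t_from, t_to
        s_from, s_to = auc.sample_at(patient, tf), auc.sample_at(patient, tt)
        if s_from is None or s_to is None:
            continue
        a_from = auc.values.at[s_from, drug]
        a_to = auc.values.at[s_to, drug]
        if np.isnan(a_from) or np.isnan(a_to):
            continue
        early.append(float(a_from))
        late.append(float(a_to))
    return np.asarray(early), np.asarray(late)


def paired_shift(
    auc: DrugResponseTable,
    group: Iterable[str],
    drug: str,
    method: str = "paired_t",
    group_label: str = "",
    t_from: int | None = None,
    t_to: int | None = None,
    p_cut: float = 0.1,
    lfc_cut: float = 0.2,
) -> DrugShiftResult:
    """Test a drug's AUC shift between paired timepoints within a group.

    log2FC is the mean of per-patient paired log ratios, and p is two-sided
    from the chosen paired test applied on the log2 AUC scale. With fewer
    than two complete pairs, or a degenerate (zero-variance) paired t, the
    result is flagged not-testable.
    """
    if method not in METHODS:
        raise ValidationError(f"unknown method {method!r}")
    if drug not in auc.values.columns:
        raise ValidationError(f"unknown drug {drug!r}")
    early, late = _paired_auc(auc, group, drug, t_from, t_to)
    n = len(early)
    if n < 2:
        return DrugShiftResult(drug, group_label, n, float("nan"), float("nan"),
                               "none", testable=False)
    if (early <= 0).any() or (late <= 0).any():
        raise ValidationError("zero AUC encountered; log fold change undefined")
    diffs = np.log2(late) - np.log2(early)
    log2fc = float(diffs.mean())
    if method == "paired_t":
        if np.allclose(diffs, diffs[0]):
            p = float("nan")
        else:
            p = float(stats.ttest_rel(np.log2(late), np.log2(early)).pvalue)
    else:
        if np.all(diffs == 0):
            p = float("nan")
        else:
            p = float(stats.wilcoxon(diffs).pvalue)
    testable = np.isfinite(p)
    direction = _direction(p, log2fc, p_cut, lfc_cut)
    return DrugShiftResult(drug, group_label, n, log2fc, p, direction, testable)


def _direction(p: float, log2fc: float, p_cut: float, lfc_cut: float) -> str:
    if not np.isfinite(p) or p >= p_cut:
        return "none"
    if log2fc <= -lfc_cut:
        return "sensitive"
    if log2fc >= lfc_cut:
        return "resistant"
    return "none"


def select_candidates(
    results: Sequence[DrugShiftResult],
    p_cut: float = 0.1,
    lfc_cut: float = 0.2,
) -> dict[str, list[str]]:
    """Partition drugs into sensitive/resistant candidates by the cutoff rule.

    Drugs are sorted by p then by |log2FC| descending.
    """
    sensitive, resistant = [], []
    for res in sorted(results, key=lambda r: (r.p if np.isfinite(r.p) else np.inf,
                                              -abs(r.log2fc))):
        if not res.testable:
            continue
        direction = _direction(res.p, res.log2fc, p_cut, lfc_cut)
        if direction == "sensitive":
            sensitive.append(res.drug)
        elif direction == "resistant":
            resistant.append(res.drug)
    return {"sensitive": sensitive, "resistant": resistant}


def shift_table(results: Sequence[DrugShiftResult]) -> pd.DataFrame:
    """Volcano-style result table (drug, group, n, log2fc, p, direction)."""
    return pd.DataFrame(
        [
            {
                "drug": r.drug, "group": r.group, "n": r.n,
                "log2fc": r.log2fc, "p": r.p, "direction": r.direction,
            }
            for r in results
        ]
    )
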