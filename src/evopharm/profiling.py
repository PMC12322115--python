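"""Drug-tolerant subclone profiling: single-cell QC, cluster signatures,
bulk deconvolution, treatment staging and prediction performance.

QC drops cells with mitochondrial UMI fraction strictly above 30%, or a
detected-feature count strictly below 200 or strictly above 6,000 (boundary
cells are kept). Cluster signatures are rank-sum DEGs on counts-per-10k
normalized data. Bulk samples are deconvolved into cell-type fractions by
non-negative least squares with sum-to-one renormalization — a documented
stand-in for MuSiC's cross-subject weighting with the same input/output
contract. Treatment stages follow the EGFR–TKI sequence BASELINE → POST1
(1st/2nd-gen TKI) → POST2 (T790M acquired) → POST3 (osimertinib).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import nnls
from sklearn.metrics import roc_auc_score

from evopharm.io import ExpressionMatrix, ValidationError

log = logging.getLogger("evopharm")

STAGES = ("BASELINE", "POST1", "POST2", "POST3")


# ------------------------------------------------------------------ QC

@dataclass(frozen=True)
class QcParams:
    mito_max: float = 0.30
    feat_min: int = 200
    feat_max: int = 6000

    def __post_init__(self) -> None:
        if not 0 < self.mito_max < 1:
            raise ValidationError("mito_max must be in (0, 1)")
        if not 0 < self.feat_min < self.feat_max:
            raise ValidationError("require 0 < feat_min < feat_max")


def qc_filter(
    counts: pd.DataFrame,
    mito_genes: Sequence[str],
    params: QcParams = QcParams(),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Filter a cells x genes UMI count matrix; return (kept, per-cell report).

    The report lists, for every cell, its mito fraction, feature count,
    whether it was dropped, and the triggering rule(s). Strict inequalities:
    a cell at exactly 30% mito and exactly 200 features is kept. Filtering
    is idempotent.
    """
    arr = counts.to_numpy()
    if (arr < 0).any() or not np.issubdtype(arr.dtype, np.number):
        raise ValidationError("counts must be non-negative numbers")
    mito = [g for g in mito_genes if g in counts.columns]
    if len(mito) == len(counts.columns):
        raise ValidationError("need at least one non-mito gene")
    total = counts.sum(axis=1)
    mito_frac = counts[mito].sum(axis=1) / total.replace(0, np.nan) if mito \
        else pd.Series(0.0, index=counts.index)
    mito_frac = mito_frac.fillna(0.0)
    n_features = (counts > 0).sum(axis=1)

    reasons = []
    for cell in counts.index:
        rules = []
        if mito_frac[cell] > params.mito_max:
            rules.append("mito_fraction")
        if n_features[cell] < params.feat_min:
            rules.append("low_features")
        if n_features[cell] > params.feat_max:
            rules.append("high_features")
        reasons.append(";".join(rules))
    report = pd.DataFrame(
        {
            "mito_fraction": mito_frac,
            "n_features": n_features,
            "dropped": [bool(r) for r in reasons],
            "rule": reasons,
        },
        index=counts.index,
    )
    kept = counts.loc[~report["dropped"]]
    if kept.empty and not counts.empty:
        log.warning("qc_filter dropped every cell")
    return kept, report


# ---------------------------------------------------- cluster signatures

@dataclass
class ClusterSignature:
    cluster: str
    table: pd.DataFrame  # columns: gene, log2fc, p; sorted by p asc, lfc desc

    @property
    def genes(self) -> list[str]:
        return list(self.table["gene"])


def cluster_signature(
    counts: pd.DataFrame,
    labels: Mapping[str, str] | pd.Series,
    cluster: str,
    top_n: int = 50,
) -> ClusterSignature:
    """Marker genes of one cluster versus the rest.

    Counts are library-size normalized (counts per 10,000); per gene a
    two-sided Wilcoxon rank-sum test compares cluster vs rest and the
    log2FC is log2((mean_cluster+1)/(mean_rest+1)) on normalized values.
    """
    labels = pd.Series(labels).reindex(counts.index)
    in_cluster = labels == cluster
    if in_cluster.sum() < 3 or (~in_cluster).sum() < 3:
        raise ValidationError("cluster and rest each need >= 3 cells")
    lib = counts.sum(axis=1).replace(0, 1)
    norm = counts.div(lib, axis=0) * 1e4
    a = norm.loc[in_cluster].to_numpy()
    b = norm.loc[~in_cluster].to_numpy()
    with np.errstate(invalid="ignore", divide="ignore"):
        res = stats.ranksums(a, b, axis=0)
    lfc = np.log2((a.mean(axis=0) + 1) / (b.mean(axis=0) + 1))
    table = pd.DataFrame(
        {"gene": counts.columns, "log2fc": lfc, "p": res.pvalue}
    )
    table = table.sort_values(
        ["p", "log2fc"], ascending=[True, False], kind="mergesort"
    ).head(top_n).reset_index(drop=True)
    return ClusterSignature(str(cluster), table)


# ----------------------------------------------------------- deconvolution

def deconvolve(bulk: ExpressionMatrix, ref: pd.DataFrame) -> pd.DataFrame:
    """Estimate cell-type fractions per bulk sample by NNLS.

    `ref` is a celltype x gene reference profile matrix whose genes must be
    a subset of the bulk genes and whose rows must be linearly independent.
    Per sample, solve min ||bulk - f.T @ ref||_2 with f >= 0, then
    renormalize f to sum to one.
    """
    if ref.shape[0] < 2:
        raise ValidationError("need >= 2 cell types")
    missing = [g for g in ref.columns if g not in bulk.df.index]
    if missing:
        raise ValidationError(f"reference genes absent from bulk: {missing[:5]}")
    ref_arr = ref.to_numpy(dtype=float)
    if np.linalg.matrix_rank(ref_arr) < ref.shape[0]:
        raise ValidationError("reference profiles are rank-deficient")
    design = ref_arr.T  # genes x celltypes
    out = np.zeros((len(bulk.samples), ref.shape[0]))
    sub = bulk.df.loc[list(ref.columns)]
    for j, sample in enumerate(bulk.samples):
        f, _ = nnls(design, sub[sample].to_numpy(dtype=float))
        total = f.sum()
        out[j] = f / total if total > 0 else np.full(len(f), 1 / len(f))
    return pd.DataFrame(out, index=bulk.samples, columns=ref.index)


# ----------------------------------------------------------------- staging

def stage_patient(
    tki_generation: int, t790m_status: bool, osimertinib_flag: bool
) -> str:
    """EGFR–TKI treatment stage with precedence POST3 > POST2 > POST1 > BASELINE.

    `tki_generation` is 0 for treatment-naive, 1/2 for 1st/2nd-generation
    TKI, 3 for a third-generation inhibitor.
    """
    if osimertinib_flag and tki_generation == 0:
        raise ValidationError("contradictory record: treatment-naive but osimertinib-treated")
    if t790m_status and tki_generation == 0:
        raise ValidationError("contradictory record: T790M acquisition without TKI")
    if osimertinib_flag or tki_generation == 3:
        return "POST3"
    if t790m_status:
        return "POST2"
    if tki_generation in (1, 2):
        return "POST1"
    return "BASELINE"


def stage_patients(history: pd.DataFrame) -> pd.Series:
    """Stage every patient from a history table.

    Expects columns patient_id, tki_generation, t790m_status,
    osimertinib_flag; returns a patient -> stage Series.
    """
    required = ["patient_id", "tki_generation", "t790m_status", "osimertinib_flag"]
    missing = [c for c in required if c not in history.columns]
    if missing:
        raise ValidationError(f"missing column(s): {missing}")
    out = {}
    for row in history.itertuples():
        out[row.patient_id] = stage_patient(
            int(row.tki_generation), bool(row.t790m_status),
            bool(row.osimertinib_flag),
        )
    return pd.Series(out, name="stage")


# -------------------------------------------------------------------- ROC

def roc_auc(scores: Mapping[str, float] | pd.Series,
            labels: Mapping[str, int] | pd.Series) -> float:
    """Mann–Whitney ROC AUC: P(score+ > score-) + 0.5 * P(tie)."""
    scores = pd.Series(scores, dtype=float)
    labels = pd.Series(labels).reindex(scores.index)
    if labels.isna().any():
        raise ValidationError("labels missing for some samples")
    if labels.nunique() < 2:
        raise ValidationError("both classes must be present")
    return float(roc_auc_score(labels.astype(int), scores))
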