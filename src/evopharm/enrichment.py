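"""Gene-set enrichment: preranked GSEA and per-sample set scoring.

`preranked_gsea` implements the weighted Kolmogorov–Smirnov running-sum
statistic on a preranked list: set members ("hits") increment the running
sum by |stat|^p normalized over set members, non-members decrement it by
1/(N - |set|); ES is the signed maximum deviation. The null is gene-label
permutation: random same-size sets. NES divides ES by the mean |permuted
ES| of the same sign, and the permutation p uses add-one smoothing so the
smallest attainable p is 1/(n_perm + 1).

`sample_set_score` is a per-sample rank-based set score in the ssGSEA
style (hit weights are normalized-rank^alpha, score is the integrated
running-sum difference). It is a deliberate, simpler stand-in for GSVA's
kernel-CDF statistic: both are per-sample rank statistics, and this one is
exactly invariant under strictly monotone transforms of a sample's
expression vector.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

from evopharm.io import ExpressionMatrix, GeneSetCollection, ValidationError


@dataclass
class EnrichmentResult:
    set_name: str
    es: float
    nes: float
    p_perm: float
    leading_edge: list[str]
    n_hits: int


def _running_es(stat_sorted: np.ndarray, hit_mask: np.ndarray, p: float):
    """Signed maximum deviation of the running sum and its position."""
    n = len(stat_sorted)
    n_hits = int(hit_mask.sum())
    if n_hits == 0:
        raise ValidationError("gene set does not intersect the ranked list")
    if n_hits == n:
        raise ValidationError("gene set covers the whole list; no misses")
    weights = np.abs(stat_sorted) ** p
    norm = weights[hit_mask].sum()
    if norm == 0:
        increments = np.where(hit_mask, 1.0 / n_hits, 0.0)
    else:
        increments = np.where(hit_mask, weights / norm, 0.0)
    decrements = np.where(hit_mask, 0.0, 1.0 / (n - n_hits))
    running = np.cumsum(increments - decrements)
    pos = int(np.argmax(np.abs(running)))
    return float(running[pos]), pos, running


def preranked_gsea(
    ranked: Mapping[str, float] | pd.Series,
    gene_set: Iterable[str],
    n_perm: int = 1000,
    weight: float = 1.0,
    seed: int = 0,
) -> EnrichmentResult:
    """Enrichment of a gene set in a preranked gene -> statistic list.

    Genes are ordered by statistic descending (ties by symbol). The
    permutation null redraws the hit positions uniformly, preserving the
    ranked statistics.
    """
    series = pd.Series(ranked, dtype=float)
    if len(series) < 2:
        raise ValidationError("ranked list needs >= 2 genes")
    # descending statistic; ties broken by gene symbol for determinism
    idx = np.lexsort((series.index.to_numpy(), -series.to_numpy()))
    genes = series.index.to_numpy()[idx]
    stat_sorted = series.to_numpy()[idx]
    hit_mask = np.isin(genes, list(gene_set))
    es, pos, _ = _running_es(stat_sorted, hit_mask, weight)
    n_hits = int(hit_mask.sum())

    rng = np.random.default_rng(seed)
    n = len(genes)
    perm_es = np.empty(n_perm)
    for i in range(n_perm):
        mask = np.zeros(n, dtype=bool)
        mask[rng.choice(n, size=n_hits, replace=False)] = True
        perm_es[i], _, _ = _running_es(stat_sorted, mask, weight)

    same_sign = perm_es >= 0 if es >= 0 else perm_es < 0
    exceed = int(np.sum(same_sign & (np.abs(perm_es) >= abs(es))))
    p_perm = (1 + exceed) / (n_perm + 1)
    denom = float(np.mean(np.abs(perm_es[same_sign]))) if same_sign.any() else np.nan
    nes = es / denom if denom and np.isfinite(denom) else float("nan")

    if es >= 0:
        leading = [g for g, h in zip(genes[:pos + 1], hit_mask[:pos + 1]) if h]
    else:
        leading = [g for g, h in zip(genes[pos:], hit_mask[pos:]) if h]
    return EnrichmentResult(str(getattr(gene_set, "name", "")) or "",
                            es, nes, p_perm, list(leading), n_hits)


def enrichment_table(
    ranked, sets: GeneSetCollection, n_perm: int = 1000,
    weight: float = 1.0, seed: int = 0,
) -> pd.DataFrame:
    rows = []
    for name, genes in sets.items():
        res = preranked_gsea(ranked, genes, n_perm=n_perm, weight=weight, seed=seed)
        rows.append({"set": name, "es": res.es, "nes": res.nes,
                     "p": res.p_perm, "n_hits": res.n_hits})
    return pd.DataFrame(rows)


# --------------------------------------------------- per-sample set scores

def sample_set_score(
    expr: ExpressionMatrix,
    sets: GeneSetCollection,
    alpha: float = 0.25,
    normalize: bool = False,
) -> pd.DataFrame:
    """Gene set x sample matrix of rank-based enrichment scores.

    Per sample, genes are ordered by expression descending (ties broken by
    symbol for determinism); hits are weighted by (normalized rank)^alpha
    and the score is the sum of running-sum deviations. A set with no
    expressed member in the matrix is flagged missing (NaN). With
    `normalize`, scores are min-max scaled across samples per set.
    """
    genes = np.asarray(expr.genes)
    n = len(genes)
    if n < 2:
        raise ValidationError("need >= 2 genes")
    values = expr.df.to_numpy(dtype=float)
    scores = pd.DataFrame(
        np.nan, index=list(sets), columns=expr.samples, dtype=float
    )
    member_masks = {
        name: np.isin(genes, members) for name, members in sets.items()
    }
    for j, sample in enumerate(expr.samples):
        col = values[:, j]
        # descending expression; ties by gene symbol
        order = np.lexsort((genes, -col))
        ranks = np.arange(n, 0, -1, dtype=float) / n  # normalized rank weights
        for name, mask in member_masks.items():
            hit = mask[order]
            n_hits = int(hit.sum())
            if n_hits == 0 or n_hits == n:
                continue
            weights = ranks**alpha
            inc = np.where(hit, weights, 0.0)
            inc /= inc.sum()
            dec = np.where(hit, 0.0, 1.0 / (n - n_hits))
            running = np.cumsum(inc - dec)
            scores.at[name, sample] = float(running.sum())
    if normalize:
        rng_span = scores.max(axis=1) - scores.min(axis=1)
        rng_span = rng_span.replace(0, 1.0)
        scores = scores.sub(scores.min(axis=1), axis=0).div(rng_span, axis=0)
    return scores


# ------------------------------------------------------------ score deltas

@dataclass
class ScoreDelta:
    group: str
    set_name: str
    delta: float
    p: float
    n: int


def score_delta(
    scores: pd.DataFrame,
    pairing: Mapping[str, tuple[str, str]],
    group: Iterable[str] | None = None,
    test: str = "paired_t",
    group_label: str = "",
) -> list[ScoreDelta]:
    """Mean score change from T_n to T_{n+1} over paired patients, per set.

    `pairing` maps patient -> (sample at T_n, sample at T_{n+1}). The p
    value is two-sided from a paired t-test or Welch's t-test on the two
    score vectors.
    """
    if test not in ("paired_t", "welch_t"):
        raise ValidationError(f"unknown test {test!r}")
    patients = sorted(pairing) if group is None else sorted(set(group))
    pairs = []
    for patient in patients:
        if patient not in pairing:
            raise ValidationError(f"patient {patient!r} missing from pairing")
        s_from, s_to = pairing[patient]
        if s_from not in scores.columns or s_to not in scores.columns:
            raise ValidationError(f"unmatched pairing for patient {patient!r}")
        pairs.append((s_from, s_to))
    if len(pairs) < 2:
        raise ValidationError("need >= 2 pairs")
    out = []
    for set_name in scores.index:
        early = np.array([scores.at[set_name, s] for s, _ in pairs])
        late = np.array([scores.at[set_name, s] for _, s in pairs])
        keep = np.isfinite(early) & np.isfinite(late)
        early, late = early[keep], late[keep]
        delta = float(late.mean() - early.mean())
        with np.errstate(invalid="ignore", divide="ignore"):
            if test == "paired_t":
                p = float(stats.ttest_rel(late, early).pvalue)
            else:
                p = float(stats.ttest_ind(late, early, equal_var=False).pvalue)
        out.append(ScoreDelta(group_label, str(set_name), delta, p, int(keep.sum())))
    return out
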