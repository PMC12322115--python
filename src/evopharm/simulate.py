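"""Synthetic longitudinal cohort with known ground truth for every stage.

The generator emulates the structure of a refractory-lung-cancer
patient-derived-cell cohort: 34 patients sampled at 2–4 timepoints, a
48-drug AUC screen, targeted-sequencing variant tables, fusion lists, bulk
expression composed of cell-type mixtures, dose–response combination
grids and survival follow-up. Planted constructs and their labels are
returned alongside the data:

* each patient carries an evolution class for a focal truncal mutation —
  persistence (present at every timepoint), extinction (present early,
  absent later), expansion (a second same-gene variant appears late);
  planted-present variants have their alt counts resampled until they
  clear the presence rule, so classification failures cannot be an
  artifact of read-count noise;
* variant allele fractions are Beta distributed (truncal high, private
  low), depth is Poisson, alt counts Binomial;
* drug AUC shifts by a chosen log2 fold change delta between paired
  timepoints for designated sensitive drugs in a designated class, with
  per-timepoint Gaussian noise on the log2 scale — delta is literally the
  planted log2FC, and delta = 0 yields a calibrated null for the paired
  test;
* bulk expression is a Dirichlet mixture of log-normal cell-type reference
  profiles plus Gaussian noise, with a sparse linear gene -> AUC link for
  designated drugs (for signature-recovery experiments);
* survival time is exponential with a planted hazard ratio and
  independent exponential censoring;
* combination grids come from Hill curves; at zero synergy offset the
  combination wells are Loewe-additive (CI = 1 by construction) and a
  positive offset adds excess inhibition (CI < 1).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from evopharm.config import derive_seed
from evopharm.io import ExpressionMatrix, ValidationError, VariantTable
from evopharm.pharmaco import DrugResponseTable
from evopharm.synergy import DoseResponseGrid

CLASSES = ("persistence", "extinction", "expansion")


@dataclass
class SimulationParams:
    """Study conditions for the synthetic cohort."""

    # cohort structure
    n_patients: int = 34
    min_timepoints: int = 2
    max_timepoints: int = 4
    focal_gene: str = "EGFR"
    #: explicit per-patient class labels; None draws from class_probs
    evolution_classes: Sequence[str] | None = None
    #: cohort proportions follow the EGFR evolution groups (13:4:1)
    class_probs: dict = field(default_factory=lambda: {
        "persistence": 13 / 18, "extinction": 4 / 18, "expansion": 1 / 18,
    })

    # variant read counts
    depth_mean: float = 200.0
    vaf_truncal: tuple[float, float] = (8.0, 12.0)   # Beta, mean 0.40
    vaf_private: tuple[float, float] = (2.0, 18.0)   # Beta, mean 0.10
    n_private_mean: float = 3.0
    presence_min_alt: int = 3
    presence_min_vaf: float = 0.02

    # drug screen
    n_drugs: int = 48
    n_sensitive: int = 3
    effect_log2fc: float = -0.5
    auc_sigma: float = 0.1
    effect_class: str = "extinction"

    # expression / cell-type mixtures / signature link
    n_genes: int = 2000
    n_celltypes: int = 7
    dirichlet_conc: float = 1.0
    expr_noise: float = 0.05          # noise sd as a fraction of mean signal
    n_signature_drugs: int = 2
    n_informative: int = 20
    link_scale: float = 0.15          # AUC sd contributed by the gene signal
    link_noise_frac: float = 0.1      # residual sd relative to link_scale

    # survival
    hazard_beta: float = math.log(2.0)
    base_hazard: float = 0.02         # events per month
    censor_hazard: float = 0.01

    # dose-response grids
    hill_m: float = 2.0
    hill_dm_a: float = 10.0
    hill_dm_b: float = 10.0
    synergy_offset: float = 0.0
    grid_noise: float = 0.0

    # fusions
    fusion_pool_size: int = 30
    fusion_mean: float = 3.0

    def __post_init__(self) -> None:
        if self.min_timepoints < 2:
            raise ValidationError(
                "evolution classes need >= 2 timepoints per patient"
            )
        if self.max_timepoints < self.min_timepoints:
            raise ValidationError("max_timepoints < min_timepoints")
        if self.evolution_classes is not None:
            if len(self.evolution_classes) != self.n_patients:
                raise ValidationError("evolution_classes length != n_patients")
            bad = set(self.evolution_classes) - set(CLASSES)
            if bad:
                raise ValidationError(f"unknown class label(s): {sorted(bad)}")
        if self.n_celltypes < 2:
            raise ValidationError("need >= 2 cell types")


@dataclass
class CohortBundle:
    variant_table: VariantTable
    fusion_lists: dict[str, set[str]]
    auc: DrugResponseTable
    expression: ExpressionMatrix
    reference_profiles: pd.DataFrame
    survival: pd.DataFrame
    grids: dict[str, DoseResponseGrid]
    truth: dict


# ------------------------------------------------------------- components

def _present_counts(rng, depth_mean, vaf_a, vaf_b, min_alt, min_vaf):
    """Depth/alt draw guaranteed to clear the presence rule."""
    for _ in range(200):
        depth = max(int(rng.poisson(depth_mean)), min_alt)
        vaf = rng.beta(vaf_a, vaf_b)
        alt = rng.binomial(depth, vaf)
        if alt >= min_alt and alt / depth >= min_vaf:
            return depth, alt
    alt = max(min_alt, math.ceil(min_vaf * depth))
    return depth, alt


def simulate_variants(params: SimulationParams, seed: int):
    """Variant table with planted evolution classes; returns (table, truth)."""
    rng = np.random.default_rng(seed)
    patients = [f"P{i + 1:03d}" for i in range(params.n_patients)]
    if params.evolution_classes is not None:
        classes = list(params.evolution_classes)
    else:
        names = list(params.class_probs)
        probs = np.array([params.class_probs[c] for c in names], dtype=float)
        classes = list(rng.choice(names, size=params.n_patients,
                                  p=probs / probs.sum()))
    n_timepoints = rng.integers(params.min_timepoints,
                                params.max_timepoints + 1,
                                size=params.n_patients)
    gene_pool = [f"GENE{i:04d}" for i in range(200)]
    rows = []
    truth_class: dict[str, str] = {}
    truth_pattern: dict[str, str] = {}
    sample_index: list[tuple[str, str, int]] = []
    for patient, cls, k in zip(patients, classes, n_timepoints):
        truth_class[patient] = cls
        truth_pattern[patient] = {
            "persistence": "1>1", "extinction": "1>0", "expansion": "1>2",
        }[cls]
        for t in range(1, int(k) + 1):
            sample = f"{patient}_T{t}"
            sample_index.append((sample, patient, t))
            focal_variants = []
            if cls == "persistence":
                focal_variants = ["L858R"]
            elif cls == "extinction":
                focal_variants = ["L858R"] if t == 1 else []
            elif cls == "expansion":
                focal_variants = ["L858R"] if t == 1 else ["L858R", "I744M"]
            for change in focal_variants:
                depth, alt = _present_counts(
                    rng, params.depth_mean, *params.vaf_truncal,
                    params.presence_min_alt, params.presence_min_vaf,
                )
                rows.append((patient, sample, t, params.focal_gene, change,
                             depth - alt, alt))
            n_private = rng.poisson(params.n_private_mean)
            if not focal_variants:
                # every screened sample must carry a variant profile
                n_private = max(n_private, 1)
            pick = rng.choice(len(gene_pool), size=min(n_private, len(gene_pool)),
                              replace=False)
            for g in pick:
                depth = max(int(rng.poisson(params.depth_mean)), 1)
                vaf = rng.beta(*params.vaf_private)
                alt = int(rng.binomial(depth, vaf))
                if alt == depth:
                    alt -= 1  # keep ref + alt > 0 with nonzero ref
                rows.append((patient, sample, t, gene_pool[g], "P100L",
                             depth - alt, max(alt, 1)))
    df = pd.DataFrame(rows, columns=[
        "patient_id", "sample_id", "timepoint", "gene", "protein_change",
        "ref_count", "alt_count",
    ])
    truth = {"evolution_class": truth_class, "pattern": truth_pattern,
             "samples": sample_index}
    return VariantTable(df), truth


def simulate_fusions(sample_index, params: SimulationParams, seed: int):
    """Per-sample fusion sets with maintained/vanished/acquired turnover."""
    rng = np.random.default_rng(seed)
    pool = [f"FUS{i:03d}" for i in range(params.fusion_pool_size)]
    by_patient: dict[str, dict[int, set[str]]] = {}
    for sample, patient, t in sample_index:
        by_patient.setdefault(patient, {})[t] = set()
    fusion_lists: dict[str, set[str]] = {}
    for patient, tps in by_patient.items():
        current: set[str] = set(
            rng.choice(pool, size=min(rng.poisson(params.fusion_mean), len(pool)),
                       replace=False)
        )
        for t in sorted(tps):
            if t > 1:
                kept = {f for f in current if rng.random() < 0.5}
                n_new = rng.poisson(1.0)
                fresh = set(rng.choice(pool, size=min(n_new, len(pool)),
                                       replace=False))
                current = kept | fresh
            fusion_lists[f"{patient}_T{t}"] = set(current)
    return fusion_lists


def simulate_auc(sample_index, truth_class, params: SimulationParams, seed: int):
    """Samples x drugs AUC matrix with a planted group-by-time effect.

    log2 AUC at a later timepoint equals the patient baseline plus delta
    (for sensitive drugs in the affected class) plus N(0, sigma^2) noise
    drawn independently per timepoint.
    """
    rng = np.random.default_rng(seed)
    drugs = [f"drug{i + 1:02d}" for i in range(params.n_drugs)]
    sensitive = drugs[: params.n_sensitive]
    samples = [s for s, _, _ in sample_index]
    meta = pd.DataFrame(
        {"patient_id": [p for _, p, _ in sample_index],
         "timepoint": [t for _, _, t in sample_index]},
        index=samples,
    )
    patients = sorted({p for _, p, _ in sample_index})
    baseline = {p: np.log2(rng.beta(4.0, 6.0, size=params.n_drugs).clip(0.05, 0.95))
                for p in patients}
    values = np.empty((len(samples), params.n_drugs))
    for i, (sample, patient, t) in enumerate(sample_index):
        log_auc = baseline[patient] + rng.normal(0.0, params.auc_sigma,
                                                 size=params.n_drugs)
        if t > 1 and truth_class.get(patient) == params.effect_class:
            for j, drug in enumerate(drugs):
                if drug in sensitive:
                    log_auc[j] += params.effect_log2fc
        values[i] = np.clip(2.0**log_auc, 1e-6, 1.0)
    table = DrugResponseTable(pd.DataFrame(values, index=samples, columns=drugs),
                              meta)
    return table, {"sensitive_drugs": sensitive,
                   "effect_class": params.effect_class,
                   "effect_log2fc": params.effect_log2fc}


def make_reference_profiles(n_celltypes: int, n_genes: int, seed: int,
                            marker_fold: float = 5.0) -> pd.DataFrame:
    """Log-normal cell-type reference profiles with marker-gene blocks."""
    rng = np.random.default_rng(seed)
    base = np.exp(rng.normal(np.log(5.0), 1.0, size=n_genes))
    profiles = np.empty((n_celltypes, n_genes))
    block = max(n_genes // (4 * n_celltypes), 1)
    for k in range(n_celltypes):
        jitter = np.exp(rng.normal(0.0, 0.5, size=n_genes))
        profiles[k] = base * jitter
        lo = k * block
        profiles[k, lo:lo + block] *= marker_fold
    genes = [f"GENE{i:04d}" for i in range(n_genes)]
    types = [f"celltype{k + 1}" for k in range(n_celltypes)]
    return pd.DataFrame(profiles, index=types, columns=genes)


def simulate_mixtures(ref: pd.DataFrame, n_samples: int, seed: int,
                      dirichlet_conc: float = 1.0, noise_frac: float = 0.05,
                      sample_names: Sequence[str] | None = None):
    """Bulk expression = Dirichlet mixture of reference profiles + noise."""
    rng = np.random.default_rng(seed)
    k = ref.shape[0]
    fractions = rng.dirichlet(np.full(k, dirichlet_conc), size=n_samples)
    signal = fractions @ ref.to_numpy()
    noise = rng.normal(0.0, noise_frac * signal.mean(), size=signal.shape)
    bulk = np.clip(signal + noise, 0.0, None)
    if sample_names is None:
        sample_names = [f"S{i + 1:03d}" for i in range(n_samples)]
    expr = ExpressionMatrix(pd.DataFrame(bulk.T, index=ref.columns,
                                         columns=list(sample_names)))
    frac_df = pd.DataFrame(fractions, index=list(sample_names), columns=ref.index)
    return expr, frac_df


def generate_expression_response(
    n_samples: int,
    n_genes: int = 2000,
    n_informative: int = 20,
    seed: int = 0,
    n_celltypes: int = 7,
    dirichlet_conc: float = 1.0,
    expr_noise: float = 0.5,
    link_scale: float = 0.15,
    link_noise_frac: float = 0.1,
    baseline_auc: float = 0.5,
):
    """Expression with a sparse linear AUC link: the signature-recovery design.

    Returns (expression, auc Series, truth) where truth holds the
    informative genes, their coefficients and the mixture fractions. The
    response is baseline + link_scale * standardized(Z w) + noise, clipped
    to [0, 1], with Z the per-gene z-scored expression.
    """
    ref = make_reference_profiles(n_celltypes, n_genes,
                                  derive_seed(seed, "ref_profiles"))
    expr, fractions = simulate_mixtures(
        ref, n_samples, derive_seed(seed, "mixtures"),
        dirichlet_conc=dirichlet_conc, noise_frac=expr_noise,
    )
    rng = np.random.default_rng(derive_seed(seed, "signature_link"))
    genes = np.asarray(expr.genes)
    informative_idx = rng.choice(n_genes, size=n_informative, replace=False)
    coefs = rng.uniform(0.5, 1.0, size=n_informative) * rng.choice(
        [-1.0, 1.0], size=n_informative)
    X = expr.df.to_numpy().T  # samples x genes
    std = X.std(axis=0)
    Z = (X - X.mean(axis=0)) / np.where(std == 0, 1.0, std)
    signal = Z[:, informative_idx] @ coefs
    sd = signal.std() or 1.0
    auc = baseline_auc + link_scale * signal / sd + rng.normal(
        0.0, link_scale * link_noise_frac, size=n_samples)
    auc = np.clip(auc, 1e-6, 1.0)
    y = pd.Series(auc, index=expr.samples, name="auc")
    truth = {
        "informative_genes": [str(g) for g in genes[informative_idx]],
        "coefficients": dict(zip(genes[informative_idx], coefs)),
        "fractions": fractions,
    }
    return expr, y, truth


def generate_survival(
    n: int,
    hazard_ratio: float = 2.0,
    seed: int = 0,
    base_hazard: float = 0.02,
    censor_hazard: float = 0.01,
    scores: np.ndarray | None = None,
) -> pd.DataFrame:
    """Exponential survival with a planted hazard ratio and random censoring.

    With `scores` given, the hazard is base_hazard * HR**score (a per-unit
    effect); otherwise subjects split into two equal groups with score 0/1.
    """
    rng = np.random.default_rng(seed)
    if scores is None:
        scores = np.zeros(n)
        scores[n // 2:] = 1.0
    else:
        scores = np.asarray(scores, dtype=float)
        if len(scores) != n:
            raise ValidationError("scores length != n")
    rate = base_hazard * hazard_ratio**scores
    event_time = rng.exponential(1.0 / rate)
    censor_time = rng.exponential(1.0 / censor_hazard, size=n)
    time = np.minimum(event_time, censor_time)
    event = (event_time <= censor_time).astype(int)
    return pd.DataFrame({
        "subject_id": [f"S{i + 1:04d}" for i in range(n)],
        "time_months": np.maximum(time, 1e-6),
        "event": event,
        "score": scores,
    })


def generate_dose_response_grid(
    doses_a: Sequence[float],
    doses_b: Sequence[float],
    m: float = 2.0,
    dm_a: float = 10.0,
    dm_b: float = 10.0,
    synergy_offset: float = 0.0,
    noise: float = 0.0,
    seed: int = 0,
) -> DoseResponseGrid:
    """Hill-model combination grid with a controllable interaction term.

    Single agents follow fa = 1/(1 + (Dm/D)^m). Combination wells are
    Loewe-additive for the shared slope m — the effective normalized dose
    is u = d1/Dm_a + d2/Dm_b and fa = u^m/(1+u^m) — plus `synergy_offset`
    excess inhibition, so offset 0 gives CI = 1 by construction.
    """
    doses_a = np.asarray(sorted(set([0.0, *doses_a])), dtype=float)
    doses_b = np.asarray(sorted(set([0.0, *doses_b])), dtype=float)
    rng = np.random.default_rng(seed)
    grid = np.zeros((len(doses_a), len(doses_b)))
    for i, da in enumerate(doses_a):
        for j, db in enumerate(doses_b):
            if da == 0 and db == 0:
                fa = 0.0
            else:
                u = da / dm_a + db / dm_b
                fa = u**m / (1.0 + u**m)
                if da > 0 and db > 0:
                    fa += synergy_offset
            if noise > 0 and (da > 0 or db > 0):
                fa += rng.normal(0.0, noise)
            grid[i, j] = min(max(fa, 0.0), 1.0)
    return DoseResponseGrid(doses_a, doses_b, grid)


def generate_cell_counts(
    n_cells: int = 300,
    n_genes: int = 200,
    n_clusters: int = 3,
    markers_per_cluster: int = 30,
    seed: int = 0,
    n_mito: int = 10,
    marker_fold: float = 8.0,
    dispersion: float = 2.0,
    depth: float = 20.0,
):
    """Toy negative-binomial cells x genes UMI matrix with planted markers.

    Returns (counts, labels, mito_genes, truth). This is intentionally a
    simple generator for QC-filter and marker-recovery tests, not a
    realistic droplet simulator.
    """
    rng = np.random.default_rng(seed)
    mito_genes = [f"MT-{i + 1}" for i in range(n_mito)]
    other = [f"G{i + 1:04d}" for i in range(n_genes - n_mito)]
    genes = mito_genes + other
    base = rng.gamma(2.0, 0.5, size=n_genes)
    labels = pd.Series(
        [f"cluster{(i % n_clusters) + 1}" for i in range(n_cells)],
        index=[f"cell{i + 1:04d}" for i in range(n_cells)],
    )
    markers = {}
    free = np.arange(n_mito, n_genes)
    rng.shuffle(free)
    for k in range(n_clusters):
        idx = free[k * markers_per_cluster:(k + 1) * markers_per_cluster]
        markers[f"cluster{k + 1}"] = [genes[i] for i in idx]
    mean = np.tile(base, (n_cells, 1))
    for k in range(n_clusters):
        rows = labels.to_numpy() == f"cluster{k + 1}"
        idx = [genes.index(g) for g in markers[f"cluster{k + 1}"]]
        mean[np.ix_(rows, idx)] *= marker_fold
    mean = mean / mean.sum(axis=1, keepdims=True) * depth * n_genes / 10
    p = dispersion / (dispersion + mean)
    counts = rng.negative_binomial(dispersion, p)
    frame = pd.DataFrame(counts, index=labels.index, columns=genes)
    return frame, labels, mito_genes, {"markers": markers}


# ------------------------------------------------------------- the bundle

def generate_cohort(params: SimulationParams, seed: int) -> CohortBundle:
    """Generate the full synthetic cohort; bit-identical given params+seed."""
    variant_table, var_truth = simulate_variants(
        params, derive_seed(seed, "variants"))
    sample_index = var_truth.pop("samples")
    fusion_lists = simulate_fusions(sample_index, params,
                                    derive_seed(seed, "fusions"))
    auc, auc_truth = simulate_auc(sample_index, var_truth["evolution_class"],
                                  params, derive_seed(seed, "auc"))

    ref = make_reference_profiles(params.n_celltypes, params.n_genes,
                                  derive_seed(seed, "ref_profiles"))
    samples = [s for s, _, _ in sample_index]
    expr, fractions = simulate_mixtures(
        ref, len(samples), derive_seed(seed, "mixtures"),
        dirichlet_conc=params.dirichlet_conc, noise_frac=params.expr_noise,
        sample_names=samples,
    )

    # sparse expression -> AUC link for the designated signature drugs
    rng = np.random.default_rng(derive_seed(seed, "signature_link"))
    genes = np.asarray(expr.genes)
    X = expr.df.to_numpy().T
    std = X.std(axis=0)
    Z = (X - X.mean(axis=0)) / np.where(std == 0, 1.0, std)
    signature_drugs = auc.drugs[-params.n_signature_drugs:] \
        if params.n_signature_drugs else []
    informative: dict[str, list[str]] = {}
    values = auc.values.copy()
    for drug in signature_drugs:
        idx = rng.choice(params.n_genes, size=params.n_informative, replace=False)
        coefs = rng.uniform(0.5, 1.0, size=params.n_informative) * rng.choice(
            [-1.0, 1.0], size=params.n_informative)
        signal = Z[:, idx] @ coefs
        sd = signal.std() or 1.0
        y = 0.5 + params.link_scale * signal / sd + rng.normal(
            0.0, params.link_scale * params.link_noise_frac, size=len(samples))
        values[drug] = np.clip(y, 1e-6, 1.0)
        informative[drug] = [str(g) for g in genes[idx]]
    auc = DrugResponseTable(values, auc.sample_meta)

    # survival: hazard driven by the planted fraction of the last cell type
    residual_type = ref.index[-1]
    patients = sorted({p for _, p, _ in sample_index})
    first_sample = {p: f"{p}_T1" for p in patients}
    score = np.array([fractions.at[first_sample[p], residual_type]
                      for p in patients])
    z = (score - score.mean()) / (score.std() or 1.0)
    survival = generate_survival(
        len(patients), hazard_ratio=math.exp(params.hazard_beta),
        seed=derive_seed(seed, "survival"), base_hazard=params.base_hazard,
        censor_hazard=params.censor_hazard, scores=z,
    )
    survival["subject_id"] = patients

    doses = [2.5, 5.0, 10.0, 20.0, 40.0]
    grids = {
        drug: generate_dose_response_grid(
            doses, doses, m=params.hill_m, dm_a=params.hill_dm_a,
            dm_b=params.hill_dm_b, synergy_offset=params.synergy_offset,
            noise=params.grid_noise, seed=derive_seed(seed, f"grid:{drug}"),
        )
        for drug in auc_truth["sensitive_drugs"]
    }

    truth = {
        **var_truth, **auc_truth,
        "informative_genes": informative,
        "fractions": fractions,
        "hazard_beta": params.hazard_beta,
        "residual_celltype": str(residual_type),
        "synergy_offset": params.synergy_offset,
    }
    return CohortBundle(variant_table, fusion_lists, auc, expr, ref,
                        survival, grids, truth)


def simulate_auc_pairs(
    n_pairs: int,
    n_drugs: int = 48,
    delta: float = 0.0,
    sigma: float = 0.1,
    seed: int = 0,
) -> DrugResponseTable:
    """Minimal paired AUC design: n_pairs patients x 2 timepoints.

    Every drug carries the same planted log2 shift `delta` between the two
    timepoints, with independent N(0, sigma^2) log2-scale noise per
    timepoint. The distributional model matches the full cohort generator;
    this fast path exists for the repeated-cohort calibration and power
    experiments.
    """
    rng = np.random.default_rng(seed)
    drugs = [f"drug{i + 1:02d}" for i in range(n_drugs)]
    rows, meta_rows, index = [], [], []
    for i in range(n_pairs):
        patient = f"P{i + 1:03d}"
        baseline = np.log2(rng.beta(4.0, 6.0, size=n_drugs).clip(0.05, 0.95))
        for t in (1, 2):
            log_auc = baseline + rng.normal(0.0, sigma, size=n_drugs)
            if t == 2:
                log_auc = log_auc + delta
            rows.append(np.clip(2.0**log_auc, 1e-6, 1.0))
            meta_rows.append({"patient_id": patient, "timepoint": t})
            index.append(f"{patient}_T{t}")
    values = pd.DataFrame(rows, index=index, columns=drugs)
    meta = pd.DataFrame(meta_rows, index=index)
    return DrugResponseTable(values, meta)
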