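"""Clonal-evolution analysis of longitudinal variant profiles.

Variants are partitioned into truncal (present at every timepoint of a
patient) and private (present in a proper nonempty subset of timepoints)
using a deterministic read-level presence rule. Per focal gene, each
patient's evolution between two timepoints is summarised as a pattern
string "a>b" (a = number of distinct gene variants present at the earlier
timepoint, b at the later) and classified:

* persistence — the same non-empty variant set at both timepoints ("1>1")
* extinction  — variants present early, none late ("1>0")
* expansion   — a strict superset late, or gained from none ("1>2", "0>1")
* complex     — same count but different identity (turnover)
* absent      — no variants of the gene at either timepoint

The module also provides the MATH intratumor-heterogeneity score, a
Nei–Gojobori-style counting dN/dS estimator, fusion maintained/vanished/
acquired dynamics, and mutation-by-metastasis contingency statistics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from evopharm.io import ValidationError, VariantTable

log = logging.getLogger("evopharm")

Variant = tuple[str, str]  # (gene, protein_change)

#: MAD consistency constant making MAD comparable to a standard deviation
#: under normality; part of the established MATH definition.
MAD_CONSTANT = 1.4826

BASES = ("A", "C", "G", "T")

# Standard genetic code, DNA alphabet; "*" marks stop codons.
GENETIC_CODE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}


# ----------------------------------------------------------- presence rule

@dataclass(frozen=True)
class PresenceRule:
    """A variant is present iff alt_count >= min_alt and VAF >= min_vaf."""

    min_alt: int = 3
    min_vaf: float = 0.02

    def __post_init__(self) -> None:
        if self.min_alt < 1:
            raise ValidationError("min_alt must be >= 1")
        if not 0 <= self.min_vaf < 1:
            raise ValidationError("min_vaf must be in [0, 1)")


def _presence_by_timepoint(
    table: VariantTable, patient_id: str, rule: PresenceRule
) -> dict[int, set[Variant]]:
    """Timepoint -> set of variants present under the rule (union over samples)."""
    df = table.with_vaf()
    sub = df[df["patient_id"] == patient_id]
    present = sub[(sub["alt_count"] >= rule.min_alt) & (sub["vaf"] >= rule.min_vaf)]
    out: dict[int, set[Variant]] = {
        int(t): set() for t in sub["timepoint"].unique()
    }
    for row in present.itertuples():
        out[int(row.timepoint)].add((row.gene, row.protein_change))
    return out


@dataclass
class PatientPartition:
    patient_id: str
    truncal: set[Variant]
    #: sorted tuple of timepoints where present -> variants private to them
    private: dict[tuple[int, ...], set[Variant]]


def partition_variants(
    table: VariantTable, rule: PresenceRule = PresenceRule()
) -> dict[str, PatientPartition]:
    """Split each eligible patient's variants into truncal and private sets.

    Patients with a single timepoint are skipped with a warning.
    """
    out: dict[str, PatientPartition] = {}
    for patient in sorted(table.df["patient_id"].unique()):
        timepoints = table.timepoints(patient)
        if len(timepoints) < 2:
            log.warning("patient %s has one timepoint; skipped", patient)
            continue
        by_tp = _presence_by_timepoint(table, patient, rule)
        all_variants: set[Variant] = set().union(*by_tp.values()) if by_tp else set()
        truncal = set(all_variants)
        for tp in timepoints:
            truncal &= by_tp.get(tp, set())
        private: dict[tuple[int, ...], set[Variant]] = {}
        for variant in all_variants - truncal:
            where = tuple(t for t in timepoints if variant in by_tp.get(t, set()))
            private.setdefault(where, set()).add(variant)
        out[patient] = PatientPartition(patient, truncal, private)
    return out


# ------------------------------------------------------- evolution typing

@dataclass
class EvolutionCall:
    patient_id: str
    gene: str
    pattern: str  # "a>b"
    label: str  # persistence | extinction | expansion | complex | absent
    variants_from: frozenset[Variant]
    variants_to: frozenset[Variant]


def classify_evolution(
    table: VariantTable,
    patient_id: str,
    gene: str,
    rule: PresenceRule = PresenceRule(),
    t_from: int | None = None,
    t_to: int | None = None,
) -> EvolutionCall:
    """Classify a patient's evolution type for one focal gene.

    Defaults to the patient's two earliest timepoints when t_from/t_to are
    not given.
    """
    timepoints = table.timepoints(patient_id)
    if t_from is None or t_to is None:
        if len(timepoints) < 2:
            raise ValidationError(
                f"patient {patient_id!r} has fewer than two timepoints"
            )
        t_from, t_to = timepoints[0], timepoints[1]
    for t in (t_from, t_to):
        if t not in timepoints:
            raise ValidationError(
                f"patient {patient_id!r} has no sample at timepoint {t}"
            )
    by_tp = _presence_by_timepoint(table, patient_id, rule)
    a = frozenset(v for v in by_tp.get(t_from, set()) if v[0] == gene)
    b = frozenset(v for v in by_tp.get(t_to, set()) if v[0] == gene)
    pattern = f"{len(a)}>{len(b)}"
    if not a and not b:
        label = "absent"
    elif a and a == b:
        label = "persistence"
    elif a and not b:
        label = "extinction"
    elif b > a or (not a and b):
        label = "expansion"
    else:
        label = "complex"
    return EvolutionCall(patient_id, gene, pattern, label, a, b)


def classify_cohort(
    table: VariantTable,
    genes: Sequence[str],
    rule: PresenceRule = PresenceRule(),
) -> list[EvolutionCall]:
    """Evolution calls for every eligible patient x focal gene."""
    calls = []
    for patient in table.longitudinal_patients():
        for gene in genes:
            calls.append(classify_evolution(table, patient, gene, rule))
    return calls


# -------------------------------------------------------------- MATH score

@dataclass
class MathScore:
    sample_id: str
    value: float
    computable: bool
    mad: float = float("nan")
    median_vaf: float = float("nan")


def math_score(vafs: Iterable[float], sample_id: str = "") -> MathScore:
    """Mutant-allele tumor heterogeneity: 100 * 1.4826*MAD / median(VAF).

    Zero iff all VAFs are equal; invariant under rescaling all VAFs by a
    positive constant. Flagged not-computable for fewer than two variants.
    """
    values = np.asarray(list(vafs), dtype=float)
    if len(values) < 2:
        return MathScore(sample_id, float("nan"), computable=False)
    if ((values <= 0) | (values > 1)).any():
        raise ValidationError("VAFs must lie in (0, 1]")
    med = float(np.median(values))
    if med == 0:
        raise ValidationError("median VAF is zero")
    mad = MAD_CONSTANT * float(np.median(np.abs(values - med)))
    return MathScore(sample_id, 100.0 * mad / med, True, mad, med)


def math_scores_by_sample(table: VariantTable) -> list[MathScore]:
    df = table.with_vaf()
    return [
        math_score(sub["vaf"], sample_id=str(sample))
        for sample, sub in df.groupby("sample_id")
    ]


# ------------------------------------------------------------------- dN/dS

@dataclass
class DnDsEstimate:
    n_obs: int
    s_obs: int
    n_sites: float
    s_sites: float

    @property
    def omega(self) -> float | None:
        """dN/dS ratio; None (flagged undefined) when s_obs == 0."""
        if self.s_obs == 0:
            return None
        return (self.n_obs / self.n_sites) / (self.s_obs / self.s_sites)


def _validate_cds(cds_id: str, seq: str) -> str:
    seq = seq.upper()
    if len(seq) % 3 != 0:
        raise ValidationError(f"CDS {cds_id!r} length is not a multiple of 3")
    if any(base not in BASES for base in seq):
        raise ValidationError(f"CDS {cds_id!r} contains non-ACGT characters")
    for i in range(0, len(seq), 3):
        if GENETIC_CODE[seq[i:i + 3]] == "*":
            raise ValidationError(f"CDS {cds_id!r} contains a stop codon")
    return seq


def codon_site_counts(codon: str) -> tuple[float, float]:
    """Nonsynonymous and synonymous site counts for one codon.

    Each of the 9 possible single-nucleotide changes contributes 1/3 site;
    a change to a stop codon counts as nonsynonymous.
    """
    aa = GENETIC_CODE[codon]
    n_sites = s_sites = 0.0
    for pos in range(3):
        for base in BASES:
            if base == codon[pos]:
                continue
            mutant = codon[:pos] + base + codon[pos + 1:]
            if GENETIC_CODE[mutant] == aa:
                s_sites += 1 / 3
            else:
                n_sites += 1 / 3
    return n_sites, s_sites


def cds_site_counts(seq: str) -> tuple[float, float]:
    n_total = s_total = 0.0
    for i in range(0, len(seq), 3):
        n, s = codon_site_counts(seq[i:i + 3])
        n_total += n
        s_total += s
    return n_total, s_total


def dnds_ratio(
    mutations: Sequence[tuple[str, int, str, str]],
    cds: Mapping[str, str],
) -> DnDsEstimate:
    """Counting dN/dS estimator over single-nucleotide coding mutations.

    `mutations` rows are (cds_id, position, ref_base, alt_base) with 0-based
    positions. Site counts are Nei–Gojobori-style per-codon enumerations of
    all 9 single-nucleotide changes (no multiple-hit correction: observed
    counts per sample are low enough that the correction is immaterial).
    """
    sequences = {cid: _validate_cds(cid, seq) for cid, seq in cds.items()}
    n_sites = s_sites = 0.0
    for seq in sequences.values():
        n, s = cds_site_counts(seq)
        n_sites += n
        s_sites += s
    n_obs = s_obs = 0
    for cds_id, pos, ref, alt in mutations:
        if cds_id not in sequences:
            raise ValidationError(f"unknown CDS {cds_id!r}")
        seq = sequences[cds_id]
        if not 0 <= pos < len(seq):
            raise ValidationError(f"position {pos} out of bounds for {cds_id!r}")
        ref, alt = ref.upper(), alt.upper()
        if seq[pos] != ref:
            raise ValidationError(
                f"ref mismatch for {cds_id!r}:{pos} (expected {seq[pos]}, got {ref})"
            )
        if alt not in BASES or alt == ref:
            raise ValidationError(f"invalid alt base {alt!r} at {cds_id!r}:{pos}")
        start = (pos // 3) * 3
        codon = seq[start:start + 3]
        mutant = codon[:pos - start] + alt + codon[pos - start + 1:]
        if GENETIC_CODE[mutant] == GENETIC_CODE[codon]:
            s_obs += 1
        else:
            n_obs += 1
    return DnDsEstimate(n_obs, s_obs, n_sites, s_sites)


def dnds_delta(
    mutations_from: Sequence[tuple[str, int, str, str]],
    mutations_to: Sequence[tuple[str, int, str, str]],
    cds: Mapping[str, str],
) -> tuple[DnDsEstimate, DnDsEstimate, float | None]:
    """dN/dS at two timepoints and their difference (omega_to - omega_from)."""
    est_from = dnds_ratio(mutations_from, cds)
    est_to = dnds_ratio(mutations_to, cds)
    if est_from.omega is None or est_to.omega is None:
        return est_from, est_to, None
    return est_from, est_to, est_to.omega - est_from.omega


# ---------------------------------------------------------------- fusions

@dataclass
class FusionDynamics:
    patient_id: str
    maintained: int
    vanished: int
    acquired: int


def classify_fusions(
    fusions_by_timepoint: Mapping[int, set[str]],
    t_from: int,
    t_to: int,
    patient_id: str = "",
) -> FusionDynamics:
    """Count maintained, vanished and acquired fusions between timepoints."""
    for t in (t_from, t_to):
        if t not in fusions_by_timepoint:
            raise ValidationError(f"missing timepoint {t}")
    f_from = set(fusions_by_timepoint[t_from])
    f_to = set(fusions_by_timepoint[t_to])
    return FusionDynamics(
        patient_id,
        maintained=len(f_from & f_to),
        vanished=len(f_from - f_to),
        acquired=len(f_to - f_from),
    )


# ---------------------------------------------------------- 2x2 association

@dataclass
class ContingencyTable:
    """2x2 mutation-by-metastasis table with OR and Pearson chi-square."""

    a: int
    b: int
    c: int
    d: int
    odds_ratio: float = float("nan")
    chi2: float = float("nan")
    p: float = float("nan")
    computable: bool = True


def metastasis_association(a: int, b: int, c: int, d: int) -> ContingencyTable:
    """Odds ratio and chi-squared test for a 2x2 contingency table.

    Pearson chi-square without continuity correction, df=1. The OR is
    flagged infinite when b*c == 0 (and ad > 0); the chi-square is flagged
    not-computable when any margin is zero.
    """
    cells = (a, b, c, d)
    if any(x < 0 for x in cells):
        raise ValidationError("cell counts must be >= 0")
    n = sum(cells)
    if n == 0:
        raise ValidationError("grand total must be > 0")
    if b * c == 0:
        odds = float("inf") if a * d > 0 else float("nan")
    else:
        odds = (a * d) / (b * c)
    margins = [(a + b), (c + d), (a + c), (b + d)]
    if any(m == 0 for m in margins):
        return ContingencyTable(a, b, c, d, odds, computable=False)
    chi2 = n * (a * d - b * c) ** 2 / np.prod([float(m) for m in margins])
    p = float(stats.chi2.sf(chi2, df=1))
    return ContingencyTable(a, b, c, d, odds, float(chi2), p)
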