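"""Drug-combination synergy: HSA excess and Chou–Talalay combination index.

The highest-single-agent (HSA) score is 100 x the mean excess of each
combination well's inhibition over the better of its two constituent
single agents. The Chou–Talalay analysis fits each drug's median-effect
line log10(fa/fu) = m*log10(D) - m*log10(Dm) on the wells with 0 < fa < 1,
then reports CI = d1/Dx1 + d2/Dx2 at a target effect level fa, where
Dx_k = Dm_k * (fa/(1-fa))^(1/m_k) is the dose of drug k alone producing
that effect. CI < 1 indicates synergy, 1 additivity, > 1 antagonism.
Inhibition is 1 - viability normalized to the untreated (0,0) well.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from evopharm.io import ValidationError

log = logging.getLogger("evopharm")


@dataclass
class DoseResponseGrid:
    """Complete inhibition lattice over (doses_a x doses_b), zero included."""

    doses_a: np.ndarray
    doses_b: np.ndarray
    inhibition: np.ndarray  # len(doses_a) x len(doses_b), in [0, 1]

    def __post_init__(self) -> None:
        self.doses_a = np.asarray(self.doses_a, dtype=float)
        self.doses_b = np.asarray(self.doses_b, dtype=float)
        self.inhibition = np.asarray(self.inhibition, dtype=float)
        if self.inhibition.shape != (len(self.doses_a), len(self.doses_b)):
            raise ValidationError("inhibition shape does not match dose axes")
        if self.doses_a[0] != 0 or self.doses_b[0] != 0:
            raise ValidationError("dose axes must start at 0 (single-agent margins)")
        if (np.diff(self.doses_a) <= 0).any() or (np.diff(self.doses_b) <= 0).any():
            raise ValidationError("dose axes must be strictly increasing")
        if not np.isfinite(self.inhibition).all():
            raise ValidationError("non-finite inhibition values")

    @classmethod
    def from_plate(cls, plate: pd.DataFrame) -> "DoseResponseGrid":
        """Build a grid from a plate table (dose_a, dose_b, viability, replicate).

        Replicates are averaged; viability is normalized to the untreated
        (0, 0) well and inhibition = 1 - normalized viability, clipped to
        [0, 1].
        """
        mean = plate.groupby(["dose_a", "dose_b"])["viability"].mean()
        doses_a = np.sort(plate["dose_a"].unique())
        doses_b = np.sort(plate["dose_b"].unique())
        if (0.0, 0.0) not in mean.index:
            raise ValidationError("untreated (0, 0) well is required")
        v0 = mean[(0.0, 0.0)]
        if v0 <= 0:
            raise ValidationError("untreated-well viability must be positive")
        grid = np.empty((len(doses_a), len(doses_b)))
        for i, da in enumerate(doses_a):
            for j, db in enumerate(doses_b):
                if (da, db) not in mean.index:
                    raise ValidationError(f"missing well ({da}, {db})")
                grid[i, j] = 1.0 - mean[(da, db)] / v0
        return cls(doses_a, doses_b, np.clip(grid, 0.0, 1.0))

    def single_agent_a(self) -> tuple[np.ndarray, np.ndarray]:
        return self.doses_a[1:], self.inhibition[1:, 0]

    def single_agent_b(self) -> tuple[np.ndarray, np.ndarray]:
        return self.doses_b[1:], self.inhibition[0, 1:]


def hsa_score(grid: DoseResponseGrid) -> float:
    """Mean excess inhibition over the highest single agent, x100."""
    if len(grid.doses_a) < 2 or len(grid.doses_b) < 2:
        raise ValidationError("grid needs combination wells beyond the margins")
    excesses = []
    for i in range(1, len(grid.doses_a)):
        for j in range(1, len(grid.doses_b)):
            best_single = max(grid.inhibition[i, 0], grid.inhibition[0, j])
            excesses.append(grid.inhibition[i, j] - best_single)
    return 100.0 * float(np.mean(excesses))


@dataclass
class MedianEffectFit:
    m: float       # slope of the median-effect line
    dm: float      # median-effect dose (same units as the input doses)
    r2: float
    n_points: int


def median_effect_fit(doses: np.ndarray, fa: np.ndarray) -> MedianEffectFit:
    """Least-squares median-effect fit on log10(fa/(1-fa)) vs log10(dose).

    Points with fa outside (0, 1) carry no information on the log-odds
    scale and are excluded with a warning; at least two usable points with
    positive dose are required.
    """
    doses = np.asarray(doses, dtype=float)
    fa = np.asarray(fa, dtype=float)
    usable = (fa > 0) & (fa < 1) & (doses > 0)
    n_excluded = int((~usable).sum())
    if n_excluded:
        log.warning("median_effect_fit excluded %d point(s) with fa outside (0,1)",
                    n_excluded)
    if usable.sum() < 2:
        raise ValidationError("need >= 2 points with 0 < fa < 1 and dose > 0")
    x = np.log10(doses[usable])
    y = np.log10(fa[usable] / (1.0 - fa[usable]))
    fit = stats.linregress(x, y)
    m = float(fit.slope)
    if m == 0:
        raise ValidationError("degenerate median-effect fit (zero slope)")
    dm = float(10 ** (-fit.intercept / m))
    return MedianEffectFit(m, dm, float(fit.rvalue**2), int(usable.sum()))


def effect_dose(fit: MedianEffectFit, fa: float) -> float:
    """Dose producing effect fa under a median-effect fit."""
    if not 0 < fa < 1:
        raise ValidationError("fa must be in (0, 1)")
    return fit.dm * (fa / (1.0 - fa)) ** (1.0 / fit.m)


@dataclass
class CombinationIndex:
    ci: float
    fa: float
    d1: float
    d2: float
    dx1: float
    dx2: float


def combination_index(
    fit1: MedianEffectFit, fit2: MedianEffectFit,
    d1: float, d2: float, fa: float,
) -> CombinationIndex:
    """Chou–Talalay CI = d1/Dx1 + d2/Dx2 at effect level fa."""
    dx1 = effect_dose(fit1, fa)
    dx2 = effect_dose(fit2, fa)
    return CombinationIndex(d1 / dx1 + d2 / dx2, fa, d1, d2, dx1, dx2)


@dataclass
class SynergyResult:
    hsa: float
    ci_table: pd.DataFrame  # one row per combination well
    fit_a: MedianEffectFit
    fit_b: MedianEffectFit

    @property
    def median_ci(self) -> float:
        return float(self.ci_table["ci"].median())


def synergy_from_grid(grid: DoseResponseGrid) -> SynergyResult:
    """HSA score plus a CI per combination well at its achieved effect.

    Each drug's median-effect curve is fitted from the grid's single-agent
    margins; for every combination well with observed 0 < fa < 1 the CI is
    evaluated at that well's achieved fa.
    """
    hsa = hsa_score(grid)
    fit_a = median_effect_fit(*grid.single_agent_a())
    fit_b = median_effect_fit(*grid.single_agent_b())
    rows = []
    for i in range(1, len(grid.doses_a)):
        for j in range(1, len(grid.doses_b)):
            fa = grid.inhibition[i, j]
            if not 0 < fa < 1:
                continue
            res = combination_index(fit_a, fit_b, grid.doses_a[i],
                                    grid.doses_b[j], fa)
            rows.append({"dose_a": res.d1, "dose_b": res.d2, "fa": fa,
                         "dx1": res.dx1, "dx2": res.dx2, "ci": res.ci})
    return SynergyResult(hsa, pd.DataFrame(rows), fit_a, fit_b)
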