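import numpy as np
import pandas as pd
import pytest

from evopharm.io import ValidationError
from evopharm.simulate import generate_dose_response_grid
from evopharm.synergy import (
    DoseResponseGrid,
    combination_index,
    hsa_score,
    median_effect_fit,
    synergy_from_grid,
)


def grid_from_margins(single_a, single_b, combo):
    """Build a grid with given single-agent inhibitions and combo matrix."""
    doses_a = np.arange(len(single_a) + 1, dtype=float)
    doses_b = np.arange(len(single_b) + 1, dtype=float)
    inh = np.zeros((len(doses_a), len(doses_b)))
    inh[1:, 0] = single_a
    inh[0, 1:] = single_b
    inh[1:, 1:] = combo
    return DoseResponseGrid(doses_a, doses_b, inh)


def test_hsa_zero_when_combo_equals_best_single():
    sa, sb = [0.2, 0.4], [0.3, 0.5]
    combo = np.array([[max(a, b) for b in sb] for a in sa])
    assert hsa_score(grid_from_margins(sa, sb, combo)) == 0.0


def test_hsa_uniform_excess():
    sa, sb = [0.2, 0.4], [0.3, 0.5]
    combo = np.array([[max(a, b) + 0.10 for b in sb] for a in sa])
    assert hsa_score(grid_from_margins(sa, sb, combo)) == pytest.approx(10.0)


def test_hsa_two_by_two_hand_example():
    grid = grid_from_margins([0.3], [0.5], np.array([[0.65]]))
    assert hsa_score(grid) == pytest.approx(15.0)


def test_hsa_extra_null_wells_shrink_score_toward_zero():
    sa, sb = [0.2, 0.4], [0.3, 0.5]
    combo = np.array([[max(a, b) + 0.10 for b in sb] for a in sa])
    base = hsa_score(grid_from_margins(sa, sb, combo))
    sa2 = sa + [0.6]
    combo2 = np.vstack([combo, [max(0.6, b) for b in sb]])  # zero-excess row
    shrunk = hsa_score(grid_from_margins(sa2, sb, combo2))
    assert 0 < shrunk < base


def test_hsa_requires_margins():
    with pytest.raises(ValidationError):
        DoseResponseGrid(np.array([1.0, 2.0]), np.array([0.0, 1.0]),
                         np.zeros((2, 2)))


@pytest.mark.parametrize("m", [0.5, 1.0, 2.0, 4.0])
def test_median_effect_exact_recovery(m):
    dm = 10.0
    doses = np.array([2.0, 5.0, 10.0, 20.0, 50.0])
    fa = 1.0 / (1.0 + (dm / doses) ** m)
    fit = median_effect_fit(doses, fa)
    assert fit.m == pytest.approx(m, abs=1e-9)
    assert fit.dm == pytest.approx(dm, abs=1e-9)
    assert fit.r2 == pytest.approx(1.0, abs=1e-12)


def test_median_effect_three_point_hill():
    fit = median_effect_fit(np.array([5.0, 10.0, 20.0]),
                            np.array([0.2, 0.5, 0.8]))
    assert fit.m == pytest.approx(2.0, abs=1e-9)
    assert fit.dm == pytest.approx(10.0, abs=1e-9)


def test_median_effect_excludes_saturated_points():
    fit = median_effect_fit(np.array([1.0, 5.0, 10.0, 20.0, 100.0]),
                            np.array([0.0, 0.2, 0.5, 0.8, 1.0]))
    assert fit.n_points == 3


def test_median_effect_needs_two_usable_points():
    with pytest.raises(ValidationError):
        median_effect_fit(np.array([1.0, 10.0]), np.array([0.0, 1.0]))


def test_ci_additive_for_identical_drugs():
    fit = median_effect_fit(np.array([5.0, 10.0, 20.0]),
                            np.array([0.2, 0.5, 0.8]))
    fa = 0.6
    dx = fit.dm * (fa / (1 - fa)) ** (1 / fit.m)
    res = combination_index(fit, fit, dx / 2, dx / 2, fa)
    assert res.ci == pytest.approx(1.0, abs=1e-9)


def test_ci_single_agent_at_effect_dose():
    fit = median_effect_fit(np.array([5.0, 10.0, 20.0]),
                            np.array([0.2, 0.5, 0.8]))
    dx1 = fit.dm * (0.5 / 0.5) ** (1 / fit.m)
    res = combination_index(fit, fit, dx1, 0.0, 0.5)
    assert res.ci == pytest.approx(1.0, abs=1e-9)


def test_ci_linear_in_doses():
    fit = median_effect_fit(np.array([5.0, 10.0, 20.0]),
                            np.array([0.2, 0.5, 0.8]))
    full = combination_index(fit, fit, 4.0, 6.0, 0.7).ci
    half = combination_index(fit, fit, 2.0, 3.0, 0.7).ci
    assert half == pytest.approx(full / 2, rel=1e-12)


def test_ci_requires_fractional_effect():
    fit = median_effect_fit(np.array([5.0, 10.0, 20.0]),
                            np.array([0.2, 0.5, 0.8]))
    with pytest.raises(ValidationError):
        combination_index(fit, fit, 1.0, 1.0, 1.0)


def test_plate_normalization_and_replicates():
    rows = []
    for rep in (1, 2):
        rows += [
            {"dose_a": 0.0, "dose_b": 0.0, "viability": 1.0, "replicate": rep},
            {"dose_a": 1.0, "dose_b": 0.0, "viability": 0.7, "replicate": rep},
            {"dose_a": 0.0, "dose_b": 1.0, "viability": 0.5, "replicate": rep},
            {"dose_a": 1.0, "dose_b": 1.0, "viability": 0.35 if rep == 1 else 0.25,
             "replicate": rep},
        ]
    grid = DoseResponseGrid.from_plate(pd.DataFrame(rows))
    assert grid.inhibition[1, 1] == pytest.approx(0.70)  # mean of replicates
    assert hsa_score(grid) == pytest.approx(100 * (0.70 - 0.5))


def test_plate_missing_untreated_well_rejected():
    rows = [{"dose_a": 1.0, "dose_b": 0.0, "viability": 0.7, "replicate": 1}]
    with pytest.raises(ValidationError):
        DoseResponseGrid.from_plate(pd.DataFrame(rows))


def test_simulated_offset_controls_ci():
    """CI ~ 1 at zero synergy offset (median over 100 noisy grids),
    CI < 1 for a positive offset."""
    doses = [2.5, 5.0, 10.0, 20.0, 40.0]
    null_cis, syn_cis = [], []
    for seed in range(100):
        g0 = generate_dose_response_grid(doses, doses, synergy_offset=0.0,
                                         noise=0.01, seed=seed)
        g1 = generate_dose_response_grid(doses, doses, synergy_offset=0.15,
                                         noise=0.01, seed=seed)
        null_cis.append(synergy_from_grid(g0).median_ci)
        syn_cis.append(synergy_from_grid(g1).median_ci)
    assert 0.9 <= np.median(null_cis) <= 1.1
    assert np.median(syn_cis) < 1.0
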