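"""Generate the synthetic longitudinal cohort used by the downstream steps.

Emulates the study design: 34 patients sampled at 2-4 timepoints, a
48-drug AUC screen, targeted variant tables with planted evolution
classes, fusion lists, bulk expression as 7-cell-type mixtures, combination
grids and survival follow-up. Writes the bundle and its ground truth under
results/cohort/.
"""

import json
from collections import Counter
from pathlib import Path

import pandas as pd

from evopharm import io
from evopharm.simulate import SimulationParams, generate_cohort

OUT = Path(__file__).resolve().parent.parent / "results" / "cohort"
SEED = 20240901


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    params = SimulationParams()  # the default study conditions
    bundle = generate_cohort(params, seed=SEED)

    io.write_variant_table(bundle.variant_table, OUT / "variants.tsv")
    io.write_fusion_table(bundle.fusion_lists, OUT / "fusions.tsv")
    bundle.auc.to_tsv(OUT / "auc.tsv")
    io.write_expression(bundle.expression, OUT / "expression.tsv")
    bundle.reference_profiles.to_csv(OUT / "reference_profiles.tsv", sep="\t")
    io.write_survival_table(bundle.survival, OUT / "survival.tsv")
    bundle.truth["fractions"].to_csv(OUT / "true_fractions.tsv", sep="\t")
    truth = {k: v for k, v in bundle.truth.items() if k != "fractions"}
    (OUT / "truth.json").write_text(json.dumps(truth, indent=2, sort_keys=True))
    for drug, grid in bundle.grids.items():
        rows = [{"dose_a": grid.doses_a[i], "dose_b": grid.doses_b[j],
                 "viability": 1.0 - grid.inhibition[i, j], "replicate": 1}
                for i in range(len(grid.doses_a))
                for j in range(len(grid.doses_b))]
        pd.DataFrame(rows).to_csv(OUT / f"grid_{drug}.csv", index=False)

    counts = Counter(truth["evolution_class"].values())
    n_samples = bundle.variant_table.df["sample_id"].nunique()
    print(f"cohort: {params.n_patients} patients, {n_samples} samples, "
          f"{params.n_drugs} drugs")
    print(f"planted evolution classes: {dict(counts)}")
    print(f"sensitive drugs (class={truth['effect_class']}, "
          f"log2FC={truth['effect_log2fc']}): {truth['sensitive_drugs']}")
    print(f"written to {OUT}")


if __name__ == "__main__":
    main()
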