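#!/usr/bin/env python
"""Generate every synthetic input for the downstream analyses.

Produces, under results/data/: a 667-assay two-plate pooled Cq array with 20
planted 2-cycle effects and a mild intensity-dependent bias, ten transcripts
with planted miR-99a seed sites, and a 41-pair cohort with the sex-dimorphic
expression scenario and planted outcome slopes.  Ground-truth manifests sit
next to each output.
"""

from pathlib import Path

import yaml

from placmir import qpcr_screen, synthetic
from placmir.seed_match import MatureMiRNA

SEED = 1
OUT = Path(__file__).resolve().parent.parent / "results" / "data"
CONFIGS = Path(__file__).resolve().parent.parent / "configs" / "scenarios"

MIR99A = MatureMiRNA("miR-99a", "AACCCGUAGAUCCGAUCUUGUG")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)

    cq, truth_array = synthetic.simulate_cq_array(
        seed=SEED,
        de_spec={"n": 20, "delta": 2.0, "cq_window": (18, 30)},
        bias_coeffs=(0.1, 0.01, 0.002),
    )
    qpcr_screen.write_cq_table(cq, OUT / "cq_table.tsv")
    truth_array.to_json(OUT / "truth_array.json")
    print(f"array: 667 assays, {len(truth_array.planted_de)} planted 2-cycle effects")

    synthetic.write_mirnas([MIR99A], OUT / "mirnas.fasta")
    genes, truth_tr = synthetic.simulate_transcripts(
        [MIR99A],
        n_genes=10,
        length_range=(300, 1000),
        seed=SEED + 1,
        plant_spec=[
            {"gene": 0, "mirna": "miR-99a", "mismatches": 0, "region": "3UTR"},
            {"gene": 1, "mirna": "miR-99a", "mismatches": 1, "region": "CDS"},
            {"gene": 2, "mirna": "miR-99a", "mismatches": 2, "region": "3UTR"},
            {"gene": 3, "mirna": "miR-99a", "mismatches": 0, "region": "CDS"},
        ],
    )
    synthetic.write_transcripts(genes, OUT / "transcripts.fasta", OUT / "regions.tsv")
    truth_tr.to_json(OUT / "truth_transcripts.json")
    n_planted = sum(len(v) for v in truth_tr.planted_sites.values())
    print(f"transcripts: {len(genes)} genes, {n_planted} planted seed sites")

    scenario = yaml.safe_load((CONFIGS / "mir99a_sex_dimorphic.yaml").read_text())
    betas = yaml.safe_load((CONFIGS / "planted_associations.yaml").read_text())
    cohort, validation, truth_cohort = synthetic.simulate_cohort(
        seed=SEED + 2,
        cell_effects=scenario["cell_effects"],
        cohort_betas=betas["cohort_betas"],
    )
    cohort.to_csv(OUT / "cohort.csv", index=False)
    validation.to_csv(OUT / "validation_cq.csv", index=False)
    truth_cohort.to_json(OUT / "truth_cohort.json")
    print(f"cohort: {len(cohort)} mother-offspring pairs, "
          f"{cohort['cell'].value_counts().to_dict()}")


if __name__ == "__main__":
    main()
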