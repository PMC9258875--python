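#!/usr/bin/env python
"""Generate seeded synthetic family cohorts, one per inheritance model.

Writes a VCF/PED/BED/annotation/truth bundle per model under
results/simulated/<model>/ and prints a short description of each cohort.
These are the inputs the downstream drivers (02, 03) can be pointed at, and
the same generator the test suite uses.
"""

import sys

sys.path.insert(0, "src")

from famvar.segregation import (
    AUTOSOMAL_DOMINANT,
    AUTOSOMAL_RECESSIVE_HOM,
    COMPOUND_HETEROZYGOUS,
)
from famvar.simulate import (
    CausalSpec,
    SimulationConfig,
    inject_digenic,
    mendelian_check,
    sib_pair_pedigree,
    simulate_cohort,
    two_generation_pedigree,
)

SEED = 2026

MODELS = {
    AUTOSOMAL_DOMINANT: two_generation_pedigree(
        n_affected_children=2, parents_affected=(True, False)),
    AUTOSOMAL_RECESSIVE_HOM: two_generation_pedigree(
        n_affected_children=2, n_unaffected_children=1,
        parents_affected=(False, False)),
    COMPOUND_HETEROZYGOUS: two_generation_pedigree(
        n_affected_children=2, n_unaffected_children=1,
        parents_affected=(False, False)),
}


def main() -> None:
    for model, ped in MODELS.items():
        cfg = SimulationConfig(
            pedigree=ped,
            n_background_variants=1000,
            causal_specs=[CausalSpec(model=model, gene_symbol="CAUSAL",
                                     maf=0.001, cadd=35.0, penetrance=1.0)],
            seed=SEED,
        )
        cohort = simulate_cohort(cfg)
        violations = mendelian_check(cohort.records, cohort.pedigree)
        paths = cohort.write(f"results/simulated/{model}")
        print(f"[{model}] {len(cohort.records)} sites over "
              f"{len(cohort.samples)} samples; "
              f"{len(violations)} Mendelian violations; "
              f"causal: {cohort.truth.expected_pass_per_model}")
        print(f"  -> {paths['vcf']}")

    digenic = inject_digenic(
        SimulationConfig(pedigree=sib_pair_pedigree(2),
                         n_background_variants=1000, seed=SEED),
        "SMYD1", "BMP10",
    )
    paths = digenic.write("results/simulated/digenic_pair")
    print(f"[digenic_pair] injected pair: {digenic.truth.expected_pairs}")
    print(f"  -> {paths['vcf']}")


if __name__ == "__main__":
    main()
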