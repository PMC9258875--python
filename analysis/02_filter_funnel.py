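#!/usr/bin/env python
"""Filter funnel over the simulated cohorts from 01_simulate_cohorts.py.

For each simulated model cohort: restrict to capture targets, apply the
frequency (MAF <= 0.01) and impact (CADD >= 20) filters, and write the
per-step funnel to results/funnels/<model>_funnel.tsv.  Prints observed vs
analytically expected background survival so drift in the generator or
the filters is visible at a glance.
"""

import os
import sys

import numpy as np

sys.path.insert(0, "src")

from famvar.annotation import load_annotation_table
from famvar.filters import FilterConfig, run_filters
from famvar.intervals import read_bed
from famvar.pedigree import parse_pedigrees
from famvar.variants import read_callset

SIM_ROOT = "results/simulated"


def main() -> None:
    if not os.path.isdir(SIM_ROOT):
        sys.exit("run analysis/01_simulate_cohorts.py first")
    os.makedirs("results/funnels", exist_ok=True)
    # expected survival under the generator defaults: log-uniform MAF on
    # [1e-5, 0.05] and 15% CADD mass at >= 20
    p_freq = np.log(0.01 / 1e-5) / np.log(0.05 / 1e-5)
    p_surv = p_freq * 0.15
    for model in sorted(os.listdir(SIM_ROOT)):
        d = os.path.join(SIM_ROOT, model)
        records = read_callset(os.path.join(d, "cohort.vcf"))
        with open(os.path.join(d, "cohort.ped")) as fh:
            ped = next(iter(parse_pedigrees(fh).values()))
        with open(os.path.join(d, "annotation.tsv")) as fh:
            anns = load_annotation_table(fh)
        with open(os.path.join(d, "targets.bed")) as fh:
            targets = read_bed(fh)
        triples = [(s, c, anns[s.key]) for s, c in records if s.key in anns]
        survivors, funnel = run_filters(
            triples, FilterConfig(target_regions=targets), pedigree=ped)
        out = f"results/funnels/{model}_funnel.tsv"
        with open(out, "w") as fh:
            fh.write(funnel.to_tsv())
        n = len(triples)
        print(f"[{model}] {n} -> {len(survivors)} survivors "
              f"(expected background ~{n * p_surv:.0f}); funnel -> {out}")


if __name__ == "__main__":
    main()
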