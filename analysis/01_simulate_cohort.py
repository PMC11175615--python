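#!/usr/bin/env python
"""Generate the synthetic study cohort and write its data files.

Produces the full study-shaped cohort — 69 mother-fetus pairs (35 highland
natives: 16 male / 19 female newborns; 34 lowland migrants: 21 / 13), each
placenta dissected into 7 layers — with genotypes (VCF), allele-specific
read counts, per-layer expression count matrices, metadata with 11 newborn
traits, a 192-gene selection-nominated panel, and the ground-truth JSON.

Output: results/cohort/
"""

import sys
import time
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from placentome.simulate import SimConfig, simulate_cohort, write_cohort  # noqa: E402

OUT = Path(__file__).resolve().parents[1] / "results" / "cohort"


def main(seed: int = 1) -> None:
    t0 = time.time()
    config = SimConfig(seed=seed)
    cohort = simulate_cohort(config)
    paths = write_cohort(cohort, OUT)
    n_male_deg = len({g for layer in cohort.truth.deg["male"].values() for g in layer})
    n_female_deg = len({g for layer in cohort.truth.deg["female"].values() for g in layer})
    print(f"cohort: {config.n_pairs} pairs x {len(config.layers)} layers "
          f"= {len(cohort.metadata)} samples, {config.n_genes} genes, "
          f"{config.n_snps} SNPs  ({time.time() - t0:.1f}s)")
    print(f"planted truth: {n_male_deg} male-stratum effect genes vs "
          f"{n_female_deg} female-stratum ({config.male_bias_factor:.0f}x bias), "
          f"{len(cohort.truth.module_assignment)} module genes in "
          f"{config.n_modules} modules, panel of {len(cohort.truth.panel)}")
    print(f"wrote {len(paths)} files under {OUT}")


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else 1)
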