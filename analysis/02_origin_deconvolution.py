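#!/usr/bin/env python
"""Estimate maternal vs fetal origin of every placental-layer sample.

Reads the cohort written by 01_simulate_cohort.py, classifies informative
SNPs per mother-fetus pair, pools allele-specific reads over five random
tag-SNP subsets, and converts the replicate-averaged fetal-specific allelic
ratio into a fetal fraction. The expected picture: UC and VF essentially
100% fetal, AN/CP/VI/VM >95% fetal, CN mostly maternal (~30% fetal).

Output: results/origin_estimates.tsv and a per-layer summary on stdout.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

import pandas as pd  # noqa: E402

from placentome.deconv import estimate_origins  # noqa: E402
from placentome.io import (  # noqa: E402
    read_allelic_counts_tsv,
    read_metadata_tsv,
    read_vcf_genotypes,
)
from placentome.simulate import SimTruth  # noqa: E402

BASE = Path(__file__).resolve().parents[1] / "results"


def main(seed: int = 1) -> None:
    cohort_dir = BASE / "cohort"
    meta = read_metadata_tsv(cohort_dir / "metadata.tsv")
    estimates, failures = estimate_origins(
        read_allelic_counts_tsv(cohort_dir / "allelic_counts.tsv"),
        read_vcf_genotypes(cohort_dir / "mothers.vcf"),
        read_vcf_genotypes(cohort_dir / "fetuses.vcf"),
        meta,
        seed=seed,
    )
    estimates.to_csv(BASE / "origin_estimates.tsv", sep="\t", index=False)

    truth = SimTruth.from_json((cohort_dir / "truth.json").read_text())
    truth_f = pd.Series(truth.fetal_fraction)
    estimates["abs_error"] = (
        estimates.set_index("sample_id")["fetal_fraction"] - truth_f
    ).abs().to_numpy()
    by_layer = estimates.groupby("layer").agg(
        mean_fetal_fraction=("fetal_fraction", "mean"),
        mean_abs_error=("abs_error", "mean"),
        n=("sample_id", "size"),
    ).round(4)
    print(by_layer.to_string())
    print(f"\noverall mean |error| vs truth: {estimates['abs_error'].mean():.4f}; "
          f"{len(failures)} samples skipped")


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else 1)
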