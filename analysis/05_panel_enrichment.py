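#!/usr/bin/env python
"""Permutation enrichment of the selection-nominated panel in the DEG sets.

Draws panel-sized random gene sets from the expressed universe 10,000 times
and compares the observed panel-DEG overlap with the null, separately for
the combined, male-only and female-only DEG unions, alongside the exact
hypergeometric tail. In the male-biased regime the male-only set should be
the enriched one.

Output: results/enrichment.json.
"""

import json
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from placentome._utils import LAYERS  # noqa: E402
from placentome.de import deg_sets_from_results, run_de  # noqa: E402
from placentome.enrich import permutation_enrichment  # noqa: E402
from placentome.io import read_counts_tsv, read_gene_list, read_metadata_tsv  # noqa: E402

BASE = Path(__file__).resolve().parents[1] / "results"


def main(seed: int = 1) -> None:
    cohort_dir = BASE / "cohort"
    meta = read_metadata_tsv(cohort_dir / "metadata.tsv")
    counts = {layer: read_counts_tsv(cohort_dir / f"counts_{layer}.tsv") for layer in LAYERS}
    panel = read_gene_list(cohort_dir / "panel.txt")

    out = {}
    universe = None
    for stratum in ("combined", "male", "female"):
        results = run_de(counts, meta, stratum=stratum,
                         population_levels=("Tibetan", "Han"))
        if universe is None:
            first = next(iter(results.values()))
            universe = sorted(first.index[~first["p"].isna()])
        coll = deg_sets_from_results(results, stratum)
        deg_union = {g for s in coll.sets.values() for g in s} & set(universe)
        res = permutation_enrichment(
            universe, deg_union, panel=[g for g in panel if g in set(universe)],
            n_perm=10_000, seed=seed, name=stratum,
        )
        out[stratum] = res.to_dict()
        print(f"{stratum:>8}: overlap {res.observed_overlap} of panel "
              f"{res.panel_size} vs {res.deg_set_size} DEGs in {res.universe_size} "
              f"genes -> empirical p {res.empirical_p_label} "
              f"(hypergeometric {res.hypergeom_p:.3g})")

    (BASE / "enrichment.json").write_text(json.dumps(out, indent=1, sort_keys=True))
    print(f"\nwrote {BASE / 'enrichment.json'}")


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else 1)
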