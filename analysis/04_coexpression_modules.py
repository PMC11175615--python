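#!/usr/bin/env python
"""Co-expression modules and module-trait association, per sex stratum.

For each layer x sex network: variance-stabilized expression of the most
variable genes, soft power by scale-free fit, TOM-based module detection,
eigengene correlation with population and the 11 newborn traits, SDM and
key-module calling under the 0.05/Meff trait threshold, and hub genes
(kME > 0.2, |trait r| > 0.8, top-3 intra-module connectivity).

Outputs: results/modules/<layer>_<stratum>/ tables and a summary on stdout.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

import warnings  # noqa: E402

from placentome._utils import LAYERS, TRAITS  # noqa: E402
from placentome.coexpr import (  # noqa: E402
    detect_modules,
    effective_trait_number,
    flag_sdm_and_key,
    hub_genes,
    module_trait_association,
    pick_soft_power,
    vst_like_transform,
)
from placentome.de import deg_sets_from_results, run_de  # noqa: E402
from placentome.io import read_counts_tsv, read_metadata_tsv  # noqa: E402

BASE = Path(__file__).resolve().parents[1] / "results"
N_TOP_GENES = 1500


def main() -> None:
    cohort_dir = BASE / "cohort"
    outbase = BASE / "modules"
    meta = read_metadata_tsv(cohort_dir / "metadata.tsv")
    counts = {layer: read_counts_tsv(cohort_dir / f"counts_{layer}.tsv") for layer in LAYERS}

    for stratum in ("male", "female"):
        sub = meta[meta["infant_sex"] == stratum]
        trait_corr = sub.drop_duplicates("pair_id")[list(TRAITS)].corr()
        meff, trait_alpha = effective_trait_number(trait_corr)
        print(f"\n=== {stratum}: Meff {meff:.2f} -> trait threshold {trait_alpha:.4g} ===")
        de_results = run_de(counts, meta, stratum=stratum,
                            population_levels=("Tibetan", "Han"))
        collections = deg_sets_from_results(de_results, stratum)
        for layer in LAYERS:
            cols = sorted(set(counts[layer].columns) & set(sub["sample_id"]))
            expr = vst_like_transform(counts[layer][cols])
            top = expr.var(axis=0).nlargest(min(N_TOP_GENES, expr.shape[1])).index
            expr = expr[top]
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                power = pick_soft_power(expr)
            mset = detect_modules(expr, power, layer=layer, stratum=stratum)
            if not mset.module_ids:
                print(f"{layer}/{stratum}: power {power}, no modules above size floor")
                continue
            sample_meta = sub.set_index("sample_id").loc[expr.index]
            stats_tab = module_trait_association(
                mset.eigengenes, sample_meta[list(TRAITS)], sample_meta["population"]
            )
            flagged = flag_sdm_and_key(
                stats_tab, mset, set(collections.sets[layer]),
                collections.universe_size, meff,
            )
            hubs = hub_genes(mset, expr, sample_meta[list(TRAITS)])
            outdir = outbase / f"{layer}_{stratum}"
            outdir.mkdir(parents=True, exist_ok=True)
            mset.assignments.rename("module").to_csv(
                outdir / "modules.tsv", sep="\t", index_label="gene_id")
            mset.eigengenes.to_csv(outdir / "eigengenes.tsv", sep="\t",
                                   index_label="sample_id")
            flagged.to_csv(outdir / "module_trait.tsv", sep="\t")
            hubs.to_csv(outdir / "hubs.tsv", sep="\t", index=False)
            sdms = flagged[flagged["is_sdm"]]
            key = flagged[flagged["is_key"]]
            msg = (f"{layer}/{stratum}: power {power}, {len(mset.module_ids)} modules, "
                   f"{len(sdms)} SDM (meff rule), {int(flagged['is_sdm_05'].sum())} at 0.05, "
                   f"{len(hubs)} hub genes")
            if len(key):
                k = key.index[0]
                msg += (f"; key module {k} (best trait {key.iloc[0]['best_trait']}, "
                        f"p {key.iloc[0]['min_trait_p']:.2g}, "
                        f"DEG overlap {int(key.iloc[0]['deg_overlap'])})")
            print(msg)


if __name__ == "__main__":
    main()
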