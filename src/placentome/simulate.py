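"""Synthetic mother-fetus placental cohort generator.

Emulates the data entering the analysis stages with known ground truth:

* a cohort of mother-fetus pairs from two populations living at the same
  altitude (default 35 highland natives vs 34 lowland migrants, with the
  study's male/female newborn split of 16/19 and 21/13), each placenta
  dissected into seven layers (UC, AN, CN, CP, VF, VI, VM);
* maternal genotypes in Hardy-Weinberg proportions and Mendelian-consistent
  fetal genotypes (one transmitted maternal allele plus one population
  allele), from which informative SNPs arise naturally;
* allele-specific read counts per placental sample whose mixing proportion
  is the layer's fetal fraction (UC and VF purely fetal, CN mostly maternal);
* negative-binomial expression counts with a population effect concentrated
  in specific layers and strongly male-biased, plus maternal-age and
  fetal-sex nuisance effects and planted co-expression modules;
* newborn traits driven by the module latents, so module-trait association
  has a recoverable signal.

Every random draw flows from a single seed through named substreams, and the
generator returns a :class:`SimTruth` alongside the data so recovery can be
scored exactly.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._utils import LAYERS, TRAITS, stage_rng

__all__ = [
    "SimConfig",
    "SimTruth",
    "Cohort",
    "default_deg_architecture",
    "default_trait_loadings",
    "simulate_fetus_genotypes",
    "simulate_allelic_counts",
    "simulate_counts",
    "simulate_traits",
    "simulate_cohort",
    "write_cohort",
]

#: Default per-layer fetal fractions: umbilical cord and fetal villus are
#: purely fetal tissue, chorion is mostly maternal (~70%), the remaining
#: layers carry a small maternal contamination.
DEFAULT_FETAL_FRACTION = {
    "UC": 1.0,
    "AN": 0.97,
    "CN": 0.30,
    "CP": 0.97,
    "VF": 1.0,
    "VI": 0.97,
    "VM": 0.96,
}


def default_deg_architecture(male_bias_factor: float = 10.0) -> dict:
    """Per-layer counts of true population-effect genes by effect class.

    ``shared`` effects act in both sexes and are concentrated in the villus
    layers (the combined-analysis regime); ``male`` effects act only in
    male-newborn samples and are concentrated in UC/AN/VF (the sex-stratified
    regime); ``female`` counts are the male counts divided by
    ``male_bias_factor`` (floor 1 where the male layer count is positive).
    """
    male = {"UC": 400, "AN": 180, "CN": 10, "CP": 10, "VF": 190, "VI": 10, "VM": 10}
    shared = {"UC": 8, "AN": 8, "CN": 8, "CP": 8, "VF": 170, "VI": 300, "VM": 8}
    female = {
        layer: (max(1, int(round(n / male_bias_factor))) if n > 0 else 0)
        for layer, n in male.items()
    }
    return {"shared": shared, "male": male, "female": female}


def default_trait_loadings() -> dict:
    """Module -> trait generative coefficients (birth weight and placental
    volume on module 1, amniotic-fluid traits on module 2, etc.)."""
    return {
        1: {"BW": 0.6, "PLV": 0.4},
        2: {"AFI": 0.5, "AFMD": 0.5},
        3: {"AG": 0.5},
        4: {"FH": 0.5},
        5: {"FUH": 0.5},
    }


@dataclass
class SimConfig:
    """Generator settings; defaults are the study conditions."""

    n_pairs_pop1: int = 35
    n_pairs_pop2: int = 34
    #: (male, female) newborn counts per population
    sex_split: Mapping[str, tuple] = field(
        default_factory=lambda: {"pop1": (16, 19), "pop2": (21, 13)}
    )
    population_names: tuple = ("Tibetan", "Han")
    layers: tuple = LAYERS
    n_snps: int = 800
    n_genes: int = 17284
    layer_fetal_fraction: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_FETAL_FRACTION)
    )
    read_depth: float = 30.0
    seq_error: float = 0.002
    deg_architecture: Mapping[str, Mapping[str, int]] = field(
        default_factory=default_deg_architecture
    )
    male_bias_factor: float = 10.0
    lfc_mean: float = 1.5
    lfc_sd: float = 0.5
    lfc_min: float = 0.5
    dispersion_shape: float = 2.0
    dispersion_scale: float = 0.05
    libsize_sd: float = 0.3
    baseline_log2_mean: float = 5.0
    baseline_log2_sd: float = 2.0
    frac_age_genes: float = 0.05
    age_coef_sd: float = 0.05
    frac_sex_genes: float = 0.05
    sex_coef_sd: float = 0.5
    n_modules: int = 5
    module_sizes: Sequence[int] = (100, 80, 60, 50, 40)
    module_strength: float = 1.0
    trait_loadings: Mapping[int, Mapping[str, float]] = field(
        default_factory=default_trait_loadings
    )
    #: per-module mean shift of the latent in population 1 — the generative
    #: analogue of a significantly differential module (population-associated
    #: and trait-associated at once)
    module_pop_shift: Mapping[int, float] = field(default_factory=lambda: {1: 0.8})
    trait_noise_sd: float = 0.5
    panel_size: int = 192
    panel_n_from_male_degs: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for name in ("n_pairs_pop1", "n_pairs_pop2", "n_snps", "n_genes", "n_modules"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for pop, n_pairs in (("pop1", self.n_pairs_pop1), ("pop2", self.n_pairs_pop2)):
            male, female = self.sex_split[pop]
            if male + female != n_pairs:
                raise ValueError(f"sex_split[{pop}] must sum to the pair count")
        for layer in self.layers:
            f = self.layer_fetal_fraction[layer]
            if not 0.0 <= f <= 1.0:
                raise ValueError(f"fetal fraction for {layer} outside [0, 1]")
        if not 0.0 <= self.seq_error < 1.0:
            raise ValueError("seq_error must lie in [0, 1)")
        if len(self.module_sizes) != self.n_modules:
            raise ValueError("module_sizes length must equal n_modules")
        if sum(self.module_sizes) > self.n_genes:
            raise ValueError("module sizes exceed the gene universe")
        required = sum(self.module_sizes) + sum(
            max(sum(counts.values()), *counts.values())
            for counts in self.deg_architecture.values()
            if counts
        )
        if required > self.n_genes:
            raise ValueError(
                f"gene universe too small: modules + effect-gene pools need "
                f"{required} genes but n_genes={self.n_genes}"
            )
        for mod in self.module_pop_shift:
            if not 1 <= mod <= self.n_modules:
                raise ValueError(f"module_pop_shift references unknown module {mod}")
        for mod, loads in self.trait_loadings.items():
            if not 1 <= mod <= self.n_modules:
                raise ValueError(f"trait loading references unknown module {mod}")
            for trait in loads:
                if trait not in TRAITS:
                    raise ValueError(f"unknown trait name {trait!r} in loadings")

    @property
    def n_pairs(self) -> int:
        return self.n_pairs_pop1 + self.n_pairs_pop2


@dataclass
class SimTruth:
    """Ground truth emitted with every cohort."""

    fetal_fraction: dict  # sample_id -> true mixing fraction
    deg: dict  # effect class -> layer -> {gene_id: signed log2FC}
    module_assignment: dict  # gene_id -> module id (members only; absent = 0)
    trait_loadings: dict  # module -> {trait: coefficient}
    age_genes: dict  # gene_id -> maternal-age coefficient (per z-score unit)
    sex_genes: dict  # gene_id -> male-vs-female log2 effect
    panel: list  # selection-nominated panel gene ids

    def to_json(self) -> str:
        payload = dataclasses.asdict(self)
        payload["deg"] = {
            cls: {layer: dict(genes) for layer, genes in layers.items()}
            for cls, layers in self.deg.items()
        }
        return json.dumps(payload, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "SimTruth":
        d = json.loads(text)
        d["trait_loadings"] = {int(k): v for k, v in d["trait_loadings"].items()}
        return cls(**d)


@dataclass
class Cohort:
    """In-memory synthetic cohort: data tables plus ground truth."""

    config: SimConfig
    metadata: pd.DataFrame  # one row per placental sample (pair x layer)
    pair_table: pd.DataFrame  # one row per mother-fetus pair
    allele_freqs: pd.Series  # alt-allele frequency per variant
    mother_gt: pd.DataFrame  # variants x pairs, 0/1/2 (-1 missing)
    fetus_gt: pd.DataFrame
    allelic_counts: pd.DataFrame  # long: sample_id, variant_id, a_count, b_count
    counts: dict  # layer -> genes x samples integer DataFrame
    traits: pd.DataFrame  # pairs x 11 traits (standardized scale)
    truth: SimTruth


# ---------------------------------------------------------------------------
# genotypes


def _variant_ids(n_snps: int, rng: np.random.Generator) -> list:
    bases = np.array(list("ACGT"))
    chroms = 1 + (np.arange(n_snps) % 22)
    pos = np.unique(rng.integers(10_000, 50_000_000, size=2 * n_snps + 16))
    while pos.size < n_snps:  # vanishingly unlikely at any realistic n_snps
        pos = np.unique(np.concatenate([pos, rng.integers(10_000, 50_000_000, size=n_snps)]))
    pos = np.sort(rng.choice(pos, size=n_snps, replace=False))
    ref = bases[rng.integers(0, 4, n_snps)]
    alt_offset = rng.integers(1, 4, n_snps)
    alt = bases[(np.searchsorted(bases, ref) + alt_offset) % 4]
    return [f"chr{c}:{p}:{r}:{a}" for c, p, r, a in zip(chroms, pos, ref, alt)]


def simulate_fetus_genotypes(
    mother_gt: pd.DataFrame, allele_freqs: pd.Series, seed: int
) -> pd.DataFrame:
    """Draw fetal genotypes Mendelian-consistently from the mothers.

    Each fetus receives one transmitted maternal allele (a fair coin at
    heterozygous sites) and one paternal allele drawn from the population
    alt-allele frequency. Missing maternal genotypes (coded -1) propagate to
    the fetus.
    """
    freqs = allele_freqs.loc[mother_gt.index].to_numpy(float)
    if ((freqs <= 0) | (freqs >= 1)).any():
        raise ValueError("allele frequencies must lie strictly in (0, 1)")
    gm = mother_gt.to_numpy()
    if not np.isin(gm, (-1, 0, 1, 2)).all():
        raise ValueError("genotypes must be 0/1/2 (or -1 for missing)")
    rng = np.random.default_rng(seed)
    n_var, n_pairs = gm.shape
    transmitted = np.where(
        gm == 1, rng.integers(0, 2, size=gm.shape), (gm == 2).astype(np.int64)
    )
    paternal = rng.binomial(1, freqs[:, None], size=gm.shape)
    gf = (transmitted + paternal).astype(np.int8)
    gf[gm == -1] = -1
    return pd.DataFrame(gf, index=mother_gt.index, columns=mother_gt.columns)


# ---------------------------------------------------------------------------
# allele-specific reads


def simulate_allelic_counts(
    mother_gt: pd.Series,
    fetus_gt: pd.Series,
    fetal_fraction: float,
    depth: float,
    seq_error: float,
    seed: int | np.random.Generator,
) -> pd.DataFrame:
    """Per-variant (a_count, b_count) reads for one placental sample.

    Read depth per variant is Poisson around ``depth``; each read originates
    from the fetal allele pool with probability ``fetal_fraction`` and the
    maternal pool otherwise, and is miscalled with probability ``seq_error``.
    ``a_count`` counts reference reads, ``b_count`` alternate reads.
    """
    if depth <= 0:
        raise ValueError("depth must be positive")
    if not 0.0 <= fetal_fraction <= 1.0:
        raise ValueError("fetal_fraction must lie in [0, 1]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    gm = mother_gt.to_numpy(float)
    gf = fetus_gt.to_numpy(float)
    usable = (gm >= 0) & (gf >= 0)
    p_alt = fetal_fraction * gf / 2.0 + (1.0 - fetal_fraction) * gm / 2.0
    p_obs = p_alt * (1.0 - seq_error) + (1.0 - p_alt) * seq_error
    n = rng.poisson(depth, size=gm.shape)
    b = np.where(usable, rng.binomial(np.where(usable, n, 0), np.where(usable, p_obs, 0.0)), 0)
    n = np.where(usable, n, 0)
    return pd.DataFrame(
        {
            "variant_id": mother_gt.index,
            "a_count": (n - b).astype(np.int64),
            "b_count": b.astype(np.int64),
        }
    )


# ---------------------------------------------------------------------------
# cohort metadata and traits


def _build_pairs(config: SimConfig) -> pd.DataFrame:
    rows = []
    k = 0
    for pop_key, pop_name, n_pairs in (
        ("pop1", config.population_names[0], config.n_pairs_pop1),
        ("pop2", config.population_names[1], config.n_pairs_pop2),
    ):
        n_male, n_female = config.sex_split[pop_key]
        sexes = ["male"] * n_male + ["female"] * n_female
        for sex in sexes:
            k += 1
            rows.append({"pair_id": f"P{k:03d}", "population": pop_name, "infant_sex": sex})
    return pd.DataFrame(rows)


def simulate_traits(
    eigengene_latents: np.ndarray,
    loadings: Mapping[int, Mapping[str, float]],
    noise_sd: float,
    seed: int | np.random.Generator,
) -> pd.DataFrame:
    """Newborn traits as linear combinations of module latents plus noise.

    ``eigengene_latents`` is pairs x modules (module ids 1..n_modules by
    column). Traits live on a standardized scale; with all-zero loadings they
    are independent of every module.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n_pairs, n_modules = eigengene_latents.shape
    values = rng.normal(0.0, noise_sd, size=(n_pairs, len(TRAITS)))
    trait_index = {t: i for i, t in enumerate(TRAITS)}
    for mod, coefs in loadings.items():
        if not 1 <= int(mod) <= n_modules:
            raise ValueError(f"loading references unknown module {mod}")
        for trait, coef in coefs.items():
            if trait not in trait_index:
                raise ValueError(f"unknown trait name {trait!r}")
            values[:, trait_index[trait]] += coef * eigengene_latents[:, int(mod) - 1]
    return pd.DataFrame(values, columns=list(TRAITS))


# ---------------------------------------------------------------------------
# expression counts


def _draw_lfc(rng: np.random.Generator, n: int, config: SimConfig) -> np.ndarray:
    mag = np.maximum(config.lfc_min, rng.normal(config.lfc_mean, config.lfc_sd, n))
    sign = rng.choice((-1.0, 1.0), n)
    return sign * mag


def _allocate_truth(config: SimConfig, genes: np.ndarray, rng: np.random.Generator) -> tuple:
    """Partition genes into module members, DE pools and nuisance-effect sets."""
    shuffled = genes[rng.permutation(genes.size)]
    cursor = 0
    module_assignment: dict = {}
    module_members: dict = {}
    for mod, size in enumerate(config.module_sizes, start=1):
        members = shuffled[cursor : cursor + size]
        cursor += size
        module_members[mod] = list(members)
        for g in members:
            module_assignment[g] = mod

    deg: dict = {}
    for cls, layer_counts in config.deg_architecture.items():
        # the class pool sizing lets independent per-layer draws overlap,
        # which is what produces multi-layer-shared effect genes
        pool_size = max(sum(layer_counts.values()), max(layer_counts.values() or [1]))
        pool = shuffled[cursor : cursor + pool_size]
        cursor += pool_size
        deg[cls] = {}
        for layer, n in layer_counts.items():
            if n == 0:
                deg[cls][layer] = {}
                continue
            chosen = rng.choice(pool, size=n, replace=False)
            deg[cls][layer] = dict(zip(chosen.tolist(), _draw_lfc(rng, chosen.size, config)))

    n_age = int(round(config.frac_age_genes * genes.size))
    n_sex = int(round(config.frac_sex_genes * genes.size))
    age_genes = dict(
        zip(
            rng.choice(genes, n_age, replace=False).tolist(),
            rng.normal(0.0, config.age_coef_sd, n_age),
        )
    )
    sex_genes = dict(
        zip(
            rng.choice(genes, n_sex, replace=False).tolist(),
            rng.normal(0.0, config.sex_coef_sd, n_sex),
        )
    )
    return module_assignment, module_members, deg, age_genes, sex_genes


def simulate_counts(
    config: SimConfig,
    metadata: pd.DataFrame,
    truth: SimTruth,
    seed: int,
    module_latents: np.ndarray | None = None,
) -> dict:
    """Negative-binomial gene x sample count matrices, one per layer.

    Per gene g and sample j the mean is
    ``libsize_j * baseline_g * 2^(x_j * beta + age_z_j * gamma + male_j * delta
    + module loading * latent)`` with gene-wise gamma-distributed dispersion;
    the population coefficient ``beta`` is nonzero exactly for the ground-truth
    effect genes of the sample's layer and effect class.
    """
    rng = np.random.default_rng(seed)
    genes = np.array([f"G{i:06d}" for i in range(1, config.n_genes + 1)])
    pair_ids = metadata["pair_id"].drop_duplicates().tolist()
    pair_meta = metadata.drop_duplicates("pair_id").set_index("pair_id")
    gene_pos = {g: i for i, g in enumerate(genes)}

    baseline = 2.0 ** rng.normal(config.baseline_log2_mean, config.baseline_log2_sd, genes.size)
    dispersion = rng.gamma(config.dispersion_shape, config.dispersion_scale, genes.size)
    dispersion = np.maximum(dispersion, 1e-4)
    libsize = {
        s: np.exp(rng.normal(0.0, config.libsize_sd)) for s in metadata["sample_id"]
    }

    age_z = pair_meta.loc[pair_ids, "maternal_age"].to_numpy(float)
    age_z = (age_z - age_z.mean()) / age_z.std()
    is_pop1 = (
        pair_meta.loc[pair_ids, "population"].to_numpy() == config.population_names[0]
    ).astype(float)
    is_male = (pair_meta.loc[pair_ids, "infant_sex"].to_numpy() == "male").astype(float)

    # per-gene covariate coefficient vectors
    age_coef = np.zeros(genes.size)
    for g, c in truth.age_genes.items():
        age_coef[gene_pos[g]] = c
    sex_coef = np.zeros(genes.size)
    for g, c in truth.sex_genes.items():
        sex_coef[gene_pos[g]] = c
    module_load = np.zeros(genes.size)
    module_of = np.zeros(genes.size, dtype=int)
    for g, mod in truth.module_assignment.items():
        module_load[gene_pos[g]] = config.module_strength * rng.uniform(0.3, 0.8)
        module_of[gene_pos[g]] = mod

    counts: dict = {}
    for layer in config.layers:
        beta = np.zeros(genes.size)  # shared-class effect
        beta_m = np.zeros(genes.size)  # male-only
        beta_f = np.zeros(genes.size)  # female-only
        for cls, vec in (("shared", beta), ("male", beta_m), ("female", beta_f)):
            for g, lfc in truth.deg.get(cls, {}).get(layer, {}).items():
                vec[gene_pos[g]] = lfc
        log2_mu = (
            np.log2(baseline)[:, None]
            + np.outer(beta, is_pop1)
            + np.outer(beta_m, is_pop1 * is_male)
            + np.outer(beta_f, is_pop1 * (1.0 - is_male))
            + np.outer(age_coef, age_z)
            + np.outer(sex_coef, is_male)
        )
        if module_latents is not None:
            member = module_of > 0
            log2_mu[member, :] += (
                module_load[member, None]
                * module_latents[:, module_of[member] - 1].T
            )
        sample_ids = [f"{p}_{layer}" for p in pair_ids]
        lib = np.array([libsize[s] for s in sample_ids])
        mu = lib[None, :] * 2.0**log2_mu
        r = 1.0 / dispersion
        y = rng.negative_binomial(r[:, None], r[:, None] / (r[:, None] + mu))
        counts[layer] = pd.DataFrame(y, index=genes, columns=sample_ids)
    return counts


# ---------------------------------------------------------------------------
# full cohort


def simulate_cohort(config: SimConfig | None = None) -> Cohort:
    """Generate the full synthetic cohort (all tables plus ground truth)."""
    config = config or SimConfig()
    seed = config.seed

    pair_table = _build_pairs(config)
    rng_meta = stage_rng(seed, "metadata")
    pair_table["maternal_age"] = np.round(rng_meta.normal(28.0, 4.0, len(pair_table)), 1)

    # genotypes
    rng_gt = stage_rng(seed, "genotypes")
    variant_ids = _variant_ids(config.n_snps, rng_gt)
    freqs = pd.Series(rng_gt.uniform(0.05, 0.95, config.n_snps), index=variant_ids)
    gm = rng_gt.binomial(2, freqs.to_numpy()[:, None], size=(config.n_snps, config.n_pairs))
    mother_gt = pd.DataFrame(
        gm.astype(np.int8), index=variant_ids, columns=pair_table["pair_id"].tolist()
    )
    fetus_seed = int(stage_rng(seed, "fetus").integers(2**31 - 1))
    fetus_gt = simulate_fetus_genotypes(mother_gt, freqs, fetus_seed)

    # gene-level ground truth
    genes = np.array([f"G{i:06d}" for i in range(1, config.n_genes + 1)])
    rng_truth = stage_rng(seed, "truth")
    module_assignment, module_members, deg, age_genes, sex_genes = _allocate_truth(
        config, genes, rng_truth
    )

    # metadata: one sample per pair x layer
    meta_rows = []
    for _, pair in pair_table.iterrows():
        for layer in config.layers:
            meta_rows.append(
                {
                    "sample_id": f"{pair.pair_id}_{layer}",
                    "pair_id": pair.pair_id,
                    "population": pair.population,
                    "infant_sex": pair.infant_sex,
                    "layer": layer,
                    "maternal_age": pair.maternal_age,
                }
            )
    metadata = pd.DataFrame(meta_rows)

    # module latents and traits (per pair, shared across layers)
    rng_mod = stage_rng(seed, "modules")
    latents = rng_mod.standard_normal((config.n_pairs, config.n_modules))
    in_pop1 = (pair_table["population"] == config.population_names[0]).to_numpy()
    for mod, shift in config.module_pop_shift.items():
        latents[in_pop1, mod - 1] += shift
    traits = simulate_traits(
        latents, config.trait_loadings, config.trait_noise_sd, stage_rng(seed, "traits")
    )
    traits.index = pair_table["pair_id"].tolist()
    metadata = metadata.merge(
        traits.reset_index().rename(columns={"index": "pair_id"}), on="pair_id"
    )

    # selection-nominated panel: a handful of male-stratum effect genes plus
    # random non-effect genes from the universe
    rng_panel = stage_rng(seed, "panel")
    male_degs = sorted({g for layer in deg["male"].values() for g in layer})
    n_hit = min(config.panel_n_from_male_degs, len(male_degs), config.panel_size)
    panel = list(rng_panel.choice(male_degs, n_hit, replace=False))
    non_deg = np.array(sorted(set(genes) - set(male_degs) - set(panel)))
    panel += list(rng_panel.choice(non_deg, config.panel_size - n_hit, replace=False))
    panel = sorted(panel)

    truth = SimTruth(
        fetal_fraction={
            row.sample_id: config.layer_fetal_fraction[row.layer]
            for row in metadata.itertuples()
        },
        deg=deg,
        module_assignment=module_assignment,
        trait_loadings={int(k): dict(v) for k, v in config.trait_loadings.items()},
        age_genes=age_genes,
        sex_genes=sex_genes,
        panel=panel,
    )

    # allele-specific reads
    rng_reads = stage_rng(seed, "allelic_counts")
    chunks = []
    for row in metadata.itertuples():
        tab = simulate_allelic_counts(
            mother_gt[row.pair_id],
            fetus_gt[row.pair_id],
            truth.fetal_fraction[row.sample_id],
            config.read_depth,
            config.seq_error,
            rng_reads,
        )
        tab.insert(0, "sample_id", row.sample_id)
        chunks.append(tab)
    allelic_counts = pd.concat(chunks, ignore_index=True)

    counts_seed = int(stage_rng(seed, "counts").integers(2**31 - 1))
    counts = simulate_counts(config, metadata, truth, counts_seed, module_latents=latents)

    return Cohort(
        config=config,
        metadata=metadata,
        pair_table=pair_table,
        allele_freqs=freqs,
        mother_gt=mother_gt,
        fetus_gt=fetus_gt,
        allelic_counts=allelic_counts,
        counts=counts,
        traits=traits,
        truth=truth,
    )


# ---------------------------------------------------------------------------
# writers


def _write_vcf(path: Path, gt: pd.DataFrame) -> None:
    """Minimal GT-only VCF. Variant ids are CHROM:POS:REF:ALT."""
    code = {-1: "./.", 0: "0/0", 1: "0/1", 2: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for c in range(1, 23):
            fh.write(f"##contig=<ID=chr{c}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(gt.columns) + "\n")
        for vid, row in zip(gt.index, gt.to_numpy()):
            chrom, pos, ref, alt = vid.split(":")
            calls = "\t".join(code[int(v)] for v in row)
            fh.write(f"{chrom}\t{pos}\t{vid}\t{ref}\t{alt}\t.\tPASS\t.\tGT\t{calls}\n")


def write_cohort(cohort: Cohort, outdir: str | Path) -> dict:
    """Write all cohort artifacts; returns the path map."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "mothers_vcf": outdir / "mothers.vcf",
        "fetuses_vcf": outdir / "fetuses.vcf",
        "allelic_counts": outdir / "allelic_counts.tsv",
        "metadata": outdir / "metadata.tsv",
        "truth": outdir / "truth.json",
        "panel": outdir / "panel.txt",
    }
    _write_vcf(paths["mothers_vcf"], cohort.mother_gt)
    _write_vcf(paths["fetuses_vcf"], cohort.fetus_gt)
    cohort.allelic_counts.to_csv(paths["allelic_counts"], sep="\t", index=False)
    cohort.metadata.to_csv(paths["metadata"], sep="\t", index=False)
    paths["truth"].write_text(cohort.truth.to_json())
    paths["panel"].write_text("\n".join(cohort.truth.panel) + "\n")
    for layer, mat in cohort.counts.items():
        p = outdir / f"counts_{layer}.tsv"
        mat.to_csv(p, sep="\t", index_label="gene_id")
        paths[f"counts_{layer}"] = p
    return paths
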