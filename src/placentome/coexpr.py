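"""Weighted gene co-expression modules and module-trait association.

The network is built WGCNA-style: unsigned adjacency ``|cor|^beta`` with the
soft power chosen by scale-free topology fit, topological overlap (TOM) as
the similarity, average-linkage hierarchical clustering on 1-TOM with a
static height cut, and module summaries by eigengene (first principal
component). Module eigengenes are correlated with population membership and
newborn traits; a module is a significantly differential module (SDM) when
it associates with the population (p < 0.05) and with at least one trait
below the configured threshold — either nominal 0.05 or the Bonferroni
threshold 0.05/Meff, with Meff the effective number of independent traits
from the trait correlation spectrum. Hub genes satisfy three criteria:
gene-module correlation (kME) > 0.2, best gene-trait correlation > 0.8, and
intra-module connectivity ranked in the top 3.

All expression matrices here are samples x genes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .de import size_factors
from .enrich import hypergeom_overlap_p

__all__ = [
    "ModuleSet",
    "vst_like_transform",
    "pick_soft_power",
    "detect_modules",
    "module_eigengene",
    "module_trait_association",
    "effective_trait_number",
    "flag_sdm_and_key",
    "hub_genes",
]


@dataclass
class ModuleSet:
    """Module detection output for one layer x stratum network."""

    layer: str
    stratum: str
    soft_power: int
    assignments: pd.Series  # gene -> module id, 0 = unassigned
    eigengenes: pd.DataFrame  # samples x modules (columns are module ids)
    tom: pd.DataFrame  # gene x gene topological overlap

    def members(self, module: int) -> list:
        return list(self.assignments.index[self.assignments == module])

    @property
    def module_ids(self) -> list:
        return [m for m in sorted(self.assignments.unique()) if m != 0]


def vst_like_transform(counts: pd.DataFrame, sf: pd.Series | None = None) -> pd.DataFrame:
    """Variance-stabilizing log transform: log2(count / size_factor + 1).

    Input is genes x samples (as written by the count simulator); output is
    samples x genes, ready for network construction. Scaling a sample's
    counts by its own size factor leaves the transformed values unchanged.
    """
    s = (sf if sf is not None else size_factors(counts)).to_numpy(float)
    return pd.DataFrame(
        np.log2(counts.to_numpy(float) / s[None, :] + 1.0).T,
        index=counts.columns,
        columns=counts.index,
    )


def _drop_constant(expr: pd.DataFrame) -> pd.DataFrame:
    sd = expr.std(axis=0, ddof=0)
    kept = expr.loc[:, sd > 0]
    if kept.shape[1] == 0:
        raise ValueError("all genes are constant; no network can be built")
    return kept


def _scale_free_r2(k: np.ndarray, n_bins: int = 10, min_count: int = 5) -> float:
    """Signed R^2 of the log10 p(k) ~ log10 k regression over degree bins.

    Bins holding fewer than ``min_count`` genes are dropped (singleton tail
    bins fake a power law for any right-skewed degree distribution), and
    positive slopes flip the sign so the opposite of scale-free decay never
    scores well.
    """
    k = k[k > 0]
    if k.size < 3 or np.allclose(k.min(), k.max()):
        return -1.0
    edges = np.linspace(k.min(), k.max() * (1 + 1e-9), n_bins + 1)
    which = np.digitize(k, edges) - 1
    xs, ys = [], []
    for b in range(n_bins):
        mask = which == b
        if mask.sum() < min_count:
            continue
        xs.append(np.log10(k[mask].mean()))
        ys.append(np.log10(mask.sum() / k.size))
    if len(xs) < 3:
        return -1.0
    slope, _, r, _, _ = stats.linregress(xs, ys)
    return float(r**2 if slope < 0 else -(r**2))


def pick_soft_power(
    expr: pd.DataFrame,
    candidate_powers: range = range(1, 21),
    r2_target: float = 0.8,
    n_bins: int = 10,
    min_mean_k: float = 1.0,
) -> int:
    """Smallest power whose scale-free topology fit reaches ``r2_target``.

    A power is only selectable while mean connectivity stays at or above
    ``min_mean_k``: any correlation matrix looks heavy-tailed once the
    network is raised to a power that disconnects it, so without the floor
    structureless data would pass the fit criterion spuriously. When no
    eligible power reaches the target, the best-fitting power is returned
    with a warning (the fallback regime for data without scale-free
    structure).
    """
    expr = _drop_constant(expr)
    if expr.shape[0] < 20:
        warnings.warn("fewer than 20 samples; soft-power fit is unstable", stacklevel=2)
    c = np.abs(np.corrcoef(expr.to_numpy(float), rowvar=False))
    np.fill_diagonal(c, 0.0)
    fits = {}
    for power in candidate_powers:
        k = (c**power).sum(axis=0)
        fits[power] = _scale_free_r2(k, n_bins=n_bins)
        if fits[power] >= r2_target and k.mean() >= min_mean_k:
            return int(power)
    best = max(fits, key=fits.get)
    warnings.warn(
        f"no power reached scale-free R^2 {r2_target} at mean connectivity >= "
        f"{min_mean_k}; using power {best} (R^2 = {fits[best]:.3f})",
        stacklevel=2,
    )
    return int(best)


def _tom_matrix(adj: np.ndarray) -> np.ndarray:
    """Topological overlap from an adjacency with zeroed diagonal."""
    shared = adj @ adj
    k = adj.sum(axis=1)
    denom = np.minimum.outer(k, k) + 1.0 - adj
    tom = (shared + adj) / denom
    np.fill_diagonal(tom, 1.0)
    return tom


def detect_modules(
    expr: pd.DataFrame,
    power: int,
    min_size: int = 30,
    cut_height: float = 0.99,
    layer: str = "",
    stratum: str = "",
) -> ModuleSet:
    """Detect co-expression modules by average-linkage clustering on 1-TOM.

    The dendrogram is cut at the fixed dissimilarity ``cut_height`` (a static
    cut; structureless genes merge above it and stay unassigned) and clusters
    below ``min_size`` are sent to module 0. Modules are renumbered 1..k by
    decreasing size.
    """
    if power < 1:
        raise ValueError("power must be >= 1")
    expr = _drop_constant(expr)
    genes = expr.columns
    if len(genes) < min_size:
        warnings.warn("fewer genes than min_size; all genes unassigned", stacklevel=2)
        assignments = pd.Series(0, index=genes)
        return ModuleSet(layer, stratum, power, assignments, pd.DataFrame(index=expr.index), pd.DataFrame(np.eye(len(genes)), index=genes, columns=genes))

    adj = np.abs(np.corrcoef(expr.to_numpy(float), rowvar=False)) ** power
    np.fill_diagonal(adj, 0.0)
    tom = _tom_matrix(adj)
    dist = 1.0 - tom
    np.fill_diagonal(dist, 0.0)
    dist = (dist + dist.T) / 2.0  # exact symmetry for squareform
    Z = linkage(squareform(np.clip(dist, 0.0, None), checks=False), method="average")
    raw = fcluster(Z, t=cut_height, criterion="distance")

    sizes = pd.Series(raw).value_counts()
    big = sizes[sizes >= min_size].index
    order = sorted(big, key=lambda c: (-sizes[c], c))
    relabel = {c: i + 1 for i, c in enumerate(order)}
    assignments = pd.Series([relabel.get(c, 0) for c in raw], index=genes)

    eig = {}
    for mod in sorted(relabel.values()):
        members = assignments.index[assignments == mod]
        eig[mod] = module_eigengene(expr[members])
    eigengenes = pd.DataFrame(eig, index=expr.index)
    return ModuleSet(
        layer=layer,
        stratum=stratum,
        soft_power=int(power),
        assignments=assignments,
        eigengenes=eigengenes,
        tom=pd.DataFrame(tom, index=genes, columns=genes),
    )


def module_eigengene(expr_members: pd.DataFrame) -> pd.Series:
    """First principal component of the standardized member submatrix.

    Unit variance, sign-oriented so the mean correlation with the member
    genes is nonnegative (so flipping the input's sign changes nothing).
    """
    if expr_members.shape[1] < 2:
        raise ValueError("eigengene requires at least 2 member genes")
    x = expr_members.to_numpy(float)
    mu = x.mean(axis=0)
    sd = x.std(axis=0, ddof=0)
    sd[sd == 0] = 1.0
    z = (x - mu) / sd
    u, s, _ = np.linalg.svd(z, full_matrices=False)
    pc = u[:, 0]
    pc = (pc - pc.mean()) / pc.std(ddof=0)
    with np.errstate(invalid="ignore"):
        mean_cor = np.nanmean([np.corrcoef(pc, z[:, j])[0, 1] for j in range(z.shape[1])])
    if mean_cor < 0:
        pc = -pc
    return pd.Series(pc, index=expr_members.index)


def _pearson_with_p(x: np.ndarray, y: np.ndarray, min_n: int = 4) -> tuple[float, float, int]:
    """Pairwise-complete Pearson r with the t-based two-sided p-value."""
    mask = np.isfinite(x) & np.isfinite(y)
    n = int(mask.sum())
    if n < min_n:
        return float("nan"), float("nan"), n
    xv, yv = x[mask], y[mask]
    if xv.std() == 0 or yv.std() == 0:
        return float("nan"), float("nan"), n
    r = float(np.corrcoef(xv, yv)[0, 1])
    r = max(min(r, 1.0), -1.0)
    if abs(r) == 1.0:
        return r, 0.0, n
    t = r * np.sqrt((n - 2) / (1.0 - r**2))
    p = float(2.0 * stats.t.sf(abs(t), n - 2))
    return r, p, n


def module_trait_association(
    eigengenes: pd.DataFrame,
    traits: pd.DataFrame,
    population_labels: pd.Series,
    min_n: int = 4,
) -> pd.DataFrame:
    """Correlate every module eigengene with population and each trait.

    Population membership is coded 0/1 (point-biserial). Traits with zero
    variance over the complete pairs give NA with a warning. Returns one row
    per module with r/p per trait, the population association, and the
    minimum trait p with its trait name.
    """
    pop = pd.Categorical(population_labels.loc[eigengenes.index])
    if len(pop.categories) != 2:
        raise ValueError("population must have exactly two levels")
    pop01 = (pop.codes == 0).astype(float)
    rows = []
    for mod in eigengenes.columns:
        e = eigengenes[mod].to_numpy(float)
        r_pop, p_pop, _ = _pearson_with_p(e, pop01, min_n)
        row = {"module": mod, "r_pop": r_pop, "p_pop": p_pop}
        best_p, best_trait = float("inf"), None
        for trait in traits.columns:
            tv = traits.loc[eigengenes.index, trait].to_numpy(float)
            r, p, n = _pearson_with_p(e, tv, min_n)
            if np.isnan(r):
                warnings.warn(f"trait {trait}: undefined correlation (n={n})", stacklevel=2)
            row[f"r_{trait}"] = r
            row[f"p_{trait}"] = p
            if np.isfinite(p) and p < best_p:
                best_p, best_trait = p, trait
        row["min_trait_p"] = best_p if best_trait else float("nan")
        row["best_trait"] = best_trait
        rows.append(row)
    return pd.DataFrame(rows).set_index("module")


def effective_trait_number(trait_corr: pd.DataFrame | np.ndarray) -> tuple[float, float]:
    """Effective number of independent traits and the Bonferroni threshold.

    Uses the eigenvalue-based estimator
    ``Meff = sum_i I(lambda_i >= 1) + (lambda_i - floor(lambda_i))`` on the
    trait correlation spectrum, then ``trait_alpha = 0.05 / round(Meff)``
    (half-up). An identity correlation gives Meff = n_traits; a rank-one
    all-ones matrix gives Meff = 1.
    """
    c = np.asarray(trait_corr, dtype=float)
    if c.ndim != 2 or c.shape[0] != c.shape[1]:
        raise ValueError("correlation matrix must be square")
    if not np.allclose(c, c.T, atol=1e-10):
        raise ValueError("correlation matrix must be symmetric")
    if not np.allclose(np.diag(c), 1.0, atol=1e-8):
        raise ValueError("correlation matrix must have unit diagonal")
    lam = np.linalg.eigvalsh(c)
    if lam.min() < -1e-8:
        raise ValueError("correlation matrix is not positive semidefinite")
    lam = np.clip(lam, 0.0, None)
    # round before flooring: an eigenvalue of exactly k computed as k - eps
    # would otherwise contribute ~1 extra through the fractional part
    lam = np.round(lam, 10)
    meff = float(np.sum((lam >= 1.0).astype(float) + (lam - np.floor(lam))))
    meff_int = max(int(np.floor(meff + 0.5)), 1)
    return meff, 0.05 / meff_int


def flag_sdm_and_key(
    stats_table: pd.DataFrame,
    module_set: ModuleSet,
    deg_genes: set,
    universe_size: int,
    meff: float,
    pop_alpha: float = 0.05,
    trait_threshold: str = "meff",
) -> pd.DataFrame:
    """Flag significantly differential modules (SDMs) and the key module.

    SDM: population association p < ``pop_alpha`` and at least one trait
    below the threshold — both the nominal 0.05 rule and the 0.05/Meff rule
    are reported; ``trait_threshold`` picks which one drives ``is_sdm``. Each
    module's overlap with the DEG set is scored by the hypergeometric upper
    tail; the key module is the SDM minimizing (trait p, overlap p)
    lexicographically.
    """
    if trait_threshold not in ("0.05", "meff"):
        raise ValueError("trait_threshold must be '0.05' or 'meff'")
    meff_int = max(int(np.floor(meff + 0.5)), 1)
    alpha_meff = 0.05 / meff_int

    out = stats_table.copy()
    out["meff"] = meff
    out["trait_alpha"] = alpha_meff if trait_threshold == "meff" else 0.05
    overlaps, overlap_ps, sizes = [], [], []
    for mod in out.index:
        members = set(module_set.members(mod))
        k = len(members & deg_genes)
        sizes.append(len(members))
        overlaps.append(k)
        if not deg_genes:
            overlap_ps.append(1.0)
        else:
            overlap_ps.append(
                hypergeom_overlap_p(universe_size, len(deg_genes), len(members), k)
            )
    out["size"] = sizes
    out["deg_overlap"] = overlaps
    out["overlap_p"] = overlap_ps
    out["is_sdm_05"] = (out["p_pop"] < pop_alpha) & (out["min_trait_p"] < 0.05)
    out["is_sdm_meff"] = (out["p_pop"] < pop_alpha) & (out["min_trait_p"] < alpha_meff)
    out["is_sdm"] = out["is_sdm_meff"] if trait_threshold == "meff" else out["is_sdm_05"]
    out["is_key"] = False
    sdms = out[out["is_sdm"]]
    if len(sdms):
        key = sdms.sort_values(["min_trait_p", "overlap_p"]).index[0]
        out.loc[key, "is_key"] = True
    return out


def hub_genes(
    module_set: ModuleSet,
    expr: pd.DataFrame,
    traits: pd.DataFrame,
    kme_min: float = 0.2,
    trait_r_min: float = 0.8,
    top_degree: int = 3,
) -> pd.DataFrame:
    """Hub genes per module under the three-criteria rule.

    Intra-module connectivity is the row sum of the module's TOM submatrix
    (self excluded); genes tied with the ``top_degree``-th value are all
    eligible and flagged. kME is the gene-eigengene correlation; the trait
    criterion uses the best absolute gene-trait correlation.
    """
    rows = []
    traits_aligned = traits.loc[expr.index]
    for mod in module_set.module_ids:
        members = module_set.members(mod)
        if len(members) < 2:
            continue
        tom_sub = module_set.tom.loc[members, members].to_numpy(float)
        degree = tom_sub.sum(axis=1) - np.diag(tom_sub)
        uniq = np.sort(np.unique(degree))[::-1]
        cutoff = uniq[min(top_degree, len(uniq)) - 1]
        eigen = module_set.eigengenes[mod].to_numpy(float)
        for gi, gene in enumerate(members):
            if degree[gi] < cutoff:
                continue
            x = expr[gene].to_numpy(float)
            kme, _, _ = _pearson_with_p(x, eigen)
            best_r, best_trait = 0.0, None
            for trait in traits_aligned.columns:
                r, _, _ = _pearson_with_p(x, traits_aligned[trait].to_numpy(float))
                if np.isfinite(r) and abs(r) > abs(best_r):
                    best_r, best_trait = r, trait
            rank = int((degree > degree[gi]).sum()) + 1
            tied = bool((degree == degree[gi]).sum() > 1)
            if kme > kme_min and abs(best_r) > trait_r_min:
                rows.append(
                    {
                        "module": mod,
                        "gene_id": gene,
                        "kme": kme,
                        "best_trait": best_trait,
                        "best_trait_r": best_r,
                        "degree": float(degree[gi]),
                        "degree_rank": rank,
                        "tied_at_cutoff": tied,
                    }
                )
    return pd.DataFrame(
        rows,
        columns=[
            "module",
            "gene_id",
            "kme",
            "best_trait",
            "best_trait_r",
            "degree",
            "degree_rank",
            "tied_at_cutoff",
        ],
    )
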