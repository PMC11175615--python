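"""Negative-binomial differential expression between populations.

Per placental layer and sex stratum, gene counts are modelled as
NB(mean = s_j * q_gj, dispersion alpha_g) with log link,

    log q_gj = beta0 + beta_pop * x_j + covariates,

where s_j are median-of-ratios size factors and x_j indicates the first
population level. Dispersions are gene-wise moment estimates (Pearson
moment matching started from the plain residual-moment value; a small
floor, no shrinkage across genes); coefficients are fitted by iteratively
reweighted least squares vectorized across genes, and the population
coefficient is tested with a Wald statistic referred to a t distribution
on residual degrees of freedom. Benjamini-Hochberg
adjustment is applied per layer x stratum, and genes below a mean normalized
count filter are excluded from testing (NA p, not counted in the correction).

Sign convention: log2FC > 0 means higher expression in the first population
level (the reference cohort lists the highland natives first).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
import numpy as np
import pandas as pd
from scipy import stats

from ._utils import bh_adjust, percent

__all__ = [
    "DEGSetCollection",
    "size_factors",
    "nb_glm_wald",
    "run_de",
    "deg_sets_from_results",
    "classify_layer_sharing",
    "direction_discordance",
]

_LN2 = np.log(2.0)


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors against the geometric-mean pseudo-sample.

    Falls back to total-count scaling (normalized to geometric mean 1) with a
    warning when no gene is expressed in every sample.
    """
    y = counts.to_numpy(float)
    if (y < 0).any():
        raise ValueError("counts must be nonnegative")
    all_pos = (y > 0).all(axis=1)
    if not all_pos.any():
        warnings.warn(
            "no gene expressed in all samples; falling back to total-count scaling",
            stacklevel=2,
        )
        totals = y.sum(axis=0)
        if (totals <= 0).any():
            raise ValueError("sample with zero total counts")
        sf = totals / np.exp(np.mean(np.log(totals)))
    else:
        ref = np.exp(np.mean(np.log(y[all_pos]), axis=1))
        sf = np.median(y[all_pos] / ref[:, None], axis=0)
    return pd.Series(sf, index=counts.columns, name="size_factor")


def _design_matrix(
    metadata: pd.DataFrame, covariates: list, population_levels: tuple
) -> tuple[np.ndarray, list]:
    """Intercept + population indicator + encoded covariates.

    Numeric covariates are z-scored (maternal age in particular, for
    numerical stability); two-level categoricals are coded 0/1.
    """
    n = len(metadata)
    cols = [np.ones(n), (metadata["population"] == population_levels[0]).to_numpy(float)]
    names = ["intercept", "population"]
    for cov in covariates:
        v = metadata[cov]
        if pd.api.types.is_numeric_dtype(v):
            x = v.to_numpy(float)
            sd = x.std()
            cols.append((x - x.mean()) / sd if sd > 0 else np.zeros(n))
        else:
            levels = sorted(v.unique())
            if len(levels) != 2:
                raise ValueError(f"covariate {cov!r} must be numeric or two-level")
            cols.append((v == levels[1]).to_numpy(float))
        names.append(cov)
    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("singular design matrix")
    return X, names


def _irls(
    y: np.ndarray, X: np.ndarray, offset: np.ndarray, alpha: np.ndarray, n_iter: int = 60
) -> tuple[np.ndarray, np.ndarray]:
    """Batched IRLS for NB (or Poisson when alpha=0) GLM with log link.

    Returns (beta [G x p], covariance [G x p x p]).
    """
    G, n = y.shape
    p = X.shape[1]
    mu = y + 0.5
    eta = np.log(mu)
    beta = np.zeros((G, p))
    a = np.broadcast_to(np.asarray(alpha, float).reshape(-1, 1), (G, 1))
    for _ in range(n_iter):
        W = mu / (1.0 + a * mu)
        z = (eta - offset[None, :]) + (y - mu) / mu
        XtWX = np.einsum("np,gn,nq->gpq", X, W, X, optimize=True)
        XtWz = np.einsum("np,gn,gn->gp", X, W, z, optimize=True)
        XtWX.reshape(G, p * p)[:, :: p + 1] += 1e-10  # ridge for degenerate genes
        new_beta = np.linalg.solve(XtWX, XtWz[..., None])[..., 0]
        delta = np.nanmax(np.abs(new_beta - beta))
        beta = new_beta
        eta = np.clip(beta @ X.T + offset[None, :], -30.0, 30.0)
        mu = np.exp(eta)
        if delta < 1e-8:
            break
    W = mu / (1.0 + a * mu)
    XtWX = np.einsum("np,gn,nq->gpq", X, W, X, optimize=True)
    XtWX.reshape(G, p * p)[:, :: p + 1] += 1e-10
    cov = np.linalg.inv(XtWX)
    return beta, cov


def _mom_dispersion(y: np.ndarray, mu: np.ndarray, p: int, floor: float = 1e-8) -> np.ndarray:
    """Residual method-of-moments NB dispersion with a small-sample df
    correction: alpha = sum((r^2 - mu)/mu^2) / (n - p), floored."""
    n = y.shape[1]
    with np.errstate(divide="ignore", invalid="ignore"):
        contrib = ((y - mu) ** 2 - mu) / mu**2
    alpha = np.nansum(contrib, axis=1) / max(n - p, 1)
    return np.maximum(alpha, floor)


def _pearson_dispersion(
    y: np.ndarray, mu: np.ndarray, p: int, floor: float = 1e-8, n_iter: int = 20
) -> np.ndarray:
    """Gene-wise NB dispersion by Pearson moment matching.

    Solves, per gene, sum (y - mu)^2 / (mu + alpha mu^2) = n - p by Newton
    iteration from the plain moment estimate. Weighting residuals by the NB
    variance (rather than mu^2 alone) makes the estimate markedly less noisy
    for high-count genes, which keeps the Wald tail calibrated.
    """
    n = y.shape[1]
    df = max(n - p, 1)
    r2 = (y - mu) ** 2
    a = _mom_dispersion(y, mu, p, floor=floor)
    for _ in range(n_iter):
        V = mu + a[:, None] * mu**2
        f = (r2 / V).sum(axis=1) - df
        fprime = -(r2 * mu**2 / V**2).sum(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            step = f / fprime
        a = np.maximum(a - np.where(np.isfinite(step), step, 0.0), floor)
    return a


def nb_glm_wald(
    counts: pd.DataFrame,
    metadata: pd.DataFrame,
    covariates: list | None = None,
    alpha: float = 0.05,
    min_mean: float = 1.0,
    population_levels: tuple | None = None,
    sf: pd.Series | None = None,
) -> pd.DataFrame:
    """Per-gene NB Wald test of the population effect.

    ``metadata`` rows must match ``counts`` columns (sample_id keyed).
    Returns a frame with base_mean, log2FC, lfc_se, wald_stat, p, p_adj and
    is_deg; filtered or failed genes carry NA p and are excluded from the BH
    correction.
    """
    covariates = list(covariates or [])
    meta = metadata.set_index("sample_id").loc[counts.columns].reset_index()
    pops = population_levels or tuple(pd.unique(meta["population"]))
    if len(pops) != 2:
        raise ValueError("exactly two population levels required")
    for lvl in pops:
        if (meta["population"] == lvl).sum() < 2:
            raise ValueError(f"fewer than 2 samples in population {lvl!r}")
    if meta[covariates].isna().any().any():
        raise ValueError("covariates must be complete for the used samples")

    X, _ = _design_matrix(meta, covariates, pops)
    y = counts.to_numpy(float)
    s = (sf if sf is not None else size_factors(counts)).to_numpy(float)
    offset = np.log(s)
    base_mean = (y / s[None, :]).mean(axis=1)
    keep = base_mean >= min_mean

    G = y.shape[0]
    lfc = np.full(G, np.nan)
    se = np.full(G, np.nan)
    wald = np.full(G, np.nan)
    pval = np.full(G, np.nan)
    if keep.any():
        yk = y[keep]
        # Poisson fit for preliminary means, then MoM dispersion, then NB fit
        beta0, _ = _irls(yk, X, offset, np.zeros(keep.sum()), n_iter=30)
        mu0 = np.exp(np.clip(beta0 @ X.T + offset[None, :], -30.0, 30.0))
        disp = _pearson_dispersion(yk, mu0, X.shape[1])
        beta, cov = _irls(yk, X, offset, disp)
        b = beta[:, 1]
        v = cov[:, 1, 1]
        ok = np.isfinite(b) & np.isfinite(v) & (v > 0)
        z = np.where(ok, b / np.sqrt(np.where(v > 0, v, np.nan)), np.nan)
        idx = np.flatnonzero(keep)
        lfc[idx] = b / _LN2
        se[idx] = np.sqrt(v) / _LN2
        wald[idx] = z
        # t reference on residual df rather than normal: with a few dozen
        # samples and moment-estimated dispersions the normal tail is
        # anticonservative for the smallest p-values
        df = max(y.shape[1] - X.shape[1], 1)
        pval[idx] = np.where(ok, 2.0 * stats.t.sf(np.abs(z), df), np.nan)

    padj = bh_adjust(pval)
    res = pd.DataFrame(
        {
            "gene_id": counts.index,
            "base_mean": base_mean,
            "log2FC": lfc,
            "lfc_se": se,
            "wald_stat": wald,
            "p": pval,
            "p_adj": padj,
        }
    ).set_index("gene_id")
    res["is_deg"] = res["p_adj"] < alpha
    return res


def run_de(
    counts_by_layer: dict,
    metadata: pd.DataFrame,
    stratum: str = "combined",
    alpha: float = 0.05,
    min_mean: float = 1.0,
    population_levels: tuple | None = None,
) -> dict:
    """Population DE for every layer within one sex stratum.

    ``combined`` adjusts for fetal sex and maternal age; the sex-stratified
    runs subset to one infant sex and adjust for maternal age only.
    """
    if stratum == "combined":
        covariates, meta = ["infant_sex", "maternal_age"], metadata
    elif stratum in ("male", "female"):
        covariates = ["maternal_age"]
        meta = metadata[metadata["infant_sex"] == stratum]
    else:
        raise ValueError(f"unknown stratum {stratum!r}")
    out = {}
    for layer, counts in counts_by_layer.items():
        cols = [c for c in counts.columns if c in set(meta["sample_id"])]
        out[layer] = nb_glm_wald(
            counts[cols],
            meta,
            covariates=covariates,
            alpha=alpha,
            min_mean=min_mean,
            population_levels=population_levels,
        )
    return out


@dataclass
class DEGSetCollection:
    """Per-layer DEG sets (gene -> direction) for one stratum."""

    stratum: str
    sets: dict  # layer -> {gene_id: "up" | "down"}
    universe_size: int

    def __post_init__(self) -> None:
        for layer, genes in self.sets.items():
            for d in genes.values():
                if d not in ("up", "down"):
                    raise ValueError(f"bad direction {d!r} in layer {layer}")

    @property
    def n_distinct(self) -> int:
        return len({g for s in self.sets.values() for g in s})

    def universe_share_pct(self, ndigits: int = 1) -> float:
        """Distinct DEGs as a percentage of the expressed-gene universe."""
        return percent(self.n_distinct, self.universe_size, ndigits=ndigits)


def deg_sets_from_results(
    results_by_layer: dict, stratum: str, universe_size: int | None = None
) -> DEGSetCollection:
    sets = {}
    for layer, res in results_by_layer.items():
        deg = res[res["is_deg"].fillna(False)]
        sets[layer] = {
            g: ("up" if l > 0 else "down") for g, l in zip(deg.index, deg["log2FC"])
        }
    if universe_size is None:
        universe_size = int(next(iter(results_by_layer.values())).shape[0])
    return DEGSetCollection(stratum=stratum, sets=sets, universe_size=universe_size)


def classify_layer_sharing(collection: DEGSetCollection) -> tuple[pd.DataFrame, dict]:
    """Label each DEG by the number (and identity) of layers calling it.

    Returns (per-gene table, summary). The summary reports counts per k
    (k-layer-shared), per layer, per layer combination, and the one-layer
    share as a half-up two-decimal percentage of distinct DEGs. Both the
    distinct-gene total and the per-layer occurrence total are given, since
    layer-level tallies count a shared gene once per layer.
    """
    membership: dict = {}
    for layer, genes in collection.sets.items():
        for g in genes:
            membership.setdefault(g, []).append(layer)
    if not membership:
        return pd.DataFrame(columns=["gene_id", "k", "layers", "sharing_class"]), {
            "n_distinct": 0,
            "occurrence_total": 0,
            "per_k": {},
            "per_layer": {l: 0 for l in collection.sets},
            "per_combination": {},
            "one_layer_pct": float("nan"),
        }
    rows = []
    for g, layers in sorted(membership.items()):
        layers = sorted(layers)
        k = len(layers)
        label = "one-layer" if k == 1 else f"{k}-layer-shared"
        rows.append(
            {
                "gene_id": g,
                "k": k,
                "layers": ",".join(layers),
                "sharing_class": f"{label} ({','.join(layers)})",
            }
        )
    per_gene = pd.DataFrame(rows)
    per_k = per_gene["k"].value_counts().sort_index().to_dict()
    per_layer = {layer: len(genes) for layer, genes in collection.sets.items()}
    per_comb = per_gene[per_gene["k"] > 1]["layers"].value_counts().to_dict()
    n_distinct = len(per_gene)
    summary = {
        "n_distinct": n_distinct,
        "occurrence_total": int(sum(per_layer.values())),
        "per_k": {int(k): int(v) for k, v in per_k.items()},
        "per_layer": per_layer,
        "per_combination": per_comb,
        "one_layer_pct": percent(per_k.get(1, 0), n_distinct),
    }
    return per_gene, summary


def direction_discordance(
    male_results: pd.DataFrame, female_results: pd.DataFrame
) -> dict:
    """Fraction of male-stratum DEGs whose female log2FC has the opposite sign.

    Both frames are per-gene results for the same layer. A zero female effect
    counts as non-opposite; genes absent from the female results are excluded
    from the denominator and tallied.
    """
    male_degs = male_results[male_results["is_deg"].fillna(False)]
    joined = male_degs.join(
        female_results[["log2FC"]].rename(columns={"log2FC": "log2FC_female"}), how="left"
    )
    missing = joined["log2FC_female"].isna()
    used = joined[~missing]
    opposite = (used["log2FC"] * used["log2FC_female"]) < 0
    n = len(used)
    return {
        "n_male_degs": int(len(joined)),
        "n_used": n,
        "n_excluded": int(missing.sum()),
        "n_opposite": int(opposite.sum()),
        "discordance_pct": percent(int(opposite.sum()), n) if n else float("nan"),
    }
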