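"""Maternal/fetal origin estimation from allele-specific read counts.

A placental sample is a mixture of fetal and maternal RNA. At a
*fetal-specific* informative SNP — heterozygous in the fetus, homozygous in
the mother — reads carrying the allele the mother does not have must come
from the fetal genome; a het fetus contributes that specific allele at rate
1/2 per fetal read. Maternal-specific SNPs (mother het, fetus hom) mirror
the definition. Pooling reads over a random tag subset of each class gives
the allelic ratio R = B/(B+A), whose expectation is f/2 at fetal-specific
sites and (1-f)/2 at maternal-specific sites for fetal fraction f. The
estimator samples the tag subset five times, averages the replicate R
values, and converts the fetal-specific ratio to a fraction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "InformativeSNPSet",
    "OriginEstimate",
    "InsufficientSNPsError",
    "find_informative_snps",
    "allelic_ratio",
    "estimate_origin",
    "estimate_origins",
]


class InsufficientSNPsError(ValueError):
    """Raised when a sample lacks the minimum covered informative SNPs."""


@dataclass
class InformativeSNPSet:
    """Informative SNP classification for one mother-fetus pair.

    ``specific_allele`` records, per variant, which count column carries the
    pair-specific allele B ("alt" when the homozygous parent is reference
    homozygous, "ref" otherwise).
    """

    pair_id: str
    fetal_specific: list
    maternal_specific: list
    specific_allele: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if set(self.fetal_specific) & set(self.maternal_specific):
            raise ValueError("fetal- and maternal-specific lists must be disjoint")


@dataclass
class OriginEstimate:
    sample_id: str
    R_f: float
    R_m: float
    replicate_R_f: list
    replicate_R_m: list
    fetal_fraction: float
    n_snps_f: int  # covered fetal-specific SNPs available
    n_snps_m: int
    n_snps_per_replicate: int
    seed: int


def find_informative_snps(
    mother_gt: pd.Series, fetus_gt: pd.Series, pair_id: str = ""
) -> InformativeSNPSet:
    """Classify shared variants into fetal- and maternal-specific sets.

    Fetal-specific: fetus heterozygous while the mother is homozygous (either
    homozygote; the specific allele is whichever the mother lacks).
    Maternal-specific is the mirror image. Sites het in both or hom in both
    are uninformative and excluded; missing genotypes (-1/NaN) are skipped.
    """
    shared = mother_gt.index.intersection(fetus_gt.index)
    if shared.empty:
        raise ValueError("no shared variants between mother and fetus tables")
    gm = mother_gt.loc[shared].to_numpy(float)
    gf = fetus_gt.loc[shared].to_numpy(float)
    ok = np.isfinite(gm) & np.isfinite(gf) & (gm >= 0) & (gf >= 0)

    fetal = ok & (gf == 1) & ((gm == 0) | (gm == 2))
    maternal = ok & (gm == 1) & ((gf == 0) | (gf == 2))

    specific = {}
    ids = np.asarray(shared)
    for vid, m, f in zip(ids[fetal], gm[fetal], gf[fetal]):
        specific[vid] = "alt" if m == 0 else "ref"
    for vid, m, f in zip(ids[maternal], gm[maternal], gf[maternal]):
        specific[vid] = "alt" if f == 0 else "ref"
    return InformativeSNPSet(
        pair_id=pair_id,
        fetal_specific=list(ids[fetal]),
        maternal_specific=list(ids[maternal]),
        specific_allele=specific,
    )


def allelic_ratio(a_counts: np.ndarray, b_counts: np.ndarray) -> float:
    """Pooled allelic ratio R = sum(B) / (sum(A) + sum(B)) over a tag subset.

    B is the pair-specific allele count. Pooling (rather than averaging
    per-SNP ratios) keeps low-depth sites from dominating; the two agree
    exactly when depth is equal across sites. Zero total reads is undefined
    and raises rather than returning 0.
    """
    a = np.asarray(a_counts, dtype=float)
    b = np.asarray(b_counts, dtype=float)
    if a.size == 0:
        raise ValueError("allelic_ratio requires a nonempty SNP subset")
    total = a.sum() + b.sum()
    if total <= 0:
        raise ValueError("allelic_ratio undefined: zero total reads over subset")
    return float(b.sum() / total)


def _specific_counts(counts: pd.DataFrame, snpset: InformativeSNPSet) -> pd.DataFrame:
    """Orient counts so column 'b' is the specific allele at every variant."""
    tab = counts.set_index("variant_id")[["a_count", "b_count"]]
    orient_ref = pd.Series(snpset.specific_allele).reindex(tab.index) == "ref"
    b = np.where(orient_ref, tab["a_count"], tab["b_count"])
    a = np.where(orient_ref, tab["b_count"], tab["a_count"])
    return pd.DataFrame({"a": a, "b": b}, index=tab.index)


def estimate_origin(
    allelic_counts: pd.DataFrame,
    snpset: InformativeSNPSet,
    sample_id: str = "",
    n_reps: int = 5,
    min_snps: int = 5,
    tag_snps: int | None = None,
    min_depth: int = 10,
    seq_error: float = 0.0,
    method: str = "2rf",
    seed: int = 0,
) -> OriginEstimate:
    """Replicate-averaged allelic ratios and the derived fetal fraction.

    Each of ``n_reps`` replicates samples ``tag_snps`` (default ``min_snps``)
    covered SNPs without replacement from each informative class and pools
    their reads. ``R_f``/``R_m`` are the replicate means. The fraction is
    ``clip(2*(R_f - e) / (1 - 2e), 0, 1)`` (method ``"2rf"``; at e=0 simply
    2*R_f) or ``R_f / (R_f + R_m)`` (method ``"ratio"``).

    Raises :class:`InsufficientSNPsError` when either class has fewer than
    ``min_snps`` variants with depth >= ``min_depth``.
    """
    if method not in ("2rf", "ratio"):
        raise ValueError(f"unknown fraction method {method!r}")
    oriented = _specific_counts(allelic_counts, snpset)
    depth_ok = (oriented["a"] + oriented["b"]) >= min_depth

    covered = {
        "fetal": [v for v in snpset.fetal_specific if v in oriented.index and depth_ok.get(v, False)],
        "maternal": [
            v for v in snpset.maternal_specific if v in oriented.index and depth_ok.get(v, False)
        ],
    }
    k = tag_snps if tag_snps is not None else min_snps
    for cls, snps in covered.items():
        if len(snps) < min_snps:
            raise InsufficientSNPsError(
                f"sample {sample_id or '?'}: only {len(snps)} covered "
                f"{cls}-specific SNPs (need >= {min_snps})"
            )

    rng = np.random.default_rng(seed)
    reps_f, reps_m = [], []
    for _ in range(n_reps):
        sub_f = rng.choice(covered["fetal"], size=min(k, len(covered["fetal"])), replace=False)
        sub_m = rng.choice(
            covered["maternal"], size=min(k, len(covered["maternal"])), replace=False
        )
        reps_f.append(allelic_ratio(oriented.loc[sub_f, "a"], oriented.loc[sub_f, "b"]))
        reps_m.append(allelic_ratio(oriented.loc[sub_m, "a"], oriented.loc[sub_m, "b"]))
    r_f = float(np.mean(reps_f))
    r_m = float(np.mean(reps_m))

    if method == "2rf":
        e = seq_error
        frac = float(np.clip(2.0 * (r_f - e) / (1.0 - 2.0 * e), 0.0, 1.0))
    else:
        frac = float(r_f / (r_f + r_m)) if (r_f + r_m) > 0 else float("nan")
    return OriginEstimate(
        sample_id=sample_id,
        R_f=r_f,
        R_m=r_m,
        replicate_R_f=reps_f,
        replicate_R_m=reps_m,
        fetal_fraction=frac,
        n_snps_f=len(covered["fetal"]),
        n_snps_m=len(covered["maternal"]),
        n_snps_per_replicate=k,
        seed=seed,
    )


def estimate_origins(
    allelic_counts: pd.DataFrame,
    mother_gt: pd.DataFrame,
    fetus_gt: pd.DataFrame,
    metadata: pd.DataFrame,
    seed: int = 0,
    **kwargs,
) -> tuple[pd.DataFrame, list]:
    """Run :func:`estimate_origin` for every sample in the metadata.

    Returns (estimates table, list of per-sample failures). A sample without
    enough informative SNPs is recorded and skipped; the run continues.
    """
    snpsets = {
        pair: find_informative_snps(mother_gt[pair], fetus_gt[pair], pair_id=pair)
        for pair in metadata["pair_id"].unique()
    }
    by_sample = dict(tuple(allelic_counts.groupby("sample_id", sort=False)))
    rows, failures = [], []
    for i, row in enumerate(metadata.itertuples()):
        counts = by_sample.get(row.sample_id)
        if counts is None:
            failures.append((row.sample_id, "no allelic counts"))
            continue
        try:
            est = estimate_origin(
                counts,
                snpsets[row.pair_id],
                sample_id=row.sample_id,
                seed=seed + i,
                **kwargs,
            )
        except InsufficientSNPsError as err:
            failures.append((row.sample_id, str(err)))
            continue
        rows.append(
            {
                "sample_id": est.sample_id,
                "layer": row.layer,
                "R_f": est.R_f,
                "R_m": est.R_m,
                "fetal_fraction": est.fetal_fraction,
                "n_snps_f": est.n_snps_f,
                "n_snps_m": est.n_snps_m,
                "seed": est.seed,
            }
        )
    return pd.DataFrame(rows), failures
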