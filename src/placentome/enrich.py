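"""Permutation enrichment of a gene panel within DEG sets.

The question: is a fixed panel of selection-nominated genes over-represented
among the differentially expressed genes? The test draws the panel size at
random from the expressed-gene universe (without replacement), counts the
overlap with the DEG set, and repeats; the empirical p-value is the fraction
of replicates with overlap at least as large as observed. A zero count is
reported as the upper bound "< 1/n_perm". Because the null is exactly
hypergeometric sampling, the closed-form upper tail serves as an oracle.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
from scipy import stats

from ._utils import format_p_upper_bound

__all__ = [
    "EnrichmentResult",
    "empirical_p_from_count",
    "permutation_enrichment",
    "hypergeom_overlap_p",
]


def empirical_p_from_count(
    count: int, n_perm: int, plus_one: bool = False
) -> tuple[float, str, bool]:
    """Empirical p-value conventions: (value, printed label, is_upper_bound).

    Default convention is count/n_perm, reported as the upper bound
    "< 1/n_perm" when no permutation reaches the observed statistic (603 of
    10,000 gives 0.0603; 10,000 of 10,000 gives 1; 0 of 10,000 gives
    "<1e-4"). ``plus_one`` switches to (count+1)/(n_perm+1).
    """
    if not 0 <= count <= n_perm:
        raise ValueError("count must lie in [0, n_perm]")
    if plus_one:
        p = (count + 1) / (n_perm + 1)
        return p, f"{p:g}", False
    if count > 0:
        p = count / n_perm
        return p, f"{p:g}", False
    return 0.0, format_p_upper_bound(n_perm), True


@dataclass
class EnrichmentResult:
    deg_set_name: str
    universe_size: int
    panel_size: int
    deg_set_size: int
    observed_overlap: int
    n_perm: int
    n_ge_observed: int
    empirical_p: float  # count/n_perm (0.0 when no replicate reaches observed)
    empirical_p_label: str  # "0.0603" style, or "<1e-4" upper bound
    is_upper_bound: bool
    hypergeom_p: float
    seed: int

    def to_dict(self) -> dict:
        return asdict(self)


def hypergeom_overlap_p(N: int, K: int, n: int, k: int) -> float:
    """Exact upper-tail overlap probability P(X >= k), X ~ Hypergeom(N, K, n).

    N: universe size, K: panel size, n: DEG-set size, k: observed overlap.
    k = 0 gives 1; k beyond the support gives 0. Symmetric in (K, n).
    """
    if n > N or K > N:
        raise ValueError("set sizes cannot exceed the universe size")
    if min(N, K, n) < 0 or k < 0:
        raise ValueError("sizes must be nonnegative")
    if k == 0:
        return 1.0
    if k > min(K, n):
        return 0.0
    # survival function is computed in log space internally by scipy
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def permutation_enrichment(
    universe: list,
    deg_set: set,
    panel: list | None = None,
    panel_size: int | None = None,
    observed_overlap: int | None = None,
    n_perm: int = 10_000,
    seed: int = 0,
    name: str = "",
    plus_one: bool = False,
) -> EnrichmentResult:
    """Permutation over-representation test of a panel against a DEG set.

    Supply either ``panel`` (a gene list, must be a subset of the universe;
    the observed overlap is computed) or ``panel_size`` together with
    ``observed_overlap``. ``plus_one`` switches to the (count+1)/(n_perm+1)
    convention; the default is count/n_perm with a "< 1/n_perm" label when
    the count is zero.
    """
    universe = list(universe)
    uni_set = set(universe)
    if not deg_set <= uni_set:
        raise ValueError("DEG set must be a subset of the universe")
    if panel is not None:
        extra = set(panel) - uni_set
        if extra:
            raise ValueError(f"panel genes outside universe: {sorted(extra)[:5]} ...")
        panel_size = len(panel)
        observed_overlap = len(set(panel) & deg_set)
    if panel_size is None or observed_overlap is None:
        raise ValueError("need either a panel or (panel_size, observed_overlap)")
    if panel_size > len(universe):
        raise ValueError("panel_size cannot exceed the universe size")

    rng = np.random.default_rng(seed)
    in_deg = np.fromiter((g in deg_set for g in universe), dtype=bool, count=len(universe))
    n_univ = len(universe)
    count = 0
    for _ in range(n_perm):
        idx = rng.choice(n_univ, size=panel_size, replace=False)
        if int(in_deg[idx].sum()) >= observed_overlap:
            count += 1

    emp, label, upper = empirical_p_from_count(count, n_perm, plus_one=plus_one)
    return EnrichmentResult(
        deg_set_name=name,
        universe_size=n_univ,
        panel_size=panel_size,
        deg_set_size=len(deg_set),
        observed_overlap=observed_overlap,
        n_perm=n_perm,
        n_ge_observed=count,
        empirical_p=emp,
        empirical_p_label=label,
        is_upper_bound=upper,
        hypergeom_p=hypergeom_overlap_p(n_univ, panel_size, len(deg_set), observed_overlap),
        seed=seed,
    )
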