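"""Shared numeric helpers: seeding, rounding conventions, p-value formatting."""

from __future__ import annotations

import zlib
from decimal import Decimal, ROUND_HALF_UP

import numpy as np

#: Canonical placental layer order, fetal side to maternal side:
#: umbilical cord, amnion, chorion, chorionic plate, villus (fetal /
#: intermediate / maternal).
LAYERS = ("UC", "AN", "CN", "CP", "VF", "VI", "VM")

#: Newborn traits investigated for module-trait association: birth weight,
#: biparietal diameter, femur length, gestation time, placental weight,
#: placental volume, abdominal girth, amniotic fluid max depth, amniotic
#: fluid index, fetal heart, fundal height.
TRAITS = ("BW", "BPD", "FL", "GT", "PW", "PLV", "AG", "AFMD", "AFI", "FH", "FUH")


def stage_rng(seed: int, name: str) -> np.random.Generator:
    """Named, reproducible substream of the global seed.

    The stream key is a CRC32 of the stage name, so the mapping is stable
    across processes and Python versions (unlike ``hash``).
    """
    return np.random.default_rng(np.random.SeedSequence((int(seed), zlib.crc32(name.encode()))))


def percent(numerator: float, denominator: float, ndigits: int = 2) -> float:
    """Percentage with half-up rounding (so 399/579 -> 68.91, not 68.9).

    Banker's rounding (Python's built-in ``round``) would disagree with the
    reporting convention on exact .xx5 boundaries; Decimal half-up matches it.
    """
    if denominator == 0:
        raise ZeroDivisionError("percent undefined for zero denominator")
    frac = Decimal(str(numerator)) * 100 / Decimal(str(denominator))
    q = Decimal(1).scaleb(-ndigits)
    return float(frac.quantize(q, rounding=ROUND_HALF_UP))


def format_p_upper_bound(n_perm: int) -> str:
    """Upper-bound label for an empirical p with zero exceedances.

    Powers of ten render in scientific shorthand ("<1e-4" at 10,000
    permutations); other permutation counts fall back to a plain decimal.
    """
    recip = 1.0 / n_perm
    exp = int(np.round(np.log10(n_perm)))
    if 10**exp == n_perm:
        return f"<1e-{exp}"
    return f"<{recip:g}"


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment.

    NaNs pass through untouched and do not count toward the number of tests.
    Output is monotone in the sorted raw p-values and capped at 1.
    """
    p = np.asarray(p, dtype=float)
    out = np.full(p.shape, np.nan)
    mask = ~np.isnan(p)
    pv = p[mask]
    if ((pv < 0) | (pv > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = pv.size
    if m == 0:
        return out
    order = np.argsort(pv, kind="mergesort")
    ranked = pv[order] * m / np.arange(1, m + 1)
    # enforce step-up monotonicity from the largest p downwards
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    res = np.empty(m)
    res[order] = adj
    out[mask] = res
    return out
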