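"""Gene-set over-representation, rank-sum machinery and bench calculators.

The Wilcoxon rank-sum test is exact (full enumeration over splits of the
pooled sample, correct under ties) for small samples and a tie-corrected
normal approximation otherwise.  Over-representation is a one-sided Fisher
exact test on the 2x2 overlap table with BH adjustment across sets.  The
bench-side calculators implement the 2^-dCt relative-expression readout,
the percent-of-input MeDIP recovery model (amplification efficiency fixed
at 2.0), and the one-sample t-test.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import comb
from scipy.stats import rankdata

from .io_formats import GeneSetCollection, ValidationError
from .paired_ewas import adjust_bh

__all__ = [
    "EnrichmentResult",
    "QPCRMeasurement",
    "rank_sum_test",
    "fisher_enrichment",
    "ddct_expression",
    "medip_percent_input",
    "one_sample_t",
    "EXACT_ENUMERATION_LIMIT",
]

# largest number of pooled splits enumerated exactly; beyond this (or when
# the pooled sample exceeds 50 observations) the normal approximation with
# tie correction is used
EXACT_ENUMERATION_LIMIT = 200_000


@dataclass
class EnrichmentResult:
    set_name: str
    n_set: int
    n_hits: int
    n_query: int
    n_universe: int
    odds_ratio: float
    p: float
    q: float = float("nan")


@dataclass
class QPCRMeasurement:
    """Replicate Ct readings for one sample: target and housekeeping gene."""

    sample_id: str
    target_ct: Sequence[float]
    housekeeping_ct: Sequence[float]

    def __post_init__(self) -> None:
        for name, vals in (("target", self.target_ct), ("housekeeping", self.housekeeping_ct)):
            if len(vals) < 2:
                raise ValidationError(f"{name} needs >= 2 replicates")
            if any(not 0 < v < 45 for v in vals):
                raise ValidationError(f"{name} Ct outside (0, 45)")


def rank_sum_test(a: Sequence[float], b: Sequence[float]) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum test of samples *a* vs *b*.

    Returns (W, p) where W is the rank sum of *a* in the pooled sample.
    Exact by enumeration of all C(n_a + n_b, n_a) splits when the pooled
    sample is small (handles ties correctly); otherwise a tie-corrected
    normal approximation without continuity correction.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    na, nb = len(a), len(b)
    if na == 0 or nb == 0:
        raise ValidationError("rank-sum test needs non-empty samples")
    n = na + nb
    pooled = np.concatenate([a, b])
    ranks = rankdata(pooled)
    w = float(ranks[:na].sum())
    mu = na * (n + 1) / 2.0

    if n <= 50 and comb(n, na, exact=True) <= EXACT_ENUMERATION_LIMIT:
        dev = abs(w - mu)
        count = 0
        total = 0
        for idx in combinations(range(n), na):
            total += 1
            if abs(ranks[list(idx)].sum() - mu) >= dev - 1e-9:
                count += 1
        return w, count / total

    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = (tie_counts**3 - tie_counts).sum() / (n * (n - 1))
    var = na * nb / 12.0 * (n + 1 - tie_term)
    if var <= 0:
        return w, 1.0
    z = (w - mu) / math.sqrt(var)
    return w, float(2 * stats.norm.sf(abs(z)))


def fisher_enrichment(
    query_genes: Sequence[str],
    universe: Sequence[str],
    sets: GeneSetCollection,
) -> pd.DataFrame:
    """One-sided (greater) Fisher over-representation of each gene set.

    Sets are intersected with the universe; the query must be a subset of
    the universe.  Returns a frame sorted by p with BH q across sets.
    """
    universe_set = set(universe)
    query = set(query_genes)
    if not query:
        raise ValidationError("empty query gene list")
    stray = query - universe_set
    if stray:
        raise ValidationError(f"query gene {sorted(stray)[0]!r} not in universe")
    n_universe = len(universe_set)
    n_query = len(query)
    rows = []
    for name, members in sets:
        inset = set(members) & universe_set
        hits = len(query & inset)
        a = hits
        b = n_query - hits
        c = len(inset) - hits
        d = n_universe - n_query - len(inset) + hits
        odds, p = stats.fisher_exact([[a, b], [c, d]], alternative="greater")
        rows.append(
            EnrichmentResult(
                set_name=name,
                n_set=len(inset),
                n_hits=hits,
                n_query=n_query,
                n_universe=n_universe,
                odds_ratio=float(odds),
                p=float(p),
            )
        )
    out = pd.DataFrame([vars(r) for r in rows])
    out["q"] = adjust_bh(out["p"].to_numpy())
    return out.sort_values("p", kind="mergesort").reset_index(drop=True)


def ddct_expression(meas: QPCRMeasurement) -> dict:
    """Relative expression by the 2^-dCt method.

    dCt = mean target Ct - mean housekeeping Ct; expression = 2^-dCt.
    Replicate scatter is propagated on the Ct scale
    (sd_dCt = sqrt(sd_t^2/n_t + sd_h^2/n_h)) and reported both as Ct and as
    a multiplicative spread of the expression value.  Replicate SD above
    one cycle flags the measurement as unreliable (it is still computed).
    """
    t = np.asarray(meas.target_ct, float)
    h = np.asarray(meas.housekeeping_ct, float)
    delta_ct = float(t.mean() - h.mean())
    expression = 2.0 ** (-delta_ct)
    sd_t, sd_h = t.std(ddof=1), h.std(ddof=1)
    sd_dct = math.sqrt(sd_t**2 / len(t) + sd_h**2 / len(h))
    unreliable = bool(sd_t > 1 or sd_h > 1)
    if unreliable:
        warnings.warn(
            f"{meas.sample_id}: replicate SD exceeds 1 cycle; measurement unreliable",
            stacklevel=2,
        )
    return {
        "sample_id": meas.sample_id,
        "delta_ct": delta_ct,
        "expression": expression,
        "sd_delta_ct": sd_dct,
        "expression_sd_factor": 2.0**sd_dct,
        "unreliable": unreliable,
    }


def medip_percent_input(
    ct_ip: float, ct_input: float, input_fraction: float
) -> tuple[float, bool]:
    """Percent-of-input recovery for MeDIP-qPCR.

    The input Ct is first adjusted for its dilution
    (Ct* = ct_input - log2(input_fraction)); recovery is
    100 * 2^(Ct* - ct_ip) assuming doubling per cycle.  Returns
    (percent, flagged) where flagged marks recoveries above 100%
    (pipetting or calibration warning; the value is still returned).
    """
    if not 0 < input_fraction <= 1:
        raise ValidationError("input_fraction must lie in (0, 1]")
    ct_star = ct_input - math.log2(input_fraction)
    percent = 100.0 * 2.0 ** (ct_star - ct_ip)
    return percent, percent > 100.0


def one_sample_t(values: Sequence[float], mu0: float = 0.0) -> tuple[float, float]:
    """Two-sided one-sample t-test of the mean against mu0."""
    v = np.asarray(values, float)
    if len(v) < 2:
        raise ValidationError("one-sample t needs n >= 2")
    sd = v.std(ddof=1)
    if sd == 0:
        raise ValidationError("zero variance: t statistic undefined")
    t = (v.mean() - mu0) / (sd / math.sqrt(len(v)))
    p = float(2 * stats.t.sf(abs(t), len(v) - 1))
    return float(t), p
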