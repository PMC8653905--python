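"""Paired differential-methylation testing with empirical-Bayes moderation.

The paired design is reduced to a one-sample problem on within-pair
M-value differences (affected minus unaffected twin), which is
algebraically equivalent to a pair-blocked two-group linear model.  Probe
variances are shrunk toward a common prior estimated by moment matching on
the log sample variances — the moderated-t model of microarray linear
modelling — and unmodelled batch structure is captured by the leading
right-singular vectors of the centred difference matrix, with the number
of components chosen by parallel analysis against row-permuted data.

The reference epigenome-wide significance level (p < 3.6e-8) is exposed as
a constant for reporting; it is never used as a filter.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import special, stats

from .io_formats import BetaMatrix, ProbeManifest, TwinDesign, ValidationError

__all__ = [
    "GENOME_WIDE_SIGNIFICANCE",
    "MValueMatrix",
    "PairDiffMatrix",
    "EBayesPrior",
    "SurrogateSet",
    "beta_to_m",
    "m_to_beta",
    "pair_differences",
    "estimate_surrogates",
    "fit_moderated",
    "call_dmps",
    "adjust_bh",
]

GENOME_WIDE_SIGNIFICANCE = 3.6e-8


@dataclass
class MValueMatrix:
    """Probes x samples M values, M = log2(beta / (1 - beta)) after clipping."""

    m: pd.DataFrame
    epsilon: float


@dataclass
class PairDiffMatrix:
    """Probes x pairs within-pair M differences (affected minus unaffected)."""

    d: pd.DataFrame

    @property
    def n_pairs(self) -> int:
        return self.d.shape[1]


@dataclass
class EBayesPrior:
    """Hyper-parameters of the variance prior.

    ``d0`` is the prior degrees of freedom (``math.inf`` when the log
    sample variances show no excess spread over the chi-square expectation),
    ``s0_sq`` the prior variance, ``d`` the residual df per probe.
    """

    d0: float
    s0_sq: float
    d: int


@dataclass
class SurrogateSet:
    """Data-derived covariates capturing unmodelled batch structure."""

    q: int
    loadings: np.ndarray  # pairs x q, orthonormal columns


def beta_to_m(beta: BetaMatrix | pd.DataFrame, epsilon: float = 1e-3) -> MValueMatrix:
    """Logit (base-2) transform of beta, clipped to [epsilon, 1 - epsilon]."""
    if not 0 < epsilon < 0.5:
        raise ValidationError(f"epsilon must lie in (0, 0.5), got {epsilon}")
    df = beta.beta if isinstance(beta, BetaMatrix) else beta
    b = np.clip(df.to_numpy(float), epsilon, 1 - epsilon)
    m = np.log2(b / (1 - b))
    return MValueMatrix(pd.DataFrame(m, index=df.index, columns=df.columns), epsilon)


def m_to_beta(m: MValueMatrix | pd.DataFrame) -> pd.DataFrame:
    df = m.m if isinstance(m, MValueMatrix) else m
    v = df.to_numpy(float)
    return pd.DataFrame(
        np.exp2(v) / (1 + np.exp2(v)), index=df.index, columns=df.columns
    )


def pair_differences(m: MValueMatrix | pd.DataFrame, design: TwinDesign) -> PairDiffMatrix:
    """Within-pair contrast: one column per twin pair, affected minus unaffected."""
    df = m.m if isinstance(m, MValueMatrix) else m
    missing = design.sample_ids.difference(df.columns)
    if len(missing):
        raise ValidationError(f"sample {missing[0]!r} missing from the M matrix")
    members = design.pair_members()
    diff = {
        pair: df[row["affected"]].to_numpy() - df[row["unaffected"]].to_numpy()
        for pair, row in members.iterrows()
    }
    out = pd.DataFrame(diff, index=df.index)
    out.columns.name = "pair_id"
    return PairDiffMatrix(out)


def estimate_surrogates(
    D: PairDiffMatrix,
    n_perm: int = 20,
    alpha: float = 0.05,
    seed: int = 0,
) -> SurrogateSet:
    """Surrogate covariates by residual SVD with parallel analysis.

    Each probe row of D is centred, the singular values of the centred
    matrix are compared component-wise with the (1 - alpha) quantile of the
    singular values of ``n_perm`` row-wise independently permuted copies,
    and the leading run of components exceeding their permutation threshold
    is retained.  The conservative ("higher") empirical quantile is used.
    Returns the corresponding right-singular vectors (orthonormal, and
    orthogonal to the intercept because rows are centred).
    """
    if n_perm < 1:
        raise ValidationError("n_perm must be >= 1")
    if D.n_pairs < 3:
        raise ValidationError("need at least 3 pairs to estimate surrogates")
    X = D.d.to_numpy(float)
    Xc = X - X.mean(axis=1, keepdims=True)
    sv = np.linalg.svd(Xc, compute_uv=False)
    rng = np.random.default_rng(seed)
    perm_sv = np.empty((n_perm, len(sv)))
    for i in range(n_perm):
        perm_sv[i] = np.linalg.svd(rng.permuted(Xc, axis=1), compute_uv=False)
    thresh = np.quantile(perm_sv, 1 - alpha, axis=0, method="higher")
    q = 0
    while q < len(sv) - 1 and sv[q] > thresh[q]:
        q += 1
    if q == 0:
        return SurrogateSet(0, np.empty((D.n_pairs, 0)))
    _, _, vt = np.linalg.svd(Xc, full_matrices=False)
    return SurrogateSet(q, vt[:q].T)


def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x by Newton iteration (monotone, tol 1e-8)."""
    if x <= 0:
        raise ValueError("trigamma inverse needs a positive argument")
    y = 0.5 + 1.0 / x
    for _ in range(100):
        tri = special.polygamma(1, y)
        step = tri * (1 - tri / x) / special.polygamma(2, y)
        y = y + step
        if abs(step) < 1e-8 * y:
            break
    return float(y)


def fit_moderated(
    D: PairDiffMatrix,
    surrogates: Optional[SurrogateSet] = None,
    d0_override: Optional[float] = None,
) -> tuple[EBayesPrior, pd.DataFrame]:
    """Per-probe moderated one-sample test of the within-pair differences.

    Each probe's differences are regressed on an intercept plus the
    surrogate columns; the intercept estimate is the mean within-pair
    difference and the residual variance s_g^2 has d = n_pairs - 1 - q
    degrees of freedom.  The variance prior (d0, s0^2) is estimated by
    moment matching on z_g = log s_g^2: with e_g = z_g - psi(d/2) +
    log(d/2), solve psi'(d0/2) = var(e) - psi'(d/2) for d0 (infinite when
    the right-hand side is non-positive) and set log s0^2 = mean(e) +
    psi(d0/2) - log(d0/2).  The posterior variance is the df-weighted blend
    (d0 s0^2 + d s_g^2) / (d0 + d), the moderated t is
    mean_diff * sqrt(n_eff) / s_post with n_eff the reciprocal of the
    intercept-coefficient variance factor, and the two-sided p uses a t
    reference with d + d0 df (normal when d0 is infinite).

    ``d0_override`` replaces the estimated prior df (0 disables moderation
    entirely, recovering the ordinary paired t).
    """
    X = D.d.to_numpy(float)
    n_probes, n = X.shape
    q = surrogates.q if surrogates is not None else 0
    d = n - 1 - q
    if d < 1:
        raise ValidationError(
            f"residual df = n_pairs - 1 - q = {d} < 1: insufficient replication"
        )
    design = np.ones((n, 1))
    if q:
        design = np.hstack([design, surrogates.loadings])
    xtx_inv = np.linalg.inv(design.T @ design)
    coef = X @ design @ xtx_inv.T
    resid = X - coef @ design.T
    s_sq = (resid**2).sum(axis=1) / d
    effect = coef[:, 0]
    n_eff = 1.0 / xtx_inv[0, 0]

    # moment matching on log variances
    z = np.log(np.maximum(s_sq, 1e-300))
    e = z - special.digamma(d / 2) + math.log(d / 2)
    e_bar = float(e.mean())
    v = float(e.var(ddof=1)) if n_probes > 1 else 0.0
    rhs = v - special.polygamma(1, d / 2)
    if rhs <= 0:
        d0 = math.inf
        s0_sq = math.exp(e_bar)
    else:
        d0 = 2 * _trigamma_inverse(rhs)
        s0_sq = math.exp(e_bar + special.digamma(d0 / 2) - math.log(d0 / 2))

    if d0_override is not None:
        d0 = float(d0_override)

    if d0 == 0:
        s_post = s_sq
        df_total = float(d)
    elif math.isinf(d0):
        s_post = np.full_like(s_sq, s0_sq)
        df_total = math.inf
    else:
        s_post = (d0 * s0_sq + d * s_sq) / (d0 + d)
        df_total = d + d0

    t_mod = effect * math.sqrt(n_eff) / np.sqrt(s_post)
    if math.isinf(df_total):
        p = 2 * stats.norm.sf(np.abs(t_mod))
    else:
        p = 2 * stats.t.sf(np.abs(t_mod), df_total)

    table = pd.DataFrame(
        {
            "mean_diff_m": effect,
            "s_sq": s_sq,
            "s_sq_post": s_post,
            "t_mod": t_mod,
            "p": p,
            "df_total": df_total,
        },
        index=D.d.index,
    )
    return EBayesPrior(d0=d0, s0_sq=float(s0_sq), d=d), table


def adjust_bh(p: np.ndarray | pd.Series | list) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment with monotonicity, capped at 1."""
    p = np.asarray(p, float)
    m = p.size
    if m == 0:
        return np.empty(0)
    if (p < 0).any() or (p > 1).any():
        raise ValidationError("p-values outside [0, 1]")
    order = np.argsort(p, kind="mergesort")
    scaled = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum(np.minimum.accumulate(scaled[::-1])[::-1], 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


def call_dmps(
    stats_table: pd.DataFrame,
    beta: BetaMatrix | pd.DataFrame,
    design: TwinDesign,
    p_threshold: float = 0.005,
    manifest: Optional[ProbeManifest] = None,
) -> pd.DataFrame:
    """Assemble the per-probe DMP table and flag significant positions.

    delta_beta is the mean over pairs of (beta affected - beta unaffected)
    computed on the supplied (filtered, normalized) beta matrix; q is the
    BH adjustment over all tested probes; ``significant`` uses a strict
    p < threshold rule.  When a manifest is given, records carry chrom/pos
    and are sorted by genomic coordinate.
    """
    if not 0 < p_threshold < 1:
        raise ValidationError(f"p_threshold must lie in (0, 1), got {p_threshold}")
    bdf = beta.beta if isinstance(beta, BetaMatrix) else beta
    if not stats_table.index.equals(bdf.index):
        bdf = bdf.loc[stats_table.index]
    members = design.pair_members()
    diffs = np.column_stack(
        [
            bdf[row["affected"]].to_numpy() - bdf[row["unaffected"]].to_numpy()
            for _, row in members.iterrows()
        ]
    )
    out = stats_table.copy()
    out.insert(0, "delta_beta", diffs.mean(axis=1))
    out["q"] = adjust_bh(out["p"].to_numpy())
    out["significant"] = out["p"] < p_threshold
    out.index.name = "probe_id"
    if manifest is not None:
        coords = manifest.positions(out.index)
        out.insert(0, "pos", coords["pos"].to_numpy())
        out.insert(0, "chrom", coords["chrom"].to_numpy())
        out = out.sort_values(["chrom", "pos"], kind="mergesort")
    return out
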