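"""CLR/Gaussian-mixture co-expression clustering and group contrast.

Counts are size-factor normalized (median-of-ratios), pseudocounted and
turned into per-gene compositional profiles; the centred log-ratio (CLR)
transform of those profiles (rows sum to zero) is clustered with a
diagonal-covariance Gaussian mixture fitted by EM, with the number of
clusters chosen by ICL (BIC plus twice the assignment entropy).  Genes are
assigned to a cluster only when their posterior responsibility exceeds a
threshold (default 0.9, strict).  Each cluster's affected/unaffected
contrast compares per-gene group means of normalized expression by the
Wilcoxon rank-sum test, and clusters are ranked by |log ratio|.

``paired_de`` is a simplified differential-expression stand-in: a paired
moderated t on log-CPM within-pair differences (it reuses the EWAS
moderation machinery), not a negative-binomial GLM.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.cluster import kmeans_plusplus

from .enrichment_stats import rank_sum_test
from .io_formats import CountMatrix, TwinDesign, ValidationError
from .paired_ewas import PairDiffMatrix, adjust_bh, fit_moderated

__all__ = [
    "CLRMatrix",
    "GMMModel",
    "ClusterContrast",
    "size_factors",
    "clr_transform",
    "fit_gmm",
    "assign_members",
    "contrast_cluster",
    "paired_de",
    "UNASSIGNED",
]

UNASSIGNED = -1
_VAR_FLOOR = 1e-8


@dataclass
class CLRMatrix:
    """Genes x samples centred log-ratio profiles (rows sum to zero)."""

    values: pd.DataFrame
    flagged_zero_genes: list[str] = field(default_factory=list)


@dataclass
class GMMModel:
    """Fitted diagonal-covariance Gaussian mixture over gene CLR profiles."""

    K: int
    weights: np.ndarray            # (K,)
    means: np.ndarray              # (K, p)
    variances: np.ndarray          # (K, p)
    responsibilities: pd.DataFrame  # genes x K
    log_likelihood: float
    bic: float
    icl: float
    loglik_trace: list[float]
    selection: pd.DataFrame        # per-K log-likelihood / BIC / ICL


@dataclass
class ClusterContrast:
    cluster_id: int
    n_genes: int
    ratio: float
    W: float
    p: float
    rank: int = 0


def size_factors(counts: CountMatrix | pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors, rescaled to geometric mean 1.

    Each sample's factor is the median, over genes positive in every
    sample, of the ratio of the sample's count to the gene's geometric
    mean.  When no gene is positive everywhere the factors fall back to
    total counts (with a warning).
    """
    df = counts.counts if isinstance(counts, CountMatrix) else counts
    y = df.to_numpy(float)
    allpos = (y > 0).all(axis=1)
    if allpos.any():
        logs = np.log(y[allpos])
        log_geo = logs.mean(axis=1, keepdims=True)
        sf = np.exp(np.median(logs - log_geo, axis=0))
    else:
        warnings.warn(
            "no gene has positive counts in all samples; "
            "falling back to library-size factors",
            stacklevel=2,
        )
        totals = y.sum(axis=0)
        if (totals <= 0).any():
            raise ValidationError("sample with zero total counts")
        sf = totals
    sf = sf / np.exp(np.mean(np.log(sf)))
    return pd.Series(sf, index=df.columns, name="size_factor")


def clr_transform(
    counts: CountMatrix | pd.DataFrame,
    factors: Optional[pd.Series] = None,
    pseudocount: float = 1.0,
) -> CLRMatrix:
    """Centred log-ratio transform of per-gene expression profiles.

    Counts are divided by their sample's size factor, pseudocounted, and
    renormalized to a per-gene composition across samples; the CLR is the
    log composition minus its per-gene mean.  An all-zero gene maps to a
    row of exact zeros (the centre of the simplex) and is flagged.
    """
    df = counts.counts if isinstance(counts, CountMatrix) else counts
    if factors is None:
        factors = size_factors(df)
    y = df.to_numpy(float) / factors.to_numpy(float) + pseudocount
    prof = y / y.sum(axis=1, keepdims=True)
    logp = np.log(prof)
    clr = logp - logp.mean(axis=1, keepdims=True)
    flagged = list(df.index[(df.to_numpy() == 0).all(axis=1)])
    return CLRMatrix(
        pd.DataFrame(clr, index=df.index, columns=df.columns), flagged
    )


def _log_gauss_diag(x: np.ndarray, means: np.ndarray, variances: np.ndarray) -> np.ndarray:
    """(n, K) log density of each point under each diagonal Gaussian."""
    n, p = x.shape
    inv = 1.0 / variances  # (K, p)
    # (x - mu)^2 / var expanded into three BLAS products
    quad = (x**2) @ inv.T - 2.0 * x @ (means * inv).T + (means**2 * inv).sum(axis=1)
    return -0.5 * (p * math.log(2 * math.pi) + np.log(variances).sum(axis=1) + quad)


class _ComponentCollapse(Exception):
    pass


def _em_once(
    x: np.ndarray,
    K: int,
    rng: np.random.Generator,
    tol: float,
    max_iter: int,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, float, list[float]]:
    n, p = x.shape
    seed = int(rng.integers(2**31))
    if K == 1:
        centers = x.mean(axis=0, keepdims=True)
    else:
        centers, _ = kmeans_plusplus(x, n_clusters=K, random_state=seed)
    # hard-assignment initialisation with a shared variance
    d2 = ((x[:, None, :] - centers[None]) ** 2).sum(axis=2)
    lab = d2.argmin(axis=1)
    weights = np.array([(lab == k).mean() for k in range(K)])
    weights = np.maximum(weights, 1.0 / n)
    weights /= weights.sum()
    means = centers.copy()
    variances = np.tile(x.var(axis=0) + _VAR_FLOOR, (K, 1))

    trace: list[float] = []
    resp = None
    for _ in range(max_iter):
        logpdf = _log_gauss_diag(x, means, variances) + np.log(weights)
        mx = logpdf.max(axis=1, keepdims=True)
        lse = mx[:, 0] + np.log(np.exp(logpdf - mx).sum(axis=1))
        ll = float(lse.sum())
        resp = np.exp(logpdf - lse[:, None])
        if trace and ll < trace[-1] - 1e-8 * max(1.0, abs(trace[-1])):
            raise AssertionError("EM log-likelihood decreased")
        # relative convergence: tol scaled by the log-likelihood magnitude
        converged = bool(trace) and abs(ll - trace[-1]) < tol * (1.0 + abs(ll))
        trace.append(ll)
        if converged:
            break
        nk = resp.sum(axis=0)
        if (nk < 1e-10).any():
            raise _ComponentCollapse
        weights = nk / n
        means = (resp.T @ x) / nk[:, None]
        variances = (resp.T @ (x**2)) / nk[:, None] - means**2
        if (variances < _VAR_FLOOR).any():
            raise _ComponentCollapse
    return weights, means, variances, resp, trace[-1], trace


def fit_gmm(
    X: CLRMatrix | pd.DataFrame,
    K_grid: Sequence[int] = range(2, 26),
    restarts: int = 5,
    tol: float = 1e-6,
    max_iter: int = 300,
    seed: int = 0,
) -> GMMModel:
    """Fit diagonal Gaussian mixtures over a K grid and select K by ICL.

    Each K is fitted ``restarts`` times from k-means++ initialisations and
    the best log-likelihood kept; a restart whose smallest component
    variance drops below 1e-8 (or that empties a component) is
    re-initialised, and a K whose restarts all collapse is skipped.  ICL =
    BIC + 2 * assignment entropy; the model minimising ICL is returned.
    """
    df = X.values if isinstance(X, CLRMatrix) else X
    x = df.to_numpy(float)
    n, p = x.shape
    K_grid = list(K_grid)
    if n <= max(K_grid):
        raise ValidationError("need more genes than the largest K in the grid")
    rng = np.random.default_rng(seed)

    rows = []
    fits: dict[int, tuple] = {}
    for K in K_grid:
        best = None
        for _ in range(restarts):
            fitted = None
            for _attempt in range(3):
                try:
                    fitted = _em_once(x, K, rng, tol, max_iter)
                    break
                except _ComponentCollapse:
                    continue
            if fitted is None:
                continue
            if best is None or fitted[4] > best[4]:
                best = fitted
        if best is None:
            continue  # every restart collapsed: K unfittable on this data
        weights, means, variances, resp, ll, trace = best
        npar = (K - 1) + 2 * K * p
        bic = -2 * ll + npar * math.log(n)
        with np.errstate(divide="ignore", invalid="ignore"):
            ent = float(-np.nansum(resp * np.log(np.where(resp > 0, resp, 1.0))))
        icl = bic + 2 * ent
        rows.append({"K": K, "log_likelihood": ll, "bic": bic, "icl": icl})
        fits[K] = (weights, means, variances, resp, ll, trace, bic, icl)
    if not fits:
        raise ValidationError("no mixture could be fitted on any K in the grid")
    selection = pd.DataFrame(rows).set_index("K")
    best_K = int(selection["icl"].idxmin())
    weights, means, variances, resp, ll, trace, bic, icl = fits[best_K]
    return GMMModel(
        K=best_K,
        weights=weights,
        means=means,
        variances=variances,
        responsibilities=pd.DataFrame(
            resp, index=df.index, columns=range(best_K)
        ),
        log_likelihood=ll,
        bic=bic,
        icl=icl,
        loglik_trace=trace,
        selection=selection,
    )


def assign_members(model: GMMModel, tau_threshold: float = 0.9) -> pd.Series:
    """Cluster assignment per gene: argmax responsibility if it strictly
    exceeds the threshold, else UNASSIGNED (-1)."""
    if not 0 < tau_threshold < 1:
        raise ValidationError("tau_threshold must lie in (0, 1)")
    resp = model.responsibilities.to_numpy()
    best = resp.argmax(axis=1)
    tau = resp[np.arange(len(best)), best]
    out = np.where(tau > tau_threshold, best, UNASSIGNED)
    return pd.Series(out, index=model.responsibilities.index, name="cluster")


def contrast_cluster(
    assignment: pd.Series,
    normalized_expression: pd.DataFrame,
    design: TwinDesign,
) -> pd.DataFrame:
    """Affected/unaffected contrast of each cluster's expression profile.

    For every assigned cluster: A = per-gene mean normalized expression
    over affected samples, B = the same over unaffected samples;
    ratio = mean(A)/mean(B); two-sided Wilcoxon rank-sum comparing the
    per-gene values of A against B.  Clusters are ranked by |log ratio|
    (rank 1 = most dysregulated).  Clusters with no assigned genes are
    skipped with a warning.
    """
    aff = design.affected_samples
    unaff = design.unaffected_samples
    rows = []
    for cluster in sorted(c for c in assignment.unique() if c != UNASSIGNED):
        genes = assignment.index[assignment == cluster]
        if len(genes) == 0:
            warnings.warn(f"cluster {cluster} has no assigned genes; skipped", stacklevel=2)
            continue
        sub = normalized_expression.loc[genes]
        a = sub[aff].mean(axis=1).to_numpy()
        b = sub[unaff].mean(axis=1).to_numpy()
        if b.mean() <= 0:
            raise ValidationError(f"cluster {cluster}: non-positive mean expression")
        w, p = rank_sum_test(a, b)
        rows.append(
            ClusterContrast(
                cluster_id=int(cluster),
                n_genes=len(genes),
                ratio=float(a.mean() / b.mean()),
                W=w,
                p=p,
            )
        )
    if not rows:
        warnings.warn("no cluster had assigned genes", stacklevel=2)
        return pd.DataFrame(
            columns=["cluster_id", "n_genes", "ratio", "W", "p", "rank"]
        )
    out = pd.DataFrame([vars(r) for r in rows])
    order = np.abs(np.log(out["ratio"].to_numpy())).argsort()[::-1]
    ranks = np.empty(len(out), dtype=int)
    ranks[order] = np.arange(1, len(out) + 1)
    out["rank"] = ranks
    return out.sort_values("rank", kind="mergesort").reset_index(drop=True)


def paired_de(
    counts: CountMatrix | pd.DataFrame,
    design: TwinDesign,
    fdr: float = 0.1,
) -> pd.DataFrame:
    """Simplified paired differential expression on log-CPM (moderated t).

    log-CPM = log2((y + 0.5) / (libsize + 1) * 1e6); within-pair
    differences (affected minus unaffected) are tested with the same
    empirical-Bayes moderated one-sample machinery as the methylation arm.
    logFC is the mean within-pair log2 difference.  This is a documented
    stand-in for a count-model GLM, calibrated but not dispersion-aware.
    """
    df = counts.counts if isinstance(counts, CountMatrix) else counts
    missing = design.sample_ids.difference(df.columns)
    if len(missing):
        raise ValidationError(f"sample {missing[0]!r} missing from count matrix")
    y = df.to_numpy(float)
    lib = y.sum(axis=0)
    logcpm = pd.DataFrame(
        np.log2((y + 0.5) / (lib + 1.0) * 1e6), index=df.index, columns=df.columns
    )
    diffs = pair_differences_frame(logcpm, design)
    prior, table = fit_moderated(PairDiffMatrix(diffs))
    out = pd.DataFrame(
        {
            "logFC": table["mean_diff_m"],
            "t_mod": table["t_mod"],
            "p": table["p"],
        },
        index=df.index,
    )
    out["q"] = adjust_bh(out["p"].to_numpy())
    out["sig_fdr"] = out["q"] < fdr
    out["sig_nominal"] = out["p"] < 0.05
    out.index.name = "gene_id"
    return out


def pair_differences_frame(values: pd.DataFrame, design: TwinDesign) -> pd.DataFrame:
    """Within-pair (affected minus unaffected) differences of any matrix."""
    members = design.pair_members()
    diff = {
        pair: values[row["affected"]].to_numpy() - values[row["unaffected"]].to_numpy()
        for pair, row in members.iterrows()
    }
    out = pd.DataFrame(diff, index=values.index)
    out.columns.name = "pair_id"
    return out
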