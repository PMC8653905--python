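"""Synthetic discordant monozygotic-twin cohorts with known ground truth.

The methylation generator emulates the statistical structure the analysis
assumes: bimodal baseline beta values, strong within-pair correlation from a
shared pair effect, additive disease effects on the M (logit) scale at
spiked probes — some isolated, some clustered into sub-kilobase regions —
a batch offset on a subset of samples, and sporadic detection failures.
The expression generator produces negative-binomial counts organised into
latent co-expression clusters whose affected-sample means are multiplied by
a per-cluster group ratio.

All effects are additive on the M scale so that beta stays inside (0, 1).
A single ``numpy.random.default_rng`` stream per call, seeded from the
config, makes every fixture bit reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .io_formats import (
    BetaMatrix,
    CountMatrix,
    ProbeManifest,
    TwinDesign,
    ValidationError,
)

__all__ = [
    "MethSimConfig",
    "SimTruth",
    "simulate_twin_methylation",
    "simulate_twin_counts",
]

_CHROMS = ["chr1", "chr2", "chr3", "chr4", "chr5", "chr6"]


@dataclass
class MethSimConfig:
    """Parameters of the twin-methylation simulation.

    Scales: ``sigma_pair``, ``sigma_noise``, ``delta_m`` and ``batch_shift``
    are standard deviations / offsets on the M (log2-odds) scale.
    ``delta_m`` is the additive disease effect applied to the affected
    member at spiked probes.  ``batch_shift`` is applied to the affected
    member in half of the pairs, to the unaffected member in an equal
    number of pairs, and to both members of any odd pair left over, so the
    batch pattern survives within-pair differencing (as real scan-batch
    effects do) while staying mean-balanced and orthogonal to the disease
    contrast — a batch imbalanced across the within-pair differences would
    be a genuine confound no covariate could separate.  The offset touches
    only a random fraction ``batch_frac_probes`` of probes: a shift common
    to all probes of a sample would be a monotone per-sample transform and
    quantile normalization would erase it, which real probe-specific batch
    artefacts escape.
    """

    n_pairs: int = 7
    n_probes: int = 20_000
    frac_bimodal_low: float = 0.4
    frac_bimodal_high: float = 0.4
    sigma_pair: float = 1.0
    sigma_noise: float = 0.3
    n_dmp_singletons: int = 50
    n_regions: int = 10
    probes_per_region: int = 3
    region_span_bp: int = 600
    delta_m: float = 0.8
    batch_shift: float = 0.5
    batch_frac_probes: float = 0.5
    detp_fail_rate: float = 0.001
    n_discordant_regions: int = 0
    seed: int = 17

    def __post_init__(self) -> None:
        if min(self.sigma_pair, self.sigma_noise) < 0:
            raise ValidationError("standard deviations must be >= 0")
        for rate in (
            self.frac_bimodal_low,
            self.frac_bimodal_high,
            self.detp_fail_rate,
            self.batch_frac_probes,
        ):
            if not 0 <= rate <= 1:
                raise ValidationError("rates must lie in [0, 1]")
        if self.frac_bimodal_low + self.frac_bimodal_high > 1:
            raise ValidationError("bimodal fractions sum above 1")
        if self.probes_per_region < 2:
            raise ValidationError("probes_per_region must be >= 2")
        if self.region_span_bp > 1000:
            raise ValidationError("region_span_bp must be <= 1000")
        if self.n_discordant_regions > self.n_regions:
            raise ValidationError("n_discordant_regions exceeds n_regions")
        needed = self.n_regions * self.probes_per_region + self.n_dmp_singletons
        if self.n_probes < needed:
            raise ValidationError(
                f"n_probes={self.n_probes} too small to host {needed} spiked probes"
            )


@dataclass
class SimTruth:
    """Ground truth of a simulated cohort.

    ``spiked`` has one row per spiked probe (probe_id index; columns sign,
    delta_m, region_id with NaN for singletons).  ``regions`` has one row
    per spiked region (region_id index; chrom, start, end, concordant).
    ``batch`` maps sample_id -> batch label.  For count simulations,
    ``cluster_labels`` maps gene -> latent cluster and ``cluster_ratio``
    maps cluster -> true affected/unaffected mean ratio.
    """

    spiked: Optional[pd.DataFrame] = None
    regions: Optional[pd.DataFrame] = None
    batch: Optional[dict] = None
    cluster_labels: Optional[pd.Series] = None
    cluster_ratio: Optional[dict] = None
    library_factors: Optional[pd.Series] = None


def _expit2(m: np.ndarray) -> np.ndarray:
    """Inverse of the M transform: beta = 2^M / (1 + 2^M), numerically safe."""
    out = np.empty_like(m, dtype=float)
    pos = m >= 0
    out[pos] = 1.0 / (1.0 + np.exp2(-m[pos]))
    out[~pos] = np.exp2(m[~pos]) / (1.0 + np.exp2(m[~pos]))
    return out


def simulate_twin_methylation(
    config: MethSimConfig,
) -> tuple[BetaMatrix, ProbeManifest, TwinDesign, SimTruth]:
    """Simulate a discordant MZ-twin methylation cohort.

    Per probe g and pair i the M value of member s is

        M = m_g + a_gi + batch_s + noise + (sign_g * delta_m if affected and spiked)

    with baseline m_g from a three-component mixture (low ~ beta 0.1,
    high ~ beta 0.9, intermediate), shared pair effect
    a_gi ~ N(0, sigma_pair^2) and noise ~ N(0, sigma_noise^2); then
    beta = 2^M / (1 + 2^M).  Manifest positions keep region probes within
    ``region_span_bp`` of each other and all other probes >= 2000 bp apart.
    Detection p-values are U(0, 0.01) except sporadic failures U(0.011, 1).
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    n_samples = 2 * cfg.n_pairs

    # --- design ---------------------------------------------------------
    half = cfg.n_pairs // 2
    sample_ids, pair_ids, affected, batch_member = [], [], [], []
    for i in range(cfg.n_pairs):
        pair = f"P{i + 1}"
        for aff in (True, False):
            sample_ids.append(f"{pair}_{'A' if aff else 'U'}")
            pair_ids.append(pair)
            affected.append(aff)
            if i < half:
                carries = aff          # affected member in batch B2
            elif i < 2 * half:
                carries = not aff      # unaffected member in batch B2
            else:
                carries = True         # odd pair: both members (cancels in D)
            batch_member.append(carries)
    batch_label = ["B2" if b else "B1" for b in batch_member]
    design = TwinDesign(
        pd.DataFrame(
            {"pair_id": pair_ids, "affected": affected, "batch": batch_label},
            index=pd.Index(sample_ids, name="sample_id"),
        )
    )

    # --- genome layout ---------------------------------------------------
    # units: region blocks plus single probes, shuffled then laid out
    n_singles = cfg.n_probes - cfg.n_regions * cfg.probes_per_region
    units = np.array([1] * cfg.n_regions + [0] * n_singles)
    rng.shuffle(units)
    chrom_of_unit = np.arange(len(units)) % len(_CHROMS)

    probe_chrom: list[str] = []
    probe_pos: list[int] = []
    probe_region: list[int] = []  # -1 for singletons
    cursors = {c: 10_000 for c in _CHROMS}
    region_counter = 0
    for unit, ci in zip(units, chrom_of_unit):
        chrom = _CHROMS[ci]
        if unit == 0:
            probe_chrom.append(chrom)
            probe_pos.append(cursors[chrom])
            probe_region.append(-1)
            cursors[chrom] += int(rng.integers(2000, 5001))
        else:
            k = cfg.probes_per_region
            step = cfg.region_span_bp // (k - 1)
            start = cursors[chrom]
            for j in range(k):
                probe_chrom.append(chrom)
                probe_pos.append(start + j * step)
                probe_region.append(region_counter)
            region_counter += 1
            cursors[chrom] += cfg.region_span_bp + int(rng.integers(2000, 5001))

    n = len(probe_pos)
    probe_ids = [f"cg{i:07d}" for i in range(n)]
    manifest = ProbeManifest(
        pd.DataFrame(
            {
                "chrom": probe_chrom,
                "pos": probe_pos,
                "snp_flag": False,
                "mask_flag": False,
                "strand": "+",
            },
            index=pd.Index(probe_ids, name="probe_id"),
        )
    )
    probe_region = np.asarray(probe_region)

    # --- spiked effects --------------------------------------------------
    region_sign = rng.choice([-1.0, 1.0], size=cfg.n_regions)
    discordant = np.zeros(cfg.n_regions, dtype=bool)
    if cfg.n_discordant_regions:
        discordant[
            rng.choice(cfg.n_regions, size=cfg.n_discordant_regions, replace=False)
        ] = True

    effect_sign = np.zeros(n)
    in_region = probe_region >= 0
    for r in range(cfg.n_regions):
        idx = np.flatnonzero(probe_region == r)
        signs = np.full(len(idx), region_sign[r])
        if discordant[r]:
            # flip one probe so the region mixes signs
            signs[int(rng.integers(len(idx)))] *= -1
        effect_sign[idx] = signs

    single_idx = np.flatnonzero(~in_region)
    spike_singles = rng.choice(single_idx, size=cfg.n_dmp_singletons, replace=False)
    effect_sign[spike_singles] = rng.choice([-1.0, 1.0], size=cfg.n_dmp_singletons)
    spiked_mask = effect_sign != 0

    # --- M values --------------------------------------------------------
    u = rng.random(n)
    m_base = np.where(
        u < cfg.frac_bimodal_low,
        rng.normal(np.log2(0.1 / 0.9), 0.5, size=n),
        np.where(
            u < cfg.frac_bimodal_low + cfg.frac_bimodal_high,
            rng.normal(np.log2(0.9 / 0.1), 0.5, size=n),
            rng.normal(0.0, 1.0, size=n),
        ),
    )
    pair_effect = rng.normal(0.0, cfg.sigma_pair, size=(n, cfg.n_pairs))
    noise = rng.normal(0.0, cfg.sigma_noise, size=(n, n_samples))
    batch_probes = rng.random(n) < cfg.batch_frac_probes

    M = np.empty((n, n_samples))
    for j, sid in enumerate(sample_ids):
        i_pair = j // 2
        M[:, j] = m_base + pair_effect[:, i_pair] + noise[:, j]
        if batch_member[j]:
            M[:, j] += cfg.batch_shift * batch_probes
        if affected[j]:
            M[:, j] += effect_sign * cfg.delta_m
    beta = _expit2(M)

    detp = rng.uniform(0.0, 0.01, size=(n, n_samples))
    fails = rng.random((n, n_samples)) < cfg.detp_fail_rate
    detp[fails] = rng.uniform(0.011, 1.0, size=int(fails.sum()))

    idx = pd.Index(probe_ids, name="probe_id")
    cols = pd.Index(sample_ids, name="sample_id")
    bm = BetaMatrix(
        pd.DataFrame(beta, index=idx, columns=cols),
        pd.DataFrame(detp, index=idx, columns=cols),
    )

    # --- truth -----------------------------------------------------------
    spiked_rows = pd.DataFrame(
        {
            "sign": effect_sign[spiked_mask],
            "delta_m": cfg.delta_m,
            "region_id": np.where(
                in_region[spiked_mask], probe_region[spiked_mask].astype(float), np.nan
            ),
        },
        index=pd.Index(np.array(probe_ids)[spiked_mask], name="probe_id"),
    )
    region_rows = []
    for r in range(cfg.n_regions):
        idx_r = np.flatnonzero(probe_region == r)
        region_rows.append(
            {
                "region_id": r,
                "chrom": probe_chrom[idx_r[0]],
                "start": int(min(probe_pos[i] for i in idx_r)),
                "end": int(max(probe_pos[i] for i in idx_r)),
                "concordant": not discordant[r],
                "sign": region_sign[r],
            }
        )
    regions = (
        pd.DataFrame(region_rows).set_index("region_id")
        if region_rows
        else pd.DataFrame(
            columns=["chrom", "start", "end", "concordant", "sign"]
        ).rename_axis("region_id")
    )
    truth = SimTruth(
        spiked=spiked_rows,
        regions=regions,
        batch=dict(zip(sample_ids, batch_label)),
    )
    return bm, manifest, design, truth


def simulate_twin_counts(
    n_genes: int,
    K_true: int,
    design: TwinDesign,
    dispersion: float = 0.05,
    ratio_per_cluster: Optional[Sequence[float]] = None,
    seed: int = 17,
    base_mean_range: tuple[float, float] = (50.0, 500.0),
    template_sd: float = 0.7,
    libsize_jitter: tuple[float, float] = (0.7, 1.3),
) -> tuple[CountMatrix, SimTruth]:
    """Simulate RNA counts organised into latent co-expression clusters.

    Each gene belongs to one of ``K_true`` clusters.  A cluster template
    assigns a log-normal multiplier to every *pair* (shared by both twins,
    mirroring the strong familial component of expression), giving each
    cluster a distinctive per-sample profile; genes within a cluster share
    the cluster's base mean, so under a unit group ratio the per-gene group
    summaries of different genes are exchangeable.  Affected-sample means
    are multiplied by the cluster's ratio; counts are negative binomial
    with the given dispersion (var = mu + dispersion * mu^2) and per-sample
    library factors jittered uniformly.
    """
    if K_true < 2:
        raise ValidationError("K_true must be >= 2")
    if ratio_per_cluster is None:
        ratio_per_cluster = [1.0] * K_true
    ratio_per_cluster = list(ratio_per_cluster)
    if len(ratio_per_cluster) != K_true:
        raise ValidationError("ratio_per_cluster length must equal K_true")
    if any(r <= 0 for r in ratio_per_cluster):
        raise ValidationError("cluster ratios must be > 0")

    rng = np.random.default_rng(seed)
    samples = list(design.sample_ids)
    pairs = design.pair_ids
    pair_index = {p: i for i, p in enumerate(pairs)}

    labels = rng.permuted(np.arange(n_genes) % K_true)
    lo, hi = base_mean_range
    base = np.exp(rng.uniform(np.log(lo), np.log(hi), size=K_true))
    template = np.exp(rng.normal(0.0, template_sd, size=(K_true, len(pairs))))
    lib = rng.uniform(*libsize_jitter, size=len(samples))

    mu = np.empty((n_genes, len(samples)))
    for j, sid in enumerate(samples):
        row = design.table.loc[sid]
        t = template[:, pair_index[row["pair_id"]]]
        m = base * t
        if row["affected"]:
            m = m * np.asarray(ratio_per_cluster)
        mu[:, j] = m[labels] * lib[j]

    r = 1.0 / dispersion
    counts = rng.negative_binomial(r, r / (r + mu))
    cm = CountMatrix(
        pd.DataFrame(
            counts,
            index=pd.Index([f"gene{i:05d}" for i in range(n_genes)], name="gene_id"),
            columns=pd.Index(samples, name="sample_id"),
        )
    )
    truth = SimTruth(
        cluster_labels=pd.Series(labels, index=cm.genes, name="cluster"),
        cluster_ratio={k: ratio_per_cluster[k] for k in range(K_true)},
        library_factors=pd.Series(lib, index=cm.samples, name="library_factor"),
    )
    return cm, truth
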