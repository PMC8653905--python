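"""Probe-filter cascade and between-sample quantile normalization.

Filters are applied in a fixed order — detection failure, SNP overlap,
underperforming-probe mask, sex chromosomes — and each probe is tallied in
the first filter that removes it, so the QC report bins always sum to the
input probe count.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .io_formats import (
    SEX_CHROMOSOMES,
    BetaMatrix,
    ProbeManifest,
    ValidationError,
)

__all__ = ["QCReport", "filter_probes", "quantile_normalize"]


@dataclass
class QCReport:
    n_input_probes: int
    n_removed_detection: int
    n_removed_snp: int
    n_removed_mask: int
    n_removed_sexchrom: int
    n_retained: int

    @property
    def retained_fraction(self) -> float:
        return self.n_retained / self.n_input_probes if self.n_input_probes else float("nan")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["retained_fraction"] = self.retained_fraction
        return d


def filter_probes(
    beta: BetaMatrix,
    manifest: ProbeManifest,
    detp_threshold: float = 0.01,
) -> tuple[BetaMatrix, QCReport]:
    """Remove unreliable probes and report per-filter tallies.

    In order: (1) probes whose detection p-value exceeds *detp_threshold*
    (strict >) in one or more samples; (2) probes overlapping a variant
    (snp_flag); (3) masked/underperforming probes; (4) probes on the X or Y
    chromosome.  Every probe in the matrix must appear in the manifest.
    """
    probes = beta.probes
    missing = probes.difference(manifest.table.index)
    if len(missing):
        raise ValidationError(f"probe {missing[0]!r} absent from manifest")
    meta = manifest.table.loc[probes]

    detect_fail = (beta.detp.to_numpy() > detp_threshold).any(axis=1)
    snp = meta["snp_flag"].to_numpy(bool)
    mask = meta["mask_flag"].to_numpy(bool)
    sexchrom = meta["chrom"].isin(SEX_CHROMOSOMES).to_numpy()

    removed = detect_fail.copy()
    n_det = int(detect_fail.sum())
    n_snp = int((snp & ~removed).sum())
    removed |= snp
    n_mask = int((mask & ~removed).sum())
    removed |= mask
    n_sex = int((sexchrom & ~removed).sum())
    removed |= sexchrom

    keep = probes[~removed]
    report = QCReport(
        n_input_probes=len(probes),
        n_removed_detection=n_det,
        n_removed_snp=n_snp,
        n_removed_mask=n_mask,
        n_removed_sexchrom=n_sex,
        n_retained=len(keep),
    )
    return beta.subset_probes(keep), report


def quantile_normalize(beta: BetaMatrix) -> BetaMatrix:
    """Classic quantile normalization of the beta matrix across samples.

    The k-th smallest value in every sample is replaced by the mean of the
    k-th smallest values across samples, so all columns end up with the
    identical sorted vector.  Tied values receive the mean of the target
    values at the ranks they jointly occupy (rank-average interpolation),
    which makes the operation deterministic and idempotent.
    """
    values = beta.beta.to_numpy(float)
    n, m = values.shape
    if m < 2:
        raise ValidationError("quantile normalization needs at least 2 samples")
    sorted_means = np.sort(values, axis=0).mean(axis=1)
    ranks = rankdata(values, axis=0)  # average-ties ranks in [1, n]
    normalized = np.interp(ranks, np.arange(1, n + 1), sorted_means)
    out = pd.DataFrame(normalized, index=beta.beta.index, columns=beta.beta.columns)
    return BetaMatrix(out, beta.detp)
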