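"""Chain significant DMPs into regions and annotate genomic context.

"Within 1 kb" is implemented transitively: position-sorted significant
probes on one chromosome are chained while the gap between consecutive
probes is <= max_gap (inclusive), and chains with at least min_probes
members are emitted.  This is the only reading consistent with regions
holding more than two probes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .io_formats import GeneModel, ProbeManifest, ValidationError

__all__ = [
    "Region",
    "ContextSummary",
    "annotate_probes",
    "chain_regions",
    "classify_concordance",
    "summarize_context",
]

CONTEXTS = ("promoter", "body", "intergenic")


@dataclass
class Region:
    """A chained run of significant probes on one chromosome.

    start/end are the 1-based inclusive span of the member probes.
    ``concordant`` is True when every member delta-beta strictly shares one
    sign; ``direction`` is hyper/hypo/mixed in affected vs unaffected.
    """

    chrom: str
    start: int
    end: int
    probe_ids: list[str]
    min_p: float
    concordant: Optional[bool] = None
    direction: Optional[str] = None
    zero_delta_flagged: bool = False

    @property
    def n_probes(self) -> int:
        return len(self.probe_ids)


@dataclass
class ContextSummary:
    """Genomic-context fractions of DMPs next to the tested-probe background."""

    dmp_fractions: dict[str, float]
    background_fractions: dict[str, float]
    n_dmps: int
    n_background: int


def annotate_probes(
    manifest: ProbeManifest,
    gene_model: GeneModel,
    promoter_up: int = 1500,
    promoter_down: int = 500,
) -> pd.DataFrame:
    """Assign each probe a genomic context (promoter / body / intergenic).

    The promoter is a strand-aware window around the TSS: on the plus
    strand [TSS - promoter_up, TSS + promoter_down), mirrored on the minus
    strand.  The gene body is the rest of the transcribed span.  Promoter
    takes precedence over body; probes on chromosomes without genes are
    intergenic.  Returns a frame indexed by probe_id with columns
    ``context`` and ``gene`` (empty string when intergenic).
    """
    probes = manifest.table
    gene = np.full(len(probes), "", dtype=object)
    pos = probes["pos"].to_numpy()
    chrom = probes["chrom"].to_numpy()

    # 0 = intergenic, 1 = body, 2 = promoter; first gene wins at equal priority
    priority = np.zeros(len(probes), dtype=int)
    for gid, row in gene_model.table.iterrows():
        on_chrom = chrom == row["chrom"]
        if not on_chrom.any():
            continue
        tss, tes = int(row["tss"]), int(row["tes"])
        if row["strand"] == "+":
            prom = on_chrom & (pos >= tss - promoter_up) & (pos < tss + promoter_down)
        else:
            prom = on_chrom & (pos > tss - promoter_down) & (pos <= tss + promoter_up)
        lo, hi = min(tss, tes), max(tss, tes)
        body = on_chrom & (pos >= lo) & (pos <= hi) & ~prom
        up = prom & (priority < 2)
        gene[up] = gid
        priority[up] = 2
        up = body & (priority < 1)
        gene[up] = gid
        priority[up] = 1
    context = np.where(
        priority == 2, "promoter", np.where(priority == 1, "body", "intergenic")
    )
    return pd.DataFrame({"context": context, "gene": gene}, index=probes.index)


def chain_regions(
    dmps: pd.DataFrame,
    manifest: ProbeManifest,
    max_gap: int = 1000,
    min_probes: int = 2,
) -> list[Region]:
    """Greedy per-chromosome chaining of significant probes.

    *dmps* must contain only significant probes (indexed by probe_id, with
    a ``p`` column).  Probes are sorted by position; a chain is extended
    while the gap to the next probe is <= max_gap, and emitted when it
    holds >= min_probes members.  Every input probe belongs to exactly one
    chain (possibly a dropped short one), so the operation is a partition.
    """
    if len(dmps) == 0:
        return []
    coords = manifest.positions(dmps.index)
    table = pd.DataFrame(
        {
            "chrom": coords["chrom"].to_numpy(),
            "pos": coords["pos"].to_numpy(),
            "p": dmps["p"].to_numpy(),
        },
        index=dmps.index,
    ).sort_values(["chrom", "pos"], kind="mergesort")

    regions: list[Region] = []
    for chrom, sub in table.groupby("chrom", sort=True):
        pos = sub["pos"].to_numpy()
        breaks = np.flatnonzero(np.diff(pos) > max_gap) + 1
        for chunk in np.split(np.arange(len(pos)), breaks):
            if len(chunk) < min_probes:
                continue
            members = sub.iloc[chunk]
            regions.append(
                Region(
                    chrom=str(chrom),
                    start=int(members["pos"].iloc[0]),
                    end=int(members["pos"].iloc[-1]),
                    probe_ids=list(members.index),
                    min_p=float(members["p"].min()),
                )
            )
    return regions


def classify_concordance(region: Region, dmps: pd.DataFrame) -> Region:
    """Set the concordance flag and direction of a region from member delta-betas.

    Concordant iff all member delta-beta values strictly share one sign;
    direction is hyper (all > 0), hypo (all < 0) or mixed.  A member with
    delta-beta exactly zero makes the region mixed and flags it.
    """
    missing = [p for p in region.probe_ids if p not in dmps.index]
    if missing:
        raise ValidationError(f"region member {missing[0]!r} absent from DMP table")
    delta = dmps.loc[region.probe_ids, "delta_beta"].to_numpy(float)
    if (delta == 0).any():
        region.concordant = False
        region.direction = "mixed"
        region.zero_delta_flagged = True
    elif (delta > 0).all():
        region.concordant = True
        region.direction = "hyper"
    elif (delta < 0).all():
        region.concordant = True
        region.direction = "hypo"
    else:
        region.concordant = False
        region.direction = "mixed"
    return region


def summarize_context(
    dmps: pd.DataFrame,
    all_tested_probes: pd.Index | list,
    annotation: pd.DataFrame,
) -> ContextSummary:
    """Genomic-context fractions of the DMPs and of the tested background."""
    tested = pd.Index(all_tested_probes)
    missing = tested.difference(annotation.index)
    if len(missing):
        raise ValidationError(f"probe {missing[0]!r} missing from annotation")
    bg = annotation.loc[tested, "context"].value_counts()
    background = {c: float(bg.get(c, 0)) / len(tested) for c in CONTEXTS}
    if len(dmps) == 0:
        warnings.warn("empty DMP list: context fractions undefined", stacklevel=2)
        fractions = {c: float("nan") for c in CONTEXTS}
    else:
        fg = annotation.loc[dmps.index, "context"].value_counts()
        fractions = {c: float(fg.get(c, 0)) / len(dmps) for c in CONTEXTS}
    return ContextSummary(
        dmp_fractions=fractions,
        background_fractions=background,
        n_dmps=len(dmps),
        n_background=len(tested),
    )
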