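"""Readers and writers for every on-disk format the pipeline touches.

All tabular interchange is plain TSV (tab separator, decimal point, no
quoting); floating point values are written with 17 significant digits so
that a write/read round trip is bit exact.  Genomic positions are 1-based
in memory (Illumina-manifest convention); only the BED export converts to
0-based half-open coordinates.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FormatError",
    "ValidationError",
    "ProbeManifest",
    "BetaMatrix",
    "TwinDesign",
    "GeneModel",
    "CountMatrix",
    "GeneSetCollection",
    "read_manifest",
    "read_matrix",
    "read_design",
    "read_gene_model",
    "read_gmt",
    "write_matrix",
    "write_manifest",
    "write_design",
    "write_table",
    "write_regions_bed",
    "write_run_manifest",
    "write_outputs",
    "FLOAT_FORMAT",
]

FLOAT_FORMAT = "%.17g"

SEX_CHROMOSOMES = frozenset({"chrX", "chrY", "X", "Y"})


class FormatError(ValueError):
    """A file does not conform to the expected on-disk format."""


class ValidationError(ValueError):
    """Parsed content violates a domain invariant."""


# ---------------------------------------------------------------------------
# Domain containers
# ---------------------------------------------------------------------------


@dataclass
class ProbeManifest:
    """Probe universe of the methylation array.

    ``table`` is indexed by probe_id with columns ``chrom`` (str), ``pos``
    (1-based int), ``snp_flag``/``mask_flag`` (bool) and ``strand``
    (one of ``+ - unknown``).
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table
        required = {"chrom", "pos", "snp_flag", "mask_flag"}
        missing = required - set(t.columns)
        if missing:
            raise ValidationError(f"manifest missing columns: {sorted(missing)}")
        if t.index.has_duplicates:
            dup = t.index[t.index.duplicated()][0]
            raise ValidationError(f"duplicate probe_id in manifest: {dup!r}")
        if (t["pos"] < 1).any():
            bad = t.index[t["pos"] < 1][0]
            raise ValidationError(f"probe {bad!r} has pos < 1")
        if (t["chrom"].astype(str).str.len() == 0).any():
            raise ValidationError("empty chromosome name in manifest")
        coords = pd.MultiIndex.from_arrays([t["chrom"], t["pos"]])
        if coords.has_duplicates:
            chrom, pos = coords[coords.duplicated()][0]
            raise ValidationError(
                f"duplicate genomic coordinate in manifest: {chrom}:{pos}"
            )
        if "strand" not in t.columns:
            t = t.copy()
            t["strand"] = "unknown"
            self.table = t

    @property
    def probe_ids(self) -> pd.Index:
        return self.table.index

    def positions(self, probes: Sequence[str]) -> pd.DataFrame:
        """chrom/pos lookup for a probe subset, preserving order."""
        missing = [p for p in probes if p not in self.table.index]
        if missing:
            raise ValidationError(f"probe {missing[0]!r} absent from manifest")
        return self.table.loc[list(probes), ["chrom", "pos"]]


@dataclass
class BetaMatrix:
    """Probes x samples methylated fractions with companion detection p-values."""

    beta: pd.DataFrame
    detp: pd.DataFrame

    def __post_init__(self) -> None:
        if self.beta.shape != self.detp.shape:
            raise ValidationError(
                f"beta shape {self.beta.shape} != detp shape {self.detp.shape}"
            )
        if not self.beta.index.equals(self.detp.index) or not self.beta.columns.equals(
            self.detp.columns
        ):
            raise ValidationError("beta and detp row/column labels differ")
        if self.beta.columns.has_duplicates:
            raise ValidationError("duplicate sample_id in beta matrix")
        if self.beta.index.has_duplicates:
            raise ValidationError("duplicate probe_id in beta matrix")
        v = self.beta.to_numpy()
        if np.isnan(v).any():
            raise ValidationError("beta matrix contains missing values")
        if (v < 0).any() or (v > 1).any():
            raise ValidationError("beta values outside [0, 1]")

    @property
    def probes(self) -> pd.Index:
        return self.beta.index

    @property
    def samples(self) -> pd.Index:
        return self.beta.columns

    def subset_probes(self, probes: Sequence[str]) -> "BetaMatrix":
        return BetaMatrix(self.beta.loc[list(probes)], self.detp.loc[list(probes)])


@dataclass
class TwinDesign:
    """Pair/affection structure of the cohort.

    The unit of inference is the within-pair difference (affected minus
    unaffected member of each monozygotic pair).
    """

    table: pd.DataFrame  # index sample_id; columns pair_id, affected[, batch]

    def __post_init__(self) -> None:
        t = self.table
        if t.index.has_duplicates:
            raise ValidationError("duplicate sample_id in design")
        counts = t.groupby("pair_id").size()
        bad = counts[counts != 2]
        if len(bad):
            raise ValidationError(
                f"pair {bad.index[0]!r} has {bad.iloc[0]} members (expected 2)"
            )
        aff = t.groupby("pair_id")["affected"].sum()
        disc = aff[aff != 1]
        if len(disc):
            raise ValidationError(
                f"pair {disc.index[0]!r} has {int(disc.iloc[0])} affected members "
                "(expected exactly one affected and one unaffected)"
            )

    @property
    def sample_ids(self) -> pd.Index:
        return self.table.index

    @property
    def pair_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for p in self.table["pair_id"]:
            seen.setdefault(p, None)
        return list(seen)

    @property
    def n_pairs(self) -> int:
        return len(self.pair_ids)

    def pair_members(self) -> pd.DataFrame:
        """One row per pair: columns ``affected`` and ``unaffected`` sample ids."""
        rows = {}
        for pair in self.pair_ids:
            sub = self.table[self.table["pair_id"] == pair]
            rows[pair] = {
                "affected": sub.index[sub["affected"]][0],
                "unaffected": sub.index[~sub["affected"]][0],
            }
        return pd.DataFrame.from_dict(rows, orient="index")

    @property
    def affected_samples(self) -> list[str]:
        return list(self.table.index[self.table["affected"]])

    @property
    def unaffected_samples(self) -> list[str]:
        return list(self.table.index[~self.table["affected"]])


@dataclass
class GeneModel:
    """Minimal gene annotation: TSS/TES per gene, strand aware.

    For minus-strand genes the transcription start (``tss``) lies at the
    numerically larger coordinate.
    """

    table: pd.DataFrame  # index gene_id; columns chrom, strand, tss, tes

    def __post_init__(self) -> None:
        t = self.table
        if t.index.has_duplicates:
            raise ValidationError("duplicate gene_id in gene model")
        if (t["tss"] == t["tes"]).any():
            bad = t.index[t["tss"] == t["tes"]][0]
            raise ValidationError(f"gene {bad!r} has tss == tes")
        bad_strand = ~t["strand"].isin(["+", "-"])
        if bad_strand.any():
            raise ValidationError(
                f"gene {t.index[bad_strand][0]!r} has invalid strand"
            )


@dataclass
class CountMatrix:
    """Genes x samples non-negative integer read counts."""

    counts: pd.DataFrame

    def __post_init__(self) -> None:
        v = self.counts.to_numpy()
        if np.isnan(v.astype(float)).any():
            raise ValidationError("count matrix contains missing values")
        if (v < 0).any():
            raise ValidationError("negative entry in count matrix")
        if not np.allclose(v, np.round(v.astype(float))):
            raise ValidationError("non-integer entry in count matrix")
        if self.counts.columns.has_duplicates:
            raise ValidationError("duplicate sample_id in count matrix")

    @property
    def genes(self) -> pd.Index:
        return self.counts.index

    @property
    def samples(self) -> pd.Index:
        return self.counts.columns


@dataclass
class GeneSetCollection:
    """Named gene sets (GMT-style) with optional descriptions."""

    sets: dict[str, list[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not members:
                raise ValidationError(f"gene set {name!r} is empty")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets.items())


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------


def read_manifest(path: str | Path) -> ProbeManifest:
    """Read a probe manifest TSV (probe_id, chrom, pos, snp_flag, mask_flag[, strand])."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = ["probe_id", "chrom", "pos", "snp_flag", "mask_flag"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"manifest {path}: missing columns {missing}")
    pos = pd.to_numeric(df["pos"], errors="coerce")
    if pos.isna().any():
        # +2: one for the header line, one for 0-based row index
        line = int(np.flatnonzero(pos.isna())[0]) + 2
        raise FormatError(
            f"manifest {path}: non-numeric pos {df['pos'].iloc[line - 2]!r} on line {line}"
        )
    out = pd.DataFrame(
        {
            "chrom": df["chrom"].astype(str).to_numpy(),
            "pos": pos.astype(int).to_numpy(),
            "snp_flag": _parse_bool(df["snp_flag"], "snp_flag").to_numpy(),
            "mask_flag": _parse_bool(df["mask_flag"], "mask_flag").to_numpy(),
            "strand": (
                df["strand"].astype(str).to_numpy()
                if "strand" in df.columns
                else "unknown"
            ),
        },
        index=pd.Index(df["probe_id"].to_numpy(), name="probe_id"),
    )
    return ProbeManifest(out)


def _parse_bool(s: pd.Series, name: str) -> pd.Series:
    mapping = {"0": False, "1": True, "true": True, "false": False,
               "True": True, "False": False}
    out = s.map(mapping)
    if out.isna().any():
        raise FormatError(f"column {name}: unparseable boolean {s[out.isna()].iloc[0]!r}")
    return out.astype(bool)


def _read_tsv_matrix(path: str | Path) -> pd.DataFrame:
    # round_trip parsing: the write/read cycle must be bit exact
    df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    if df.isna().any().any():
        raise FormatError(f"{path}: missing values or ragged rows")
    return df


def read_matrix(path: str | Path, kind: str) -> pd.DataFrame:
    """Read a row-id x sample-id TSV matrix.

    kind='beta' enforces values in [0, 1]; kind='detp' the same; kind='counts'
    enforces non-negative integers.  Row and column order is preserved.
    """
    if kind not in {"beta", "detp", "counts"}:
        raise ValueError(f"unknown matrix kind {kind!r}")
    df = _read_tsv_matrix(path)
    v = df.to_numpy()
    if kind in {"beta", "detp"}:
        if (v < 0).any() or (v > 1).any():
            raise ValidationError(f"{path}: {kind} value outside [0, 1]")
        return df.astype(float)
    if (v < 0).any():
        raise ValidationError(f"{path}: negative count")
    if not np.allclose(v.astype(float), np.round(v.astype(float))):
        raise ValidationError(f"{path}: non-integer count")
    return df.astype(np.int64)


def read_design(path: str | Path) -> TwinDesign:
    """Read a twin-design TSV (sample_id, pair_id, affected in {0,1}[, batch])."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = ["sample_id", "pair_id", "affected"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"design {path}: missing columns {missing}")
    aff = df["affected"].map({"0": False, "1": True})
    if aff.isna().any():
        raise FormatError(f"design {path}: affected must be 0 or 1")
    table = pd.DataFrame(
        {
            "pair_id": df["pair_id"].astype(str).to_numpy(),
            "affected": aff.astype(bool).to_numpy(),
        },
        index=pd.Index(df["sample_id"].to_numpy(), name="sample_id"),
    )
    if "batch" in df.columns:
        table["batch"] = df["batch"].astype(str).values
    return TwinDesign(table)


def read_gene_model(path: str | Path) -> GeneModel:
    """Read a gene-model TSV (gene_id, chrom, strand, tss, tes)."""
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "chrom": str, "strand": str})
    required = ["gene_id", "chrom", "strand", "tss", "tes"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"gene model {path}: missing columns {missing}")
    table = df.set_index("gene_id")[["chrom", "strand", "tss", "tes"]]
    table["tss"] = table["tss"].astype(int)
    table["tes"] = table["tes"].astype(int)
    return GeneModel(table)


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a GMT file: one set per line, ``name TAB description TAB member...``."""
    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}: line {lineno} has {len(fields)} fields (expected >= 3)"
                )
            name, desc, *members = fields
            members = [m for m in members if m]
            if not members:
                raise FormatError(f"{path}: set {name!r} on line {lineno} has no members")
            if name in sets:
                raise FormatError(f"{path}: duplicate set name {name!r}")
            sets[name] = members
            descriptions[name] = desc
    return GeneSetCollection(sets, descriptions)


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------


def write_matrix(df: pd.DataFrame, path: str | Path, index_label: str = "id") -> None:
    df.to_csv(path, sep="\t", float_format=FLOAT_FORMAT, index_label=index_label)


def write_manifest(manifest: ProbeManifest, path: str | Path) -> None:
    out = manifest.table.copy()
    out["snp_flag"] = out["snp_flag"].astype(int)
    out["mask_flag"] = out["mask_flag"].astype(int)
    out.to_csv(path, sep="\t", index_label="probe_id")


def write_design(design: TwinDesign, path: str | Path) -> None:
    out = design.table.copy()
    out["affected"] = out["affected"].astype(int)
    out.to_csv(path, sep="\t", index_label="sample_id")


def write_table(df: pd.DataFrame, path: str | Path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", float_format=FLOAT_FORMAT, index=index)


def write_regions_bed(regions: Iterable, path: str | Path) -> None:
    """Write chained DMP regions as BED6.

    In-memory spans are 1-based inclusive; BED is 0-based half-open, so
    start = min pos - 1 and end = max pos.  name carries the probe count,
    score is -log10 of the smallest member p-value, strand is '.'.
    """
    with open(path, "w") as fh:
        for r in regions:
            score = -math.log10(r.min_p) if r.min_p > 0 else 999.0
            fh.write(
                f"{r.chrom}\t{r.start - 1}\t{r.end}\tn={r.n_probes}\t"
                f"{FLOAT_FORMAT % score}\t.\n"
            )


def write_run_manifest(info: Mapping, path: str | Path) -> None:
    """Machine-readable record of inputs, parameters, seed and versions."""
    with open(path, "w") as fh:
        json.dump(info, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")


def write_outputs(results: Mapping[str, object], out_dir: str | Path) -> list[Path]:
    """Write any collection of stage results into *out_dir*.

    Recognised keys: ``dmp_table`` / ``ewas_table`` / any ``*_table``
    (DataFrame -> TSV), ``regions`` (list of Region -> BED6 + TSV is the
    caller's job), ``qc_report`` / ``run_manifest`` (mapping -> JSON).
    Returns the paths written, in deterministic (sorted-key) order.
    """
    out = Path(out_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
    except OSError as exc:  # unwritable parent
        raise OSError(f"cannot create output directory {out}: {exc}") from exc
    written: list[Path] = []
    for key in sorted(results):
        value = results[key]
        if key == "regions":
            path = out / "regions.bed"
            write_regions_bed(value, path)
        elif isinstance(value, pd.DataFrame):
            path = out / f"{key.removesuffix('_table')}.tsv"
            write_table(value, path)
        elif isinstance(value, Mapping):
            path = out / f"{key}.json"
            write_run_manifest(value, path)
        else:
            raise TypeError(f"unsupported result type for key {key!r}: {type(value)}")
        written.append(path)
    return written
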