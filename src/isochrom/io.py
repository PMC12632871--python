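"""Readers and writers for the standard formats the pipeline touches.

One coordinate convention everywhere: 0-based, half-open intervals.  GTF is
1-based closed on disk and is converted on read (``start - 1``) and back on
write; BED is already half-open and passes through unchanged.  Chromosome
names are passed through verbatim (no ``chr`` normalisation).
"""

from __future__ import annotations

import dataclasses
from collections import OrderedDict
from pathlib import Path
from typing import Iterable, Mapping

import gffutils
import numpy as np
import pandas as pd

from isochrom.errors import DataError, ParseError

STRANDS = ("+", "-", ".")


@dataclasses.dataclass(frozen=True)
class GenomicInterval:
    """A genomic interval, 0-based half-open."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise DataError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(require 0 <= start < end)"
            )
        if self.strand not in STRANDS:
            raise DataError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclasses.dataclass
class TranscriptModel:
    """A transcript as an ordered list of exons on one strand.

    ``principal`` carries the annotation-designated (APPRIS-like) primary
    isoform flag; it is an input, never recomputed.
    """

    gene_id: str
    transcript_id: str
    strand: str
    exons: list[GenomicInterval]
    principal: bool = False

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise DataError(
                f"transcript {self.transcript_id}: strand must be '+' or '-'"
            )
        if not self.exons:
            raise DataError(f"transcript {self.transcript_id}: needs >=1 exon")
        self.exons = sorted(self.exons, key=lambda e: e.start)
        chroms = {e.chrom for e in self.exons}
        if len(chroms) != 1:
            raise DataError(
                f"transcript {self.transcript_id}: exons on multiple chromosomes"
            )
        for a, b in zip(self.exons, self.exons[1:]):
            if a.end > b.start:
                raise DataError(
                    f"transcript {self.transcript_id}: overlapping exons "
                    f"{a.start}-{a.end} and {b.start}-{b.end}"
                )

    @property
    def chrom(self) -> str:
        return self.exons[0].chrom

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(
            self.chrom, self.exons[0].start, self.exons[-1].end, self.strand
        )

    def tss(self) -> int:
        """Strand-aware transcription start site (0-based position)."""
        return self.exons[0].start if self.strand == "+" else self.exons[-1].end - 1

    def junctions(self) -> list[tuple[int, int]]:
        """Intron (donor_bp, acceptor_bp) pairs in genomic order.

        donor_bp is the half-open end of the upstream exon; acceptor_bp the
        start of the downstream exon (both genomic-left-to-right here; strand
        orientation is applied by the event classifier).
        """
        return [
            (a.end, b.start) for a, b in zip(self.exons, self.exons[1:])
        ]


@dataclasses.dataclass
class PeakSet:
    """Accessibility peaks plus a peak x sample normalized signal matrix."""

    peaks: list[GenomicInterval]
    signal: np.ndarray
    sample_labels: list[str]
    peak_ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=float)
        if self.signal.ndim != 2 or self.signal.shape[0] != len(self.peaks):
            raise DataError(
                f"signal has {self.signal.shape[0]} rows for {len(self.peaks)} peaks"
            )
        if self.signal.shape[1] != len(self.sample_labels):
            raise DataError("signal column count != number of sample labels")
        if not np.all(np.isfinite(self.signal)) or np.any(self.signal < 0):
            raise DataError("signal values must be finite and >= 0")
        if self.peak_ids is None:
            self.peak_ids = [f"peak_{i}" for i in range(len(self.peaks))]


class ExpressionMatrix:
    """Isoform x sample matrix with condition labels.

    ``scale_tag`` is either ``counts`` (non-negative integers) or ``log2cpm``.
    Backed by a pandas DataFrame (rows = transcript ids, columns = samples).
    """

    def __init__(
        self,
        values: pd.DataFrame,
        conditions: Mapping[str, str],
        scale_tag: str = "counts",
    ) -> None:
        if scale_tag not in ("counts", "log2cpm"):
            raise DataError(f"unknown scale_tag {scale_tag!r}")
        if values.isna().any().any():
            raise DataError("expression matrix contains missing values")
        if values.index.duplicated().any():
            dups = values.index[values.index.duplicated()].unique().tolist()
            raise DataError(f"duplicated transcript_id(s): {dups}")
        if scale_tag == "counts":
            arr = values.to_numpy()
            if np.any(arr < 0):
                r, c = np.argwhere(arr < 0)[0]
                raise DataError(
                    f"negative count at row {values.index[r]!r}, "
                    f"column {values.columns[c]!r}"
                )
            if not np.allclose(arr, np.round(arr)):
                raise DataError("counts matrix contains non-integer values")
        missing = [s for s in values.columns if s not in conditions]
        if missing:
            raise DataError(f"samples without condition label: {missing}")
        self.values = values
        self.conditions = {s: conditions[s] for s in values.columns}
        self.scale_tag = scale_tag

    @property
    def transcript_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    def condition_samples(self, condition: str) -> list[str]:
        return [s for s, c in self.conditions.items() if c == condition]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ExpressionMatrix):
            return NotImplemented
        return (
            self.scale_tag == other.scale_tag
            and self.conditions == other.conditions
            and self.values.equals(other.values)
        )

    def __repr__(self) -> str:
        return (
            f"ExpressionMatrix({self.values.shape[0]} isoforms x "
            f"{self.values.shape[1]} samples, {self.scale_tag})"
        )


# ---------------------------------------------------------------------------
# GTF


def read_gtf(path: str | Path) -> list[TranscriptModel]:
    """Read exon features from an Ensembl-dialect GTF into transcript models.

    1-based closed GTF coordinates become 0-based half-open.  A transcript is
    flagged principal when any of its exon lines carries a ``tag`` attribute
    starting with ``appris_principal``.
    """
    exons: "OrderedDict[str, dict]" = OrderedDict()
    for lineno, feature in enumerate(gffutils.DataIterator(str(path)), start=1):
        if feature.featuretype != "exon":
            continue
        attrs = feature.attributes
        if "transcript_id" not in attrs:
            raise ParseError(f"{path}: exon feature without transcript_id (line {lineno})")
        if "gene_id" not in attrs:
            raise ParseError(f"{path}: exon feature without gene_id (line {lineno})")
        tid = attrs["transcript_id"][0]
        rec = exons.setdefault(
            tid,
            {
                "gene_id": attrs["gene_id"][0],
                "strand": feature.strand,
                "exons": [],
                "principal": False,
            },
        )
        rec["exons"].append(
            GenomicInterval(feature.seqid, feature.start - 1, feature.end, feature.strand)
        )
        for tag in attrs.get("tag", []):
            if tag.startswith("appris_principal"):
                rec["principal"] = True
    return [
        TranscriptModel(
            gene_id=rec["gene_id"],
            transcript_id=tid,
            strand=rec["strand"],
            exons=rec["exons"],
            principal=rec["principal"],
        )
        for tid, rec in exons.items()
    ]


def write_gtf(transcripts: Iterable[TranscriptModel], path: str | Path) -> None:
    """Write exon lines in Ensembl GTF dialect (1-based closed on disk)."""
    with open(path, "w") as fh:
        for t in transcripts:
            for ex in t.exons:
                attrs = f'gene_id "{t.gene_id}"; transcript_id "{t.transcript_id}";'
                if t.principal:
                    attrs += ' tag "appris_principal_1";'
                fh.write(
                    f"{ex.chrom}\tisochrom\texon\t{ex.start + 1}\t{ex.end}\t.\t"
                    f"{t.strand}\t.\t{attrs}\n"
                )


def read_principal_flags(path: str | Path) -> dict[str, bool]:
    """Read a two-column sidecar TSV (transcript_id, principal in {0,1,true,false})."""
    df = pd.read_csv(path, sep="\t", header=None, names=["transcript_id", "principal"])
    truthy = {"1", "true", "True", "TRUE", 1, True}
    return {
        str(r.transcript_id): (r.principal in truthy) for r in df.itertuples()
    }


# ---------------------------------------------------------------------------
# Counts


def read_counts(
    path: str | Path, conditions: Mapping[str, str]
) -> ExpressionMatrix:
    """Read a counts TSV (first column transcript_id, header of sample names)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    for col in df.columns:
        bad = pd.to_numeric(df[col], errors="coerce")
        if bad.isna().any():
            row = df.index[bad.isna().to_numpy().nonzero()[0][0]]
            raise DataError(
                f"{path}: non-numeric cell at row {row!r}, column {col!r}"
            )
        neg = bad < 0
        if neg.any():
            row = df.index[neg.to_numpy().nonzero()[0][0]]
            raise DataError(f"{path}: negative count at row {row!r}, column {col!r}")
    return ExpressionMatrix(df.astype(float), conditions, scale_tag="counts")


def write_counts(matrix: ExpressionMatrix, path: str | Path) -> None:
    out = matrix.values
    if matrix.scale_tag == "counts":
        out = out.astype(int)
    out.to_csv(path, sep="\t", index_label="transcript_id")


# ---------------------------------------------------------------------------
# BED peaks + signal


def read_bed_peaks(
    bed_path: str | Path,
    signal_path: str | Path,
    conditions: Mapping[str, str] | None = None,
) -> PeakSet:
    """Read BED3+ intervals and an aligned signal TSV (header = sample names).

    The signal table must have exactly one row per BED interval, in order
    (or keyed by a ``peak_id`` first column matching BED column 4).
    """
    ncols = min(6, _bed_ncols(bed_path))
    bed = pd.read_csv(
        bed_path, sep="\t", header=None, comment="#",
        names=["chrom", "start", "end", "name", "score", "strand"][:ncols],
        usecols=range(ncols),
    )
    sig = pd.read_csv(signal_path, sep="\t")
    if sig.columns[0] in ("peak_id", "name"):
        sig = sig.set_index(sig.columns[0])
    if len(sig) != len(bed):
        raise DataError(
            f"signal has {len(sig)} rows but BED has {len(bed)} peaks"
        )
    strands = bed["strand"] if "strand" in bed else ["."] * len(bed)
    peaks = [
        GenomicInterval(str(c), int(s), int(e), str(st))
        for c, s, e, st in zip(bed["chrom"], bed["start"], bed["end"], strands)
    ]
    ids = (
        [str(n) for n in bed["name"]]
        if "name" in bed
        else [f"peak_{i}" for i in range(len(bed))]
    )
    samples = list(sig.columns)
    return PeakSet(
        peaks=peaks,
        signal=sig.to_numpy(dtype=float),
        sample_labels=samples,
        peak_ids=ids,
    )


def _bed_ncols(path: str | Path) -> int:
    with open(path) as fh:
        for line in fh:
            if line.strip() and not line.startswith("#"):
                return len(line.rstrip("\n").split("\t"))
    return 3


def write_bed_peaks(peakset: PeakSet, bed_path: str | Path, signal_path: str | Path) -> None:
    with open(bed_path, "w") as fh:
        for pid, p in zip(peakset.peak_ids, peakset.peaks):
            fh.write(f"{p.chrom}\t{p.start}\t{p.end}\t{pid}\t0\t{p.strand}\n")
    pd.DataFrame(
        peakset.signal, index=pd.Index(peakset.peak_ids, name="peak_id"),
        columns=peakset.sample_labels,
    ).to_csv(signal_path, sep="\t")


# ---------------------------------------------------------------------------
# Junction-count tables (long format: event, sample, incl_up, incl_down, skip)

JUNCTION_COLUMNS = ["gene_id", "event_id", "sample", "incl_up", "incl_down", "skip"]


def read_junction_counts(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in JUNCTION_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: junction table missing columns {missing}")
    for col in ("incl_up", "incl_down", "skip"):
        if (df[col] < 0).any():
            raise DataError(f"{path}: negative junction count in column {col}")
    return df


def write_junction_counts(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False, columns=JUNCTION_COLUMNS)
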