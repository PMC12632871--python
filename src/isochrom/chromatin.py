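"""Promoter accessibility calls and differential peaks.

Peaks are assigned to genes by overlap with a window around the TSS
(default +/- 2 kb; the strand-aware 5' end of the gene's 5'-most transcript).
A gene's promoter is "open" in a sample when an assigned peak's normalized
signal reaches a threshold there; differential peaks follow a plain
fold-change-on-means rule (default: > 2-fold, with a +1 pseudo-count).
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from isochrom.errors import DataError
from isochrom.io import GenomicInterval, PeakSet, TranscriptModel


@dataclasses.dataclass
class PromoterCall:
    gene_id: str
    samples: list[str]
    status: list[str]          # "open"/"closed" per sample
    signal: np.ndarray         # per-sample signal of the representative peak
    peak_id: str | None        # None when the gene has no assigned peak

    def open_in(self, sample: str) -> bool:
        return self.status[self.samples.index(sample)] == "open"


def gene_tss(transcripts: Sequence[TranscriptModel]) -> dict[str, tuple[str, int, str]]:
    """Per gene: (chrom, TSS position, strand) of the gene's 5'-most transcript.

    For '+' genes the 5'-most transcript is the one with the smallest start;
    for '-' genes the one with the largest end.
    """
    out: dict[str, tuple[str, int, str]] = {}
    for t in transcripts:
        cur = out.get(t.gene_id)
        if cur is None:
            out[t.gene_id] = (t.chrom, t.tss(), t.strand)
        else:
            _, pos, strand = cur
            if (t.strand == "+" and t.tss() < pos) or (
                t.strand == "-" and t.tss() > pos
            ):
                out[t.gene_id] = (t.chrom, t.tss(), t.strand)
    return out


def annotate_peaks_to_promoters(
    peaks: PeakSet,
    transcripts: Sequence[TranscriptModel],
    window_bp: int = 2000,
) -> dict[str, list[str]]:
    """Map gene -> assigned peak ids.

    A peak is assigned when it overlaps [TSS - window, TSS + window); a peak
    may serve several genes; genes without any overlapping peak map to [].
    """
    tss = gene_tss(transcripts)
    mapping: dict[str, list[str]] = {g: [] for g in tss}
    for gene, (chrom, pos, _strand) in tss.items():
        win = GenomicInterval(chrom, max(0, pos - window_bp), pos + window_bp)
        for pid, peak in zip(peaks.peak_ids, peaks.peaks):
            if peak.overlaps(win):
                mapping[gene].append(pid)
    return mapping


def call_open_status(
    peaks: PeakSet,
    gene_peaks: Mapping[str, Sequence[str]],
    open_threshold: float | None = None,
) -> list[PromoterCall]:
    """Per-gene, per-sample open/closed promoter status.

    When a gene has several assigned peaks the max-mean-signal peak
    represents it.  status = open iff that peak's signal >= threshold in the
    sample; the default threshold is the median of nonzero peak signals.
    Genes without an assigned peak are closed everywhere.
    """
    sig = peaks.signal
    if open_threshold is None:
        nonzero = sig[sig > 0]
        open_threshold = float(np.median(nonzero)) if nonzero.size else 0.0
    index = {pid: i for i, pid in enumerate(peaks.peak_ids)}
    calls = []
    for gene in sorted(gene_peaks):
        pids = list(gene_peaks[gene])
        if not pids:
            calls.append(
                PromoterCall(
                    gene_id=gene,
                    samples=list(peaks.sample_labels),
                    status=["closed"] * len(peaks.sample_labels),
                    signal=np.zeros(len(peaks.sample_labels)),
                    peak_id=None,
                )
            )
            continue
        rows = [index[p] for p in pids]
        best = rows[int(np.argmax(sig[rows].mean(axis=1)))]
        s = sig[best]
        calls.append(
            PromoterCall(
                gene_id=gene,
                samples=list(peaks.sample_labels),
                status=["open" if v >= open_threshold else "closed" for v in s],
                signal=s.copy(),
                peak_id=peaks.peak_ids[best],
            )
        )
    return calls


def designate_de_peaks(
    peaks: PeakSet,
    condition_labels: Mapping[str, str],
    fold_threshold: float = 2.0,
    contrast: tuple[str, str] | None = None,
) -> dict[str, set[str]]:
    """Differential peaks by fold change on condition means.

    ratio = (mean(condition2) + 1) / (mean(condition1) + 1); pass
    ``contrast=(cond1, cond2)`` to fix the direction, else sorted label
    order; more_open iff ratio > fold_threshold, less_open iff
    ratio < 1/fold_threshold (both strict).
    """
    conds = list(contrast) if contrast else sorted(set(condition_labels.values()))
    if set(conds) != set(condition_labels.values()) or len(conds) != 2:
        raise DataError(f"need exactly 2 conditions matching labels, got {conds}")
    cols1 = [i for i, s in enumerate(peaks.sample_labels)
             if condition_labels[s] == conds[0]]
    cols2 = [i for i, s in enumerate(peaks.sample_labels)
             if condition_labels[s] == conds[1]]
    if not cols1 or not cols2:
        raise DataError("need >=1 sample per condition")
    m1 = peaks.signal[:, cols1].mean(axis=1) + 1.0
    m2 = peaks.signal[:, cols2].mean(axis=1) + 1.0
    ratio = m2 / m1
    more = {pid for pid, r in zip(peaks.peak_ids, ratio) if r > fold_threshold}
    less = {pid for pid, r in zip(peaks.peak_ids, ratio) if r < 1.0 / fold_threshold}
    return {"more_open": more, "less_open": less}


def promoter_call_table(calls: Sequence[PromoterCall]) -> pd.DataFrame:
    rows = []
    for c in calls:
        for s, st, v in zip(c.samples, c.status, c.signal):
            rows.append(
                {"gene_id": c.gene_id, "sample": s, "status": st,
                 "signal": v, "peak_id": c.peak_id or ""}
            )
    return pd.DataFrame(rows)
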