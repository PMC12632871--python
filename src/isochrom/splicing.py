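"""Alternative-splicing event classification and junction-based PSI.

Events are classified by pairwise comparison of a gene's transcript models
(SUPPA-style local events, not a full splice graph).  The seven canonical
classes are:

* ``SE`` — skipped (cassette) exon,
* ``A5`` / ``A3`` — alternative 5' donor / 3' acceptor splice site,
* ``AF`` / ``AL`` — alternative first / last exon,
* ``MX`` — mutually exclusive exons,
* ``RI`` — retained intron.

Classification runs on strand-oriented coordinates (the genome axis is
negated for minus-strand genes) so that donor/acceptor semantics follow the
transcript, not the reference.  Emitted junctions are reported in genomic
order as (upstream exon end, downstream exon start), 0-based half-open
boundaries — the keys a junction-count table naturally uses.

PSI (percent spliced in) for a skipped exon is estimated from the two
inclusion junctions and the skipping junction as

    psi = ((incl_up + incl_down) / 2) / ((incl_up + incl_down) / 2 + skip)

a deliberate simplification of full isoform-assignment machinery: the two
inclusion junctions are averaged, all junction reads are weighted equally.
"""

from __future__ import annotations

import dataclasses
import itertools
from math import comb
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from isochrom.errors import ConfigError, DataError
from isochrom.io import TranscriptModel

EVENT_TYPES = ("SE", "A5", "A3", "AF", "AL", "MX", "RI")

# (n_inclusion, n_exclusion) junction arithmetic per event type
_JUNCTION_ARITY = {
    "SE": (2, 1),
    "A5": (1, 1),
    "A3": (1, 1),
    "AF": (1, 1),
    "AL": (1, 1),
    "MX": (2, 2),
    "RI": (1, 0),
}

Junction = tuple[int, int]


@dataclasses.dataclass
class SpliceEvent:
    gene_id: str
    type: str
    inclusion_junctions: list[Junction]
    exclusion_junctions: list[Junction]
    involved_transcripts: tuple[frozenset, frozenset]
    chrom: str = "."
    strand: str = "+"

    def __post_init__(self) -> None:
        arity = _JUNCTION_ARITY[self.type]
        got = (len(self.inclusion_junctions), len(self.exclusion_junctions))
        if got != arity:
            raise DataError(
                f"{self.type} event needs {arity} (inclusion, exclusion) "
                f"junctions, got {got}"
            )

    @property
    def key(self) -> tuple:
        """Identity for de-duplication: type + junction sets."""
        return (
            self.gene_id,
            self.type,
            tuple(sorted(self.inclusion_junctions)),
            tuple(sorted(self.exclusion_junctions)),
        )

    @property
    def event_id(self) -> str:
        inc = ",".join(f"{d}-{a}" for d, a in sorted(self.inclusion_junctions))
        exc = ",".join(f"{d}-{a}" for d, a in sorted(self.exclusion_junctions))
        return f"{self.gene_id}:{self.type}:{inc}|{exc}"


@dataclasses.dataclass
class PsiEstimate:
    event_id: str
    samples: list[str]
    psi: np.ndarray           # nan where undefined
    counts: np.ndarray        # n_samples x 3 (incl_up, incl_down, skip)

    @property
    def defined(self) -> np.ndarray:
        return ~np.isnan(self.psi)


# ---------------------------------------------------------------------------
# classification


def _oriented_exons(t: TranscriptModel) -> list[tuple[int, int]]:
    """Exons as (start, end) on the transcript-oriented axis, 5' -> 3'."""
    if t.strand == "+":
        return [(e.start, e.end) for e in t.exons]
    return [(-e.end, -e.start) for e in reversed(t.exons)]


def _junctions(exons: Sequence[tuple[int, int]]) -> list[tuple[int, int]]:
    return [(a[1], b[0]) for a, b in zip(exons, exons[1:])]


def _overlap(a: tuple[int, int], b: tuple[int, int]) -> bool:
    return a[0] < b[1] and b[0] < a[1]


def _to_genomic(j: tuple[int, int], strand: str) -> Junction:
    return j if strand == "+" else (-j[1], -j[0])


def classify_events(transcripts: Sequence[TranscriptModel]) -> list[SpliceEvent]:
    """Classify alternative-splicing events among one gene's transcripts.

    Every unordered transcript pair is compared; duplicate events (same type
    and junction set) arising from different pairs are merged, with
    ``involved_transcripts`` accumulated.
    """
    if not transcripts:
        return []
    genes = {t.gene_id for t in transcripts}
    if len(genes) > 1:
        raise DataError(f"classify_events: multiple genes {sorted(genes)}")
    strands = {t.strand for t in transcripts}
    if len(strands) > 1:
        raise DataError(f"gene {transcripts[0].gene_id}: mixed strands")
    strand = transcripts[0].strand
    chrom = transcripts[0].chrom
    gene_id = transcripts[0].gene_id

    merged: dict[tuple, SpliceEvent] = {}
    for ta, tb in itertools.combinations(transcripts, 2):
        for ev in _pair_events(ta, tb, gene_id, strand, chrom):
            prev = merged.get(ev.key)
            if prev is None:
                merged[ev.key] = ev
            else:
                prev.involved_transcripts = (
                    prev.involved_transcripts[0] | ev.involved_transcripts[0],
                    prev.involved_transcripts[1] | ev.involved_transcripts[1],
                )
    return list(merged.values())


def _pair_events(
    ta: TranscriptModel,
    tb: TranscriptModel,
    gene_id: str,
    strand: str,
    chrom: str,
) -> Iterable[SpliceEvent]:
    A = _oriented_exons(ta)
    B = _oriented_exons(tb)
    jA, jB = _junctions(A), _junctions(B)
    jA_set, jB_set = set(jA), set(jB)

    def make(etype, incl, excl, incl_t, excl_t):
        return SpliceEvent(
            gene_id=gene_id,
            type=etype,
            inclusion_junctions=sorted(_to_genomic(j, strand) for j in incl),
            exclusion_junctions=sorted(_to_genomic(j, strand) for j in excl),
            involved_transcripts=(frozenset([incl_t]), frozenset([excl_t])),
            chrom=chrom,
            strand=strand,
        )

    # SE: internal exon of one transcript absent from the other, flanking
    # introns' outer splice sites shared (the other transcript carries the
    # direct donor->acceptor skipping junction).
    for (X, jX, tx), (Y, jY_set, ty) in (
        ((A, jA, ta), (B, jB_set, tb)),
        ((B, jB, tb), (A, jA_set, ta)),
    ):
        for i in range(1, len(X) - 1):
            e = X[i]
            if any(_overlap(e, y) for y in Y):
                continue
            d, a = jX[i - 1][0], jX[i][1]
            if (d, a) in jY_set:
                yield make(
                    "SE", [(d, e[0]), (e[1], a)], [(d, a)],
                    tx.transcript_id, ty.transcript_id,
                )

    # MX: one internal exon per transcript, mutually non-overlapping, shared
    # outer flanking splice sites, neither transcript containing both exons.
    for i in range(1, len(A) - 1):
        eA = A[i]
        if eA in B:
            continue
        dA, aA = jA[i - 1][0], jA[i][1]
        for k in range(1, len(B) - 1):
            eB = B[k]
            if eB in A or _overlap(eA, eB):
                continue
            dB, aB = jB[k - 1][0], jB[k][1]
            if (dA, aA) != (dB, aB):
                continue
            first, second = (ta, tb) if eA[0] <= eB[0] else (tb, ta)
            incl = [(dA, eA[0]), (eA[1], aA)] if eA[0] <= eB[0] else [(dB, eB[0]), (eB[1], aB)]
            excl = [(dB, eB[0]), (eB[1], aB)] if eA[0] <= eB[0] else [(dA, eA[0]), (eA[1], aA)]
            yield make(
                "MX", incl, excl, first.transcript_id, second.transcript_id
            )

    # RI: an exon of one transcript spans a junction of the other with both
    # splice sites strictly internal to the exon.
    for (X, ty_junc, tx, ty) in (
        (A, jB, ta, tb),
        (B, jA, tb, ta),
    ):
        for (d, a) in ty_junc:
            for (s, e) in X:
                if s < d and a < e:
                    # inclusion junction belongs to the spliced transcript
                    yield make("RI", [(d, a)], [], ty.transcript_id, tx.transcript_id)

    # A5 / A3: shared intron boundary on one side, differing donor (A5) or
    # acceptor (A3) on the other, with the alternative exons overlapping
    # (non-overlap means AF/AL territory).
    exonA_by_end = {e[1]: e for e in A}
    exonA_by_start = {e[0]: e for e in A}
    exonB_by_end = {e[1]: e for e in B}
    exonB_by_start = {e[0]: e for e in B}
    for (d1, a1) in jA:
        for (d2, a2) in jB:
            if a1 == a2 and d1 != d2:
                if _overlap(exonA_by_end[d1], exonB_by_end[d2]):
                    # the longer exonic form (3'-shifted donor) is "inclusion"
                    incl, excl = ((d1, a1), (d2, a2)) if d1 > d2 else ((d2, a2), (d1, a1))
                    it, et = (ta, tb) if d1 > d2 else (tb, ta)
                    yield make("A5", [incl], [excl], it.transcript_id, et.transcript_id)
            if d1 == d2 and a1 != a2:
                if _overlap(exonA_by_start[a1], exonB_by_start[a2]):
                    incl, excl = ((d1, a1), (d2, a2)) if a1 < a2 else ((d2, a2), (d1, a1))
                    it, et = (ta, tb) if a1 < a2 else (tb, ta)
                    yield make("A3", [incl], [excl], it.transcript_id, et.transcript_id)

    # AF / AL: differing, non-overlapping first/last exon whose junction into
    # the shared body lands on the same acceptor (AF) / leaves the same donor (AL).
    if len(A) > 1 and len(B) > 1:
        fA, fB = A[0], B[0]
        if not _overlap(fA, fB) and jA[0][1] == jB[0][1] and jA[0][0] != jB[0][0]:
            first, second = (ta, tb) if fA[0] <= fB[0] else (tb, ta)
            incl, excl = (jA[0], jB[0]) if fA[0] <= fB[0] else (jB[0], jA[0])
            yield make("AF", [incl], [excl], first.transcript_id, second.transcript_id)
        lA, lB = A[-1], B[-1]
        if not _overlap(lA, lB) and jA[-1][0] == jB[-1][0] and jA[-1][1] != jB[-1][1]:
            first, second = (ta, tb) if lA[1] >= lB[1] else (tb, ta)
            incl, excl = (jA[-1], jB[-1]) if lA[1] >= lB[1] else (jB[-1], jA[-1])
            yield make("AL", [incl], [excl], first.transcript_id, second.transcript_id)


def event_type_proportions(
    events: Sequence[SpliceEvent],
) -> tuple[dict[str, float], bool]:
    """Fraction of events per type.

    Returns ``(fractions, empty)``; on an empty event list all fractions are
    zero and the flag is True.
    """
    counts = {t: 0 for t in EVENT_TYPES}
    for ev in events:
        counts[ev.type] += 1
    n = len(events)
    if n == 0:
        return {t: 0.0 for t in EVENT_TYPES}, True
    return {t: c / n for t, c in counts.items()}, False


# ---------------------------------------------------------------------------
# PSI


def compute_psi(
    counts: np.ndarray | Sequence[Sequence[int]],
    samples: Sequence[str] | None = None,
    event_id: str = "",
) -> PsiEstimate:
    """PSI per sample from (incl_up, incl_down, skip) junction counts.

    psi = mean(inclusion junctions) / (mean(inclusion junctions) + skip).
    Undefined (NaN, flagged) when all three counts are zero.
    """
    arr = np.asarray(counts, dtype=float)
    if arr.ndim == 1:
        arr = arr[None, :]
    if arr.shape[1] != 3:
        raise DataError("counts must have 3 columns (incl_up, incl_down, skip)")
    if np.any(arr < 0):
        raise DataError("negative junction count")
    if not np.allclose(arr, np.round(arr)):
        raise DataError("junction counts must be integers")
    incl = (arr[:, 0] + arr[:, 1]) / 2.0
    denom = incl + arr[:, 2]
    with np.errstate(invalid="ignore", divide="ignore"):
        psi = np.where(denom > 0, incl / np.where(denom > 0, denom, 1.0), np.nan)
    if samples is None:
        samples = [f"s{i}" for i in range(arr.shape[0])]
    return PsiEstimate(
        event_id=event_id, samples=list(samples), psi=psi, counts=arr.astype(int)
    )


def psi_table(
    junction_counts: pd.DataFrame,
) -> pd.DataFrame:
    """Wide PSI table (event x sample) from a long junction-count table."""
    rows = []
    for (gene, event), grp in junction_counts.groupby(
        ["gene_id", "event_id"], sort=True
    ):
        est = compute_psi(
            grp[["incl_up", "incl_down", "skip"]].to_numpy(),
            samples=list(grp["sample"]),
            event_id=str(event),
        )
        for s, v in zip(est.samples, est.psi):
            rows.append({"gene_id": gene, "event_id": event, "sample": s, "psi": v})
    long = pd.DataFrame(rows)
    return long.pivot(index="event_id", columns="sample", values="psi")


# ---------------------------------------------------------------------------
# differential PSI


_EXHAUSTIVE_LIMIT = 10_000


def differential_psi(
    psi_matrix: pd.DataFrame,
    condition_labels: dict[str, str],
    n_permutations: int = 10_000,
    seed: int | None = None,
    contrast: tuple[str, str] | None = None,
) -> pd.DataFrame:
    """Per-event (delta PSI, permutation p) between two conditions.

    delta = mean(condition 2) - mean(condition 1); pass ``contrast=(cond1,
    cond2)`` to fix the direction, else conditions are taken in sorted label
    order.  The permutation p-value is the fraction of relabelled
    group assignments whose |delta| is at least |delta_obs|; assignments are
    enumerated exhaustively when their number is <= 10,000, otherwise sampled
    with add-one smoothing.  Events with fewer than two defined PSI values in
    either condition are flagged skipped.
    """
    conds = list(contrast) if contrast else sorted(set(condition_labels.values()))
    if set(conds) != set(condition_labels.values()) or len(conds) != 2:
        raise DataError(f"need exactly 2 conditions matching labels, got {conds}")
    if seed is None and n_permutations and _needs_sampling(psi_matrix, condition_labels):
        raise ConfigError("seed required for Monte-Carlo permutations")
    rng = np.random.default_rng(seed)
    out = []
    for event_id, row in psi_matrix.iterrows():
        samples = [s for s in psi_matrix.columns if not np.isnan(row[s])]
        g1 = [row[s] for s in samples if condition_labels[s] == conds[0]]
        g2 = [row[s] for s in samples if condition_labels[s] == conds[1]]
        if len(g1) < 2 or len(g2) < 2:
            out.append(
                {"event_id": event_id, "delta_psi": np.nan, "p": np.nan,
                 "flag": "skipped_too_few_defined"}
            )
            continue
        delta, p = _permutation_test(
            np.array(g1, dtype=float), np.array(g2, dtype=float),
            n_permutations, rng,
        )
        out.append({"event_id": event_id, "delta_psi": delta, "p": p, "flag": "ok"})
    return pd.DataFrame(out).set_index("event_id")


def _needs_sampling(psi_matrix, condition_labels) -> bool:
    n = len(psi_matrix.columns)
    n1 = sum(1 for s in psi_matrix.columns
             if condition_labels[s] == sorted(set(condition_labels.values()))[0])
    return comb(n, n1) > _EXHAUSTIVE_LIMIT


def _permutation_test(
    g1: np.ndarray, g2: np.ndarray, n_permutations: int, rng: np.random.Generator
) -> tuple[float, float]:
    pooled = np.concatenate([g1, g2])
    n1 = len(g1)
    obs = g2.mean() - g1.mean()
    tol = 1e-12
    n_total = comb(len(pooled), n1)
    if n_total <= _EXHAUSTIVE_LIMIT:
        count = 0
        for idx in itertools.combinations(range(len(pooled)), n1):
            mask = np.zeros(len(pooled), dtype=bool)
            mask[list(idx)] = True
            d = pooled[~mask].mean() - pooled[mask].mean()
            if abs(d) >= abs(obs) - tol:
                count += 1
        return float(obs), count / n_total
    count = 0
    for _ in range(n_permutations):
        perm = rng.permutation(pooled)
        d = perm[n1:].mean() - perm[:n1].mean()
        if abs(d) >= abs(obs) - tol:
            count += 1
    return float(obs), (count + 1) / (n_permutations + 1)


def sashimi_text(
    event: SpliceEvent, junction_counts: pd.DataFrame
) -> str:
    """Plain-text junction summary for one event (stand-in for a sashimi plot)."""
    grp = junction_counts[junction_counts["event_id"] == event.event_id]
    lines = [f"# {event.event_id} ({event.type}, {event.chrom}, strand {event.strand})"]
    lines.append("junction\trole\t" + "\t".join(grp["sample"]))
    roles = [("incl_up", "inclusion"), ("incl_down", "inclusion"), ("skip", "skipping")]
    juncs = list(event.inclusion_junctions) + list(event.exclusion_junctions)
    for (col, role), j in zip(roles, juncs + [None] * (3 - len(juncs))):
        if j is None:
            continue
        counts = "\t".join(str(int(c)) for c in grp[col])
        lines.append(f"{j[0]}-{j[1]}\t{role}\t{counts}")
    return "\n".join(lines) + "\n"
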