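"""Synthetic two-condition data with known ground truth.

Emulates a wildtype vs transgenic bulk design (default 3 replicates per
condition): transcript annotation with planted alternative-splicing events,
negative-binomial isoform counts with planted differential isoforms
(including non-principal-isoform switches), binomial junction reads with
planted PSI shifts, promoter accessibility signals with planted coordinated
open+up / closed+down genes, and background sequence with planted
occurrences of a 21-bp RE1-like motif.

All generators are deterministic given the master seed: each derives its own
random stream by stable hashing of its name, so adding a generator never
perturbs the others.  The ground truth returned alongside each output is
sufficient to score the corresponding downstream stage.
"""

from __future__ import annotations

import dataclasses
import zlib
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from isochrom.errors import ConfigError
from isochrom.io import (
    ExpressionMatrix,
    GenomicInterval,
    PeakSet,
    TranscriptModel,
)
from isochrom.motif import MotifPWM
from isochrom.splicing import EVENT_TYPES, SpliceEvent, classify_events

CONDITIONS = ("wildtype", "transgenic")

# default planted event mix: the canonical field proportions for a
# differential-alternative-transcript signature (fractions of all genes;
# the remainder are single-transcript genes with no event)
DEFAULT_EVENT_MIX = {
    "AF": 0.27, "A5": 0.23, "SE": 0.22, "A3": 0.13,
    "RI": 0.08, "AL": 0.05, "MX": 0.01,
}

_GENE_SPAN = 10_000  # bp reserved per gene on the synthetic chromosome


@dataclasses.dataclass
class SimulationConfig:
    n_genes: int = 200
    n_replicates_per_condition: int = 3
    planted_event_mix: dict[str, float] = dataclasses.field(
        default_factory=lambda: dict(DEFAULT_EVENT_MIX)
    )
    planted_de_fraction: float = 0.1
    de_log2_effect: float = 2.0
    planted_psi_pair: tuple[float, float] = (0.02, 0.25)
    nb_dispersion: float = 0.1
    coordination_fraction: float = 0.1
    coordination_log2_effect: float = 2.0
    atac_fold: float = 4.0
    atac_noise_sigma: float = 0.3
    junction_depth: float = 2000.0
    motif_insertion_rate: float = 0.05   # motifs per kb
    sequence_length: int = 1_000_000
    gc_content: float = 0.42
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("planted_de_fraction", "coordination_fraction", "gc_content"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ConfigError(f"{name} must be in [0, 1], got {v}")
        bad = set(self.planted_event_mix) - set(EVENT_TYPES)
        if bad:
            raise ConfigError(f"unknown event types in mix: {sorted(bad)}")
        if any(f < 0 for f in self.planted_event_mix.values()):
            raise ConfigError("event-mix fractions must be >= 0")
        if sum(self.planted_event_mix.values()) > 1 + 1e-9:
            raise ConfigError("event-mix fractions must sum to <= 1")
        if self.nb_dispersion < 0:
            raise ConfigError("nb_dispersion must be >= 0")
        for psi in self.planted_psi_pair:
            if not (0 <= psi <= 1):
                raise ConfigError(f"planted PSI {psi} outside [0, 1]")
        if self.n_replicates_per_condition < 1:
            raise ConfigError("need >= 1 replicate per condition")

    @property
    def samples(self) -> list[str]:
        return [
            f"{cond}_{i + 1}"
            for cond in CONDITIONS
            for i in range(self.n_replicates_per_condition)
        ]

    @property
    def condition_labels(self) -> dict[str, str]:
        return {s: s.rsplit("_", 1)[0] for s in self.samples}

    def stream(self, name: str) -> np.random.Generator:
        """Independent, deterministic random stream per generator name."""
        key = zlib.crc32(name.encode())
        return np.random.default_rng(
            np.random.SeedSequence(entropy=int(self.seed), spawn_key=(key,))
        )


@dataclasses.dataclass
class GroundTruth:
    de_isoforms: set = dataclasses.field(default_factory=set)
    alt_switch_genes: set = dataclasses.field(default_factory=set)
    event_catalog: list = dataclasses.field(default_factory=list)  # (gene, type)
    psi_truth: dict = dataclasses.field(default_factory=dict)      # gene -> (psi1, psi2)
    coordinated_genes: dict = dataclasses.field(default_factory=dict)  # gene -> class
    motif_positions: list = dataclasses.field(default_factory=list)    # (chrom, start, strand)


# ---------------------------------------------------------------------------
# annotation


def _allocate_event_types(config: SimulationConfig) -> list[str | None]:
    """Largest-remainder allocation of event types to genes (deterministic)."""
    n = config.n_genes
    mix = config.planted_event_mix
    exact = {t: mix.get(t, 0.0) * n for t in EVENT_TYPES}
    counts = {t: int(np.floor(v)) for t, v in exact.items()}
    leftover = int(round(sum(mix.values()) * n)) - sum(counts.values())
    order = sorted(EVENT_TYPES, key=lambda t: exact[t] - counts[t], reverse=True)
    for t in order[:leftover]:
        counts[t] += 1
    types: list[str | None] = []
    for t in EVENT_TYPES:
        types.extend([t] * counts[t])
    types.extend([None] * (n - len(types)))
    return types


# exon templates per event type, on the + strand, coordinates relative to the
# gene start; each is (transcript1 exons, transcript2 exons) and the pair
# realises exactly one event of the named type
_TEMPLATES: dict[str, tuple[list, list]] = {
    "SE": ([(0, 150), (450, 600), (900, 1050)], [(0, 150), (900, 1050)]),
    "RI": ([(0, 150), (450, 600)], [(0, 600)]),
    "A5": ([(0, 210), (450, 600)], [(0, 150), (450, 600)]),
    "A3": ([(0, 150), (390, 600)], [(0, 150), (450, 600)]),
    "AF": ([(0, 150), (600, 750)], [(250, 400), (600, 750)]),
    "AL": ([(0, 150), (450, 600)], [(0, 150), (700, 850)]),
    "MX": (
        [(0, 150), (450, 600), (1000, 1150)],
        [(0, 150), (700, 850), (1000, 1150)],
    ),
    "null3": ([(0, 150), (450, 600), (900, 1050)], None),
}

# minimum number of exons the geometry of each event type requires
_MIN_EXONS = {"SE": 3, "RI": 2, "A5": 2, "A3": 2, "AF": 2, "AL": 2, "MX": 3}


def generate_annotation(
    config: SimulationConfig,
) -> tuple[list[TranscriptModel], GroundTruth]:
    """Annotation with, per planted gene, the minimal transcript pair
    realising its event type.  Strand is random per gene; minus-strand
    templates are mirrored within the gene span so the transcript-oriented
    event type is preserved.  Deterministic given the seed.
    """
    rng = config.stream("annotation")
    types = _allocate_event_types(config)
    truth = GroundTruth()
    transcripts: list[TranscriptModel] = []
    for i, etype in enumerate(types):
        gene = f"gene{i:05d}"
        start = i * _GENE_SPAN
        strand = "+" if rng.random() < 0.5 else "-"
        key = etype if etype is not None else "null3"
        t1_rel, t2_rel = _TEMPLATES[key]
        mirror_span = max(
            e for rel in (t1_rel, t2_rel) if rel is not None for _, e in rel
        )
        for k, rel in enumerate((t1_rel, t2_rel)):
            if rel is None:
                continue
            if strand == "-":
                rel = sorted((mirror_span - e, mirror_span - s) for s, e in rel)
            exons = [
                GenomicInterval("chrS", start + s, start + e, strand)
                for s, e in rel
            ]
            transcripts.append(
                TranscriptModel(
                    gene_id=gene,
                    transcript_id=f"{gene}.t{k + 1}",
                    strand=strand,
                    exons=exons,
                    principal=(k == 0),
                )
            )
        if etype is not None:
            truth.event_catalog.append((gene, etype))
            if etype == "SE":
                truth.psi_truth[gene] = tuple(config.planted_psi_pair)
    return transcripts, truth


# ---------------------------------------------------------------------------
# counts


def _coordination_assignment(
    gene_ids: Sequence[str], config: SimulationConfig
) -> dict[str, str]:
    """Deterministic gene -> {open_up, closed_down, null} assignment.

    Shared by the counts and accessibility generators so their planted
    effects agree on the same genes.
    """
    rng = config.stream("coordination")
    n = len(gene_ids)
    n_coord = int(round(config.coordination_fraction * n))
    chosen = rng.choice(n, size=n_coord, replace=False)
    classes = {g: "null" for g in gene_ids}
    for j, idx in enumerate(sorted(chosen)):
        classes[gene_ids[idx]] = "open_up" if j % 2 == 0 else "closed_down"
    return classes


def generate_counts(
    annotation: Sequence[TranscriptModel],
    config: SimulationConfig,
) -> tuple[ExpressionMatrix, GroundTruth]:
    """Negative-binomial isoform counts with planted effects.

    Gene base means are log-uniform in [20, 2000] and split across the
    gene's isoforms.  A ``planted_de_fraction`` of genes receives the
    configured log2 effect in the transgenic condition, applied to a
    non-principal transcript whenever the gene has one (alternative-isoform
    switch genes).  Coordinated genes additionally receive a gene-level
    shift matching their accessibility class.  Variance model:
    mu + dispersion * mu^2 (Poisson at dispersion 0).
    """
    if config.n_replicates_per_condition < 1:
        raise ConfigError("zero replicates")
    rng = config.stream("counts")
    truth = GroundTruth()
    genes: dict[str, list[TranscriptModel]] = {}
    for t in annotation:
        genes.setdefault(t.gene_id, []).append(t)
    gene_ids = sorted(genes)
    coord = _coordination_assignment(gene_ids, config)
    truth.coordinated_genes = coord

    n_de = int(round(config.planted_de_fraction * len(gene_ids)))
    de_genes = set(
        gene_ids[i] for i in rng.choice(len(gene_ids), size=n_de, replace=False)
    )

    samples = config.samples
    n_rep = config.n_replicates_per_condition
    rows = []
    index = []
    for gene in gene_ids:
        txs = genes[gene]
        base = float(np.exp(rng.uniform(np.log(20.0), np.log(2000.0))))
        split = rng.dirichlet(np.full(len(txs), 5.0))
        planted_tx = None
        if gene in de_genes:
            non_principal = [t for t in txs if not t.principal]
            planted_tx = (non_principal[0] if non_principal else txs[0]).transcript_id
            truth.de_isoforms.add(planted_tx)
            if non_principal:
                truth.alt_switch_genes.add(gene)
        gene_shift = {"open_up": config.coordination_log2_effect,
                      "closed_down": -config.coordination_log2_effect,
                      "null": 0.0}[coord[gene]]
        for t, frac in zip(txs, split):
            mu_wt = base * frac
            mu_tg = mu_wt * 2.0 ** gene_shift
            if t.transcript_id == planted_tx:
                mu_tg *= 2.0 ** config.de_log2_effect
            mus = [mu_wt] * n_rep + [mu_tg] * n_rep
            counts = [_nb_draw(rng, m, config.nb_dispersion) for m in mus]
            rows.append(counts)
            index.append(t.transcript_id)
    df = pd.DataFrame(rows, index=index, columns=samples, dtype=float)
    return (
        ExpressionMatrix(df, config.condition_labels, scale_tag="counts"),
        truth,
    )


def _nb_draw(rng: np.random.Generator, mu: float, alpha: float) -> int:
    if alpha <= 0:
        return int(rng.poisson(mu))
    n = 1.0 / alpha
    p = n / (n + mu)
    return int(rng.negative_binomial(n, p))


# ---------------------------------------------------------------------------
# junction counts


def generate_junction_counts(
    events: Sequence[SpliceEvent],
    psi_truth: Mapping[str, tuple[float, float]],
    config: SimulationConfig,
    depth: float | None = None,
) -> pd.DataFrame:
    """Binomial junction reads for skipped-exon events.

    Per sample, the junction total is Poisson(depth); the skipping junction
    is Binomial(total, 1 - psi) and each inclusion junction Binomial(total,
    psi), so the PSI estimator recovers psi in expectation.  psi is the
    condition-1 value for wildtype samples and the condition-2 value for
    transgenic samples.
    """
    depth = config.junction_depth if depth is None else depth
    rng = config.stream("junctions")
    rows = []
    for ev in events:
        if ev.type != "SE":
            continue
        pair = psi_truth.get(ev.gene_id)
        if pair is None:
            continue
        for psi, cond in zip(pair, CONDITIONS):
            if not (0 <= psi <= 1):
                raise ConfigError(f"psi {psi} outside [0, 1]")
            for i in range(config.n_replicates_per_condition):
                total = int(rng.poisson(depth))
                rows.append(
                    {
                        "gene_id": ev.gene_id,
                        "event_id": ev.event_id,
                        "sample": f"{cond}_{i + 1}",
                        "incl_up": int(rng.binomial(total, psi)),
                        "incl_down": int(rng.binomial(total, psi)),
                        "skip": int(rng.binomial(total, 1.0 - psi)),
                    }
                )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# accessibility


def generate_atac(
    annotation: Sequence[TranscriptModel],
    config: SimulationConfig,
) -> tuple[PeakSet, GroundTruth]:
    """One promoter peak per gene with planted coordination classes.

    open_up genes: transgenic signal raised by ``atac_fold`` (clears the
    2-fold rule); closed_down: lowered by the same factor; null genes have
    no systematic shift.  Log-normal multiplicative noise throughout.

    Coordinated genes draw their baseline from the low (open_up) or high
    (closed_down) end of the signal range so that their wildtype and
    transgenic samples land on opposite sides of the open-status threshold
    (median signal) — i.e. the planted pattern really is closed-then-open
    (or open-then-closed) chromatin, not just a fold change.
    """
    from isochrom.chromatin import gene_tss

    rng = config.stream("atac")
    tss = gene_tss(annotation)
    gene_ids = sorted(tss)
    coord = _coordination_assignment(gene_ids, config)
    truth = GroundTruth(coordinated_genes=coord)

    n_rep = config.n_replicates_per_condition
    peaks, ids, signal = [], [], []
    for gene in gene_ids:
        chrom, pos, _ = tss[gene]
        peaks.append(GenomicInterval(chrom, max(0, pos - 250), pos + 250))
        ids.append(f"peak_{gene}")
        lo, hi = {
            "null": (20.0, 200.0),
            "open_up": (20.0, 50.0),       # closed in WT, opened by the fold
            "closed_down": (80.0, 200.0),  # open in WT, closed by the fold
        }[coord[gene]]
        base = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
        fold = {"open_up": config.atac_fold,
                "closed_down": 1.0 / config.atac_fold,
                "null": 1.0}[coord[gene]]
        noise = rng.lognormal(0.0, config.atac_noise_sigma, size=2 * n_rep)
        means = np.array([base] * n_rep + [base * fold] * n_rep)
        signal.append(means * noise)
    peakset = PeakSet(
        peaks=peaks,
        signal=np.array(signal),
        sample_labels=config.samples,
        peak_ids=ids,
    )
    return peakset, truth


# ---------------------------------------------------------------------------
# sequences


def re1_like_pwm(information: float = 0.9) -> MotifPWM:
    """Synthetic 21-bp RE1-like matrix (repressor-element-1 consensus shape).

    Built from a canonical 21-bp consensus with the stated probability on
    the consensus base per column; a constructed stand-in, not a database
    matrix.
    """
    consensus = "TTCAGCACCACGGACAGCGCC"
    probs = np.full((4, len(consensus)), (1.0 - information) / 3.0)
    for j, b in enumerate(consensus):
        probs["ACGT".index(b), j] = information
    return MotifPWM(id="RE1_synthetic", counts=probs * 1000.0)


def generate_sequences(
    config: SimulationConfig,
    pwm: MotifPWM | None = None,
    exact_consensus: bool = False,
) -> tuple[dict[str, str], GroundTruth]:
    """Background sequence with motif occurrences planted at recorded positions.

    i.i.d. background at the configured GC content; insertion sites are
    sampled without overlap at ``motif_insertion_rate`` per kb; each
    insertion is sampled from the PWM (or its exact consensus) on a random
    strand.  Returns {chrom: sequence} and the ground-truth positions.
    """
    pwm = pwm or re1_like_pwm()
    rng = config.stream("sequences")
    L, w = config.sequence_length, pwm.width
    n_sites = int(round(config.motif_insertion_rate * L / 1000.0))
    if n_sites * 2 * w > L:
        raise ConfigError(
            f"insertion rate {config.motif_insertion_rate}/kb too high to "
            f"avoid overlap on {L} bp"
        )
    gc = config.gc_content
    base_p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    seq = rng.choice(np.array(list("ACGT")), size=L, p=base_p)

    # non-overlapping positions: sample slots on a 2w grid
    n_slots = L // (2 * w)
    slots = rng.choice(n_slots, size=n_sites, replace=False)
    truth = GroundTruth()
    probs = pwm.probabilities
    for slot in sorted(slots):
        start = int(slot * 2 * w)
        strand = "+" if rng.random() < 0.5 else "-"
        if exact_consensus:
            ins = pwm.consensus()
        else:
            ins = "".join(
                "ACGT"[rng.choice(4, p=probs[:, j])] for j in range(w)
            )
        if strand == "-":
            ins = _revcomp(ins)
        seq[start: start + w] = list(ins)
        truth.motif_positions.append(("chrS", start, strand))
    return {"chrS": "".join(seq)}, truth


_COMP = str.maketrans("ACGT", "TGCA")


def _revcomp(s: str) -> str:
    return s.translate(_COMP)[::-1]


# ---------------------------------------------------------------------------
# TF target sets (for exercising the enrichment stage end-to-end)


def generate_target_sets(
    gene_ids: Sequence[str],
    coordinated_genes: Mapping[str, str],
    config: SimulationConfig,
    n_tfs: int = 20,
    enriched_tf: str = "TF_planted",
) -> "TargetSets":
    """Synthetic TF target sets over the gene universe.

    One planted TF targets most coordinated genes (so enrichment against the
    coordinated set is real); the remaining TFs draw targets uniformly.
    """
    from isochrom.motif import TargetSets

    rng = config.stream("targets")
    universe = set(gene_ids)
    coord = [g for g in gene_ids if coordinated_genes.get(g, "null") != "null"]
    sets: dict[str, set] = {}
    planted = set(
        g for g in coord if rng.random() < 0.8
    ) | set(
        np.asarray(gene_ids)[rng.choice(len(gene_ids), size=max(1, len(gene_ids) // 20), replace=False)]
    )
    sets[enriched_tf] = planted
    for i in range(n_tfs - 1):
        size = int(rng.integers(max(2, len(gene_ids) // 20), max(3, len(gene_ids) // 5)))
        members = rng.choice(len(gene_ids), size=size, replace=False)
        sets[f"TF_{i:03d}"] = {gene_ids[j] for j in members}
    return TargetSets(sets=sets, universe=universe)


# ---------------------------------------------------------------------------
# convenience: classify the generated annotation (construction oracle)


def planted_events(
    annotation: Sequence[TranscriptModel],
) -> list[SpliceEvent]:
    """Classify each generated gene's transcripts (used to key junction tables)."""
    genes: dict[str, list[TranscriptModel]] = {}
    for t in annotation:
        genes.setdefault(t.gene_id, []).append(t)
    events: list[SpliceEvent] = []
    for gene in sorted(genes):
        events.extend(classify_events(genes[gene]))
    return events
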