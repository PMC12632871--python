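"""PWM motif scanning with exact DP p-values, and TF-target enrichment.

Scores are log2 odds (bits) of motif vs a 0-order background.  P-values come
from the exact distribution of the score under the background model,
computed by dynamic programming: per-column scores are discretized onto an
integer grid and the distribution of their sum is built by convolution
across columns.  Scanning uses the same integer grid, so a scanned window's
p-value is exactly the DP survival value of its integer score (the only
approximation is the discretization itself, with absolute score error
bounded by width / scale).

Multiple testing across scanned windows is controlled by Benjamini-Hochberg;
TF-target overlap is tested with the upper-tail hypergeometric against an
explicit, caller-supplied gene universe.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from Bio import motifs as bio_motifs
from scipy import stats
from statsmodels.stats.multitest import multipletests

from isochrom.errors import ConfigError, DataError
from isochrom.io import TranscriptModel

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}


@dataclasses.dataclass
class MotifPWM:
    """Position weight matrix with background model.

    ``counts`` is a 4 x width matrix over rows A, C, G, T (counts or
    probabilities; a pseudocount is added before normalisation either way).
    """

    id: str
    counts: np.ndarray
    pseudocount: float = 0.1
    background: np.ndarray = dataclasses.field(
        default_factory=lambda: np.full(4, 0.25)
    )

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.shape[0] != 4 or self.counts.shape[1] < 1:
            raise DataError("counts must be 4 x width with width >= 1")
        if self.pseudocount <= 0:
            raise ConfigError("pseudocount must be > 0")
        self.background = np.asarray(self.background, dtype=float)
        if not np.isclose(self.background.sum(), 1.0):
            raise DataError("background probabilities must sum to 1")

    @property
    def width(self) -> int:
        return self.counts.shape[1]

    @property
    def probabilities(self) -> np.ndarray:
        p = self.counts + self.pseudocount
        return p / p.sum(axis=0, keepdims=True)

    @property
    def log_odds(self) -> np.ndarray:
        """4 x width log2(p_col(base) / background(base))."""
        return np.log2(self.probabilities / self.background[:, None])

    def consensus(self) -> str:
        return "".join(BASES[i] for i in np.argmax(self.probabilities, axis=0))

    def reverse_complement(self) -> "MotifPWM":
        # background is complemented too, so rc.log_odds == log_odds[::-1, ::-1]
        return MotifPWM(
            id=self.id + "_rc",
            counts=self.counts[::-1, ::-1].copy(),
            pseudocount=self.pseudocount,
            background=self.background[::-1].copy(),
        )


@dataclasses.dataclass
class MotifHit:
    chrom: str
    start: int          # 0-based, forward strand
    strand: str
    score: float        # log2-odds bits
    p: float
    q: float = np.nan


@dataclasses.dataclass
class TargetSets:
    sets: dict[str, set]
    universe: set

    def __post_init__(self) -> None:
        for tf, genes in self.sets.items():
            extra = set(genes) - self.universe
            if extra:
                raise DataError(
                    f"target set {tf!r} has genes outside the universe: "
                    f"{sorted(extra)[:5]}"
                )


# ---------------------------------------------------------------------------
# motif file formats (via Bio.motifs)


def read_jaspar(path: str | Path, **pwm_kwargs) -> list[MotifPWM]:
    with open(path) as fh:
        parsed = bio_motifs.parse(fh, "jaspar")
    return [_from_bio(m, **pwm_kwargs) for m in parsed]


def read_meme(path: str | Path, **pwm_kwargs) -> list[MotifPWM]:
    with open(path) as fh:
        parsed = bio_motifs.parse(fh, "minimal")
    return [_from_bio(m, **pwm_kwargs) for m in parsed]


def _from_bio(m, **pwm_kwargs) -> MotifPWM:
    counts = np.array([list(m.counts[b]) for b in BASES], dtype=float)
    name = getattr(m, "matrix_id", None) or m.name or "motif"
    return MotifPWM(id=str(name), counts=counts, **pwm_kwargs)


# ---------------------------------------------------------------------------
# exact score p-values by DP


class ScoreDistribution:
    """Discretized exact null distribution of the PWM score.

    Column scores are shifted to be non-negative and scaled onto an integer
    grid with `bins` total levels; the distribution of the integer sum under
    the background is built by convolution.  ``pvalue_of_window`` and the
    scanner share the integer representation, so scanning p-values are the
    DP values exactly.
    """

    def __init__(self, pwm: MotifPWM, discretization_bins: int = 10_000) -> None:
        if discretization_bins < 100:
            raise ConfigError("discretization_bins must be >= 100")
        lo = pwm.log_odds
        self.offsets = lo.min(axis=0)                  # per-column minimum
        shifted = lo - self.offsets[None, :]
        total_range = shifted.max(axis=0).sum()
        self.scale = (discretization_bins - 1) / total_range if total_range > 0 else 1.0
        self.int_scores = np.rint(shifted * self.scale).astype(np.int64)
        max_total = int(self.int_scores.max(axis=0).sum())
        pmf = np.zeros(max_total + 1)
        pmf[0] = 1.0
        bg = pwm.background
        for j in range(pwm.width):
            nxt = np.zeros_like(pmf)
            for b in range(4):
                s = self.int_scores[b, j]
                nxt[s:] += bg[b] * pmf[: len(pmf) - s if s else None]
            pmf = nxt
        self.pmf = pmf
        # survival: P(S >= s)
        self.sf = np.cumsum(pmf[::-1])[::-1]
        self.min_p = float(self.sf[-1])

    def int_score(self, base_indices: Sequence[int]) -> int:
        return int(
            sum(self.int_scores[b, j] for j, b in enumerate(base_indices))
        )

    def pvalue_of_int(self, s: int) -> float:
        if s <= 0:
            return 1.0
        if s >= len(self.sf):
            return self.min_p
        return float(self.sf[s])

    def real_to_int(self, score: float) -> int:
        return int(np.rint((score - self.offsets.sum()) * self.scale))

    def pvalue(self, score: float) -> float:
        """P(score >= s) under the background, via the integer grid."""
        return self.pvalue_of_int(self.real_to_int(score))


def score_pvalue_table(
    pwm: MotifPWM, discretization_bins: int = 10_000
) -> ScoreDistribution:
    """Exact DP null distribution of the PWM score (see ScoreDistribution)."""
    return ScoreDistribution(pwm, discretization_bins)


# ---------------------------------------------------------------------------
# scanning


def encode_sequence(seq: str) -> np.ndarray:
    """ACGT -> 0..3; anything else (N) -> -1."""
    table = np.full(256, -1, dtype=np.int8)
    for b, i in _BASE_INDEX.items():
        table[ord(b)] = i
        table[ord(b.lower())] = i
    return table[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def _window_scores(
    enc: np.ndarray, int_scores: np.ndarray, real_scores: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Integer and real scores for every window; mask of N-free windows."""
    w = int_scores.shape[1]
    n_win = len(enc) - w + 1
    if n_win <= 0:
        return np.empty(0, dtype=np.int64), np.empty(0), np.empty(0, dtype=bool)
    valid = np.ones(n_win, dtype=bool)
    int_tot = np.zeros(n_win, dtype=np.int64)
    real_tot = np.zeros(n_win)
    safe = np.where(enc < 0, 0, enc)
    for j in range(w):
        col = safe[j: j + n_win]
        valid &= enc[j: j + n_win] >= 0
        int_tot += int_scores[col, j]
        real_tot += real_scores[col, j]
    return int_tot, real_tot, valid


def scan_sequence(
    seq: str,
    pwm: MotifPWM,
    p_threshold: float = 1e-4,
    chrom: str = ".",
    discretization_bins: int = 10_000,
    dist: ScoreDistribution | None = None,
) -> list[MotifHit]:
    """Scan both strands; emit hits with p <= p_threshold.

    Coordinates are forward-strand 0-based window starts; windows containing
    N are skipped.  Reverse-strand windows are scored with the
    reverse-complement matrix on the forward sequence (score distribution is
    identical, so one DP table serves both strands).
    """
    enc = encode_sequence(seq)
    if len(enc) < pwm.width:
        return []
    if dist is None:
        dist = score_pvalue_table(pwm, discretization_bins)
    real = pwm.log_odds
    hits: list[MotifHit] = []
    rc = pwm.reverse_complement()
    rc_int = dist.int_scores[::-1, ::-1]
    rc_real = rc.log_odds
    for strand, ints, reals in (
        ("+", dist.int_scores, real),
        ("-", rc_int, rc_real),
    ):
        int_tot, real_tot, valid = _window_scores(enc, ints, reals)
        for i in np.nonzero(valid)[0]:
            p = dist.pvalue_of_int(int(int_tot[i]))
            if p <= p_threshold:
                hits.append(
                    MotifHit(
                        chrom=chrom, start=int(i), strand=strand,
                        score=float(real_tot[i]), p=p,
                    )
                )
    hits.sort(key=lambda h: (h.start, h.strand))
    return hits


def add_qvalues(hits: Sequence[MotifHit]) -> list[MotifHit]:
    """Attach BH q-values across a hit list (in place); returns the list."""
    if not hits:
        return list(hits)
    q = bh_adjust([h.p for h in hits])
    for h, qv in zip(hits, q):
        h.q = float(qv)
    return list(hits)


# ---------------------------------------------------------------------------
# multiple testing and enrichment


def bh_adjust(pvals: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, input order preserved."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise DataError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def tf_target_enrichment(
    query: set, targets: TargetSets
) -> pd.DataFrame:
    """Upper-tail hypergeometric overlap test per TF target set.

    Population = |universe|, successes = |targets|, draws = |query|;
    p = P(X >= observed overlap).  q across TFs by Benjamini-Hochberg.
    """
    extra = set(query) - targets.universe
    if extra:
        raise DataError(
            f"query genes outside the universe: {sorted(extra)[:10]}"
        )
    M = len(targets.universe)
    n_draw = len(query)
    rows = []
    for tf in sorted(targets.sets):
        tset = targets.sets[tf]
        k = len(query & tset)
        K = len(tset)
        p = float(stats.hypergeom.sf(k - 1, M, K, n_draw))
        rows.append(
            {
                "tf": tf, "overlap": k, "set_size": K,
                "expected": K * n_draw / M, "p": min(p, 1.0),
            }
        )
    df = pd.DataFrame(rows)
    if len(df):
        df["q"] = bh_adjust(df["p"].to_numpy())
    return df


def annotate_genes_with_motif(
    hits: Sequence[MotifHit],
    transcripts: Sequence[TranscriptModel],
    promoter_window: int = 0,
) -> dict[str, list[MotifHit]]:
    """Assign hits to genes whose span (optionally promoter-extended) contains them.

    The gene span runs from the 5'-most start to the 3'-most end across the
    gene's transcripts; ``promoter_window`` extends it on both sides.
    """
    spans: dict[str, list] = {}
    for t in transcripts:
        s = spans.setdefault(t.gene_id, [t.chrom, t.span.start, t.span.end])
        s[1] = min(s[1], t.span.start)
        s[2] = max(s[2], t.span.end)
    out: dict[str, list[MotifHit]] = {g: [] for g in spans}
    for h in hits:
        for g, (chrom, s, e) in spans.items():
            if h.chrom == chrom and s - promoter_window <= h.start < e + promoter_window:
                out[g].append(h)
    return out


# ---------------------------------------------------------------------------
# GMT-style target-set IO


def read_target_sets(path: str | Path, universe: set | None = None) -> TargetSets:
    """Read GMT-style TSV: TF <tab> description <tab> gene1 <tab> gene2 ...

    When ``universe`` is None it defaults to the union of all sets.
    """
    sets: dict[str, set] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            sets[parts[0]] = set(g for g in parts[2:] if g)
    if universe is None:
        universe = set().union(*sets.values()) if sets else set()
    return TargetSets(sets=sets, universe=universe)


def write_target_sets(targets: TargetSets, path: str | Path) -> None:
    with open(path, "w") as fh:
        for tf in sorted(targets.sets):
            genes = "\t".join(sorted(targets.sets[tf]))
            fh.write(f"{tf}\ttargets\t{genes}\n")
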