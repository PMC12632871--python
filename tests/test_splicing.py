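import itertools
from math import comb

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from isochrom.errors import DataError
from isochrom.splicing import (
    EVENT_TYPES,
    classify_events,
    compute_psi,
    differential_psi,
    event_type_proportions,
)
from tests.conftest import make_transcript

# hand-built minimal transcript pairs, one per event class (+ strand)
PAIRS = {
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
}


def _mirror(exons, span=1200):
    return sorted((span - e, span - s) for s, e in exons)


class TestClassifyEvents:
    @pytest.mark.parametrize("etype", sorted(PAIRS))
    @pytest.mark.parametrize("strand", ["+", "-"])
    def test_minimal_pair_is_classified_as_planted_type(self, etype, strand):
        """Each minimal pair yields exactly one event of its own class,
        on either strand (minus-strand pair mirrored on the genome axis)."""
        e1, e2 = PAIRS[etype]
        if strand == "-":
            e1, e2 = _mirror(e1), _mirror(e2)
        t1 = make_transcript("g", "t1", strand, e1)
        t2 = make_transcript("g", "t2", strand, e2)
        events = classify_events([t1, t2])
        assert [e.type for e in events] == [etype]

    def test_exon_skipping_pair(self, se_pair):
        """A transcript lacking one internal exon with shared flanks is a
        single SE event with 2 inclusion + 1 exclusion junction."""
        events = classify_events(se_pair)
        assert len(events) == 1
        ev = events[0]
        assert ev.type == "SE"
        assert sorted(ev.inclusion_junctions) == [(150, 450), (600, 900)]
        assert ev.exclusion_junctions == [(150, 900)]

    def test_single_transcript_no_events(self):
        t = make_transcript("g", "t1", "+", [(0, 100), (200, 300)])
        assert classify_events([t]) == []

    def test_unspliced_transcript_gives_ri_per_intron(self):
        """A 3-exon transcript against an unspliced transcript covering it
        yields one retained-intron event per intron."""
        spliced = make_transcript("g", "t1", "+", [(0, 100), (200, 300), (400, 500)])
        unspliced = make_transcript("g", "t2", "+", [(0, 500)])
        events = classify_events([spliced, unspliced])
        assert sorted(e.type for e in events) == ["RI", "RI"]
        assert sorted(tuple(e.inclusion_junctions) for e in events) == [
            ((100, 200),), ((300, 400),)
        ]

    def test_a5_a3_swap_when_strand_flips_without_reflection(self):
        """The same genomic geometry is A5 on one strand and A3 on the other:
        donor/acceptor are transcript-strand concepts."""
        e1, e2 = PAIRS["A5"]
        plus = classify_events(
            [make_transcript("g", "t1", "+", e1), make_transcript("g", "t2", "+", e2)]
        )
        minus = classify_events(
            [make_transcript("g", "t1", "-", e1), make_transcript("g", "t2", "-", e2)]
        )
        assert [e.type for e in plus] == ["A5"]
        assert [e.type for e in minus] == ["A3"]

    def test_mixed_strand_gene_is_error(self):
        t1 = make_transcript("g", "t1", "+", [(0, 100)])
        t2 = make_transcript("g", "t2", "-", [(0, 100)])
        with pytest.raises(DataError, match="strand"):
            classify_events([t1, t2])

    def test_classification_idempotent_and_duplicate_free(self, se_pair):
        # a third transcript identical to t2 must not duplicate the SE event
        t3 = make_transcript("g1", "t3", "+", [(0, 150), (900, 1050)])
        once = classify_events(se_pair + [t3])
        twice = classify_events(se_pair + [t3])
        assert [e.key for e in once] == [e.key for e in twice]
        assert len({e.key for e in once}) == len(once)
        # both skipping transcripts recorded on the exclusion side
        (ev,) = [e for e in once if e.type == "SE"]
        assert ev.involved_transcripts[1] == frozenset({"t2", "t3"})


class TestEventProportions:
    def test_fractions(self):
        events = []
        for i, t in enumerate(["SE"] * 22 + ["AF"] * 78):
            exons = PAIRS[t]
            events.append(
                classify_events(
                    [
                        make_transcript(f"g{i}", "a", "+", exons[0]),
                        make_transcript(f"g{i}", "b", "+", exons[1]),
                    ]
                )[0]
            )
        props, empty = event_type_proportions(events)
        assert not empty
        assert props["SE"] == pytest.approx(0.22)
        assert sum(props.values()) == pytest.approx(1.0)

    def test_empty_flag(self):
        props, empty = event_type_proportions([])
        assert empty and all(v == 0.0 for v in props.values())
        assert set(props) == set(EVENT_TYPES)


class TestComputePsi:
    def test_boundary_full_inclusion(self):
        est = compute_psi([(10, 10, 0)])
        assert est.psi[0] == 1.0

    def test_formula_forced_value(self):
        # ((6+4)/2) / ((6+4)/2 + 15) = 5/20
        est = compute_psi([(6, 4, 15)])
        assert est.psi[0] == pytest.approx(0.25)

    def test_undefined_flagged(self):
        est = compute_psi([(0, 0, 0), (1, 1, 1)])
        assert not est.defined[0] and est.defined[1]

    def test_negative_count_rejected(self):
        with pytest.raises(DataError):
            compute_psi([(1, -1, 2)])

    @given(
        iu=st.integers(0, 50), idn=st.integers(0, 50), sk=st.integers(0, 50),
        d=st.integers(1, 10),
    )
    @settings(max_examples=200, derandomize=True)
    def test_monotonicity(self, iu, idn, sk, d):
        """PSI is non-decreasing in inclusion counts, non-increasing in skip."""
        base = compute_psi([(iu, idn, sk)]).psi[0]
        up = compute_psi([(iu + d, idn, sk)]).psi[0]
        down = compute_psi([(iu, idn, sk + d)]).psi[0]
        if not np.isnan(base):
            assert up >= base - 1e-12
            assert down <= base + 1e-12


def _brute_force_perm_p(g1, g2):
    pooled = np.concatenate([g1, g2])
    n1 = len(g1)
    obs = abs(np.mean(g2) - np.mean(g1))
    hits = total = 0
    for idx in itertools.combinations(range(len(pooled)), n1):
        mask = np.zeros(len(pooled), bool)
        mask[list(idx)] = True
        if abs(pooled[~mask].mean() - pooled[mask].mean()) >= obs - 1e-12:
            hits += 1
        total += 1
    return hits / total


class TestDifferentialPsi:
    def _frame(self, cond1, cond2):
        samples = [f"a{i}" for i in range(len(cond1))] + [
            f"b{i}" for i in range(len(cond2))
        ]
        labels = {s: ("wildtype" if s.startswith("a") else "transgenic") for s in samples}
        df = pd.DataFrame([list(cond1) + list(cond2)], index=["ev"], columns=samples)
        return df, labels

    def test_degenerate_identical_values(self):
        df, labels = self._frame([0.5] * 3, [0.5] * 3)
        out = differential_psi(df, labels, seed=0, contrast=("wildtype", "transgenic"))
        assert out.loc["ev", "delta_psi"] == 0.0
        assert out.loc["ev", "p"] == 1.0

    def test_exhaustive_enumeration_matches_brute_force(self):
        g1, g2 = np.array([0.02, 0.02, 0.02]), np.array([0.25, 0.25, 0.25])
        df, labels = self._frame(g1, g2)
        out = differential_psi(df, labels, seed=0, contrast=("wildtype", "transgenic"))
        assert out.loc["ev", "delta_psi"] == pytest.approx(0.23)
        assert out.loc["ev", "p"] == pytest.approx(_brute_force_perm_p(g1, g2))
        # n=3+3 exhaustive floor: only the two extreme arrangements qualify
        assert out.loc["ev", "p"] == pytest.approx(2 / comb(6, 3))

    def test_exhaustive_matches_brute_force_on_noisy_data(self, rng):
        g1, g2 = rng.normal(0.3, 0.05, 4), rng.normal(0.4, 0.05, 3)
        df, labels = self._frame(g1, g2)
        out = differential_psi(df, labels, seed=0, contrast=("wildtype", "transgenic"))
        assert out.loc["ev", "p"] == pytest.approx(_brute_force_perm_p(g1, g2))

    def test_label_swap_negates_delta_keeps_p(self, rng):
        g1, g2 = rng.normal(0.2, 0.05, 3), rng.normal(0.5, 0.05, 3)
        df, labels = self._frame(g1, g2)
        fwd = differential_psi(df, labels, seed=0, contrast=("wildtype", "transgenic"))
        rev = differential_psi(df, labels, seed=0, contrast=("transgenic", "wildtype"))
        assert fwd.loc["ev", "delta_psi"] == pytest.approx(-rev.loc["ev", "delta_psi"])
        assert fwd.loc["ev", "p"] == rev.loc["ev", "p"]

    def test_too_few_defined_values_skipped(self):
        df, labels = self._frame([0.5, np.nan, np.nan], [0.5, 0.6, 0.7])
        out = differential_psi(df, labels, seed=0)
        assert out.loc["ev", "flag"] == "skipped_too_few_defined"
        assert np.isnan(out.loc["ev", "p"])
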