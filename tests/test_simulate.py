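import collections

import numpy as np
import pytest

from isochrom.chromatin import designate_de_peaks
from isochrom.errors import ConfigError
from isochrom.io import write_gtf
from isochrom.motif import scan_sequence
from isochrom.simulate import (
    SimulationConfig,
    _nb_draw,
    generate_annotation,
    generate_atac,
    generate_counts,
    generate_junction_counts,
    generate_sequences,
    generate_target_sets,
    planted_events,
    re1_like_pwm,
)
from isochrom.splicing import compute_psi


class TestConfig:
    @pytest.mark.parametrize(
        "kw",
        [
            {"planted_de_fraction": 1.5},
            {"planted_event_mix": {"SE": 0.7, "AF": 0.5}},
            {"planted_event_mix": {"XX": 0.1}},
            {"planted_psi_pair": (0.5, 1.2)},
            {"nb_dispersion": -0.1},
            {"n_replicates_per_condition": 0},
        ],
    )
    def test_invalid_configs_rejected(self, kw):
        with pytest.raises(ConfigError):
            SimulationConfig(seed=1, **kw)

    def test_streams_are_independent_of_other_generators(self):
        cfg = SimulationConfig(seed=9)
        a = cfg.stream("annotation").integers(0, 1000, 5)
        cfg.stream("counts").integers(0, 1000, 5)  # consuming another stream
        b = cfg.stream("annotation").integers(0, 1000, 5)
        assert np.array_equal(a, b)


class TestAnnotation:
    def test_pure_se_mix_classifies_as_one_se_per_gene(self):
        cfg = SimulationConfig(n_genes=10, planted_event_mix={"SE": 1.0}, seed=3)
        ann, truth = generate_annotation(cfg)
        by_gene = collections.defaultdict(list)
        for e in planted_events(ann):
            by_gene[e.gene_id].append(e.type)
        assert len(by_gene) == 10
        assert all(v == ["SE"] for v in by_gene.values())

    def test_full_mix_recovered_by_classifier(self):
        cfg = SimulationConfig(n_genes=100, seed=3)
        ann, truth = generate_annotation(cfg)
        got = collections.Counter(e.type for e in planted_events(ann))
        planted = collections.Counter(t for _, t in truth.event_catalog)
        assert got == planted

    def test_deterministic_gtf_bytes(self, tmp_path):
        cfg = SimulationConfig(n_genes=25, seed=7)
        for name in ("a.gtf", "b.gtf"):
            ann, _ = generate_annotation(SimulationConfig(n_genes=25, seed=7))
            write_gtf(ann, tmp_path / name)
        assert (tmp_path / "a.gtf").read_bytes() == (tmp_path / "b.gtf").read_bytes()


class TestCounts:
    def test_poisson_limit_at_zero_dispersion(self, rng):
        draws = np.array([_nb_draw(rng, 100.0, 0.0) for _ in range(4000)])
        assert np.var(draws) / np.mean(draws) == pytest.approx(1.0, abs=0.15)

    def test_overdispersion_matches_model(self, rng):
        mu, alpha = 200.0, 0.1
        draws = np.array([_nb_draw(rng, mu, alpha) for _ in range(6000)])
        assert np.var(draws) == pytest.approx(mu + alpha * mu**2, rel=0.15)

    def test_planted_isoforms_are_non_principal_when_possible(self):
        cfg = SimulationConfig(n_genes=60, seed=5)
        ann, _ = generate_annotation(cfg)
        _, truth = generate_counts(ann, cfg)
        principal = {t.transcript_id for t in ann if t.principal}
        multi = {t.gene_id for t in ann} - {
            g for g, n in collections.Counter(t.gene_id for t in ann).items() if n == 1
        }
        for iso in truth.de_isoforms:
            gene = iso.rsplit(".", 1)[0]
            if gene in multi:
                assert iso not in principal

    def test_ground_truth_ids_exist(self):
        cfg = SimulationConfig(n_genes=30, seed=5)
        ann, _ = generate_annotation(cfg)
        em, truth = generate_counts(ann, cfg)
        assert truth.de_isoforms <= set(em.transcript_ids)
        assert set(truth.coordinated_genes) == {t.gene_id for t in ann}


class TestJunctions:
    def test_psi_one_means_zero_skipping_reads(self):
        cfg = SimulationConfig(
            n_genes=5, planted_event_mix={"SE": 1.0}, seed=2,
            planted_psi_pair=(1.0, 1.0),
        )
        ann, truth = generate_annotation(cfg)
        jc = generate_junction_counts(planted_events(ann), truth.psi_truth, cfg)
        assert (jc["skip"] == 0).all()

    def test_estimator_recovers_planted_psi(self):
        """200 replicate draws at depth 2000: mean estimated PSI within
        0.25 +/- 0.02 of truth."""
        cfg = SimulationConfig(
            n_genes=1, planted_event_mix={"SE": 1.0}, seed=2,
            planted_psi_pair=(0.25, 0.25), n_replicates_per_condition=100,
        )
        ann, truth = generate_annotation(cfg)
        jc = generate_junction_counts(planted_events(ann), truth.psi_truth, cfg)
        est = compute_psi(jc[["incl_up", "incl_down", "skip"]].to_numpy())
        assert est.psi.mean() == pytest.approx(0.25, abs=0.02)

    def test_delta_psi_sign_positive_in_condition2(self):
        cfg = SimulationConfig(n_genes=6, planted_event_mix={"SE": 1.0}, seed=2)
        ann, truth = generate_annotation(cfg)
        jc = generate_junction_counts(planted_events(ann), truth.psi_truth, cfg)
        est = {
            cond: compute_psi(
                grp[["incl_up", "incl_down", "skip"]].to_numpy()
            ).psi.mean()
            for cond, grp in jc.groupby(jc["sample"].str.rsplit("_", n=1).str[0])
        }
        assert est["transgenic"] > est["wildtype"]


class TestAtac:
    def test_planted_open_up_gene_passes_two_fold_rule(self):
        cfg = SimulationConfig(n_genes=60, seed=4)
        ann, _ = generate_annotation(cfg)
        peaks, truth = generate_atac(ann, cfg)
        de = designate_de_peaks(
            peaks, cfg.condition_labels, contrast=("wildtype", "transgenic")
        )
        for gene, cls in truth.coordinated_genes.items():
            if cls == "open_up":
                assert f"peak_{gene}" in de["more_open"]
            elif cls == "closed_down":
                assert f"peak_{gene}" in de["less_open"]

    def test_truth_keys_equal_gene_set(self):
        cfg = SimulationConfig(n_genes=20, seed=4)
        ann, _ = generate_annotation(cfg)
        _, truth = generate_atac(ann, cfg)
        assert set(truth.coordinated_genes) == {t.gene_id for t in ann}

    def test_no_coordination_flags_near_noise_level(self):
        cfg = SimulationConfig(n_genes=500, coordination_fraction=0.0, seed=4)
        ann, _ = generate_annotation(cfg)
        peaks, _ = generate_atac(ann, cfg)
        de = designate_de_peaks(peaks, cfg.condition_labels)
        frac = (len(de["more_open"]) + len(de["less_open"])) / 500
        assert frac < 0.05


class TestSequences:
    def test_exact_consensus_insertions_recovered_exactly(self):
        cfg = SimulationConfig(seed=6, sequence_length=50_000, motif_insertion_rate=0.2)
        pwm = re1_like_pwm()
        seqs, truth = generate_sequences(cfg, pwm, exact_consensus=True)
        hits = scan_sequence(seqs["chrS"], pwm, p_threshold=1e-8, chrom="chrS")
        hit_keys = {(h.start, h.strand) for h in hits}
        planted = {(s, st) for _, s, st in truth.motif_positions}
        assert planted <= hit_keys

    def test_rate_too_high_rejected(self):
        cfg = SimulationConfig(seed=6, sequence_length=10_000, motif_insertion_rate=30.0)
        with pytest.raises(ConfigError, match="rate"):
            generate_sequences(cfg)

    def test_deterministic(self):
        a, _ = generate_sequences(SimulationConfig(seed=6, sequence_length=20_000))
        b, _ = generate_sequences(SimulationConfig(seed=6, sequence_length=20_000))
        assert a == b

    def test_gc_content_respected(self):
        cfg = SimulationConfig(
            seed=6, sequence_length=100_000, motif_insertion_rate=0.0, gc_content=0.6
        )
        seqs, truth = generate_sequences(cfg)
        assert truth.motif_positions == []
        s = seqs["chrS"]
        gc = (s.count("G") + s.count("C")) / len(s)
        assert gc == pytest.approx(0.6, abs=0.01)


class TestTargetSets:
    def test_planted_tf_enriched_in_coordinated_genes(self):
        from isochrom.motif import tf_target_enrichment

        cfg = SimulationConfig(n_genes=200, seed=8)
        ann, _ = generate_annotation(cfg)
        _, truth = generate_atac(ann, cfg)
        gene_ids = sorted({t.gene_id for t in ann})
        ts = generate_target_sets(gene_ids, truth.coordinated_genes, cfg)
        coord = {g for g, c in truth.coordinated_genes.items() if c != "null"}
        df = tf_target_enrichment(coord, ts).set_index("tf")
        assert df.loc["TF_planted", "q"] < 0.01
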