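"""Pipeline orchestration: simulate -> events/psi -> de -> peaks -> integrate
-> motif -> enrich, driven by one sectioned key=value config file.

All stage outputs are plain text (GTF/BED/TSV/FASTA/GMT) under the configured
output directory, and the whole run is deterministic given the configured
seed: rerunning with the same config reproduces every output byte-identically
(timings go to the human-readable log only).  The machine surface is
``report.tsv``: stage list, sha256 digests of every output, and the counts
at each filter.
"""

from __future__ import annotations

import configparser
import dataclasses
import hashlib
import sys
import time
from pathlib import Path

import pandas as pd

from isochrom import __version__
from isochrom.bayes import BayesModelConfig, classify_coordination, integrate, summary_table
from isochrom.chromatin import (
    annotate_peaks_to_promoters,
    call_open_status,
    designate_de_peaks,
    promoter_call_table,
)
from isochrom.de import (
    cpm_normalize,
    filter_de,
    filter_zero_isoforms,
    moderated_t_test,
    prioritize_alt_isoform_genes,
)
from isochrom.errors import ConfigError
from isochrom.io import (
    write_bed_peaks,
    write_counts,
    write_gtf,
    write_junction_counts,
)
from isochrom.motif import (
    add_qvalues,
    scan_sequence,
    tf_target_enrichment,
    write_target_sets,
)
from isochrom.simulate import (
    CONDITIONS,
    SimulationConfig,
    generate_annotation,
    generate_atac,
    generate_counts,
    generate_junction_counts,
    generate_sequences,
    generate_target_sets,
    planted_events,
    re1_like_pwm,
)
from isochrom.splicing import differential_psi, event_type_proportions, psi_table

CONTRAST = tuple(CONDITIONS)  # (wildtype, transgenic): log2FC is transgenic - wildtype

_SCHEMA: dict[str, dict[str, tuple[type, object]]] = {
    "simulation": {
        "n_genes": (int, lambda v: v > 0),
        "n_replicates_per_condition": (int, lambda v: v >= 1),
        "seed": (int, lambda v: True),
        "planted_de_fraction": (float, lambda v: 0 <= v <= 1),
        "de_log2_effect": (float, lambda v: True),
        "psi_wildtype": (float, lambda v: 0 <= v <= 1),
        "psi_transgenic": (float, lambda v: 0 <= v <= 1),
        "nb_dispersion": (float, lambda v: v >= 0),
        "coordination_fraction": (float, lambda v: 0 <= v <= 1),
        "coordination_log2_effect": (float, lambda v: True),
        "atac_fold": (float, lambda v: v > 0),
        "junction_depth": (float, lambda v: v > 0),
        "motif_insertion_rate": (float, lambda v: v >= 0),
        "sequence_length": (int, lambda v: v > 0),
        "gc_content": (float, lambda v: 0 <= v <= 1),
    },
    "paths": {"outdir": (str, lambda v: True)},
    "de": {
        "p_threshold": (float, lambda v: 0 < v <= 1),
        "lfc_threshold": (float, lambda v: v >= 0),
        "d0_override": (float, lambda v: v >= 0),
    },
    "chromatin": {
        "window_bp": (int, lambda v: v > 0),
        "fold_threshold": (float, lambda v: v > 1),
        "open_threshold": (float, lambda v: v >= 0),
    },
    "integration": {
        "iterations": (int, lambda v: v > 0),
        "burnin": (int, lambda v: v >= 0),
        "chains": (int, lambda v: v >= 1),
        "hdi_mass": (float, lambda v: 0 < v < 1),
        "significance": (float, lambda v: 0.5 < v < 1),
        "grouping": (str, lambda v: v in ("per-sample", "per-condition")),
    },
    "motif": {
        "p_threshold": (float, lambda v: 0 < v <= 1),
        "q_threshold": (float, lambda v: 0 < v <= 1),
        "discretization_bins": (int, lambda v: v >= 100),
    },
    "enrichment": {"n_tfs": (int, lambda v: v >= 1)},
}

STAGES = ("simulate", "events", "psi", "de", "peaks", "integrate", "motif", "enrich")


@dataclasses.dataclass
class Finding:
    severity: str  # "fatal" | "warning"
    message: str


@dataclasses.dataclass
class RunReport:
    stages: list[str]
    digests: dict[str, str]
    counts: dict[str, object]
    config_echo: dict[str, dict[str, str]]
    seed: int
    timings: dict[str, float]

    def to_tsv(self) -> str:
        """Deterministic machine-readable report (no timings)."""
        lines = [f"isochrom\t{__version__}", f"seed\t{self.seed}"]
        lines += [f"stage\t{s}" for s in self.stages]
        for name in sorted(self.digests):
            lines.append(f"digest\t{name}\t{self.digests[name]}")
        for key in sorted(self.counts):
            lines.append(f"count\t{key}\t{self.counts[key]}")
        for section, kv in sorted(self.config_echo.items()):
            for k, v in sorted(kv.items()):
                lines.append(f"config\t{section}.{k}\t{v}")
        return "\n".join(lines) + "\n"


def validate_config(config_path: str | Path) -> list[Finding]:
    """Schema-check a config file; returns findings (fatal findings block runs)."""
    findings: list[Finding] = []
    path = Path(config_path)
    if not path.exists():
        return [Finding("fatal", f"config file not found: {path}")]
    cp = configparser.ConfigParser()
    try:
        cp.read(path)
    except configparser.Error as exc:
        return [Finding("fatal", f"cannot parse config: {exc}")]
    for section in cp.sections():
        if section not in _SCHEMA:
            findings.append(Finding("warning", f"unknown section [{section}]"))
            continue
        for key, raw in cp.items(section):
            if key not in _SCHEMA[section]:
                findings.append(
                    Finding("warning", f"unknown key {key!r} in [{section}]")
                )
                continue
            typ, check = _SCHEMA[section][key]
            try:
                val = typ(raw)
            except ValueError:
                findings.append(
                    Finding("fatal", f"[{section}] {key}={raw!r}: not a {typ.__name__}")
                )
                continue
            if not check(val):
                findings.append(
                    Finding("fatal", f"[{section}] {key}={raw!r}: out of range")
                )
    if not cp.has_option("simulation", "seed"):
        findings.append(
            Finding("fatal", "[simulation] seed is mandatory (stochastic stages)")
        )
    return findings


def _get(cp, section, key, typ, default):
    if cp.has_option(section, key):
        return typ(cp.get(section, key))
    return default


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _log(stage: str, msg: str) -> None:
    print(f"[{stage}] {msg}", file=sys.stderr)


def run_pipeline(config_path: str | Path, last_stage: str = "enrich") -> RunReport:
    """Execute stages in dependency order up to ``last_stage``; any failure
    aborts with a stage-named error.  Returns the run report (also written
    to the outdir).
    """
    if last_stage not in STAGES:
        raise ConfigError(f"unknown stage {last_stage!r}; choose from {STAGES}")
    findings = validate_config(config_path)
    fatal = [f for f in findings if f.severity == "fatal"]
    for f in findings:
        _log("validate", f"{f.severity}: {f.message}")
    if fatal:
        raise ConfigError("; ".join(f.message for f in fatal))

    cp = configparser.ConfigParser()
    cp.read(config_path)
    outdir = Path(_get(cp, "paths", "outdir", str, "isochrom_out"))
    outdir.mkdir(parents=True, exist_ok=True)

    sim = SimulationConfig(
        n_genes=_get(cp, "simulation", "n_genes", int, 200),
        n_replicates_per_condition=_get(
            cp, "simulation", "n_replicates_per_condition", int, 3
        ),
        planted_de_fraction=_get(cp, "simulation", "planted_de_fraction", float, 0.1),
        de_log2_effect=_get(cp, "simulation", "de_log2_effect", float, 2.0),
        planted_psi_pair=(
            _get(cp, "simulation", "psi_wildtype", float, 0.02),
            _get(cp, "simulation", "psi_transgenic", float, 0.25),
        ),
        nb_dispersion=_get(cp, "simulation", "nb_dispersion", float, 0.1),
        coordination_fraction=_get(
            cp, "simulation", "coordination_fraction", float, 0.1
        ),
        coordination_log2_effect=_get(
            cp, "simulation", "coordination_log2_effect", float, 2.0
        ),
        atac_fold=_get(cp, "simulation", "atac_fold", float, 4.0),
        junction_depth=_get(cp, "simulation", "junction_depth", float, 2000.0),
        motif_insertion_rate=_get(
            cp, "simulation", "motif_insertion_rate", float, 0.05
        ),
        sequence_length=_get(cp, "simulation", "sequence_length", int, 200_000),
        gc_content=_get(cp, "simulation", "gc_content", float, 0.42),
        seed=cp.getint("simulation", "seed"),
    )

    counts: dict[str, object] = {}
    timings: dict[str, float] = {}
    stages_run: list[str] = []

    last_index = STAGES.index(last_stage)

    def stage(name):
        def wrap(fn):
            if STAGES.index(name) > last_index:
                return
            t0 = time.perf_counter()
            try:
                fn()
            except Exception as exc:
                raise type(exc)(f"stage {name!r} failed: {exc}") from exc
            timings[name] = time.perf_counter() - t0
            stages_run.append(name)
            _log(name, f"done in {timings[name]:.1f}s")
        return wrap

    # ---- simulate
    state: dict = {}

    @stage("simulate")
    def _simulate():
        ann, ann_truth = generate_annotation(sim)
        expr, counts_truth = generate_counts(ann, sim)
        events = planted_events(ann)
        junctions = generate_junction_counts(events, ann_truth.psi_truth, sim)
        peaks, atac_truth = generate_atac(ann, sim)
        gene_ids = sorted({t.gene_id for t in ann})
        targets = generate_target_sets(
            gene_ids, atac_truth.coordinated_genes, sim,
            n_tfs=_get(cp, "enrichment", "n_tfs", int, 20),
        )
        seqs, seq_truth = generate_sequences(sim)
        write_gtf(ann, outdir / "annotation.gtf")
        write_counts(expr, outdir / "counts.tsv")
        write_junction_counts(junctions, outdir / "junctions.tsv")
        write_bed_peaks(peaks, outdir / "peaks.bed", outdir / "peak_signal.tsv")
        write_target_sets(targets, outdir / "targets.gmt")
        with open(outdir / "sequence.fa", "w") as fh:
            for chrom, s in seqs.items():
                fh.write(f">{chrom}\n")
                for i in range(0, len(s), 80):
                    fh.write(s[i: i + 80] + "\n")
        _write_truth_manifest(
            outdir / "ground_truth.tsv", ann_truth, counts_truth,
            atac_truth, seq_truth,
        )
        state.update(
            ann=ann, expr=expr, events=events, junctions=junctions,
            peaks=peaks, targets=targets,
            truth={"annotation": ann_truth, "counts": counts_truth,
                   "atac": atac_truth, "sequences": seq_truth},
        )
        counts["simulated_genes"] = sim.n_genes
        counts["simulated_isoforms"] = len(ann)

    # ---- events
    @stage("events")
    def _events():
        events = state["events"]
        props, _ = event_type_proportions(events)
        pd.DataFrame(
            [
                {
                    "event_id": e.event_id, "gene_id": e.gene_id, "type": e.type,
                    "chrom": e.chrom, "strand": e.strand,
                    "inclusion_junctions": ";".join(f"{d}-{a}" for d, a in e.inclusion_junctions),
                    "exclusion_junctions": ";".join(f"{d}-{a}" for d, a in e.exclusion_junctions),
                }
                for e in events
            ]
        ).to_csv(outdir / "events.tsv", sep="\t", index=False)
        for t, frac in props.items():
            counts[f"events_{t}"] = sum(1 for e in events if e.type == t)

    # ---- psi
    @stage("psi")
    def _psi():
        pt = psi_table(state["junctions"])
        pt.to_csv(outdir / "psi.tsv", sep="\t")
        dpsi = differential_psi(
            pt, sim.condition_labels, seed=sim.seed, contrast=CONTRAST
        )
        dpsi.to_csv(outdir / "delta_psi.tsv", sep="\t")
        counts["psi_events"] = len(pt)
        # at n=3+3 the exhaustive permutation floor is p=0.1; count events at
        # the attainable floor rather than an unattainable 0.05
        p_floor = float(dpsi["p"].min()) if len(dpsi) else 1.0
        counts["dpsi_at_permutation_floor"] = int((dpsi["p"] <= p_floor + 1e-12).sum())
        state["dpsi"] = dpsi

    # ---- de
    @stage("de")
    def _de():
        expr = state["expr"]
        filt, removed = filter_zero_isoforms(expr)
        log2 = cpm_normalize(filt)
        tg = {t.transcript_id: t.gene_id for t in state["ann"]}
        d0_override = (
            float(cp.get("de", "d0_override"))
            if cp.has_option("de", "d0_override") else None
        )
        res = moderated_t_test(log2, tg, d0_override=d0_override, contrast=CONTRAST)
        p_thr = _get(cp, "de", "p_threshold", float, 0.05)
        lfc_thr = _get(cp, "de", "lfc_threshold", float, 0.5)
        parts = filter_de(res, p_thr, lfc_thr)
        from isochrom.motif import bh_adjust

        de_df = pd.DataFrame(
            [
                {
                    "transcript_id": r.transcript_id, "gene_id": r.gene_id,
                    "log2fc_transgenic_minus_wildtype": r.log2fc,
                    "t": r.t_stat, "p": r.p, "df": r.df,
                    "mean_log2cpm": r.mean_log2cpm,
                }
                for r in res
            ]
        )
        # the partition filters on raw p; the BH column is informational
        de_df["q_bh"] = bh_adjust(de_df["p"].to_numpy()) if len(de_df) else []
        de_df.to_csv(outdir / "de_isoforms.tsv", sep="\t", index=False)
        pri = prioritize_alt_isoform_genes(res, state["ann"], p_thr, lfc_thr)
        pri.to_csv(outdir / "prioritized_genes.tsv", sep="\t", index=False)
        counts["isoforms_excluded_zero"] = len(removed)
        counts["de_up"] = len(parts["up"])
        counts["de_down"] = len(parts["down"])
        counts["prioritized_alt_isoform_genes"] = len(pri)
        state.update(log2=log2, de_results=res, tg=tg)

    # ---- peaks
    @stage("peaks")
    def _peaks():
        peaks = state["peaks"]
        window = _get(cp, "chromatin", "window_bp", int, 2000)
        fold = _get(cp, "chromatin", "fold_threshold", float, 2.0)
        open_thr = (
            float(cp.get("chromatin", "open_threshold"))
            if cp.has_option("chromatin", "open_threshold") else None
        )
        gene_peaks = annotate_peaks_to_promoters(peaks, state["ann"], window)
        calls = call_open_status(peaks, gene_peaks, open_thr)
        de_peaks = designate_de_peaks(
            peaks, sim.condition_labels, fold, contrast=CONTRAST
        )
        promoter_call_table(calls).to_csv(
            outdir / "promoter_calls.tsv", sep="\t", index=False
        )
        with open(outdir / "de_peaks.bed", "w") as fh:
            index = {pid: p for pid, p in zip(peaks.peak_ids, peaks.peaks)}
            for direction in ("more_open", "less_open"):
                for pid in sorted(de_peaks[direction]):
                    p = index[pid]
                    fh.write(
                        f"{p.chrom}\t{p.start}\t{p.end}\t{pid}\t0\t.\t{direction}\n"
                    )
        counts["de_peaks_more_open"] = len(de_peaks["more_open"])
        counts["de_peaks_less_open"] = len(de_peaks["less_open"])
        state.update(promoter_calls=calls, de_peaks=de_peaks)

    # ---- integrate
    @stage("integrate")
    def _integrate():
        bcfg = BayesModelConfig(
            n_iterations=_get(cp, "integration", "iterations", int, 4000),
            n_burnin=_get(cp, "integration", "burnin", int, 1000),
            n_chains=_get(cp, "integration", "chains", int, 2),
            hdi_mass=_get(cp, "integration", "hdi_mass", float, 0.95),
            significance=_get(cp, "integration", "significance", float, 0.999),
            seed=sim.seed,
        )
        grouping = _get(cp, "integration", "grouping", str, "per-sample")
        summaries = integrate(
            state["log2"], state["promoter_calls"], bcfg,
            transcript_genes=state["tg"], grouping=grouping,
            condition_labels=sim.condition_labels,
        )
        calls = classify_coordination(
            summaries, state["promoter_calls"], state["de_peaks"], bcfg
        )
        table = summary_table(summaries, calls)
        table.to_csv(outdir / "integration.tsv", sep="\t", index=False)
        counts["integration_skipped"] = int(
            sum(s.status.startswith("skipped") for s in summaries)
        )
        for cls in ("open_up", "closed_down"):
            counts[f"coordinated_{cls}"] = sum(
                1 for c in calls if c.coordination == cls
            )
        state["coordination"] = calls

    # ---- motif
    @stage("motif")
    def _motif():
        pwm = re1_like_pwm()
        p_thr = _get(cp, "motif", "p_threshold", float, 1e-4)
        q_thr = _get(cp, "motif", "q_threshold", float, 0.01)
        bins = _get(cp, "motif", "discretization_bins", int, 10_000)
        seq = _read_fasta_single(outdir / "sequence.fa")
        hits = add_qvalues(
            scan_sequence(seq, pwm, p_thr, chrom="chrS", discretization_bins=bins)
        )
        pd.DataFrame(
            [
                {"chrom": h.chrom, "start": h.start, "strand": h.strand,
                 "score": h.score, "p": h.p, "q": h.q}
                for h in hits
            ]
        ).to_csv(outdir / "motif_hits.tsv", sep="\t", index=False)
        counts["motif_hits"] = len(hits)
        counts["motif_hits_q_lt_threshold"] = sum(1 for h in hits if h.q < q_thr)
        state["motif_hits"] = hits

    # ---- enrich
    @stage("enrich")
    def _enrich():
        coord_genes = {
            c.gene_id for c in state["coordination"] if c.coordination != "null"
        }
        targets = state["targets"]
        # an empty query would make every test degenerate; report and move on
        if not coord_genes:
            (outdir / "enrichment.tsv").write_text(
                "tf\toverlap\tset_size\texpected\tp\tq\n"
            )
            counts["enriched_tfs"] = 0
            return
        df = tf_target_enrichment(coord_genes, targets)
        df.to_csv(outdir / "enrichment.tsv", sep="\t", index=False)
        counts["enriched_tfs"] = int((df["q"] < 0.05).sum()) if len(df) else 0

    digests = {
        p.name: _sha256(p)
        for p in sorted(outdir.iterdir())
        if p.is_file() and p.name not in ("report.tsv", "report.txt")
    }
    report = RunReport(
        stages=stages_run,
        digests=digests,
        counts=counts,
        config_echo={s: dict(cp.items(s)) for s in cp.sections()},
        seed=sim.seed,
        timings=timings,
    )
    (outdir / "report.tsv").write_text(report.to_tsv())
    human = [f"isochrom {__version__} run report (seed {sim.seed})"]
    human += [f"  {s}: {timings[s]:.1f}s" for s in stages_run]
    human += [f"  {k} = {v}" for k, v in sorted(counts.items())]
    (outdir / "report.txt").write_text("\n".join(human) + "\n")
    return report


def _read_fasta_single(path: Path) -> str:
    from Bio import SeqIO

    rec = next(SeqIO.parse(str(path), "fasta"))
    return str(rec.seq)


def _write_truth_manifest(path: Path, ann_truth, counts_truth, atac_truth, seq_truth):
    with open(path, "w") as fh:
        fh.write("category\tkey\tvalue\n")
        for gene, etype in ann_truth.event_catalog:
            fh.write(f"event\t{gene}\t{etype}\n")
        for gene, pair in ann_truth.psi_truth.items():
            fh.write(f"psi\t{gene}\t{pair[0]},{pair[1]}\n")
        for iso in sorted(counts_truth.de_isoforms):
            fh.write(f"de_isoform\t{iso}\t1\n")
        for gene in sorted(counts_truth.alt_switch_genes):
            fh.write(f"alt_switch_gene\t{gene}\t1\n")
        for gene, cls in sorted(atac_truth.coordinated_genes.items()):
            if cls != "null":
                fh.write(f"coordination\t{gene}\t{cls}\n")
        for chrom, start, strand in seq_truth.motif_positions:
            fh.write(f"motif\t{chrom}:{start}\t{strand}\n")
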