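"""Isoform-level differential expression.

The pipeline consumes isoform counts (e.g. from a pseudo-alignment
quantifier), removes isoforms with a zero in any sample, log-CPM transforms,
and tests each isoform between two conditions with an empirical-Bayes
moderated t-statistic: per-row sample variances are shrunk towards a common
prior variance s0^2 with prior degrees of freedom d0, both estimated by
method of moments on the log sample variances.  This is the log-CPM +
moderated-t core of the standard voom/limma workflow; voom's per-observation
precision weights are deliberately not reimplemented.

Genes whose *non-principal* isoforms change are prioritised: the working
hypothesis of the analysis is that condition-driven regulation can act
through alternative rather than principal transcripts.

Default thresholds: p < 0.05, |log2FC| > 0.5 (symmetric).
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import special, stats

from isochrom.errors import DataError
from isochrom.io import ExpressionMatrix, TranscriptModel


@dataclasses.dataclass
class DeResult:
    transcript_id: str
    gene_id: str
    log2fc: float      # condition2 - condition1 (e.g. transgenic - wildtype)
    t_stat: float
    p: float
    df: float
    mean_log2cpm: float


def cpm_normalize(m: ExpressionMatrix) -> ExpressionMatrix:
    """log2 counts-per-million: log2((count + 0.5) / (libsize + 1) * 1e6)."""
    if m.scale_tag != "counts":
        raise DataError("cpm_normalize expects a counts matrix")
    counts = m.values.to_numpy(dtype=float)
    libsize = counts.sum(axis=0)
    if np.any(libsize == 0):
        zero = [m.samples[i] for i in np.nonzero(libsize == 0)[0]]
        raise DataError(f"all-zero column(s): {zero}")
    log2cpm = np.log2((counts + 0.5) / (libsize + 1.0) * 1e6)
    return ExpressionMatrix(
        pd.DataFrame(log2cpm, index=m.values.index, columns=m.values.columns),
        m.conditions,
        scale_tag="log2cpm",
    )


def filter_zero_isoforms(
    m: ExpressionMatrix,
) -> tuple[ExpressionMatrix, list[str]]:
    """Drop isoforms with zero expression in any sample.

    Returns the filtered matrix and the list of removed transcript ids.
    """
    if m.scale_tag != "counts":
        raise DataError("filter_zero_isoforms expects a counts matrix")
    has_zero = (m.values == 0).any(axis=1)
    removed = list(m.values.index[has_zero])
    kept = m.values.loc[~has_zero]
    return ExpressionMatrix(kept, m.conditions, scale_tag="counts"), removed


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y by Newton iteration (monotone decreasing)."""
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x += dif
        if abs(dif) < 1e-10 * x:
            break
    return float(x)


def _fit_prior_variance(s2: np.ndarray, d_r: float) -> tuple[float, float]:
    """Method-of-moments fit of (d0, s0^2) from per-row sample variances.

    With s_r^2 ~ s0^2 * F(d_r, d0), z = log s_r^2 satisfies
      E[z]   = log s0^2 + psi(d_r/2) - log(d_r/2) - psi(d0/2) + log(d0/2)
      Var[z] = psi'(d_r/2) + psi'(d0/2)
    so d0 comes from a trigamma inversion and s0^2 from the mean identity.
    """
    z = np.log(np.maximum(s2, 1e-300))
    e_gz = special.digamma(d_r / 2) - np.log(d_r / 2)
    var_z = float(np.var(z, ddof=1))
    excess = var_z - float(special.polygamma(1, d_r / 2))
    if excess <= 0:
        d0 = np.inf
        log_s0 = float(np.mean(z)) - e_gz
    else:
        d0 = 2.0 * _trigamma_inverse(excess)
        log_s0 = (
            float(np.mean(z))
            - e_gz
            + special.digamma(d0 / 2)
            - np.log(d0 / 2)
        )
    return d0, float(np.exp(log_s0))


def moderated_t_test(
    m: ExpressionMatrix,
    transcript_genes: Mapping[str, str] | None = None,
    d0_override: float | None = None,
    contrast: tuple[str, str] | None = None,
) -> list[DeResult]:
    """Two-group moderated t-test on a log2cpm matrix.

    The contrast is condition2 - condition1; pass ``contrast=(cond1, cond2)``
    explicitly (e.g. ``("wildtype", "transgenic")`` for the conventional
    transgenic-minus-wildtype log fold change), else sorted label order.

    ``d0_override`` forces the prior degrees of freedom: 0 recovers the
    ordinary pooled-variance t-test, ``inf`` fully trusts the prior variance.
    """
    if m.scale_tag != "log2cpm":
        raise DataError("moderated_t_test expects a log2cpm matrix")
    conds = list(contrast) if contrast else sorted(set(m.conditions.values()))
    if set(conds) != set(m.conditions.values()) or len(conds) != 2:
        raise DataError(f"need exactly 2 conditions matching labels, got {conds}")
    s1 = m.condition_samples(conds[0])
    s2 = m.condition_samples(conds[1])
    n1, n2 = len(s1), len(s2)
    if n1 < 2 or n2 < 2:
        raise DataError("need >=2 samples per condition")

    x1 = m.values[s1].to_numpy(dtype=float)
    x2 = m.values[s2].to_numpy(dtype=float)
    mean1, mean2 = x1.mean(axis=1), x2.mean(axis=1)
    d_r = n1 + n2 - 2
    ss = ((x1 - mean1[:, None]) ** 2).sum(axis=1) + (
        (x2 - mean2[:, None]) ** 2
    ).sum(axis=1)
    s2_pooled = ss / d_r

    if d0_override is not None:
        d0 = float(d0_override)
        if d0 > 0 and len(s2_pooled) >= 2:
            _, s0sq = _fit_prior_variance(s2_pooled, d_r)
        else:
            s0sq = float(np.exp(np.mean(np.log(np.maximum(s2_pooled, 1e-300)))))
    elif len(s2_pooled) < 2:
        warnings.warn(
            "fewer than 2 rows: falling back to ordinary t (d0=0)", stacklevel=2
        )
        d0, s0sq = 0.0, 1.0
    else:
        d0, s0sq = _fit_prior_variance(s2_pooled, d_r)

    if d0 == 0:
        s2_post = s2_pooled
        df_total = float(d_r)
    elif np.isinf(d0):
        s2_post = np.full_like(s2_pooled, s0sq)
        df_total = np.inf
    else:
        s2_post = (d0 * s0sq + d_r * s2_pooled) / (d0 + d_r)
        df_total = float(d0 + d_r)

    se = np.sqrt(s2_post * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (mean2 - mean1) / se
    if np.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df_total)

    transcript_genes = transcript_genes or {}
    results = []
    for i, tid in enumerate(m.transcript_ids):
        results.append(
            DeResult(
                transcript_id=tid,
                gene_id=transcript_genes.get(tid, tid),
                log2fc=float(mean2[i] - mean1[i]),
                t_stat=float(t[i]),
                p=float(min(p[i], 1.0)),
                df=df_total,
                mean_log2cpm=float((mean1[i] * n1 + mean2[i] * n2) / (n1 + n2)),
            )
        )
    return results


def filter_de(
    results: Sequence[DeResult],
    p_threshold: float = 0.05,
    lfc_threshold: float = 0.5,
) -> dict[str, list[DeResult]]:
    """Partition results into up / down / ns by p and |log2FC| thresholds."""
    up = [r for r in results if r.p < p_threshold and r.log2fc > lfc_threshold]
    down = [r for r in results if r.p < p_threshold and r.log2fc < -lfc_threshold]
    flagged = {id(r) for r in up} | {id(r) for r in down}
    ns = [r for r in results if id(r) not in flagged]
    return {"up": up, "down": down, "ns": ns}


def prioritize_alt_isoform_genes(
    de_results: Sequence[DeResult],
    transcripts: Sequence[TranscriptModel],
    p_threshold: float = 0.05,
    lfc_threshold: float = 0.5,
) -> pd.DataFrame:
    """Genes with a differentially expressed *non-principal* isoform.

    Returns a gene-level table with reason codes naming the transcript and
    direction.  Genes whose only DE isoforms are principal are excluded.
    Genes lacking any annotated principal transcript are still reported, with
    a warning code.
    """
    principal = {t.transcript_id: t.principal for t in transcripts}
    gene_has_principal: dict[str, bool] = {}
    for t in transcripts:
        gene_has_principal[t.gene_id] = (
            gene_has_principal.get(t.gene_id, False) or t.principal
        )
    parts = filter_de(de_results, p_threshold, lfc_threshold)
    rows: dict[str, dict] = {}
    for direction in ("up", "down"):
        for r in parts[direction]:
            if principal.get(r.transcript_id, False):
                continue
            rec = rows.setdefault(
                r.gene_id, {"gene_id": r.gene_id, "reasons": []}
            )
            code = f"non-principal {direction}: {r.transcript_id}"
            if not gene_has_principal.get(r.gene_id, False):
                code += " [warning: gene has no annotated principal transcript]"
            rec["reasons"].append(code)
    return pd.DataFrame(
        [
            {"gene_id": g, "reason": "; ".join(rec["reasons"])}
            for g, rec in sorted(rows.items())
        ]
    )


def ddcq_fold_change(
    cq_target_cond: float,
    cq_ref_cond: float,
    cq_target_ctrl: float,
    cq_ref_ctrl: float,
) -> float:
    """Comparative 2^-ddCq relative quantification.

    ddCq = (Cq_target,condition - Cq_reference,condition)
         - (Cq_target,control  - Cq_reference,control); returns 2^-ddCq.
    """
    for v in (cq_target_cond, cq_ref_cond, cq_target_ctrl, cq_ref_ctrl):
        if not np.isfinite(v):
            raise DataError("Cq values must be finite")
    ddcq = (cq_target_cond - cq_ref_cond) - (cq_target_ctrl - cq_ref_ctrl)
    return float(2.0 ** (-ddcq))
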