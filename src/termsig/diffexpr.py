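"""Per-gene differential expression between two genotypes.

Expression per gene and replicate is the median of in-span probes; the
significance test runs on the log2 of those per-replicate values (Student's
t-test by default -- the two genotypes are hybridized and processed
identically, and with triplicates the equal-variance test is the one whose
type-I error matches its nominal level; Welch's and Wilcoxon rank-sum
variants are available), and the fold change
compares the across-replicate mean expression of the two genotypes as a
signed ratio whose magnitude is always >= 1.  A gene is called *under* when
fc <= -fc_threshold and p < alpha, *over* when fc >= +fc_threshold and
p < alpha (thresholds inclusive, significance strict); everything else
measurable is *unchanged*.  Raw p-values are used by default; an optional
Benjamini-Hochberg adjustment is available but off, mirroring FC-gated raw-p
reporting conventions for triplicate arrays.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .annotation import GenomeAnnotation
from .signal import SignalSet, region_signal

__all__ = ["DEConfig", "signed_fold_change", "call_de", "DE_COLUMNS"]

DE_COLUMNS = ["gene_id", "expr_wt", "expr_mut", "fc", "p", "call", "biotype"]


@dataclass
class DEConfig:
    """Thresholds and test choice for differential-expression calling."""

    fc_threshold: float = 1.9
    alpha: float = 0.01
    test: str = "student_t_on_log2"  # or "welch_t_on_log2", "wilcoxon_ranksum"
    adjust: str = "none"  # or "bh"

    def __post_init__(self):
        if not self.fc_threshold > 1:
            raise ValueError("fc_threshold must be > 1")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.test not in ("student_t_on_log2", "welch_t_on_log2",
                             "wilcoxon_ranksum"):
            raise ValueError(f"unknown test {self.test!r}")
        if self.adjust not in ("none", "bh"):
            raise ValueError(f"unknown adjustment {self.adjust!r}")


def signed_fold_change(expr_wt: float, expr_mut: float) -> float:
    """Signed fold change with |fc| >= 1: mut/wt if mut >= wt else -(wt/mut)."""
    if not (expr_wt > 0 and expr_mut > 0):
        raise ValueError("expressions must be positive (apply the floor upstream)")
    if expr_mut >= expr_wt:
        return expr_mut / expr_wt
    return -(expr_wt / expr_mut)


def _replicate_matrix(
    sset: SignalSet, genes, genotype: str, region_attr: str
) -> np.ndarray:
    """(n_genes, n_replicates) per-replicate gene medians; NaN = unmeasured."""
    reps = sset.replicates
    out = np.full((len(genes), len(reps)), np.nan)
    for j, rep in enumerate(reps):
        tracks = {s: sset.track(genotype, rep, s) for s in sset.strands}
        for i, g in enumerate(genes):
            region = getattr(g, region_attr)
            region = region if not callable(region) else region()
            track = tracks.get(g.strand)
            if track is None:
                continue
            out[i, j] = region_signal(track, region, stat="median")
    return out


def call_de(
    sset: SignalSet,
    annotation: GenomeAnnotation,
    cfg: Optional[DEConfig] = None,
    wt: str = "wt",
    mut: str = "mut",
    region: str = "span",
) -> pd.DataFrame:
    """Call per-gene differential expression between two genotypes.

    ``region`` selects the summarized interval: ``span`` (default, whole
    annotated gene) or ``orf`` (coding region only, used as the "no change
    in the coding region" gate of the read-through analysis).  Returns one
    row per gene, gene_id ascending, with columns ``gene_id, expr_wt,
    expr_mut, fc, p, call, biotype``; genes with a replicate lacking probes
    are called ``unmeasured``.
    """
    cfg = cfg or DEConfig()
    if region not in ("span", "orf"):
        raise ValueError(f"unknown region {region!r}")
    if len(sset.replicates) < 2:
        raise ValueError("need >= 2 replicates per genotype for a variance estimate")
    genes = sorted(annotation, key=lambda g: g.gene_id)
    region_attr = "span" if region == "span" else "orf"
    mat_wt = _replicate_matrix(sset, genes, wt, region_attr)
    mat_mut = _replicate_matrix(sset, genes, mut, region_attr)

    measured = ~(np.isnan(mat_wt).any(axis=1) | np.isnan(mat_mut).any(axis=1))
    expr_wt = np.where(measured, np.nanmean(mat_wt, axis=1), np.nan)
    expr_mut = np.where(measured, np.nanmean(mat_mut, axis=1), np.nan)

    p = np.full(len(genes), np.nan)
    if measured.any():
        lw = np.log2(np.maximum(mat_wt[measured], np.finfo(float).tiny))
        lm = np.log2(np.maximum(mat_mut[measured], np.finfo(float).tiny))
        if cfg.test in ("student_t_on_log2", "welch_t_on_log2"):
            res = stats.ttest_ind(
                lm, lw, axis=1, equal_var=cfg.test == "student_t_on_log2"
            )
            pvals = np.asarray(res.pvalue, dtype=float)
        else:
            pvals = np.array(
                [
                    stats.mannwhitneyu(a, b, alternative="two-sided").pvalue
                    for a, b in zip(lm, lw)
                ]
            )
        pvals = np.where(np.isnan(pvals), 1.0, pvals)  # zero-variance ties
        if cfg.adjust == "bh":
            pvals = stats.false_discovery_control(pvals, method="bh")
        p[measured] = pvals

    fc = np.full(len(genes), np.nan)
    call = np.full(len(genes), "unmeasured", dtype=object)
    for i, g in enumerate(genes):
        if not measured[i]:
            continue
        fc[i] = signed_fold_change(float(expr_wt[i]), float(expr_mut[i]))
        if p[i] < cfg.alpha and fc[i] <= -cfg.fc_threshold:
            call[i] = "under"
        elif p[i] < cfg.alpha and fc[i] >= cfg.fc_threshold:
            call[i] = "over"
        else:
            call[i] = "unchanged"

    return pd.DataFrame(
        {
            "gene_id": [g.gene_id for g in genes],
            "expr_wt": expr_wt,
            "expr_mut": expr_mut,
            "fc": fc,
            "p": p,
            "call": call,
            "biotype": [g.biotype for g in genes],
        }
    )
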