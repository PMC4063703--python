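"""End-to-end orchestration: simulate/load -> normalize -> DE -> read-through
-> genomic-context tests, with deterministic, machine-readable outputs.

Each stage writes its table under the output directory and failures abort
with the failing stage named.  The summary JSON contains only values the
run itself computed (calls, context p-values, and — when ground truth is
available — recovery metrics), and is byte-identical across runs with the
same seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import __version__
from .annotation import GenomeAnnotation, read_gff3, write_gff3, upstream_same_strand_partner
from .context import (
    PermutationConfig,
    compute_quantity,
    ks_set_vs_null,
    permutation_median_test,
    wilcoxon_departure_from_zero,
)
from .diffexpr import DEConfig, call_de
from .readthrough import ReadthroughConfig, call_readthrough
from .signal import (
    SignalSet,
    quantile_normalize,
    read_signal_tsv,
    write_signal_tsv,
)
from .simulate import GroundTruth, SimulationConfig, simulate_annotation, simulate_signal

__all__ = ["RunConfig", "PipelineError", "run_pipeline", "context_report"]

log = logging.getLogger("termsig")


class PipelineError(RuntimeError):
    """A stage failed; ``stage`` names it."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage {stage!r} failed: {message}")


@dataclass
class RunConfig:
    """Everything one pipeline run needs."""

    out_dir: str = "termsig_out"
    annotation_path: Optional[str] = None
    signal_path: Optional[str] = None
    truth_path: Optional[str] = None
    simulate: bool = False
    seed: int = 0
    n_permutations: int = 10_000
    permutation_mode: str = "sampled"
    write_normalized_signal: bool = False
    log_level: str = "INFO"
    de: DEConfig = field(default_factory=DEConfig)
    rt: ReadthroughConfig = field(default_factory=ReadthroughConfig)
    sim: SimulationConfig = field(default_factory=SimulationConfig)
    wt: str = "wt"
    mut: str = "mut"


def _recovery(called: set[str], truth: set[str]) -> dict:
    tp = len(called & truth)
    sens = tp / len(truth) if truth else float("nan")
    prec = tp / len(called) if called else float("nan")
    return {
        "n_called": len(called),
        "n_truth": len(truth),
        "true_positives": tp,
        "sensitivity": sens,
        "precision": prec,
    }


def context_report(
    annotation: GenomeAnnotation,
    sset: SignalSet,
    de_span: pd.DataFrame,
    rt_table: pd.DataFrame,
    n_permutations: int = 10_000,
    seed: int = 0,
    mode: str = "sampled",
    wt: str = "wt",
) -> dict:
    """The genomic-context test battery for the called gene sets.

    For the under-expressed set: permutation test of the median upstream
    intergenic distance, signed-rank test of the wild-type log2 expression
    ratios of upstream neighbour over focal gene, and a KS comparison of
    the set's antisense-coverage fractions against pooled random-set
    values.  For the read-through (gTERM) set: permutation test of the
    median convergent-pair distance.
    """
    report: dict = {}
    down = sorted(de_span.loc[de_span["call"] == "under", "gene_id"])
    gterm = sorted(rt_table.loc[rt_table["is_gterm"], "gene_id"]) if len(rt_table) else []
    expr_wt = de_span.set_index("gene_id")["expr_wt"]

    def perm(universe: pd.Series, observed: list[str], sub_seed: int) -> Optional[dict]:
        obs = [g for g in observed if g in universe.index]
        if len(obs) < 3:
            return None
        cfg = PermutationConfig(
            n_random_sets=n_permutations, set_size=len(obs),
            seed=seed + sub_seed, mode=mode,
        )
        res = permutation_median_test(universe, obs, cfg)
        return {
            "set_size": len(obs),
            "universe_size": int(universe.size),
            "observed_median": res.observed_stat,
            "k_le": res.k_le,
            "k_ge": res.k_ge,
            "p_le": res.p_le,
            "p_ge": res.p_ge,
            "p_report": res.p_report,
        }

    igr_universe = compute_quantity(annotation, "igr")
    report["down_igr"] = perm(igr_universe, down, 1)

    # signed-rank test: log2(upstream neighbour / focal) expression in wild type
    logratios = []
    for gid in down:
        pairing = upstream_same_strand_partner(annotation, gid)
        if pairing is None:
            continue
        e_f = expr_wt.get(gid, np.nan)
        e_p = expr_wt.get(pairing.partner, np.nan)
        if np.isnan(e_f) or np.isnan(e_p) or e_f <= 0 or e_p <= 0:
            continue
        logratios.append(float(np.log2(e_p / e_f)))
    report["down_neighbour_logratio"] = (
        {
            "n": len(logratios),
            "median_log2_ratio": float(np.median(logratios)),
            "wilcoxon_p": wilcoxon_departure_from_zero(logratios),
        }
        if len(logratios) >= 3
        else None
    )

    fas_universe = compute_quantity(annotation, "f_as")
    obs_fas = [g for g in down if g in fas_universe.index]
    if len(obs_fas) >= 3:
        rng = np.random.default_rng(seed + 2)
        values = fas_universe.to_numpy()
        pooled = np.concatenate(
            [
                values[rng.choice(values.size, size=len(obs_fas), replace=False)]
                for _ in range(n_permutations)
            ]
        )
        d, p = ks_set_vs_null(fas_universe.loc[obs_fas].to_numpy(), pooled)
        report["down_fas_ks"] = {
            "n_observed": len(obs_fas),
            "observed_mean_fas": float(fas_universe.loc[obs_fas].mean()),
            "null_mean_fas": float(pooled.mean()),
            "D": d,
            "p": p,
        }
    else:
        report["down_fas_ks"] = None

    igrterm_universe = compute_quantity(annotation, "igr_term")
    report["gterm_igr_term"] = perm(igrterm_universe, gterm, 3)
    return report


def run_pipeline(cfg: RunConfig) -> dict:
    """Run all stages; returns the summary dict (also written as JSON)."""
    logging.basicConfig(level=getattr(logging, cfg.log_level.upper(), logging.INFO))
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    truth: Optional[GroundTruth] = None

    # --- annotation ---------------------------------------------------
    try:
        if cfg.simulate:
            sim = dataclasses.replace(cfg.sim, seed=cfg.seed)
            annotation, truth = simulate_annotation(sim)
            write_gff3(annotation, out / "annotation.gff3")
            truth.to_json(out / "truth.json")
        else:
            if not cfg.annotation_path or not os.path.exists(cfg.annotation_path):
                raise FileNotFoundError(
                    f"annotation path {cfg.annotation_path!r} not found"
                )
            annotation = read_gff3(cfg.annotation_path)
            if cfg.truth_path and os.path.exists(cfg.truth_path):
                truth = GroundTruth.from_json(cfg.truth_path)
    except Exception as exc:
        raise PipelineError("annotation", str(exc)) from exc
    log.info("annotation: %d genes on %d chromosomes", len(annotation),
             len(annotation.chrom_lengths))

    # --- signal -------------------------------------------------------
    try:
        if cfg.simulate:
            sset = simulate_signal(annotation, truth, sim)
        else:
            if not cfg.signal_path or not os.path.exists(cfg.signal_path):
                raise FileNotFoundError(f"signal path {cfg.signal_path!r} not found")
            sset = read_signal_tsv(cfg.signal_path)
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("signal", str(exc)) from exc

    # --- normalize ----------------------------------------------------
    try:
        sset = quantile_normalize(sset)
        if cfg.write_normalized_signal:
            write_signal_tsv(sset, out / "signal_normalized.tsv")
    except Exception as exc:
        raise PipelineError("normalize", str(exc)) from exc

    # --- differential expression -------------------------------------
    try:
        de_span = call_de(sset, annotation, cfg.de, wt=cfg.wt, mut=cfg.mut,
                          region="span")
        de_orf = call_de(sset, annotation, cfg.de, wt=cfg.wt, mut=cfg.mut,
                         region="orf")
        de_span.to_csv(out / "de.tsv", sep="\t", index=False)
    except Exception as exc:
        raise PipelineError("de", str(exc)) from exc

    # --- read-through -------------------------------------------------
    try:
        rt_table = call_readthrough(sset, annotation, de_orf, cfg.rt,
                                    wt=cfg.wt, mut=cfg.mut)
        rt_table.to_csv(out / "readthrough.tsv", sep="\t", index=False)
    except Exception as exc:
        raise PipelineError("readthrough", str(exc)) from exc

    # --- genomic context ----------------------------------------------
    try:
        context = context_report(
            annotation, sset, de_span, rt_table,
            n_permutations=cfg.n_permutations, seed=cfg.seed,
            mode=cfg.permutation_mode, wt=cfg.wt,
        )
        with open(out / "context.json", "w") as fh:
            json.dump(context, fh, indent=2, sort_keys=True)
    except Exception as exc:
        raise PipelineError("context", str(exc)) from exc

    # --- summary -------------------------------------------------------
    try:
        summary: dict = {
            "termsig_version": __version__,
            "seed": cfg.seed,
            "n_genes": len(annotation),
            "de_counts": de_span["call"].value_counts().to_dict(),
            "n_gterm": int(rt_table["is_gterm"].sum()) if len(rt_table) else 0,
            "context": context,
        }
        if truth is not None:
            down_called = set(de_span.loc[de_span["call"] == "under", "gene_id"])
            up_called = set(de_span.loc[de_span["call"] == "over", "gene_id"])
            gterm_called = (
                set(rt_table.loc[rt_table["is_gterm"], "gene_id"])
                if len(rt_table) else set()
            )
            summary["recovery"] = {
                "de_down": _recovery(down_called, set(truth.de_down)),
                "de_up": _recovery(up_called, set(truth.de_up)),
                "readthrough": _recovery(gterm_called, set(truth.readthrough)),
            }
        with open(out / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True)
        with open(out / "run.log", "w") as fh:
            fh.write(f"termsig {__version__}\n")
            fh.write(f"seed: {cfg.seed}\n")
            fh.write(f"config: {dataclasses.asdict(cfg)}\n")
    except Exception as exc:
        raise PipelineError("summary", str(exc)) from exc
    return summary
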