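"""Genomic-context statistics and their empirical nulls.

Three per-gene quantities describe the neighbourhood of a gene:

* ``igr`` -- intergenic distance in bp between the 3'UTR end of the upstream
  same-strand neighbour and the 5'UTR start of the focal gene (ORF boundary
  fallback when a UTR is unannotated); negative when the features overlap;
* ``igr_term`` -- distance between the focal gene's 3' end and the facing
  boundary of the first downstream reverse-orientation gene (gene spans);
  negative when the convergent pair overlaps;
* ``f_as`` -- fraction of the gene span covered by antisense transcription
  (union of opposite-strand gene spans), in [0, 1].

Whether a flagged gene set sits in an unusual context is judged against an
empirical null: the median of the quantity over the flagged set is compared
with medians of many random gene sets of the same size drawn from the
genome.  When no random median is as extreme as the observed one the result
is reported as a bound, "< 1/N".  Supporting tests: an exact signed-rank
test of log-ratios against zero, a two-sample Kolmogorov-Smirnov comparison
of a set's values against the pooled null, and a Mann-Whitney rank-sum
utility for replicate comparisons.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .annotation import (
    GenomeAnnotation,
    GenePairing,
    antisense_overlap_bp,
    downstream_reverse_partner,
    upstream_same_strand_partner,
)

__all__ = [
    "PermutationConfig",
    "ContextTestResult",
    "igr",
    "igr_term",
    "f_as",
    "compute_quantity",
    "permutation_median_test",
    "wilcoxon_departure_from_zero",
    "ks_set_vs_null",
    "ranksum_compare",
]

EXHAUSTIVE_SUBSET_LIMIT = 1_000_000
EXACT_WILCOXON_MAX_N = 25
EXACT_RANKSUM_MIN_GROUP = 8
EXACT_RANKSUM_ENUM_LIMIT = 500_000


# ---------------------------------------------------------------------------
# per-gene quantities


def igr(annotation: GenomeAnnotation, pairing: GenePairing) -> int:
    """Intergenic distance for an upstream same-strand pairing.

    Measured between the partner's 3'UTR end and the focal gene's 5'UTR
    start (ORF boundaries when UTRs are absent), orientation-aware: 0 when
    abutting, negative when overlapping.
    """
    if pairing.relation != "upstream_same_strand":
        raise ValueError("igr requires an upstream_same_strand pairing")
    focal = annotation[pairing.focal]
    partner = annotation[pairing.partner]
    if focal.chrom != partner.chrom:
        raise ValueError("pairing spans different chromosomes")
    f5 = focal.five_prime_interval()
    p3 = partner.three_prime_interval()
    if focal.strand == "+":
        return f5.start - p3.end
    return p3.start - f5.end


def igr_term(annotation: GenomeAnnotation, pairing: GenePairing) -> int:
    """Distance between a gene's 3' end and its convergent downstream partner.

    Uses gene spans; negative iff the spans overlap (the usual situation for
    genes with termination defects).
    """
    if pairing.relation != "downstream_reverse":
        raise ValueError("igr_term requires a downstream_reverse pairing")
    focal = annotation[pairing.focal]
    partner = annotation[pairing.partner]
    if focal.chrom != partner.chrom:
        raise ValueError("pairing spans different chromosomes")
    if focal.strand == partner.strand:
        raise ValueError("downstream_reverse pairing must be opposite-strand")
    if focal.strand == "+":
        return partner.span.start - focal.span.end
    return focal.span.start - partner.span.end


def f_as(annotation: GenomeAnnotation, gene_id: str) -> float:
    """Fraction of the gene span covered by antisense transcription."""
    gene = annotation[gene_id]
    length = gene.span.length
    if length == 0:
        return 0.0
    return antisense_overlap_bp(annotation, gene_id) / length


def compute_quantity(
    annotation: GenomeAnnotation,
    quantity: str,
    biotype: Optional[str] = None,
) -> pd.Series:
    """Per-gene values of one context quantity over the whole annotation.

    Genes for which the quantity is undefined (no partner gene) are omitted,
    so the returned series is directly usable as a sampling universe.
    ``biotype`` optionally restricts the universe to one biotype stratum.
    """
    values: dict[str, float] = {}
    for gene in annotation:
        if biotype is not None and gene.biotype != biotype:
            continue
        gid = gene.gene_id
        if quantity == "igr":
            pairing = upstream_same_strand_partner(annotation, gid)
            if pairing is not None:
                values[gid] = igr(annotation, pairing)
        elif quantity == "igr_term":
            pairing = downstream_reverse_partner(annotation, gid)
            if pairing is not None:
                values[gid] = igr_term(annotation, pairing)
        elif quantity == "f_as":
            values[gid] = f_as(annotation, gid)
        else:
            raise ValueError(f"unknown quantity {quantity!r}")
    s = pd.Series(values, dtype=float).sort_index()
    s.name = quantity
    return s


# ---------------------------------------------------------------------------
# permutation null of the median


@dataclass
class PermutationConfig:
    """How the empirical null of the set median is built."""

    n_random_sets: int = 10_000
    set_size: int = 47
    statistic: str = "median"
    seed: Optional[int] = None
    mode: str = "sampled"  # or "exhaustive"

    def __post_init__(self):
        if self.n_random_sets < 1:
            raise ValueError("n_random_sets must be >= 1")
        if self.statistic != "median":
            raise ValueError("only the median statistic is supported")
        if self.mode not in ("sampled", "exhaustive"):
            raise ValueError(f"unknown mode {self.mode!r}")


@dataclass
class ContextTestResult:
    """Observed set median against an empirical null of random-set medians.

    Tie medians count toward both exceedance sides (conservative).  In
    sampled mode the stored p-values use the add-one convention
    p = (k + 1) / (n + 1) (never exactly zero); in exhaustive mode they are
    the exact enumeration probabilities k / n (the observed set is itself
    one of the enumerated subsets, so k >= 1 on its own side).  When a
    sampled exceedance count is zero, ``p_report`` additionally carries the
    bound-style report "< 1/n".
    """

    observed_stat: float
    null_stats: np.ndarray
    k_le: int
    k_ge: int
    p_le: float
    p_ge: float
    p_report: Optional[str]
    mode: str
    seed: Optional[int] = None

    @property
    def n(self) -> int:
        return int(self.null_stats.size)


def permutation_median_test(
    universe: pd.Series,
    observed_set: Iterable[str],
    cfg: PermutationConfig,
) -> ContextTestResult:
    """Compare the median over a flagged gene set with random-set medians.

    ``universe`` maps gene_id -> quantity value for every gene the quantity
    is defined on; random sets are simple random samples without replacement
    of ``cfg.set_size`` genes from it, drawn independently of each other.
    In exhaustive mode all subsets are enumerated instead (guarded to
    universes with at most 10^6 subsets).
    """
    observed_set = sorted(set(observed_set))
    missing = [g for g in observed_set if g not in universe.index]
    if missing:
        raise ValueError(f"observed genes not in universe: {missing[:5]} ...")
    values = universe.to_numpy(dtype=float)
    n_universe = values.size
    set_size = cfg.set_size
    if set_size > n_universe:
        raise ValueError(
            f"set_size {set_size} exceeds universe size {n_universe}"
        )
    observed_stat = float(np.median(universe.loc[observed_set].to_numpy()))

    seed = cfg.seed
    if cfg.mode == "exhaustive":
        n_subsets = math.comb(n_universe, set_size)
        if n_subsets > EXHAUSTIVE_SUBSET_LIMIT:
            raise ValueError(
                f"{n_subsets} subsets exceed the exhaustive-mode guard "
                f"({EXHAUSTIVE_SUBSET_LIMIT})"
            )
        null = np.fromiter(
            (np.median(np.asarray(c)) for c in combinations(values, set_size)),
            dtype=float,
            count=n_subsets,
        )
    else:
        if seed is None:
            seed = int(np.random.SeedSequence().entropy % (2**31))
            warnings.warn(
                f"no seed supplied; using generated seed {seed}", stacklevel=2
            )
        rng = np.random.default_rng(seed)
        # each row of random keys yields one uniform subset (the set_size
        # smallest keys), vectorized in memory-bounded chunks
        chunk = max(1, int(2e7) // max(1, n_universe))
        null = np.empty(cfg.n_random_sets)
        done = 0
        while done < cfg.n_random_sets:
            m = min(chunk, cfg.n_random_sets - done)
            keys = rng.random((m, n_universe))
            idx = np.argpartition(keys, set_size - 1, axis=1)[:, :set_size]
            null[done : done + m] = np.median(values[idx], axis=1)
            done += m

    k_le = int(np.sum(null <= observed_stat))
    k_ge = int(np.sum(null >= observed_stat))
    n = null.size
    if cfg.mode == "exhaustive":
        p_le = k_le / n
        p_ge = k_ge / n
    else:
        p_le = (k_le + 1) / (n + 1)
        p_ge = (k_ge + 1) / (n + 1)
    p_report = None
    if min(k_le, k_ge) == 0:
        p_report = f"< 1/{n:,}"
    return ContextTestResult(
        observed_stat=observed_stat,
        null_stats=null,
        k_le=k_le,
        k_ge=k_ge,
        p_le=p_le,
        p_ge=p_ge,
        p_report=p_report,
        mode=cfg.mode,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# rank tests


def _signed_rank_exact_p(ranks: np.ndarray, w_pos: float) -> float:
    """Two-sided exact p for the signed-rank statistic, midranks allowed.

    Works on doubled ranks (integers even with .5 midranks) and convolves
    the sign-flip distribution, so ties in |x| are handled exactly.
    """
    doubled = np.rint(2 * ranks).astype(int)
    total = int(doubled.sum())
    counts = np.zeros(total + 1)
    counts[0] = 1.0
    for d in doubled:
        shifted = np.zeros_like(counts)
        shifted[d:] = counts[: total + 1 - d]
        counts = counts + shifted
    counts /= counts.sum()
    w2 = int(round(2 * w_pos))
    p_le = counts[: w2 + 1].sum()
    p_ge = counts[w2:].sum()
    return float(min(1.0, 2 * min(p_le, p_ge)))


def wilcoxon_departure_from_zero(values: Sequence[float]) -> float:
    """Two-sided Wilcoxon signed-rank p-value that the values center on zero.

    Zeros are discarded first (signed-rank convention).  The null is exact
    (full sign-assignment distribution over midranks) for n <= 25 after
    zero-removal and a tie-corrected normal approximation beyond.  An
    all-zero input carries no evidence: p = 1 with a warning.
    """
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise ValueError("need at least one value")
    x = x[x != 0]
    if x.size == 0:
        warnings.warn("all values are zero; degenerate input", stacklevel=2)
        return 1.0
    if x.size <= EXACT_WILCOXON_MAX_N:
        ranks = stats.rankdata(np.abs(x))
        w_pos = float(ranks[x > 0].sum())
        return _signed_rank_exact_p(ranks, w_pos)
    res = stats.wilcoxon(
        x, alternative="two-sided", method="approx", correction=False
    )
    return float(res.pvalue)


def _ranksum_exact_enum_p(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sided exact rank-sum p by enumerating group assignments (ties ok)."""
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)
    na = a.size
    r_obs = float(ranks[:na].sum())
    k_le = k_ge = total = 0
    for idx in combinations(range(pooled.size), na):
        r = float(ranks[list(idx)].sum())
        total += 1
        if r <= r_obs:
            k_le += 1
        if r >= r_obs:
            k_ge += 1
    return min(1.0, 2 * min(k_le, k_ge) / total)


def ranksum_compare(
    a: Sequence[float], b: Sequence[float], method: str = "auto"
) -> float:
    """Two-sided Mann-Whitney rank-sum p-value comparing two samples.

    ``method="auto"`` uses the exact null when the smaller group has <= 8
    observations and a tie-corrected normal approximation otherwise;
    ``"exact"`` forces the exact null (the network distribution when the
    samples are tie-free, group-assignment enumeration when ties are
    present) and ``"asymptotic"`` forces the approximation.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    if method not in ("auto", "exact", "asymptotic"):
        raise ValueError(f"unknown method {method!r}")
    has_ties = np.unique(np.concatenate([a, b])).size < a.size + b.size
    want_exact = method == "exact" or (
        method == "auto" and min(a.size, b.size) <= EXACT_RANKSUM_MIN_GROUP
    )
    if want_exact:
        if not has_ties:
            return float(
                stats.mannwhitneyu(a, b, alternative="two-sided", method="exact").pvalue
            )
        if math.comb(a.size + b.size, min(a.size, b.size)) <= EXACT_RANKSUM_ENUM_LIMIT:
            if a.size <= b.size:
                return _ranksum_exact_enum_p(a, b)
            return _ranksum_exact_enum_p(b, a)
        if method == "exact":
            raise ValueError("samples too large to enumerate the tied exact null")
    return float(
        stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic").pvalue
    )


def ks_set_vs_null(
    observed_values: Sequence[float], null_values: Sequence[float]
) -> tuple[float, float]:
    """Two-sample Kolmogorov-Smirnov D and asymptotic two-sided p-value.

    Compares a flagged set's values (e.g. its antisense-coverage fractions)
    with the pooled values of the random sets forming the empirical null.
    """
    observed_values = np.asarray(observed_values, dtype=float)
    null_values = np.asarray(null_values, dtype=float)
    if observed_values.size == 0 or null_values.size == 0:
        raise ValueError("both samples must be non-empty")
    res = stats.ks_2samp(observed_values, null_values, method="asymp")
    return float(res.statistic), float(res.pvalue)
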