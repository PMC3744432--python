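"""Evaluation statistics for gBGC tract predictions.

Base-level accuracy against planted truth tracts (TPR/FPR/PPV), the
weak->strong derived-allele-frequency skew (a normalized Mann-Whitney U
comparing W->S against S->W DAFs; 0.5 = no fixation bias), per-tract
W->S substitution bias polarized by an outgroup, GC- and length-matched
control-region resampling, and one-sided empirical p-values.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np

from .alignment_io import A, C, G, T, N, AlignmentBlock, GenomicInterval

logger = logging.getLogger(__name__)

WEAK_BASES = frozenset("AT")
STRONG_BASES = frozenset("CG")


# ---------------------------------------------------------------------------
# SNP records and W/S classification


@dataclass
class SNPRecord:
    """A biallelic polymorphic site with ancestral/derived polarity."""

    chrom: str
    pos: int                # 0-based
    ancestral: str | None
    derived: str
    derived_count: int
    sample_size: int
    quality: float = 99.0
    n_alleles: int = 2

    @property
    def daf(self) -> float:
        return self.derived_count / self.sample_size


def classify_ws(ancestral: str, derived: str) -> str:
    """Classify a change as 'WtoS', 'StoW' or 'other' (W={A,T}, S={C,G})."""
    a, d = ancestral.upper(), derived.upper()
    for b in (a, d):
        if b not in WEAK_BASES | STRONG_BASES:
            raise ValueError(f"invalid base {b!r}")
    if a in WEAK_BASES and d in STRONG_BASES:
        return "WtoS"
    if a in STRONG_BASES and d in WEAK_BASES:
        return "StoW"
    return "other"


def filter_snps(
    records: Iterable[SNPRecord], min_gq: float = 5.0
) -> list[SNPRecord]:
    """Drop low-quality (GQ < min_gq), multi-allelic, or unpolarized sites."""
    return [
        r
        for r in records
        if r.quality >= min_gq and r.n_alleles <= 2 and r.ancestral
    ]


def read_snp_table(path: str) -> list[SNPRecord]:
    """Read a TSV of (chrom, pos, ancestral, derived, count, size[, GQ])."""
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            out.append(
                SNPRecord(
                    chrom=f[0],
                    pos=int(f[1]),
                    ancestral=f[2] if f[2] not in (".", "") else None,
                    derived=f[3],
                    derived_count=int(f[4]),
                    sample_size=int(f[5]),
                    quality=float(f[6]) if len(f) > 6 else 99.0,
                )
            )
    return out


# ---------------------------------------------------------------------------
# DAF skew


def _mann_whitney_u(x: np.ndarray, y: np.ndarray) -> float:
    """U statistic counting pairs (x_i > y_j) with ties as 1/2, via ranks."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    allv = np.concatenate([x, y])
    order = np.argsort(allv, kind="mergesort")
    ranks = np.empty(allv.size)
    ranks[order] = np.arange(1, allv.size + 1)
    # average ranks over ties
    sv = allv[order]
    i = 0
    while i < sv.size:
        j = i
        while j + 1 < sv.size and sv[j + 1] == sv[i]:
            j += 1
        if j > i:
            ranks[order[i : j + 1]] = (i + j + 2) / 2.0
        i = j + 1
    r1 = ranks[: x.size].sum()
    return float(r1 - x.size * (x.size + 1) / 2.0)


def daf_skew(
    ws_dafs: Sequence[float],
    sw_dafs: Sequence[float],
    n_bootstrap: int = 1000,
    seed: int = 0,
    ci: bool = True,
) -> tuple[float, tuple[float, float] | None]:
    """W->S DAF skew: normalized Mann-Whitney U in [0, 1].

    skew = U / (n1*n2) where U counts pairs with a W->S DAF above an S->W
    DAF (ties as one half); 0.5 means no bias, > 0.5 means W->S alleles
    segregate at higher frequencies.  The 95% CI is a percentile bootstrap
    over SNPs.
    """
    ws = np.asarray(ws_dafs, dtype=float)
    sw = np.asarray(sw_dafs, dtype=float)
    if ws.size == 0 or sw.size == 0:
        raise ValueError("both DAF lists must be non-empty")
    skew = _mann_whitney_u(ws, sw) / (ws.size * sw.size)
    if not ci:
        return skew, None
    rng = np.random.default_rng(seed)
    boots = np.empty(n_bootstrap)
    for b in range(n_bootstrap):
        wsb = ws[rng.integers(0, ws.size, ws.size)]
        swb = sw[rng.integers(0, sw.size, sw.size)]
        boots[b] = _mann_whitney_u(wsb, swb) / (ws.size * sw.size)
    lo, hi = np.percentile(boots, [2.5, 97.5])
    return skew, (float(lo), float(hi))


# ---------------------------------------------------------------------------
# Target-lineage W->S substitution bias


def ws_substitutions(
    block: AlignmentBlock,
    start: int | None = None,
    end: int | None = None,
    sister: str | None = None,
    outgroup: str | None = None,
) -> tuple[int, int]:
    """Count target-lineage (W->S, S->W) substitutions in [start, end).

    A column contributes when target != sister and the outgroup matches
    exactly one of them; the outgroup allele is taken as ancestral.  By
    default sister/outgroup are the second and third taxa of the block
    (chimpanzee and orangutan in the canonical order).
    """
    names = block.species
    sister = sister or names[1 if block.target_row != 1 else 0]
    outgroup = outgroup or names[2]
    t = block.seqs[block.target_row]
    s = block.seqs[names.index(sister)]
    o = block.seqs[names.index(outgroup)]
    sel = np.ones(block.n_columns, dtype=bool)
    if start is not None:
        sel &= block.ref_coords >= start
    if end is not None:
        sel &= block.ref_coords < end
    valid = sel & (t < 4) & (s < 4) & (o < 4) & (t != s)
    # outgroup must match exactly one of target/sister; ancestral = outgroup
    anc_is_sister = valid & (o == s) & (o != t)
    weak = np.isin(o, (A, T))
    strong = np.isin(o, (C, G))
    t_strong = np.isin(t, (C, G))
    t_weak = np.isin(t, (A, T))
    ws = int((anc_is_sister & weak & t_strong).sum())
    sw = int((anc_is_sister & strong & t_weak).sum())
    return ws, sw


def ws_bias_per_tract(
    tract: GenomicInterval,
    block: AlignmentBlock,
    outgroup: str | None = None,
) -> float | None:
    """Fraction of target-lineage W<->S substitutions in the tract that are
    W->S; None (undefined) when the tract has no such substitutions."""
    ws, sw = ws_substitutions(
        block, tract.start, tract.end, outgroup=outgroup
    )
    if ws + sw == 0:
        return None
    return ws / (ws + sw)


# ---------------------------------------------------------------------------
# Base-level accuracy


@dataclass
class AccuracyResult:
    """Base-level TPR/FPR/PPV with the underlying base counts."""

    tpr: float
    fpr: float
    ppv: float | None       # None when zero bases were predicted
    n_truth: int
    n_predicted: int
    n_correct: int
    universe_size: int


def _interval_mask(intervals: Sequence, universe_size: int) -> np.ndarray:
    mask = np.zeros(universe_size, dtype=bool)
    for iv in intervals:
        if iv.start < 0 or iv.end > universe_size:
            raise ValueError(f"interval {iv} outside universe")
        mask[iv.start : iv.end] = True
    return mask


def prediction_accuracy(
    predicted: Sequence, truth: Sequence, universe_size: int
) -> AccuracyResult:
    """Base-level accuracy: TPR = correct/truth bases, FPR = incorrect
    predicted/non-truth bases, PPV = correct/predicted bases."""
    pred = _interval_mask(predicted, universe_size)
    tru = _interval_mask(truth, universe_size)
    n_correct = int((pred & tru).sum())
    n_pred = int(pred.sum())
    n_tru = int(tru.sum())
    tpr = n_correct / n_tru if n_tru else 0.0
    neg = universe_size - n_tru
    fpr = (n_pred - n_correct) / neg if neg else 0.0
    ppv = n_correct / n_pred if n_pred else None
    return AccuracyResult(
        tpr=tpr, fpr=fpr, ppv=ppv,
        n_truth=n_tru, n_predicted=n_pred, n_correct=n_correct,
        universe_size=universe_size,
    )


# ---------------------------------------------------------------------------
# Matched control regions and empirical significance


@dataclass
class ControlRegionSet:
    """Replicated control regions matched to a query interval set."""

    replicates: list[list[GenomicInterval]]
    gc_bins: list[int]          # per query region
    n_gc_bins: int


def _gc_fraction(seq_codes: np.ndarray, start: int, end: int) -> float | None:
    win = seq_codes[start:end]
    known = win < 4
    if not known.any():
        return None
    return float(np.isin(win[known], (C, G)).mean())


def sample_control_regions(
    query: Sequence[GenomicInterval],
    genome: dict[str, np.ndarray],
    n_replicates: int = 1000,
    n_gc_bins: int = 100,
    seed: int = 0,
    max_tries: int = 100_000,
) -> ControlRegionSet:
    """Sample control regions matched in number, length, chromosome and GC.

    ``genome`` maps chromosome name to encoded sequence (uint8 codes).
    GC bins are equal-width on [0, 1]; per replicate each query region gets
    a random same-length, same-chromosome, GC-bin-matched interval that
    does not overlap any query region.  After ``max_tries`` rejections the
    GC constraint is relaxed to the nearest populated bin with a warning.
    """
    rng = np.random.default_rng(seed)
    cum_gc: dict[str, np.ndarray] = {}
    for chrom, codes in genome.items():
        cum_gc[chrom] = np.concatenate(
            [[0], np.cumsum(np.isin(codes, (C, G)) & (codes < 4))]
        )
    qbins: list[int] = []
    kept_query: list[GenomicInterval] = []
    for q in query:
        gc = _gc_fraction(genome[q.chrom], q.start, q.end)
        if gc is None:
            warnings.warn(f"query region {q.chrom}:{q.start}-{q.end} is all-N;"
                          " excluded from matching")
            continue
        qbins.append(min(int(gc * n_gc_bins), n_gc_bins - 1))
        kept_query.append(q)

    qmask = {
        chrom: _interval_mask(
            [q for q in kept_query if q.chrom == chrom], len(genome[chrom])
        )
        for chrom in genome
    }

    replicates = []
    for _ in range(n_replicates):
        regions = []
        for q, qbin in zip(kept_query, qbins):
            regions.append(
                _sample_one(q, qbin, genome, cum_gc, qmask, n_gc_bins,
                            rng, max_tries)
            )
        replicates.append(regions)
    return ControlRegionSet(
        replicates=replicates, gc_bins=qbins, n_gc_bins=n_gc_bins
    )


def _sample_one(q, qbin, genome, cum_gc, qmask, n_gc_bins, rng, max_tries):
    codes = genome[q.chrom]
    length = len(q)
    limit = len(codes) - length
    if limit < 0:
        raise ValueError(
            f"cannot place control for {q.chrom}:{q.start}-{q.end}: "
            "chromosome shorter than region"
        )
    best, best_dist = None, np.inf
    for trial in range(max_tries):
        start = int(rng.integers(0, limit + 1))
        if qmask[q.chrom][start : start + length].any():
            continue
        n_gc = cum_gc[q.chrom][start + length] - cum_gc[q.chrom][start]
        gc = n_gc / length
        b = min(int(gc * n_gc_bins), n_gc_bins - 1)
        if b == qbin:
            return GenomicInterval(q.chrom, start, start + length)
        if abs(b - qbin) < best_dist:
            best, best_dist = (start, b), abs(b - qbin)
    if best is None:
        raise ValueError(
            f"cannot place control for {q.chrom}:{q.start}-{q.end}: "
            "no non-overlapping position found"
        )
    warnings.warn(
        f"control for {q.chrom}:{q.start}-{q.end}: GC bin relaxed "
        f"{qbin} -> {best[1]}"
    )
    return GenomicInterval(q.chrom, best[0], best[0] + length)


def empirical_pvalue(
    observed_stat: float,
    control_stats: Sequence[float],
    direction: Literal["ge", "le"] = "ge",
) -> tuple[float, str]:
    """One-sided empirical p-value: fraction of control statistics at least
    as extreme as observed (ties count).  Returns (p, report string); a
    zero count reports "< 1/N"."""
    stats = np.asarray(control_stats, dtype=float)
    if stats.size == 0:
        raise ValueError("need at least one control statistic")
    if direction == "ge":
        count = int((stats >= observed_stat).sum())
    elif direction == "le":
        count = int((stats <= observed_stat).sum())
    else:
        raise ValueError("direction must be 'ge' or 'le'")
    n = stats.size
    p = count / n
    report = f"p < {1 / n:g}" if count == 0 else f"p = {p:g}"
    return p, report


def overlap_statistics(
    query: Sequence[GenomicInterval], features: Sequence[GenomicInterval]
) -> tuple[int, int]:
    """(number of query regions overlapping >= 1 feature, total overlapping
    bases), half-open semantics; inputs must be sorted by (chrom, start)."""
    for seq in (query, features):
        keys = [(iv.chrom, iv.start) for iv in seq]
        if keys != sorted(keys):
            raise ValueError("intervals must be sorted by (chrom, start)")
    n_regions = 0
    n_bases = 0
    feats = list(features)
    j0 = 0
    for q in query:
        overlap = 0
        for f in feats:
            if f.chrom < q.chrom or (f.chrom == q.chrom and f.end <= q.start):
                continue
            if f.chrom > q.chrom or f.start >= q.end:
                if f.chrom == q.chrom and f.start >= q.end:
                    break
                continue
            overlap += min(q.end, f.end) - max(q.start, f.start)
        if overlap > 0:
            n_regions += 1
            n_bases += overlap
    return n_regions, n_bases
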