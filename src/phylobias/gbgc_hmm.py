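"""Four-state phylo-HMM for gBGC tract detection.

States, in order: n (neutral), b (neutral + gBGC), c (conserved),
cb (conserved + gBGC).  The transition matrix is the cross product of an
independent two-state conservation chain (rates nu in / mu out) and a
two-state gBGC chain (beta in / alpha out), so e.g. P(n -> cb) = nu * beta.
Emissions are phylogenetic column likelihoods from
:mod:`phylobias.phylo_model`, cached over the <= 5^4 distinct column
patterns of a block.

Inference is forward/backward with per-column scaling (no underflow at any
block length); beta, the only free transition parameter, is fitted per
block by Baum-Welch restricted to that single parameter.  Tracts are
maximal runs of columns whose marginal posterior of gBGC, P(b) + P(cb),
is at least 0.5 - posterior thresholding rather than Viterbi, because path
uncertainty about tract endpoints makes max-product decoding miss tracts
whose posterior is high.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace

import numpy as np
from numba import njit

from .alignment_io import (
    AlignmentBlock,
    GenomicInterval,
    drop_target_gap_columns,
    partition_blocks,
    read_alignment,
    write_posterior_wig,
    write_tracts_bed,
)
from .phylo_model import (
    NeutralModel,
    PhyloTree,
    StateModelSet,
    build_state_models,
    column_patterns,
    fit_neutral_model,
    pattern_log_likelihoods,
)

logger = logging.getLogger(__name__)

STATE_NAMES = ("n", "b", "c", "cb")
GBGC_STATES = (1, 3)
BETA_FLOOR = 1e-8


@dataclass
class HMMParams:
    """State-transition parameters of the four-state chain.

    Defaults follow the phastCons conservation values (mu, nu) and a prior
    expected gBGC tract length of 1/alpha = 1000 bp; beta is fitted per
    block by EM.
    """

    mu: float = 0.022
    nu: float = 0.0095
    alpha: float = 0.001
    beta: float = 1e-5

    def __post_init__(self) -> None:
        # zero is tolerated (degenerate chain with no transitions of that
        # kind); one is not, since 1-v must stay a valid self-loop prob
        for name in ("mu", "nu", "alpha", "beta"):
            v = getattr(self, name)
            if not 0 <= v < 1:
                raise ValueError(f"{name}={v} must lie in [0, 1)")


def build_transition_matrix(params: HMMParams) -> np.ndarray:
    """Cross-product transition matrix over states (n, b, c, cb)."""
    cons = np.array([[1 - params.nu, params.nu], [params.mu, 1 - params.mu]])
    gbgc = np.array([[1 - params.beta, params.beta],
                     [params.alpha, 1 - params.alpha]])
    return np.kron(cons, gbgc)


def initial_distribution(params: HMMParams) -> np.ndarray:
    """Stationary distribution of the cross-product chain."""
    cons_total = params.mu + params.nu
    gbgc_total = params.alpha + params.beta
    pc = params.nu / cons_total if cons_total > 0 else 0.0   # P(conserved)
    pg = params.beta / gbgc_total if gbgc_total > 0 else 0.0  # P(gBGC)
    return np.kron([1 - pc, pc], [1 - pg, pg])


# ---------------------------------------------------------------------------
# Scaled forward/backward and Viterbi (numba kernels)


@njit(cache=True)
def _forward_backward_kernel(init, P, em):  # pragma: no cover - jitted
    L, S = em.shape
    alpha = np.empty((L, S))
    beta = np.empty((L, S))
    scale = np.empty(L)
    a = init * em[0]
    s = a.sum()
    alpha[0] = a / s
    scale[0] = s
    for t in range(1, L):
        a = (alpha[t - 1] @ P) * em[t]
        s = a.sum()
        alpha[t] = a / s
        scale[t] = s
    beta[L - 1] = 1.0
    for t in range(L - 2, -1, -1):
        beta[t] = (P @ (em[t + 1] * beta[t + 1])) / scale[t + 1]
    post = alpha * beta
    xi = np.zeros((S, S))
    for t in range(L - 1):
        w = em[t + 1] * beta[t + 1] / scale[t + 1]
        for i in range(S):
            for j in range(S):
                xi[i, j] += alpha[t, i] * P[i, j] * w[j]
    return post, scale, xi


@njit(cache=True)
def _viterbi_kernel(log_init, logP, logem):  # pragma: no cover - jitted
    L, S = logem.shape
    delta = log_init + logem[0]
    back = np.zeros((L, S), dtype=np.int64)
    for t in range(1, L):
        nd = np.empty(S)
        for j in range(S):
            best, arg = -1e300, 0
            for i in range(S):
                v = delta[i] + logP[i, j]
                if v > best:
                    best, arg = v, i
            nd[j] = best + logem[t, j]
            back[t, j] = arg
        delta = nd
    path = np.empty(L, dtype=np.int64)
    path[L - 1] = np.argmax(delta)
    for t in range(L - 2, -1, -1):
        path[t] = back[t + 1, path[t + 1]]
    return path


@dataclass
class PosteriorTrack:
    """Per-column state posteriors with reference coordinates."""

    ref_coords: np.ndarray
    state_posteriors: np.ndarray   # (L, 4), rows sum to 1
    chrom: str = "chrSim"

    @property
    def p_gbgc(self) -> np.ndarray:
        return self.state_posteriors[:, GBGC_STATES].sum(axis=1)


def emission_log_likelihoods(
    block: AlignmentBlock, models: StateModelSet
) -> np.ndarray:
    """(L, 4) emission log-likelihood matrix via column-pattern caching."""
    inv, pats = column_patterns(block)
    per_pat = np.column_stack(
        [pattern_log_likelihoods(pats, m) for m in models.models]
    )
    return per_pat[inv]


def forward_backward(
    block: AlignmentBlock,
    models: StateModelSet,
    params: HMMParams,
    logem: np.ndarray | None = None,
    init: np.ndarray | None = None,
) -> tuple[PosteriorTrack, float, np.ndarray]:
    """Exact state posteriors, total log-likelihood and expected transition
    counts for one block."""
    if logem is None:
        logem = emission_log_likelihoods(block, models)
    P = build_transition_matrix(params)
    if init is None:
        init = initial_distribution(params)
    shift = logem.max(axis=1, keepdims=True)
    em = np.exp(logem - shift)
    post, scale, xi = _forward_backward_kernel(init, P, em)
    loglik = float(np.log(scale).sum() + shift.sum())
    track = PosteriorTrack(
        ref_coords=block.ref_coords, state_posteriors=post, chrom=block.chrom
    )
    return track, loglik, xi


def viterbi(
    block: AlignmentBlock, models: StateModelSet, params: HMMParams
) -> np.ndarray:
    """Max-product state path (diagnostics only; not used for tract calls)."""
    logem = emission_log_likelihoods(block, models)
    with np.errstate(divide="ignore"):
        logP = np.log(build_transition_matrix(params))
        log_init = np.log(initial_distribution(params))
    return _viterbi_kernel(log_init, logP, logem)


# ---------------------------------------------------------------------------
# EM for beta


def em_fit_beta(
    block: AlignmentBlock,
    models: StateModelSet,
    params: HMMParams,
    tol: float = 1e-4,
    max_iter: int = 100,
    logem: np.ndarray | None = None,
) -> tuple[HMMParams, list[float]]:
    """Baum-Welch restricted to beta (all other parameters fixed).

    Per iteration beta_hat = E[# transitions from {n,c} into {b,cb}] /
    E[# transitions out of {n,c}]; the log-likelihood is non-decreasing.
    The initial state distribution is held at the stationary distribution
    of the starting parameters throughout, so the single-parameter M-step
    is exact.  A fit collapsing toward zero is clamped at ``BETA_FLOOR``
    with a warning (no gBGC signal in the block).
    """
    if logem is None:
        logem = emission_log_likelihoods(block, models)
    init = initial_distribution(params)
    trace: list[float] = []
    beta = params.beta
    non_g, g = (0, 2), (1, 3)
    for _ in range(max_iter):
        cur = replace(params, beta=beta)
        _, ll, xi = forward_backward(block, models, cur, logem=logem, init=init)
        trace.append(ll)
        denom = xi[non_g, :].sum()
        numer = xi[np.ix_(non_g, g)].sum()
        new_beta = max(numer / denom if denom > 0 else 0.0, BETA_FLOOR)
        if len(trace) >= 2 and abs(trace[-1] - trace[-2]) < tol:
            beta = new_beta
            break
        beta = new_beta
    if beta < 10 * BETA_FLOOR:
        warnings.warn("EM drove beta to ~0; clamped (no gBGC signal)")
        beta = BETA_FLOOR
    return replace(params, beta=beta), trace


# ---------------------------------------------------------------------------
# Tract calling


@dataclass
class Tract:
    """A predicted gBGC tract: reference interval, mean posterior score and
    (optional) count of target-lineage W->S substitutions inside it."""

    interval: GenomicInterval
    score: float
    n_ws: int | None = None

    @property
    def chrom(self) -> str:
        return self.interval.chrom

    @property
    def start(self) -> int:
        return self.interval.start

    @property
    def end(self) -> int:
        return self.interval.end


def call_tracts(
    track: PosteriorTrack,
    threshold: float = 0.5,
    max_coord_gap: int = 1000,
) -> list[Tract]:
    """Maximal runs of columns with P(gBGC) >= threshold (inclusive).

    Coordinate gaps between consecutive columns (from filtered columns) do
    not break a run unless they exceed ``max_coord_gap`` reference bp.
    """
    if not 0 < threshold < 1:
        raise ValueError("threshold must lie in (0, 1)")
    p = track.p_gbgc
    above = p >= threshold
    tracts: list[Tract] = []
    i, L = 0, len(p)
    while i < L:
        if not above[i]:
            i += 1
            continue
        j = i
        while (
            j + 1 < L
            and above[j + 1]
            and track.ref_coords[j + 1] - track.ref_coords[j] <= max_coord_gap
        ):
            j += 1
        iv = GenomicInterval(
            track.chrom,
            int(track.ref_coords[i]),
            int(track.ref_coords[j]) + 1,
            score=float(p[i : j + 1].mean()),
        )
        tracts.append(Tract(interval=iv, score=iv.score))
        i = j + 1
    return tracts


def merge_tracts(tracts: list[Tract], max_gap: int = 1000) -> list[Tract]:
    """Merge same-chromosome tracts separated by <= max_gap bp.

    Input must be sorted and non-overlapping; scores are recombined as
    length-weighted means of the inputs.
    """
    for a, b in zip(tracts, tracts[1:]):
        if a.chrom == b.chrom and b.start < a.end:
            raise ValueError("tracts overlap or are unsorted")
    out: list[Tract] = []
    for t in tracts:
        if out and t.chrom == out[-1].chrom and t.start - out[-1].end <= max_gap:
            prev = out[-1]
            w1, w2 = prev.end - prev.start, t.end - t.start
            score = (prev.score * w1 + t.score * w2) / (w1 + w2)
            n_ws = (
                prev.n_ws + t.n_ws
                if prev.n_ws is not None and t.n_ws is not None
                else None
            )
            out[-1] = Tract(
                GenomicInterval(prev.chrom, prev.start, t.end, score=score),
                score=score,
                n_ws=n_ws,
            )
        else:
            out.append(t)
    return out


def _count_ws_substitutions(block: AlignmentBlock, tract: Tract) -> int:
    """Target-lineage W->S substitutions inside a tract, polarized by the
    outgroup (third leaf) matching exactly one of target/sister."""
    from .popgen_eval import ws_substitutions  # local import to avoid cycle

    ws, _ = ws_substitutions(block, tract.start, tract.end)
    return ws


# ---------------------------------------------------------------------------
# End-to-end pipeline


@dataclass
class BlockResult:
    """Per-block fitting and prediction summary."""

    chrom: str
    start: int
    end: int
    n_columns: int
    neutral: NeutralModel
    loglik_neutral: float
    params: HMMParams
    loglik_hmm: float
    em_iterations: int
    track: PosteriorTrack
    tracts: list[Tract]


@dataclass
class PipelineResult:
    blocks: list[BlockResult]
    tracts: list[Tract]

    def report_frame(self):
        import pandas as pd

        rows = []
        for b in self.blocks:
            rows.append(
                {
                    "chrom": b.chrom,
                    "start": b.start,
                    "end": b.end,
                    "n_columns": b.n_columns,
                    "lambda": b.neutral.lam,
                    "kappa": b.neutral.kappa,
                    "pi_A": b.neutral.pi[0],
                    "pi_C": b.neutral.pi[1],
                    "pi_G": b.neutral.pi[2],
                    "pi_T": b.neutral.pi[3],
                    "beta": b.params.beta,
                    "loglik": b.loglik_hmm,
                    "em_iterations": b.em_iterations,
                    "n_tracts": len(b.tracts),
                }
            )
        return pd.DataFrame(rows)


def predict_tracts(
    blocks: list[AlignmentBlock],
    tree: PhyloTree,
    B: float = 3.0,
    rho: float = 0.31,
    params: HMMParams | None = None,
    threshold: float = 0.5,
    merge_gap: int = 0,
    preprocess: bool = True,
    block_size: int = 10_000_000,
) -> PipelineResult:
    """Library entry point: preprocess, fit, decode and call tracts.

    Per block: fit the neutral model, build the four state models with the
    given tuning B and rho, EM-fit beta, run forward/backward and call
    posterior tracts.  Deterministic given inputs and configuration.
    """
    params = params or HMMParams()
    if preprocess:
        blocks = [drop_target_gap_columns(b) for b in blocks]
        blocks = partition_blocks(blocks, block_size=block_size)
    results: list[BlockResult] = []
    all_tracts: list[Tract] = []
    for blk in blocks:
        blk = _reorder_to_tree(blk, tree)
        neutral, ll_neutral = fit_neutral_model(blk, tree)
        models = build_state_models(neutral, rho=rho, B=B)
        logem = emission_log_likelihoods(blk, models)
        fitted, trace = em_fit_beta(blk, models, params, logem=logem)
        track, ll, _ = forward_backward(blk, models, fitted, logem=logem)
        tracts = call_tracts(track, threshold=threshold)
        if merge_gap > 0:
            tracts = merge_tracts(tracts, max_gap=merge_gap)
        for t in tracts:
            t.n_ws = _count_ws_substitutions(blk, t)
        logger.info(
            "block %s:%d-%d  cols=%d beta=%.3g logL=%.2f tracts=%d",
            blk.chrom, blk.start, blk.end, blk.n_columns,
            fitted.beta, ll, len(tracts),
        )
        results.append(
            BlockResult(
                chrom=blk.chrom,
                start=blk.start,
                end=blk.end,
                n_columns=blk.n_columns,
                neutral=neutral,
                loglik_neutral=ll_neutral,
                params=fitted,
                loglik_hmm=ll,
                em_iterations=len(trace),
                track=track,
                tracts=tracts,
            )
        )
        all_tracts.extend(tracts)
    all_tracts.sort(key=lambda t: (t.chrom, t.start))
    return PipelineResult(blocks=results, tracts=all_tracts)


def _reorder_to_tree(block: AlignmentBlock, tree: PhyloTree) -> AlignmentBlock:
    if block.species == tree.leaf_names:
        return block
    try:
        idx = [block.species.index(sp) for sp in tree.leaf_names]
    except ValueError as exc:
        raise ValueError(f"block lacks tree taxon: {exc}") from exc
    return replace(block, species=list(tree.leaf_names), seqs=block.seqs[idx])


def run_pipeline(
    alignment_path: str,
    target: str,
    out_prefix: str,
    format: str = "maf",
    tree: PhyloTree | None = None,
    B: float = 3.0,
    rho: float = 0.31,
    params: HMMParams | None = None,
    threshold: float = 0.5,
    merge_gap: int = 0,
    block_size: int = 10_000_000,
    provenance: str = "",
) -> PipelineResult:
    """File-to-file pipeline: alignment in, BED + WIG + TSV report out."""
    tree = tree or PhyloTree.default(target=target)
    if tree.target != target:
        tree = replace(tree, target=target)
    blocks = read_alignment(
        alignment_path, format=format, target=target, species=tree.leaf_names
    )
    result = predict_tracts(
        blocks, tree, B=B, rho=rho, params=params,
        threshold=threshold, merge_gap=merge_gap, block_size=block_size,
    )
    write_tracts_bed(
        [t.interval for t in result.tracts],
        f"{out_prefix}.tracts.bed",
        header=provenance or f"gBGC tracts (B={B})",
    )
    for i, br in enumerate(result.blocks):
        suffix = f".block{i}" if len(result.blocks) > 1 else ""
        write_posterior_wig(
            br.track.ref_coords,
            br.track.p_gbgc,
            br.chrom,
            f"{out_prefix}{suffix}.posterior.wig",
        )
    frame = result.report_frame()
    with open(f"{out_prefix}.report.tsv", "w") as fh:
        if provenance:
            fh.write(f"# {provenance}\n")
        frame.to_csv(fh, sep="\t", index=False)
    return result
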