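"""Synthetic four-species alignments with planted gBGC tracts.

Two complementary modes:

* **De novo simulation** draws a root sequence from the stationary
  distribution and evolves it down every branch of the tree with
  per-column, per-category transition matrices, planting conserved
  elements and gBGC tracts with known (truth) coordinates.

* **Conditional target-leaf resimulation** takes any existing alignment
  (real or de novo), assigns each column one of eight category models
  (conserved x CpG x gBGC), and replaces only the target row with a draw
  from the marginal distribution of the target leaf conditional on the
  other species - so every feature of the non-target rows (missing data,
  rate variation, composition) is preserved bit-exactly.

Category models compose the neutral model with: branch scaling by rho
(conserved), a lambda multiplier for CpG-flagged columns (elevated
mutability), and the gBGC rate modification on the target branch.
All randomness flows from a single integer seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np

from .alignment_io import A, C, G, T, N, AlignmentBlock, GenomicInterval
from .phylo_model import (
    NeutralModel,
    StateModel,
    column_patterns,
    leaf_conditional_distributions,
)

logger = logging.getLogger(__name__)


@dataclass
class SimConfig:
    """Study conditions for a simulation run.

    ``coverage`` is the fraction of columns inside gBGC tracts (0.001
    matches a genome sparsely touched by biased conversion); tract lengths
    are fixed.  ``conserved_fraction`` and the geometric mean element
    length shape the planted conserved elements in de novo mode.
    """

    seed: int
    n_columns: int = 1_000_000
    tract_length: int = 1000
    B_sim: float = 3.0
    coverage: float = 0.001
    conserved_fraction: float = 0.05
    conserved_mean_length: float = 100.0
    cpg_handling: bool = False
    cpg_scale: float = 8.0

    def __post_init__(self) -> None:
        if not 0 <= self.coverage < 1:
            raise ValueError("coverage must lie in [0, 1)")
        if self.seed is None:
            raise ValueError("a seed is mandatory")


@dataclass
class CategoryTrack:
    """Per-column binary labels driving the eight-way model assignment."""

    conserved: np.ndarray
    cpg: np.ndarray
    gbgc: np.ndarray

    def model_index(self) -> np.ndarray:
        """Index into the 8-model list: conserved*4 + cpg*2 + gbgc."""
        return (
            self.conserved.astype(np.int64) * 4
            + self.cpg.astype(np.int64) * 2
            + self.gbgc.astype(np.int64)
        )


# ---------------------------------------------------------------------------
# Annotation and tract placement


def annotate_cpg_columns(block: AlignmentBlock) -> np.ndarray:
    """Flag columns that are part of a CpG dinucleotide in ANY species row."""
    s = block.seqs
    cg = (s[:, :-1] == C) & (s[:, 1:] == G)
    is_c = np.zeros(block.n_columns, dtype=bool)
    pair = cg.any(axis=0)
    is_c[:-1] |= pair
    is_c[1:] |= pair
    return is_c


def place_tracts(
    n_columns: int, config: SimConfig, rng: np.random.Generator | None = None
) -> tuple[list[GenomicInterval], np.ndarray]:
    """Plant fixed-length, non-overlapping tracts at random locations until
    coverage reaches the configured target; deterministic under the seed."""
    rng = rng or np.random.default_rng(config.seed)
    L = config.tract_length
    target_bases = config.coverage * n_columns
    n_tracts = int(np.ceil(target_bases / L)) if target_bases > 0 else 0
    if n_tracts * L > n_columns // 2:
        raise ValueError(
            f"coverage {config.coverage} unreachable with tract length {L}"
        )
    labels = np.zeros(n_columns, dtype=bool)
    tracts: list[GenomicInterval] = []
    tries = 0
    while len(tracts) < n_tracts:
        tries += 1
        if tries > 100_000:
            raise RuntimeError("tract placement failed (too many rejections)")
        start = int(rng.integers(0, n_columns - L + 1))
        # keep tracts separated by >= 1 bp so truth intervals stay distinct
        if labels[max(0, start - 1) : start + L + 1].any():
            continue
        labels[start : start + L] = True
        tracts.append(GenomicInterval("chrSim", start, start + L))
    tracts.sort(key=lambda t: t.start)
    return tracts, labels


def _place_conserved(
    n_columns: int, frac: float, mean_len: float, rng: np.random.Generator
) -> np.ndarray:
    """Plant geometric-length conserved elements to ~frac of columns."""
    labels = np.zeros(n_columns, dtype=bool)
    if frac <= 0:
        return labels
    target = frac * n_columns
    covered = 0
    while covered < target:
        length = int(rng.geometric(1.0 / mean_len))
        start = int(rng.integers(0, max(1, n_columns - length)))
        seg = labels[start : start + length]
        covered += int((~seg).sum())
        seg[:] = True
    return labels


# ---------------------------------------------------------------------------
# Category models


def build_category_models(
    neutral: NeutralModel,
    rho: float = 0.31,
    B_sim: float = 3.0,
    cpg_scale: float = 8.0,
) -> list[StateModel]:
    """Eight models over (conserved, cpg, gbgc) combinations.

    Index = conserved*4 + cpg*2 + gbgc.  CpG columns use a single lambda
    multiplier (elevated substitution rate) rather than a neighbor-dependent
    process; conserved scales all branches by rho; gBGC modifies the target
    branch with disparity B_sim.
    """
    if cpg_scale <= 1:
        raise ValueError("cpg_scale must exceed 1 (elevated rate)")
    models = []
    for conserved in (0, 1):
        for cpg in (0, 1):
            for gbgc in (0, 1):
                scale = (rho if conserved else 1.0) * (
                    cpg_scale if cpg else 1.0
                )
                models.append(
                    StateModel.build(
                        neutral,
                        branch_scale=scale,
                        B=B_sim if gbgc else 0.0,
                    )
                )
    return models


# ---------------------------------------------------------------------------
# Conditional resimulation of the target leaf


def resimulate_target_leaf(
    block: AlignmentBlock,
    models: list[StateModel],
    model_index: np.ndarray,
    seed: int,
) -> AlignmentBlock:
    """Replace the target row with draws from its conditional distribution.

    For every column, the new target base is sampled from
    P(target | other leaves) under the column's assigned category model;
    every non-target symbol (including gaps and missing data) is preserved
    bit-exactly.  Columns where the target row is a gap are left untouched.
    """
    rng = np.random.default_rng(seed)
    tgt_row = block.target_row
    seqs = block.seqs.copy()
    # mask the target so the pattern key depends only on the other rows
    masked = np.minimum(seqs, N)
    masked[tgt_row] = N
    resim = block.seqs[tgt_row] != 5  # '-' columns untouched
    inv, pats = column_patterns(
        replace(block, seqs=masked)
    )
    u = rng.random(block.n_columns)
    new_base = np.full(block.n_columns, N, dtype=np.uint8)
    for m_idx in np.unique(model_index[resim]):
        dists = leaf_conditional_distributions(pats, models[m_idx])
        cdf = np.cumsum(dists, axis=1)
        sel = resim & (model_index == m_idx)
        new_base[sel] = np.argmax(
            u[sel, None] < cdf[inv[sel]], axis=1
        ).astype(np.uint8)
    seqs[tgt_row, resim] = new_base[resim]
    return replace(block, seqs=seqs)


# ---------------------------------------------------------------------------
# De novo simulation


def simulate_full_alignment(
    tree,
    neutral: NeutralModel,
    config: SimConfig,
) -> tuple[AlignmentBlock, CategoryTrack, list[GenomicInterval]]:
    """Simulate a complete alignment from the root down, with truth labels.

    The root sequence is drawn from pi; each branch evolves every column
    with the transition matrix of its assigned category.  Conserved
    elements are planted as geometric-length runs, gBGC tracts per
    :func:`place_tracts`; CpG columns (optional) are flagged from CpG
    dinucleotides in the root sequence.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_columns
    tracts, gbgc = place_tracts(n, config, rng=rng)
    conserved = _place_conserved(
        n, config.conserved_fraction, config.conserved_mean_length, rng
    )

    root = rng.choice(4, size=n, p=neutral.pi).astype(np.uint8)
    cpg = np.zeros(n, dtype=bool)
    if config.cpg_handling:
        pair = (root[:-1] == C) & (root[1:] == G)
        cpg[:-1] |= pair
        cpg[1:] |= pair
    cats = CategoryTrack(conserved=conserved, cpg=cpg, gbgc=gbgc)
    model_index = cats.model_index()

    models = build_category_models(
        neutral, rho=0.31, B_sim=config.B_sim, cpg_scale=config.cpg_scale
    )

    # evolve down the tree: resolve nodes whose parent is already simulated
    state = {tree.root: root}
    pending = [v for v in range(tree.n_nodes - 1)]
    while pending:
        nxt = []
        for node in pending:
            par = tree.parent[node]
            if par not in state:
                nxt.append(node)
                continue
            state[node] = _evolve_branch(
                state[par], node, model_index, models, rng
            )
        if len(nxt) == len(pending):
            raise RuntimeError("tree traversal stalled")
        pending = nxt

    seqs = np.vstack([state[i] for i in range(tree.n_leaves)])
    block = AlignmentBlock(
        species=list(tree.leaf_names),
        seqs=seqs,
        ref_coords=np.arange(n, dtype=np.int64),
        chrom="chrSim",
        target=tree.target,
    )
    return block, cats, tracts


def _evolve_branch(parent_seq, node, model_index, models, rng):
    """Sample child states column-wise given parent states and categories."""
    n = parent_seq.shape[0]
    child = np.empty(n, dtype=np.uint8)
    u = rng.random(n)
    for m_idx in np.unique(model_index):
        P = models[m_idx].P[node]
        cdf = np.cumsum(P, axis=1)
        sel = model_index == m_idx
        child[sel] = np.argmax(
            u[sel, None] < cdf[parent_seq[sel]], axis=1
        ).astype(np.uint8)
    return child


def simulate_with_planted_tracts(
    tree,
    neutral: NeutralModel,
    config: SimConfig,
) -> tuple[AlignmentBlock, CategoryTrack, list[GenomicInterval]]:
    """De novo scaffold + conditional resimulation of the target leaf.

    First simulates a fully neutral alignment (no gBGC anywhere), then
    replaces the target row by conditional resimulation under the
    two-category assignment {background, gBGC tract} - mirroring a
    protocol where only the target genome is synthetic and the other rows
    come from an existing alignment.
    """
    scaffold_cfg = replace(config, coverage=0.0, tract_length=1)
    block, cats, _ = simulate_full_alignment(tree, neutral, scaffold_cfg)
    tracts, gbgc = place_tracts(
        config.n_columns, config, rng=np.random.default_rng(config.seed + 1)
    )
    cats = replace(cats, gbgc=gbgc)
    models = build_category_models(
        neutral, rho=0.31, B_sim=config.B_sim, cpg_scale=config.cpg_scale
    )
    block = resimulate_target_leaf(
        block, models, cats.model_index(), seed=config.seed + 2
    )
    return block, cats, tracts


def write_truth_bed(tracts: list[GenomicInterval], path: str, seed: int) -> None:
    with open(path, "w") as fh:
        fh.write(f'track name=truth_tracts description="seed={seed}"\n')
        for i, t in enumerate(tracts):
            fh.write(f"{t.chrom}\t{t.start}\t{t.end}\ttruth_{i + 1}\n")


def write_category_tsv(cats: CategoryTrack, path: str, seed: int) -> None:
    with open(path, "w") as fh:
        fh.write(f"# seed={seed}\ncolumn\tconserved\tcpg\tgbgc\n")
        for i in range(len(cats.gbgc)):
            fh.write(
                f"{i}\t{int(cats.conserved[i])}\t{int(cats.cpg[i])}"
                f"\t{int(cats.gbgc[i])}\n"
            )
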