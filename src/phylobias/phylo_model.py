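"""Phylogenetic substitution models for the four-state gBGC HMM.

The neutral process is HKY85 on a fixed four-taxon tree
(((human, chimpanzee), orangutan), rhesus macaque) with branch-length
proportions held fixed and scaled by a free factor lambda.  Evolutionary
conservation multiplies every branch by rho < 1, as in phastCons.  GC-biased
gene conversion modifies the rate matrix on the terminal branch leading to
the designated target genome: weak->strong (A/T -> C/G) rates are multiplied
by the relative fixation factor f(B) = B / (1 - e^-B) and strong->weak rates
by f(-B), where B is the population-scaled GC-disparity.  The modified
matrix is deliberately NOT renormalized - the elevated W->S substitution
rate on the target branch is the signal the HMM detects.

Column likelihoods are computed by Felsenstein pruning, vectorized over the
<= 5^4 distinct column patterns of a block.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from io import StringIO

import numpy as np
from scipy import linalg, optimize
from Bio import Phylo

from .alignment_io import A, C, G, T, N, N_SYMBOLS, AlignmentBlock

logger = logging.getLogger(__name__)

WEAK = (A, T)
STRONG = (C, G)

#: Default leaf order and branch-length proportions (substitutions/site on
#: the neutral tree, hg18-era primate estimates from fourfold degenerate
#: sites); lambda rescales all of them jointly.
DEFAULT_NEWICK = (
    "(((human:0.0066,chimpanzee:0.0073):0.0244,orangutan:0.0189)"
    ":0.0138,rhesus:0.0365);"
)


@dataclass
class PhyloTree:
    """Rooted binary tree with fixed branch-length proportions.

    Nodes are indexed 0..n_nodes-1 with leaves first (in ``leaf_names``
    order) and internal nodes in postorder, the root last.  ``branch_prop``
    holds the proportion of the branch above each non-root node.
    """

    leaf_names: list[str]
    parent: np.ndarray          # parent index per node (root: -1)
    children: list[tuple[int, int]]  # per internal node, in postorder
    postorder_internal: list[int]
    branch_prop: np.ndarray
    target: str = "human"

    def __post_init__(self) -> None:
        if len(set(self.leaf_names)) != len(self.leaf_names):
            raise ValueError("leaf labels must be unique")
        if self.target not in self.leaf_names:
            raise ValueError(f"target {self.target!r} is not a leaf")
        if np.any(self.branch_prop[:-1] < 0):
            raise ValueError("branch proportions must be non-negative")

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_names)

    @property
    def n_nodes(self) -> int:
        return len(self.parent)

    @property
    def root(self) -> int:
        return self.n_nodes - 1

    @property
    def target_node(self) -> int:
        return self.leaf_names.index(self.target)

    @classmethod
    def from_newick(cls, newick: str, target: str = "human") -> "PhyloTree":
        """Parse a rooted newick string; branch lengths become proportions."""
        tree = Phylo.read(StringIO(newick), "newick")
        clades = []          # postorder over all clades
        for cl in tree.root.find_clades(order="postorder"):
            clades.append(cl)
        leaves = [cl for cl in clades if cl.is_terminal()]
        internals = [cl for cl in clades if not cl.is_terminal()]
        index = {id(cl): i for i, cl in enumerate(leaves)}
        for j, cl in enumerate(internals):
            index[id(cl)] = len(leaves) + j
        n = len(clades)
        parent = np.full(n, -1, dtype=np.int64)
        prop = np.zeros(n)
        children = []
        for cl in internals:
            if len(cl.clades) != 2:
                raise ValueError("tree must be binary")
            children.append(tuple(index[id(ch)] for ch in cl.clades))
            for ch in cl.clades:
                parent[index[id(ch)]] = index[id(cl)]
        for cl in clades:
            prop[index[id(cl)]] = cl.branch_length or 0.0
        return cls(
            leaf_names=[cl.name for cl in leaves],
            parent=parent,
            children=children,
            postorder_internal=list(range(len(leaves), n)),
            branch_prop=prop,
            target=target,
        )

    @classmethod
    def default(cls, target: str = "human") -> "PhyloTree":
        return cls.from_newick(DEFAULT_NEWICK, target=target)


# ---------------------------------------------------------------------------
# Rate matrices


def hky_rate_matrix(kappa: float, pi: np.ndarray) -> np.ndarray:
    """HKY85 instantaneous rate matrix, normalized to one expected
    substitution per unit branch length at stationarity.

    q(i->j) = kappa * pi_j for transitions (A<->G, C<->T), pi_j for
    transversions; the diagonal makes rows sum to zero.
    """
    pi = np.asarray(pi, dtype=float)
    if kappa <= 0:
        raise ValueError("kappa must be positive")
    if pi.shape != (4,) or np.any(pi <= 0) or abs(pi.sum() - 1) > 1e-8:
        raise ValueError("pi must be 4 positive frequencies summing to 1")
    Q = np.tile(pi, (4, 1))
    for i, j in ((A, G), (G, A), (C, T), (T, C)):
        Q[i, j] *= kappa
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    rate = -np.dot(pi, np.diag(Q))
    return Q / rate


def gbgc_fixation_factor(x: float | np.ndarray) -> float | np.ndarray:
    """Relative fixation probability f(x) = x / (1 - e^-x) of a new allele
    with population-scaled additive advantage x; f(0) = 1 by continuity.

    Satisfies f(x) * e^-x = f(-x), so f(B)/f(-B) = e^B.
    """
    x = np.asarray(x, dtype=float)
    small = np.abs(x) < 1e-8
    with np.errstate(divide="ignore", invalid="ignore"):
        f = np.where(small, 1.0 + x / 2.0, x / -np.expm1(-np.where(small, 1.0, x)))
    return float(f) if f.ndim == 0 else f


def apply_gbgc(Q: np.ndarray, B: float) -> np.ndarray:
    """Modify a rate matrix for gBGC of strength B on one branch.

    W->S entries are multiplied by f(B), S->W entries by f(-B); W->W and
    S->S entries are untouched and the diagonal is recomputed.  The overall
    rate is NOT renormalized: gBGC genuinely accelerates W->S substitution.
    """
    if B < 0:
        raise ValueError("GC-disparity B must be non-negative")
    Q = np.array(Q, dtype=float)
    fB = gbgc_fixation_factor(B)
    fmB = gbgc_fixation_factor(-B)
    for w in WEAK:
        for s in STRONG:
            Q[w, s] *= fB
            Q[s, w] *= fmB
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return Q


def branch_transition_probs(Q: np.ndarray, t: float) -> np.ndarray:
    """P(t) = exp(Qt) via eigendecomposition, falling back to scipy's
    scaling-and-squaring expm when the matrix is (numerically) defective."""
    if t < 0:
        raise ValueError("branch length must be non-negative")
    Qt = np.asarray(Q, dtype=float) * t
    try:
        w, V = np.linalg.eig(Qt)
        P = (V * np.exp(w)) @ np.linalg.inv(V)
        P = np.real_if_close(P, tol=1000)
        P = np.real(P)
        if not np.allclose(P.sum(axis=1), 1.0, atol=1e-12) or P.min() < -1e-12:
            raise np.linalg.LinAlgError
    except np.linalg.LinAlgError:
        P = linalg.expm(Qt)
    np.clip(P, 0.0, None, out=P)
    return P


# ---------------------------------------------------------------------------
# Models


@dataclass
class NeutralModel:
    """HKY neutral model: kappa, stationary pi, branch scale lambda, tree."""

    kappa: float
    pi: np.ndarray
    lam: float
    tree: PhyloTree

    def __post_init__(self) -> None:
        self.pi = np.asarray(self.pi, dtype=float)
        hky_rate_matrix(self.kappa, self.pi)  # validates
        if self.lam <= 0:
            raise ValueError("lambda must be positive")

    @property
    def Q(self) -> np.ndarray:
        return hky_rate_matrix(self.kappa, self.pi)

    def to_keyvalue(self) -> str:
        """Serialize to a plain-text key=value block (round-trip exact)."""
        lines = [
            f"kappa={float(self.kappa)!r}",
            f"lambda={float(self.lam)!r}",
            "pi=" + ",".join(repr(float(p)) for p in self.pi),
            f"target={self.tree.target}",
            f"tree={_tree_newick(self.tree)}",
        ]
        return "\n".join(lines) + "\n"

    @classmethod
    def from_keyvalue(cls, text: str) -> "NeutralModel":
        kv = dict(
            line.split("=", 1)
            for line in text.splitlines()
            if line.strip() and not line.startswith("#")
        )
        tree = PhyloTree.from_newick(kv["tree"], target=kv["target"])
        return cls(
            kappa=float(kv["kappa"]),
            pi=np.array([float(x) for x in kv["pi"].split(",")]),
            lam=float(kv["lambda"]),
            tree=tree,
        )


def _tree_newick(tree: PhyloTree) -> str:
    def fmt(node: int) -> str:
        if node < tree.n_leaves:
            name = tree.leaf_names[node]
        else:
            i = tree.postorder_internal.index(node)
            l, r = tree.children[i]
            name = f"({fmt(l)},{fmt(r)})"
        if node == tree.root:
            return name + ";"
        return f"{name}:{tree.branch_prop[node]:.10g}"

    return fmt(tree.root)


def default_neutral_model(target: str = "human") -> NeutralModel:
    """Human-like defaults: kappa=4, 41% GC, lambda=1."""
    return NeutralModel(
        kappa=4.0,
        pi=np.array([0.295, 0.205, 0.205, 0.295]),
        lam=1.0,
        tree=PhyloTree.default(target=target),
    )


@dataclass
class StateModel:
    """One concrete emission model: per-branch transition matrices + root pi.

    ``P`` has shape (n_nodes, 4, 4); the root entry is unused (identity).
    """

    tree: PhyloTree
    pi: np.ndarray
    P: np.ndarray

    @classmethod
    def build(
        cls,
        neutral: NeutralModel,
        branch_scale: float = 1.0,
        B: float = 0.0,
    ) -> "StateModel":
        tree = neutral.tree
        Q = neutral.Q
        Qg = apply_gbgc(Q, B) if B > 0 else Q
        P = np.broadcast_to(np.eye(4), (tree.n_nodes, 4, 4)).copy()
        for node in range(tree.n_nodes - 1):
            t = neutral.lam * branch_scale * tree.branch_prop[node]
            Qb = Qg if (B > 0 and node == tree.target_node) else Q
            P[node] = branch_transition_probs(Qb, t)
        return cls(tree=tree, pi=neutral.pi.copy(), P=P)


@dataclass
class StateModelSet:
    """The four HMM emission models: n, b (gBGC), c (conserved), cb (both)."""

    neutral: NeutralModel
    rho: float
    B: float
    models: list[StateModel]

    STATE_NAMES = ("n", "b", "c", "cb")
    GBGC_STATES = (1, 3)   # b, cb

    def __getitem__(self, i: int) -> StateModel:
        return self.models[i]


def build_state_models(
    neutral: NeutralModel, rho: float = 0.31, B: float = 3.0
) -> StateModelSet:
    """Compose the four state models from the fitted neutral model.

    c and cb scale every branch by rho; b and cb apply the gBGC modification
    with disparity B on the target branch only.
    """
    if not 0 < rho <= 1:
        raise ValueError("rho must be in (0, 1]")
    if B < 0:
        raise ValueError("B must be non-negative")
    models = [
        StateModel.build(neutral, 1.0, 0.0),
        StateModel.build(neutral, 1.0, B),
        StateModel.build(neutral, rho, 0.0),
        StateModel.build(neutral, rho, B),
    ]
    return StateModelSet(neutral=neutral, rho=rho, B=B, models=models)


# ---------------------------------------------------------------------------
# Likelihoods (Felsenstein pruning, vectorized over column patterns)

_POW5 = None


def _pow5(n_leaves: int) -> np.ndarray:
    return N_SYMBOLS ** np.arange(n_leaves, dtype=np.int64)


def column_patterns(block: AlignmentBlock) -> tuple[np.ndarray, np.ndarray]:
    """Encode each column as a base-5 pattern id (gaps count as missing).

    Returns (pattern_id_per_column, unique_pattern_matrix) where the matrix
    is (n_patterns, n_leaves) with symbol codes 0..4 and row index equal to
    the pattern id's rank among the uniques.
    """
    codes = np.minimum(block.seqs, N).astype(np.int64)   # '-' -> N
    ids = _pow5(codes.shape[0]) @ codes
    uniq, inv = np.unique(ids, return_inverse=True)
    pats = (uniq[:, None] // _pow5(codes.shape[0])[None, :]) % N_SYMBOLS
    return inv, pats


def pattern_log_likelihoods(
    patterns: np.ndarray, model: StateModel
) -> np.ndarray:
    """Pruning log-likelihood of each (n_patterns, n_leaves) column pattern."""
    patterns = np.asarray(patterns, dtype=np.int64)
    if patterns.ndim == 1:
        patterns = patterns[None, :]
    if patterns.max(initial=0) > N or patterns.min(initial=0) < 0:
        raise ValueError("invalid symbol code in column")
    npat, nleaf = patterns.shape
    tree = model.tree
    if nleaf != tree.n_leaves:
        raise ValueError("pattern width != number of leaves")
    partial = np.empty((tree.n_nodes, npat, 4))
    eye5 = np.vstack([np.eye(4), np.ones(4)])   # row N = all ones
    for leaf in range(nleaf):
        partial[leaf] = eye5[patterns[:, leaf]]
    for k, node in enumerate(tree.postorder_internal):
        l, r = tree.children[k]
        partial[node] = (partial[l] @ model.P[l].T) * (partial[r] @ model.P[r].T)
    lik = partial[tree.root] @ model.pi
    return np.log(lik)


def column_log_likelihood(column, model: StateModel) -> float:
    """Log-likelihood of a single column (symbols or codes; N = missing)."""
    codes = _column_codes(column)
    return float(pattern_log_likelihoods(codes[None, :], model)[0])


def _column_codes(column) -> np.ndarray:
    if isinstance(column, str):
        lut = {ch: i for i, ch in enumerate("ACGTN")}
        try:
            return np.array([lut[ch.upper()] for ch in column], dtype=np.int64)
        except KeyError as exc:
            raise ValueError(f"invalid symbol {exc}") from exc
    return np.asarray(column, dtype=np.int64)


def leaf_conditional_distribution(column, model: StateModel) -> np.ndarray:
    """P(target base | other leaves) under the model, as a 4-vector.

    The target's own symbol in ``column`` is ignored (treated as missing).
    """
    codes = _column_codes(column)
    return leaf_conditional_distributions(codes[None, :], model)[0]


def leaf_conditional_distributions(
    patterns: np.ndarray, model: StateModel
) -> np.ndarray:
    """Vectorized conditional distribution of the target leaf per pattern."""
    patterns = np.array(patterns, dtype=np.int64)
    if patterns.ndim == 1:
        patterns = patterns[None, :]
    tgt = model.tree.target_node
    logl = np.empty((patterns.shape[0], 4))
    for b in range(4):
        patterns[:, tgt] = b
        logl[:, b] = pattern_log_likelihoods(patterns, model)
    logl -= logl.max(axis=1, keepdims=True)
    w = np.exp(logl)
    return w / w.sum(axis=1, keepdims=True)


# ---------------------------------------------------------------------------
# Neutral-model fitting


def fit_neutral_model(
    blocks: AlignmentBlock | list[AlignmentBlock],
    tree: PhyloTree,
    min_columns: int = 1000,
    kappa0: float = 4.0,
    lam0: float = 1.0,
    tol: float = 1e-6,
) -> tuple[NeutralModel, float]:
    """Fit the neutral HKY model to one or more alignment blocks.

    pi is set to the observed base frequencies over all non-missing symbols;
    kappa and lambda are maximized numerically (bounded quasi-Newton on
    (log kappa, log lambda)) against the summed column log-likelihoods with
    branch lengths lambda x proportions.  Conserved elements and gBGC tracts
    are assumed sparse enough not to distort block-level averages.
    """
    if isinstance(blocks, AlignmentBlock):
        blocks = [blocks]
    pats_list, counts_list, base_counts = [], [], np.zeros(4)
    n_informative = 0
    for b in blocks:
        inv, pats = column_patterns(b)
        cnt = np.bincount(inv, minlength=pats.shape[0]).astype(float)
        pats_list.append(pats)
        counts_list.append(cnt)
        codes = np.minimum(b.seqs, N)
        base_counts += np.bincount(codes[codes < 4].ravel(), minlength=4)
        n_informative += int(((np.minimum(b.seqs, N) < 4).any(axis=0)).sum())
    if n_informative < min_columns:
        raise ValueError(
            f"too few informative columns ({n_informative} < {min_columns})"
        )
    pi = base_counts / base_counts.sum()

    def neg_ll(x: np.ndarray) -> float:
        kappa, lam = np.exp(x)
        model = StateModel.build(
            NeutralModel(kappa=kappa, pi=pi, lam=lam, tree=tree)
        )
        total = 0.0
        for pats, cnt in zip(pats_list, counts_list):
            total += float(cnt @ pattern_log_likelihoods(pats, model))
        return -total

    x0 = np.log([kappa0, lam0])
    res = optimize.minimize(
        neg_ll,
        x0,
        method="L-BFGS-B",
        bounds=[(np.log(0.05), np.log(50.0)), (np.log(1e-4), np.log(100.0))],
        options={"ftol": tol, "maxiter": 200},
    )
    if not res.success and "ABNORMAL" in str(res.message).upper():
        raise RuntimeError(f"neutral-model fit did not converge: {res.message}")
    kappa, lam = np.exp(res.x)
    ll0 = -neg_ll(x0)
    ll = -res.fun
    if ll + 1e-6 < ll0:
        raise RuntimeError("optimizer returned a worse likelihood than start")
    model = NeutralModel(kappa=float(kappa), pi=pi, lam=float(lam), tree=tree)
    logger.info(
        "fit_neutral_model: kappa=%.4f lambda=%.5f logL=%.2f", kappa, lam, ll
    )
    return model, float(ll)
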