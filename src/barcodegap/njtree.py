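"""Neighbor-joining tree construction, nonparametric bootstrap, Newick I/O.

The Saitou–Nei agglomeration is implemented directly on the distance matrix:
at each step the pair minimising the Q-criterion is joined (ties broken by the
lowest (row, column) index pair in the current matrix ordering), branch
lengths to the new node are computed, negative lengths are clamped to zero
with the deficit moved to the sister edge, and the matrix is reduced until
three clusters remain, which are joined at an (arbitrary) trifurcating anchor
node.

Bootstrap supports resample alignment columns with replacement, rebuild the
NJ tree per replicate, and annotate each internal edge of the reference tree
with the percentage of replicates containing the same bipartition. Replicates
whose resample leaves some pair without comparable sites (or K2P-saturated)
are redrawn and counted.

Internally, bipartitions are tracked as integer bitmasks over the input
sample order; the public :class:`PhyloTree` exposes them as frozensets of tip
labels, canonicalised to the side *not* containing the lexicographically
smallest tip.
"""

from __future__ import annotations

import logging
from pathlib import Path

import dendropy
import numpy as np

from .distances import PairwiseDistanceMatrix, encode_alignment, one_hot, pair_counts
from .errors import BootstrapError, NewickParseError, TreeError
from .seqio import MarkerAlignment

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Core agglomeration
# ---------------------------------------------------------------------------

def _clamp_pair(li: float, lj: float) -> tuple[float, float]:
    """Zero a negative branch length, transferring the deficit to its sister."""
    if li < 0.0:
        lj = max(lj + li, 0.0)
        li = 0.0
    elif lj < 0.0:
        li = max(li + lj, 0.0)
        lj = 0.0
    return li, lj


def _nj_agglomerate(D0: np.ndarray):
    """Run neighbor joining on a square distance matrix.

    Returns ``(children, root_children, splits)`` where ``children`` maps an
    internal node id to its two ``(child_id, branch_length)`` entries (leaf
    ids are 0..n-1, internal ids count up from n), ``root_children`` is the
    final three-way join, and ``splits`` is the set of internal-edge
    bitmasks, canonicalised to exclude leaf 0.
    """
    n = D0.shape[0]
    if n < 3:
        raise TreeError("neighbor joining needs >= 3 samples")
    if not np.all(np.isfinite(D0)):
        raise TreeError("non-finite entry in distance matrix")
    D = D0.astype(np.float64, copy=True)
    active = list(range(n))
    masks = [1 << i for i in range(n)]
    full = (1 << n) - 1
    children: dict[int, list[tuple[int, float]]] = {}
    splits: set[int] = set()
    next_id = n
    m = n
    while m > 3:
        r = D.sum(axis=1)
        Q = (m - 2) * D - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        i, j = divmod(int(np.argmin(Q)), m)
        if i > j:
            i, j = j, i
        dij = float(D[i, j])
        li = 0.5 * dij + (r[i] - r[j]) / (2.0 * (m - 2))
        li, lj = _clamp_pair(li, dij - li)
        children[next_id] = [(active[i], li), (active[j], lj)]
        new_mask = masks[i] | masks[j]
        pc = new_mask.bit_count()
        if 2 <= pc <= n - 2:
            splits.add(new_mask if not (new_mask & 1) else full ^ new_mask)
        new_row = 0.5 * (D[i, :] + D[j, :] - dij)
        D[i, :] = new_row
        D[:, i] = new_row
        D[i, i] = 0.0
        keep = [k for k in range(m) if k != j]
        D = D[np.ix_(keep, keep)]
        active[i] = next_id
        masks[i] = new_mask
        del active[j]
        del masks[j]
        next_id += 1
        m -= 1
    dab, dac, dbc = float(D[0, 1]), float(D[0, 2]), float(D[1, 2])
    la = 0.5 * (dab + dac - dbc)
    lb = 0.5 * (dab + dbc - dac)
    lc = 0.5 * (dac + dbc - dab)
    root_children = [
        (active[0], max(la, 0.0)),
        (active[1], max(lb, 0.0)),
        (active[2], max(lc, 0.0)),
    ]
    return children, root_children, splits


def _nj_splits(D: np.ndarray) -> set[int]:
    """Internal-edge bitmasks of the NJ tree (bootstrap hot path)."""
    return _nj_agglomerate(D)[2]


def _newick_from_joins(children, root_children, labels) -> str:
    """Assemble a Newick string bottom-up (children always precede parents)."""
    text: dict[int, str] = {}
    n = len(labels)
    for node_id in range(n):
        text[node_id] = labels[node_id]
    for node_id in sorted(children):
        (a, la), (b, lb) = children[node_id]
        text[node_id] = f"({text[a]}:{la:.10g},{text[b]}:{lb:.10g})"
    parts = ",".join(f"{text[c]}:{l:.10g}" for c, l in root_children)
    return f"({parts});"


# ---------------------------------------------------------------------------
# Tree container
# ---------------------------------------------------------------------------

class PhyloTree:
    """Unrooted tree with branch lengths and optional per-edge supports.

    Wraps a :class:`dendropy.Tree`; supports (percent, 0-100) are keyed by
    canonical bipartition (frozenset of the tip labels on the side not
    containing the lexicographically smallest tip).
    """

    def __init__(
        self,
        tree: dendropy.Tree,
        supports: dict[frozenset, float] | None = None,
    ) -> None:
        self._tree = tree
        self.supports = supports
        self.bootstrap_redraws = 0
        tips = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
        if len(set(tips)) != len(tips):
            raise TreeError("duplicate tip labels")
        self.tips = tuple(tips)
        self._ref_tip = min(tips)

    @property
    def dendropy_tree(self) -> dendropy.Tree:
        return self._tree

    def __len__(self) -> int:
        return len(self.tips)

    def canonical(self, side: frozenset) -> frozenset:
        """Canonicalise a split side to the one excluding the reference tip."""
        if self._ref_tip in side:
            return frozenset(self.tips) - side
        return frozenset(side)

    def bipartitions(self, include_trivial: bool = False) -> dict[frozenset, float | None]:
        """Canonical bipartition -> support (None when not annotated)."""
        n = len(self.tips)
        out: dict[frozenset, float | None] = {}
        leafsets: dict[int, frozenset] = {}
        for node in self._tree.postorder_node_iter():
            if node.is_leaf():
                leafsets[id(node)] = frozenset([node.taxon.label])
            else:
                leafsets[id(node)] = frozenset().union(
                    *(leafsets[id(c)] for c in node.child_nodes())
                )
        root = self._tree.seed_node
        for node in self._tree.preorder_node_iter():
            if node is root:
                continue
            side = leafsets[id(node)]
            if not include_trivial and not (2 <= len(side) <= n - 2):
                continue
            if len(side) in (0, n):
                continue
            key = self.canonical(side)
            support = None
            if self.supports is not None:
                support = self.supports.get(key)
            out.setdefault(key, support)
        return out

    def path_distance_matrix(self, order: tuple[str, ...]) -> np.ndarray:
        """Patristic (path-length) distances between tips, in ``order``."""
        pdm = self._tree.phylogenetic_distance_matrix()
        taxa = {t.label: t for t in self._tree.taxon_namespace}
        n = len(order)
        out = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                d = pdm.patristic_distance(taxa[order[i]], taxa[order[j]])
                out[i, j] = out[j, i] = d
        return out

    def as_newick(self) -> str:
        """Newick string; supports become internal-node labels."""
        leafsets: dict[int, frozenset] = {}
        for node in self._tree.postorder_node_iter():
            if node.is_leaf():
                leafsets[id(node)] = frozenset([node.taxon.label])
            else:
                leafsets[id(node)] = frozenset().union(
                    *(leafsets[id(c)] for c in node.child_nodes())
                )

        def render(node) -> str:
            if node.is_leaf():
                s = node.taxon.label
            else:
                inner = ",".join(render(c) for c in node.child_nodes())
                label = ""
                if self.supports is not None and node is not self._tree.seed_node:
                    sup = self.supports.get(self.canonical(leafsets[id(node)]))
                    if sup is not None:
                        label = f"{sup:.10g}"
                s = f"({inner}){label}"
            if node is not self._tree.seed_node and node.edge.length is not None:
                s += f":{node.edge.length:.10g}"
            return s

        return render(self._tree.seed_node) + ";"


def neighbor_joining(matrix: PairwiseDistanceMatrix) -> PhyloTree:
    """Build the neighbor-joining tree for a pairwise distance matrix."""
    children, root_children, _ = _nj_agglomerate(matrix.values)
    newick = _newick_from_joins(children, root_children, list(matrix.sample_ids))
    return parse_newick(newick)


# ---------------------------------------------------------------------------
# Newick I/O
# ---------------------------------------------------------------------------

def parse_newick(text: str) -> PhyloTree:
    """Parse a Newick string; numeric internal-node labels become supports."""
    try:
        tree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises several parse error types
        raise NewickParseError(f"malformed Newick: {exc}") from exc
    for leaf in tree.leaf_node_iter():
        if leaf.taxon is None or not leaf.taxon.label:
            raise NewickParseError("Newick contains an unlabeled tip")
    ptree = PhyloTree(tree)
    supports: dict[frozenset, float] = {}
    bips = ptree.bipartitions()
    leafsets: dict[int, frozenset] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            leafsets[id(node)] = frozenset([node.taxon.label])
        else:
            leafsets[id(node)] = frozenset().union(
                *(leafsets[id(c)] for c in node.child_nodes())
            )
            if node is not tree.seed_node and node.label is not None:
                try:
                    val = float(node.label)
                except ValueError:
                    continue
                key = ptree.canonical(leafsets[id(node)])
                if key in bips:
                    supports[key] = val
    if supports:
        ptree.supports = supports
    return ptree


def read_newick(path: str | Path) -> PhyloTree:
    return parse_newick(Path(path).read_text())


def write_newick(tree: PhyloTree, path: str | Path) -> None:
    Path(path).write_text(tree.as_newick() + "\n")


# ---------------------------------------------------------------------------
# Bootstrap
# ---------------------------------------------------------------------------

def _matrix_from_onehot(x: np.ndarray, model: str) -> np.ndarray | None:
    """Distance matrix from a one-hot tensor; None when any pair is invalid."""
    comparable, ts, tv, mism = pair_counts(x)
    zero = comparable == 0
    np.fill_diagonal(zero, False)
    if zero.any():
        return None
    if model == "p_distance":
        d = mism / comparable
        np.fill_diagonal(d, 0.0)
        return d
    P = ts / comparable
    Q = tv / comparable
    w1 = 1.0 - 2.0 * P - Q
    w2 = 1.0 - 2.0 * Q
    bad = (w1 <= 0) | (w2 <= 0)
    np.fill_diagonal(bad, False)
    if bad.any():
        return None
    with np.errstate(divide="ignore"):
        d = -0.5 * np.log(w1) - 0.25 * np.log(w2)
    np.fill_diagonal(d, 0.0)
    return d


def bootstrap_supports(
    alignment: MarkerAlignment,
    model: str = "k2p",
    n_replicates: int = 1000,
    seed: int = 0,
) -> PhyloTree:
    """NJ tree from the full alignment with bootstrap supports per edge.

    Replicate ``r``'s column resample depends only on ``(seed, r)``; invalid
    resamples (a pair without comparable sites, or K2P saturation) are
    redrawn from the same replicate stream, counted in
    ``tree.bootstrap_redraws``, and abandoned with :class:`BootstrapError`
    after ``10 * n_replicates`` total redraws.
    """
    if n_replicates < 1:
        raise BootstrapError("n_replicates must be >= 1")
    codes = encode_alignment(alignment)
    x = one_hot(codes)
    d_ref = _matrix_from_onehot(x, model)
    if d_ref is None:
        raise TreeError(
            f"{alignment.marker_name}: reference distances undefined or saturated"
        )
    children, root_children, ref_splits = _nj_agglomerate(d_ref)
    newick = _newick_from_joins(children, root_children, list(alignment.sample_ids))

    L = alignment.length
    counts: dict[int, int] = {s: 0 for s in ref_splits}
    redraws = 0
    for rep in range(n_replicates):
        rng = np.random.default_rng(np.random.SeedSequence((seed, rep)))
        while True:
            cols = rng.integers(0, L, size=L)
            d = _matrix_from_onehot(np.ascontiguousarray(x[:, :, cols]), model)
            if d is not None:
                break
            redraws += 1
            if redraws > 10 * n_replicates:
                raise BootstrapError(
                    f"{alignment.marker_name}: >{10 * n_replicates} invalid "
                    "bootstrap resamples (persistent saturation)"
                )
        for s in _nj_splits(d):
            if s in counts:
                counts[s] += 1
    if redraws:
        log.info(
            "%s: %d bootstrap resamples redrawn", alignment.marker_name, redraws
        )

    ptree = parse_newick(newick)
    idx = {sid: k for k, sid in enumerate(alignment.sample_ids)}

    def mask_to_side(mask: int) -> frozenset:
        return frozenset(
            sid for sid in alignment.sample_ids if (mask >> idx[sid]) & 1
        )

    supports = {
        ptree.canonical(mask_to_side(mask)): 100.0 * c / n_replicates
        for mask, c in counts.items()
    }
    ptree.supports = supports
    ptree.bootstrap_redraws = redraws
    return ptree
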