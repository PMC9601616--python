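"""Synthetic multilocus barcode datasets with known species structure.

The generator emulates the structure of a multi-marker fungal barcoding
study: a set of species related by a species tree, several individuals per
species, and a handful of nuclear markers that share the species history but
differ in substitution rate. Sequences evolve under the Kimura two-parameter
(K80) substitution model.

Within-species variation follows a simple lineage-joining model: each
individual's lineage merges onto its species' ancestral lineage at a depth
drawn uniformly from ``[0, intraspecific_depth]`` and evolves independently
down to the present (tips are contemporaneous). When the joining depth is
small relative to the species' terminal branch this is effectively a
within-species star; when it rivals species divergence times, lineages join
*above* speciation events — incomplete lineage sorting — and conspecific
individuals genuinely cease to form a clade, which is the regime in which
species-level signal is destroyed. Optional single-column deletions are
applied per species-tree lineage, keeping columns homologous.

All randomness derives from the single config seed through documented
``numpy.random.SeedSequence`` streams, so a config is bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .distances import distance_matrix, partition_by_species
from .njtree import PhyloTree, parse_newick, write_newick
from .seqio import MarkerAlignment, SpeciesLabelMap

_BASES = np.array(list("ACGT"))

# SeedSequence stream tags (first element after the user seed).
_STREAM_TREE = 0
_STREAM_COUNTS = 1
_STREAM_MARKER = 2  # (seed, 2, marker_index)
_STREAM_INDEL = 3  # (seed, 3, marker_index)
_STREAM_SWAP = 4
_STREAM_ATTACH = 5


@dataclass(frozen=True)
class MarkerSpec:
    """One simulated marker: name, aligned length, relative substitution rate."""

    name: str
    length_bp: int
    rate_multiplier: float


@dataclass
class SimulationConfig:
    """Parameters of one synthetic study.

    Defaults emulate a 45-species / 260-individual four-marker design with
    marker-specific variability spanning a conserved protein-coding gene to a
    fast ribosomal spacer: interspecific divergences of roughly 0.3-13% and
    intraspecific divergences of roughly 0.04-0.06% across markers.
    """

    n_species: int = 45
    individuals_per_species: int | list[int] | None = None  # None: draw 1-20, total 260
    markers: list[MarkerSpec] = field(
        default_factory=lambda: [
            MarkerSpec("ITS", 452, 1.9),
            MarkerSpec("EF1a", 312, 1.05),
            MarkerSpec("RPB1", 420, 0.85),
            MarkerSpec("RPB2", 391, 0.085),
        ]
    )
    interspecific_depth: float = 0.05
    intraspecific_depth: float = 0.0003
    kappa: float = 2.0
    indel_rate: float = 0.02
    label_swap_fraction: float = 0.0
    total_individuals: int = 260  # used only when individuals_per_species is None
    max_per_species: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_species < 2:
            raise ValueError("need at least 2 species")
        if self.interspecific_depth < 0 or self.intraspecific_depth < 0:
            raise ValueError("depths must be >= 0")
        if self.kappa <= 0:
            raise ValueError("kappa must be > 0")
        if not self.markers:
            raise ValueError("at least one marker required")
        for m in self.markers:
            if m.length_bp < 1 or m.rate_multiplier <= 0:
                raise ValueError(f"invalid marker spec {m}")
        if not 0.0 <= self.indel_rate <= 1.0:
            raise ValueError("indel_rate must be a probability")
        if not 0.0 <= self.label_swap_fraction <= 1.0:
            raise ValueError("label_swap_fraction must be a probability")

    def to_dict(self) -> dict:
        return {
            "n_species": self.n_species,
            "individuals_per_species": self.individuals_per_species,
            "markers": [
                {"name": m.name, "length_bp": m.length_bp, "rate_multiplier": m.rate_multiplier}
                for m in self.markers
            ],
            "interspecific_depth": self.interspecific_depth,
            "intraspecific_depth": self.intraspecific_depth,
            "kappa": self.kappa,
            "indel_rate": self.indel_rate,
            "label_swap_fraction": self.label_swap_fraction,
            "total_individuals": self.total_individuals,
            "max_per_species": self.max_per_species,
            "seed": self.seed,
        }


@dataclass
class SimulatedDataset:
    """One generated study: per-marker alignments plus ground truth."""

    alignments: dict[str, MarkerAlignment]
    truth_species: SpeciesLabelMap
    species_tree: PhyloTree
    realized_stats: dict[str, tuple[float, float]]
    config: SimulationConfig

    def write(self, out_dir: str | Path) -> None:
        """Emit FASTA per marker, metadata TSV, true tree, and a config echo."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name, aln in self.alignments.items():
            aln.write_fasta(out / f"{name}.fasta")
        self.truth_species.to_tsv(out / "metadata.tsv")
        write_newick(self.species_tree, out / "species_tree.nwk")
        with open(out / "config.yaml", "w") as fh:
            yaml.safe_dump(self.config.to_dict(), fh, sort_keys=True)


def simulate_species_tree(n_species: int, depth: float, seed: int) -> PhyloTree:
    """Random species tree: uniform pair joins, unit edges, rescaled depth.

    Topology is built by repeatedly joining a uniformly random pair of
    lineages (a coalescent-style join order). Every edge gets the same length
    and the tree is rescaled so the mean root-to-tip path equals ``depth`` —
    a curated-species-set geometry in which no two species split at a
    vanishingly small fraction of the tree height.
    """
    if n_species < 2:
        raise ValueError("need at least 2 species")
    rng = np.random.default_rng(np.random.SeedSequence((seed, _STREAM_TREE)))
    labels = [f"sp{i + 1:03d}" for i in range(n_species)]
    text = {i: labels[i] for i in range(n_species)}
    # Track, per cluster, each leaf's edge count up to the cluster root so the
    # unit-edge tree can be rescaled to the requested mean depth.
    depths: dict[int, dict[str, int]] = {i: {labels[i]: 0} for i in range(n_species)}
    ids = list(range(n_species))
    next_id = n_species
    parts: dict[int, tuple[int, int]] = {}
    while len(ids) > 1:
        i, j = sorted(rng.choice(len(ids), size=2, replace=False))
        a, b = ids[i], ids[j]
        parts[next_id] = (a, b)
        depths[next_id] = {
            **{k: v + 1 for k, v in depths[a].items()},
            **{k: v + 1 for k, v in depths[b].items()},
        }
        ids[i] = next_id
        del ids[j]
        next_id += 1
    root = ids[0]
    mean_depth = float(np.mean(list(depths[root].values())))
    scale = depth / mean_depth if mean_depth > 0 else 0.0
    for node_id in sorted(parts):
        a, b = parts[node_id]
        text[node_id] = f"({text[a]}:{scale:.12g},{text[b]}:{scale:.12g})"
    return parse_newick(text[root] + ";")


def _substitution_probs(branch_length: float, kappa: float) -> tuple[float, float]:
    """K80 site change probabilities (transition, each transversion).

    The rate matrix is normalised so that ``branch_length`` is the expected
    number of substitutions per site: alpha + 2*beta = 1 with alpha/beta =
    kappa.
    """
    beta = 1.0 / (kappa + 2.0)
    alpha = kappa * beta
    t = branch_length
    e1 = np.exp(-4.0 * beta * t)
    e2 = np.exp(-2.0 * (alpha + beta) * t)
    p_ts = 0.25 + 0.25 * e1 - 0.5 * e2
    p_tv_each = 0.25 - 0.25 * e1
    return float(p_ts), float(p_tv_each)


def _evolve_codes(
    codes: np.ndarray, branch_length: float, kappa: float, rng: np.random.Generator
) -> np.ndarray:
    """Evolve a code vector (A=0,C=1,G=2,T=3) along one branch."""
    if branch_length == 0.0:
        return codes.copy()
    p_ts, p_tv = _substitution_probs(branch_length, kappa)
    u = rng.random(codes.shape[0])
    out = codes.copy()
    ts = u < p_ts
    tv1 = (u >= p_ts) & (u < p_ts + p_tv)
    tv2 = (u >= p_ts + p_tv) & (u < p_ts + 2 * p_tv)
    out[ts] ^= 2  # A<->G, C<->T
    out[tv1] ^= 1  # A<->C, G<->T
    out[tv2] ^= 3  # A<->T, C<->G
    return out


def evolve_k2p(
    parent_seq: str,
    branch_length: float,
    kappa: float,
    seed: int | np.random.Generator,
) -> str:
    """Evolve a gap-free sequence along one branch under the K80 model."""
    if branch_length < 0:
        raise ValueError("branch_length must be >= 0")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(np.random.SeedSequence((seed,)))
    )
    lookup = np.full(256, 255, dtype=np.uint8)
    for i, b in enumerate("ACGT"):
        lookup[ord(b)] = i
    codes = lookup[np.frombuffer(parent_seq.upper().encode("ascii"), dtype=np.uint8)]
    if (codes == 255).any():
        raise ValueError("parent sequence must be gap-free A/C/G/T")
    child = _evolve_codes(codes, branch_length, kappa, rng)
    return "".join(_BASES[child])


def _draw_individual_counts(config: SimulationConfig) -> list[int]:
    if isinstance(config.individuals_per_species, int):
        return [config.individuals_per_species] * config.n_species
    if config.individuals_per_species is not None:
        counts = list(config.individuals_per_species)
        if len(counts) != config.n_species:
            raise ValueError("per-species counts length != n_species")
        return counts
    if config.total_individuals < config.n_species:
        raise ValueError("total_individuals < n_species")
    rng = np.random.default_rng(np.random.SeedSequence((config.seed, _STREAM_COUNTS)))
    counts = [1] * config.n_species
    for _ in range(config.total_individuals - config.n_species):
        open_idx = [i for i, c in enumerate(counts) if c < config.max_per_species]
        counts[int(rng.choice(open_idx))] += 1
    return counts


def simulate_dataset(config: SimulationConfig) -> SimulatedDataset:
    """Generate a full multilocus dataset under the config.

    Per marker: a uniform-random ancestral sequence evolves down the species
    tree (branch lengths scaled by the marker's rate multiplier). Each
    individual's lineage joins its species' root-ward lineage at a uniform
    depth in ``[0, intraspecific_depth]`` (clamped at the root, shared across
    markers) and evolves independently down to the present, so tips are
    contemporaneous and deep joins produce incomplete lineage sorting.
    Deletions are applied per column at ``indel_rate``, hitting all
    individuals of species descending from a uniformly chosen species-tree
    edge.
    """
    tree = simulate_species_tree(
        config.n_species, config.interspecific_depth, config.seed
    )
    counts = _draw_individual_counts(config)
    species_labels = sorted(tree.tips)
    sample_ids: list[str] = []
    species_of: dict[str, str] = {}
    for sp, k in zip(species_labels, counts):
        for i in range(k):
            sid = f"{sp}_{i + 1:02d}"
            sample_ids.append(sid)
            species_of[sid] = sp

    dtree = tree.dendropy_tree
    nodes = list(dtree.preorder_node_iter())
    # Species descending from each non-root node (for lineage deletions).
    below: dict[int, list[str]] = {}
    for node in dtree.postorder_node_iter():
        if node.is_leaf():
            below[id(node)] = [node.taxon.label]
        else:
            below[id(node)] = sorted(
                sp for c in node.child_nodes() for sp in below[id(c)]
            )
    non_root = [node for node in nodes if node is not dtree.seed_node]

    # Root-ward edge path per species: (node, edge length, cumulative depth
    # at the edge's root-ward end), tip first. Baseline (unmultiplied) units.
    tip_node = {leaf.taxon.label: leaf for leaf in dtree.leaf_node_iter()}
    paths: dict[str, list[tuple[object, float, float]]] = {}
    for sp in species_labels:
        path = []
        node = tip_node[sp]
        depth = 0.0
        while node.parent_node is not None:
            length = node.edge.length or 0.0
            path.append((node, length, depth + length))
            depth += length
            node = node.parent_node
        paths[sp] = path

    # Joining depth per individual (shared across markers: one organismal
    # history per individual), clamped at the species' root depth.
    arng = np.random.default_rng(np.random.SeedSequence((config.seed, _STREAM_ATTACH)))
    join_depth: dict[str, float] = {}
    for sid in sample_ids:
        root_depth = paths[species_of[sid]][-1][2]
        join_depth[sid] = min(
            float(arng.uniform(0.0, config.intraspecific_depth)), root_depth
        )

    # Map each individual to (edge node, breakpoint distance from the edge's
    # root-ward end) on its species' path.
    edge_breakpoints: dict[int, list[tuple[float, str]]] = {}
    for sid in sample_ids:
        tau = join_depth[sid]
        for node, length, cum_rootward in paths[species_of[sid]]:
            if tau <= cum_rootward or (node, length, cum_rootward) == paths[species_of[sid]][-1]:
                pos_from_root = cum_rootward - tau  # may clamp to 0 at root
                edge_breakpoints.setdefault(id(node), []).append(
                    (max(pos_from_root, 0.0), sid)
                )
                break

    alignments: dict[str, MarkerAlignment] = {}
    realized: dict[str, tuple[float, float]] = {}
    truth = SpeciesLabelMap(dict(species_of))
    for m_idx, marker in enumerate(config.markers):
        rng = np.random.default_rng(
            np.random.SeedSequence((config.seed, _STREAM_MARKER, m_idx))
        )
        mult = marker.rate_multiplier
        L = marker.length_bp
        ancestral = rng.integers(0, 4, size=L, dtype=np.uint8)
        node_seq: dict[int, np.ndarray] = {id(dtree.seed_node): ancestral}
        join_state: dict[str, np.ndarray] = {}
        for node in nodes:
            if node is dtree.seed_node:
                continue
            cur = node_seq[id(node.parent_node)]
            length = node.edge.length or 0.0
            prev = 0.0
            for pos, sid in sorted(edge_breakpoints.get(id(node), [])):
                cur = _evolve_codes(cur, (pos - prev) * mult, config.kappa, rng)
                join_state[sid] = cur
                prev = pos
            node_seq[id(node)] = _evolve_codes(
                cur, (length - prev) * mult, config.kappa, rng
            )
        rows_codes = {
            sid: _evolve_codes(join_state[sid], join_depth[sid] * mult, config.kappa, rng)
            for sid in sample_ids
        }
        rows = {sid: "".join(_BASES[c]) for sid, c in rows_codes.items()}

        if config.indel_rate > 0:
            irng = np.random.default_rng(
                np.random.SeedSequence((config.seed, _STREAM_INDEL, m_idx))
            )
            hit_cols = np.nonzero(irng.random(L) < config.indel_rate)[0]
            arr = {sid: list(rows[sid]) for sid in sample_ids}
            for col in hit_cols:
                edge_node = non_root[int(irng.integers(len(non_root)))]
                for sp in below[id(edge_node)]:
                    for sid in sample_ids:
                        if species_of[sid] == sp:
                            arr[sid][col] = "-"
            rows = {sid: "".join(chars) for sid, chars in arr.items()}

        aln = MarkerAlignment(
            marker_name=marker.name,
            sample_ids=list(sample_ids),
            species_of=dict(species_of),
            rows=rows,
        )
        alignments[marker.name] = aln
        part = partition_by_species(distance_matrix(aln, "k2p"), truth)
        mean_intra = float(np.mean(part.pooled_intra)) if part.pooled_intra else 0.0
        mean_inter = float(np.mean(part.pooled_inter)) if part.pooled_inter else 0.0
        realized[marker.name] = (mean_intra, mean_inter)

    if config.label_swap_fraction > 0:
        srng = np.random.default_rng(np.random.SeedSequence((config.seed, _STREAM_SWAP)))
        n_swap = int(round(config.label_swap_fraction * len(sample_ids)))
        swap_ids = srng.choice(len(sample_ids), size=n_swap, replace=False)
        entries = dict(truth.entries)
        for k in swap_ids:
            sid = sample_ids[int(k)]
            others = [sp for sp in species_labels if sp != entries[sid]]
            entries[sid] = others[int(srng.integers(len(others)))]
        truth = SpeciesLabelMap(entries)
        for aln in alignments.values():
            aln.species_of = dict(entries)

    return SimulatedDataset(alignments, truth, tree, realized, config)
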