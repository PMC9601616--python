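"""Site classification, marker variability statistics, and pairwise distances.

Two distance models are provided, both under pairwise deletion of gaps,
``N`` and IUPAC ambiguity codes:

* **p-distance** — the uncorrected proportion of differing comparable sites.
* **K2P** — the Kimura two-parameter correction
  ``d = -1/2 ln(1 - 2P - Q) - 1/4 ln(1 - 2Q)`` where ``P`` and ``Q`` are the
  transition (A<->G, C<->T) and transversion proportions.

The pairwise counting is vectorised: sequences are one-hot encoded and the
transition/transversion/match counts for all pairs are obtained with a handful
of matrix products, which keeps bootstrap loops cheap.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

import numpy as np

from .errors import (
    EvaluationError,
    InsufficientDataError,
    MetadataError,
    SaturationError,
    UndefinedDistanceError,
)
from .seqio import NUCLEOTIDES, MarkerAlignment, SpeciesLabelMap

# Nucleotide codes: A=0, C=1, G=2, T=3; anything else (gap, N, ambiguity) = 4
# and is treated as missing. With this coding, transitions are exactly the
# pairs whose codes differ by XOR 2 (A<->G, C<->T).
_MISSING = 4
_CODE_TABLE = np.full(256, _MISSING, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _CODE_TABLE[ord(_b)] = _i
    _CODE_TABLE[ord(_b.lower())] = _i


def encode_alignment(alignment: MarkerAlignment) -> np.ndarray:
    """Encode rows (in ``sample_ids`` order) as an (n, L) uint8 code matrix."""
    raw = np.frombuffer(
        "".join(alignment.sequences()).encode("ascii"), dtype=np.uint8
    ).reshape(alignment.n_samples, alignment.length)
    return _CODE_TABLE[raw]


def one_hot(codes: np.ndarray) -> np.ndarray:
    """One-hot float32 tensor of shape (5, n, L) from an (n, L) code matrix."""
    return (codes[None, :, :] == np.arange(5, dtype=np.uint8)[:, None, None]).astype(
        np.float32
    )


def pair_counts(x: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """All-pairs site counts from a one-hot tensor.

    Returns integer-valued float64 (n, n) matrices
    ``(comparable, transitions, transversions, mismatches)``.
    """
    a, c, g, t = x[0], x[1], x[2], x[3]
    valid = a + c + g + t
    comparable = valid @ valid.T
    matches = a @ a.T + c @ c.T + g @ g.T + t @ t.T
    s = a @ g.T + c @ t.T
    transitions = s + s.T
    mismatches = comparable - matches
    transversions = mismatches - transitions
    return (
        comparable.astype(np.float64),
        transitions.astype(np.float64),
        transversions.astype(np.float64),
        mismatches.astype(np.float64),
    )


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round with ties away from zero (the reporting convention used here)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def percent(numerator: int, denominator: int, ndigits: int = 2) -> float:
    """100*numerator/denominator rounded half-up, computed in exact decimal."""
    numerator, denominator = int(numerator), int(denominator)
    if denominator <= 0:
        raise EvaluationError("percentage with non-positive denominator")
    q = Decimal(1).scaleb(-ndigits)
    val = (Decimal(100) * Decimal(numerator) / Decimal(denominator)).quantize(
        q, rounding=ROUND_HALF_UP
    )
    return float(val)


@dataclass(frozen=True)
class SiteClassification:
    """Alignment columns partitioned into indel, SNP and monomorphic sites.

    A column containing any gap is an indel site; it additionally counts as a
    SNP site when its gap-free rows still show two or more distinct
    unambiguous nucleotides (toggleable), so SNP and indel tallies add the way
    variable-site percentages are reported.
    """

    n_sites: int
    snp_sites: frozenset[int]
    indel_sites: frozenset[int]
    monomorphic_sites: frozenset[int]

    @property
    def n_snps(self) -> int:
        return len(self.snp_sites)

    @property
    def n_indels(self) -> int:
        return len(self.indel_sites)


def classify_sites(
    alignment: MarkerAlignment, count_gapped_polymorphic_as_snp: bool = True
) -> SiteClassification:
    """Classify every column as indel and/or SNP, else monomorphic."""
    if alignment.n_samples < 2:
        raise InsufficientDataError("site classification needs >= 2 samples")
    cols = np.array([list(s) for s in alignment.sequences()])
    snp: set[int] = set()
    indel: set[int] = set()
    mono: set[int] = set()
    for j in range(alignment.length):
        col = cols[:, j]
        has_gap = "-" in col
        nucs = {b for b in col if b in NUCLEOTIDES}
        is_poly = len(nucs) >= 2
        if has_gap:
            indel.add(j)
            if is_poly and count_gapped_polymorphic_as_snp:
                snp.add(j)
        elif is_poly:
            snp.add(j)
        else:
            mono.add(j)
    return SiteClassification(
        alignment.length, frozenset(snp), frozenset(indel), frozenset(mono)
    )


@dataclass(frozen=True)
class PairwiseDistanceMatrix:
    """Symmetric matrix of pairwise distances under one model."""

    sample_ids: tuple[str, ...]
    values: np.ndarray
    model: str
    comparable_sites: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.sample_ids)
        if self.values.shape != (n, n) or self.comparable_sites.shape != (n, n):
            raise ValueError("matrix shape does not match sample count")

    @property
    def n(self) -> int:
        return len(self.sample_ids)

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("sample_id\t" + "\t".join(self.sample_ids) + "\n")
            for i, sid in enumerate(self.sample_ids):
                fh.write(
                    sid + "\t" + "\t".join(f"{v:.8f}" for v in self.values[i]) + "\n"
                )

    def to_phylip(self, path: str | Path) -> None:
        """PHYLIP square distance format (names padded to 10 characters)."""
        with open(path, "w") as fh:
            fh.write(f"{self.n}\n")
            for i, sid in enumerate(self.sample_ids):
                name = sid[:10].ljust(10)
                fh.write(name + "  ".join(f"{v:.8f}" for v in self.values[i]) + "\n")


def _k2p_from_counts(
    comparable: np.ndarray,
    transitions: np.ndarray,
    transversions: np.ndarray,
    d_max: float | None,
    context: str,
) -> np.ndarray:
    """K2P distances from count matrices; saturation errors or capping."""
    with np.errstate(divide="ignore", invalid="ignore"):
        P = transitions / comparable
        Q = transversions / comparable
        w1 = 1.0 - 2.0 * P - Q
        w2 = 1.0 - 2.0 * Q
        d = -0.5 * np.log(w1) - 0.25 * np.log(w2)
    bad = (w1 <= 0) | (w2 <= 0)
    np.fill_diagonal(bad, False)
    if bad.any():
        if d_max is None:
            i, j = np.argwhere(bad)[0]
            raise SaturationError(
                f"{context}: K2P saturated for pair ({i}, {j}): "
                f"P={P[i, j]:.4f}, Q={Q[i, j]:.4f}"
            )
        d = np.where(bad, d_max, d)
    np.fill_diagonal(d, 0.0)
    return d


def distance_matrix(
    alignment: MarkerAlignment,
    model: str = "k2p",
    d_max: float | None = None,
) -> PairwiseDistanceMatrix:
    """All-pairs distance matrix under ``p_distance`` or ``k2p``.

    Pairwise deletion throughout; a pair with zero comparable sites raises
    :class:`UndefinedDistanceError`. K2P saturation raises
    :class:`SaturationError` unless ``d_max`` enables cap mode.
    """
    if alignment.n_samples < 2:
        raise InsufficientDataError("distance matrix needs >= 2 samples")
    if model not in ("p_distance", "k2p"):
        raise ValueError(f"unknown model {model!r}")
    codes = encode_alignment(alignment)
    comparable, ts, tv, mism = pair_counts(one_hot(codes))
    zero = comparable == 0
    np.fill_diagonal(zero, False)
    if zero.any():
        i, j = np.argwhere(zero)[0]
        raise UndefinedDistanceError(
            f"{alignment.marker_name}: no comparable sites between "
            f"{alignment.sample_ids[i]!r} and {alignment.sample_ids[j]!r}"
        )
    if model == "p_distance":
        with np.errstate(invalid="ignore"):
            values = mism / comparable
        np.fill_diagonal(values, 0.0)
    else:
        values = _k2p_from_counts(comparable, ts, tv, d_max, alignment.marker_name)
    return PairwiseDistanceMatrix(
        tuple(alignment.sample_ids), values, model, comparable.astype(np.int64)
    )


def _pair_site_counts(seq_a: str, seq_b: str) -> tuple[int, int, int, int]:
    if len(seq_a) != len(seq_b):
        raise InsufficientDataError("sequences differ in length")
    a = _CODE_TABLE[np.frombuffer(seq_a.upper().encode("ascii"), dtype=np.uint8)]
    b = _CODE_TABLE[np.frombuffer(seq_b.upper().encode("ascii"), dtype=np.uint8)]
    comp = (a != _MISSING) & (b != _MISSING)
    diff = comp & (a != b)
    ts = diff & ((a ^ b) == 2)
    n_comp = int(comp.sum())
    n_diff = int(diff.sum())
    n_ts = int(ts.sum())
    return n_comp, n_ts, n_diff - n_ts, n_diff


def p_distance_pair(seq_a: str, seq_b: str) -> tuple[float, int]:
    """Uncorrected distance for one pair: (p, number of comparable sites)."""
    n_comp, _, _, n_diff = _pair_site_counts(seq_a, seq_b)
    if n_comp == 0:
        raise UndefinedDistanceError("no comparable sites for the pair")
    return n_diff / n_comp, n_comp


def k2p_distance_pair(
    seq_a: str, seq_b: str, d_max: float | None = None
) -> tuple[float, float, float]:
    """K2P distance for one pair: (d, P, Q)."""
    n_comp, n_ts, n_tv, _ = _pair_site_counts(seq_a, seq_b)
    if n_comp == 0:
        raise UndefinedDistanceError("no comparable sites for the pair")
    P = n_ts / n_comp
    Q = n_tv / n_comp
    w1 = 1.0 - 2.0 * P - Q
    w2 = 1.0 - 2.0 * Q
    if w1 <= 0 or w2 <= 0:
        if d_max is None:
            raise SaturationError(f"K2P saturated: P={P:.4f}, Q={Q:.4f}")
        return d_max, P, Q
    return -0.5 * math.log(w1) - 0.25 * math.log(w2), P, Q


@dataclass(frozen=True)
class DistancePartition:
    """Pairwise distances split into conspecific and heterospecific pools.

    ``intra[sp]`` holds the distances among that species' samples;
    ``inter[sp]`` holds distances from that species' samples to every
    heterospecific sample (so per-species inter lists share elements across
    species). The pooled lists contain each unordered pair exactly once.
    """

    intra: dict[str, list[float]]
    inter: dict[str, list[float]]
    pooled_intra: list[float]
    pooled_inter: list[float]
    model: str


def partition_by_species(
    matrix: PairwiseDistanceMatrix, species: SpeciesLabelMap
) -> DistancePartition:
    """Split a distance matrix by the species labels of its samples."""
    labels = []
    for sid in matrix.sample_ids:
        if sid not in species.entries:
            raise MetadataError(f"sample {sid!r} has no species label")
        labels.append(species.entries[sid])
    present = sorted(set(labels))
    intra: dict[str, list[float]] = {sp: [] for sp in present}
    inter: dict[str, list[float]] = {sp: [] for sp in present}
    pooled_intra: list[float] = []
    pooled_inter: list[float] = []
    vals = matrix.values
    for i in range(matrix.n):
        for j in range(i + 1, matrix.n):
            d = float(vals[i, j])
            if labels[i] == labels[j]:
                intra[labels[i]].append(d)
                pooled_intra.append(d)
            else:
                inter[labels[i]].append(d)
                inter[labels[j]].append(d)
                pooled_inter.append(d)
    return DistancePartition(intra, inter, pooled_intra, pooled_inter, matrix.model)


@dataclass(frozen=True)
class VariabilityStats:
    """One marker's variability row: length, SNP/indel tallies and mean
    intra-/interspecific divergence (substitutions per site)."""

    marker: str
    length_bp: int
    n_snps: int
    pct_snp: float
    n_indels: int
    pct_variable: float
    mean_intra: float
    mean_inter: float


def pct_snp(n_snps: int, length_bp: int) -> float:
    """SNP sites as a half-up percentage of the aligned length."""
    return percent(n_snps, length_bp)


def pct_variable(n_snps: int, n_indels: int, length_bp: int) -> float:
    """SNP + indel sites as a half-up percentage of the aligned length."""
    return percent(n_snps + n_indels, length_bp)


def variability_stats(
    alignment: MarkerAlignment,
    matrix_k2p: PairwiseDistanceMatrix,
    partition: DistancePartition,
    count_gapped_polymorphic_as_snp: bool = True,
) -> VariabilityStats:
    """Assemble the per-marker variability summary row.

    Mean intra/inter divergences are unweighted arithmetic means over the
    pooled pair lists (0 when a pool is empty).
    """
    if tuple(alignment.sample_ids) != matrix_k2p.sample_ids:
        raise MetadataError("matrix was not computed on this alignment")
    sites = classify_sites(alignment, count_gapped_polymorphic_as_snp)
    mean_intra = float(np.mean(partition.pooled_intra)) if partition.pooled_intra else 0.0
    mean_inter = float(np.mean(partition.pooled_inter)) if partition.pooled_inter else 0.0
    return VariabilityStats(
        marker=alignment.marker_name,
        length_bp=alignment.length,
        n_snps=sites.n_snps,
        pct_snp=pct_snp(sites.n_snps, alignment.length),
        n_indels=sites.n_indels,
        pct_variable=pct_variable(sites.n_snps, sites.n_indels, alignment.length),
        mean_intra=mean_intra,
        mean_inter=mean_inter,
    )


def write_variability_table(stats: list[VariabilityStats], path: str | Path) -> None:
    """Write marker variability rows as a TSV table."""
    with open(path, "w") as fh:
        fh.write(
            "marker\tlength_bp\tn_snps\tpct_snp\tn_indels\tpct_variable\t"
            "mean_intra\tmean_inter\n"
        )
        for s in stats:
            fh.write(
                f"{s.marker}\t{s.length_bp}\t{s.n_snps}\t{s.pct_snp:.2f}\t"
                f"{s.n_indels}\t{s.pct_variable:.2f}\t"
                f"{s.mean_intra:.6f}\t{s.mean_inter:.6f}\n"
            )
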