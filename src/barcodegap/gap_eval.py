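"""Barcoding-gap (PWG-distance) species discrimination.

A species is successfully identified by the distance criterion when its
minimum interspecific distance strictly exceeds its maximum intraspecific
distance. The identification rate is the percentage of evaluated species that
succeed, rounded half-up to two decimals.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .distances import DistancePartition, percent
from .errors import EvaluationError
from .seqio import MarkerSet

SINGLETON_POLICIES = ("count_success_if_positive_inter", "exclude")


@dataclass(frozen=True)
class SpeciesGapRecord:
    """Per-species barcoding-gap verdict.

    ``max_intra`` is NaN for singleton species evaluated under the
    count-success policy (no conspecific pair exists).
    """

    species: str
    n_individuals: int
    max_intra: float
    min_inter: float
    success: bool


@dataclass(frozen=True)
class DiscriminationResult:
    """Identification-rate summary for one (marker set, method, model) cell."""

    marker_set: MarkerSet
    method: str
    model: str
    n_success: int
    n_species: int
    rate_pct: float


@dataclass(frozen=True)
class DivergenceHistogram:
    """Binned intra- and interspecific pairwise divergences (barcoding gap).

    ``overlap_range`` is the [pooled min inter, pooled max intra] interval
    when the two distributions overlap, else None.
    """

    bin_edges: np.ndarray
    intra_counts: np.ndarray
    inter_counts: np.ndarray
    overlap_range: tuple[float, float] | None


def pwg_species_test(
    partition: DistancePartition,
    species: str,
    singleton_policy: str = "count_success_if_positive_inter",
) -> SpeciesGapRecord | None:
    """Evaluate one species under the distance criterion.

    Returns None when a singleton species is excluded by policy. Strict
    inequality: a tie between min-inter and max-intra is a failure.
    """
    if singleton_policy not in SINGLETON_POLICIES:
        raise ValueError(f"unknown singleton_policy {singleton_policy!r}")
    if species not in partition.intra:
        raise EvaluationError(f"species {species!r} not present in partition")
    inter = partition.inter[species]
    if not inter:
        raise EvaluationError(f"species {species!r} has no heterospecific comparisons")
    intra = partition.intra[species]
    min_inter = min(inter)
    if intra:
        # k conspecific pairs => (1 + sqrt(1+8k))/2 individuals
        n_ind = round((1 + math.isqrt(1 + 8 * len(intra))) / 2)
        max_intra = max(intra)
        return SpeciesGapRecord(
            species, n_ind, max_intra, min_inter, bool(min_inter > max_intra)
        )
    if singleton_policy == "exclude":
        return None
    # Singleton: treat max_intra as 0, succeed iff its nearest neighbour is
    # at positive distance.
    return SpeciesGapRecord(species, 1, float("nan"), min_inter, min_inter > 0.0)


def pwg_all_species(
    partition: DistancePartition,
    singleton_policy: str = "count_success_if_positive_inter",
) -> list[SpeciesGapRecord]:
    """Gap records for every species in the partition (policy-filtered)."""
    records = []
    for sp in sorted(partition.intra):
        rec = pwg_species_test(partition, sp, singleton_policy)
        if rec is not None:
            records.append(rec)
    return records


def pwg_discrimination_rate(
    records: list[SpeciesGapRecord], marker_set: MarkerSet, model: str
) -> DiscriminationResult:
    """Identification rate over a list of per-species gap records."""
    if not records:
        raise EvaluationError("no species records to evaluate")
    n_success = sum(r.success for r in records)
    n_species = len(records)
    return DiscriminationResult(
        marker_set=marker_set,
        method="pwg_distance",
        model=model,
        n_success=n_success,
        n_species=n_species,
        rate_pct=percent(n_success, n_species),
    )


def divergence_histogram(
    partition: DistancePartition, bin_width: float = 0.005
) -> DivergenceHistogram:
    """Histogram of pooled intra vs inter divergences on shared bins."""
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    intra = np.asarray(partition.pooled_intra, dtype=float)
    inter = np.asarray(partition.pooled_inter, dtype=float)
    if intra.size == 0 and inter.size == 0:
        raise EvaluationError("empty partition: nothing to histogram")
    dmax = float(max(intra.max(initial=0.0), inter.max(initial=0.0)))
    n_bins = max(1, int(math.ceil(dmax / bin_width + 1e-12)))
    edges = np.arange(n_bins + 1) * bin_width
    # np.histogram's last bin is closed; widen it marginally so every bin
    # behaves half-open [lo, hi) and the maximum still lands in-range.
    count_edges = edges.copy()
    count_edges[-1] = np.nextafter(edges[-1], np.inf)
    intra_counts, _ = np.histogram(intra, bins=count_edges)
    inter_counts, _ = np.histogram(inter, bins=count_edges)
    overlap = None
    if intra.size and inter.size:
        lo, hi = float(inter.min()), float(intra.max())
        if hi > lo:
            overlap = (lo, hi)
    return DivergenceHistogram(edges, intra_counts, inter_counts, overlap)


def write_gap_records(records: list[SpeciesGapRecord], path) -> None:
    with open(path, "w") as fh:
        fh.write("species\tn_individuals\tmax_intra\tmin_inter\tsuccess\n")
        for r in records:
            mi = "NA" if math.isnan(r.max_intra) else f"{r.max_intra:.8f}"
            fh.write(
                f"{r.species}\t{r.n_individuals}\t{mi}\t{r.min_inter:.8f}\t"
                f"{str(r.success).lower()}\n"
            )


def write_histogram(hist: DivergenceHistogram, path) -> None:
    with open(path, "w") as fh:
        fh.write("bin_low\tbin_high\tintra_count\tinter_count\n")
        for i in range(len(hist.intra_counts)):
            fh.write(
                f"{hist.bin_edges[i]:.6f}\t{hist.bin_edges[i + 1]:.6f}\t"
                f"{hist.intra_counts[i]}\t{hist.inter_counts[i]}\n"
            )
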