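"""Tree-based species discrimination: monophyly with bootstrap support.

A species is successfully identified by the tree criterion when all of its
individuals form a monophyletic group and (for multi-individual species) the
subtending edge has bootstrap support strictly above the threshold (default
50%). Singleton species are monophyletic by convention.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

from .distances import percent
from .errors import EvaluationError, TreeError
from .gap_eval import SINGLETON_POLICIES, DiscriminationResult
from .njtree import PhyloTree
from .seqio import MarkerSet, SpeciesLabelMap

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class MonophylyRecord:
    """Per-species monophyly verdict; ``support_pct`` is NaN when undefined."""

    species: str
    n_individuals: int
    is_monophyletic: bool
    support_pct: float
    success: bool


def is_species_monophyletic(
    tree: PhyloTree, tip_subset: set[str] | frozenset[str]
) -> tuple[bool, float | None]:
    """Does some edge of the unrooted tree split off exactly ``tip_subset``?

    Returns ``(is_monophyletic, support_pct)``; support is None for trivial
    (pendant) splits or when the tree carries no supports.
    """
    subset = frozenset(tip_subset)
    if not subset:
        raise EvaluationError("empty tip subset")
    tips = set(tree.tips)
    unknown = subset - tips
    if unknown:
        raise TreeError(f"tips not in tree: {sorted(unknown)}")
    k = len(subset)
    n = len(tips)
    if k == 1 or k == n:
        return True, None
    if k == n - 1:
        # Complement is a single tip: the pendant edge realises the split.
        return True, None
    key = tree.canonical(subset)
    bips = tree.bipartitions()
    if key not in bips:
        return False, None
    return True, bips[key]


def tree_discrimination_rate(
    tree: PhyloTree,
    species: SpeciesLabelMap,
    marker_set: MarkerSet,
    model: str,
    support_threshold: float = 50.0,
    singleton_policy: str = "count_success_if_positive_inter",
) -> tuple[DiscriminationResult, list[MonophylyRecord]]:
    """Identification rate under the tree criterion, with per-species records.

    Success requires monophyly and, for multi-individual species, support
    strictly above ``support_threshold``. When the tree carries no support
    annotations at all, success falls back to topology-only with a warning.
    Under the ``exclude`` singleton policy, singleton species are dropped
    from the denominator.
    """
    if singleton_policy not in SINGLETON_POLICIES:
        raise ValueError(f"unknown singleton_policy {singleton_policy!r}")
    tips = set(tree.tips)
    by_species: dict[str, set[str]] = {}
    for tip in tips:
        if tip not in species.entries:
            raise TreeError(f"tree tip {tip!r} has no species label")
        by_species.setdefault(species.entries[tip], set()).add(tip)
    topology_only = tree.supports is None
    if topology_only:
        log.warning(
            "%s: tree has no bootstrap supports; scoring on topology alone",
            marker_set.label,
        )
    records: list[MonophylyRecord] = []
    for sp in sorted(by_species):
        members = by_species[sp]
        if len(members) == 1:
            if singleton_policy == "exclude":
                continue
            records.append(MonophylyRecord(sp, 1, True, float("nan"), True))
            continue
        mono, support = is_species_monophyletic(tree, members)
        if not mono:
            records.append(MonophylyRecord(sp, len(members), False, float("nan"), False))
            continue
        if support is None:
            if not topology_only:
                log.warning(
                    "%s/%s: monophyletic edge lacks a support annotation; "
                    "scoring on topology alone",
                    marker_set.label,
                    sp,
                )
            records.append(MonophylyRecord(sp, len(members), True, float("nan"), True))
        else:
            records.append(
                MonophylyRecord(
                    sp, len(members), True, support, support > support_threshold
                )
            )
    if not records:
        raise EvaluationError("no species to evaluate on the tree")
    n_success = sum(r.success for r in records)
    result = DiscriminationResult(
        marker_set=marker_set,
        method="nj_tree",
        model=model,
        n_success=n_success,
        n_species=len(records),
        rate_pct=percent(n_success, len(records)),
    )
    return result, records


def write_monophyly_records(records: list[MonophylyRecord], path) -> None:
    with open(path, "w") as fh:
        fh.write("species\tn_individuals\tmonophyletic\tsupport\tsuccess\n")
        for r in records:
            sup = "NA" if math.isnan(r.support_pct) else f"{r.support_pct:.2f}"
            fh.write(
                f"{r.species}\t{r.n_individuals}\t{str(r.is_monophyletic).lower()}\t"
                f"{sup}\t{str(r.success).lower()}\n"
            )
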