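"""Full evaluation sweep: every marker set x method x model, plus tables.

``run_evaluation`` drives the whole pipeline for a catalog of markers:
enumerate all non-empty marker combinations, concatenate each, compute
distance matrices under the requested models, score species by the
barcoding-gap (PWG-distance) criterion and by NJ-tree monophyly with
bootstrap support, and assemble one identification-rate row per
(marker set, method, model) cell. ``render_tables`` persists everything as
TSV/Newick/YAML; ``verify_output_dir`` recomputes every rate from the
persisted per-species records and trees.
"""

from __future__ import annotations

import logging
import math
import time
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .distances import (
    VariabilityStats,
    distance_matrix,
    partition_by_species,
    percent,
    variability_stats,
    write_variability_table,
)
from .errors import BarcodeGapError, EvaluationError
from .gap_eval import (
    DiscriminationResult,
    DivergenceHistogram,
    SpeciesGapRecord,
    divergence_histogram,
    pwg_all_species,
    pwg_discrimination_rate,
    write_gap_records,
    write_histogram,
)
from .njtree import PhyloTree, bootstrap_supports, read_newick, write_newick
from .seqio import (
    MarkerAlignment,
    MarkerSet,
    SpeciesLabelMap,
    concatenate_markers,
    enumerate_marker_sets,
    read_alignment_fasta,
)
from .tree_eval import (
    MonophylyRecord,
    tree_discrimination_rate,
    write_monophyly_records,
)

log = logging.getLogger(__name__)

MODELS = ("p_distance", "k2p")
METHODS = ("pwg_distance", "nj_tree")


@dataclass
class EvaluationConfig:
    """Run-time constants for one evaluation sweep.

    Markers may be given as files (``marker_files`` + ``metadata_path``) or
    directly in memory (``alignments`` + ``species``). Defaults follow the
    usual barcoding-evaluation settings: both distance models, both methods,
    1000 bootstrap replicates, strict >50% support, singletons counted.
    """

    marker_files: dict[str, str] | None = None
    metadata_path: str | None = None
    alignments: dict[str, MarkerAlignment] | None = None
    species: SpeciesLabelMap | None = None
    models: tuple[str, ...] = MODELS
    methods: tuple[str, ...] = METHODS
    n_bootstrap: int = 1000
    support_threshold: float = 50.0
    singleton_policy: str = "count_success_if_positive_inter"
    missing_policy: str = "intersect"
    bin_width: float | None = 0.005
    seed: int = 0
    output_dir: str | None = None

    def __post_init__(self) -> None:
        if not self.models or any(m not in MODELS for m in self.models):
            raise ValueError(f"models must be a non-empty subset of {MODELS}")
        if not self.methods or any(m not in METHODS for m in self.methods):
            raise ValueError(f"methods must be a non-empty subset of {METHODS}")
        if self.n_bootstrap < 1:
            raise ValueError("n_bootstrap must be >= 1")
        has_files = self.marker_files is not None and self.metadata_path is not None
        has_memory = self.alignments is not None and self.species is not None
        if not (has_files or has_memory):
            raise ValueError("provide marker_files+metadata_path or alignments+species")

    def echo(self) -> dict:
        return {
            "marker_files": dict(self.marker_files) if self.marker_files else None,
            "metadata_path": self.metadata_path,
            "models": list(self.models),
            "methods": list(self.methods),
            "n_bootstrap": self.n_bootstrap,
            "support_threshold": self.support_threshold,
            "singleton_policy": self.singleton_policy,
            "missing_policy": self.missing_policy,
            "bin_width": self.bin_width,
            "seed": self.seed,
            "version": __version__,
        }


@dataclass
class DiscriminationSummary:
    """Everything one sweep produced, keyed by (marker-set label, model)."""

    rows: list[DiscriminationResult] = field(default_factory=list)
    gap_records: dict[tuple[str, str], list[SpeciesGapRecord]] = field(default_factory=dict)
    mono_records: dict[tuple[str, str], list[MonophylyRecord]] = field(default_factory=dict)
    trees: dict[tuple[str, str], PhyloTree] = field(default_factory=dict)
    histograms: dict[str, DivergenceHistogram] = field(default_factory=dict)
    variability: list[VariabilityStats] = field(default_factory=list)
    failures: list[str] = field(default_factory=list)

    def rate(self, marker_set_label: str, method: str, model: str) -> float:
        for row in self.rows:
            if (
                row.marker_set.label == marker_set_label
                and row.method == method
                and row.model == model
            ):
                return row.rate_pct
        raise KeyError((marker_set_label, method, model))


def load_inputs(config: EvaluationConfig) -> tuple[dict[str, MarkerAlignment], SpeciesLabelMap]:
    """Resolve the config to in-memory alignments and a species map."""
    if config.alignments is not None and config.species is not None:
        return dict(config.alignments), config.species
    species = SpeciesLabelMap.from_tsv(config.metadata_path)
    alignments = {
        name: read_alignment_fasta(path, name, species)
        for name, path in config.marker_files.items()
    }
    return alignments, species


def _derived_seed(seed: int, set_idx: int, model_idx: int) -> int:
    return (seed * 1000003 + set_idx * 101 + model_idx) % (2**31)


def run_evaluation(config: EvaluationConfig) -> DiscriminationSummary:
    """Run the full sweep; writes artifacts when ``output_dir`` is set.

    A stage failure (e.g. K2P saturation for one marker set) is recorded in
    ``summary.failures`` and the sweep continues with the remaining cells.
    Fully deterministic given the config seed.
    """
    alignments, species = load_inputs(config)
    catalog = list(alignments)
    summary = DiscriminationSummary()
    t0 = time.perf_counter()
    log.info("sweep: %d markers, seed=%d", len(catalog), config.seed)

    for set_idx, marker_set in enumerate(enumerate_marker_sets(catalog)):
        try:
            concat = concatenate_markers(
                [alignments[n] for n in marker_set.names],
                marker_set,
                config.missing_policy,
            )
        except BarcodeGapError as exc:
            summary.failures.append(f"{marker_set.label}/concatenate: {exc}")
            continue
        for model_idx, model in enumerate(config.models):
            t_cell = time.perf_counter()
            try:
                matrix = distance_matrix(concat, model)
                partition = partition_by_species(matrix, species)
            except BarcodeGapError as exc:
                summary.failures.append(f"{marker_set.label}/{model}/distances: {exc}")
                continue
            if model == "k2p" and config.bin_width is not None:
                try:
                    summary.histograms[marker_set.label] = divergence_histogram(
                        partition, config.bin_width
                    )
                except EvaluationError as exc:
                    summary.failures.append(f"{marker_set.label}/histogram: {exc}")
            if "pwg_distance" in config.methods:
                try:
                    records = pwg_all_species(partition, config.singleton_policy)
                    summary.gap_records[(marker_set.label, model)] = records
                    summary.rows.append(
                        pwg_discrimination_rate(records, marker_set, model)
                    )
                except BarcodeGapError as exc:
                    summary.failures.append(f"{marker_set.label}/{model}/pwg: {exc}")
            if "nj_tree" in config.methods:
                try:
                    tree = bootstrap_supports(
                        concat,
                        model,
                        config.n_bootstrap,
                        _derived_seed(config.seed, set_idx, model_idx),
                    )
                    result, mono = tree_discrimination_rate(
                        tree,
                        species,
                        marker_set,
                        model,
                        config.support_threshold,
                        config.singleton_policy,
                    )
                    summary.trees[(marker_set.label, model)] = tree
                    summary.mono_records[(marker_set.label, model)] = mono
                    summary.rows.append(result)
                    if tree.bootstrap_redraws:
                        log.info(
                            "%s/%s: %d bootstrap redraws",
                            marker_set.label,
                            model,
                            tree.bootstrap_redraws,
                        )
                except BarcodeGapError as exc:
                    summary.failures.append(f"{marker_set.label}/{model}/nj: {exc}")
            log.info(
                "%s/%s done in %.2fs", marker_set.label, model,
                time.perf_counter() - t_cell,
            )

    # Per-single-marker variability rows (always under K2P, as reported).
    for name in catalog:
        try:
            aln = alignments[name]
            mat = distance_matrix(aln, "k2p")
            part = partition_by_species(mat, species)
            summary.variability.append(variability_stats(aln, mat, part))
        except BarcodeGapError as exc:
            summary.failures.append(f"{name}/variability: {exc}")

    log.info("sweep finished in %.2fs", time.perf_counter() - t0)
    if config.output_dir is not None:
        render_tables(summary, summary.variability, config.output_dir, config, species)
    return summary


def _rates_lines(rows: list[DiscriminationResult]) -> list[str]:
    lines = []
    for r in sorted(rows, key=lambda r: (len(r.marker_set), r.marker_set.label, r.method, r.model)):
        lines.append(
            f"{r.marker_set.label}\t{r.method}\t{r.model}\t{r.n_success}\t"
            f"{r.n_species}\t{r.rate_pct:.2f}"
        )
    return lines


def render_tables(
    summary: DiscriminationSummary,
    stats: list[VariabilityStats],
    output_dir: str | Path,
    config: EvaluationConfig | None = None,
    species: SpeciesLabelMap | None = None,
) -> list[Path]:
    """Persist the sweep: rates, variability, histograms, trees, records.

    Output is byte-stable for a fixed config and seed (no timestamps).
    """
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    p = out / "variability.tsv"
    write_variability_table(stats, p)
    written.append(p)

    p = out / "rates.tsv"
    with open(p, "w") as fh:
        fh.write("marker_set\tmethod\tmodel\tn_success\tn_species\trate_pct\n")
        for line in _rates_lines(summary.rows):
            fh.write(line + "\n")
    written.append(p)

    cells = sorted({(r.method, r.model) for r in summary.rows})
    sets = sorted(
        {r.marker_set for r in summary.rows}, key=lambda s: (len(s), s.label)
    )
    p = out / "rates_wide.tsv"
    with open(p, "w") as fh:
        fh.write("marker_set\t" + "\t".join(f"{m}_{mod}" for m, mod in cells) + "\n")
        for ms in sets:
            vals = []
            for method, model in cells:
                try:
                    vals.append(f"{summary.rate(ms.label, method, model):.2f}")
                except KeyError:
                    vals.append("NA")
            fh.write(ms.label + "\t" + "\t".join(vals) + "\n")
    written.append(p)

    if summary.histograms:
        hdir = out / "histograms"
        hdir.mkdir(exist_ok=True)
        for label in sorted(summary.histograms):
            p = hdir / f"{label}.tsv"
            write_histogram(summary.histograms[label], p)
            written.append(p)

    if summary.trees:
        tdir = out / "trees"
        tdir.mkdir(exist_ok=True)
        for label, model in sorted(summary.trees):
            p = tdir / f"{label}.{model}.nwk"
            write_newick(summary.trees[(label, model)], p)
            written.append(p)

    if summary.gap_records or summary.mono_records:
        gdir = out / "gap_records"
        gdir.mkdir(exist_ok=True)
        for label, model in sorted(summary.gap_records):
            p = gdir / f"{label}.{model}.pwg.tsv"
            write_gap_records(summary.gap_records[(label, model)], p)
            written.append(p)
        for label, model in sorted(summary.mono_records):
            p = gdir / f"{label}.{model}.monophyly.tsv"
            write_monophyly_records(summary.mono_records[(label, model)], p)
            written.append(p)

    if summary.failures:
        p = out / "failures.txt"
        p.write_text("".join(f + "\n" for f in summary.failures))
        written.append(p)

    if species is not None:
        p = out / "metadata.tsv"
        species.to_tsv(p)
        written.append(p)

    p = out / "manifest.yaml"
    manifest = {"config": config.echo() if config else None}
    with open(p, "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)
    written.append(p)
    return written


def verify_output_dir(output_dir: str | Path) -> bool:
    """Recompute every rates.tsv row from the persisted per-species records.

    PWG rows are re-derived from ``gap_records/*.pwg.tsv`` success flags;
    NJ rows from ``gap_records/*.monophyly.tsv``. Raises
    :class:`EvaluationError` on the first mismatch; returns True otherwise.
    """
    out = Path(output_dir)
    rates = (out / "rates.tsv").read_text().splitlines()[1:]
    for line in rates:
        label, method, model, n_success, n_species, rate_pct = line.split("\t")
        kind = "pwg" if method == "pwg_distance" else "monophyly"
        rec_path = out / "gap_records" / f"{label}.{model}.{kind}.tsv"
        rec_lines = rec_path.read_text().splitlines()[1:]
        successes = sum(1 for rl in rec_lines if rl.split("\t")[-1] == "true")
        total = len(rec_lines)
        if successes != int(n_success) or total != int(n_species):
            raise EvaluationError(
                f"{label}/{method}/{model}: counts {successes}/{total} != "
                f"{n_success}/{n_species}"
            )
        if not math.isclose(percent(successes, total), float(rate_pct), abs_tol=5e-3):
            raise EvaluationError(f"{label}/{method}/{model}: rate mismatch")
        if method == "nj_tree":
            tree_path = out / "trees" / f"{label}.{model}.nwk"
            read_newick(tree_path)  # parseable, consistent tip set
    return True
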