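"""Reading, validating and combining aligned marker data.

Inputs are pre-aligned per-marker FASTA files (IUPAC DNA plus ``-`` gaps) and a
two-column tab-separated metadata table mapping sample IDs to species labels.
Combined (multilocus) barcodes are plain column-wise concatenations of the
per-marker alignments.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO

from .errors import AlignmentError, AlphabetError, MetadataError

#: IUPAC nucleotide one-letter codes, N, and the alignment gap character.
DNA_ALPHABET = frozenset("ACGTRYSWKMBDHVN-")

#: Unambiguous nucleotides.
NUCLEOTIDES = frozenset("ACGT")


@dataclass(frozen=True)
class SpeciesLabelMap:
    """Assignment of every sample ID to a species label."""

    entries: dict[str, str]

    def __post_init__(self) -> None:
        if not self.entries:
            raise MetadataError("species map is empty")
        for sid, sp in self.entries.items():
            if not sid or not sp:
                raise MetadataError(f"empty sample id or species label: {sid!r} -> {sp!r}")

    @property
    def species(self) -> set[str]:
        return set(self.entries.values())

    @property
    def counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for sp in self.entries.values():
            out[sp] = out.get(sp, 0) + 1
        return out

    def __len__(self) -> int:
        return len(self.entries)

    def __getitem__(self, sample_id: str) -> str:
        try:
            return self.entries[sample_id]
        except KeyError:
            raise MetadataError(f"sample {sample_id!r} has no species label") from None

    @classmethod
    def from_tsv(cls, path: str | Path) -> "SpeciesLabelMap":
        """Read a two-column (sample_id, species) TSV with a header line."""
        entries: dict[str, str] = {}
        lines = Path(path).read_text().splitlines()
        if not lines:
            raise MetadataError(f"{path}: empty metadata file")
        for lineno, line in enumerate(lines[1:], start=2):
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise MetadataError(f"{path}:{lineno}: expected 2 tab-separated columns")
            sid, sp = parts[0].strip(), parts[1].strip()
            if sid in entries:
                raise MetadataError(f"{path}:{lineno}: duplicate sample id {sid!r}")
            entries[sid] = sp
        return cls(entries)

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("sample_id\tspecies\n")
            for sid, sp in self.entries.items():
                fh.write(f"{sid}\t{sp}\n")


@dataclass
class MarkerAlignment:
    """One marker's aligned sequences with sample IDs and species labels.

    ``blocks`` records (marker, start, end) column spans (0-based half-open)
    for concatenated alignments; single markers carry one block.
    """

    marker_name: str
    sample_ids: list[str]
    species_of: dict[str, str]
    rows: dict[str, str]
    length: int = field(default=-1)
    blocks: list[tuple[str, int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.sample_ids:
            raise AlignmentError(f"{self.marker_name}: no samples")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise AlignmentError(f"{self.marker_name}: duplicate sample ids")
        lengths = {len(self.rows[s]) for s in self.sample_ids}
        if len(lengths) != 1:
            raise AlignmentError(
                f"{self.marker_name}: unequal row lengths {sorted(lengths)}"
            )
        (length,) = lengths
        if length < 1:
            raise AlignmentError(f"{self.marker_name}: zero-length alignment")
        if self.length == -1:
            self.length = length
        elif self.length != length:
            raise AlignmentError(
                f"{self.marker_name}: declared length {self.length} != rows {length}"
            )
        for sid in self.sample_ids:
            if sid not in self.species_of:
                raise MetadataError(f"{self.marker_name}: sample {sid!r} unlabeled")
            bad = set(self.rows[sid]) - DNA_ALPHABET
            if bad:
                raise AlphabetError(
                    f"{self.marker_name}/{sid}: illegal characters {sorted(bad)}"
                )
        if not self.blocks:
            self.blocks = [(self.marker_name, 0, self.length)]

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def sequences(self) -> list[str]:
        """Rows in ``sample_ids`` order."""
        return [self.rows[s] for s in self.sample_ids]

    def write_fasta(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for sid in self.sample_ids:
                fh.write(f">{sid}\n{self.rows[sid]}\n")

    def write_partition_table(self, path: str | Path) -> None:
        """Marker block offsets as TSV (marker, start, end), 1-based inclusive."""
        with open(path, "w") as fh:
            fh.write("marker\tstart\tend\n")
            for name, start, end in self.blocks:
                fh.write(f"{name}\t{start + 1}\t{end}\n")


@dataclass(frozen=True)
class MarkerSet:
    """An ordered, duplicate-free subset of the marker catalog."""

    names: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.names:
            raise MetadataError("empty marker set")
        if len(set(self.names)) != len(self.names):
            raise MetadataError(f"duplicate markers in set {self.names}")

    @property
    def label(self) -> str:
        return "+".join(self.names)

    def __len__(self) -> int:
        return len(self.names)


def read_alignment_fasta(
    path: str | Path, marker_name: str, metadata: SpeciesLabelMap
) -> MarkerAlignment:
    """Read one marker's aligned FASTA, matching record IDs to ``metadata``.

    Sequences are upper-cased; any record ID absent from the metadata, any
    length mismatch, and any character outside IUPAC DNA + ``-`` raise.
    """
    sample_ids: list[str] = []
    rows: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        sid = rec.id
        if sid in rows:
            raise AlignmentError(f"{path}: duplicate record id {sid!r}")
        if sid not in metadata.entries:
            raise MetadataError(f"{path}: record {sid!r} absent from metadata")
        sample_ids.append(sid)
        rows[sid] = str(rec.seq).upper()
    if not sample_ids:
        raise AlignmentError(f"{path}: no FASTA records")
    species_of = {sid: metadata[sid] for sid in sample_ids}
    return MarkerAlignment(marker_name, sample_ids, species_of, rows)


def concatenate_markers(
    alignments: Sequence[MarkerAlignment],
    markers: MarkerSet | None = None,
    missing_policy: str = "intersect",
) -> MarkerAlignment:
    """Concatenate per-marker alignments into one multilocus alignment.

    Under ``intersect`` (default) only samples present in every selected marker
    are kept; under ``pad_with_gaps`` the union of samples is kept and a sample
    missing a marker receives a run of ``-`` across that marker's block.
    """
    if not alignments:
        raise AlignmentError("no alignments to concatenate")
    if missing_policy not in ("intersect", "pad_with_gaps"):
        raise ValueError(f"unknown missing_policy {missing_policy!r}")
    by_name = {a.marker_name: a for a in alignments}
    if len(by_name) != len(alignments):
        raise AlignmentError("duplicate marker names among alignments")
    if markers is None:
        markers = MarkerSet(tuple(a.marker_name for a in alignments))
    try:
        selected = [by_name[name] for name in markers.names]
    except KeyError as exc:
        raise MetadataError(f"marker {exc.args[0]!r} not among alignments") from None

    # Species labels must agree wherever a sample appears in several markers.
    species_of: dict[str, str] = {}
    for aln in selected:
        for sid in aln.sample_ids:
            sp = aln.species_of[sid]
            if species_of.setdefault(sid, sp) != sp:
                raise MetadataError(
                    f"sample {sid!r}: conflicting species labels "
                    f"{species_of[sid]!r} vs {sp!r}"
                )

    if missing_policy == "intersect":
        keep = set(selected[0].sample_ids)
        for aln in selected[1:]:
            keep &= set(aln.sample_ids)
        if not keep:
            raise MetadataError("no sample is present in all selected markers")
        ordered = [s for s in selected[0].sample_ids if s in keep]
    else:
        seen: set[str] = set()
        ordered = []
        for aln in selected:
            for sid in aln.sample_ids:
                if sid not in seen:
                    seen.add(sid)
                    ordered.append(sid)

    blocks: list[tuple[str, int, int]] = []
    offset = 0
    for aln in selected:
        blocks.append((aln.marker_name, offset, offset + aln.length))
        offset += aln.length

    rows = {
        sid: "".join(
            aln.rows.get(sid, "-" * aln.length) for aln in selected
        )
        for sid in ordered
    }
    return MarkerAlignment(
        marker_name=markers.label,
        sample_ids=ordered,
        species_of={sid: species_of[sid] for sid in ordered},
        rows=rows,
        length=offset,
        blocks=blocks,
    )


def enumerate_marker_sets(catalog: Iterable[str]) -> list[MarkerSet]:
    """All 2^n - 1 non-empty marker subsets: singletons, pairs, triples, ...

    Order within each size follows the catalog order, matching the usual
    single-then-combined barcode presentation.
    """
    names = list(catalog)
    if not names:
        raise MetadataError("empty marker catalog")
    if len(set(names)) != len(names):
        raise MetadataError("duplicate names in marker catalog")
    out: list[MarkerSet] = []
    for k in range(1, len(names) + 1):
        for combo in combinations(names, k):
            out.append(MarkerSet(combo))
    return out
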