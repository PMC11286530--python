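"""Readers and writers for the on-disk formats the pipeline touches.

Four text formats enter or leave the pipeline:

* a ``.pairs``-dialect TSV holding RNA-DNA contact pairs (one RNA end and
  one DNA end per record), as produced upstream by in-situ proximity
  ligation protocols such as iMARGI;
* GTF/GFF gene annotation carrying gene biotypes;
* BED3+ region sets;
* bedGraph signal tracks (the text interchange for ChIP/ATAC coverage).

All internal coordinates are 0-based half-open.  The 1-based conventions of
the pairs and GTF formats are converted at the parser/writer boundary and
nowhere else.  Every reader transparently accepts gzip-compressed input.
"""

from __future__ import annotations

import gzip
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Iterator, Mapping, Sequence

import numpy as np

__all__ = [
    "RNA_CLASSES",
    "GenomeAssembly",
    "GenomicInterval",
    "ContactPair",
    "GeneModel",
    "SignalTrack",
    "PairsParseError",
    "read_pairs",
    "load_pairs",
    "write_pairs",
    "read_gene_annotation",
    "write_gene_annotation",
    "read_bed",
    "write_bed",
    "read_signal_bedgraph",
    "write_signal_bedgraph",
]

#: Closed vocabulary of RNA classes a gene may belong to.
RNA_CLASSES = (
    "protein_coding",
    "lncRNA",
    "snoRNA",
    "snRNA",
    "miRNA",
    "rRNA",
    "other_ncRNA",
)

PAIRS_COLUMNS = ("readID", "chrom1", "pos1", "chrom2", "pos2", "strand1", "strand2")


class PairsParseError(ValueError):
    """Raised for malformed records in a pairs-dialect file."""


def _open_text(path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


@dataclass(frozen=True)
class GenomeAssembly:
    """An ordered set of named chromosomes with lengths.

    The assembly is a runtime input (e.g. read from a ``chrom.sizes`` file);
    no reference genome is hard-coded anywhere in the package.
    """

    chrom_names: tuple[str, ...]
    chrom_lengths: tuple[int, ...]

    def __post_init__(self):
        if len(self.chrom_names) != len(set(self.chrom_names)):
            raise ValueError("chromosome names must be unique")
        if len(self.chrom_names) != len(self.chrom_lengths):
            raise ValueError("names and lengths differ in length")
        for name, length in zip(self.chrom_names, self.chrom_lengths):
            if length <= 0:
                raise ValueError(f"chromosome {name!r} has non-positive length {length}")

    @classmethod
    def from_dict(cls, sizes: Mapping[str, int]) -> "GenomeAssembly":
        return cls(tuple(sizes), tuple(int(v) for v in sizes.values()))

    @classmethod
    def from_chrom_sizes(cls, path) -> "GenomeAssembly":
        names, lengths = [], []
        with _open_text(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                fields = line.split()
                names.append(fields[0])
                lengths.append(int(fields[1]))
        return cls(tuple(names), tuple(lengths))

    def write_chrom_sizes(self, path) -> None:
        with _open_text(path, "wt") as fh:
            for name, length in zip(self.chrom_names, self.chrom_lengths):
                fh.write(f"{name}\t{length}\n")

    def __contains__(self, chrom: str) -> bool:
        return chrom in self._length_map

    def __len__(self) -> int:
        return len(self.chrom_names)

    @property
    def _length_map(self) -> dict[str, int]:
        # cached on first access; the dataclass is frozen so this is safe
        m = self.__dict__.get("_length_map_cache")
        if m is None:
            m = dict(zip(self.chrom_names, self.chrom_lengths))
            object.__setattr__(self, "_length_map_cache", m)
        return m

    def length(self, chrom: str) -> int:
        try:
            return self._length_map[chrom]
        except KeyError:
            raise KeyError(f"chromosome {chrom!r} not in assembly") from None

    def n_bins(self, chrom: str, bin_size: int) -> int:
        return math.ceil(self.length(chrom) / bin_size)

    def validate_interval(self, iv: "GenomicInterval") -> None:
        if iv.chrom not in self:
            raise ValueError(f"chromosome {iv.chrom!r} not in assembly")
        if iv.end > self.length(iv.chrom):
            raise ValueError(
                f"interval {iv.chrom}:{iv.start}-{iv.end} exceeds chromosome "
                f"length {self.length(iv.chrom)}"
            )


@dataclass(frozen=True, slots=True)
class GenomicInterval:
    """A 0-based half-open genomic interval with optional strand."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self):
        if not 0 <= self.start < self.end:
            raise ValueError(
                f"require 0 <= start < end, got [{self.start}, {self.end})"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def overlap_length(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


@dataclass(frozen=True, slots=True)
class ContactPair:
    """One RNA-end/DNA-end read pair from a proximity-ligation library."""

    read_id: str
    rna_end: GenomicInterval
    dna_end: GenomicInterval


@dataclass(frozen=True, slots=True)
class GeneModel:
    """A gene as an interval plus its RNA class (biotype)."""

    gene_id: str
    gene_name: str
    rna_class: str
    span: GenomicInterval

    def __post_init__(self):
        if self.rna_class not in RNA_CLASSES:
            raise ValueError(f"unknown rna_class {self.rna_class!r}")
        if self.span.strand not in ("+", "-"):
            raise ValueError("gene span must be stranded (+/-)")


@dataclass
class SignalTrack:
    """Binned genome-wide signal (coverage) with a normalization tag."""

    assembly: GenomeAssembly
    bin_size: int
    values: dict[str, np.ndarray]
    normalization: str = "raw"

    def __post_init__(self):
        if self.bin_size < 1:
            raise ValueError("bin_size must be >= 1")
        if self.normalization not in ("raw", "CPM"):
            raise ValueError(f"unknown normalization {self.normalization!r}")
        for chrom in self.assembly.chrom_names:
            expected = self.assembly.n_bins(chrom, self.bin_size)
            vec = self.values.get(chrom)
            if vec is None:
                self.values[chrom] = np.zeros(expected)
            elif len(vec) != expected:
                raise ValueError(
                    f"{chrom}: expected {expected} bins, got {len(vec)}"
                )

    @classmethod
    def zeros(cls, assembly: GenomeAssembly, bin_size: int) -> "SignalTrack":
        return cls(assembly, bin_size, {}, "raw")

    def total_signal(self) -> float:
        return float(sum(v.sum() for v in self.values.values()))

    def copy(self) -> "SignalTrack":
        return SignalTrack(
            self.assembly,
            self.bin_size,
            {c: v.copy() for c, v in self.values.items()},
            self.normalization,
        )


# ---------------------------------------------------------------------------
# pairs dialect

def read_pairs(
    path,
    assembly: GenomeAssembly,
    *,
    swap_sides: bool = False,
    skip_counter: list | None = None,
) -> Iterator[ContactPair]:
    """Stream :class:`ContactPair` records from a pairs-dialect TSV.

    The format is tab-separated with ``#`` comment lines and columns
    ``readID chrom1 pos1 chrom2 pos2 strand1 strand2``; positions are
    1-based single base positions (pairs-format convention) and become
    0-based length-1 intervals.  Side 1 is the RNA end and side 2 the DNA
    end unless ``swap_sides`` is set.

    Records on chromosomes absent from *assembly* are skipped, not fatal;
    pass a one-element list as ``skip_counter`` to receive the count
    (incremented in place as the stream is consumed).
    """
    if skip_counter is None:
        skip_counter = [0]
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 7:
                raise PairsParseError(
                    f"line {lineno}: expected 7 tab-separated columns "
                    f"({' '.join(PAIRS_COLUMNS)}), got {len(fields)}"
                )
            read_id, chrom1, pos1, chrom2, pos2, strand1, strand2 = fields
            if swap_sides:
                chrom1, pos1, strand1, chrom2, pos2, strand2 = (
                    chrom2, pos2, strand2, chrom1, pos1, strand1,
                )
            if chrom1 not in assembly or chrom2 not in assembly:
                skip_counter[0] += 1
                continue
            try:
                p1, p2 = int(pos1), int(pos2)
            except ValueError as exc:
                raise PairsParseError(f"line {lineno}: non-integer position") from exc
            for chrom, pos in ((chrom1, p1), (chrom2, p2)):
                if not 1 <= pos <= assembly.length(chrom):
                    raise PairsParseError(
                        f"line {lineno}: position {pos} outside {chrom} "
                        f"(length {assembly.length(chrom)})"
                    )
            yield ContactPair(
                read_id=read_id,
                rna_end=GenomicInterval(chrom1, p1 - 1, p1, strand1),
                dna_end=GenomicInterval(chrom2, p2 - 1, p2, strand2),
            )


def load_pairs(path, assembly: GenomeAssembly, **kwargs) -> tuple[list[ContactPair], int]:
    """Eagerly read a pairs file; returns ``(pairs, n_skipped)``."""
    counter = [0]
    pairs = list(read_pairs(path, assembly, skip_counter=counter, **kwargs))
    return pairs, counter[0]


def write_pairs(pairs: Iterable[ContactPair], path) -> int:
    """Write pairs-dialect TSV (1-based positions). Returns records written."""
    n = 0
    with _open_text(path, "wt") as fh:
        fh.write("# pairs format v1.0\n")
        fh.write("#columns: " + " ".join(PAIRS_COLUMNS) + "\n")
        for p in pairs:
            fh.write(
                f"{p.read_id}\t{p.rna_end.chrom}\t{p.rna_end.start + 1}\t"
                f"{p.dna_end.chrom}\t{p.dna_end.start + 1}\t"
                f"{p.rna_end.strand}\t{p.dna_end.strand}\n"
            )
            n += 1
    return n


# ---------------------------------------------------------------------------
# gene annotation (GTF/GFF)

_BIOTYPE_ATTRS = ("gene_biotype", "gene_type", "biotype")


def read_gene_annotation(
    path,
    assembly: GenomeAssembly,
    biotype_map: Mapping[str, str] | None = None,
    *,
    skip_counter: list | None = None,
) -> list[GeneModel]:
    """Read ``gene`` features from a GTF/GFF file into :class:`GeneModel`s.

    Raw biotypes are mapped to the closed RNA-class vocabulary through
    *biotype_map*; biotypes absent from the map fall back to
    ``other_ncRNA``.  GTF 1-based inclusive coordinates become 0-based
    half-open.  Genes on chromosomes absent from the assembly are skipped
    and counted; duplicate gene ids are an error.
    """
    import gffutils

    if biotype_map is None:
        biotype_map = {c: c for c in RNA_CLASSES}
    if skip_counter is None:
        skip_counter = [0]

    with _open_text(path) as fh:
        text = fh.read()
    try:
        db = gffutils.create_db(
            text,
            dbfn=":memory:",
            from_string=True,
            keep_order=True,
            merge_strategy="error",
            disable_infer_genes=True,
            disable_infer_transcripts=True,
        )
    except ValueError as exc:
        raise ValueError(f"duplicate or conflicting feature ids in {path}: {exc}") from exc

    genes: list[GeneModel] = []
    seen: set[str] = set()
    for feat in db.features_of_type("gene"):
        gene_id = feat.attributes.get("gene_id", [feat.id])[0]
        if gene_id in seen:
            raise ValueError(f"duplicate gene_id {gene_id!r}")
        seen.add(gene_id)
        if feat.seqid not in assembly:
            skip_counter[0] += 1
            continue
        raw_biotype = None
        for key in _BIOTYPE_ATTRS:
            if key in feat.attributes:
                raw_biotype = feat.attributes[key][0]
                break
        rna_class = biotype_map.get(raw_biotype, "other_ncRNA")
        gene_name = feat.attributes.get("gene_name", [gene_id])[0]
        span = GenomicInterval(feat.seqid, feat.start - 1, feat.end, feat.strand)
        assembly.validate_interval(span)
        genes.append(GeneModel(gene_id, gene_name, rna_class, span))
    return genes


def write_gene_annotation(genes: Iterable[GeneModel], path) -> None:
    """Write genes as GTF ``gene`` records (1-based inclusive coordinates)."""
    with _open_text(path, "wt") as fh:
        for g in genes:
            attrs = (
                f'gene_id "{g.gene_id}"; gene_name "{g.gene_name}"; '
                f'gene_biotype "{g.rna_class}";'
            )
            fh.write(
                f"{g.span.chrom}\tcarna\tgene\t{g.span.start + 1}\t{g.span.end}\t"
                f".\t{g.span.strand}\t.\t{attrs}\n"
            )


# ---------------------------------------------------------------------------
# BED

def read_bed(path, assembly: GenomeAssembly) -> list[GenomicInterval]:
    """Read a BED3+ file (0-based half-open) preserving input order."""
    out: list[GenomicInterval] = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split()
            if len(fields) < 3:
                raise ValueError(f"line {lineno}: BED needs >= 3 columns")
            chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            if start >= end:
                raise ValueError(f"line {lineno}: start {start} >= end {end}")
            strand = fields[5] if len(fields) >= 6 and fields[5] in ("+", "-") else "."
            iv = GenomicInterval(chrom, start, end, strand)
            assembly.validate_interval(iv)
            out.append(iv)
    return out


def write_bed(regions: Iterable[GenomicInterval], path) -> None:
    with _open_text(path, "wt") as fh:
        for i, r in enumerate(regions):
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\tregion_{i}\t0\t{r.strand if r.strand != '.' else '+'}\n")


# ---------------------------------------------------------------------------
# bedGraph

def read_signal_bedgraph(path, assembly: GenomeAssembly, bin_size: int) -> SignalTrack:
    """Bin a bedGraph file (0-based half-open, non-overlapping records).

    Each bin's value is the coverage-weighted mean of overlapping record
    values with uncovered bases contributing zero, i.e.
    ``sum(value * overlap) / bin_size``.  Overlapping records are an error:
    the dialect is declared non-overlapping.
    """
    if bin_size < 1:
        raise ValueError("bin_size must be >= 1")
    track = SignalTrack.zeros(assembly, bin_size)
    last_end: dict[str, int] = {}
    records: dict[str, list[tuple[int, int, float]]] = {}
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split()
            if len(fields) < 4:
                raise ValueError(f"line {lineno}: bedGraph needs 4 columns")
            chrom, start, end, value = fields[0], int(fields[1]), int(fields[2]), float(fields[3])
            if start >= end:
                raise ValueError(f"line {lineno}: start {start} >= end {end}")
            if value < 0 or not math.isfinite(value):
                raise ValueError(f"line {lineno}: invalid signal value {value}")
            iv = GenomicInterval(chrom, start, end)
            assembly.validate_interval(iv)
            records.setdefault(chrom, []).append((start, end, value))
    for chrom, recs in records.items():
        recs.sort()
        prev_end = -1
        vec = track.values[chrom]
        for start, end, value in recs:
            if start < prev_end:
                raise ValueError(
                    f"overlapping bedGraph records on {chrom} at {start}"
                )
            prev_end = end
            first_bin = start // bin_size
            last_bin = (end - 1) // bin_size
            for b in range(first_bin, last_bin + 1):
                bin_start = b * bin_size
                overlap = min(end, bin_start + bin_size) - max(start, bin_start)
                vec[b] += value * overlap / bin_size
    return track


def write_signal_bedgraph(track: SignalTrack, path) -> None:
    """Write one bedGraph record per non-zero bin (run-length merged)."""
    with _open_text(path, "wt") as fh:
        for chrom in track.assembly.chrom_names:
            vec = track.values[chrom]
            chrom_len = track.assembly.length(chrom)
            run_start = None
            run_value = 0.0
            for b, v in enumerate(vec):
                if run_start is not None and v != run_value:
                    fh.write(f"{chrom}\t{run_start * track.bin_size}\t{min(b * track.bin_size, chrom_len)}\t{run_value:g}\n")
                    run_start = None
                if v != 0 and run_start is None:
                    run_start, run_value = b, v
            if run_start is not None:
                fh.write(f"{chrom}\t{run_start * track.bin_size}\t{chrom_len}\t{run_value:g}\n")
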