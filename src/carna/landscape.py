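"""Class-level interaction landscapes, per-gene profiles and trans-acting calls.

The landscape summarizes an annotated contact set three ways:

* globally — what fraction of all contacts is cis vs trans;
* per RNA class — each class's share of all annotated cis (or trans)
  contacts, and the trans fraction within the class;
* per gene — total contacts, trans contacts and trans fraction, feeding
  the trans-acting caller.

A gene is called *trans-acting* when it has at least ``min_contacts``
chromatin contacts of which at least ``min_trans_fraction`` are trans
(defaults 10 and 0.20, both inclusive).  Unannotated contacts count toward
the global cis/trans fractions but not toward class shares or gene
profiles: they are not an RNA class.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .annotate import AnnotatedContact
from .contacts_io import RNA_CLASSES, GenomeAssembly, GenomicInterval, _open_text

__all__ = [
    "ClassLandscape",
    "GeneContactProfile",
    "TransActingParams",
    "InteractionMap",
    "class_landscape",
    "gene_profiles",
    "call_trans_acting",
    "is_trans_acting",
    "interaction_map",
    "qpcr_enrichment",
]


@dataclass
class ClassLandscape:
    """Cis/trans contact counts per RNA class plus global totals."""

    n_cis: dict[str, int]
    n_trans: dict[str, int]
    n_unannotated_cis: int = 0
    n_unannotated_trans: int = 0

    @property
    def n_total(self) -> int:
        return (
            sum(self.n_cis.values())
            + sum(self.n_trans.values())
            + self.n_unannotated_cis
            + self.n_unannotated_trans
        )

    @property
    def n_annotated(self) -> int:
        return sum(self.n_cis.values()) + sum(self.n_trans.values())

    @property
    def n_unannotated(self) -> int:
        return self.n_unannotated_cis + self.n_unannotated_trans

    @property
    def global_cis_fraction(self) -> float | None:
        """Cis fraction over all contacts, annotated or not."""
        total = self.n_total
        if total == 0:
            return None
        cis = sum(self.n_cis.values()) + self.n_unannotated_cis
        return cis / total

    @property
    def global_trans_fraction(self) -> float | None:
        f = self.global_cis_fraction
        return None if f is None else 1.0 - f

    @property
    def share_of_cis(self) -> dict[str, float | None]:
        """Each class's share of annotated cis contacts (sums to 1)."""
        denom = sum(self.n_cis.values())
        return {c: (self.n_cis[c] / denom if denom else None) for c in self.n_cis}

    @property
    def share_of_trans(self) -> dict[str, float | None]:
        denom = sum(self.n_trans.values())
        return {c: (self.n_trans[c] / denom if denom else None) for c in self.n_trans}

    @property
    def trans_fraction_within_class(self) -> dict[str, float | None]:
        """Per class: n_trans / (n_cis + n_trans), None for empty classes."""
        out: dict[str, float | None] = {}
        for c in self.n_cis:
            total = self.n_cis[c] + self.n_trans[c]
            out[c] = self.n_trans[c] / total if total else None
        return out

    def to_rows(self) -> list[dict]:
        soc, sot, tf = self.share_of_cis, self.share_of_trans, self.trans_fraction_within_class
        return [
            {
                "rna_class": c,
                "n_cis": self.n_cis[c],
                "n_trans": self.n_trans[c],
                "share_of_cis": soc[c],
                "share_of_trans": sot[c],
                "trans_fraction_within_class": tf[c],
            }
            for c in self.n_cis
        ]


def class_landscape(contacts: Iterable[AnnotatedContact]) -> ClassLandscape:
    """Tally exact cis/trans counts per class over an annotated stream."""
    n_cis = {c: 0 for c in RNA_CLASSES}
    n_trans = {c: 0 for c in RNA_CLASSES}
    un_cis = un_trans = 0
    for c in contacts:
        if c.gene_id is None:
            if c.locality == "cis":
                un_cis += 1
            else:
                un_trans += 1
        elif c.locality == "cis":
            n_cis[c.rna_class] += 1
        else:
            n_trans[c.rna_class] += 1
    return ClassLandscape(n_cis, n_trans, un_cis, un_trans)


@dataclass(frozen=True, slots=True)
class GeneContactProfile:
    """Per-gene contact totals: n_total, n_trans and the trans fraction."""

    gene_id: str
    rna_class: str
    n_total: int
    n_trans: int

    def __post_init__(self):
        if not 0 <= self.n_trans <= self.n_total or self.n_total < 1:
            raise ValueError("require 0 <= n_trans <= n_total and n_total >= 1")

    @property
    def trans_fraction(self) -> float:
        return self.n_trans / self.n_total


def gene_profiles(contacts: Iterable[AnnotatedContact]) -> list[GeneContactProfile]:
    """One profile per gene with >= 1 annotated contact (unannotated excluded)."""
    totals: dict[str, int] = {}
    trans: dict[str, int] = {}
    classes: dict[str, str] = {}
    for c in contacts:
        if c.gene_id is None:
            continue
        totals[c.gene_id] = totals.get(c.gene_id, 0) + 1
        if c.locality == "trans":
            trans[c.gene_id] = trans.get(c.gene_id, 0) + 1
        classes[c.gene_id] = c.rna_class
    return [
        GeneContactProfile(g, classes[g], totals[g], trans.get(g, 0))
        for g in sorted(totals)
    ]


@dataclass(frozen=True)
class TransActingParams:
    """Dual threshold for the trans-acting call; both bounds inclusive."""

    min_contacts: int = 10
    min_trans_fraction: float = 0.20

    def __post_init__(self):
        if self.min_contacts < 1:
            raise ValueError("min_contacts must be >= 1")
        if not 0.0 <= self.min_trans_fraction <= 1.0:
            raise ValueError("min_trans_fraction must be in [0, 1]")


def is_trans_acting(profile: GeneContactProfile, params: TransActingParams = TransActingParams()) -> bool:
    return (
        profile.n_total >= params.min_contacts
        and profile.trans_fraction >= params.min_trans_fraction
    )


def call_trans_acting(
    profiles: Iterable[GeneContactProfile],
    params: TransActingParams = TransActingParams(),
) -> list[GeneContactProfile]:
    """Genes passing both thresholds, sorted by n_trans descending
    (ties by trans fraction descending, then gene id)."""
    called = [p for p in profiles if is_trans_acting(p, params)]
    called.sort(key=lambda p: (-p.n_trans, -p.trans_fraction, p.gene_id))
    return called


@dataclass
class InteractionMap:
    """Genome-wide binned contact frequencies for one focal gene, plus arcs
    (source locus, target bin, locality, count) for circos-style export."""

    gene_id: str
    gene_span: GenomicInterval
    bin_size: int
    frequencies: dict[tuple[str, int], int]
    arcs: list[tuple[GenomicInterval, GenomicInterval, str, int]]

    @property
    def n_total(self) -> int:
        return sum(self.frequencies.values())

    def write_arcs(self, path) -> None:
        with _open_text(path, "wt") as fh:
            fh.write(
                "gene_id\tsrc_chrom\tsrc_start\tsrc_end\t"
                "tgt_chrom\ttgt_start\ttgt_end\tlocality\tcount\n"
            )
            for src, tgt, locality, count in self.arcs:
                fh.write(
                    f"{self.gene_id}\t{src.chrom}\t{src.start}\t{src.end}\t"
                    f"{tgt.chrom}\t{tgt.start}\t{tgt.end}\t{locality}\t{count}\n"
                )


def interaction_map(
    gene_id: str,
    contacts: Iterable[AnnotatedContact],
    bin_size: int,
    assembly: GenomeAssembly,
    gene_span: GenomicInterval | None = None,
) -> InteractionMap:
    """Bin the DNA ends of one gene's contacts genome-wide.

    Emits one arc per non-zero bin from the gene span to the bin, labeled
    cis or trans.  Bin frequencies sum to the gene's total contact count.
    Raises ``KeyError`` if the gene has no annotated contact.
    """
    freqs: dict[tuple[str, int], int] = {}
    loc_by_bin: dict[tuple[str, int], str] = {}
    span = gene_span
    found = False
    for c in contacts:
        if c.gene_id != gene_id:
            continue
        found = True
        key = (c.pair.dna_end.chrom, c.pair.dna_end.start // bin_size)
        freqs[key] = freqs.get(key, 0) + 1
        loc_by_bin[key] = c.locality
        if span is None:
            # fall back to the RNA-end footprint if no gene span was given
            span = c.pair.rna_end
    if not found:
        raise KeyError(f"gene {gene_id!r} has no annotated contacts")
    arcs = []
    for (chrom, b), count in sorted(freqs.items()):
        tgt = GenomicInterval(
            chrom, b * bin_size, min((b + 1) * bin_size, assembly.length(chrom))
        )
        arcs.append((span, tgt, loc_by_bin[(chrom, b)], count))
    return InteractionMap(gene_id, span, bin_size, freqs, arcs)


def qpcr_enrichment(ct_pair: float, ct_rna: float, efficiency: float = 2.0) -> float:
    """Enrichment of an RNA-DNA ligation product over the candidate RNA.

    Computed from qPCR cycle thresholds as ``efficiency ** (ct_rna - ct_pair)``
    — the ratio of PCR amplification of the RNA-DNA product to that of the
    candidate RNA, assuming per-cycle amplification factor *efficiency*
    (default 2.0, perfect doubling).
    """
    if not (math.isfinite(ct_pair) and math.isfinite(ct_rna)):
        raise ValueError("cycle thresholds must be finite")
    if efficiency <= 1.0:
        raise ValueError("efficiency must exceed 1")
    return efficiency ** (ct_rna - ct_pair)
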