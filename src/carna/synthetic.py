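"""Truth-known synthetic inputs for every pipeline stage.

The generator emulates the statistical structure of an RNA-DNA contact
experiment rather than its reads: a small genome, a nested gene
annotation (a configurable fraction of snoRNAs placed strictly inside
same-strand lncRNA hosts, as with SNHG-family host genes), contact pairs
with per-class trans rates and an exponential cis distance decay around
the source gene, a handful of trans-hotspot genes, and chromatin-mark
tracks with planted enrichment clusters.  Every draw is recorded in a
truth table so downstream estimates can be checked against what was
simulated.

Default per-class trans rates encode the experimentally observed
structure: mRNAs and lncRNAs contact chromatin almost exclusively near
their site of transcription (trans rates of a few percent), while
snoRNAs and snRNAs are predominantly trans-acting (rate 0.8).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .contacts_io import (
    RNA_CLASSES,
    ContactPair,
    GeneModel,
    GenomeAssembly,
    GenomicInterval,
)

__all__ = [
    "DEFAULT_TRANS_RATES",
    "DEFAULT_EXPRESSION_WEIGHTS",
    "ContactSimConfig",
    "SimTruth",
    "make_genome",
    "make_annotation",
    "simulate_contacts",
    "make_regions",
    "simulate_tracks",
]

#: Per-class probability that a contact is inter-chromosomal.
DEFAULT_TRANS_RATES: dict[str, float] = {
    "protein_coding": 0.02,
    "lncRNA": 0.03,
    "miRNA": 0.05,
    "snoRNA": 0.80,
    "snRNA": 0.80,
    "rRNA": 0.50,
    "other_ncRNA": 0.05,
}

#: Relative sampling weight per gene of each class (mRNAs dominate the
#: interactome by volume).
DEFAULT_EXPRESSION_WEIGHTS: dict[str, float] = {
    "protein_coding": 1.0,
    "lncRNA": 0.4,
    "miRNA": 0.1,
    "snoRNA": 0.3,
    "snRNA": 0.3,
    "rRNA": 0.2,
    "other_ncRNA": 0.1,
}


def make_genome(
    n_chroms: int,
    lengths: Sequence[int] | int,
    seed: int = 0,
) -> GenomeAssembly:
    """A deterministic assembly named chr1..chrN.

    ``lengths`` may be one length for all chromosomes or a per-chromosome
    sequence.  At least two chromosomes are required: trans contacts need
    a second chromosome to land on.
    """
    if n_chroms < 2:
        raise ValueError("need >= 2 chromosomes (trans requires two)")
    if isinstance(lengths, int):
        lengths = [lengths] * n_chroms
    if len(lengths) != n_chroms:
        raise ValueError("lengths must match n_chroms")
    return GenomeAssembly(
        tuple(f"chr{i + 1}" for i in range(n_chroms)),
        tuple(int(l) for l in lengths),
    )


DEFAULT_LENGTH_RANGES: dict[str, tuple[int, int]] = {
    "protein_coding": (5_000, 50_000),
    "lncRNA": (2_000, 20_000),
    "miRNA": (60, 120),
    "snoRNA": (100, 300),
    "snRNA": (100, 300),
    "rRNA": (1_000, 5_000),
    "other_ncRNA": (200, 2_000),
}


def make_annotation(
    assembly: GenomeAssembly,
    class_counts: Mapping[str, int],
    length_ranges: Mapping[str, tuple[int, int]] | None = None,
    nest_snorna_in_hosts: float = 0.0,
    seed: int = 0,
    max_retries: int = 2000,
) -> list[GeneModel]:
    """Place genes on the assembly; returns a list of :class:`GeneModel`.

    Non-nested genes are placed uniformly at random without overlap
    (bounded rejection sampling).  A ``nest_snorna_in_hosts`` fraction of
    the snoRNAs is instead placed strictly inside a randomly chosen
    same-strand lncRNA span, emulating snoRNA host genes.
    """
    if not 0.0 <= nest_snorna_in_hosts <= 1.0:
        raise ValueError("nest_snorna_in_hosts must be in [0, 1]")
    ranges = dict(DEFAULT_LENGTH_RANGES)
    if length_ranges:
        ranges.update(length_ranges)
    rng = np.random.default_rng(seed)
    occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in assembly.chrom_names}
    genes: list[GeneModel] = []

    def place_free(length: int) -> GenomicInterval:
        for _ in range(max_retries):
            ci = rng.integers(len(assembly.chrom_names))
            chrom = assembly.chrom_names[ci]
            chrom_len = assembly.chrom_lengths[ci]
            if chrom_len <= length:
                continue
            start = int(rng.integers(0, chrom_len - length))
            end = start + length
            if all(end <= s or start >= e for s, e in occupied[chrom]):
                occupied[chrom].append((start, end))
                strand = "+" if rng.random() < 0.5 else "-"
                return GenomicInterval(chrom, start, end, strand)
        raise RuntimeError(
            f"could not place a gene of length {length} after {max_retries} tries"
        )

    n_sno = int(class_counts.get("snoRNA", 0))
    n_nested = int(round(n_sno * nest_snorna_in_hosts))

    # hosts first, so nested snoRNAs have somewhere to go
    class_order = sorted(class_counts, key=lambda c: c != "lncRNA")
    counters: dict[str, int] = {}
    for cls in class_order:
        if cls not in RNA_CLASSES:
            raise ValueError(f"unknown class {cls!r} in class_counts")
        count = int(class_counts[cls])
        lo, hi = ranges[cls]
        n_free = count - n_nested if cls == "snoRNA" else count
        for _ in range(n_free):
            length = int(rng.integers(lo, hi + 1))
            span = place_free(length)
            idx = counters.get(cls, 0)
            counters[cls] = idx + 1
            genes.append(GeneModel(f"{cls}_{idx:04d}", f"{cls}_{idx:04d}", cls, span))

    if n_nested:
        hosts = [g for g in genes if g.rna_class == "lncRNA"]
        lo, hi = ranges["snoRNA"]
        if not hosts:
            raise ValueError("nesting requested but no lncRNA hosts in class_counts")
        for _ in range(n_nested):
            length = int(rng.integers(lo, hi + 1))
            candidates = [h for h in hosts if h.span.length > length + 2]
            if not candidates:
                raise RuntimeError("no lncRNA host long enough for nesting")
            host = candidates[rng.integers(len(candidates))]
            start = int(
                rng.integers(host.span.start + 1, host.span.end - length)
            )
            span = GenomicInterval(
                host.span.chrom, start, start + length, host.span.strand
            )
            idx = counters.get("snoRNA", 0)
            counters["snoRNA"] = idx + 1
            genes.append(
                GeneModel(f"snoRNA_{idx:04d}", f"snoRNA_{idx:04d}", "snoRNA", span)
            )
    return genes


@dataclass
class ContactSimConfig:
    """Study-condition parameters for the contact simulator."""

    n_pairs: int = 100_000
    #: per-class trans probability, or a single float applied to every class
    trans_rates: Mapping[str, float] | float = field(
        default_factory=lambda: dict(DEFAULT_TRANS_RATES)
    )
    expression_weights: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_EXPRESSION_WEIGHTS)
    )
    #: scale (bases) of the exponential distance kernel for cis DNA ends
    cis_decay_scale: float = 100_000.0
    #: gene_id -> elevated trans rate, overriding the class rate
    hotspot_genes: Mapping[str, float] = field(default_factory=dict)
    seed: int = 0

    def rate_for(self, gene: GeneModel) -> float:
        if gene.gene_id in self.hotspot_genes:
            return float(self.hotspot_genes[gene.gene_id])
        if isinstance(self.trans_rates, Mapping):
            return float(self.trans_rates.get(gene.rna_class, 0.0))
        return float(self.trans_rates)

    def validate(self, assembly: GenomeAssembly) -> None:
        if self.n_pairs < 0:
            raise ValueError("n_pairs must be >= 0")
        if self.cis_decay_scale <= 0:
            raise ValueError("cis_decay_scale must be > 0")
        rates = (
            list(self.trans_rates.values())
            if isinstance(self.trans_rates, Mapping)
            else [self.trans_rates]
        )
        rates += list(self.hotspot_genes.values())
        if any(not 0.0 <= r <= 1.0 for r in rates):
            raise ValueError("trans rates must be in [0, 1]")
        if len(assembly) < 2 and any(r > 0 for r in rates):
            raise ValueError("trans contacts require >= 2 chromosomes")
        if isinstance(self.expression_weights, Mapping) and any(
            w <= 0 for w in self.expression_weights.values()
        ):
            raise ValueError("expression weights must be > 0")


@dataclass
class SimTruth:
    """Ground truth for a simulated dataset: the per-pair draws and the
    per-gene expectations implied by the configuration."""

    pairs: pd.DataFrame  # read_id, gene_id, rna_class, locality
    gene_trans_rate: dict[str, float]
    gene_expected_total: dict[str, float]

    @property
    def trans_fraction(self) -> float | None:
        if len(self.pairs) == 0:
            return None
        return float((self.pairs["locality"] == "trans").mean())

    def class_trans_fraction(self) -> pd.Series:
        return self.pairs.groupby("rna_class")["locality"].apply(
            lambda s: (s == "trans").mean()
        )


def simulate_contacts(
    annotation: Sequence[GeneModel],
    assembly: GenomeAssembly,
    config: ContactSimConfig,
) -> tuple[list[ContactPair], SimTruth]:
    """Draw contact pairs under the configured study conditions.

    Per pair: the source gene is drawn proportional to per-class
    expression weights; the RNA end uniform within the gene span with the
    gene's strand; locality is Bernoulli with the gene's trans rate
    (hotspot-overridden); cis DNA ends land at an exponentially
    distributed distance (scale ``cis_decay_scale``) from the gene
    midpoint on the same chromosome, clipped to chromosome bounds; trans
    DNA ends are uniform on a uniformly chosen other chromosome.
    """
    config.validate(assembly)
    genes = list(annotation)
    if config.n_pairs and not genes:
        raise ValueError("cannot simulate contacts without genes")
    rng = np.random.default_rng(config.seed)
    n = config.n_pairs
    if n == 0:
        truth = SimTruth(
            pd.DataFrame(columns=["read_id", "gene_id", "rna_class", "locality"]),
            {}, {},
        )
        return [], truth

    weights = np.array(
        [config.expression_weights.get(g.rna_class, 0.0) for g in genes]
    )
    if weights.sum() <= 0:
        raise ValueError("no gene has positive expression weight")
    probs = weights / weights.sum()
    chrom_index = {c: i for i, c in enumerate(assembly.chrom_names)}
    g_chrom = np.array([chrom_index[g.span.chrom] for g in genes])
    g_start = np.array([g.span.start for g in genes])
    g_len = np.array([g.span.length for g in genes])
    g_mid = np.array([g.span.midpoint for g in genes])
    g_rate = np.array([config.rate_for(g) for g in genes])
    chrom_lens = np.array(assembly.chrom_lengths)

    gi = rng.choice(len(genes), size=n, p=probs)
    rna_pos = g_start[gi] + (rng.random(n) * g_len[gi]).astype(np.int64)
    is_trans = rng.random(n) < g_rate[gi]

    dna_chrom_idx = g_chrom[gi].copy()
    dna_pos = np.zeros(n, dtype=np.int64)

    cis = ~is_trans
    if cis.any():
        offsets = rng.exponential(config.cis_decay_scale, size=int(cis.sum()))
        signs = rng.choice([-1, 1], size=int(cis.sum()))
        pos = g_mid[gi[cis]] + (signs * offsets).astype(np.int64)
        pos = np.clip(pos, 0, chrom_lens[g_chrom[gi[cis]]] - 1)
        dna_pos[cis] = pos
    if is_trans.any():
        nt = int(is_trans.sum())
        # uniformly chosen chromosome other than the gene's own
        shift = rng.integers(1, len(assembly), size=nt)
        tgt = (g_chrom[gi[is_trans]] + shift) % len(assembly)
        dna_chrom_idx[is_trans] = tgt
        dna_pos[is_trans] = (rng.random(nt) * chrom_lens[tgt]).astype(np.int64)
    dna_strand = np.where(rng.random(n) < 0.5, "+", "-")

    pairs: list[ContactPair] = []
    rows_gene, rows_loc, rows_cls, rows_id = [], [], [], []
    names = assembly.chrom_names
    for i in range(n):
        g = genes[gi[i]]
        read_id = f"r{i:07d}"
        pairs.append(
            ContactPair(
                read_id,
                GenomicInterval(
                    g.span.chrom, int(rna_pos[i]), int(rna_pos[i]) + 1, g.span.strand
                ),
                GenomicInterval(
                    names[dna_chrom_idx[i]],
                    int(dna_pos[i]),
                    int(dna_pos[i]) + 1,
                    dna_strand[i],
                ),
            )
        )
        rows_id.append(read_id)
        rows_gene.append(g.gene_id)
        rows_cls.append(g.rna_class)
        rows_loc.append("trans" if is_trans[i] else "cis")

    truth_df = pd.DataFrame(
        {
            "read_id": rows_id,
            "gene_id": rows_gene,
            "rna_class": rows_cls,
            "locality": rows_loc,
        }
    )
    expected = {
        g.gene_id: float(n * probs[j]) for j, g in enumerate(genes)
    }
    rates = {g.gene_id: float(g_rate[j]) for j, g in enumerate(genes)}
    return pairs, SimTruth(truth_df, rates, expected)


def make_regions(
    assembly: GenomeAssembly,
    n_regions: int,
    region_length: int,
    seed: int = 0,
    bin_size: int = 1,
) -> list[GenomicInterval]:
    """Non-overlapping regions aligned to ``bin_size`` boundaries.

    Alignment means a region covers whole signal bins, so planted track
    values are recovered exactly by region scoring when noise is zero.
    """
    if region_length % bin_size:
        raise ValueError("region_length must be a multiple of bin_size")
    rng = np.random.default_rng(seed)
    occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in assembly.chrom_names}
    out: list[GenomicInterval] = []
    for _ in range(n_regions):
        for attempt in range(5000):
            ci = int(rng.integers(len(assembly)))
            chrom = assembly.chrom_names[ci]
            max_start_bin = (assembly.chrom_lengths[ci] - region_length) // bin_size
            if max_start_bin < 0:
                continue
            start = int(rng.integers(0, max_start_bin + 1)) * bin_size
            end = start + region_length
            if all(end <= s or start >= e for s, e in occupied[chrom]):
                occupied[chrom].append((start, end))
                strand = "+" if rng.random() < 0.5 else "-"
                out.append(GenomicInterval(chrom, start, end, strand))
                break
        else:
            raise RuntimeError("could not place all regions without overlap")
    return out


def simulate_tracks(
    assembly: GenomeAssembly,
    regions: Sequence[GenomicInterval],
    k_clusters: int,
    mark_signatures: np.ndarray,
    mark_names: Sequence[str],
    noise_sd: float = 0.0,
    seed: int = 0,
    bin_size: int = 100,
    baseline: float = 0.0,
) -> tuple[dict[str, "SignalTrack"], np.ndarray]:
    """Mark tracks with planted per-region cluster signal.

    Each region is assigned a cluster label uniformly at random; region r
    in cluster c receives, for each mark, signal
    ``signature[c][mark] + Normal(0, noise_sd)`` (floored at 0) across its
    bins.  Background bins sit at ``baseline``.  Returns the named tracks
    and the true labels.
    """
    from .contacts_io import SignalTrack

    sig = np.asarray(mark_signatures, dtype=float)
    if sig.shape != (k_clusters, len(mark_names)):
        raise ValueError(
            f"signatures shape {sig.shape} != ({k_clusters}, {len(mark_names)})"
        )
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    labels = rng.integers(0, k_clusters, size=len(regions))
    tracks = {
        name: SignalTrack(
            assembly,
            bin_size,
            {
                c: np.full(assembly.n_bins(c, bin_size), float(baseline))
                for c in assembly.chrom_names
            },
            "raw",
        )
        for name in mark_names
    }
    for i, region in enumerate(regions):
        values = sig[labels[i]] + rng.normal(0.0, noise_sd, size=len(mark_names))
        values = np.maximum(values, 0.0)
        first, last = region.start // bin_size, (region.end - 1) // bin_size
        for j, name in enumerate(mark_names):
            tracks[name].values[region.chrom][first : last + 1] = values[j]
    return tracks, labels
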