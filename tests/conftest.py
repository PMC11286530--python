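import numpy as np
import pytest

from carna.contacts_io import (
    ContactPair,
    GeneModel,
    GenomeAssembly,
    GenomicInterval,
)


@pytest.fixture
def assembly():
    return GenomeAssembly(("chr1", "chr2", "chr3"), (100_000, 80_000, 60_000))


@pytest.fixture
def genes():
    """A lncRNA host with a nested snoRNA, plus a protein-coding gene on
    chr2 and an antisense protein-coding gene on chr1."""
    return [
        GeneModel("lnc1", "LNC1", "lncRNA", GenomicInterval("chr1", 1000, 11000, "+")),
        GeneModel("sno1", "SNO1", "snoRNA", GenomicInterval("chr1", 4000, 4200, "+")),
        GeneModel("pc1", "PC1", "protein_coding", GenomicInterval("chr2", 5000, 25000, "+")),
        GeneModel("pc2", "PC2", "protein_coding", GenomicInterval("chr1", 30000, 40000, "-")),
    ]


def make_pair(read_id, rna_chrom, rna_pos, dna_chrom, dna_pos, rna_strand="+", dna_strand="+"):
    return ContactPair(
        read_id,
        GenomicInterval(rna_chrom, rna_pos, rna_pos + 1, rna_strand),
        GenomicInterval(dna_chrom, dna_pos, dna_pos + 1, dna_strand),
    )


@pytest.fixture
def random_genes_factory():
    """Random non-degenerate gene sets for oracle comparisons."""

    def factory(n, assembly, seed):
        rng = np.random.default_rng(seed)
        classes = (
            "protein_coding", "lncRNA", "snoRNA", "snRNA",
            "miRNA", "rRNA", "other_ncRNA",
        )
        out = []
        for i in range(n):
            ci = int(rng.integers(len(assembly.chrom_names)))
            chrom = assembly.chrom_names[ci]
            chrom_len = assembly.chrom_lengths[ci]
            length = int(rng.integers(50, max(51, chrom_len // 10)))
            start = int(rng.integers(0, chrom_len - length))
            strand = "+" if rng.random() < 0.5 else "-"
            cls = classes[int(rng.integers(len(classes)))]
            out.append(
                GeneModel(
                    f"g{i:04d}", f"g{i:04d}", cls,
                    GenomicInterval(chrom, start, start + length, strand),
                )
            )
        return out

    return factory
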