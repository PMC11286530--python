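"""Chromatin-mark enrichment scoring, region clustering and condition comparison.

RNA-interacting genomic regions are scored against binned signal tracks
(ChIP-seq / ATAC-seq coverage, CPM-normalized) into a regions x marks
enrichment matrix.  Regions are then grouped by k-means on the
column-z-scored matrix into activity clusters C1..Ck, with C1 the cluster
of highest mean signal for a labeling mark (H3K27ac by default, so C1 is
the transcriptionally active group).  A separate comparison computes
per-region log2 signal ratios between two conditions (e.g. knockdown vs
control) over the same region set.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from sklearn.cluster import KMeans

from .contacts_io import GenomicInterval, SignalTrack, _open_text

__all__ = [
    "EnrichmentMatrix",
    "ClusterAssignment",
    "SignalComparison",
    "cpm_normalize",
    "score_regions",
    "average_profile",
    "cluster_regions",
    "compare_conditions",
]


def cpm_normalize(track: SignalTrack, library_size: float) -> SignalTrack:
    """Scale every bin by 1e6 / library_size; tags the track 'CPM'.

    ``library_size`` is the total raw signal units of the library (e.g.
    mapped read count).  Normalizing an already-CPM track is an error.
    """
    if track.normalization != "raw":
        raise ValueError("track is already normalized (double normalization)")
    if library_size <= 0:
        raise ValueError("library_size must be > 0")
    out = track.copy()
    factor = 1e6 / library_size
    for vec in out.values.values():
        vec *= factor
    out.normalization = "CPM"
    return out


@dataclass
class EnrichmentMatrix:
    """Regions x marks matrix of mean signal per region."""

    regions: list[GenomicInterval]
    marks: list[str]
    scores: np.ndarray  # shape (n_regions, n_marks), finite, >= 0

    def __post_init__(self):
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.shape != (len(self.regions), len(self.marks)):
            raise ValueError(
                f"matrix shape {self.scores.shape} != "
                f"({len(self.regions)}, {len(self.marks)})"
            )
        if self.scores.size and not np.all(np.isfinite(self.scores)):
            raise ValueError("scores must be finite")

    def zscored(self) -> np.ndarray:
        """Column-z-scored copy; zero-variance columns map to all zeros."""
        mean = self.scores.mean(axis=0)
        std = self.scores.std(axis=0)
        safe = np.where(std > 0, std, 1.0)
        z = (self.scores - mean) / safe
        z[:, std == 0] = 0.0
        return z

    def mark_column(self, mark: str) -> np.ndarray:
        return self.scores[:, self.marks.index(mark)]

    def write_tsv(self, path) -> None:
        with _open_text(path, "wt") as fh:
            fh.write("chrom\tstart\tend\t" + "\t".join(self.marks) + "\n")
            for r, row in zip(self.regions, self.scores):
                fh.write(
                    f"{r.chrom}\t{r.start}\t{r.end}\t"
                    + "\t".join(f"{v:.6g}" for v in row)
                    + "\n"
                )


def _region_mean(track: SignalTrack, region: GenomicInterval) -> float:
    """Length-weighted mean of the track over the region (per-base mean)."""
    track.assembly.validate_interval(region)
    bs = track.bin_size
    vec = track.values[region.chrom]
    first, last = region.start // bs, (region.end - 1) // bs
    total = 0.0
    for b in range(first, last + 1):
        overlap = min(region.end, (b + 1) * bs) - max(region.start, b * bs)
        total += vec[b] * overlap
    return total / region.length


def score_regions(
    regions: Sequence[GenomicInterval],
    tracks: Mapping[str, SignalTrack],
) -> EnrichmentMatrix:
    """Score every region against every named track.

    score(region, mark) is the length-weighted mean of the mark's bins
    overlapped by the region.  All tracks must share an assembly and
    normalization state.
    """
    items = list(tracks.items())
    if items:
        ref_assembly = items[0][1].assembly
        ref_norm = items[0][1].normalization
        for name, t in items:
            if t.assembly is not ref_assembly and t.assembly != ref_assembly:
                raise ValueError(f"track {name!r} is on a different assembly")
            if t.normalization != ref_norm:
                raise ValueError(f"track {name!r} has mismatched normalization")
    scores = np.zeros((len(regions), len(items)))
    for j, (_, track) in enumerate(items):
        for i, region in enumerate(regions):
            scores[i, j] = _region_mean(track, region)
    return EnrichmentMatrix(list(regions), [name for name, _ in items], scores)


def _per_base(track: SignalTrack, chrom: str, start: int, end: int) -> np.ndarray:
    """Per-base signal over [start, end); bases outside the chromosome are 0."""
    out = np.zeros(end - start)
    chrom_len = track.assembly.length(chrom)
    lo, hi = max(start, 0), min(end, chrom_len)
    if lo >= hi:
        return out
    idx = np.arange(lo, hi) // track.bin_size
    out[lo - start : hi - start] = track.values[chrom][idx]
    return out


def average_profile(
    track: SignalTrack,
    regions: Sequence[GenomicInterval],
    flank: int = 0,
    n_bins: int = 100,
) -> np.ndarray:
    """Across-region mean signal profile with each region scaled to n_bins.

    Each region, extended by ``flank`` bases on both sides, is resampled to
    ``n_bins`` equal-width segments (segment value = mean per-base signal);
    minus-strand regions are reversed so profiles are strand-aware.  The
    result is the element-wise mean over regions.
    """
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    if not regions:
        return np.zeros(n_bins)
    profiles = np.zeros((len(regions), n_bins))
    for i, r in enumerate(regions):
        start, end = r.start - flank, r.end + flank
        base = _per_base(track, r.chrom, start, end)
        if r.strand == "-":
            base = base[::-1]
        # integrate the per-base step function over n_bins equal segments
        cum = np.concatenate([[0.0], np.cumsum(base)])
        L = len(base)
        edges = np.linspace(0.0, L, n_bins + 1)

        def integral(x: float) -> float:
            i0 = min(int(x), L - 1) if L else 0
            return cum[i0] + (x - i0) * (base[i0] if L else 0.0)

        vals = np.array([integral(e) for e in edges])
        seg_width = L / n_bins
        profiles[i] = np.diff(vals) / seg_width if seg_width > 0 else 0.0
    return profiles.mean(axis=0)


@dataclass
class ClusterAssignment:
    """Per-region activity-cluster labels C1..Ck, C1 = highest labeling mark."""

    labels: list[str]
    k: int
    seed: int
    labeling_mark: str
    cluster_means: dict[str, float]  # mean raw labeling-mark signal per cluster

    def as_int(self) -> np.ndarray:
        return np.array([int(l[1:]) - 1 for l in self.labels])

    def write_tsv(self, regions: Sequence[GenomicInterval], path) -> None:
        with _open_text(path, "wt") as fh:
            fh.write("chrom\tstart\tend\tcluster\n")
            for r, lab in zip(regions, self.labels):
                fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{lab}\n")


def cluster_regions(
    matrix: EnrichmentMatrix,
    k: int = 4,
    seed: int = 0,
    labeling_mark: str = "H3K27ac",
    n_restarts: int = 10,
) -> ClusterAssignment:
    """K-means on the column-z-scored matrix, best of ``n_restarts`` by
    within-cluster sum of squares; deterministic given ``seed``.

    Clusters are relabeled C1..Ck by descending mean raw ``labeling_mark``
    signal, so C1 is the most active cluster under that mark.
    """
    n = len(matrix.regions)
    if k > n:
        raise ValueError(f"k={k} exceeds number of regions ({n})")
    if labeling_mark not in matrix.marks:
        raise ValueError(f"labeling mark {labeling_mark!r} not in matrix")
    if np.all(matrix.scores.std(axis=0) == 0) and k > 1:
        raise ValueError(
            "every mark column is constant; clustering is undefined — use k=1"
        )
    z = matrix.zscored()
    km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed)
    raw_labels = km.fit_predict(z)
    mark_col = matrix.mark_column(labeling_mark)
    means = {c: float(mark_col[raw_labels == c].mean()) for c in range(k)}
    # order by descending mean labeling-mark signal; ties by cluster index
    order = sorted(range(k), key=lambda c: (-means[c], c))
    rename = {c: f"C{rank + 1}" for rank, c in enumerate(order)}
    labels = [rename[c] for c in raw_labels]
    return ClusterAssignment(
        labels=labels,
        k=k,
        seed=seed,
        labeling_mark=labeling_mark,
        cluster_means={rename[c]: means[c] for c in range(k)},
    )


@dataclass
class SignalComparison:
    """Per-region signal under two conditions and log2 ratios (B over A)."""

    regions: list[GenomicInterval]
    scores_a: np.ndarray
    scores_b: np.ndarray
    log2_ratios: np.ndarray
    pseudocount: float

    @property
    def mean_log2_ratio(self) -> float:
        return float(self.log2_ratios.mean())

    @property
    def median_log2_ratio(self) -> float:
        return float(np.median(self.log2_ratios))


def compare_conditions(
    regions: Sequence[GenomicInterval],
    track_a: SignalTrack,
    track_b: SignalTrack,
    pseudocount: float = 1.0,
) -> SignalComparison:
    """Per-region log2((score_b + pc) / (score_a + pc)) between conditions.

    Both tracks must be CPM-normalized on the same assembly; the
    pseudocount keeps ratios finite at unmarked regions.
    """
    if track_a.normalization != track_b.normalization:
        raise ValueError("normalization mismatch between conditions")
    if track_a.normalization != "CPM":
        raise ValueError("condition comparison requires CPM-normalized tracks")
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    a = np.array([_region_mean(track_a, r) for r in regions])
    b = np.array([_region_mean(track_b, r) for r in regions])
    ratios = np.log2((b + pseudocount) / (a + pseudocount))
    return SignalComparison(list(regions), a, b, ratios, pseudocount)
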