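"""End-to-end pipeline runner: config validation, staged execution, manifest.

A run is fully specified by one declarative YAML config plus its input
files.  Every default the analysis leaves open (class priority order,
trans-acting thresholds, cluster count, seeds) is surfaced in the config,
and the manifest records the config hash, input checksums and a count
reconciliation (pairs in = contacts annotated = cis + trans) so runs are
auditable and reproducible.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import yaml

from . import __version__
from .annotate import (
    ClassPriority,
    annotate_contacts,
    build_gene_index,
    write_annotated,
)
from .contacts_io import (
    GenomeAssembly,
    read_bed,
    read_gene_annotation,
    read_pairs,
    read_signal_bedgraph,
    _open_text,
)
from .landscape import (
    TransActingParams,
    call_trans_acting,
    class_landscape,
    gene_profiles,
    interaction_map,
)
from .overlay import cluster_regions, cpm_normalize, score_regions

logger = logging.getLogger("carna")

__all__ = ["RunConfig", "ConfigError", "StageError", "run_full"]


class ConfigError(ValueError):
    """Invalid or incomplete run configuration (exit code 2)."""


class StageError(RuntimeError):
    """A pipeline stage failed (exit code 3); names the stage and cause."""


@dataclass
class RunConfig:
    """Declarative description of one pipeline run."""

    pairs: Path
    gtf: Path
    chrom_sizes: Path
    out_dir: Path
    tracks: dict[str, Path] = field(default_factory=dict)
    regions: Path | None = None
    priority: tuple[str, ...] | None = None
    min_contacts: int = 10
    min_trans_fraction: float = 0.20
    map_bin_size: int = 1_000_000
    map_top_n: int = 5
    overlay_k: int = 4
    overlay_seed: int = 0
    overlay_n_restarts: int = 10
    labeling_mark: str = "H3K27ac"
    track_bin_size: int = 100
    swap_sides: bool = False
    allow_antisense: bool = False

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        try:
            cfg = cls(
                pairs=Path(raw["pairs"]),
                gtf=Path(raw["gtf"]),
                chrom_sizes=Path(raw["chrom_sizes"]),
                out_dir=Path(raw["out_dir"]),
                tracks={k: Path(v) for k, v in (raw.get("tracks") or {}).items()},
                regions=Path(raw["regions"]) if raw.get("regions") else None,
                priority=tuple(raw["priority"]) if raw.get("priority") else None,
                min_contacts=int(raw.get("min_contacts", 10)),
                min_trans_fraction=float(raw.get("min_trans_fraction", 0.20)),
                map_bin_size=int(raw.get("map_bin_size", 1_000_000)),
                map_top_n=int(raw.get("map_top_n", 5)),
                overlay_k=int(raw.get("overlay_k", 4)),
                overlay_seed=int(raw.get("overlay_seed", 0)),
                overlay_n_restarts=int(raw.get("overlay_n_restarts", 10)),
                labeling_mark=str(raw.get("labeling_mark", "H3K27ac")),
                track_bin_size=int(raw.get("track_bin_size", 100)),
                swap_sides=bool(raw.get("swap_sides", False)),
                allow_antisense=bool(raw.get("allow_antisense", False)),
            )
        except KeyError as exc:
            raise ConfigError(f"missing required config key: {exc}") from exc
        return cfg

    def validate(self) -> None:
        for name, path in [
            ("pairs", self.pairs),
            ("gtf", self.gtf),
            ("chrom_sizes", self.chrom_sizes),
            ("regions", self.regions),
            *[(f"tracks[{k}]", v) for k, v in self.tracks.items()],
        ]:
            if path is not None and not Path(path).exists():
                raise ConfigError(f"input {name} does not exist: {path}")
        TransActingParams(self.min_contacts, self.min_trans_fraction)
        if self.priority is not None:
            ClassPriority(self.priority)

    def content_hash(self) -> str:
        payload = {
            k: (str(v) if isinstance(v, Path) else v)
            for k, v in sorted(self.__dict__.items())
            if k != "tracks"
        }
        payload["tracks"] = {k: str(v) for k, v in sorted(self.tracks.items())}
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_full(config: RunConfig) -> dict[str, Any]:
    """Execute annotate -> landscape -> trans-acting -> maps -> overlay.

    Returns the run manifest (also written to ``out_dir/manifest.json``).
    Any stage failure raises :class:`StageError` naming the stage.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {
        "tool": "carna",
        "version": __version__,
        "config_hash": config.content_hash(),
        "inputs": {},
        "counts": {},
        "outputs": [],
        "parameters": {
            "min_contacts": config.min_contacts,
            "min_trans_fraction": config.min_trans_fraction,
            "priority": list(config.priority or ()) or "default",
            "overlay_k": config.overlay_k,
            "overlay_seed": config.overlay_seed,
        },
    }
    for name, path in [("pairs", config.pairs), ("gtf", config.gtf), ("chrom_sizes", config.chrom_sizes)]:
        manifest["inputs"][name] = {"path": str(path), "sha256": _sha256(path)}

    stage = "load"
    try:
        assembly = GenomeAssembly.from_chrom_sizes(config.chrom_sizes)
        gene_skips = [0]
        genes = read_gene_annotation(config.gtf, assembly, skip_counter=gene_skips)
        index = build_gene_index(genes)
        priority = ClassPriority(config.priority) if config.priority else ClassPriority()

        stage = "annotate"
        pair_skips = [0]
        stream = read_pairs(
            config.pairs, assembly, swap_sides=config.swap_sides, skip_counter=pair_skips
        )
        contacts = list(
            annotate_contacts(
                stream, index, priority, allow_antisense=config.allow_antisense
            )
        )
        annotated_path = out / "annotated.tsv"
        n_annotated = write_annotated(contacts, annotated_path)
        manifest["outputs"].append(str(annotated_path))

        stage = "landscape"
        land = class_landscape(contacts)
        land_path = out / "landscape.tsv"
        with _open_text(land_path, "wt") as fh:
            fh.write(
                "rna_class\tn_cis\tn_trans\tshare_of_cis\tshare_of_trans\t"
                "trans_fraction_within_class\n"
            )
            for row in land.to_rows():
                fmt = lambda v: "NA" if v is None else f"{v:.6g}"
                fh.write(
                    f"{row['rna_class']}\t{row['n_cis']}\t{row['n_trans']}\t"
                    f"{fmt(row['share_of_cis'])}\t{fmt(row['share_of_trans'])}\t"
                    f"{fmt(row['trans_fraction_within_class'])}\n"
                )
        manifest["outputs"].append(str(land_path))

        stage = "profiles"
        profiles = gene_profiles(contacts)
        prof_path = out / "profiles.tsv"
        with _open_text(prof_path, "wt") as fh:
            fh.write("gene_id\trna_class\tn_total\tn_trans\ttrans_fraction\n")
            for p in profiles:
                fh.write(
                    f"{p.gene_id}\t{p.rna_class}\t{p.n_total}\t{p.n_trans}\t"
                    f"{p.trans_fraction:.6g}\n"
                )
        manifest["outputs"].append(str(prof_path))

        stage = "trans_acting"
        params = TransActingParams(config.min_contacts, config.min_trans_fraction)
        called = call_trans_acting(profiles, params)
        ta_path = out / "trans_acting.tsv"
        with _open_text(ta_path, "wt") as fh:
            fh.write("gene_id\trna_class\tn_total\tn_trans\ttrans_fraction\n")
            for p in called:
                fh.write(
                    f"{p.gene_id}\t{p.rna_class}\t{p.n_total}\t{p.n_trans}\t"
                    f"{p.trans_fraction:.6g}\n"
                )
        manifest["outputs"].append(str(ta_path))
        logger.info(
            "trans-acting call (thresholds >=%d contacts, >=%.0f%% trans): %d genes",
            params.min_contacts, 100 * params.min_trans_fraction, len(called),
        )

        stage = "maps"
        maps_dir = out / "maps"
        maps_dir.mkdir(exist_ok=True)
        for p in called[: config.map_top_n]:
            gmap = interaction_map(
                p.gene_id,
                contacts,
                config.map_bin_size,
                assembly,
                gene_span=index.get(p.gene_id).span,
            )
            path = maps_dir / f"{p.gene_id}.arcs.tsv"
            gmap.write_arcs(path)
            manifest["outputs"].append(str(path))

        if config.tracks and config.regions:
            stage = "overlay"
            regions = read_bed(config.regions, assembly)
            tracks = {}
            for name, path in config.tracks.items():
                raw = read_signal_bedgraph(path, assembly, config.track_bin_size)
                total = raw.total_signal()
                tracks[name] = cpm_normalize(raw, total) if total > 0 else raw
                manifest["inputs"][f"track:{name}"] = {
                    "path": str(path), "sha256": _sha256(path),
                }
            matrix = score_regions(regions, tracks)
            matrix.write_tsv(out / "matrix.tsv")
            assignment = cluster_regions(
                matrix,
                k=config.overlay_k,
                seed=config.overlay_seed,
                labeling_mark=config.labeling_mark,
                n_restarts=config.overlay_n_restarts,
            )
            assignment.write_tsv(regions, out / "clusters.tsv")
            manifest["outputs"] += [str(out / "matrix.tsv"), str(out / "clusters.tsv")]
            manifest["counts"]["overlay_regions"] = len(regions)
    except (ConfigError, StageError):
        raise
    except Exception as exc:
        raise StageError(f"stage {stage!r} failed: {exc}") from exc

    n_cis = sum(1 for c in contacts if c.locality == "cis")
    n_trans = len(contacts) - n_cis
    n_unannotated = sum(1 for c in contacts if c.gene_id is None)
    manifest["counts"].update(
        {
            "pairs_skipped_unknown_chrom": pair_skips[0],
            "genes_skipped_unknown_chrom": gene_skips[0],
            "pairs_annotated": n_annotated,
            "n_cis": n_cis,
            "n_trans": n_trans,
            "n_unannotated": n_unannotated,
            "reconciliation_ok": bool(n_cis + n_trans == len(contacts) == n_annotated),
        }
    )
    logger.info(
        "annotated %d contacts (%d cis / %d trans, %d unannotated, %d skipped)",
        n_annotated, n_cis, n_trans, n_unannotated, pair_skips[0],
    )
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
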