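"""End-to-end orchestration: digest -> filter -> bin -> normalize -> call -> domains.

One configuration object drives the whole analysis at both resolutions
(9 kb genome-wide, 3 kb restricted to +-5 Mb of the capture regions); every
stage writes its outputs under the configured directory and the run ends with
a manifest of inputs, parameters, seeds and output checksums.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from . import io as cio
from .ditags import (DEFAULT_MAPQ_MIN, DEFAULT_MAX_SITE_DISTANCE, FilterReport,
                     filter_bona_fide)
from .domains import call_domains, directionality_index, DEFAULT_DIX_WINDOW
from .matrix import (DEFAULT_MAPABILITY_MIN, DEFAULT_WINDOW, bin_contacts,
                     filter_valid_bins, mark_enriched_bins)
from .normalization import (distance_normalize, estimate_distance_template,
                            iterative_bias_correct)
from .restriction import BinGrid, digest_genome, HINDIII_PATTERN, HINDIII_CUT_OFFSET
from .significance import (DEFAULT_FDR, DEFAULT_MIN_SEPARATION, call_interactions,
                           calls_to_bedpe)

log = logging.getLogger("chicflow")

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Paths and thresholds of one pipeline run; defaults match the method's
    published operating point (MAPQ>30, mapability>0.5, 800 bp site distance,
    q<0.05, >10 kb separation, 10 Mb windows)."""

    genome_fasta: str = ""
    pairs: List[str] = field(default_factory=list)     # one file per library
    baits_bed: str = ""
    mapability_bedgraph: str = ""
    outdir: str = "chicflow_out"
    resolutions: Tuple[int, ...] = (9_000, 3_000)
    close_cis_margin: int = 5_000_000      # 3 kb analysis: +-5 Mb of baits
    pattern: str = HINDIII_PATTERN
    cut_offset: int = HINDIII_CUT_OFFSET
    mapq_min: int = DEFAULT_MAPQ_MIN
    max_site_distance: float = DEFAULT_MAX_SITE_DISTANCE
    mapability_min: float = DEFAULT_MAPABILITY_MIN
    fdr: float = DEFAULT_FDR
    min_separation: int = DEFAULT_MIN_SEPARATION
    norm_tol: float = 1e-3
    norm_max_iter: int = 100
    window: int = DEFAULT_WINDOW
    dix_window: int = DEFAULT_DIX_WINDOW
    seed: int = 0


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(cfg: PipelineConfig) -> Dict:
    """Execute all stages and return (and write) the result manifest."""
    t0 = time.time()
    for p in [cfg.genome_fasta, cfg.baits_bed, *cfg.pairs]:
        if p and not Path(p).exists():
            raise FileNotFoundError(f"input not found: {p}")
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: Dict = {"config": asdict(cfg), "stages": {}, "outputs": {}}

    def stage(name):
        log.info("stage %s (t=%.1fs)", name, time.time() - t0)
        manifest["stages"][name] = round(time.time() - t0, 2)

    stage("digest")
    genome = cio.read_fasta(cfg.genome_fasta)
    fmap = digest_genome(genome, cfg.pattern, cfg.cut_offset)
    fmap.to_bed(out / "fragments.bed")

    baits = cio.read_bed(cfg.baits_bed) if cfg.baits_bed else []
    mapability = (
        cio.read_bedgraph(cfg.mapability_bedgraph) if cfg.mapability_bedgraph else None
    )

    stage("filter")
    libraries = []
    for li, pairs_path in enumerate(cfg.pairs):
        raw = cio.read_pairs(pairs_path)
        valid, report = filter_bona_fide(raw, fmap, cfg.max_site_distance)
        report.to_frame().to_csv(out / f"filter_report_L{li}.tsv", sep="\t", index=False)
        cio.write_pairs(valid, out / f"valid_pairs_L{li}.tsv")
        libraries.append(valid)

    calls_by_res = {}
    for res in cfg.resolutions:
        stage(f"bin_{res}")
        grid = BinGrid(fmap.chrom_lengths, res)
        enriched = mark_enriched_bins(grid, baits)
        # the finest resolution is analysed close-cis only: within +-5 Mb of
        # the capture regions, where coverage supports it
        close_cis = None
        if res != max(cfg.resolutions) and baits:
            close_cis = mark_enriched_bins(
                grid,
                [(c, max(0, s - cfg.close_cis_margin), e + cfg.close_cis_margin)
                 for c, s, e in baits],
            )
        normalized = []
        for li, valid in enumerate(libraries):
            cm = bin_contacts(valid, grid, fmap, mapability)
            cm.enriched = enriched
            if close_cis is not None:
                cm.valid &= close_cis
            cm = filter_valid_bins(cm, cfg.mapability_min)
            cm, state = iterative_bias_correct(cm, cfg.norm_tol, cfg.norm_max_iter)
            template = estimate_distance_template(cm)
            cm = distance_normalize(cm, template)
            cm.to_coo_tsv(out / f"matrix_{res}_L{li}.tsv")
            pd.DataFrame(
                {"distance": template.distance, "expected": template.expected}
            ).to_csv(out / f"template_{res}_L{li}.tsv", sep="\t", index=False)
            normalized.append(cm)
        stage(f"call_{res}")
        calls = call_interactions(
            normalized, fdr=cfg.fdr, min_sep=cfg.min_separation,
            interval_window=cfg.window,
        )
        calls.to_csv(out / f"calls_{res}.tsv", sep="\t", index=False)
        calls_to_bedpe(calls, normalized[0], out / f"calls_{res}.bedpe")
        calls_by_res[res] = calls
        if res == 9_000:
            stage("domains")
            dix = directionality_index(normalized[0], cfg.dix_window)
            dix.to_frame().to_csv(out / "dix_9000.tsv", sep="\t", index=False)
            doms = call_domains(dix)
            doms.domains.to_csv(out / "domains.bed", sep="\t", index=False, header=False)

    stage("manifest")
    for f in sorted(out.iterdir()):
        if f.is_file() and f.name != "manifest.json":
            manifest["outputs"][f.name] = _sha256(f)
    manifest["n_shared_significant"] = {
        str(res): int(calls["shared_significant"].sum())
        for res, calls in calls_by_res.items()
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
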