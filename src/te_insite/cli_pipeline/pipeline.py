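"""End-to-end orchestration: one config, deterministic outputs, a manifest.

Stage order: simulate? -> mappability -> counts -> de -> proximity -> bins
-> metaprofile -> coverage. Identical config + seed gives byte-identical
result tables; every float is written with 6 significant digits.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
import time
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .. import __version__
from ..genomic_core import io as gio
from ..genomic_core.config import PipelineConfig, parse_region
from ..genomic_core.genome import AlignmentRecord, Genome, InsertionSet, deduplicate
from ..chromatin_bins import (assign_categories, bin_signal, compare_categories,
                              coverage_track, make_filtered_bins)
from ..expression import CountMatrix, run_de
from ..mappability import kmer_mappability, paired_mappability
from ..metaprofile import (MetaMatrix, heatmap_prepare, profile_bootstrap,
                           reference_point_matrix)
from ..proximity import annotate_tss_proximity, filter_clustered, stratified_fraction
from ..sim_data import SimConfig, write_simulation

log = logging.getLogger("te_insite")

STAGES = ("simulate", "mappability", "counts", "de", "proximity", "bins",
          "metaprofile", "coverage")
FLOAT_FORMAT = "%.6g"


def _sha256(path: str) -> str:
    digest = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            digest.update(chunk)
    return digest.hexdigest()


def _write_table(frame: pd.DataFrame, path: str, index: bool = False) -> None:
    frame.to_csv(path, sep="\t", index=index, float_format=FLOAT_FORMAT)


def load_config(path: str) -> dict:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ValueError(f"config {path} must be a YAML mapping")
    return data


class PipelineRun:
    """Executes the stage graph and records a run manifest."""

    def __init__(self, config: dict, out_dir: str, seed: Optional[int] = None):
        self.config = dict(config)
        if seed is not None:
            self.config["seed"] = int(seed)
        self.seed = int(self.config.get("seed", 0))
        self.out_dir = out_dir
        os.makedirs(out_dir, exist_ok=True)
        pipeline_keys = dict(self.config.get("pipeline", {}))
        pipeline_keys.setdefault("seed", self.seed)
        self.pconf = PipelineConfig.from_dict(pipeline_keys)
        self.manifest: dict = {
            "tool": "te-insite",
            "version": __version__,
            "seed": self.seed,
            "config": self.config,
            "inputs": {},
            "stages": [],
        }
        # shared state populated by stages
        self.genome: Optional[Genome] = None
        self.insertions: Optional[InsertionSet] = None
        self.genes: Optional[pd.DataFrame] = None
        self.counts: Optional[CountMatrix] = None
        self.chip_records: Dict[str, List[AlignmentRecord]] = {}
        self.conditions: Dict[str, str] = {}
        self.map_track = None
        self.de_table: Optional[pd.DataFrame] = None

    # -- stage helpers ----------------------------------------------------

    def _record(self, stage: str, outputs: Sequence[str], started: float) -> None:
        entry = {
            "stage": stage,
            "status": "completed",
            "seconds": round(time.time() - started, 3),
            "outputs": [],
        }
        for path in outputs:
            if not (os.path.exists(path) and os.path.getsize(path) > 0):
                raise RuntimeError(f"stage {stage!r} produced missing/empty output {path}")
            entry["outputs"].append({
                "path": os.path.relpath(path, self.out_dir),
                "sha256": _sha256(path),
            })
        self.manifest["stages"].append(entry)

    def _out(self, name: str) -> str:
        return os.path.join(self.out_dir, name)

    # -- stages -----------------------------------------------------------

    def stage_simulate(self) -> List[str]:
        sim_cfg = SimConfig(seed=self.seed, **self.config.get("sim", {}))
        chip = self.config.get("chip", {})
        rna = self.config.get("rna", {})
        sim_dir = self._out("sim")
        bundle = write_simulation(
            sim_dir, sim_cfg,
            chip_depth=int(chip.get("depth", 50_000)),
            chip_replicates=int(chip.get("replicates", 2)),
            rna_replicates=int(rna.get("replicates", 4)),
            rna_depth=int(rna.get("depth", 500_000)),
            marks=tuple(chip.get("marks", ["H3K9me3"])),
        )
        self.genome = bundle["genome"]
        self.insertions = bundle["insertions"]
        self.genes = bundle["genes"]
        self.counts = bundle["counts"]
        het = parse_region(bundle["truth"].het_region)
        if self.pconf.het_region is None:
            self.pconf.het_region = het
        for (mark, condition), path in bundle["alignment_paths"].items():
            records = gio.read_alignments(path)
            for rec in records:
                self.conditions[rec.sample] = condition
            self.chip_records.setdefault(mark, []).extend(records)
        return [os.path.join(sim_dir, name) for name in (
            "genome.fa", "consensus.fa", "insertions.bed", "het_region.bed",
            "genes.tsv", "counts.tsv", "truth.json")]

    def _load_inputs(self) -> None:
        inputs = self.config.get("inputs")
        if not inputs:
            raise ValueError("config needs 'simulate: true' or an 'inputs' section")
        self.genome, self.insertions, self.genes, records = gio.load_inputs(
            inputs, self.pconf, mito_name=inputs.get("mito_name", "chrM"))
        for path in ([inputs["genome"], inputs["insertions"], inputs["genes"]]
                     + list(np.atleast_1d(inputs["alignments"]))):
            self.manifest["inputs"][os.path.basename(str(path))] = _sha256(str(path))
        conditions = self.config.get("conditions", {})
        for rec in records:
            self.conditions[rec.sample] = conditions.get(
                rec.sample, "knockdown" if "knockdown" in rec.sample else "control")
        self.chip_records["H3K9me3"] = records
        if "counts" in inputs:
            frame = pd.read_csv(inputs["counts"], sep="\t", index_col=0)
            self.counts = CountMatrix.from_frame(frame, conditions={
                s: ("knockdown" if "knockdown" in s else "control")
                for s in frame.columns if s not in ("class", "length")})

    def stage_mappability(self) -> List[str]:
        if self.genome is None:
            self._load_inputs()
        mode = self.config.get("mappability", {})
        if mode.get("paired", False):
            self.map_track = paired_mappability(
                self.genome, self.pconf.kmer_length, self.pconf.pair_gap_shift)
        else:
            self.map_track = kmer_mappability(self.genome, self.pconf.kmer_length)
        path = self._out("mappability.bedGraph")
        gio.write_bedgraph(path, self.map_track.values)
        return [path]

    def stage_counts(self) -> List[str]:
        if self.counts is None:
            raise ValueError("no count matrix available (simulate or provide inputs.counts)")
        path = self._out("counts.tsv")
        self.counts.to_frame().to_csv(path, sep="\t")
        return [path]

    def stage_de(self) -> List[str]:
        self.de_table = run_de(
            self.counts, self.counts.conditions, "knockdown", "control",
            config=self.pconf)
        path = self._out("de.tsv")
        _write_table(self.de_table.reset_index(), path)
        return [path]

    def stage_proximity(self) -> List[str]:
        filtered = filter_clustered(self.insertions, self.pconf.cluster_min_gap)
        prox = annotate_tss_proximity(self.genes, filtered, self.pconf)
        strata_edges = self.config.get("proximity", {}).get("strata", [0.0, 1.0, 2.0])
        table = stratified_fraction(self.de_table, prox, strata_edges,
                                    rpkm_min=self.pconf.rpkm_threshold)
        p1, p2 = self._out("proximity.tsv"), self._out("strata.tsv")
        _write_table(prox, p1)
        _write_table(table, p2)
        return [p1, p2]

    def _prepared_chip(self, mark: str) -> List[AlignmentRecord]:
        records = deduplicate(self.chip_records[mark])
        return [r for r in records if r.mapq >= self.pconf.mapq_chip]

    def stage_bins(self) -> List[str]:
        mark = self.config.get("chip", {}).get("marks", ["H3K9me3"])[0]
        records = self._prepared_chip(mark)
        bins = make_filtered_bins(self.genome, self.map_track, self.pconf)
        bins = assign_categories(bins, self.insertions, self.pconf)
        table = bin_signal(records, bins, self.genome, self.pconf,
                           conditions=self.conditions)
        stats = compare_categories(table, "mean_knockdown", "mean_control")
        p1, p2 = self._out("bins.tsv"), self._out("category_stats.tsv")
        _write_table(table, p1)
        _write_table(stats, p2)
        return [p1, p2]

    def stage_metaprofile(self) -> List[str]:
        mark = self.config.get("chip", {}).get("marks", ["H3K9me3"])[0]
        records = self._prepared_chip(mark)
        tracks = coverage_track(records, self.genome, self.pconf, mode="chip")
        # average replicate tracks per condition
        by_condition: Dict[str, Dict[str, np.ndarray]] = {}
        for sample, per_chrom in tracks.items():
            cond = self.conditions[sample]
            dest = by_condition.setdefault(cond, {
                c: np.zeros(n) for c, n in self.genome.lengths.items()})
            for chrom, vec in per_chrom.items():
                dest[chrom] += vec
        counts = {cond: sum(1 for s in tracks if self.conditions[s] == cond)
                  for cond in by_condition}
        for cond, dest in by_condition.items():
            for chrom in dest:
                dest[chrom] /= max(counts[cond], 1)

        points = self.insertions.subset(self.pconf.upregulated_families)
        outputs = []
        ctrl_matrix: Optional[MetaMatrix] = None
        for cond in sorted(by_condition):
            matrix = reference_point_matrix(
                by_condition[cond], points, self.pconf.matrix_before,
                self.pconf.matrix_after, self.pconf.profile_bin)
            profile = profile_bootstrap(matrix, self.pconf.n_bootstrap,
                                        self.pconf.ci_level, seed=self.seed)
            ppath = self._out(f"profile_{cond}.tsv")
            _write_table(profile, ppath)
            outputs.append(ppath)
            heat = reference_point_matrix(
                by_condition[cond], points, self.pconf.matrix_before,
                self.pconf.matrix_after, self.pconf.heatmap_bin)
            if ctrl_matrix is None:
                ctrl_matrix = heat  # conditions sort control first; rows sort by it
            capped = heatmap_prepare(heat, self.pconf.heatmap_cap_percentile,
                                     sort_reference=ctrl_matrix)
            hpath = self._out(f"heatmap_{cond}.tsv")
            _write_table(capped.to_frame(), hpath, index=True)
            outputs.append(hpath)
        return outputs

    def stage_coverage(self) -> List[str]:
        mark = self.config.get("chip", {}).get("marks", ["H3K9me3"])[0]
        records = self._prepared_chip(mark)
        tracks = coverage_track(records, self.genome, self.pconf, mode="chip")
        outputs = []
        for sample in sorted(tracks):
            path = self._out(f"coverage_{sample}.bedGraph")
            gio.write_bedgraph(path, tracks[sample])
            outputs.append(path)
        return outputs

    # -- driver -----------------------------------------------------------

    def run(self) -> dict:
        simulate = bool(self.config.get("simulate", False))
        for stage in STAGES:
            if stage == "simulate" and not simulate:
                self.manifest["stages"].append(
                    {"stage": "simulate", "status": "skipped", "outputs": []})
                continue
            started = time.time()
            log.info("stage %s: started", stage)
            try:
                outputs = getattr(self, f"stage_{stage}")()
            except Exception as exc:
                self.manifest["stages"].append(
                    {"stage": stage, "status": "failed", "error": str(exc),
                     "outputs": []})
                self._write_manifest()
                raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc
            self._record(stage, outputs, started)
            log.info("stage %s: completed (%d outputs)", stage, len(outputs))
        self._write_manifest()
        return self.manifest

    def _write_manifest(self) -> None:
        with open(self._out("manifest.json"), "w") as fh:
            json.dump(self.manifest, fh, indent=1, sort_keys=True, default=str)


def run_all(config_path: Optional[str] = None, out_dir: str = "te_insite_out",
            seed: Optional[int] = None, config: Optional[dict] = None) -> dict:
    """Run every stage from a config file (or dict) and return the manifest."""
    if config is None:
        if config_path is None:
            raise ValueError("provide config_path or config")
        config = load_config(config_path)
    return PipelineRun(config, out_dir, seed=seed).run()
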