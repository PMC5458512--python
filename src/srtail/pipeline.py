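"""End-to-end orchestration, configuration and standard-format output.

A :class:`PipelineConfig` (loadable from YAML) drives the stages
simulate? -> align -> classify -> stats -> compare?. Every stage's output
is a plain TSV with a leading comment line carrying the package version
and config hash; the config itself is echoed into the output directory, so
any stage can be reproduced from the previous stage's files alone. One
global seed drives all stage-local seeds through a documented derivation
(seed mixed with a CRC of the stage name).
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
import zlib
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
import yaml

import srtail
from srtail import align as al
from srtail import classify as cl
from srtail import simulate as sim
from srtail import tailstats as ts
from srtail.seq import read_fasta, read_reads

log = logging.getLogger("srtail")


def stage_seed(global_seed: int, stage: str) -> int:
    """Stage-local seed: global seed mixed with a CRC of the stage name."""
    return int((global_seed * 2654435761 + zlib.crc32(stage.encode())) % (2**31))


@dataclass
class PipelineConfig:
    out_dir: str = "srtail_out"
    # inputs (ignored when simulate=True, which generates them)
    genome: str | None = None
    annotation: str | None = None
    reads: str | None = None
    # simulation
    simulate: bool = False
    preset: str = "wt"
    fraction: str = "ago_bound"
    n_reads: int = 100_000
    # alignment / tail calling
    mode: str = "exact_prefix"
    k: int = 12
    max_mm: int = 2
    max_tail: int = 3
    min_prefix: int = 18
    # classification
    priority: tuple[str, ...] = cl.DEFAULT_PRIORITY
    min_overlap_frac: float = 0.5
    # normalisation
    scale_factor: float = 1.0
    # comparison (optional second sample)
    reads_b: str | None = None
    preset_b: str | None = None
    min_rpm: float = 5.0
    max_wt_rpm: float = 0.5
    pseudocount: float = 0.5
    seed: int = 0

    def validate(self) -> None:
        if self.mode not in ("exact_prefix", "terminal_mismatch"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if not self.simulate:
            for name in ("genome", "annotation", "reads"):
                path = getattr(self, name)
                if path is None:
                    raise ValueError(f"{name} path required when simulate is off")
                if not os.path.exists(path):
                    raise ValueError(f"{name} file not found: {path}")
        if not 8 <= self.k <= 16:
            raise ValueError("k must be in 8..16")
        if self.scale_factor <= 0:
            raise ValueError("scale_factor must be > 0")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        cfg = cls(**data)
        if isinstance(cfg.priority, list):
            cfg.priority = tuple(cfg.priority)
        return cfg

    def to_yaml(self, path) -> None:
        data = asdict(self)
        data["priority"] = list(self.priority)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)

    def digest(self) -> str:
        data = asdict(self)
        data.pop("out_dir")  # results must not depend on where they are written
        blob = json.dumps(data, sort_keys=True, default=list)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def _write_tsv(df: pd.DataFrame, path, cfg: PipelineConfig, index=False) -> None:
    with open(path, "w") as fh:
        fh.write(f"# srtail {srtail.__version__} config={cfg.digest()}\n")
        df.to_csv(fh, sep="\t", index=index, float_format="%.6g")


def read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all configured stages; returns a dict of result objects and paths.

    Fails before any stage runs if the config is invalid; any stage failure
    aborts with the stage name in the exception message.
    """
    config.validate()
    os.makedirs(config.out_dir, exist_ok=True)
    config.to_yaml(os.path.join(config.out_dir, "config.yaml"))
    handler = logging.FileHandler(os.path.join(config.out_dir, "pipeline.log"))
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    results: dict = {}
    try:
        log.info("srtail %s; config %s; seed %d", srtail.__version__, config.digest(), config.seed)

        # ---- stage: inputs / simulate
        stage = "simulate"
        if config.simulate:
            spec = sim.SimGenomeSpec(seed=stage_seed(config.seed, "genome"))
            genome, db = sim.build_toy_genome(spec)
            model = sim.preset_model(
                config.preset, config.fraction, n_reads=config.n_reads,
                seed=stage_seed(config.seed, "reads"),
            )
            reads, truth = sim.simulate_sample(genome, db, model)
            sim.write_sample(config.out_dir, genome, db, reads, truth)
            results["truth"] = truth
            log.info("simulate: %d reads, preset %s/%s", len(reads), config.preset, config.fraction)
        else:
            genome = read_fasta(config.genome)
            db = cl.load_annotation(config.annotation)
            reads = read_reads(config.reads)
            log.info("inputs: %d reads, %d features", len(reads), len(db.features))

        # ---- stage: align
        stage = "align"
        index = al.build_index(genome, k=config.k)
        table = al.align_sample(
            reads, index, mode=config.mode, max_mm=config.max_mm,
            max_tail=config.max_tail, min_prefix=config.min_prefix,
            seed=stage_seed(config.seed, "assign"),
        )
        log.info("align: %d/%d mapped", int(table["mapped"].sum()), len(table))

        # ---- stage: classify
        stage = "classify"
        table = cl.classify_sample(
            table, db, priority=config.priority, min_overlap_frac=config.min_overlap_frac
        )
        _write_tsv(table, os.path.join(config.out_dir, "per_read.tsv"), config)
        results["table"] = table
        log.info("classify: %d classes", table["read_class"].nunique())

        # ---- stage: stats
        stage = "stats"
        summary = ts.summarize(table, scale_factor=config.scale_factor)
        _write_tsv(
            summary.per_class.reset_index(),
            os.path.join(config.out_dir, "class_summary.tsv"), config,
        )
        report = {
            "total_reads": summary.total_reads,
            "mapped_reads": summary.mapped_reads,
            "global_tailing_fraction": summary.global_tailing_fraction,
            "tail_composition_per_read": summary.tail_composition_per_read,
            "tail_composition_per_nt": summary.tail_composition_per_nt,
            "five_prime": {k: float(v) for k, v in summary.five_prime.items()},
            "modal_length_with_tail": summary.length_hist["mode_with_tail"],
            "modal_length_without_tail": summary.length_hist["mode_without_tail"],
        }
        with open(os.path.join(config.out_dir, "summary.json"), "w") as fh:
            json.dump(report, fh, indent=1, sort_keys=True)
        results["summary"] = summary
        for strand in "+-":
            write_bedgraph(
                table, index.chrom_lengths, strand, summary.mapped_reads,
                os.path.join(config.out_dir, f"coverage_{'plus' if strand == '+' else 'minus'}.bedgraph"),
            )
        log.info("stats: tailed fraction %.4f", summary.global_tailing_fraction)

        # ---- stage: compare (optional second sample)
        stage = "compare"
        if config.reads_b or config.preset_b:
            from srtail import compare as cmp

            if config.preset_b:
                model_b = sim.preset_model(
                    config.preset_b, config.fraction, n_reads=config.n_reads,
                    seed=stage_seed(config.seed, "reads_b"),
                )
                reads_b, _ = sim.simulate_sample(genome, db, model_b)
            else:
                reads_b = read_reads(config.reads_b)
            table_b = al.align_sample(
                reads_b, index, mode=config.mode, max_mm=config.max_mm,
                max_tail=config.max_tail, min_prefix=config.min_prefix,
                seed=stage_seed(config.seed, "assign_b"),
            )
            table_b = cl.classify_sample(
                table_b, db, priority=config.priority, min_overlap_frac=config.min_overlap_frac
            )
            counts_a = cmp.per_feature_counts(table, db)
            counts_b = cmp.per_feature_counts(table_b, db)
            gains = cmp.sirna_gain_features(
                counts_a, counts_b, min_rpm=config.min_rpm, max_wt_rpm=config.max_wt_rpm
            )
            _write_tsv(gains.reset_index(), os.path.join(config.out_dir, "gain_calls.tsv"), config)
            results["table_b"] = table_b
            results["gains"] = gains
            log.info("compare: %d gain calls", int(gains["gain_flag"].sum()))
    except Exception as exc:
        log.error("stage %s failed: %s", stage, exc)
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    finally:
        log.removeHandler(handler)
        handler.close()
    return results


def write_bedgraph(
    table: pd.DataFrame, chrom_lengths: dict[str, int], strand: str, total_reads: int, path
) -> None:
    """Strand-specific RPM-scaled coverage of templated read spans.

    Intervals are sorted, non-overlapping runs of equal coverage; an empty
    strand yields a valid header-only file.
    """
    name = "plus" if strand == "+" else "minus"
    m = table[table["mapped"].astype(bool) & (table["strand"] == strand)]
    scale = 1.0e6 / total_reads if total_reads else 0.0
    with open(path, "w") as fh:
        fh.write(f'track type=bedGraph name="srtail_{name}"\n')
        for chrom in sorted(chrom_lengths):
            cov = np.zeros(chrom_lengths[chrom] + 1)
            sub = m[m["chrom"] == chrom]
            if len(sub):
                np.add.at(cov, sub["start0"].to_numpy(int), 1.0)
                np.add.at(cov, sub["end0"].to_numpy(int), -1.0)
            cov = np.cumsum(cov[:-1]) * scale
            # emit runs of equal non-zero coverage
            change = np.nonzero(np.diff(cov))[0] + 1
            bounds = np.concatenate(([0], change, [len(cov)]))
            for s, e in zip(bounds[:-1], bounds[1:]):
                v = cov[s]
                if v != 0:
                    fh.write(f"{chrom}\t{s}\t{e}\t{v:.6g}\n")
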