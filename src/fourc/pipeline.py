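"""End-to-end pipeline: digest -> count -> filter/normalize -> call.

``RunConfig`` gathers every tunable with defaults matching the
reference experimental design (40 bp minimum fragment, 10 kb viewpoint
exclusion, ±2 Mb normalization window, p < 0.0005).  ``run_pipeline``
executes the stages, writes every intermediate in its standard format
and emits a JSON manifest (config echo, filter report, fit diagnostics,
output checksums).  Stage timings go to stderr; the manifest carries no
timestamps so identical runs produce identical bytes.
"""

from __future__ import annotations

import dataclasses
import json
import os
import sys
import time
from dataclasses import dataclass, field
from typing import Dict, Optional

from . import io as fio
from .counting import assign_reads, load_counts
from .fragments import Enzyme, digest
from .model import ViewpointModel
from .profile import Viewpoint, apply_filters, normalize

__all__ = ["RunConfig", "PipelineError", "run_pipeline"]


class PipelineError(RuntimeError):
    """A stage failure, naming the failing stage."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    viewpoint_chrom: str = ""
    viewpoint_start: int = 0
    viewpoint_end: int = 0
    primary_name: str = "DpnII"
    primary_motif: str = "GATC"
    primary_cut_offset: int = 0
    secondary_name: str = "Csp6I"
    secondary_motif: str = "GTAC"
    secondary_cut_offset: int = 0
    min_len: int = 40
    exclusion_radius: int = 10_000
    norm_radius: int = 2_000_000
    target_total: float = 1.0e6
    sigma: float = 20_000.0
    alpha: float = 0.0005
    smooth_k: int = 5
    bin_width: float = 5_000.0
    seed: int = 0

    def validate(self) -> None:
        if not self.viewpoint_chrom or self.viewpoint_start >= self.viewpoint_end:
            raise ValueError("config lacks a valid viewpoint (chrom, start < end)")
        self.viewpoint()  # radius checks
        self.primary()
        self.secondary()
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must lie in (0, 1)")
        if self.min_len < 0 or self.sigma <= 0 or self.bin_width <= 0:
            raise ValueError("min_len must be >= 0; sigma and bin_width positive")

    def viewpoint(self) -> Viewpoint:
        return Viewpoint(
            chrom=self.viewpoint_chrom,
            start=self.viewpoint_start,
            end=self.viewpoint_end,
            exclusion_radius=self.exclusion_radius,
            norm_radius=self.norm_radius,
        )

    def primary(self) -> Enzyme:
        return Enzyme(self.primary_name, self.primary_motif, "primary", self.primary_cut_offset)

    def secondary(self) -> Enzyme:
        return Enzyme(self.secondary_name, self.secondary_motif, "secondary", self.secondary_cut_offset)

    def to_dict(self) -> Dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: Dict) -> "RunConfig":
        fields = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - fields
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_file(cls, path: str) -> "RunConfig":
        """Load JSON or ``key = value`` plain-text config."""
        with open(path) as fh:
            text = fh.read()
        stripped = text.lstrip()
        if stripped.startswith("{"):
            return cls.from_dict(json.loads(text))
        d: Dict = {}
        types = {f.name: f.type for f in dataclasses.fields(cls)}
        for line in text.splitlines():
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            key, _, value = line.partition("=")
            key, value = key.strip(), value.strip()
            if key not in types:
                raise ValueError(f"unknown config key {key!r}")
            current = getattr(cls(), key)
            d[key] = type(current)(value) if not isinstance(current, str) else value
        return cls.from_dict(d)

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")


def _log(msg: str) -> None:
    print(f"[fourc] {msg}", file=sys.stderr)


def run_pipeline(
    config: RunConfig,
    fasta: str,
    out_dir: str,
    reads: Optional[str] = None,
    counts: Optional[str] = None,
) -> Dict:
    """Run every stage and return the manifest (also written to disk).

    Exactly one of ``reads`` (BED/SAM of mapped intervals) or ``counts``
    (per-fragment TSV) must be provided.
    """
    config.validate()
    if (reads is None) == (counts is None):
        raise ValueError("provide exactly one of reads= or counts=")
    os.makedirs(out_dir, exist_ok=True)
    stages = []
    t0 = time.perf_counter()

    def stage(name):
        stages.append(name)
        _log(f"stage {name} ({time.perf_counter() - t0:.1f}s elapsed)")

    paths = {
        "fragments": os.path.join(out_dir, "fragments.bed"),
        "counts": os.path.join(out_dir, "counts.tsv"),
        "profile": os.path.join(out_dir, "profile.bedgraph"),
        "peaks": os.path.join(out_dir, "peaks.bed"),
        "model": os.path.join(out_dir, "model.json"),
        "fitted": os.path.join(out_dir, "fitted.bedgraph"),
        "interact": os.path.join(out_dir, "interactions.interact"),
        "longrange": os.path.join(out_dir, "interactions.longrange"),
        "manifest": os.path.join(out_dir, "manifest.json"),
    }

    try:
        stage("digest")
        genome = fio.read_fasta(fasta)
        fmap = digest(genome, config.primary(), config.secondary(), genome_id=os.path.basename(fasta))
        fio.write_fragments_bed(fmap, paths["fragments"])
    except Exception as exc:  # noqa: BLE001 - stage attribution
        raise PipelineError("digest", exc) from exc

    try:
        stage("count")
        if reads is not None:
            rc = assign_reads(fio.read_reads(reads), fmap)
        else:
            rc = load_counts(counts, fmap)
        fio.write_counts_tsv(rc, paths["counts"])
    except Exception as exc:
        raise PipelineError("count", exc) from exc

    try:
        stage("normalize")
        filtered, report = apply_filters(rc, config.viewpoint(), min_len=config.min_len)
        profile = normalize(filtered, target_total=config.target_total)
        fio.write_profile_bedgraph(profile, paths["profile"], report=report)
    except Exception as exc:
        raise PipelineError("normalize", exc) from exc

    try:
        stage("call")
        fit = ViewpointModel(
            profile,
            sigma=config.sigma,
            alpha=config.alpha,
            smooth_k=config.smooth_k,
            bin_width=config.bin_width,
        ).fit()
        fio.write_peaks_bed(fit, paths["peaks"])
        fio.write_model_json(fit, paths["model"])
        fio.write_fitted_bedgraph(fit, paths["fitted"])
        fio.write_interact(fit, paths["interact"])
        fio.write_longrange(fit, paths["longrange"])
    except Exception as exc:
        raise PipelineError("call", exc) from exc

    stage("report")
    outputs = {k: v for k, v in paths.items() if k != "manifest"}
    manifest = {
        "tool": "fourc",
        "stages": stages,
        "config": config.to_dict(),
        "inputs": {"fasta": os.path.basename(fasta), "reads": reads and os.path.basename(reads),
                   "counts": counts and os.path.basename(counts)},
        "filter_report": report.to_dict(),
        "fit": {
            "background": {"B": fit.background.B, "I_v": fit.background.I_v, "lam": fit.background.lam},
            "residual_scale": fit.residual_scale,
            "n_peaks": len(fit.peaks),
            "converged": fit.converged,
        },
        "outputs": {k: {"file": os.path.basename(v), "sha256": fio.sha256_of(v)} for k, v in outputs.items()},
    }
    with open(paths["manifest"], "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    _log(f"done ({time.perf_counter() - t0:.1f}s)")
    return manifest
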