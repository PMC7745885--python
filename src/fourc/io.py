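"""Readers and writers for the standard genomic text formats used here.

FASTA via Biopython; fragment maps as BED6 with a JSON sidecar carrying
the enzyme pair and genome label; counts as TSV; profiles as bedGraph
with a JSON sidecar (viewpoint, normalization constant, filter report);
peaks as BED plus model JSON, UCSC interact and WashU longrange records.
All writers are deterministic (no timestamps) so reruns are
byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import os
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .counting import RawCounts
from .fragments import Enzyme, FragmentMap
from .model import PeakCall, ViewpointFit
from .profile import FilterReport, NormalizedProfile, Viewpoint

__all__ = [
    "read_fasta",
    "write_fasta",
    "write_fragments_bed",
    "read_fragments_bed",
    "write_counts_tsv",
    "read_reads_bed",
    "read_reads_sam",
    "read_reads",
    "write_profile_bedgraph",
    "read_profile_bedgraph",
    "write_peaks_bed",
    "read_peaks_json",
    "write_model_json",
    "write_fitted_bedgraph",
    "write_interact",
    "write_longrange",
    "write_consensus_bed",
    "sha256_of",
]


def read_fasta(path: str) -> Dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(path, "fasta")}


def write_fasta(path: str, genome: Dict[str, str], width: int = 80) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in genome.items()]
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fasta")


def _sidecar(path: str) -> str:
    return path + ".json"


def write_fragments_bed(fmap: FragmentMap, path: str) -> None:
    """BED6: name = frag_class, score = fragment length; JSON sidecar
    records the enzyme pair, genome_id and chromosome sizes."""
    df = fmap.df
    out = pd.DataFrame(
        {
            "chrom": df["chrom"],
            "start": df["start"],
            "end": df["end"],
            "name": df["frag_class"],
            "score": df["end"] - df["start"],
            "strand": ".",
        }
    )
    out.to_csv(path, sep="\t", header=False, index=False)
    meta = {
        "genome_id": fmap.genome_id,
        "primary": dataclasses.asdict(fmap.primary),
        "secondary": dataclasses.asdict(fmap.secondary),
        "chrom_sizes": fmap.chrom_sizes,
        "flanks": {"left": list(df["left"]), "right": list(df["right"])},
    }
    with open(_sidecar(path), "w") as fh:
        json.dump(meta, fh, sort_keys=True)
        fh.write("\n")


def read_fragments_bed(path: str) -> FragmentMap:
    bed = pd.read_csv(
        path, sep="\t", header=None, names=["chrom", "start", "end", "name", "score", "strand"]
    )
    with open(_sidecar(path)) as fh:
        meta = json.load(fh)
    df = pd.DataFrame(
        {
            "chrom": bed["chrom"].astype(str),
            "start": bed["start"],
            "end": bed["end"],
            "left": meta["flanks"]["left"],
            "right": meta["flanks"]["right"],
            "frag_class": bed["name"],
        }
    )
    return FragmentMap(
        df=df,
        primary=Enzyme(**meta["primary"]),
        secondary=Enzyme(**meta["secondary"]),
        genome_id=meta["genome_id"],
        chrom_sizes={k: int(v) for k, v in meta["chrom_sizes"].items()},
    )


def write_counts_tsv(rc: RawCounts, path: str) -> None:
    rc.to_frame().to_csv(path, sep="\t", index=False)


def read_reads_bed(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    names = ["chrom", "start", "end", "name", "score", "strand"][: df.shape[1]]
    df.columns = names
    if "strand" not in df.columns:
        df["strand"] = "+"
    return df[["chrom", "start", "end", "strand"]]


def read_reads_sam(path: str) -> pd.DataFrame:
    import pysam

    rows = []
    with pysam.AlignmentFile(path, check_sq=False) as fh:
        for rec in fh:
            if rec.is_unmapped:
                continue
            rows.append(
                (
                    rec.reference_name,
                    rec.reference_start,
                    rec.reference_end or rec.reference_start + 1,
                    "-" if rec.is_reverse else "+",
                )
            )
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "strand"])


def read_reads(path: str) -> pd.DataFrame:
    if path.endswith((".sam", ".bam", ".cram")):
        return read_reads_sam(path)
    return read_reads_bed(path)


def write_profile_bedgraph(profile: NormalizedProfile, path: str, report: Optional[FilterReport] = None) -> None:
    out = pd.DataFrame(
        {
            "chrom": profile.chroms,
            "start": profile.starts,
            "end": profile.ends,
            "signal": [format(v, ".10g") for v in profile.signal],
        }
    )
    out.to_csv(path, sep="\t", header=False, index=False)
    meta = {
        "viewpoint": dataclasses.asdict(profile.viewpoint),
        "window_weight": profile.window_weight,
        "norm_constant": profile.norm_constant,
        "target_total": profile.target_total,
    }
    if report is not None:
        meta["filter_report"] = report.to_dict()
    with open(_sidecar(path), "w") as fh:
        json.dump(meta, fh, sort_keys=True)
        fh.write("\n")


def read_profile_bedgraph(path: str) -> NormalizedProfile:
    bg = pd.read_csv(path, sep="\t", header=None, names=["chrom", "start", "end", "signal"])
    with open(_sidecar(path)) as fh:
        meta = json.load(fh)
    vp = Viewpoint(**meta["viewpoint"])
    starts = bg["start"].to_numpy(np.int64)
    ends = bg["end"].to_numpy(np.int64)
    return NormalizedProfile(
        viewpoint=vp,
        chroms=bg["chrom"].astype(str).to_numpy(),
        starts=starts,
        ends=ends,
        x=(starts + ends) // 2,
        signal=bg["signal"].to_numpy(float),
        norm_constant=meta["norm_constant"],
        window_weight=meta["window_weight"],
        target_total=meta["target_total"],
        retained_mask=np.ones(len(bg), dtype=bool),
    )


def _peak_rows(fit: ViewpointFit) -> List[Tuple]:
    chrom = fit.viewpoint.chrom
    rows = []
    for i, pk in enumerate(fit.peaks, 1):
        s, e = pk.interval
        score = min(1000.0, -10.0 * np.log10(max(pk.p_value, 1e-300)))
        rows.append((chrom, s, e, f"peak_{i}", score, pk))
    return rows


def write_peaks_bed(fit: ViewpointFit, path: str) -> None:
    """Peaks as BED (score = -10 log10 p, capped) plus a JSON sidecar
    with the full call parameters."""
    with open(path, "w") as fh:
        for chrom, s, e, name, score, pk in _peak_rows(fit):
            fh.write(f"{chrom}\t{s}\t{e}\t{name}\t{score:.1f}\t.\n")
    meta = {
        "chrom": fit.viewpoint.chrom,
        "peaks": [
            {
                "centre": pk.centre,
                "amplitude": pk.amplitude,
                "sigma": pk.sigma,
                "z": pk.z,
                "p_value": pk.p_value,
                "significant": pk.significant,
            }
            for pk in fit.peaks
        ],
    }
    with open(_sidecar(path), "w") as fh:
        json.dump(meta, fh, sort_keys=True)
        fh.write("\n")


def read_peaks_json(path: str) -> List[Tuple[str, float, float, float]]:
    """Read a peaks BED sidecar into (chrom, start, end, p) intervals."""
    with open(_sidecar(path) if not path.endswith(".json") else path) as fh:
        meta = json.load(fh)
    out = []
    for pk in meta["peaks"]:
        if pk["significant"]:
            s = max(0.0, pk["centre"] - 2 * pk["sigma"])
            out.append((meta["chrom"], s, pk["centre"] + 2 * pk["sigma"], pk["p_value"]))
    return out


def write_model_json(fit: ViewpointFit, path: str) -> None:
    payload = {
        "viewpoint": dataclasses.asdict(fit.viewpoint),
        "background": {"B": fit.background.B, "I_v": fit.background.I_v, "lam": fit.background.lam},
        "residual_scale": fit.residual_scale,
        "alpha": fit.alpha,
        "n_peaks": len(fit.peaks),
        "diagnostics": {k: v for k, v in fit.diagnostics.items() if k != "init"},
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")


def write_fitted_bedgraph(fit: ViewpointFit, path: str) -> None:
    """The fitted curve S(x) evaluated on the profile's own fragments."""
    prof = fit.model.profile
    m = prof.chroms == fit.viewpoint.chrom
    pred = fit.predict(prof.x[m])
    out = pd.DataFrame(
        {
            "chrom": prof.chroms[m],
            "start": prof.starts[m],
            "end": prof.ends[m],
            "signal": [format(v, ".10g") for v in pred],
        }
    )
    out.to_csv(path, sep="\t", header=False, index=False)


def write_interact(fit: ViewpointFit, path: str) -> None:
    """Significant interactions as UCSC interact records anchored at the viewpoint."""
    vp = fit.viewpoint
    with open(path, "w") as fh:
        for chrom, s, e, name, score, pk in _peak_rows(fit):
            lo, hi = min(s, vp.start), max(e, vp.end)
            fh.write(
                "\t".join(
                    str(v)
                    for v in (
                        chrom, lo, hi, name, int(score), f"{pk.amplitude:.4g}", ".", "0",
                        chrom, vp.start, vp.end, "viewpoint", ".",
                        chrom, s, e, name, ".",
                    )
                )
                + "\n"
            )


def write_longrange(fit: ViewpointFit, path: str) -> None:
    """WashU longrange text: vp-anchor<TAB>target,score."""
    vp = fit.viewpoint
    with open(path, "w") as fh:
        for chrom, s, e, name, score, pk in _peak_rows(fit):
            fh.write(f"{vp.chrom}:{vp.start}-{vp.end}\t{chrom}:{s}-{e},{score:.1f}\n")


def write_consensus_bed(regions, path: str) -> None:
    """Consensus regions as BED: score = support count, name = supporter list."""
    with open(path, "w") as fh:
        for r in regions:
            name = ",".join(r.support)
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{name}\t{r.n_support}\t.\n")


def sha256_of(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()
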