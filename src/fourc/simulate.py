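"""Synthetic genomes and 4C count profiles with known ground truth.

Every pipeline stage can be exercised without any external data: a
random genome supplies a realistic restriction-fragment map, and counts
are drawn from the same three-component signal model the pipeline fits
(constant background + exponential decay + Gaussian peaks) with
negative-binomial noise, so parameter recovery can be scored exactly.
Blind, short and near-viewpoint fragments receive background-rate
counts so that the filters have real work to do.

All randomness flows from the single seed carried by the truth object.
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass, field
from typing import Dict, Sequence, Tuple

import numpy as np

from .counting import RawCounts
from .fragments import CSP6I, DPNII, Enzyme, FragmentMap, VALID, digest
from .model import BackgroundModel, GaussianPeak
from .profile import Viewpoint

__all__ = ["SimulationTruth", "simulate_genome", "simulate_counts", "make_fixture", "default_truth"]

_POISSON_DISPERSION = 1.0e6  # dispersion above this is treated as the Poisson limit


@dataclass(frozen=True)
class SimulationTruth:
    """Generative parameters of a synthetic 4C library.

    ``depth`` is the expected total count over eligible fragments within
    the normalization window; ``dispersion`` is the negative-binomial
    inverse-dispersion (variance mu + mu^2/dispersion; large values
    recover Poisson).  ``blind_signal`` multiplies the background rate
    assigned to fragments the filters will remove.
    """

    background: BackgroundModel
    peaks: Tuple[GaussianPeak, ...]
    viewpoint: Viewpoint
    depth: float
    dispersion: float
    blind_signal: float = 1.0
    seed: int = 0
    min_len: int = 40

    def __post_init__(self) -> None:
        if self.depth <= 0:
            raise ValueError("depth must be positive")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be positive")
        for pk in self.peaks:
            if abs(pk.centre - self.viewpoint.centre) <= self.viewpoint.exclusion_radius:
                raise ValueError("truth peaks must lie outside the viewpoint exclusion window")

    def signal(self, x: np.ndarray) -> np.ndarray:
        """Noise-free model S(x) on the viewpoint chromosome."""
        x = np.asarray(x, dtype=float)
        d = np.abs(x - self.viewpoint.centre)
        s = self.background.predict(d)
        for pk in self.peaks:
            s = s + pk.amplitude * np.exp(-0.5 * ((x - pk.centre) / pk.sigma) ** 2)
        return s

    def to_dict(self) -> Dict:
        return {
            "background": {"B": self.background.B, "I_v": self.background.I_v, "lam": self.background.lam},
            "peaks": [list(pk) for pk in self.peaks],
            "viewpoint": dataclasses.asdict(self.viewpoint),
            "depth": self.depth,
            "dispersion": self.dispersion,
            "blind_signal": self.blind_signal,
            "seed": self.seed,
            "min_len": self.min_len,
        }

    @classmethod
    def from_dict(cls, d: Dict) -> "SimulationTruth":
        return cls(
            background=BackgroundModel(**d["background"]),
            peaks=tuple(GaussianPeak(*pk) for pk in d["peaks"]),
            viewpoint=Viewpoint(**d["viewpoint"]),
            depth=d["depth"],
            dispersion=d["dispersion"],
            blind_signal=d.get("blind_signal", 1.0),
            seed=d["seed"],
            min_len=d.get("min_len", 40),
        )


def simulate_genome(length: int, seed: int, gc: float = 0.41) -> str:
    """I.i.d. random DNA of the given length and GC content (human-like 0.41)."""
    if length <= 0:
        raise ValueError("length must be positive")
    if not (0 <= gc <= 1):
        raise ValueError("gc must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    return rng.choice(bases, size=length, p=p).tobytes().decode("ascii")


def simulate_counts(fmap: FragmentMap, truth: SimulationTruth) -> RawCounts:
    """Draw per-fragment counts from the truth model.

    Fragments that would survive the filters (valid class, length >=
    ``truth.min_len``, outside the exclusion window) get means
    proportional to S(x), scaled so that the in-window expected total
    equals ``truth.depth``.  All other fragments get the background rate
    times ``blind_signal``.  Counts are negative-binomial with the
    truth's dispersion and seed.
    """
    vp = truth.viewpoint
    df = fmap.df
    mid = fmap.midpoints()
    on_vp = (df["chrom"] == vp.chrom).to_numpy()
    d = np.abs(mid - vp.centre)
    eligible = (
        (df["frag_class"] == VALID).to_numpy()
        & ((df["end"] - df["start"]).to_numpy() >= truth.min_len)
        & on_vp
        & (d > vp.exclusion_radius)
    )
    shape = np.full(len(df), truth.background.B, dtype=float)
    shape[on_vp] = truth.signal(mid[on_vp])
    in_window = eligible & (d <= vp.norm_radius)
    total = float(shape[in_window].sum())
    if total <= 0 or not in_window.any():
        raise ValueError("no eligible fragments in the normalization window")
    c = truth.depth / total
    mu = np.where(eligible, c * shape, c * truth.background.B * truth.blind_signal)
    mu = np.maximum(mu, 0.0)

    rng = np.random.default_rng(truth.seed)
    if truth.dispersion >= _POISSON_DISPERSION:
        counts = rng.poisson(mu)
    else:
        r = truth.dispersion
        counts = np.where(mu > 0, rng.negative_binomial(r, r / (r + np.maximum(mu, 1e-300))), 0)
    return RawCounts(fmap=fmap, counts=counts.astype(np.int64))


def default_truth(
    viewpoint: Viewpoint,
    seed: int = 7,
    depth: float = 200_000.0,
    dispersion: float = 5.0,
    background: BackgroundModel | None = None,
    peaks: Sequence[Tuple[float, float, float]] | None = None,
) -> SimulationTruth:
    """Study-default truth: decay (B=0.5, I_v=20, lambda=50 kb) and two
    peaks 350 kb and 430 kb from the viewpoint (a strong narrow one and
    a weaker broader one), loosely mirroring a promoter-like contact
    plus a broader distal regulatory region."""
    if background is None:
        background = BackgroundModel(B=0.5, I_v=20.0, lam=50_000.0)
    if peaks is None:
        peaks = [(350_000.0, 15.0, 20_000.0), (430_000.0, 8.0, 30_000.0)]
    xv = viewpoint.centre
    return SimulationTruth(
        background=background,
        peaks=tuple(GaussianPeak(xv + off, amp, sig) for off, amp, sig in peaks),
        viewpoint=viewpoint,
        depth=depth,
        dispersion=dispersion,
        seed=seed,
    )


def make_fixture(
    out_dir: str,
    length: int = 5_000_000,
    seed: int = 7,
    depth: float = 200_000.0,
    dispersion: float = 5.0,
    gc: float = 0.41,
    chrom: str = "chrS",
    peaks: Sequence[Tuple[float, float, float]] | None = None,
    primary: Enzyme = DPNII,
    secondary: Enzyme = CSP6I,
) -> Dict[str, str]:
    """Write a complete synthetic input set (FASTA, fragment BED, counts
    TSV, truth JSON) and return the file paths.  Byte-identical for
    identical arguments (no timestamps)."""
    from . import io as fio  # local import to avoid a cycle at module load

    os.makedirs(out_dir, exist_ok=True)
    rng = np.random.default_rng(seed)
    genome_seed, count_seed = (int(s) for s in rng.integers(0, 2**31 - 1, size=2))
    seq = simulate_genome(length, seed=genome_seed, gc=gc)
    genome = {chrom: seq}
    fmap = digest(genome, primary, secondary, genome_id=f"synthetic-{seed}")
    centre = length // 2
    vp = Viewpoint(chrom=chrom, start=centre - 78, end=centre + 78)
    truth = default_truth(vp, seed=count_seed, depth=depth, dispersion=dispersion, peaks=peaks)
    rc = simulate_counts(fmap, truth)

    paths = {
        "fasta": os.path.join(out_dir, "genome.fa"),
        "fragments": os.path.join(out_dir, "fragments.bed"),
        "counts": os.path.join(out_dir, "counts.tsv"),
        "truth": os.path.join(out_dir, "truth.json"),
    }
    fio.write_fasta(paths["fasta"], genome)
    fio.write_fragments_bed(fmap, paths["fragments"])
    fio.write_counts_tsv(rc, paths["counts"])
    with open(paths["truth"], "w") as fh:
        json.dump(truth.to_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")
    return paths
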