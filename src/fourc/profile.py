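"""Fragment filtering and viewpoint-anchored normalization.

Three filters remove uninformative fragments before any modelling:

* **class** — blind fragments (flanked by two sites of the same enzyme)
  and terminal fragments carry no usable ligation junction;
* **length** — fragments shorter than ``min_len`` (default 40 bp) map
  unreliably;
* **proximity** — fragments whose midpoint lies within
  ``exclusion_radius`` (default 10 kb) of the viewpoint centre are
  dominated by self-ligation and re-ligation artefacts.

The retained profile is then scaled so that the summed signal of
retained fragments within ``norm_radius`` (default ±2 Mb) of the
viewpoint equals ``target_total`` (default 1e6, i.e. signal per million
in-window reads), making libraries of different depth comparable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd

from .counting import RawCounts
from .fragments import VALID, FragmentMap

__all__ = ["Viewpoint", "FilterReport", "FilteredCounts", "NormalizedProfile", "apply_filters", "normalize"]


@dataclass(frozen=True)
class Viewpoint:
    """The anchor locus whose contacts are assayed.

    ``start``/``end`` delimit the primer region (0-based half-open);
    the profile's position variable is the distance of each fragment
    midpoint from ``centre``.
    """

    chrom: str
    start: int
    end: int
    exclusion_radius: int = 10_000
    norm_radius: int = 2_000_000

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError("viewpoint start must be < end")
        if self.exclusion_radius <= 0 or self.norm_radius <= 0:
            raise ValueError("radii must be positive")
        if self.exclusion_radius >= self.norm_radius:
            raise ValueError("exclusion_radius must be smaller than norm_radius")

    @property
    def centre(self) -> int:
        return (self.start + self.end) // 2

    @classmethod
    def parse(cls, spec: str, **kwargs) -> "Viewpoint":
        """Parse ``chrom:start-end`` notation."""
        chrom, rng = spec.rsplit(":", 1)
        s, e = rng.replace(",", "").split("-")
        return cls(chrom=chrom, start=int(s), end=int(e), **kwargs)


@dataclass
class FilterReport:
    removed_class: int = 0
    removed_length: int = 0
    removed_proximity: int = 0
    retained: int = 0

    @property
    def removed_total(self) -> int:
        return self.removed_class + self.removed_length + self.removed_proximity

    def to_dict(self) -> Dict[str, int]:
        return {
            "removed_class": self.removed_class,
            "removed_length": self.removed_length,
            "removed_proximity": self.removed_proximity,
            "removed_total": self.removed_total,
            "retained": self.retained,
        }


@dataclass
class FilteredCounts:
    """Raw counts plus the boolean retained mask over the fragment map."""

    fmap: FragmentMap
    counts: np.ndarray
    retained: np.ndarray  # bool per fragment
    viewpoint: Viewpoint
    min_len: int
    report: FilterReport


def apply_filters(
    counts: RawCounts | FilteredCounts,
    vp: Viewpoint,
    min_len: int = 40,
) -> Tuple[FilteredCounts, FilterReport]:
    """Apply the class / length / proximity filters, in that order.

    A fragment failing several rules is attributed to the first rule in
    the order class -> length -> proximity, so the per-rule tallies sum
    to the total removed.  Idempotent: filtering an already-filtered
    object yields the same mask and report.
    """
    fmap = counts.fmap
    raw = np.asarray(counts.counts)
    if vp.chrom not in set(fmap.df["chrom"]):
        raise ValueError(f"viewpoint chromosome {vp.chrom!r} absent from fragment map")

    df = fmap.df
    mid = fmap.midpoints()
    cls_bad = (df["frag_class"] != VALID).to_numpy()
    len_bad = (df["end"] - df["start"]).to_numpy() < min_len
    prox_bad = (df["chrom"] == vp.chrom).to_numpy() & (np.abs(mid - vp.centre) <= vp.exclusion_radius)

    removed_class = int(cls_bad.sum())
    removed_length = int((~cls_bad & len_bad).sum())
    removed_prox = int((~cls_bad & ~len_bad & prox_bad).sum())
    retained = ~(cls_bad | len_bad | prox_bad)
    report = FilterReport(
        removed_class=removed_class,
        removed_length=removed_length,
        removed_proximity=removed_prox,
        retained=int(retained.sum()),
    )
    filtered = FilteredCounts(
        fmap=fmap, counts=raw, retained=retained, viewpoint=vp, min_len=min_len, report=report
    )
    return filtered, report


@dataclass
class NormalizedProfile:
    """Per-fragment normalized 4C signal as a function of position.

    Arrays hold the *retained* fragments only, in fragment-map order.
    ``norm_constant`` is the multiplicative scale applied to raw counts;
    the sum of ``signal`` over retained fragments within ``norm_radius``
    of the viewpoint equals ``target_total`` up to floating error.
    """

    viewpoint: Viewpoint
    chroms: np.ndarray
    starts: np.ndarray
    ends: np.ndarray
    x: np.ndarray  # fragment midpoints
    signal: np.ndarray
    norm_constant: float
    window_weight: float  # W: summed raw counts in the normalization window
    target_total: float
    retained_mask: np.ndarray = field(repr=False)
    fmap: Optional[FragmentMap] = field(default=None, repr=False)

    def __len__(self) -> int:
        return len(self.x)

    def cis(self) -> Tuple[np.ndarray, np.ndarray]:
        """(x, signal) on the viewpoint chromosome, sorted by position."""
        m = self.chroms == self.viewpoint.chrom
        x = self.x[m]
        s = self.signal[m]
        order = np.argsort(x, kind="stable")
        return x[order], s[order]

    def in_window(self) -> np.ndarray:
        """Mask of retained fragments inside the normalization window."""
        return (self.chroms == self.viewpoint.chrom) & (
            np.abs(self.x - self.viewpoint.centre) <= self.viewpoint.norm_radius
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": self.chroms,
                "start": self.starts,
                "end": self.ends,
                "x": self.x,
                "signal": self.signal,
            }
        )


def normalize(filtered: FilteredCounts, target_total: float = 1.0e6) -> NormalizedProfile:
    """Scale retained counts so the ±norm_radius window sums to ``target_total``.

    Raises
    ------
    ValueError
        If no retained fragment in the normalization window carries a
        read (W = 0), since the profile scale would be undefined.
    """
    vp = filtered.viewpoint
    fmap = filtered.fmap
    keep = filtered.retained
    df = fmap.df
    mid = fmap.midpoints()

    chroms = df["chrom"].to_numpy()[keep]
    x = mid[keep]
    raw = filtered.counts[keep].astype(float)
    in_win = (chroms == vp.chrom) & (np.abs(x - vp.centre) <= vp.norm_radius)
    W = float(raw[in_win].sum())
    if W <= 0:
        raise ValueError("no signal in normalization window")
    k = target_total / W
    if not in_win.any():
        warnings.warn("no retained fragments in the normalization window", stacklevel=2)
    return NormalizedProfile(
        viewpoint=vp,
        chroms=chroms,
        starts=df["start"].to_numpy()[keep],
        ends=df["end"].to_numpy()[keep],
        x=x,
        signal=raw * k,
        norm_constant=k,
        window_weight=W,
        target_total=float(target_total),
        retained_mask=keep,
        fmap=fmap,
    )
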