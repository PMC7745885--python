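import numpy as np
import pandas as pd
import pytest

import fourc
from fourc.fragments import CSP6I, DPNII, FragmentMap

GENOME_SEED = 20240901
GENOME_LEN = 5_000_000


@pytest.fixture(scope="session")
def genome5m() -> str:
    return fourc.simulate_genome(GENOME_LEN, seed=GENOME_SEED)


@pytest.fixture(scope="session")
def map5m(genome5m) -> FragmentMap:
    fmap = fourc.digest({"chrS": genome5m})
    fmap.validate()
    return fmap


@pytest.fixture(scope="session")
def vp5m() -> fourc.Viewpoint:
    # a 156-bp primer region centred on the chromosome middle
    return fourc.Viewpoint("chrS", 2_499_922, 2_500_078)


def build_map(rows, chrom_sizes=None) -> FragmentMap:
    """Hand-built fragment map from (chrom, start, end, left, right) rows."""
    from fourc.fragments import classify_flanks

    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "left", "right"])
    df["frag_class"] = [classify_flanks(l, r) for l, r in zip(df["left"], df["right"])]
    if chrom_sizes is None:
        chrom_sizes = df.groupby("chrom", sort=False)["end"].max().to_dict()
    return FragmentMap(df=df, primary=DPNII, secondary=CSP6I, chrom_sizes=chrom_sizes)


@pytest.fixture
def toy_map() -> FragmentMap:
    """Six fragments exercising every filter rule exactly once or twice.

    With a viewpoint centred at 15,000 (exclusion radius 10 kb) the
    retained set is {[0,100), [12000,40000)}: one blind, one terminal
    (class rule), one 30-bp fragment (length rule) and one fragment
    whose midpoint falls inside the exclusion window (proximity rule).
    """
    rows = [
        ("chrT", 0, 100, "secondary", "primary"),  # valid, retained
        ("chrT", 100, 200, "primary", "primary"),  # blind_primary
        ("chrT", 200, 230, "primary", "secondary"),  # valid but 30 bp
        ("chrT", 230, 12_000, "secondary", "primary"),  # valid, near viewpoint
        ("chrT", 12_000, 40_000, "primary", "secondary"),  # valid, retained
        ("chrT", 40_000, 60_000, "secondary", "end"),  # terminal
    ]
    return build_map(rows)


@pytest.fixture
def toy_vp() -> fourc.Viewpoint:
    return fourc.Viewpoint("chrT", 14_950, 15_050)


def simulate_profile(fmap, truth):
    """Run counts -> filters -> normalization for a truth object."""
    rc = fourc.simulate_counts(fmap, truth)
    filtered, report = fourc.apply_filters(rc, truth.viewpoint)
    return fourc.normalize(filtered), report
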