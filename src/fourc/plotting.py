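"""Profile-plus-fit figure."""

from __future__ import annotations

import numpy as np

from .model import ViewpointFit
from .profile import NormalizedProfile


def plot_profile(profile: NormalizedProfile, fit: ViewpointFit | None = None, ax=None, path: str | None = None):
    """Scatter the cis profile, overlay the fitted background and peaks."""
    import matplotlib

    if path is not None:
        matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(9, 3.5))
    x, s = profile.cis()
    xv = profile.viewpoint.centre
    ax.scatter((x - xv) / 1e6, s, s=3, alpha=0.4, color="0.4", label="fragments")
    if fit is not None:
        grid = np.linspace(x.min(), x.max(), 2000)
        ax.plot((grid - xv) / 1e6, fit.predict_background(grid), color="C0", lw=1.5, label="background")
        ax.plot((grid - xv) / 1e6, fit.predict(grid), color="C3", lw=1.0, label="model")
        for pk in fit.peaks:
            ax.axvline((pk.centre - xv) / 1e6, color="C3", ls=":", lw=0.8)
    ax.axvline(0.0, color="k", ls="--", lw=0.8)
    ax.set_xlabel("distance from viewpoint (Mb)")
    ax.set_ylabel("normalized 4C signal")
    ax.legend(loc="upper right", fontsize=8)
    if path is not None:
        ax.figure.savefig(path, dpi=150, bbox_inches="tight")
    return ax
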