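"""Small plotting helpers (histogram + Gaussian overlay; density profiles)."""

from __future__ import annotations

import numpy as np

from .density import DensityProfile, locate_cp
from .radius import DeltaDistanceSet, GaussianFit, _as_values


def plot_delta_histogram(data, fit: GaussianFit | None = None, bin_width: float = 0.01, ax=None):
    """Histogram of delta_d values with the fitted Gaussian(s) overlaid."""
    import matplotlib.pyplot as plt
    from scipy import stats

    x = _as_values(data)
    if ax is None:
        _, ax = plt.subplots()
    lo = np.floor(x.min() / bin_width) * bin_width
    hi = np.ceil(x.max() / bin_width) * bin_width + bin_width / 2
    edges = np.arange(lo, hi + bin_width, bin_width)
    ax.hist(x, bins=edges, color="0.7", edgecolor="0.3")
    if fit is not None:
        grid = np.linspace(lo, hi, 400)
        dens = np.zeros_like(grid)
        for m, s, w in zip(fit.centers, fit.widths, fit.weights):
            dens += w * stats.norm.pdf(grid, m, s)
        ax.plot(grid, dens * len(x) * bin_width, "k-", lw=1.5)
    ax.set_xlabel(r"$\Delta d_\mathrm{M-D}$ / $\mathrm{\AA}$")
    ax.set_ylabel("count")
    return ax


def plot_profile(profile: DensityProfile, mark_cp: bool = True, ax=None):
    """Electron density along a bond path on a log scale, CP marked."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ax.semilogy(profile.positions, profile.densities, "-",
                label=f"{profile.metal}-{profile.donor}")
    if mark_cp:
        cp = locate_cp(profile)
        ax.plot([cp.position], [cp.density], "x", color="k", ms=8)
    ax.set_xlabel(r"distance from metal nucleus / $\mathrm{\AA}$")
    ax.set_ylabel(r"$\rho$ / a.u.")
    ax.legend()
    return ax
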