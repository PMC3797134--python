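"""Figure helpers: z-spectra, asymmetry spectra, group bar charts, APT maps.

All functions take an optional matplotlib Axes and return it, so they
compose into panels; the convenience ``save`` wrapper writes PNG with the
Agg backend.
"""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np


def plot_zspectra(spectra: dict, ax=None):
    """Z-spectra (percent) vs offset, offsets decreasing left-to-right as
    conventionally displayed."""
    ax = ax or plt.gca()
    for label, spec in spectra.items():
        ax.plot(spec.offsets, 100.0 * spec.values, marker="o", ms=3,
                label=label)
    ax.set_xlabel("offset (ppm)")
    ax.set_ylabel(r"$S_{sat}/S_0$ (%)")
    ax.invert_xaxis()
    ax.legend(frameon=False)
    return ax


def plot_asym_spectra(spectra: dict, ax=None):
    """MTR asymmetry spectra (percent) vs positive offset."""
    ax = ax or plt.gca()
    for label, spec in spectra.items():
        ax.plot(spec.offsets, spec.as_percent, marker="o", ms=3, label=label)
    ax.axhline(0.0, color="0.6", lw=0.8)
    ax.set_xlabel("offset (ppm)")
    ax.set_ylabel(r"MTR$_{asym}$ (%)")
    ax.legend(frameon=False)
    return ax


def plot_group_bar(table, offset: float = 3.5, quantity: str = "corrected",
                   ax=None):
    """Group mean ± SD bar chart at one offset from a group table."""
    ax = ax or plt.gca()
    row = table[(np.abs(table["offset_ppm"] - offset) < 1e-6)
                & (table["quantity"] == quantity)].iloc[0]
    groups = [c[len("mean_"):] for c in table.columns if c.startswith("mean_")]
    means = [row[f"mean_{g}"] for g in groups]
    sds = [row[f"sd_{g}"] for g in groups]
    ax.bar(groups, means, yerr=sds, capsize=4, color=["0.7", "0.4"])
    ax.set_ylabel(rf"MTR$_{{asym}}$({offset} ppm) (%)")
    star = "*" if row["significant"] else "n.s."
    ax.set_title(f"{quantity}: p = {row['p']:.3g} {star}")
    return ax


def plot_apt_map(apt_map, ax=None):
    """APT-weighted map in percent with the map's display window."""
    ax = ax or plt.gca()
    lo, hi = apt_map.display_window
    im = ax.imshow(apt_map.as_percent, cmap="inferno", vmin=100 * lo,
                   vmax=100 * hi)
    plt.colorbar(im, ax=ax, label=r"MTR$_{asym}$ (%)")
    ax.set_axis_off()
    return ax


def save(path, dpi: int = 120) -> None:
    plt.tight_layout()
    plt.savefig(path, dpi=dpi)
    plt.close()
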