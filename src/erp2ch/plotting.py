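"""Rendering helpers (matplotlib, Agg backend).

Pixel-level fidelity to any particular publication style is a non-goal;
these produce quick-look figures for ERP waveforms, time-frequency maps
(non-significant bins painted green, as is conventional for
permutation-masked ERSP/ITC maps) and time-trial images.
"""

from __future__ import annotations

import numpy as np


def _plt():
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt
    return plt


def plot_erp(erp, path=None, ax=None):
    plt = _plt()
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 3))
    ax.plot(erp.times, erp.values[:, 0], label="Fp1", lw=0.8)
    ax.plot(erp.times, erp.values[:, 1], label="Fp2", lw=0.8)
    ax.plot(erp.times, erp.channel_mean, "k", label="mean", lw=1.2)
    ax.axvline(0, color="grey", ls=":")
    ax.set(xlabel="time (ms)", ylabel="amplitude (μV)",
           title=f"{erp.kind} ERP (n={erp.n_epochs})")
    ax.legend(fontsize=7)
    if path:
        ax.figure.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(ax.figure)
    return ax


def plot_tfmap(tfmap, path=None, ax=None, crop=True):
    plt = _plt()
    m = tfmap.crop() if crop else tfmap
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 3))
    values = m.values.copy()
    cmap = "RdBu_r" if m.kind == "ersp_dB" else "viridis"
    img = ax.pcolormesh(m.times, m.freqs, values, cmap=cmap, shading="auto")
    if m.mask is not None:
        green = np.ma.masked_where(m.mask, np.zeros_like(values))
        ax.pcolormesh(m.times, m.freqs, green, cmap="Greens_r",
                      shading="auto", vmin=-1, vmax=1)
    ax.figure.colorbar(img, ax=ax, label="dB" if m.kind == "ersp_dB" else "ITC")
    ax.set(xlabel="time (ms)", ylabel="frequency (Hz)", title=m.kind)
    if path:
        ax.figure.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(ax.figure)
    return ax


def plot_trial_time(ttmap, path=None, ax=None):
    plt = _plt()
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 3))
    img = ax.pcolormesh(ttmap.times, np.arange(ttmap.values.shape[0]),
                        ttmap.values, cmap="RdBu_r", shading="auto")
    ax.figure.colorbar(img, ax=ax, label="μV")
    ax.set(xlabel="time (ms)", ylabel="trial (smoothed)",
           title=f"{ttmap.kind} time-trial map")
    if path:
        ax.figure.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(ax.figure)
    return ax
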