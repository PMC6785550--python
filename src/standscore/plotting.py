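"""Optional matplotlib renderings: scalogram contours and ranking colormaps.

matplotlib is imported lazily; install the ``plot`` extra to use these.
"""

from __future__ import annotations

import numpy as np

from .predict import RankedPrediction
from .spectral_features import TimeFrequencyMap


def plot_scalogram(tf: TimeFrequencyMap, ax=None, n_levels: int = 30,
                   log_freq: bool = True):
    """Contour plot of a time-frequency power map."""
    import matplotlib.pyplot as plt
    if ax is None:
        _, ax = plt.subplots()
    cs = ax.contourf(tf.times, tf.freqs, tf.power, levels=n_levels,
                     cmap="viridis")
    if log_freq:
        ax.set_yscale("log")
    ax.set_xlabel("time (s)")
    ax.set_ylabel("frequency (Hz)")
    ax.set_title(f"{tf.method} power")
    plt.colorbar(cs, ax=ax, label="power (µV²)")
    return ax


def plot_ranking(rp: RankedPrediction, ax=None):
    """Horizontal bar colormap of per-muscle ranking scores.

    Red shades mark activations labeled assisted (score <= 0.5), blue
    shades independent (> 0.5); the exact ramp is presentation only.
    """
    import matplotlib.pyplot as plt
    from matplotlib.colors import TwoSlopeNorm
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 0.4 * len(rp.per_muscle_score) + 1))
    muscles = list(rp.per_muscle_score)
    scores = np.array([rp.per_muscle_score[m] for m in muscles])
    norm = TwoSlopeNorm(vmin=0.0, vcenter=0.5, vmax=1.0)
    colors = plt.get_cmap("RdBu")(norm(scores))
    ax.barh(np.arange(len(muscles)), scores, color=colors)
    ax.axvline(0.5, color="k", lw=0.8, ls="--")
    ax.set_yticks(np.arange(len(muscles)), muscles)
    ax.set_xlim(0, 1)
    ax.set_xlabel("independent-standing posterior")
    ax.set_title(f"L={rp.aggregate_left:.2f}  R={rp.aggregate_right:.2f}  "
                 f"T={rp.aggregate_total:.2f}")
    return ax
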