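"""Optional plot rendering (fingerprint bars, response curves).

Matplotlib is imported lazily with the Agg backend so headless runs and the
CLI's ``--plots`` flag work without a display.
"""

from __future__ import annotations

import numpy as np

_DIRECTION_COLORS = {"up": "#c0392b", "down": "#2980b9", "none": "#95a5a6"}


def _pyplot():
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    return plt


def plot_fingerprint(fingerprint_frame, path) -> None:
    """Bar plot of the CRS fingerprint: m/z on x, CRS (%) on y, colored by
    direction of regulation."""
    plt = _pyplot()
    fig, ax = plt.subplots(figsize=(8, 3))
    colors = [_DIRECTION_COLORS.get(d, "#95a5a6") for d in fingerprint_frame["direction"]]
    ax.bar(fingerprint_frame["mz"], fingerprint_frame["crs_percent"],
           width=2.5, color=colors)
    ax.set_xlabel("m/z")
    ax.set_ylabel("CRS (%)")
    ax.set_ylim(0, 105)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_response_curve(fit, conc, responses, path) -> None:
    """One feature's replicate responses with the fitted LL.4 curve."""
    plt = _pyplot()
    fig, ax = plt.subplots(figsize=(4, 3))
    conc = np.asarray(conc, dtype=float)
    ax.semilogx(conc, responses, "o", color="#34495e", alpha=0.6)
    grid = np.geomspace(conc[conc > 0].min(), conc.max(), 200)
    ax.semilogx(grid, fit.predict(grid), "-", color="#c0392b")
    ax.set_xlabel("concentration")
    ax.set_ylabel("response")
    ax.set_title(f"m/z {fit.feature_mz:.2f}")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
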