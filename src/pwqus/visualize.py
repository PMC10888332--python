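"""PNG export of phantoms, B-mode images and QUS maps."""

from __future__ import annotations

import numpy as np

from .estimators import QUSImage

__all__ = ["save_png", "save_bmode_png", "save_qus_png"]


def save_png(array: np.ndarray, path, title: str = "", cmap: str = "viridis",
             colorbar: bool = True, vmin=None, vmax=None) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4.2))
    im = ax.imshow(np.asarray(array), cmap=cmap, aspect="auto", vmin=vmin, vmax=vmax)
    ax.set_title(title)
    ax.set_xlabel("lateral")
    ax.set_ylabel("depth")
    if colorbar:
        fig.colorbar(im, ax=ax, shrink=0.85)
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)


def save_bmode_png(envelope: np.ndarray, path, dynamic_range_db: float = 50.0) -> None:
    """Log-compressed envelope display."""
    env = np.asarray(envelope, dtype=float)
    peak = env.max() if env.max() > 0 else 1.0
    db = 20.0 * np.log10(np.maximum(env / peak, 10 ** (-dynamic_range_db / 20)))
    save_png(db, path, title="B-mode (dB)", cmap="gray", vmin=-dynamic_range_db, vmax=0)


def save_qus_png(image: QUSImage, path) -> None:
    save_png(image.values, path, title=f"{image.parameter} ({image.units})")
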