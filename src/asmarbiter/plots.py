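"""Plot helpers mirroring the toolkit's standard figures."""

from __future__ import annotations

from typing import Optional, Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .types import QualityDepthRecord, TitrationCurve

__all__ = ["quality_depth_plot", "titration_plot"]


def quality_depth_plot(
    records: Sequence[QualityDepthRecord],
    n_bs_high: int,
    path: str,
    bs_threshold: float = 1.5,
    trend: bool = True,
) -> None:
    """Density scatter of BS vs SFB (log x), annotated with n(BS > t).

    The white running-median trend line is cosmetic, marking the depth
    at which high-quality unigenes start to accumulate.
    """
    detected = [r for r in records if r.sfb > 0]
    sfb = np.array([r.sfb for r in detected])
    bs = np.array([r.bs for r in detected])
    fig, ax = plt.subplots(figsize=(5, 4))
    if len(sfb):
        ax.scatter(sfb, bs, s=4, alpha=0.4, c="darkblue", edgecolors="none")
        ax.set_xscale("log")
        if trend and len(sfb) >= 20:
            order = np.argsort(sfb)
            xs, ys = sfb[order], bs[order]
            w = max(len(xs) // 15, 5)
            med_x = [np.median(xs[i : i + w]) for i in range(0, len(xs) - w, w)]
            med_y = [np.median(ys[i : i + w]) for i in range(0, len(xs) - w, w)]
            ax.plot(med_x, med_y, color="white", lw=2.5)
            ax.plot(med_x, med_y, color="black", lw=1.0)
    ax.axhline(bs_threshold, color="grey", ls="--", lw=0.8)
    ax.set_xlabel("Sequence depth (sequenced fragments / bp)")
    ax.set_ylabel("Assembly quality (normalized bit score)")
    ax.set_ylim(0, 2.2)
    ax.annotate(
        f"n(BS > {bs_threshold:g}) = {n_bs_high}",
        xy=(0.05, 0.92),
        xycoords="axes fraction",
    )
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def titration_plot(
    curve: TitrationCurve,
    path: str,
    expected: Optional[Sequence[float]] = None,
) -> None:
    """Gene-accumulation curve; optionally overlays the analytic mean."""
    xs = [p[0] for p in curve.sample_points]
    ys = [p[1] for p in curve.sample_points]
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.step(xs, ys, where="post", label="observed")
    if expected is not None:
        ax.plot(xs, expected, ls="--", color="firebrick", label="expected")
        ax.legend()
    ax.set_xlabel("Reads sampled")
    ax.set_ylabel("Unique unigenes detected")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
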