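"""Bland-Altman agreement tables and plots for device-vs-reference pairs.

Each comparison pair becomes one point: the difference (device - reference)
plotted against the mean of the two methods.  Alongside the classical
+/- 1.96 SD limits of agreement, the protocol's fixed +/- 5/10/15 mmHg
bands are drawn, and an inside-limits check reports the fraction of points
with |difference| within a given band.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .differences import ComparisonPair

__all__ = ["BAPoint", "ba_table", "inside_limits", "ba_plot"]


@dataclass(frozen=True)
class BAPoint:
    subject_id: str
    slot: str
    pressure_type: str
    mean_value: float  # (device + reference) / 2
    difference: float  # device - reference


def ba_table(pairs: Sequence[ComparisonPair]) -> list[BAPoint]:
    """One Bland-Altman point per comparison pair (count preserved)."""
    if not pairs:
        raise ValueError("no comparison pairs to tabulate")
    return [
        BAPoint(
            subject_id=p.subject_id,
            slot=p.slot,
            pressure_type=p.pressure_type,
            mean_value=(p.device_value + p.reference_value) / 2,
            difference=p.signed_difference,
        )
        for p in pairs
    ]


def inside_limits(points: Sequence[BAPoint], limit: float) -> tuple[float, bool]:
    """Fraction of points with |difference| <= limit, and an all-inside flag."""
    if limit <= 0:
        raise ValueError("limit must be positive")
    n_inside = sum(1 for p in points if abs(p.difference) <= limit)
    fraction = n_inside / len(points) if points else 0.0
    return fraction, n_inside == len(points)


def ba_plot(
    points: Sequence[BAPoint],
    limits: Iterable[float] = (5, 10, 15),
    out_path: str | Path = "bland_altman.png",
    draw_loa: bool = True,
) -> Path:
    """Scatter difference vs mean with protocol bands, one panel per type.

    Horizontal lines are drawn at zero and at +/- each fixed limit; the
    classical +/- 1.96 SD limits of agreement are added dashed when
    ``draw_loa`` is set.  Axes auto-scale but the outermost band is always
    visible.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    import numpy as np

    if not points:
        raise ValueError("no points to plot")
    limits = sorted(limits)
    types = [t for t in ("sbp", "dbp") if any(p.pressure_type == t for p in points)]
    fig, axes = plt.subplots(1, len(types), figsize=(6 * len(types), 4.5), squeeze=False)
    for ax, ptype in zip(axes[0], types):
        pts = [p for p in points if p.pressure_type == ptype]
        means = np.array([p.mean_value for p in pts])
        diffs = np.array([p.difference for p in pts])
        ax.scatter(means, diffs, s=18, alpha=0.8, edgecolor="none")
        ax.axhline(0.0, color="black", linewidth=1.0)
        for lim in limits:
            ax.axhline(lim, color="grey", linewidth=0.8)
            ax.axhline(-lim, color="grey", linewidth=0.8)
        if draw_loa and len(diffs) >= 2:
            mean_d = diffs.mean()
            loa = 1.96 * diffs.std(ddof=1)
            ax.axhline(mean_d + loa, color="tab:red", linestyle="--", linewidth=0.9,
                       label="mean ± 1.96 SD")
            ax.axhline(mean_d - loa, color="tab:red", linestyle="--", linewidth=0.9)
            ax.axhline(mean_d, color="tab:red", linestyle=":", linewidth=0.9)
            ax.legend(loc="upper right", fontsize=8)
        pad = max(limits) * 1.15
        lo = min(diffs.min(), -pad)
        hi = max(diffs.max(), pad)
        ax.set_ylim(lo - 1, hi + 1)
        ax.set_xlabel("mean of device and observer reference (mmHg)")
        ax.set_ylabel("device − reference (mmHg)")
        ax.set_title(ptype.upper())
    fig.tight_layout()
    out_path = Path(out_path)
    out_path.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(out_path, dpi=120)
    plt.close(fig)
    return out_path
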