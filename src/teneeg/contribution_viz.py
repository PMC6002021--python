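"""Tabular / graphical summaries of feature contributions on the scalp.

Provides a schematic 2-D scalp projection for the 64 standard 10/20 (10/10
extension) labels, top-K kind/band count tables and channel-pair edge lists
ready for plotting.  All summaries are pure functions of a
:class:`~teneeg.evaluation.ContributionReport`; CSV output is always
available, rendering (matplotlib) is optional.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .io_core import MontageError
from .evaluation import ContributionReport

# ---------------------------------------------------------------------------
# Standard 64-channel montage (schematic azimuthal projection)
# ---------------------------------------------------------------------------

_ROWS: list[tuple[list[str], float]] = [
    (["Fp1", "Fpz", "Fp2"], 0.90),
    (["AF7", "AF3", "AFz", "AF4", "AF8"], 0.72),
    (["F7", "F5", "F3", "F1", "Fz", "F2", "F4", "F6", "F8"], 0.54),
    (["FT7", "FC5", "FC3", "FC1", "FCz", "FC2", "FC4", "FC6", "FT8"], 0.28),
    (["T7", "C5", "C3", "C1", "Cz", "C2", "C4", "C6", "T8"], 0.0),
    (["TP7", "CP5", "CP3", "CP1", "CPz", "CP2", "CP4", "CP6", "TP8"], -0.28),
    (["P9", "P7", "P5", "P3", "P1", "Pz", "P2", "P4", "P6", "P8", "P10"], -0.54),
    (["PO7", "PO3", "POz", "PO4", "PO8"], -0.72),
    (["O1", "Oz", "O2"], -0.90),
    (["Iz"], -1.02),
]

_LATERAL = {0: 0.0, 1: 0.18, 2: 0.18, 3: 0.36, 4: 0.36, 5: 0.54, 6: 0.54,
            7: 0.72, 8: 0.72, 9: 0.88, 10: 0.88}


def _x_of(label: str) -> float:
    digits = "".join(ch for ch in label if ch.isdigit())
    if not digits:  # z line
        return 0.0
    n = int(digits)
    x = _LATERAL[n]
    return -x if n % 2 == 1 else x


def standard_montage() -> dict[str, tuple[float, float]]:
    """Schematic 2-D coordinates for the 64 standard 10/20-extension labels."""
    coords = {}
    for labels, y in _ROWS:
        for lab in labels:
            coords[lab] = (_x_of(lab), y)
    return coords


STANDARD_64_LABELS: tuple[str, ...] = tuple(
    lab for labels, _ in _ROWS for lab in labels
)


@dataclass
class TopoSummary:
    """Top channel pairs with scalp coordinates, one edge list per scale."""

    coordinates: dict            # label -> (x, y)
    edges: dict                  # scale -> list of (ch1, ch2, magnitude), sorted desc


def summarize_topk(report: ContributionReport) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Kind and band counts among the top-K features, one row per scale."""
    return report.kind_counts.copy(), report.band_counts.copy()


def pair_map(
    report: ContributionReport,
    montage: dict[str, tuple[float, float]] | None = None,
) -> TopoSummary:
    """Attach scalp coordinates to the top channel pairs of every scale."""
    if montage is None:
        montage = standard_montage()
    edges = {}
    for scale, df in report.top_pairs.items():
        rows = []
        for _, row in df.iterrows():
            for lab in (row["channel1"], row["channel2"]):
                if lab not in montage:
                    raise MontageError(f"channel {lab!r} has no montage coordinates")
            rows.append((row["channel1"], row["channel2"], float(row["magnitude"])))
        rows.sort(key=lambda e: -e[2])
        edges[scale] = rows[:10]
    used = {lab for rows in edges.values() for e in rows for lab in e[:2]}
    coords = {lab: montage[lab] for lab in sorted(used)}
    return TopoSummary(coords, edges)


def plot_pair_map(summary: TopoSummary, path=None):  # pragma: no cover - optional
    """Render the pair map with matplotlib (optional dependency)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    n = len(summary.edges)
    fig, axes = plt.subplots(1, n, figsize=(4 * n, 4), squeeze=False)
    montage = standard_montage()
    for ax, (scale, edges) in zip(axes[0], summary.edges.items()):
        circle = plt.Circle((0, 0), 1.05, fill=False)
        ax.add_patch(circle)
        for lab, (x, y) in montage.items():
            ax.plot(x, y, ".", color="0.7", ms=3)
        mags = [m for _, _, m in edges] or [1.0]
        top = max(mags)
        for c1, c2, m in edges:
            (x1, y1), (x2, y2) = montage[c1], montage[c2]
            ax.plot([x1, x2], [y1, y2], "-", lw=0.5 + 2.5 * m / top, color="C3")
            ax.plot([x1, x2], [y1, y2], "o", color="C0", ms=4)
        ax.set_title(scale)
        ax.set_xlim(-1.2, 1.2)
        ax.set_ylim(-1.2, 1.2)
        ax.set_aspect("equal")
        ax.axis("off")
    if path is not None:
        fig.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(fig)
    return fig
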