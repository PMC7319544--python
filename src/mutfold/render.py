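"""Figure generation: heatmaps, circular plots, arc diagrams, accessibility.

All renderers are deterministic for a fixed input and :class:`RenderSpec`
(SVG output is byte-for-byte reproducible: a fixed hash salt and no
embedded timestamps).  Coordinates are 1-based everywhere, ticks default
to every 10 nt, and the mutation positions are overdrawn as red guide
lines/marks in every plot type.

Color conventions follow the differential-dot-plot idiom: probability
panels use a white-to-dark grayscale (0 -> white, 1 -> darkest), and
differential panels use a diverging blue/white/red map where blue marks
pairs weakened by the mutation and red pairs strengthened by it, with
limits symmetric about zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
from matplotlib.patches import Arc

from .fold import AccessibilityProfile, BasePairMatrix

__all__ = [
    "RenderSpec",
    "render_heatmap",
    "render_diff_heatmap",
    "render_circular",
    "render_arc_diagram",
    "render_accessibility",
]


@dataclass(frozen=True)
class RenderSpec:
    """Output formats and shared styling for all plot types."""

    formats: tuple = ("png", "svg")
    dpi: int = 300
    tick_interval: int = 10
    mutation_marks: tuple = ()
    #: chords/arcs with |value| below this are not drawn (legibility)
    threshold: float = 1e-3
    #: diverging color limits are at least this wide so near-null results
    #: are not amplified into apparent signal
    diff_floor: float = 0.1

    def __post_init__(self) -> None:
        if self.tick_interval < 1:
            raise ValueError("tick_interval must be >= 1")
        if self.dpi < 72:
            raise ValueError("dpi must be >= 72")
        bad = [f for f in self.formats if f not in ("png", "svg")]
        if bad:
            raise ValueError(f"unsupported formats {bad}; choose png and/or svg")


def _save_all(fig, out, spec: RenderSpec) -> list:
    """Save one figure in every requested format, deterministically."""
    out = Path(out)
    out.parent.mkdir(parents=True, exist_ok=True)
    paths = []
    with matplotlib.rc_context({"svg.hashsalt": "mutfold"}):
        for fmt in spec.formats:
            path = out.with_suffix(f".{fmt}")
            kwargs = {"dpi": spec.dpi}
            if fmt == "svg":
                kwargs["metadata"] = {"Date": None}
            fig.savefig(path, **kwargs)
            paths.append(path)
    plt.close(fig)
    return paths


def _ticks(n: int, interval: int) -> list:
    return [t for t in range(interval, n + 1, interval)]


def _check_range(matrix: np.ndarray, lo: float, hi: float, what: str) -> None:
    if matrix.min() < lo - 1e-12 or matrix.max() > hi + 1e-12:
        raise ValueError(
            f"{what} values out of range [{lo}, {hi}]: "
            f"min={matrix.min():.6g}, max={matrix.max():.6g}"
        )


def _matrix_axes(ax, n: int, spec: RenderSpec) -> None:
    ticks = _ticks(n, spec.tick_interval)
    ax.set_xticks(ticks)
    ax.set_yticks(ticks)
    ax.set_xlim(0.5, n + 0.5)
    ax.set_ylim(n + 0.5, 0.5)  # position 1 at the top, matrix convention
    ax.set_xlabel("position (nt)")
    ax.set_ylabel("position (nt)")
    for pos in spec.mutation_marks:
        ax.axvline(pos, color="red", linewidth=0.8, alpha=0.8)
        ax.axhline(pos, color="red", linewidth=0.8, alpha=0.8)


def render_heatmap(
    matrix: np.ndarray, spec: RenderSpec, out, title: str = ""
) -> list:
    """Probability heatmap: grayscale, 0 -> white, 1 -> darkest.

    Accepts any n x n matrix of probabilities (e.g. a single-sequence
    matrix, or a combined matrix with WT in the upper and mutant in the
    lower triangle).  Mutation positions are drawn as full-length red
    guide lines on both axes.
    """
    matrix = np.asarray(matrix, dtype=float)
    n = matrix.shape[0]
    _check_range(matrix, 0.0, 1.0, "probability")
    fig, ax = plt.subplots(figsize=(6, 6))
    im = ax.imshow(
        matrix, cmap="Greys", vmin=0.0, vmax=1.0,
        extent=(0.5, n + 0.5, n + 0.5, 0.5), interpolation="nearest",
    )
    _matrix_axes(ax, n, spec)
    if title:
        ax.set_title(title)
    fig.colorbar(im, ax=ax, shrink=0.8, label="pair probability")
    return _save_all(fig, out, spec)


def render_diff_heatmap(
    delta: np.ndarray, spec: RenderSpec, out, title: str = ""
) -> list:
    """Differential heatmap: blue = weakened, red = strengthened, white = 0."""
    delta = np.asarray(delta, dtype=float)
    n = delta.shape[0]
    _check_range(delta, -1.0, 1.0, "probability difference")
    lim = max(float(np.abs(delta).max()), spec.diff_floor)
    fig, ax = plt.subplots(figsize=(6, 6))
    im = ax.imshow(
        delta, cmap="bwr", vmin=-lim, vmax=lim,
        extent=(0.5, n + 0.5, n + 0.5, 0.5), interpolation="nearest",
    )
    _matrix_axes(ax, n, spec)
    if title:
        ax.set_title(title)
    fig.colorbar(im, ax=ax, shrink=0.8, label="delta (mutant - WT)")
    return _save_all(fig, out, spec)


def _circle_xy(position: int, n: int):
    """Boundary coordinates: 5' at bottom-left, clockwise to the 3' end."""
    theta = np.deg2rad(250.0) - 2.0 * np.pi * (position - 1) / n
    return np.cos(theta), np.sin(theta)


def render_circular(
    matrix: np.ndarray,
    spec: RenderSpec,
    out,
    mutation_code: str = "",
    differential: bool = False,
    title: str = "",
) -> list:
    """Circular plot: chords between paired boundary positions.

    Chord opacity is proportional to |value|; in differential mode chords
    are blue (weakened) or red (strengthened), otherwise dark gray.  The
    mutation is annotated with its code and a red boundary mark.
    """
    matrix = np.asarray(matrix, dtype=float)
    n = matrix.shape[0]
    if differential:
        _check_range(matrix, -1.0, 1.0, "probability difference")
        scale = max(float(np.abs(matrix).max()), spec.diff_floor)
    else:
        _check_range(matrix, 0.0, 1.0, "probability")
        scale = 1.0

    fig, ax = plt.subplots(figsize=(6, 6))
    ax.set_aspect("equal")
    ax.axis("off")
    circle = plt.Circle((0, 0), 1.0, fill=False, color="black", linewidth=1.0)
    ax.add_patch(circle)
    for t in [1] + _ticks(n, spec.tick_interval):
        x, y = _circle_xy(t, n)
        ax.plot([x, 1.04 * x], [y, 1.04 * y], color="black", linewidth=0.6)
        ax.text(1.12 * x, 1.12 * y, str(t), ha="center", va="center", fontsize=7)

    for i, j in zip(*np.nonzero(np.triu(np.ones((n, n)), k=1))):
        v = matrix[i, j]
        if abs(v) < spec.threshold:
            continue
        x1, y1 = _circle_xy(i + 1, n)
        x2, y2 = _circle_xy(j + 1, n)
        if differential:
            color = "red" if v > 0 else "blue"
        else:
            color = "0.15"
        alpha = min(1.0, abs(v) / scale)
        # quadratic Bezier pulled toward the center
        tt = np.linspace(0.0, 1.0, 30)[:, None]
        pts = ((1 - tt) ** 2) * np.array([[x1, y1]]) + (tt**2) * np.array([[x2, y2]])
        ax.plot(pts[:, 0], pts[:, 1], color=color, alpha=alpha, linewidth=1.0)

    for pos in spec.mutation_marks:
        x, y = _circle_xy(pos, n)
        ax.plot([x, 1.08 * x], [y, 1.08 * y], color="red", linewidth=2.0)
    if mutation_code and spec.mutation_marks:
        x, y = _circle_xy(spec.mutation_marks[0], n)
        ax.text(1.3 * x, 1.3 * y, mutation_code, color="red",
                ha="center", va="center", fontsize=9)
    ax.set_xlim(-1.5, 1.5)
    ax.set_ylim(-1.5, 1.5)
    if title:
        ax.set_title(title)
    return _save_all(fig, out, spec)


def render_arc_diagram(
    wt: BasePairMatrix, mut: BasePairMatrix, spec: RenderSpec, out,
    title: str = "",
) -> list:
    """Arc diagram: WT arcs above the sequence line, mutant arcs below.

    Arc opacity is proportional to the pair probability; arcs never cross
    the baseline.
    """
    if wt.n != mut.n:
        raise ValueError(f"length mismatch: WT n={wt.n}, mutant n={mut.n}")
    n = wt.n
    fig, ax = plt.subplots(figsize=(8, 4))
    ax.axhline(0.0, color="black", linewidth=1.0)
    max_h = 0.0
    for P, sign, color in ((wt.P, 1.0, "0.2"), (mut.P, -1.0, "0.2")):
        for i, j in zip(*np.triu_indices(n, k=1)):
            v = P[i, j]
            if v < spec.threshold:
                continue
            center = (i + j) / 2.0 + 1.0
            width = float(j - i)
            height = width / 2.0
            max_h = max(max_h, height)
            ax.add_patch(
                Arc((center, 0.0), width, sign * 2 * height,
                    theta1=0.0, theta2=180.0,
                    color=color, alpha=min(1.0, v), linewidth=1.0)
            )
    ticks = _ticks(n, spec.tick_interval)
    ax.set_xticks(ticks)
    ax.set_yticks([])
    for pos in spec.mutation_marks:
        ax.axvline(pos, color="red", linewidth=0.8, alpha=0.8)
    pad = max(max_h, 1.0) * 1.1
    ax.set_xlim(0, n + 1)
    ax.set_ylim(-pad, pad)
    ax.set_xlabel("position (nt)")
    ax.text(0.01, 0.95, "WT", transform=ax.transAxes, fontsize=9)
    ax.text(0.01, 0.03, "mutant", transform=ax.transAxes, fontsize=9)
    if title:
        ax.set_title(title)
    return _save_all(fig, out, spec)


def render_accessibility(
    wt: AccessibilityProfile,
    mut: AccessibilityProfile,
    acc_delta: np.ndarray,
    spec: RenderSpec,
    out,
    title: str = "",
) -> list:
    """Synchronized accessibility plot: WT, mutant and the WT - mut difference.

    The blue difference curve is negative where the mutant is *more*
    accessible than the WT.
    """
    if wt.n != mut.n:
        raise ValueError(f"length mismatch: WT n={wt.n}, mutant n={mut.n}")
    n = wt.n
    x = np.arange(1, n + 1)
    fig, ax = plt.subplots(figsize=(8, 4))
    ax.plot(x, np.clip(wt.pu, 0.0, 1.0), color="0.2", label="WT unpaired prob.")
    ax.plot(x, np.clip(mut.pu, 0.0, 1.0), color="darkorange",
            label="mutant unpaired prob.")
    ax.plot(x, acc_delta, color="blue", label="difference (WT - mut)")
    ax.axhline(0.0, color="black", linewidth=0.5)
    for pos in spec.mutation_marks:
        ax.axvline(pos, color="red", linewidth=0.8, alpha=0.8)
    ax.set_xticks(_ticks(n, spec.tick_interval))
    ax.set_xlim(1, n)
    ax.set_ylim(-1.05, 1.05)
    ax.set_xlabel("position (nt)")
    ax.set_ylabel("unpaired probability / difference")
    ax.legend(loc="lower right", fontsize=8)
    if title:
        ax.set_title(title)
    return _save_all(fig, out, spec)
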