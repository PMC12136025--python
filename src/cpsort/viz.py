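"""Graphical output: the tested sequence highlighted against the scoring
matrix background, one panel per matrix.

Each panel shows, for every window column -5..+20, all residues observed in
the training set placed at the height of their contribution value (bits);
the residue actually present in the tested sequence is highlighted in its
physicochemical-class colour.  The window and transit scores printed in the
panel are taken verbatim from the prediction result -- nothing is
recomputed here, and deleting this module changes no prediction.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .matrixlib import POSITION_LABELS, POSITIONS, RESIDUES, WINDOW_LENGTH, ScoringMatrix
from .predictor import TargetingResult, _aligned_position

#: physicochemical-class palette (echoes the charge contrast between
#: plastid and PPC transit peptides)
RESIDUE_CLASS_COLORS = {
    **{a: "#333333" for a in "AVLIMFWPGC"},  # hydrophobic / small
    **{a: "#c0392b" for a in "DE"},  # acidic
    **{a: "#2471a3" for a in "KRH"},  # basic
    **{a: "#1e8449" for a in "STNQY"},  # polar
}

SUPPORTED_FORMATS = ("svg", "png")


@dataclass(frozen=True)
class PanelData:
    label: str
    # per column: list of (residue, contribution), tallest first
    columns: tuple[tuple[tuple[str, float], ...], ...]
    highlight: tuple[tuple[str | None, float], ...]  # sequence residue + its value
    score_text: str


@dataclass(frozen=True)
class ContributionPlotSpec:
    window_residues: tuple[str | None, ...]
    site: int
    panels: tuple[PanelData, ...]
    fmt: str


def window_residues(sequence: str, site: int) -> tuple[str | None, ...]:
    """The 25 residues aligned to the window at ``site`` (None past the ends)."""
    out: list[str | None] = []
    for off in POSITIONS:
        pos = _aligned_position(site, off)
        out.append(sequence[pos - 1] if 1 <= pos <= len(sequence) else None)
    return tuple(out)


def _panel(sequence: str, site: int, matrix: ScoringMatrix, score_text: str) -> PanelData:
    residues = window_residues(sequence, site)
    freq = matrix.frequencies()
    columns = []
    highlight = []
    for j in range(WINDOW_LENGTH):
        col = [
            (RESIDUES[i], float(matrix.contribution[i, j]))
            for i in range(len(RESIDUES))
            if freq[i, j] > 0.0 or matrix.contribution[i, j] != 0.0
        ]
        col.sort(key=lambda t: (-t[1], t[0]))
        columns.append(tuple(col))
        r = residues[j]
        highlight.append((r, matrix.score(r, j) if r is not None else 0.0))
    return PanelData(
        label=matrix.label or "matrix",
        columns=tuple(columns),
        highlight=tuple(highlight),
        score_text=score_text,
    )


def build_plot_spec(
    result: TargetingResult,
    sequence: str,
    matrices: Sequence[ScoringMatrix],
    fmt: str = "svg",
) -> ContributionPlotSpec:
    if result.scan is None:
        raise ValueError(f"result for {result.id!r} carries no scored window (category {result.category})")
    if not 1 <= len(matrices) <= 2:
        raise ValueError("supply one or two scoring matrices")
    if fmt not in SUPPORTED_FORMATS:
        raise ValueError(f"unsupported format {fmt!r}; expected one of {SUPPORTED_FORMATS}")
    site = result.scan.best_site
    panels = []
    for k, m in enumerate(matrices):
        if k == 0:
            text = (
                f"window score {result.scan.best_window_score:.3f} bits; "
                f"transit score {result.transit_score_plastid:.3f} bits"
            )
        else:
            tp = result.transit_score_ppc
            text = f"transit score {tp:.3f} bits" if tp is not None else "transit score NA"
        panels.append(_panel(sequence, site, m, text))
    return ContributionPlotSpec(
        window_residues=window_residues(sequence, site), site=site, panels=tuple(panels), fmt=fmt
    )


def render_contribution_plot(
    result: TargetingResult,
    sequence: str,
    matrices: Sequence[ScoringMatrix],
    path: str | Path,
    fmt: str = "svg",
) -> ContributionPlotSpec:
    """Render the per-position contribution figure; returns the plotted data.

    SVG output is deterministic (fixed hash salt, no timestamp metadata), so
    repeated renders of the same result are byte-identical.
    """
    spec = build_plot_spec(result, sequence, matrices, fmt)
    with plt.rc_context({"svg.hashsalt": "cpsort", "svg.fonttype": "none"}):
        fig, axes = plt.subplots(
            len(spec.panels), 1, figsize=(10, 3.2 * len(spec.panels)), squeeze=False
        )
        for ax, panel in zip(axes[:, 0], spec.panels):
            for j, col in enumerate(panel.columns):
                for residue, value in col:
                    ax.text(j, value, residue, ha="center", va="center",
                            fontsize=7, color="#bbbbbb", zorder=1)
            for j, (residue, value) in enumerate(panel.highlight):
                if residue is None:
                    continue
                ax.text(j, value, residue, ha="center", va="center", fontsize=10,
                        fontweight="bold", zorder=2,
                        color=RESIDUE_CLASS_COLORS.get(residue, "#333333"))
            ax.set_xticks(range(WINDOW_LENGTH))
            ax.set_xticklabels(POSITION_LABELS, fontsize=6)
            ax.set_xlim(-1, WINDOW_LENGTH)
            ymax = max((v for col in panel.columns for _, v in col), default=1.0)
            ymin = min((v for col in panel.columns for _, v in col), default=0.0)
            ax.set_ylim(min(ymin, 0.0) - 0.2, ymax + 0.4)
            ax.set_ylabel("contribution (bits)")
            ax.set_title(f"{result.id} vs {panel.label}: {panel.score_text}", fontsize=9)
        axes[-1, 0].set_xlabel("window position")
        fig.tight_layout()
        fig.savefig(str(path), format=fmt, metadata=({"Date": None} if fmt == "svg" else None))
        plt.close(fig)
    return spec
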