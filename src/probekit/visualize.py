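"""Reactivity heatmaps, barplots and VARNA export.

Color conventions follow the probing-community defaults: per-probe sequential
ramps for the heatmap (SHAPE yellow-orange-red, DMS yellow-green, CMCT
white-red), a three-bin barplot (black below 0.3, orange from 0.3 to 0.7, red
from 0.7 up), and neutral grey for positions without a readout.  Bins are
left-closed/right-open except the last, so 0.3 is orange and 0.7 is red.

VARNA itself is an optional Java renderer: :func:`varna_export` always writes
a renderer-independent per-nucleotide color-map file plus a complete
invocation descriptor, and only runs Java when a jar is configured.
"""

from __future__ import annotations

import json
import shutil
import subprocess
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import matplotlib
import numpy as np

matplotlib.use("Agg")
import matplotlib.pyplot as plt
from matplotlib import colormaps
from matplotlib.colors import to_hex

from .errors import ReconciliationError
from .normalize import SUSCEPTIBILITY
from .probing_io import ReactivityProfile
from .structures import SecondaryStructure, write_dotbracket

MISSING_COLOR = "#b0b0b0"

#: matplotlib colormap per probe, matching the named color ramps
PROBE_CMAPS = {"SHAPE": "YlOrRd", "DMS": "YlGn", "CMCT": "Reds"}

#: user-selectable alternatives
ALTERNATIVE_CMAPS = ("viridis", "plasma", "YlOrRd", "YlGn", "Reds", "Blues", "Greys")

BARPLOT_BINS = ((0.0, 0.3, "black"), (0.3, 0.7, "orange"), (0.7, 1.0, "red"))


@dataclass(frozen=True)
class ColorScheme:
    """A [0,1] -> color ramp plus the color reserved for missing positions."""

    name: str
    missing: str = MISSING_COLOR

    def colormap(self):
        cmap = colormaps[self.name].copy()
        cmap.set_bad(self.missing)
        return cmap

    def color(self, value: float, measured: bool = True) -> str:
        """Hex color for one reactivity value (pure function of its inputs)."""
        if not measured or np.isnan(value):
            return self.missing
        return to_hex(self.colormap()(float(np.clip(value, 0.0, 1.0))))


def default_scheme(probe: str, override: Optional[str] = None) -> ColorScheme:
    name = override or PROBE_CMAPS[probe]
    if name not in colormaps:
        raise ValueError(f"unknown color scheme {name!r}")
    return ColorScheme(name=name)


def bar_color(value: float) -> str:
    """Barplot bin color: black [0,0.3), orange [0.3,0.7), red [0.7,1]."""
    if value < BARPLOT_BINS[1][0]:
        return BARPLOT_BINS[0][2]
    if value < BARPLOT_BINS[2][0]:
        return BARPLOT_BINS[1][2]
    return BARPLOT_BINS[2][2]


def _sib(out_base: Path, ext: str) -> Path:
    """Sibling path with an extension appended (never replaces part of the name)."""
    return out_base.parent / (out_base.name + ext)


def _save(fig, out_base: Path) -> list[Path]:
    paths = []
    for ext in ("png", "svg"):
        p = _sib(out_base, f".{ext}")
        fig.savefig(p, dpi=150, bbox_inches="tight")
        paths.append(p)
    plt.close(fig)
    return paths


def heatmap(
    profile: ReactivityProfile,
    out_base,
    scheme: Optional[ColorScheme] = None,
    wrap: int = 50,
) -> list[Path]:
    """Row-wrapped per-nucleotide reactivity heatmap (PNG + SVG).

    One box per position, annotated with the nucleotide letter; missing
    positions use the scheme's missing color.
    """
    if not profile.normalized:
        raise ValueError("heatmap expects a normalized profile")
    scheme = scheme or default_scheme(profile.probe)
    n = len(profile)
    nrows = -(-n // wrap)
    grid = np.full((nrows, wrap), np.nan)
    for i in range(n):
        grid[i // wrap, i % wrap] = profile.values[i]
    masked = np.ma.masked_invalid(grid)
    # pad cells (beyond the sequence) rendered white, distinct from missing
    pad_mask = np.zeros_like(grid, dtype=bool)
    pad_mask.flat[n:] = True

    fig, ax = plt.subplots(figsize=(max(6, wrap * 0.22), max(1.2, nrows * 0.45)))
    cmap = scheme.colormap()
    im = ax.imshow(masked, cmap=cmap, vmin=0.0, vmax=1.0, aspect="equal")
    if pad_mask.any():
        white = np.ma.masked_where(~pad_mask, np.zeros_like(grid))
        ax.imshow(white, cmap=matplotlib.colors.ListedColormap(["white"]),
                  vmin=0, vmax=1, aspect="equal")
    for i in range(n):
        r, c = divmod(i, wrap)
        ax.text(c, r, profile.sequence[i], ha="center", va="center", fontsize=6)
    ax.set_xticks(range(9, wrap, 10), [str(c + 1) for c in range(9, wrap, 10)])
    ax.set_yticks(range(nrows), [str(r * wrap + 1) for r in range(nrows)])
    ax.set_title(f"{profile.probe} reactivity — {profile.sequence.identifier}")
    fig.colorbar(im, ax=ax, shrink=0.8, label="normalized reactivity")
    return _save(fig, Path(out_base))


def barplot(profile: ReactivityProfile, out_base) -> list[Path]:
    """Per-nucleotide reactivity barplot with three-bin coloring (PNG + SVG)."""
    if not profile.normalized:
        raise ValueError("barplot expects a normalized profile")
    n = len(profile)
    pos = np.arange(1, n + 1)
    fig, ax = plt.subplots(figsize=(max(6, n * 0.12), 3))
    for i in range(n):
        if profile.measured[i]:
            ax.bar(pos[i], profile.values[i], color=bar_color(profile.values[i]),
                   width=0.8)
        else:
            ax.plot(pos[i], 0.0, marker="|", color=MISSING_COLOR, markersize=8)
    ax.set_xlim(0.3, n + 0.7)
    ax.set_ylim(0, 1.05)
    ax.set_xlabel("position")
    ax.set_ylabel("normalized reactivity")
    ax.set_title(f"{profile.probe} reactivity — {profile.sequence.identifier}")
    return _save(fig, Path(out_base))


_VARNA_ALGORITHMS = {"radiate": "radiate", "circular": "circle", "linear": "line"}


def varna_export(
    sequence,
    structure: SecondaryStructure,
    out_base,
    profile: Optional[ReactivityProfile] = None,
    layout: str = "radiate",
    grey_out: bool = False,
    varna_jar: Optional[str] = None,
) -> dict:
    """Write VARNA color-map and invocation files for one structure.

    Returns a dict with the written paths and the java argv.  With a profile,
    a per-nucleotide color-map file is written (missing positions as ``-1``);
    with ``grey_out`` and a DMS/CMCT profile, positions whose letters are not
    susceptible to the probe are listed for grey rendering.  Without a profile
    (prediction mode) no coloring is emitted.  If ``varna_jar`` points to an
    existing jar and ``java`` is available, the renderer is actually run.
    """
    if layout not in _VARNA_ALGORITHMS:
        raise ValueError(f"unknown layout {layout!r}")
    out_base = Path(out_base)
    if profile is not None and len(profile) != structure.length:
        raise ReconciliationError(
            f"profile length {len(profile)} != structure length {structure.length}"
        )
    db = write_dotbracket(structure)
    argv = [
        "java", "-cp", varna_jar or "VARNA.jar",
        "fr.orsay.lri.varna.applications.VARNAcmd",
        "-sequenceDBN", str(sequence.residues),
        "-structureDBN", db,
        "-algorithm", _VARNA_ALGORITHMS[layout],
        "-o", str(_sib(out_base, ".png")),
    ]
    written = {}
    if profile is not None:
        cm_path = _sib(out_base, ".colormap.txt")
        cm_path.write_text(
            "".join(
                f"{profile.values[i]:.3f}\n" if profile.measured[i] else "-1\n"
                for i in range(len(profile))
            )
        )
        written["colormap"] = cm_path
        argv += ["-colorMapStyle", "energy", "-colorMap", str(cm_path)]
        if grey_out and profile.probe in ("DMS", "CMCT"):
            letters = SUSCEPTIBILITY[profile.probe]
            grey = [
                str(i + 1)
                for i, c in enumerate(profile.sequence.residues)
                if c not in letters
            ]
            if grey:
                argv += [
                    "-basesStyle1", f"fill={MISSING_COLOR}",
                    "-applyBasesStyle1on", ",".join(grey),
                ]
                written["grey_positions"] = grey

    descriptor = {
        "layout": layout,
        "structure_label": structure.label,
        "dotbracket": db,
        "argv": argv,
    }
    desc_path = _sib(out_base, ".varna.json")
    desc_path.write_text(json.dumps(descriptor, indent=2, default=str) + "\n")
    written["descriptor"] = desc_path
    written["argv"] = argv

    if varna_jar and Path(varna_jar).exists() and shutil.which("java"):
        proc = subprocess.run(argv, capture_output=True, text=True)
        if proc.returncode == 0:
            written["image"] = _sib(out_base, ".png")
    return written
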