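"""Color-coded DNA fingerprints over a marker panel.

Each cultivar's fingerprint is its ordered genotype-string vector over the
panel loci; tables are written loci-as-rows x samples-as-columns and
rendered as a heat-map grid with one fixed color per genotype class:

    AA green, AG light pink, CC yellow, CT grey, GT dark red, TT blue,
    AC pink, AT orange, CG light blue, GG purple, NN (no call) white.

The ten two-letter classes plus NN are the complete domain: genotype
strings are canonical alphabetical pairs, so e.g. "GA" is rejected rather
than silently recolored.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
from matplotlib.patches import Patch

from .genotype_io import GenotypeMatrix
from .marker_selection import MarkerPanel, find_duplicate_groups


class ColorEncodingError(KeyError):
    """Genotype string outside the color map domain."""


#: genotype class -> (color name, hex). Hex values are a fixed convention;
#: the class->name assignment is the published legend.
DEFAULT_COLOR_MAP: dict[str, tuple[str, str]] = {
    "AA": ("green", "#2ca02c"),
    "AG": ("light pink", "#ffb6c1"),
    "CC": ("yellow", "#ffd700"),
    "CT": ("grey", "#808080"),
    "GT": ("dark red", "#8b0000"),
    "TT": ("blue", "#1f77b4"),
    "AC": ("pink", "#ff69b4"),
    "AT": ("orange", "#ff7f0e"),
    "CG": ("light blue", "#add8e6"),
    "GG": ("purple", "#9467bd"),
    "NN": ("white", "#ffffff"),
}


def color_for_genotype(genotype: str, color_map: dict[str, tuple[str, str]] | None = None) -> str:
    """Hex color for a canonical genotype string; unknown strings raise."""
    cmap = color_map or DEFAULT_COLOR_MAP
    try:
        return cmap[genotype][1]
    except KeyError:
        raise ColorEncodingError(
            f"genotype {genotype!r} not in color map (canonicalize first?)"
        ) from None


@dataclass
class Fingerprint:
    """One sample's ordered genotype strings over the panel loci."""

    sample: str
    genotypes: tuple[str, ...]
    is_group_representative: bool = False


def build_fingerprint_table(
    matrix: GenotypeMatrix, panel: MarkerPanel | Sequence[str]
) -> list[Fingerprint]:
    """One fingerprint per sample, sorted by sample id.

    Samples that represent a duplicate group (identical-profile cultivars,
    likely synonyms) are annotated via ``is_group_representative``.
    """
    loci = panel.loci if isinstance(panel, MarkerPanel) else list(panel)
    if not loci:
        raise ValueError("empty panel")
    idx = [matrix.locus_index(lid) for lid in loci]
    reps = {g.representative for g in find_duplicate_groups(matrix)}
    out = [
        Fingerprint(
            sample=s,
            genotypes=matrix.profile(i, idx),
            is_group_representative=s in reps,
        )
        for i, s in enumerate(matrix.samples)
    ]
    out.sort(key=lambda f: f.sample)
    return out


def write_fingerprint_tsv(
    fingerprints: Sequence[Fingerprint], panel_loci: Sequence[str], path: str | Path
) -> None:
    """TSV with loci as rows and samples as columns (header row: sample ids)."""
    with open(path, "w") as fh:
        fh.write("locus\t" + "\t".join(f.sample for f in fingerprints) + "\n")
        for r, lid in enumerate(panel_loci):
            fh.write(lid + "\t" + "\t".join(f.genotypes[r] for f in fingerprints) + "\n")


def render_heatmap(
    fingerprints: Sequence[Fingerprint],
    panel_loci: Sequence[str],
    path: str | Path,
    color_map: dict[str, tuple[str, str]] | None = None,
    transpose: bool = False,
) -> None:
    """Render the fingerprint grid (loci rows x sample columns) with legend.

    Output format follows the file suffix (.svg or .png).  SVG output is
    byte-deterministic for identical inputs (fixed hash salt, no timestamp).
    """
    if not fingerprints:
        raise ValueError("need at least one fingerprint")
    cmap = color_map or DEFAULT_COLOR_MAP
    n_loci, n_samples = len(panel_loci), len(fingerprints)
    grid = [
        [color_for_genotype(fingerprints[c].genotypes[r], cmap) for c in range(n_samples)]
        for r in range(n_loci)
    ]
    row_labels, col_labels = list(panel_loci), [f.sample for f in fingerprints]
    if transpose:
        grid = [list(row) for row in zip(*grid)]
        row_labels, col_labels = col_labels, row_labels

    rgb = [[_hex_to_rgb(c) for c in row] for row in grid]
    with plt.rc_context({"svg.hashsalt": "kaspkit"}):
        fig_w = max(4.0, 0.18 * len(col_labels) + 2.0)
        fig_h = max(3.0, 0.28 * len(row_labels) + 2.0)
        fig, ax = plt.subplots(figsize=(fig_w, fig_h))
        ax.imshow(rgb, aspect="auto", interpolation="nearest")
        ax.set_xticks(range(len(col_labels)), col_labels, rotation=90, fontsize=5)
        ax.set_yticks(range(len(row_labels)), row_labels, fontsize=6)
        ax.set_xticks([x - 0.5 for x in range(1, len(col_labels))], minor=True)
        ax.set_yticks([y - 0.5 for y in range(1, len(row_labels))], minor=True)
        ax.grid(which="minor", color="white", linewidth=0.4)
        ax.tick_params(which="both", length=0)
        handles = [
            Patch(facecolor=hx, edgecolor="black", label=f"{gt} ({name})")
            for gt, (name, hx) in cmap.items()
        ]
        ax.legend(
            handles=handles,
            loc="upper left",
            bbox_to_anchor=(1.01, 1.0),
            fontsize=6,
            frameon=False,
        )
        fig.tight_layout()
        fig.savefig(path, metadata=_no_date_metadata(str(path)))
        plt.close(fig)


def _hex_to_rgb(hx: str) -> tuple[float, float, float]:
    hx = hx.lstrip("#")
    return tuple(int(hx[i:i + 2], 16) / 255.0 for i in (0, 2, 4))  # type: ignore[return-value]


def _no_date_metadata(path: str) -> dict | None:
    # strip volatile timestamps so identical inputs give identical bytes
    if path.endswith(".svg"):
        return {"Date": None}
    if path.endswith(".png"):
        return {"Software": None}
    return None
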