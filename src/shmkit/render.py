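"""Spatial-heatmap (SHM) rendering.

An SHM colors the anatomical features of an :class:`~shmkit.asvg.SVGDoc`
by the assay values of a chosen gene through a numeric *color key*: an
ordered list of k colors with k+1 ascending breaks.  A grid of panels
is produced over genes x conditions, together with the key and a legend
plot in which each feature keeps a fixed categorical color.

Palettes come from matplotlib colormaps.  Defaults follow common
convention: a yellow-orange-red sequential map for absolute values and
a blue-white-red diverging map centered at zero for log fold changes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
from matplotlib import colormaps
from matplotlib.colors import to_hex
from matplotlib.patches import Circle, Ellipse, Polygon, Rectangle

from .assay import AssayTable, FeatureSampleMap, aggregate_replicates
from .asvg import SVGDoc, shape_points, write_svg
from .errors import ValidationError

#: fill used for features without a measured value
NA_COLOR = "#d3d3d3"

DEFAULT_PALETTE = "YlOrRd"
DEFAULT_LFC_PALETTE = "bwr"


@dataclass
class ColorKey:
    """Numeric number-to-color key: k ordered colors over k+1 breaks."""

    colors: list[str]
    breaks: np.ndarray
    scale_mode: str = "shared"

    def __post_init__(self) -> None:
        self.breaks = np.asarray(self.breaks, dtype=float)
        if len(self.colors) < 2:
            raise ValidationError("color key needs at least 2 colors")
        if len(self.breaks) != len(self.colors) + 1:
            raise ValidationError("need exactly k+1 breaks for k colors")
        if not np.all(np.diff(self.breaks) > 0):
            raise ValidationError("breaks must be strictly ascending")


def make_color_key(
    values,
    palette: str = DEFAULT_PALETTE,
    k: int = 10,
    scale_mode: str = "shared",
    center: float | None = None,
) -> ColorKey:
    """Build a k-bin color key spanning the range of ``values``.

    Breaks are k+1 equally spaced numbers from min to max.  When all
    values coincide at v the key degenerates to breaks over [v-1, v+1]
    so every value maps to the middle color.  ``center`` forces a
    symmetric range around the given value (used for fold changes).
    """
    vals = np.asarray(list(values), dtype=float)
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        raise ValidationError("color key needs at least one finite value")
    if k < 2:
        raise ValidationError("color key needs k >= 2 bins")
    vmin, vmax = float(vals.min()), float(vals.max())
    if center is not None:
        half = max(abs(vmin - center), abs(vmax - center))
        vmin, vmax = center - half, center + half
    if vmin == vmax:
        vmin, vmax = vmin - 1.0, vmax + 1.0
    breaks = np.linspace(vmin, vmax, k + 1)
    cmap = colormaps[palette]
    colors = [to_hex(cmap((i + 0.5) / k)) for i in range(k)]
    return ColorKey(colors=colors, breaks=breaks, scale_mode=scale_mode)


def bin_of(key: ColorKey, value: float) -> int:
    """Bin index of ``value``: breaks[i] <= v < breaks[i+1].

    A value exactly on an interior break falls into the higher bin; the
    last bin is right-closed; out-of-range values clamp to the end
    bins.  NaN has no bin (-1).
    """
    if math.isnan(value):
        return -1
    k = len(key.colors)
    i = int(np.searchsorted(key.breaks, value, side="right")) - 1
    return min(max(i, 0), k - 1)


def color_of(key: ColorKey, value: float) -> str:
    """Color for ``value`` under the key; NaN maps to the NA color."""
    i = bin_of(key, value)
    return NA_COLOR if i < 0 else key.colors[i]


# ---------------------------------------------------------------------------
# SHM figure
# ---------------------------------------------------------------------------

#: fixed categorical palette for legend plots / fixed-by-group coloring
CATEGORICAL = [
    "#1f77b4", "#ff7f0e", "#2ca02c", "#d62728", "#9467bd",
    "#8c564b", "#e377c2", "#7f7f7f", "#bcbd22", "#17becf",
]


def categorical_colors(names) -> dict[str, str]:
    names = list(names)
    cmap = colormaps["tab20"]
    out = {}
    for i, n in enumerate(names):
        out[n] = CATEGORICAL[i] if i < len(CATEGORICAL) else to_hex(cmap((i % 20) / 20))
    return out


@dataclass
class SHMFigure:
    """Grid of colored anatomies over (gene, condition), plus key/legend."""

    panels: dict[tuple[str, str], SVGDoc]
    genes: list[str]
    conditions: list[str]
    key: ColorKey | dict[str, ColorKey]
    legend: SVGDoc
    genes_axis: str = "row"
    value_space: str = "normalized"

    def panel_order(self) -> list[tuple[str, str]]:
        if self.genes_axis == "row":
            return [(g, c) for g in self.genes for c in self.conditions]
        return [(g, c) for c in self.conditions for g in self.genes]

    def grid_shape(self) -> tuple[int, int]:
        ng, nc = len(self.genes), len(self.conditions)
        return (ng, nc) if self.genes_axis == "row" else (nc, ng)

    def save(self, out_dir: str | Path, png: bool = True, dpi: int = 150) -> list[Path]:
        """Write one SVG per panel (``{gene}__{condition}.svg``), the key,
        the legend, and optionally a composite PNG of the grid."""
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        written: list[Path] = []
        for (gene, cond), doc in sorted(self.panels.items()):
            p = out_dir / f"{gene}__{cond}.svg"
            write_svg(doc, p)
            written.append(p)
        write_svg(self.legend, out_dir / "legend.svg")
        written.append(out_dir / "legend.svg")
        keys = self.key if isinstance(self.key, dict) else {"shared": self.key}
        for name, key in keys.items():
            p = out_dir / f"key__{name}.svg"
            write_key_svg(key, p)
            written.append(p)
        if png:
            p = out_dir / "shm_grid.png"
            rasterize_grid(self, p, dpi=dpi)
            written.append(p)
        return written


def colorize_doc(
    doc: SVGDoc,
    fills: dict[str, str],
) -> SVGDoc:
    """Copy of ``doc`` with the given feature fills; others untouched."""
    out = doc.copy()
    for f in out.features:
        if f.id in fills:
            f.style.fill = fills[f.id]
    return out


def render_shm(
    doc: SVGDoc,
    assay: AssayTable,
    genes: list[str],
    fmap: FeatureSampleMap,
    genes_axis: str = "row",
    palette: str | None = None,
    k: int = 10,
    scale_mode: str = "shared",
    aggregate: str = "mean",
) -> SHMFigure:
    """Render an SHM grid: one colored anatomy per (gene, condition).

    Replicates are collapsed by ``aggregate`` (mean default); each
    mapped feature's fill becomes ``color_of(key, value)``; unmapped
    features keep their original fill.  With ``scale_mode='shared'``
    one key spans all panels; ``'per_gene'`` builds one key per gene.
    """
    if genes_axis not in ("row", "col"):
        raise ValidationError(f"genes_axis must be 'row' or 'col', got {genes_axis!r}")
    unknown = sorted(set(genes) - set(assay.gene_ids))
    if unknown:
        raise ValidationError(f"unknown genes: {unknown}")
    if not fmap.pairs:
        raise ValidationError("zero mapped features; nothing to color")
    if palette is None:
        palette = DEFAULT_LFC_PALETTE if assay.value_space == "lfc" else DEFAULT_PALETTE
    center = 0.0 if assay.value_space == "lfc" else None

    agg = aggregate_replicates(assay, stat=aggregate)  # genes x (feature, cond)
    conditions = assay.conditions
    mapped_labels = [l for l in assay.features if l in fmap.pairs]

    def key_for(gene_rows: list[str]) -> ColorKey:
        vals = []
        for g in gene_rows:
            for lab in mapped_labels:
                for cond in conditions:
                    if (lab, cond) in agg.columns:
                        vals.append(agg.loc[g, (lab, cond)])
        return make_color_key(vals, palette=palette, k=k, scale_mode=scale_mode,
                              center=center)

    if scale_mode == "shared":
        shared = key_for(list(genes))
        keys: ColorKey | dict[str, ColorKey] = shared
    elif scale_mode == "per_gene":
        keys = {g: key_for([g]) for g in genes}
    else:
        raise ValidationError(f"unknown scale_mode {scale_mode!r}")

    panels: dict[tuple[str, str], SVGDoc] = {}
    for gene in genes:
        key = keys if isinstance(keys, ColorKey) else keys[gene]
        for cond in conditions:
            fills = {}
            for lab in mapped_labels:
                if (lab, cond) in agg.columns:
                    fills[fmap.pairs[lab]] = color_of(key, float(agg.loc[gene, (lab, cond)]))
            panels[(gene, cond)] = colorize_doc(doc, fills)

    legend = colorize_doc(
        doc, {fmap.pairs[l]: c for l, c in
              categorical_colors(mapped_labels).items()}
    )
    return SHMFigure(
        panels=panels,
        genes=list(genes),
        conditions=conditions,
        key=keys,
        legend=legend,
        genes_axis=genes_axis,
        value_space=assay.value_space,
    )


def render_with_raster(
    doc: SVGDoc,
    raster_path: str | Path | None = None,
    alpha_raster: float = 1.0,
    grayscale: bool = False,
) -> SVGDoc:
    """Attach a raster photograph as the bottom layer of the anatomy.

    The raster is embedded below all vector features at the given
    opacity; ``grayscale`` reduces it to black and white on write.
    """
    if not 0.0 <= alpha_raster <= 1.0:
        raise ValidationError(f"alpha_raster {alpha_raster} outside [0, 1]")
    path = raster_path if raster_path is not None else doc.raster_path
    if path is None or not Path(path).is_file():
        raise OSError(f"raster image not readable: {path}")
    out = doc.copy()
    out.raster_path = str(path)
    out.raster_opacity = float(alpha_raster)
    out.raster_grayscale = bool(grayscale)
    return out


# ---------------------------------------------------------------------------
# key / rasterization helpers
# ---------------------------------------------------------------------------

def write_key_svg(key: ColorKey, path: str | Path) -> None:
    """Write the numeric color key as a horizontal bar of labeled bins."""
    from lxml import etree

    from .asvg import SVG_NS, _fmt

    k = len(key.colors)
    cell_w, cell_h, label_h = 40.0, 20.0, 14.0
    root = etree.Element(f"{{{SVG_NS}}}svg", nsmap={None: SVG_NS})
    root.set("version", "1.1")
    root.set("width", _fmt(cell_w * k))
    root.set("height", _fmt(cell_h + label_h))
    for i, color in enumerate(key.colors):
        r = etree.SubElement(root, f"{{{SVG_NS}}}rect")
        r.set("x", _fmt(i * cell_w))
        r.set("y", "0")
        r.set("width", _fmt(cell_w))
        r.set("height", _fmt(cell_h))
        r.set("fill", color)
        r.set("id", f"keybin_{i}")
    for i, b in enumerate(key.breaks):
        t = etree.SubElement(root, f"{{{SVG_NS}}}text")
        t.set("x", _fmt(i * cell_w))
        t.set("y", _fmt(cell_h + label_h - 3))
        t.set("font-size", "9")
        t.text = format(float(b), ".3g")
    Path(path).write_bytes(
        etree.tostring(root, xml_declaration=True, encoding="UTF-8", pretty_print=True)
    )


def _draw_doc(ax, doc: SVGDoc) -> None:
    """Draw a document's shapes onto a matplotlib axis (y flipped)."""
    if doc.raster_path is not None:
        from PIL import Image

        img = Image.open(doc.raster_path).convert("RGB")
        if doc.raster_grayscale:
            img = img.convert("L").convert("RGB")
        ax.imshow(
            np.asarray(img),
            extent=(0, doc.width, doc.height, 0),
            alpha=doc.raster_opacity,
            aspect="auto",
            zorder=0,
        )
    for f in sorted(doc.features, key=lambda f: f.layer_index):
        fill = f.style.fill if f.style.fill not in (None, "none") else "#ffffff"
        dx, dy = f.offset
        for shp in f.shapes:
            a = shp.attrs
            common = dict(
                facecolor=fill,
                edgecolor=f.style.stroke or "#000000",
                linewidth=f.style.stroke_width or 0.5,
                alpha=f.style.opacity,
                zorder=1 + f.layer_index,
            )
            if shp.tag == "rect":
                patch = Rectangle(
                    (float(a.get("x", 0)) + dx, float(a.get("y", 0)) + dy),
                    float(a.get("width", 0)), float(a.get("height", 0)), **common,
                )
            elif shp.tag == "circle":
                patch = Circle(
                    (float(a.get("cx", 0)) + dx, float(a.get("cy", 0)) + dy),
                    float(a.get("r", 0)), **common,
                )
            elif shp.tag == "ellipse":
                patch = Ellipse(
                    (float(a.get("cx", 0)) + dx, float(a.get("cy", 0)) + dy),
                    2 * float(a.get("rx", 0)), 2 * float(a.get("ry", 0)), **common,
                )
            else:  # polygon / polyline / path / line via outline points
                pts = [(x + dx, y + dy) for x, y in shape_points(shp)]
                if len(pts) < 2:
                    continue
                patch = Polygon(pts, closed=True, **common)
            ax.add_patch(patch)
    ax.set_xlim(0, doc.width)
    ax.set_ylim(doc.height, 0)  # SVG frame: y down
    ax.set_aspect("equal")
    ax.axis("off")


def rasterize(doc: SVGDoc, path: str | Path, dpi: int = 150) -> None:
    """Rasterize a document to PNG via matplotlib patches.

    Curved path segments are approximated by their control polygons;
    adequate for the polygonal anatomies this package generates.
    """
    fig, ax = plt.subplots(figsize=(doc.width / 96, doc.height / 96))
    try:
        _draw_doc(ax, doc)
        fig.savefig(path, dpi=dpi)
    finally:
        plt.close(fig)


def rasterize_grid(figure: SHMFigure, path: str | Path, dpi: int = 150) -> None:
    """Composite PNG of all panels in grid order, with titles."""
    nrow, ncol = figure.grid_shape()
    first = next(iter(figure.panels.values()))
    fig, axes = plt.subplots(
        nrow, ncol, squeeze=False,
        figsize=(ncol * first.width / 96, nrow * first.height / 96),
    )
    try:
        for idx, (gene, cond) in enumerate(figure.panel_order()):
            ax = axes[idx // ncol][idx % ncol]
            _draw_doc(ax, figure.panels[(gene, cond)])
            ax.set_title(f"{gene} | {cond}", fontsize=8)
        fig.savefig(path, dpi=dpi)
    finally:
        plt.close(fig)
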