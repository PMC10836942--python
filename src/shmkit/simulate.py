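"""Synthetic anatomies and simulated assay data with known ground truth.

Everything downstream of this module is testable without downloads: toy
aSVG anatomies (non-overlapping polygonal features, optional overlay
layer for transparency experiments), negative-binomial bulk counts with
planted feature-selective genes and known library-size multipliers, and
single-cell counts drawn around the bulk feature profiles with optional
disjoint spatial regions per group.

The negative binomial is parameterized by mean and dispersion with
variance mu + phi * mu**2 (phi defaults: 0.1 bulk, 0.3 single-cell).
Gene base means are log-normal(log 50, 1) and library multipliers
log-normal(0, 0.15), emulating the magnitude spread and modest
library-size variation of a typical bulk RNA-seq experiment.  All
generators are pure functions of their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .assay import AssayTable, SCAssay
from .asvg import FeatureStyle, Shape, SpatialFeature, SVGDoc, write_svg
from .errors import ValidationError


@dataclass
class SimTruth:
    """Ground truth recorded by the simulators."""

    library_multipliers: dict[str, float] = field(default_factory=dict)
    #: (gene, feature-or-condition label, planted log2 fold change)
    planted: list[tuple[str, str, float]] = field(default_factory=list)
    sc_group_sources: dict[str, str] = field(default_factory=dict)
    #: group -> (x0, y0, x1, y1) coordinate region
    spatial_layout: dict[str, tuple[float, float, float, float]] = field(
        default_factory=dict
    )
    #: true per-feature NB mean profiles (genes x features), pre-library
    feature_means: pd.DataFrame | None = None

    @property
    def planted_genes(self) -> list[str]:
        return [g for g, _, _ in self.planted]


# ---------------------------------------------------------------------------
# toy anatomy
# ---------------------------------------------------------------------------

def make_toy_asvg(
    n_features: int,
    n_layers: int = 1,
    seed: int = 0,
    path: str | Path | None = None,
) -> SVGDoc:
    """Generate a toy anatomy of non-overlapping polygonal features.

    Features ``feat_1..feat_n`` are jittered octagons on a grid (layer
    0).  With ``n_layers=2`` a semi-opaque rectangle ``overlay_1``
    covering part of the base layer is added on top, for transparency
    tests.  When ``path`` is given the document is also written to disk
    (byte-identical for identical seeds).
    """
    if n_features < 1:
        raise ValidationError("need at least one feature")
    rng = np.random.default_rng(seed)
    ncol = int(np.ceil(np.sqrt(n_features)))
    nrow = int(np.ceil(n_features / ncol))
    cell_w, cell_h, margin = 100.0, 90.0, 10.0
    width = ncol * cell_w + margin
    height = nrow * cell_h + margin

    features: list[SpatialFeature] = []
    for i in range(n_features):
        r, c = divmod(i, ncol)
        cx = margin + c * cell_w + (cell_w - margin) / 2
        cy = margin + r * cell_h + (cell_h - margin) / 2
        rad_x = (cell_w - margin) * 0.45
        rad_y = (cell_h - margin) * 0.45
        angles = np.linspace(0, 2 * np.pi, 9)[:-1]
        jitter = rng.uniform(0.75, 1.0, size=angles.size)
        pts = [
            (cx + rad_x * j * np.cos(a), cy + rad_y * j * np.sin(a))
            for a, j in zip(angles, jitter)
        ]
        points = " ".join(f"{x:.2f},{y:.2f}" for x, y in pts)
        features.append(
            SpatialFeature(
                id=f"feat_{i + 1}",
                shapes=[Shape("polygon", {"points": points})],
                layer_index=len(features),
                style=FeatureStyle(fill="#cccccc", stroke="#333333", stroke_width=1.0),
            )
        )
    if n_layers >= 2:
        for j in range(n_layers - 1):
            # overlay covers the left part of the base layer
            w = width * rng.uniform(0.35, 0.55)
            h = height * rng.uniform(0.5, 0.8)
            features.append(
                SpatialFeature(
                    id=f"overlay_{j + 1}",
                    shapes=[
                        Shape(
                            "rect",
                            {
                                "x": f"{margin / 2:.2f}",
                                "y": f"{margin / 2:.2f}",
                                "width": f"{w:.2f}",
                                "height": f"{h:.2f}",
                            },
                        )
                    ],
                    layer_index=len(features),
                    style=FeatureStyle(fill="#aa8866", stroke="#333333",
                                       stroke_width=1.0, opacity=0.85),
                )
            )
    doc = SVGDoc(features=features, width=width, height=height)
    if path is not None:
        write_svg(doc, path)
        doc.source_paths = [str(path)]
    return doc


def make_checkerboard_png(path: str | Path, size: int = 64, cells: int = 8) -> Path:
    """Write a small colored checkerboard PNG (raster-overlay fixture)."""
    from PIL import Image

    tile = size // cells
    arr = np.zeros((size, size, 3), dtype=np.uint8)
    for r in range(cells):
        for c in range(cells):
            color = (200, 60, 60) if (r + c) % 2 else (60, 60, 200)
            arr[r * tile : (r + 1) * tile, c * tile : (c + 1) * tile] = color
    Image.fromarray(arr).save(path)
    return Path(path)


# ---------------------------------------------------------------------------
# bulk counts
# ---------------------------------------------------------------------------

def _nb_draw(rng: np.random.Generator, mean: np.ndarray, phi: float) -> np.ndarray:
    """Negative-binomial draw with variance mu + phi * mu**2."""
    shape = 1.0 / phi
    p = shape / (shape + mean)
    return rng.negative_binomial(shape, p)


def simulate_bulk(
    n_genes: int,
    features: list[str],
    replicates: int = 4,
    planted_frac: float = 0.05,
    lfc: float = 3.0,
    dispersion: float = 0.1,
    seed: int = 0,
    conditions: list[str] | None = None,
    planted_on: str = "feature",
) -> tuple[AssayTable, SimTruth]:
    """Simulate a bulk counts table with planted feature-selective genes.

    A ``planted_frac`` fraction of genes receives a multiplicative
    2**lfc boost in one feature (assigned round-robin) -- or, with
    ``planted_on='condition'``, in one non-control condition across all
    features.  Library multipliers and planted assignments are recorded
    in the returned :class:`SimTruth`.
    """
    if replicates < 2:
        raise ValidationError("need >= 2 replicates")
    conditions = conditions or ["all"]
    rng = np.random.default_rng(seed)
    genes = [f"g{i + 1}" for i in range(n_genes)]
    base = rng.lognormal(mean=np.log(50.0), sigma=1.0, size=n_genes)

    feature_means = pd.DataFrame(
        {f: base.copy() for f in features}, index=genes
    )
    truth = SimTruth()
    n_pl = int(round(planted_frac * n_genes))
    pl_idx = rng.choice(n_genes, size=n_pl, replace=False) if n_pl else np.array([], int)
    cond_means: dict[tuple[str, str], np.ndarray] = {}
    for f in features:
        for c in conditions:
            cond_means[(f, c)] = base.copy()
    if planted_on == "feature":
        for j, gi in enumerate(sorted(pl_idx)):
            target = features[j % len(features)]
            feature_means.iloc[gi, features.index(target)] *= 2.0**lfc
            for c in conditions:
                cond_means[(target, c)][gi] *= 2.0**lfc
            truth.planted.append((genes[gi], target, lfc))
    elif planted_on == "condition":
        if len(conditions) < 2:
            raise ValidationError("condition-planting needs >= 2 conditions")
        noncontrol = conditions[1:]
        for j, gi in enumerate(sorted(pl_idx)):
            target = noncontrol[j % len(noncontrol)]
            for f in features:
                cond_means[(f, target)][gi] *= 2.0**lfc
            truth.planted.append((genes[gi], target, lfc))
    else:
        raise ValidationError(f"unknown planted_on {planted_on!r}")
    truth.feature_means = feature_means

    cols: dict[str, np.ndarray] = {}
    meta_rows = []
    for f in features:
        for c in conditions:
            for r in range(1, replicates + 1):
                name = f"{f}__{c}__r{r}" if len(conditions) > 1 else f"{f}__r{r}"
                mult = float(rng.lognormal(mean=0.0, sigma=0.15))
                truth.library_multipliers[name] = mult
                cols[name] = _nb_draw(rng, cond_means[(f, c)] * mult, dispersion)
                meta_rows.append({"feature": f, "condition": c, "replicate": r})
    values = pd.DataFrame(cols, index=genes, dtype=float)
    meta = pd.DataFrame(meta_rows, index=list(cols))
    return AssayTable(values=values, sample_meta=meta, value_space="counts"), truth


# ---------------------------------------------------------------------------
# single cells
# ---------------------------------------------------------------------------

def simulate_cells(
    truth: SimTruth,
    cells_per_group: int = 50,
    spatial: bool = False,
    seed: int = 0,
    dispersion: float = 0.3,
    target_total: float = 20000.0,
) -> SCAssay:
    """Simulate single cells drawn around the bulk feature profiles.

    One cell group per bulk feature: counts are negative-binomial with
    extra dispersion around that feature's true mean profile, rescaled
    so each cell's expected total is ``target_total``.  ``spatial=True``
    places each group inside its own disjoint rectangle (unit grid of
    100 x 100 blocks) with uniform jitter.  Group sources and regions
    are recorded on ``truth``.
    """
    if truth.feature_means is None:
        raise ValidationError("simulate bulk data first (feature_means missing)")
    if cells_per_group < 1:
        raise ValidationError("cells_per_group must be >= 1")
    rng = np.random.default_rng(seed)
    genes = list(truth.feature_means.index)
    features = list(truth.feature_means.columns)
    cols: dict[str, np.ndarray] = {}
    meta_rows = []
    ncolgrid = int(np.ceil(np.sqrt(len(features))))
    for gi, feat in enumerate(features):
        group = f"{feat}_cells"
        truth.sc_group_sources[group] = feat
        profile = truth.feature_means[feat].to_numpy()
        profile = profile * (target_total / profile.sum())
        if spatial:
            r, c = divmod(gi, ncolgrid)
            region = (c * 100.0, r * 100.0, c * 100.0 + 80.0, r * 100.0 + 80.0)
            truth.spatial_layout[group] = region
        for ci in range(cells_per_group):
            name = f"{group}_c{ci + 1}"
            scale = float(rng.lognormal(0.0, 0.2))
            cols[name] = _nb_draw(rng, profile * scale, dispersion)
            row: dict = {"group": group}
            if spatial:
                x0, y0, x1, y1 = truth.spatial_layout[group]
                row["x"] = float(rng.uniform(x0, x1))
                row["y"] = float(rng.uniform(y0, y1))
            meta_rows.append(row)
    values = pd.DataFrame(cols, index=genes, dtype=float)
    meta = pd.DataFrame(meta_rows, index=list(cols))
    return SCAssay(values=values, cell_meta=meta)


# ---------------------------------------------------------------------------
# fixture export (same formats the loaders read)
# ---------------------------------------------------------------------------

def write_bulk_fixture(
    assay: AssayTable, out_dir: str | Path, prefix: str = "bulk"
) -> tuple[Path, Path]:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    mpath = out_dir / f"{prefix}_matrix.tsv"
    assay.values.to_csv(mpath, sep="\t", float_format="%.10g")
    spath = out_dir / f"{prefix}_meta.tsv"
    assay.sample_meta.to_csv(spath, sep="\t", index_label="sample_id")
    return mpath, spath


def write_sc_fixture(
    sc: SCAssay, out_dir: str | Path, prefix: str = "sc"
) -> tuple[Path, Path]:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    mpath = out_dir / f"{prefix}_matrix.tsv"
    sc.values.to_csv(mpath, sep="\t", float_format="%.10g")
    spath = out_dir / f"{prefix}_meta.tsv"
    sc.cell_meta.to_csv(spath, sep="\t", index_label="cell_id")
    return mpath, spath
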