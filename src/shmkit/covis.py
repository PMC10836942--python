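"""Co-visualization of single-cell embeddings with spatial heatmaps.

The link between the two views is a :class:`TissueCellMap`: cell-group
labels associated with anatomical feature ids.  Five mapping routes are
supported -- existing annotations, marker genes from a spatial
enrichment result, manual pair tables, clustering plus a cluster->
feature table, and automated co-clustering of bulk and single-cell
profiles.  Groups that cannot be placed are *orphans* and always render
grey.

Composite figures pair a 2-D embedding scatter (left) with an anatomy
panel (right); matching components share colors.  Spatially resolved
cells can instead be drawn at their registered coordinates directly on
top of the anatomy (scSHM).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .assay import AssayTable, FeatureSampleMap, SCAssay, map_features
from .asvg import FeatureStyle, Shape, SpatialFeature, SVGDoc, combine_docs
from .enrich import EnrichmentResult
from .errors import CapabilityError, ValidationError
from .render import (
    NA_COLOR,
    ColorKey,
    categorical_colors,
    color_of,
    colorize_doc,
    make_color_key,
)

#: orphan cells/groups always render in this grey
ORPHAN_COLOR = "#bfbfbf"


@dataclass
class Embedding:
    """Cells x 2 reduced-dimension coordinates, row order = SCAssay cells."""

    coords: pd.DataFrame  # index: cell ids; columns: dim1, dim2
    method: str
    seed: int = 0
    variance_explained: np.ndarray | None = None

    def __post_init__(self) -> None:
        if not np.isfinite(self.coords.to_numpy()).all():
            raise ValidationError("embedding coordinates must be finite")


@dataclass
class TissueCellMap:
    """Association of cell-group labels with SVG feature ids."""

    pairs: dict[str, str] = field(default_factory=dict)
    orphan_groups: list[str] = field(default_factory=list)
    provenance: str = "manual"

    def __post_init__(self) -> None:
        overlap = set(self.pairs) & set(self.orphan_groups)
        if overlap:
            raise ValidationError(f"groups both mapped and orphan: {sorted(overlap)}")

    def feature_of(self, group: str) -> str | None:
        return self.pairs.get(group)


# ---------------------------------------------------------------------------
# dimensionality reduction
# ---------------------------------------------------------------------------

def reduce_dims(
    sc: SCAssay, method: str = "pca", n_components: int = 2, seed: int = 0
) -> Embedding:
    """Embed cells in 2-D (or more) by PCA, UMAP or t-SNE.

    PCA is the deterministic baseline: centered SVD with each
    component's sign fixed so its largest-magnitude gene loading is
    positive.  UMAP and t-SNE are optional plug-ins (seeded); a missing
    backend raises :class:`CapabilityError`.
    """
    if sc.values.shape[1] < 3:
        raise ValidationError("need at least 3 cells to embed")
    X = sc.values.to_numpy(dtype=float).T  # cells x genes
    cells = list(sc.values.columns)
    if method == "pca":
        Xc = X - X.mean(axis=0, keepdims=True)
        U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
        # sign convention: largest-|loading| entry of each component positive
        for k in range(Vt.shape[0]):
            i = int(np.argmax(np.abs(Vt[k])))
            if Vt[k, i] < 0:
                Vt[k] *= -1.0
                U[:, k] *= -1.0
        coords = U[:, :n_components] * S[:n_components]
        var = S**2 / max(X.shape[0] - 1, 1)
        ve = var[:n_components] / var.sum() if var.sum() > 0 else var[:n_components]
        emb = coords
        variance_explained = ve
    elif method == "umap":
        try:
            import umap
        except ImportError as exc:  # pragma: no cover - optional backend
            raise CapabilityError("umap-learn is not installed") from exc
        emb = umap.UMAP(
            n_components=n_components, random_state=seed
        ).fit_transform(X)
        variance_explained = None
    elif method == "tsne":
        from sklearn.manifold import TSNE

        emb = TSNE(
            n_components=n_components, random_state=seed, perplexity=min(30.0, max(5.0, X.shape[0] / 4)),
            init="pca",
        ).fit_transform(X)
        variance_explained = None
    else:
        raise CapabilityError(f"unknown reduction method {method!r}")
    coords = pd.DataFrame(
        np.asarray(emb, dtype=float),
        index=cells,
        columns=[f"dim{i + 1}" for i in range(n_components)],
    )
    return Embedding(coords=coords, method=method, seed=seed,
                     variance_explained=variance_explained)


# ---------------------------------------------------------------------------
# tissue-cell mapping
# ---------------------------------------------------------------------------

def _log_normalize_sc(sc: SCAssay, target: float = 1e4) -> pd.DataFrame:
    """Library-size normalize cells to ``target`` then log2(x + 1)."""
    vals = sc.values.to_numpy(dtype=float)
    tot = vals.sum(axis=0)
    if (tot == 0).any():
        raise ValidationError("all-zero cell column")
    return pd.DataFrame(
        np.log2(vals * target / tot + 1.0),
        index=sc.values.index,
        columns=sc.values.columns,
    )


def assign_cells(
    sc: SCAssay,
    doc: SVGDoc,
    method: str = "annotation",
    bulk: AssayTable | None = None,
    translation: dict[str, str] | None = None,
    enrichment: EnrichmentResult | None = None,
    manual_pairs: dict[str, str] | None = None,
    cluster_labels: dict[str, str] | None = None,
    cluster_to_feature: dict[str, str] | None = None,
    marker_margin: float = 0.5,
    seed: int = 0,
) -> TissueCellMap:
    """Build the cell-group -> anatomical-feature association.

    Methods: ``annotation`` matches existing group labels (optionally
    through a translation table) against feature ids; ``marker`` scores
    each group by mean log expression of each feature's enriched marker
    set and assigns the argmax feature when it beats the runner-up by
    ``marker_margin`` log2 units; ``manual`` validates verbatim pairs;
    ``cluster`` relabels cells by provided cluster labels and maps them
    through a cluster->feature table; ``cocluster`` delegates to
    :func:`cocluster`.
    """
    svg_ids = set(doc.feature_ids)
    groups = sc.groups
    if method == "annotation":
        fmap: FeatureSampleMap = map_features(groups, doc, translation)
        return TissueCellMap(
            pairs=dict(fmap.pairs),
            orphan_groups=list(fmap.unmatched_assay),
            provenance="annotation",
        )
    if method == "marker":
        if enrichment is None:
            raise ValidationError("marker method needs an EnrichmentResult on bulk")
        logsc = _log_normalize_sc(sc)
        markers = {
            f: [g for g in enrichment.genes(f, "enriched") if g in logsc.index]
            for f in enrichment.query_features
        }
        markers = {f: m for f, m in markers.items() if m and f in svg_ids}
        pairs: dict[str, str] = {}
        orphans: list[str] = []
        for grp in groups:
            cells = sc.cells_of(grp)
            scores = {
                f: float(logsc.loc[m, cells].to_numpy().mean())
                for f, m in markers.items()
            }
            if not scores:
                orphans.append(grp)
                continue
            ranked = sorted(scores.items(), key=lambda kv: (-kv[1], kv[0]))
            if len(ranked) > 1 and ranked[0][1] - ranked[1][1] < marker_margin:
                orphans.append(grp)
            else:
                pairs[grp] = ranked[0][0]
        return TissueCellMap(pairs=pairs, orphan_groups=orphans, provenance="marker")
    if method == "manual":
        if manual_pairs is None:
            raise ValidationError("manual method needs a pairs table")
        bad = sorted(set(manual_pairs.values()) - svg_ids)
        if bad:
            raise ValidationError(f"manual pairs name unknown features: {bad}")
        orphans = [g for g in groups if g not in manual_pairs]
        return TissueCellMap(
            pairs=dict(manual_pairs), orphan_groups=orphans, provenance="manual"
        )
    if method == "cluster":
        if cluster_labels is None or cluster_to_feature is None:
            raise ValidationError(
                "cluster method needs cluster_labels and cluster_to_feature"
            )
        bad = sorted(set(cluster_to_feature.values()) - svg_ids)
        if bad:
            raise ValidationError(f"cluster table names unknown features: {bad}")
        pairs = {}
        orphans = []
        for cl in dict.fromkeys(cluster_labels.values()):
            if cl in cluster_to_feature:
                pairs[cl] = cluster_to_feature[cl]
            else:
                orphans.append(cl)
        return TissueCellMap(pairs=pairs, orphan_groups=orphans, provenance="cluster")
    if method == "cocluster":
        if bulk is None:
            raise ValidationError("cocluster needs the bulk assay")
        return cocluster(bulk, sc, seed=seed)
    raise ValidationError(f"unknown mapping method {method!r}")


def cocluster(
    bulk: AssayTable,
    sc: SCAssay,
    k: int | None = None,
    seed: int = 0,
    min_cor: float = 0.3,
) -> TissueCellMap:
    """Assign cell clusters to source tissues by profile correlation.

    Procedure: intersect genes (>= 50 required); log-normalize both
    sides; k-means (on top PCs, k = number of bulk features by default)
    partitions the cells; each cluster's pseudo-profile (mean log
    expression) is correlated with every bulk feature's mean profile;
    a cluster is assigned to the best-correlated feature when r >=
    ``min_cor``, else it stays orphan.  Cluster groups are named
    ``cc_1..cc_k`` (stable: numbered by first cell).
    """
    shared = [g for g in bulk.gene_ids if g in set(sc.gene_ids)]
    if len(shared) < 50:
        raise ValidationError(f"only {len(shared)} shared genes; need >= 50")
    if len(bulk.features) < 2:
        raise ValidationError("cocluster needs >= 2 bulk features")
    from .assay import aggregate_replicates, normalize

    if bulk.value_space == "counts":
        bulk_log = normalize(bulk, method="cpm", log2=True)
    elif bulk.value_space == "log":
        bulk_log = bulk
    else:
        raise ValidationError("cocluster expects counts or log bulk values")
    feat_means = aggregate_replicates(bulk_log).loc[shared]
    feat_means = feat_means.T.groupby(level="feature", sort=False).mean().T

    logsc = _log_normalize_sc(sc).loc[shared]
    k = k or len(bulk.features)
    from sklearn.cluster import KMeans

    X = logsc.to_numpy(dtype=float).T  # cells x genes
    Xc = X - X.mean(axis=0, keepdims=True)
    U, S, _ = np.linalg.svd(Xc, full_matrices=False)
    npc = min(10, U.shape[1])
    pcs = U[:, :npc] * S[:npc]
    km = KMeans(n_clusters=k, random_state=seed, n_init=10).fit(pcs)
    raw = km.labels_
    # stable naming: clusters numbered by their first cell
    order = {old: i + 1 for i, old in enumerate(dict.fromkeys(raw))}
    names = {old: f"cc_{new}" for old, new in order.items()}

    pairs: dict[str, str] = {}
    orphans: list[str] = []
    assignments: dict[str, str] = {}
    for old, name in names.items():
        members = logsc.columns[raw == old]
        pseudo = logsc[members].mean(axis=1).to_numpy()
        cors = {}
        for f in feat_means.columns:
            fv = feat_means[f].to_numpy()
            if pseudo.std() == 0 or fv.std() == 0:
                cors[f] = -np.inf
            else:
                cors[f] = float(np.corrcoef(pseudo, fv)[0, 1])
        best_f, best_r = max(cors.items(), key=lambda kv: (kv[1], kv[0]))
        if best_r >= min_cor:
            pairs[name] = best_f
        else:
            orphans.append(name)
        for c in members:
            assignments[c] = name
    tcm = TissueCellMap(pairs=pairs, orphan_groups=orphans, provenance="cocluster")
    tcm.cell_clusters = assignments  # per-cell cluster names (extra attribute)
    return tcm


# ---------------------------------------------------------------------------
# coloring schemes
# ---------------------------------------------------------------------------

@dataclass
class CovisColors:
    """Output of :func:`colorize`: per-cell and per-feature colors."""

    cell_colors: pd.Series  # index: cell ids
    feature_colors: dict[str, str]
    key: ColorKey | None = None
    scheme: str = "fixed_by_group"


def _groups_series(sc: SCAssay, tcm: TissueCellMap) -> pd.Series:
    if hasattr(tcm, "cell_clusters"):
        return pd.Series(
            [tcm.cell_clusters.get(c) for c in sc.values.columns],
            index=sc.values.columns,
        )
    if "group" not in sc.cell_meta.columns:
        raise ValidationError("cells lack group labels")
    return sc.cell_meta["group"]


def colorize(
    scheme: str,
    tcm: TissueCellMap,
    sc: SCAssay,
    bulk: AssayTable | None = None,
    gene: str | None = None,
    summary: str = "mean",
    palette: str = "YlOrRd",
    k: int = 10,
) -> CovisColors:
    """Compute matched cell and feature colors for a co-visualization.

    Schemes: ``fixed_by_group`` gives each mapped feature a categorical
    color, applied to its cells; ``cell_by_group`` summarizes the
    gene's single-cell expression per group (mean/median) and colors
    cells *and* matched features through one key; ``feature_by_group``
    colors features by the gene's bulk value and propagates the color
    to their cells; ``cell_by_value`` colors every cell by its own
    value and features by bulk, sharing one key.  Orphan groups are
    always grey.
    """
    groups = _groups_series(sc, tcm)
    cells = list(sc.values.columns)
    if scheme == "fixed_by_group":
        feat_col = categorical_colors([tcm.pairs[g] for g in tcm.pairs])
        cell_colors = pd.Series(
            [
                feat_col.get(tcm.pairs.get(groups[c], ""), ORPHAN_COLOR)
                if groups[c] in tcm.pairs
                else ORPHAN_COLOR
                for c in cells
            ],
            index=cells,
        )
        return CovisColors(cell_colors, feat_col, None, scheme)
    if gene is None:
        raise ValidationError(f"scheme {scheme!r} needs a gene")
    if scheme in ("feature_by_group", "cell_by_value") and bulk is None:
        raise ValidationError(f"scheme {scheme!r} needs bulk data")
    if gene not in sc.values.index:
        raise ValidationError(f"gene {gene!r} not in single-cell matrix")
    logsc = _log_normalize_sc(sc)
    gvals = logsc.loc[gene]

    def bulk_feature_values() -> dict[str, float]:
        from .assay import aggregate_replicates, normalize

        b = bulk
        if b.value_space == "counts":
            b = normalize(b, method="cpm", log2=True)
        agg = aggregate_replicates(b)
        if gene not in agg.index:
            raise ValidationError(f"gene {gene!r} not in bulk matrix")
        per_feat = agg.loc[gene].groupby(level="feature").mean()
        return {f: float(v) for f, v in per_feat.items()}

    if scheme == "cell_by_group":
        stat = {"mean": np.mean, "median": np.median}.get(summary)
        if stat is None:
            raise ValidationError(f"unknown summary {summary!r}")
        grp_val = {
            g: float(stat(gvals[sc.cells_of(g)].to_numpy()))
            for g in dict.fromkeys(groups.dropna())
        }
        key = make_color_key(list(grp_val.values()), palette=palette, k=k)
        feat_colors = {
            tcm.pairs[g]: color_of(key, v)
            for g, v in grp_val.items()
            if g in tcm.pairs
        }
        cell_colors = pd.Series(
            [
                color_of(key, grp_val[groups[c]])
                if groups[c] in tcm.pairs
                else ORPHAN_COLOR
                for c in cells
            ],
            index=cells,
        )
        return CovisColors(cell_colors, feat_colors, key, scheme)
    if scheme == "feature_by_group":
        fv = bulk_feature_values()
        key = make_color_key(list(fv.values()), palette=palette, k=k)
        feat_colors = {f: color_of(key, v) for f, v in fv.items()}
        cell_colors = pd.Series(
            [
                feat_colors.get(tcm.pairs.get(groups[c], ""), ORPHAN_COLOR)
                if groups[c] in tcm.pairs and tcm.pairs[groups[c]] in feat_colors
                else ORPHAN_COLOR
                for c in cells
            ],
            index=cells,
        )
        return CovisColors(cell_colors, feat_colors, key, scheme)
    if scheme == "cell_by_value":
        fv = bulk_feature_values()
        key = make_color_key(
            list(gvals.to_numpy()) + list(fv.values()), palette=palette, k=k
        )
        feat_colors = {f: color_of(key, v) for f, v in fv.items()}
        cell_colors = pd.Series(
            [
                color_of(key, float(gvals[c]))
                if groups[c] in tcm.pairs
                else ORPHAN_COLOR
                for c in cells
            ],
            index=cells,
        )
        return CovisColors(cell_colors, feat_colors, key, scheme)
    raise ValidationError(f"unknown coloring scheme {scheme!r}")


# ---------------------------------------------------------------------------
# composite rendering
# ---------------------------------------------------------------------------

def _embedding_doc(
    embedding: Embedding,
    cell_colors: pd.Series,
    width: float = 300.0,
    height: float = 300.0,
    dot_r: float = 3.0,
) -> SVGDoc:
    """Scatter of embedding coordinates as an SVG document.

    Each cell becomes a circle feature (id = cell id); the y axis is
    flipped so the mathematical y-up embedding reads naturally in SVG's
    y-down frame.
    """
    coords = embedding.coords.to_numpy(dtype=float)[:, :2]
    lo = coords.min(axis=0)
    hi = coords.max(axis=0)
    span = np.where(hi - lo > 0, hi - lo, 1.0)
    pad = 0.06
    feats = []
    for i, cell in enumerate(embedding.coords.index):
        fx = (coords[i, 0] - lo[0]) / span[0]
        fy = (coords[i, 1] - lo[1]) / span[1]
        x = (pad + fx * (1 - 2 * pad)) * width
        y = (pad + (1.0 - fy) * (1 - 2 * pad)) * height
        feats.append(
            SpatialFeature(
                id=str(cell),
                shapes=[Shape("circle", {"cx": f"{x:.2f}", "cy": f"{y:.2f}",
                                         "r": f"{dot_r:.2f}"})],
                layer_index=i,
                style=FeatureStyle(fill=str(cell_colors[cell]), stroke="none"),
            )
        )
    return SVGDoc(features=feats, width=width, height=height)


@dataclass
class CovisFigure:
    """Composite co-visualization: embedding panel + anatomy panel."""

    composite: SVGDoc
    embedding_panel: SVGDoc
    shm_panel: SVGDoc
    colors: CovisColors

    def save(self, out_dir: str | Path, png: bool = True, dpi: int = 150) -> list[Path]:
        from .asvg import write_svg
        from .render import rasterize, write_key_svg

        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        written = []
        for name, doc in (
            ("covis.svg", self.composite),
            ("embedding_panel.svg", self.embedding_panel),
            ("shm_panel.svg", self.shm_panel),
        ):
            write_svg(doc, out_dir / name)
            written.append(out_dir / name)
        if self.colors.key is not None:
            write_key_svg(self.colors.key, out_dir / "key.svg")
            written.append(out_dir / "key.svg")
        if png:
            rasterize(self.composite, out_dir / "covis.png", dpi=dpi)
            written.append(out_dir / "covis.png")
        return written


def render_covis(
    doc: SVGDoc,
    embedding: Embedding,
    colors: CovisColors,
    tcm: TissueCellMap,
) -> CovisFigure:
    """Assemble the composite figure: embedding scatter + colored SHM.

    Feature fills come from ``colors.feature_colors``; unmapped
    features keep their original fill.  Matching components share
    colors by construction of :func:`colorize`.
    """
    cells = list(embedding.coords.index)
    missing = [c for c in cells if c not in colors.cell_colors.index]
    if missing:
        raise ValidationError(f"cells without colors: {missing[:5]}")
    emb_doc = _embedding_doc(embedding, colors.cell_colors,
                             width=doc.width, height=doc.height)
    shm_doc = colorize_doc(doc, colors.feature_colors)
    composite = combine_docs([emb_doc, shm_doc], arrangement="horizontal")
    return CovisFigure(
        composite=composite,
        embedding_panel=emb_doc,
        shm_panel=shm_doc,
        colors=colors,
    )


def render_scshm(
    doc: SVGDoc,
    sc: SCAssay,
    target_feature: str,
    cell_colors: pd.Series,
    plotted_cells: list[str] | None = None,
    dot_r: float = 1.5,
) -> SVGDoc:
    """Overlay spatially resolved cells onto an anatomical feature.

    Cell coordinates are registered into the target feature's bounding
    box by a uniform-scale affine map (aspect preserved, centers
    aligned), so relative pairwise distances survive up to one global
    scale.  Cells outside ``plotted_cells`` (when given) render grey.
    """
    if target_feature not in doc.feature_ids:
        raise ValidationError(f"unknown target feature {target_feature!r}")
    if "x" not in sc.cell_meta.columns:
        raise ValidationError("cells lack spatial coordinates")
    cells = list(sc.values.columns)
    missing = [c for c in cells if pd.isna(sc.cell_meta.loc[c, "x"])
               or pd.isna(sc.cell_meta.loc[c, "y"])]
    if missing:
        raise ValidationError(f"cells without coordinates: {missing[:5]}")
    xy = sc.cell_meta[["x", "y"]].to_numpy(dtype=float)
    x0, y0 = xy.min(axis=0)
    x1, y1 = xy.max(axis=0)
    fx0, fy0, fx1, fy1 = doc[target_feature].bbox()
    cw, ch = max(x1 - x0, 1e-12), max(y1 - y0, 1e-12)
    s = min((fx1 - fx0) / cw, (fy1 - fy0) / ch)
    ccx, ccy = (x0 + x1) / 2, (y0 + y1) / 2
    fcx, fcy = (fx0 + fx1) / 2, (fy0 + fy1) / 2

    out = doc.copy()
    plotted = set(plotted_cells) if plotted_cells is not None else set(cells)
    base = len(out.features)
    for i, cell in enumerate(cells):
        x = fcx + s * (xy[i, 0] - ccx)
        y = fcy + s * (xy[i, 1] - ccy)
        color = str(cell_colors[cell]) if cell in plotted else ORPHAN_COLOR
        out.features.append(
            SpatialFeature(
                id=f"cell__{cell}",
                shapes=[Shape("circle", {"cx": f"{x:.3f}", "cy": f"{y:.3f}",
                                         "r": f"{dot_r:.2f}"})],
                layer_index=base + i,
                style=FeatureStyle(fill=color, stroke="none"),
            )
        )
    return out


def deconv_view(
    bulk: AssayTable,
    cell_type_expr: pd.DataFrame,
    proportions: dict[str, float],
    gene: str,
    doc: SVGDoc,
    fmap: FeatureSampleMap,
    palette: str = "YlOrRd",
    k: int = 10,
) -> CovisFigure:
    """Co-visualize bulk data with deconvolution-inferred cell types.

    ``cell_type_expr`` is a genes x cell-types expression table (as
    produced by a deconvolution method); ``proportions`` are the
    estimated cell-type fractions (must sum to 1).  Cell types are laid
    out by PCA of their expression profiles, colored cell-by-value for
    ``gene``, with the proportion printed (2 decimals) beside each
    type; the right panel is the SHM of the same gene from bulk.
    """
    tot = sum(proportions.values())
    if abs(tot - 1.0) > 1e-6:
        raise ValidationError(f"proportions sum to {tot}, not 1")
    types = list(cell_type_expr.columns)
    if set(types) != set(proportions):
        raise ValidationError("proportions and expression columns disagree")
    if gene not in cell_type_expr.index:
        raise ValidationError(f"gene {gene!r} not in cell-type expression")

    from .assay import aggregate_replicates, normalize

    b = bulk
    if b.value_space == "counts":
        b = normalize(b, method="cpm", log2=True)
    agg = aggregate_replicates(b)
    per_feat = agg.loc[gene].groupby(level="feature").mean()
    fv = {fmap.pairs[f]: float(v) for f, v in per_feat.items() if f in fmap.pairs}

    tvals = cell_type_expr.loc[gene]
    key = make_color_key(
        list(tvals.to_numpy()) + list(fv.values()), palette=palette, k=k
    )
    # position cell types by PCA of their full profiles
    X = cell_type_expr.to_numpy(dtype=float).T
    Xc = X - X.mean(axis=0, keepdims=True)
    U, S, _ = np.linalg.svd(Xc, full_matrices=False)
    ncomp = min(2, U.shape[1])
    coords = np.zeros((len(types), 2))
    coords[:, :ncomp] = U[:, :ncomp] * S[:ncomp]

    width, height = doc.width, doc.height
    lo, hi = coords.min(axis=0), coords.max(axis=0)
    span = np.where(hi - lo > 0, hi - lo, 1.0)
    feats = []
    for i, t in enumerate(types):
        fx = (coords[i, 0] - lo[0]) / span[0]
        fy = (coords[i, 1] - lo[1]) / span[1]
        x = (0.1 + fx * 0.8) * width
        y = (0.1 + (1 - fy) * 0.8) * height
        feats.append(
            SpatialFeature(
                id=f"type__{t}",
                shapes=[Shape("circle", {"cx": f"{x:.2f}", "cy": f"{y:.2f}", "r": "8"})],
                layer_index=i,
                style=FeatureStyle(
                    fill=color_of(key, float(tvals[t])), stroke="#333333",
                    extra={"data-proportion": f"{proportions[t]:.2f}"},
                ),
            )
        )
    emb_doc = SVGDoc(features=feats, width=width, height=height)
    shm_doc = colorize_doc(doc, fv)
    composite = combine_docs([emb_doc, shm_doc], arrangement="horizontal")
    colors = CovisColors(
        cell_colors=pd.Series({t: color_of(key, float(tvals[t])) for t in types}),
        feature_colors=fv,
        key=key,
        scheme="cell_by_value",
    )
    return CovisFigure(
        composite=composite, embedding_panel=emb_doc, shm_panel=shm_doc, colors=colors
    )
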