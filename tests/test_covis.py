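"""Co-visualization: embeddings, tissue-cell maps, coloring, scSHM geometry."""

import numpy as np
import pandas as pd
import pytest

from shmkit.assay import SCAssay
from shmkit.asvg import parse_asvg
from shmkit.covis import (
    ORPHAN_COLOR,
    TissueCellMap,
    assign_cells,
    cocluster,
    colorize,
    deconv_view,
    reduce_dims,
    render_covis,
    render_scshm,
)
from shmkit.errors import ValidationError

FEATURES = ["brain", "liver", "lung", "kidney", "colon"]


def _sc_from(values: np.ndarray, groups=None, xy=None) -> SCAssay:
    n_genes, n_cells = values.shape
    cells = [f"c{i}" for i in range(n_cells)]
    meta = pd.DataFrame(index=cells)
    if groups is not None:
        meta["group"] = groups
    if xy is not None:
        meta["x"] = xy[:, 0]
        meta["y"] = xy[:, 1]
    return SCAssay(
        values=pd.DataFrame(
            values, index=[f"g{i}" for i in range(n_genes)], columns=cells
        ),
        cell_meta=meta,
    )


class TestReduceDims:
    def test_line_data_rank_one(self):
        t = np.linspace(0, 1, 10)
        vals = np.outer(np.array([1.0, 2.0, -1.0, 0.5]), t) + 3.0
        emb = reduce_dims(_sc_from(vals), "pca")
        assert emb.variance_explained[0] >= 0.999

    def test_duplicated_cells_identical_rows(self):
        rng = np.random.default_rng(1)
        vals = rng.normal(size=(20, 6))
        vals[:, 3] = vals[:, 0]
        emb = reduce_dims(_sc_from(vals), "pca")
        assert np.allclose(emb.coords.iloc[0], emb.coords.iloc[3])

    def test_pca_deterministic_and_sign_fixed(self):
        rng = np.random.default_rng(2)
        vals = rng.normal(size=(30, 12))
        e1 = reduce_dims(_sc_from(vals), "pca")
        e2 = reduce_dims(_sc_from(vals), "pca")
        assert np.array_equal(e1.coords.to_numpy(), e2.coords.to_numpy())

    def test_group_centroids_separate(self):
        """Three well-separated expression programs split cleanly in PC space."""
        from shmkit.simulate import simulate_bulk, simulate_cells

        _, truth = simulate_bulk(
            200, ["f1", "f2", "f3"], replicates=2, planted_frac=0.5, lfc=4.0,
            seed=42,
        )
        sc = simulate_cells(truth, cells_per_group=30, seed=43)
        emb = reduce_dims(sc, "pca")
        coords = emb.coords.to_numpy()
        groups = sc.cell_meta["group"].to_numpy()
        cents, spreads = [], []
        for g in dict.fromkeys(groups):
            pts = coords[groups == g]
            cents.append(pts.mean(axis=0))
            spreads.append(pts.std(axis=0).mean())
        cents = np.array(cents)
        for i in range(len(cents)):
            for j in range(i + 1, len(cents)):
                dist = np.linalg.norm(cents[i] - cents[j])
                assert dist >= 2 * max(spreads[i], spreads[j])

    def test_unknown_method_is_capability_error(self):
        from shmkit.errors import CapabilityError

        vals = np.random.default_rng(0).normal(size=(5, 4))
        with pytest.raises(CapabilityError):
            reduce_dims(_sc_from(vals), "isomap")


class TestAssignCells:
    def test_annotation_total_mapping(self, sc_sim, toy_doc):
        sc, _ = sc_sim
        translation = {f"{f}_cells": f for f in FEATURES}
        tcm = assign_cells(sc, toy_doc, method="annotation", translation=translation)
        assert len(tcm.pairs) == 5 and not tcm.orphan_groups

    def test_marker_assignment_recovers_sources(self, sc_sim, toy_doc, log_assay):
        from shmkit.enrich import spatial_enrichment

        sc, truth = sc_sim
        res = spatial_enrichment(log_assay, FEATURES, outliers=0)
        tcm = assign_cells(sc, toy_doc, method="marker", enrichment=res)
        assert tcm.provenance == "marker"
        for group, feat in tcm.pairs.items():
            assert truth.sc_group_sources[group] == feat
        assert set(tcm.pairs) | set(tcm.orphan_groups) == set(sc.groups)

    def test_marker_margin_tie_orphans_both(self, toy_doc):
        """Two groups with identical marker scores fall below the margin."""
        from shmkit.enrich import EnrichmentResult

        vals = np.full((60, 8), 32.0)
        groups = ["u"] * 4 + ["v"] * 4
        sc = _sc_from(vals, groups=groups)
        res = EnrichmentResult(
            query_features=["brain", "liver"],
            enriched={
                "brain": pd.DataFrame(
                    {"gene": ["g0", "g1"], "lfc": 2.0, "padj": 0.01, "n_support": 1}
                ),
                "liver": pd.DataFrame(
                    {"gene": ["g2", "g3"], "lfc": 2.0, "padj": 0.01, "n_support": 1}
                ),
            },
            depleted={"brain": pd.DataFrame(columns=["gene"]),
                      "liver": pd.DataFrame(columns=["gene"])},
        )
        tcm = assign_cells(sc, toy_doc, method="marker", enrichment=res)
        assert set(tcm.orphan_groups) == {"u", "v"} and not tcm.pairs

    def test_manual_unknown_feature_rejected(self, sc_sim, toy_doc):
        sc, _ = sc_sim
        with pytest.raises(ValidationError, match="spleen"):
            assign_cells(sc, toy_doc, method="manual",
                         manual_pairs={"brain_cells": "spleen"})

    def test_marker_needs_enrichment(self, sc_sim, toy_doc):
        sc, _ = sc_sim
        with pytest.raises(ValidationError):
            assign_cells(sc, toy_doc, method="marker")


class TestCocluster:
    def test_groups_assigned_to_source_features(self, log_assay, sc_sim):
        sc, truth = sc_sim
        tcm = cocluster(log_assay, sc, seed=5)
        assert not tcm.orphan_groups
        # every cell cluster maps to the source feature of its majority group
        groups = sc.cell_meta["group"]
        for cluster, feat in tcm.pairs.items():
            members = [c for c, cl in tcm.cell_clusters.items() if cl == cluster]
            majority = groups[members].mode()[0]
            assert truth.sc_group_sources[majority] == feat

    def test_uncorrelated_group_is_orphan(self, log_assay):
        rng = np.random.default_rng(6)
        genes = list(log_assay.values.index)
        vals = rng.permutation(
            rng.lognormal(3, 1, size=(len(genes), 60)), axis=0
        )
        cells = [f"n{i}" for i in range(60)]
        sc = SCAssay(
            values=pd.DataFrame(vals, index=genes, columns=cells),
            cell_meta=pd.DataFrame({"group": ["noise"] * 60}, index=cells),
        )
        tcm = cocluster(log_assay, sc, k=1, seed=7)
        assert tcm.orphan_groups == ["cc_1"] and not tcm.pairs

    def test_k1_single_cluster_best_feature(self, log_assay, sc_sim):
        sc, _ = sc_sim
        tcm = cocluster(log_assay, sc, k=1, seed=5)
        assert len(tcm.pairs) + len(tcm.orphan_groups) == 1

    def test_too_few_shared_genes_rejected(self, log_assay):
        vals = np.ones((10, 5))
        sc = _sc_from(vals)
        with pytest.raises(ValidationError, match="shared genes"):
            cocluster(log_assay, sc)


@pytest.fixture()
def simple_setup(sc_sim, toy_doc):
    sc, truth = sc_sim
    translation = {f"{f}_cells": f for f in FEATURES}
    tcm = assign_cells(sc, toy_doc, method="annotation", translation=translation)
    return sc, tcm


class TestColorize:
    def test_fixed_by_group_distinct_colors(self, simple_setup):
        sc, tcm = simple_setup
        out = colorize("fixed_by_group", tcm, sc)
        assert len(set(out.feature_colors.values())) == 5
        assert ORPHAN_COLOR not in out.cell_colors.values

    def test_orphans_grey_in_every_scheme(self, simple_setup, log_assay):
        sc, tcm = simple_setup
        partial = TissueCellMap(
            pairs={k: v for k, v in list(tcm.pairs.items())[:3]},
            orphan_groups=list(tcm.pairs)[3:],
            provenance="manual",
        )
        orphan_cells = [
            c for c in sc.values.columns
            if sc.cell_meta.loc[c, "group"] in partial.orphan_groups
        ]
        for scheme in ("fixed_by_group", "cell_by_group", "feature_by_group",
                       "cell_by_value"):
            out = colorize(scheme, partial, sc, bulk=log_assay, gene="g1")
            assert (out.cell_colors[orphan_cells] == ORPHAN_COLOR).all()

    def test_cell_by_group_mean_rule(self, toy_doc):
        vals = np.full((60, 4), 0.0)
        vals[0] = [3.0, 15.0, 3.0, 15.0]  # g0 counts differ within group
        vals[1:] = 1.0
        sc = _sc_from(vals, groups=["u", "u", "u", "u"])
        tcm = TissueCellMap(pairs={"u": "brain"}, provenance="manual")
        out = colorize("cell_by_group", tcm, sc, gene="g0")
        assert len(set(out.cell_colors)) == 1
        assert out.feature_colors["brain"] == out.cell_colors.iloc[0]

    def test_schemes_agree_when_groups_constant(self, toy_doc, log_assay):
        """cell_by_group == cell_by_value when all cells in a group share
        one value."""
        n_cells = 8
        genes = list(log_assay.values.index)
        vals = np.ones((len(genes), n_cells))
        vals[0, :4], vals[0, 4:] = 10.0, 200.0
        cells = [f"c{i}" for i in range(n_cells)]
        sc = SCAssay(
            values=pd.DataFrame(vals, index=genes, columns=cells),
            cell_meta=pd.DataFrame(
                {"group": ["u"] * 4 + ["v"] * 4}, index=cells
            ),
        )
        tcm = TissueCellMap(pairs={"u": "brain", "v": "liver"}, provenance="manual")
        by_group = colorize("cell_by_group", tcm, sc, bulk=log_assay, gene=genes[0])
        by_value = colorize("cell_by_value", tcm, sc, bulk=log_assay, gene=genes[0])
        # within each group the per-cell color equals the group color
        for cs in (by_group, by_value):
            assert len(set(cs.cell_colors[:4])) == 1
            assert len(set(cs.cell_colors[4:])) == 1

    def test_gene_required(self, simple_setup):
        sc, tcm = simple_setup
        with pytest.raises(ValidationError):
            colorize("cell_by_group", tcm, sc)


class TestRenderCovis:
    def test_matching_colors_after_svg_roundtrip(self, simple_setup, toy_doc,
                                                 tmp_path):
        sc, tcm = simple_setup
        emb = reduce_dims(sc, "pca")
        colors = colorize("fixed_by_group", tcm, sc)
        fig = render_covis(toy_doc, emb, colors, tcm)
        fig.save(tmp_path, png=False)
        shm = parse_asvg(tmp_path / "shm_panel.svg")
        embp = parse_asvg(tmp_path / "embedding_panel.svg")
        groups = sc.cell_meta["group"]
        for cell in sc.values.columns:
            grp = groups[cell]
            cell_fill = embp[cell].style.fill
            assert cell_fill == shm[tcm.pairs[grp]].style.fill

    def test_no_orphans_no_grey(self, simple_setup, toy_doc):
        sc, tcm = simple_setup
        emb = reduce_dims(sc, "pca")
        colors = colorize("fixed_by_group", tcm, sc)
        fig = render_covis(toy_doc, emb, colors, tcm)
        fills = [f.style.fill for f in fig.embedding_panel.features]
        assert ORPHAN_COLOR not in fills

    def test_single_cell_renders(self, toy_doc):
        vals = np.ones((5, 1)) * [[1], [2], [3], [4], [5]]
        sc = _sc_from(vals, groups=["u"])
        coords = pd.DataFrame([[0.0, 0.0]], index=["c0"], columns=["dim1", "dim2"])
        from shmkit.covis import Embedding

        emb = Embedding(coords=coords, method="pca")
        tcm = TissueCellMap(pairs={"u": "brain"}, provenance="manual")
        colors = colorize("fixed_by_group", tcm, sc)
        fig = render_covis(toy_doc, emb, colors, tcm)
        assert len(fig.embedding_panel.features) == 1


class TestScSHM:
    def _spatial_sc(self, n=30, seed=3):
        rng = np.random.default_rng(seed)
        xy = rng.uniform(0, 50, size=(n, 2))
        vals = rng.poisson(5, size=(10, n)).astype(float)
        return _sc_from(vals, groups=["u"] * n, xy=xy), xy

    def test_center_maps_to_center_and_inside_bbox(self, toy_doc):
        sc, xy = self._spatial_sc()
        # put one cell exactly at the bbox center
        cx = (xy[:, 0].min() + xy[:, 0].max()) / 2
        cy = (xy[:, 1].min() + xy[:, 1].max()) / 2
        sc.cell_meta.loc["c0", ["x", "y"]] = (cx, cy)
        colors = pd.Series("#ff0000", index=sc.values.columns)
        out = render_scshm(toy_doc, sc, "liver", colors)
        fx0, fy0, fx1, fy1 = toy_doc["liver"].bbox()
        dots = {
            f.id.removeprefix("cell__"): (
                float(f.shapes[0].attrs["cx"]), float(f.shapes[0].attrs["cy"])
            )
            for f in out.features
            if f.id.startswith("cell__")
        }
        assert dots["c0"][0] == pytest.approx((fx0 + fx1) / 2, abs=1e-6)
        assert dots["c0"][1] == pytest.approx((fy0 + fy1) / 2, abs=1e-6)
        for x, y in dots.values():
            assert fx0 - 1e-6 <= x <= fx1 + 1e-6
            assert fy0 - 1e-6 <= y <= fy1 + 1e-6

    def test_relative_distances_preserved_to_global_scale(self, toy_doc):
        sc, xy = self._spatial_sc(seed=9)
        colors = pd.Series("#ff0000", index=sc.values.columns)
        out = render_scshm(toy_doc, sc, "brain", colors)
        dots = np.array(
            [
                (float(f.shapes[0].attrs["cx"]), float(f.shapes[0].attrs["cy"]))
                for f in out.features
                if f.id.startswith("cell__")
            ]
        )
        d_in = np.linalg.norm(xy[:, None] - xy[None, :], axis=2)
        d_out = np.linalg.norm(dots[:, None] - dots[None, :], axis=2)
        mask = d_in > 1e-9
        ratio = d_out[mask] / d_in[mask]
        # dot coordinates are written at 3 decimals; allow that quantization
        assert ratio.std() / ratio.mean() < 1e-3

    def test_grey_vs_colored_counts(self, toy_doc, tmp_path):
        from shmkit.asvg import write_svg

        sc, _ = self._spatial_sc(n=20, seed=5)
        colors = pd.Series("#ff0000", index=sc.values.columns)
        plotted = list(sc.values.columns[:8])
        out = render_scshm(toy_doc, sc, "lung", colors, plotted_cells=plotted)
        p = tmp_path / "scshm.svg"
        write_svg(out, p)
        back = parse_asvg(p)
        fills = [
            f.style.fill for f in back.features if f.id.startswith("cell__")
        ]
        assert fills.count("#ff0000") == 8
        assert fills.count(ORPHAN_COLOR) == 12

    def test_missing_coordinates_listed(self, toy_doc):
        sc, _ = self._spatial_sc(n=5)
        sc.cell_meta.loc["c2", "x"] = np.nan
        colors = pd.Series("#ff0000", index=sc.values.columns)
        with pytest.raises(ValidationError, match="c2"):
            render_scshm(toy_doc, sc, "brain", colors)

    def test_unknown_target_rejected(self, toy_doc):
        sc, _ = self._spatial_sc(n=5)
        colors = pd.Series("#ff0000", index=sc.values.columns)
        with pytest.raises(ValidationError):
            render_scshm(toy_doc, sc, "nope", colors)


class TestDeconvView:
    def _inputs(self, log_assay, toy_doc, fmap, n_types=6):
        rng = np.random.default_rng(4)
        genes = list(log_assay.values.index)[:50]
        expr = pd.DataFrame(
            rng.lognormal(2, 1, size=(50, n_types)),
            index=genes,
            columns=[f"t{i}" for i in range(n_types)],
        )
        props = {f"t{i}": 1.0 / n_types for i in range(n_types)}
        return expr, props

    def test_six_types_labeled_with_proportions(self, log_assay, toy_doc, fmap):
        expr, props = self._inputs(log_assay, toy_doc, fmap)
        fig = deconv_view(log_assay, expr, props, "g1", toy_doc, fmap)
        dots = [f for f in fig.embedding_panel.features if f.id.startswith("type__")]
        assert len(dots) == 6
        labels = {f.style.extra.get("data-proportion") for f in dots}
        assert labels == {"0.17"}

    def test_equal_halves_print_050(self, log_assay, toy_doc, fmap):
        expr, _ = self._inputs(log_assay, toy_doc, fmap, n_types=2)
        fig = deconv_view(
            log_assay, expr, {"t0": 0.5, "t1": 0.5}, "g1", toy_doc, fmap
        )
        labels = [
            f.style.extra["data-proportion"]
            for f in fig.embedding_panel.features
        ]
        assert labels == ["0.50", "0.50"]

    def test_bad_proportions_rejected(self, log_assay, toy_doc, fmap):
        expr, _ = self._inputs(log_assay, toy_doc, fmap, n_types=2)
        with pytest.raises(ValidationError, match="sum"):
            deconv_view(log_assay, expr, {"t0": 0.7, "t1": 0.2}, "g1",
                        toy_doc, fmap)
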