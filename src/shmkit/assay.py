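"""Bulk and single-cell assay containers and their standard transforms.

Bulk data live in an :class:`AssayTable`: a genes x samples matrix with
per-sample metadata (spatial-feature label, condition label, replicate)
and an explicit ``value_space`` tag (``counts`` | ``normalized`` |
``log`` | ``lfc``) so downstream code always knows what scale it is
looking at.  Single-cell data live in an :class:`SCAssay` with per-cell
group labels and optional spatial x/y coordinates.

Normalization is median-of-ratios size factors (the standard RNA-seq
library-size estimator) or counts-per-million, optionally followed by
log2(x + pseudo).  ``relative_values`` turns a log-space table into
treatment-vs-control log2 fold changes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .asvg import SVGDoc
from .errors import ValidationError

VALUE_SPACES = ("counts", "normalized", "log", "lfc")


@dataclass
class AssayTable:
    """Genes x samples numeric matrix plus sample metadata.

    ``sample_meta`` is indexed by sample id, row order matching the
    matrix columns, with columns ``feature`` (spatial-feature label),
    ``condition`` and ``replicate``.
    """

    values: pd.DataFrame  # genes x samples
    sample_meta: pd.DataFrame
    value_space: str = "counts"

    def __post_init__(self) -> None:
        if self.value_space not in VALUE_SPACES:
            raise ValidationError(f"unknown value_space {self.value_space!r}")
        if list(self.values.columns) != list(self.sample_meta.index):
            raise ValidationError("matrix columns and metadata rows disagree")
        for col in ("feature", "condition", "replicate"):
            if col not in self.sample_meta.columns:
                raise ValidationError(f"sample_meta lacks column {col!r}")
        if self.value_space == "counts" and (self.values.to_numpy() < 0).any():
            raise ValidationError("counts space requires non-negative values")
        triples = self.sample_meta[["feature", "condition", "replicate"]]
        if triples.duplicated().any():
            dup = triples[triples.duplicated()].iloc[0].tolist()
            raise ValidationError(
                f"(feature, condition, replicate) triple not unique: {dup}"
            )

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def features(self) -> list[str]:
        """Distinct feature labels in metadata order."""
        return list(dict.fromkeys(self.sample_meta["feature"]))

    @property
    def conditions(self) -> list[str]:
        return list(dict.fromkeys(self.sample_meta["condition"]))

    def samples_of(self, feature: str | None = None, condition: str | None = None) -> list[str]:
        m = self.sample_meta
        mask = pd.Series(True, index=m.index)
        if feature is not None:
            mask &= m["feature"] == feature
        if condition is not None:
            mask &= m["condition"] == condition
        return list(m.index[mask])


@dataclass
class SCAssay:
    """Genes x cells matrix with per-cell metadata.

    ``cell_meta`` is indexed by cell id with optional columns ``group``
    (cell-group label) and spatial coordinates ``x``/``y`` (set
    together or not at all).
    """

    values: pd.DataFrame  # genes x cells
    cell_meta: pd.DataFrame

    def __post_init__(self) -> None:
        if list(self.values.columns) != list(self.cell_meta.index):
            raise ValidationError("matrix columns and cell metadata rows disagree")
        if self.cell_meta.index.duplicated().any():
            raise ValidationError("cell ids not unique")
        has_x = "x" in self.cell_meta.columns
        has_y = "y" in self.cell_meta.columns
        if has_x != has_y:
            raise ValidationError("spatial coordinates need both x and y")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def groups(self) -> list[str]:
        if "group" not in self.cell_meta.columns:
            return []
        return list(dict.fromkeys(self.cell_meta["group"].dropna()))

    def cells_of(self, group: str) -> list[str]:
        return list(self.cell_meta.index[self.cell_meta["group"] == group])


@dataclass
class FeatureSampleMap:
    """Resolved assay-label to SVG-feature-id associations."""

    pairs: dict[str, str] = field(default_factory=dict)
    unmatched_assay: list[str] = field(default_factory=list)
    unmatched_svg: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# loading
# ---------------------------------------------------------------------------

def _read_table(path: str | Path, **kw) -> pd.DataFrame:
    sep = "," if str(path).endswith(".csv") else "\t"
    return pd.read_csv(path, sep=sep, **kw)


def load_assay(
    matrix_path: str | Path,
    meta_path: str | Path,
    value_space: str = "counts",
) -> AssayTable:
    """Load a bulk matrix (genes x samples TSV/CSV) plus sample metadata.

    The matrix header names the samples; the first column holds gene
    ids.  Metadata is keyed by sample id with columns ``feature``,
    optional ``condition`` (default ``"all"``) and optional
    ``replicate`` (auto-numbered 1..n within each (feature, condition)
    when absent).  Only samples present in both files are kept, in
    matrix column order.
    """
    mat = _read_table(matrix_path, index_col=0)
    bad = mat.columns[~mat.apply(lambda c: pd.to_numeric(c, errors="coerce").notna().all())]
    if len(bad):
        col = bad[0]
        row = mat.index[pd.to_numeric(mat[col], errors="coerce").isna()][0]
        raise ValidationError(f"non-numeric value at gene {row!r}, sample {col!r}")
    mat = mat.astype(float)

    meta = _read_table(meta_path, index_col=0)
    meta.index = meta.index.astype(str)
    mat.columns = mat.columns.astype(str)
    only_mat = sorted(set(mat.columns) - set(meta.index))
    only_meta = sorted(set(meta.index) - set(mat.columns))
    if only_mat:
        raise ValidationError(
            f"samples missing from metadata: {only_mat}"
            + (f"; metadata-only samples: {only_meta}" if only_meta else "")
        )
    meta = meta.loc[list(mat.columns)]
    if "feature" not in meta.columns:
        raise ValidationError("metadata needs a 'feature' column")
    if "condition" not in meta.columns:
        meta["condition"] = "all"
    if "replicate" not in meta.columns:
        meta["replicate"] = (
            meta.groupby(["feature", "condition"], sort=False).cumcount() + 1
        )
    meta["replicate"] = meta["replicate"].astype(int)
    return AssayTable(values=mat, sample_meta=meta, value_space=value_space)


def load_sc_assay(
    matrix_path: str | Path,
    meta_path: str | Path | None = None,
) -> SCAssay:
    """Load a single-cell matrix from dense TSV/CSV or an MTX triplet.

    For MTX input, ``genes.tsv`` and ``barcodes.tsv`` sidecars are
    expected next to the matrix file.  Metadata (optional) is keyed by
    cell id with columns ``group`` and optionally ``x``, ``y``.
    """
    matrix_path = Path(matrix_path)
    if matrix_path.suffix == ".mtx":
        from scipy.io import mmread

        m = mmread(str(matrix_path)).toarray()
        genes = (
            pd.read_csv(matrix_path.parent / "genes.tsv", sep="\t", header=None)
            .iloc[:, 0].astype(str).tolist()
        )
        cells = (
            pd.read_csv(matrix_path.parent / "barcodes.tsv", sep="\t", header=None)
            .iloc[:, 0].astype(str).tolist()
        )
        mat = pd.DataFrame(m, index=genes, columns=cells)
    else:
        mat = _read_table(matrix_path, index_col=0).astype(float)
        mat.columns = mat.columns.astype(str)
    if meta_path is not None:
        meta = _read_table(meta_path, index_col=0)
        meta.index = meta.index.astype(str)
        missing = sorted(set(mat.columns) - set(meta.index))
        if missing:
            raise ValidationError(f"cells missing from metadata: {missing}")
        meta = meta.loc[list(mat.columns)]
    else:
        meta = pd.DataFrame(index=mat.columns)
    return SCAssay(values=mat, cell_meta=meta)


# ---------------------------------------------------------------------------
# transforms
# ---------------------------------------------------------------------------

def size_factors(counts: np.ndarray) -> np.ndarray:
    """Median-of-ratios size factors, rescaled to geometric mean 1.

    Per sample j: s_j = median over genes g (with positive geometric
    mean across samples) of counts[g, j] / geomean_g.
    """
    counts = np.asarray(counts, dtype=float)
    with np.errstate(divide="ignore"):
        loggeo = np.log(counts).mean(axis=1)
    ok = np.isfinite(loggeo)
    if not ok.any():
        raise ValidationError("no gene has all-positive counts; cannot estimate size factors")
    ratios = np.exp(np.log(counts[ok]) - loggeo[ok, None])
    s = np.median(ratios, axis=0)
    return s / np.exp(np.mean(np.log(s)))


def normalize(
    assay: AssayTable,
    method: str = "size_factor",
    pseudo: float = 1.0,
    log2: bool = False,
) -> AssayTable:
    """Normalize a counts-space table; optionally move to log2 space.

    ``size_factor`` divides each column by its median-of-ratios factor;
    ``cpm`` rescales each column to one million.  With ``log2=True``
    values become log2(value + pseudo) and the space tag is ``log``,
    otherwise ``normalized``.
    """
    if assay.value_space != "counts":
        raise ValidationError(f"normalize expects counts space, got {assay.value_space!r}")
    if pseudo < 0:
        raise ValidationError("pseudo-count must be >= 0")
    vals = assay.values.to_numpy(dtype=float)
    colsums = vals.sum(axis=0)
    zero = np.flatnonzero(colsums == 0)
    if zero.size:
        raise ValidationError(f"all-zero sample column: {assay.values.columns[zero[0]]!r}")
    if method == "size_factor":
        out = vals / size_factors(vals)
    elif method == "cpm":
        out = vals * 1e6 / colsums
    else:
        raise ValidationError(f"unknown normalization method {method!r}")
    if log2:
        out = np.log2(out + pseudo)
    return AssayTable(
        values=pd.DataFrame(out, index=assay.values.index, columns=assay.values.columns),
        sample_meta=assay.sample_meta.copy(),
        value_space="log" if log2 else "normalized",
    )


def relative_values(assay: AssayTable, control_condition: str) -> AssayTable:
    """Log2 fold changes of every treatment condition vs the control.

    For each gene, feature and non-control condition: mean of log
    values over treatment replicates minus mean over control
    replicates.  Control columns are dropped; the result is tagged
    ``lfc`` with one pseudo-sample per (feature, treatment).
    """
    if assay.value_space != "log":
        raise ValidationError("relative_values expects a log-space table")
    meta = assay.sample_meta
    if control_condition not in set(meta["condition"]):
        raise ValidationError(f"control condition {control_condition!r} not present")
    cols: dict[str, np.ndarray] = {}
    rows = []
    for feat in assay.features:
        ctrl = assay.samples_of(feat, control_condition)
        if not ctrl:
            raise ValidationError(f"feature {feat!r} lacks control samples")
        ctrl_mean = assay.values[ctrl].mean(axis=1)
        for cond in assay.conditions:
            if cond == control_condition:
                continue
            trt = assay.samples_of(feat, cond)
            if not trt:
                continue
            name = f"{feat}__{cond}"
            cols[name] = (assay.values[trt].mean(axis=1) - ctrl_mean).to_numpy()
            rows.append({"feature": feat, "condition": cond, "replicate": 1})
    if not cols:
        raise ValidationError("no non-control condition found")
    values = pd.DataFrame(cols, index=assay.values.index)
    sample_meta = pd.DataFrame(rows, index=list(cols))
    return AssayTable(values=values, sample_meta=sample_meta, value_space="lfc")


# ---------------------------------------------------------------------------
# label <-> SVG id resolution
# ---------------------------------------------------------------------------

def load_translation(path: str | Path) -> dict[str, str]:
    """Read a translation map TSV with columns ``assay_label``, ``svg_id``."""
    df = pd.read_csv(path, sep="\t")
    for col in ("assay_label", "svg_id"):
        if col not in df.columns:
            raise ValidationError(f"translation map lacks column {col!r}")
    return dict(zip(df["assay_label"].astype(str), df["svg_id"].astype(str)))


def map_features(
    labels_or_assay: AssayTable | list[str],
    doc: SVGDoc,
    translation: dict[str, str] | None = None,
) -> FeatureSampleMap:
    """Match assay feature labels to SVG feature ids.

    Matching is exact and case-sensitive after applying the optional
    translation map (assay label -> svg id).  Unmatched labels/ids on
    either side are reported, never fatal; a translation row pointing
    at a nonexistent svg id is an error.
    """
    if isinstance(labels_or_assay, AssayTable):
        labels = labels_or_assay.features
    else:
        labels = list(dict.fromkeys(labels_or_assay))
    svg_ids = set(doc.feature_ids)
    translation = translation or {}
    bad = sorted(v for v in translation.values() if v not in svg_ids)
    if bad:
        raise ValidationError(f"translation targets not in SVG: {bad}")
    pairs: dict[str, str] = {}
    unmatched_assay: list[str] = []
    for lab in labels:
        target = translation.get(lab, lab)
        if target in svg_ids:
            pairs[lab] = target
        else:
            unmatched_assay.append(lab)
    mapped = set(pairs.values())
    unmatched_svg = [i for i in doc.feature_ids if i not in mapped]
    if not pairs:
        import warnings

        warnings.warn("no assay label matched any SVG feature id", stacklevel=2)
    return FeatureSampleMap(
        pairs=pairs, unmatched_assay=unmatched_assay, unmatched_svg=unmatched_svg
    )


def aggregate_replicates(assay: AssayTable, stat: str = "mean") -> pd.DataFrame:
    """Collapse replicates: genes x (feature, condition) summary table.

    Returns a DataFrame whose columns are a MultiIndex (feature,
    condition); ``stat`` is ``mean`` (default) or ``median``.
    """
    if stat not in ("mean", "median"):
        raise ValidationError(f"unknown aggregation statistic {stat!r}")
    meta = assay.sample_meta
    keys = [meta["feature"].to_numpy(), meta["condition"].to_numpy()]
    grouped = assay.values.T.groupby(keys, sort=False)
    agg = grouped.mean() if stat == "mean" else grouped.median()
    agg.index.names = ["feature", "condition"]
    return agg.T
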