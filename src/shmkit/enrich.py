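"""Spatial enrichment: one-vs-rest detection of feature-selective genes.

A gene is *spatially enriched* in feature F when it is significantly up
in F relative to the other query features, and *depleted* when it is
significantly down.  "Relative to the others" means winning at least
(K-1) - outliers of the K-1 pairwise comparisons F vs G, where the
user-settable ``outliers`` relaxes the all-against-all requirement to
tolerate features that behave like F.

The per-comparison test is Welch's two-sample t on log-normalized
replicate values with Benjamini-Hochberg adjustment across genes; a
comparison supports enrichment when padj <= alpha and lfc >= lfc_min
(depletion: lfc <= -lfc_min).  The same machinery runs in *condition*
mode, where condition labels replace feature labels to find
treatment-specific genes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .assay import AssayTable
from .errors import ValidationError

#: variance floor substituted when a replicate group is constant
VAR_FLOOR = 1e-8


@dataclass
class EnrichmentResult:
    """Per-feature enriched/depleted gene tables plus the call parameters.

    Each table has columns ``gene``, ``lfc`` (min |lfc| over supporting
    comparisons, signed), ``padj`` (max adjusted p over supporting
    comparisons) and ``n_support``.
    """

    query_features: list[str]
    enriched: dict[str, pd.DataFrame]
    depleted: dict[str, pd.DataFrame]
    params: dict = field(default_factory=dict)

    def genes(self, feature: str, direction: str = "enriched") -> list[str]:
        table = (self.enriched if direction == "enriched" else self.depleted)[feature]
        return list(table["gene"])

    def write(self, out_dir: str | Path) -> list[Path]:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        written = []
        for direction, tables in (("enriched", self.enriched), ("depleted", self.depleted)):
            for feat, tab in tables.items():
                p = out_dir / f"{feat}__{direction}.tsv"
                tab.to_csv(p, sep="\t", index=False, float_format="%.6g")
                written.append(p)
        return written


def welch_t(
    a: np.ndarray, b: np.ndarray, var_floor: float = VAR_FLOOR
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized Welch two-sample t-test over matrix rows.

    ``a``, ``b``: genes x replicates.  Returns (t, df, p) with the
    Welch-Satterthwaite degrees of freedom.  Zero within-group
    variances are floored at ``var_floor`` so constant genes yield
    t = 0, p = 1 instead of NaN.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    na, nb = a.shape[1], b.shape[1]
    ma, mb = a.mean(axis=1), b.mean(axis=1)
    va = np.maximum(a.var(axis=1, ddof=1), var_floor)
    vb = np.maximum(b.var(axis=1, ddof=1), var_floor)
    se2 = va / na + vb / nb
    t = (ma - mb) / np.sqrt(se2)
    df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    p = 2.0 * stats.t.sf(np.abs(t), df)
    return t, df, p


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (step-up FDR)."""
    return multipletests(np.asarray(p, float), method="fdr_bh")[1]


def _group_matrix(assay: AssayTable, label: str, by: str) -> np.ndarray:
    meta = assay.sample_meta
    cols = list(meta.index[meta[by] == label])
    return assay.values[cols].to_numpy(dtype=float)


def pairwise_de(
    assay: AssayTable,
    a: str,
    b: str,
    by: str = "feature",
    prefilter: bool = True,
) -> pd.DataFrame:
    """Differential test between two groups of replicate samples.

    Returns a per-gene table {gene, lfc, p, padj}: lfc = mean(a) -
    mean(b) on log values, p from Welch's t, padj by BH across the
    genes of this comparison.  Genes removed by the pre-filter (zero
    variance across both groups, or weakly expressed in fewer than
    the smaller group size of samples) are absent from the table.
    """
    if assay.value_space not in ("log", "lfc"):
        raise ValidationError("pairwise_de expects log-space values")
    av = _group_matrix(assay, a, by)
    bv = _group_matrix(assay, b, by)
    for label, m in ((a, av), (b, bv)):
        if m.shape[1] < 2:
            raise ValidationError(f"group {label!r} has < 2 replicates")
    genes = np.asarray(assay.gene_ids)
    if prefilter:
        keep = _prefilter_mask(av, bv)
        av, bv, genes = av[keep], bv[keep], genes[keep]
    if genes.size == 0:
        return pd.DataFrame(columns=["gene", "lfc", "p", "padj"])
    t, _, p = welch_t(av, bv)
    lfc = av.mean(axis=1) - bv.mean(axis=1)
    # constant-gene rule: identical groups carry no evidence
    same = (np.abs(lfc) < 1e-12) & (np.abs(t) < 1e-12)
    p = np.where(same, 1.0, p)
    return pd.DataFrame(
        {"gene": genes, "lfc": lfc, "p": p, "padj": bh_adjust(p)}
    )


def _prefilter_mask(av: np.ndarray, bv: np.ndarray) -> np.ndarray:
    """Low-information gene filter applied per comparison.

    Drops genes with zero variance across the pooled replicates and
    genes exceeding the weak-expression floor (log2(cpm)+pseudo scale:
    1.0, i.e. CPM >= 1 with pseudo-count 1) in fewer than the smaller
    replicate-group-size of samples.
    """
    pooled = np.hstack([av, bv])
    nonconst = pooled.var(axis=1) > 0
    min_n = min(av.shape[1], bv.shape[1])
    expressed = (pooled >= 1.0).sum(axis=1) >= min_n
    return nonconst & expressed


def spatial_enrichment(
    assay: AssayTable,
    query_features: list[str],
    alpha: float = 0.05,
    lfc_min: float = 1.0,
    outliers: int = 0,
    mode: str = "feature",
) -> EnrichmentResult:
    """All-against-all detection of spatially enriched/depleted genes.

    For each query feature F, a gene is enriched when in at least
    (K-1) - outliers of its K-1 pairwise comparisons F vs G the
    adjusted p is <= alpha *and* the log2 fold change is >= lfc_min
    (depleted: <= -lfc_min).  ``mode='condition'`` runs the identical
    procedure on condition labels.
    """
    by = {"feature": "feature", "condition": "condition"}.get(mode)
    if by is None:
        raise ValidationError(f"unknown mode {mode!r}")
    K = len(query_features)
    if K < 2:
        raise ValidationError("need at least 2 query features")
    if not 0 <= outliers <= K - 2:
        raise ValidationError(f"outliers must be in [0, K-2] = [0, {K - 2}]")
    present = set(assay.sample_meta[by])
    missing = sorted(set(query_features) - present)
    if missing:
        raise ValidationError(f"query {by}s not in assay: {missing}")

    # one Welch+BH table per unordered pair; reuse with sign flip
    pair_tables: dict[tuple[str, str], pd.DataFrame] = {}
    for fa, fb in combinations(query_features, 2):
        pair_tables[(fa, fb)] = pairwise_de(assay, fa, fb, by=by)

    def table_for(fa: str, fb: str) -> pd.DataFrame:
        if (fa, fb) in pair_tables:
            return pair_tables[(fa, fb)]
        t = pair_tables[(fb, fa)].copy()
        t["lfc"] = -t["lfc"]
        return t

    need = (K - 1) - outliers
    enriched: dict[str, pd.DataFrame] = {}
    depleted: dict[str, pd.DataFrame] = {}
    for F in query_features:
        others = [g for g in query_features if g != F]
        tabs = [table_for(F, G).set_index("gene") for G in others]
        all_genes = sorted(set().union(*[t.index for t in tabs]))
        lfc = pd.DataFrame(
            {i: t["lfc"].reindex(all_genes) for i, t in enumerate(tabs)}
        )
        padj = pd.DataFrame(
            {i: t["padj"].reindex(all_genes) for i, t in enumerate(tabs)}
        )
        for direction, store in (("enriched", enriched), ("depleted", depleted)):
            sign = 1.0 if direction == "enriched" else -1.0
            support = (padj.le(alpha)) & (sign * lfc >= lfc_min)
            n_sup = support.sum(axis=1)
            called = n_sup[n_sup >= need].index
            rows = []
            for gene in called:
                mask = support.loc[gene].to_numpy()
                g_lfc = lfc.loc[gene].to_numpy()[mask]
                g_padj = padj.loc[gene].to_numpy()[mask]
                i_min = int(np.argmin(np.abs(g_lfc)))
                rows.append(
                    {
                        "gene": gene,
                        "lfc": float(g_lfc[i_min]),
                        "padj": float(g_padj.max()),
                        "n_support": int(mask.sum()),
                    }
                )
            store[F] = pd.DataFrame(rows, columns=["gene", "lfc", "padj", "n_support"])
    return EnrichmentResult(
        query_features=list(query_features),
        enriched=enriched,
        depleted=depleted,
        params={
            "alpha": alpha,
            "lfc_min": lfc_min,
            "outliers": outliers,
            "mode": mode,
        },
    )


# ---------------------------------------------------------------------------
# overlap summaries
# ---------------------------------------------------------------------------

def overlap_summaries(
    result: EnrichmentResult, direction: str = "enriched", venn: bool | None = None
) -> dict:
    """Set-overlap summaries of the per-feature gene calls.

    Returns ``matrix`` (K x K pairwise intersection counts, diagonal =
    set sizes), ``upset`` (exclusive count per non-empty membership
    pattern, summing to the union size) and, for K <= 5, ``venn``
    (the same exclusive region counts keyed by feature tuple).
    """
    feats = result.query_features
    K = len(feats)
    if venn is None:
        venn = K <= 5
    if venn and K > 5:
        raise ValidationError("Venn diagrams support at most 5 sets")
    sets = {f: set(result.genes(f, direction)) for f in feats}
    matrix = pd.DataFrame(
        [[len(sets[a] & sets[b]) for b in feats] for a in feats],
        index=feats,
        columns=feats,
    )
    membership: dict[tuple[str, ...], int] = {}
    for gene in set().union(*sets.values()):
        patt = tuple(f for f in feats if gene in sets[f])
        membership[patt] = membership.get(patt, 0) + 1
    upset = pd.DataFrame(
        [
            {"pattern": "&".join(patt), "degree": len(patt), "count": n}
            for patt, n in sorted(
                membership.items(), key=lambda kv: (-kv[1], kv[0])
            )
        ],
        columns=["pattern", "degree", "count"],
    )
    out = {"matrix": matrix, "upset": upset}
    if venn:
        out["venn"] = dict(membership)
    return out
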