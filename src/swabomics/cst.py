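"""Community state typing of vaginal microbiome species count tables.

Samples are clustered by Ward-linkage hierarchical clustering of pairwise
Jensen-Shannon distances between relative-abundance profiles; the number of
clusters is chosen by maximum mean silhouette.  Clusters are then labelled
with community state types (CSTs) by matching their dominant taxa against the
canonical templates (I: *L. crispatus*, II: *L. gasseri*, III: *L. iners*,
IV: *G. vaginalis*, V: *L. jensenii*, VI: *B. breve*), with a separate type
(VII) for samples dominated by any other *Lactobacillus* species.  CSTs
I/II/III/V/VII are *Lactobacillus*-dominated (LDOM); IV/VI are
*Lactobacillus*-depleted (LDEPL).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import jensenshannon, squareform
from sklearn.metrics import silhouette_score

from swabomics.containers import (
    CST_TEMPLATES,
    CSTAssignment,
    NAMED_LACTOBACILLI,
    dominance_of,
)


def filter_low_count_species(
    table: pd.DataFrame, min_total: int = 50
) -> pd.DataFrame:
    """Drop species whose total count across samples is below ``min_total``.

    The threshold is strict: a species totalling exactly ``min_total`` is
    kept.
    """
    totals = table.sum(axis=0)
    keep = totals >= min_total
    if not keep.any():
        raise ValueError("all species removed by the minimum-count filter")
    return table.loc[:, keep]


def jensen_shannon_distance(p, q) -> float:
    """Jensen-Shannon distance (sqrt of the divergence, natural log).

    ``p`` and ``q`` are probability vectors on the same support; zero entries
    follow the 0*log(0) := 0 convention.  The distance is a metric on the
    simplex, bounded by sqrt(ln 2).
    """
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if p.shape != q.shape:
        raise ValueError("p and q must have the same length")
    if np.any(p < 0) or np.any(q < 0):
        raise ValueError("probability vectors must be non-negative")
    for v in (p, q):
        if abs(v.sum() - 1.0) > 1e-9:
            raise ValueError("probability vectors must sum to 1")
    return float(jensenshannon(p, q))


def relative_abundance(table: pd.DataFrame) -> pd.DataFrame:
    """Per-sample relative abundances (rows sum to 1)."""
    totals = table.sum(axis=1)
    if (totals <= 0).any():
        raise ValueError("every sample must have at least one positive count")
    return table.div(totals, axis=0)


def js_distance_matrix(table: pd.DataFrame) -> np.ndarray:
    """Pairwise Jensen-Shannon distance matrix of relative abundances."""
    rel = relative_abundance(table).to_numpy()
    n = rel.shape[0]
    dist = np.zeros((n, n))
    for i in range(n):
        d = jensenshannon(rel[i : i + 1].T, rel[i + 1 :].T)
        dist[i, i + 1 :] = d
        dist[i + 1 :, i] = d
    # numerical noise can produce tiny negatives/nans for identical rows
    dist = np.nan_to_num(dist, nan=0.0)
    dist[dist < 0] = 0.0
    return dist


def cluster_and_select_k(
    table: pd.DataFrame, k_range: range = range(2, 16)
) -> tuple[pd.Series, dict[int, float]]:
    """Ward/Jensen-Shannon clustering with silhouette-based model selection.

    Cuts the Ward tree at each k in ``k_range``, scores the partition by mean
    silhouette on the same precomputed distance matrix, and returns the
    labels at the k maximising mean silhouette (smallest k on ties) together
    with the full silhouette curve.
    """
    ks = list(k_range)
    if len(table) < max(ks) + 1:
        raise ValueError("need more samples than the largest candidate k")
    dist = js_distance_matrix(table)
    if np.allclose(dist, 0):
        raise ValueError("degenerate distance matrix: all samples identical")
    tree = linkage(squareform(dist, checks=False), method="ward")
    curve: dict[int, float] = {}
    labels_by_k: dict[int, np.ndarray] = {}
    for k in ks:
        labels = fcluster(tree, t=k, criterion="maxclust")
        labels_by_k[k] = labels
        if len(np.unique(labels)) < 2:
            curve[k] = -1.0
            continue
        curve[k] = float(silhouette_score(dist, labels, metric="precomputed"))
    best_k = max(ks, key=lambda k: (curve[k], -k))
    labels = pd.Series(labels_by_k[best_k], index=table.index, name="cluster")
    return labels, curve


def label_clusters(
    labels: pd.Series,
    table: pd.DataFrame,
    cst_templates: dict[str, str] = CST_TEMPLATES,
    min_template_abundance: float = 0.3,
) -> CSTAssignment:
    """Map clusters to CSTs via their dominant taxa; derive dominance status.

    Each cluster takes the CST whose template taxon has the highest mean
    relative abundance among the cluster's top-5 taxa, provided that mean
    abundance reaches ``min_template_abundance`` (otherwise the cluster is
    "unassigned" and excluded downstream with a warning).  Independently of
    its cluster, any sample whose single most abundant species is a
    *Lactobacillus* other than the four named template species is reassigned
    to CST VII.
    """
    rel = relative_abundance(table)
    assignments = pd.DataFrame(index=table.index)
    assignments["cluster"] = labels.reindex(table.index)
    assignments["cst"] = pd.NA
    cluster_map: dict[int, dict] = {}
    for cl, members in rel.groupby(assignments["cluster"]):
        mean_ab = members.mean(axis=0).sort_values(ascending=False)
        top5 = mean_ab.head(5)
        best_cst, best_ab = None, -1.0
        for cst, taxon in cst_templates.items():
            ab = float(top5.get(taxon, 0.0))
            if ab > best_ab:
                best_cst, best_ab = cst, ab
        if best_ab < min_template_abundance:
            warnings.warn(
                f"cluster {cl} matches no CST template above "
                f"{min_template_abundance:.2f} mean abundance; left unassigned",
                stacklevel=2,
            )
            assigned = "unassigned"
        else:
            assigned = best_cst
        cluster_map[int(cl)] = {
            "cst": assigned,
            "top_taxa": {t: float(a) for t, a in top5.items()},
        }
        assignments.loc[members.index, "cst"] = assigned

    # CST VII override: dominance by an unlisted Lactobacillus
    dominant = rel.idxmax(axis=1)
    other_lacto = dominant.map(
        lambda sp: sp.startswith("Lactobacillus") and sp not in NAMED_LACTOBACILLI
    )
    assignments.loc[other_lacto, "cst"] = "VII"

    known = {"I", "II", "III", "IV", "V", "VI", "VII"}
    assignments["dominance"] = assignments["cst"].map(
        lambda c: dominance_of(c) if c in known else pd.NA
    )
    return CSTAssignment(assignments=assignments, cluster_map=cluster_map)


def assign_cst(
    table: pd.DataFrame,
    k_range: range = range(2, 16),
    min_total: int = 50,
    min_template_abundance: float = 0.3,
) -> CSTAssignment:
    """Full typing pipeline: count filter, clustering, CST labelling."""
    filtered = filter_low_count_species(table, min_total=min_total)
    labels, curve = cluster_and_select_k(filtered, k_range=k_range)
    result = label_clusters(
        labels, filtered, min_template_abundance=min_template_abundance
    )
    result.chosen_k = int(labels.nunique())
    result.silhouette_by_k = curve
    return result
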