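"""Drug-response profiles: AUC matrix, clustering, and concordance.

Assembles per-fit AUC values into a models x drugs matrix, runs
bidirectional hierarchical clustering (Euclidean distance, Ward linkage
on both axes -- recorded in the output metadata so alternatives can be
swept), names the k=3 drug clusters inactive / selective / pan-active by
ascending mean AUC, tests cluster-subtype enrichment with a chi-squared
contingency test, scores mechanism-of-action coherence against a
permutation null, and computes patient-PDX transcriptome concordance on
the most variant genes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist
from scipy.stats import chi2_contingency, pearsonr

from .doseresp import DoseResponseFit
from .errors import InsufficientDataError, PdxScreenError

__all__ = [
    "ActivityClassification", "assemble_matrix", "bicluster",
    "cluster_subtype_enrichment", "moa_coherence",
    "patient_pdx_concordance", "linkage_to_newick",
    "DRUG_CLASS_NAMES",
]

DRUG_CLASS_NAMES = ("inactive", "selective", "pan_active")

LINKAGE_METHOD = "ward"
DISTANCE_METRIC = "euclidean"


@dataclass
class ActivityClassification:
    """Bidirectional clustering result with named drug activity classes."""

    drug_class: Dict[str, str]        # drug -> inactive/selective/pan_active
    model_cluster: Dict[str, int]     # model -> cluster id (1..k_models)
    drug_linkage: np.ndarray = field(repr=False)
    model_linkage: np.ndarray = field(repr=False)
    drug_order: List[str] = field(default_factory=list)
    model_order: List[str] = field(default_factory=list)
    dropped_drugs: List[str] = field(default_factory=list)
    dropped_models: List[str] = field(default_factory=list)
    metadata: dict = field(default_factory=lambda: {
        "linkage": LINKAGE_METHOD, "metric": DISTANCE_METRIC})

    def class_members(self, name: str) -> List[str]:
        return [d for d, c in self.drug_class.items() if c == name]


def assemble_matrix(fits: Iterable[DoseResponseFit]) -> pd.DataFrame:
    """models x drugs AUC matrix from fit records (NaN = missing).

    Duplicate (drug, model) entries with equal AUC are deduplicated;
    conflicting duplicates raise.
    """
    rows = []
    for f in fits:
        if f.drug_id is None or f.model_id is None:
            raise PdxScreenError("fit lacks drug_id/model_id")
        rows.append((f.model_id, f.drug_id, f.auc))
    if not rows:
        raise InsufficientDataError("no fits supplied")
    df = pd.DataFrame(rows, columns=["model_id", "drug_id", "auc"])
    dup = df.groupby(["model_id", "drug_id"])["auc"].nunique()
    conflicts = dup[dup > 1]
    if len(conflicts):
        raise PdxScreenError(
            f"conflicting duplicate AUC for {list(conflicts.index)}")
    df = df.drop_duplicates(["model_id", "drug_id"])
    mat = df.pivot(index="model_id", columns="drug_id", values="auc")
    mat.index.name = "model_id"
    mat.columns.name = "drug_id"
    return mat


def _name_drug_classes(mat: pd.DataFrame, assignments: np.ndarray,
                       k: int) -> Dict[str, str]:
    means = {}
    for cid in range(1, k + 1):
        cols = mat.columns[assignments == cid]
        means[cid] = float(mat[cols].to_numpy().mean())
    order = sorted(means, key=means.get)
    if k == 3:
        names = dict(zip(order, DRUG_CLASS_NAMES))
    else:
        names = {cid: f"class_{rank + 1}"
                 for rank, cid in enumerate(order)}
    return {d: names[cid] for d, cid in zip(mat.columns, assignments)}


def bicluster(matrix: pd.DataFrame, k_drugs: int = 3, k_models: int = 3,
              max_missing_frac: float = 0.2) -> ActivityClassification:
    """Hierarchical clustering of both axes of the AUC matrix.

    Drugs missing in more than ``max_missing_frac`` of models are dropped
    (and reported); models with any remaining missing value are dropped.
    The drug tree is cut at ``k_drugs`` and, for k=3, the clusters are
    named inactive / selective / pan-active by ascending mean AUC.
    """
    if k_drugs > matrix.shape[1]:
        raise PdxScreenError(
            f"k_drugs={k_drugs} exceeds {matrix.shape[1]} drugs")
    missing_frac = matrix.isna().mean(axis=0)
    dropped_drugs = list(matrix.columns[missing_frac > max_missing_frac])
    mat = matrix.drop(columns=dropped_drugs)
    dropped_models = list(mat.index[mat.isna().any(axis=1)])
    mat = mat.drop(index=dropped_models)
    if mat.shape[0] < 2 or mat.shape[1] < k_drugs:
        raise InsufficientDataError("too little complete data to cluster")

    model_link = hierarchy.linkage(pdist(mat.to_numpy(), DISTANCE_METRIC),
                                   method=LINKAGE_METHOD)
    drug_link = hierarchy.linkage(pdist(mat.to_numpy().T, DISTANCE_METRIC),
                                  method=LINKAGE_METHOD)
    drug_assign = hierarchy.fcluster(drug_link, t=k_drugs,
                                     criterion="maxclust")
    model_assign = hierarchy.fcluster(model_link, t=min(k_models,
                                                        mat.shape[0]),
                                      criterion="maxclust")
    drug_class = _name_drug_classes(mat, drug_assign, k_drugs)
    model_cluster = {m: int(c) for m, c in zip(mat.index, model_assign)}
    return ActivityClassification(
        drug_class=drug_class, model_cluster=model_cluster,
        drug_linkage=drug_link, model_linkage=model_link,
        drug_order=[mat.columns[i]
                    for i in hierarchy.leaves_list(drug_link)],
        model_order=[mat.index[i]
                     for i in hierarchy.leaves_list(model_link)],
        dropped_drugs=dropped_drugs, dropped_models=dropped_models)


def cluster_subtype_enrichment(model_clusters: Dict[str, int],
                               subtypes: pd.Series,
                               exclude_clusters: Sequence[int] = ()):
    """Chi-squared test of the cluster x subtype contingency table.

    ``exclude_clusters`` drops named (orphan) clusters before testing.
    Returns ``(chi2, p, table)``; the statistic is uncorrected.
    """
    rows = [(c, subtypes[m]) for m, c in model_clusters.items()
            if c not in set(exclude_clusters)]
    if not rows:
        raise InsufficientDataError("no models left after exclusion")
    df = pd.DataFrame(rows, columns=["cluster", "subtype"])
    table = pd.crosstab(df["cluster"], df["subtype"])
    if table.shape[0] < 2 or table.shape[1] < 2:
        raise InsufficientDataError(
            "degenerate contingency table (need >= 2 clusters and subtypes)")
    chi2, p, _dof, _exp = chi2_contingency(table.to_numpy(),
                                           correction=False)
    return float(chi2), float(p), table


def moa_coherence(matrix: pd.DataFrame, annotations: Dict[str, str],
                  n_permutations: int = 1000,
                  rng: Optional[np.random.Generator] = None) -> pd.DataFrame:
    """Mean pairwise Pearson r of AUC columns within each mechanism class.

    Compared against a label-shuffle permutation null (class sizes
    preserved).  Singleton classes are skipped with ``n_drugs = 1`` rows.
    Returns a frame per class: n_drugs, mean_r, perm_p, null_q95.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    annotated = [d for d in matrix.columns if d in annotations]
    sub = matrix[annotated].dropna(axis=0)
    corr = sub.corr(method="pearson")

    def class_mean_r(members: List[str]) -> float:
        idx = [annotated.index(m) for m in members]
        vals = [corr.iloc[i, j] for a, i in enumerate(idx)
                for j in idx[a + 1:]]
        return float(np.mean(vals))

    classes: Dict[str, List[str]] = {}
    for d in annotated:
        classes.setdefault(annotations[d], []).append(d)

    out = []
    labels = [annotations[d] for d in annotated]
    for name, members in classes.items():
        if len(members) < 2:
            out.append({"moa_class": name, "n_drugs": 1, "mean_r": np.nan,
                        "perm_p": np.nan, "null_q95": np.nan})
            continue
        observed = class_mean_r(members)
        null = np.empty(n_permutations)
        for b in range(n_permutations):
            perm = rng.permutation(labels)
            null[b] = class_mean_r(
                [annotated[i] for i in np.flatnonzero(perm == name)])
        perm_p = float((1 + np.sum(null >= observed)) / (1 + n_permutations))
        out.append({"moa_class": name, "n_drugs": len(members),
                    "mean_r": observed, "perm_p": perm_p,
                    "null_q95": float(np.quantile(null, 0.95))})
    return pd.DataFrame(out).set_index("moa_class")


def patient_pdx_concordance(expr: pd.DataFrame, groups: pd.DataFrame,
                            n_top: int = 1000) -> pd.DataFrame:
    """Pairwise patient x PDX Pearson r on the most variant transcripts.

    ``expr`` is genes x samples (TPM); ``groups`` has columns sample_id,
    group ("patient"/"pdx"), model_id.  Expression is log2(TPM + 1)
    transformed, the ``n_top`` highest-variance genes across all samples
    are selected, and every patient-PDX pair is correlated.  The returned
    long frame flags matched pairs (same model_id).
    """
    if n_top > expr.shape[0]:
        raise PdxScreenError(
            f"n_top={n_top} exceeds {expr.shape[0]} genes")
    patients = groups[groups["group"] == "patient"]
    pdxs = groups[groups["group"] == "pdx"]
    if len(patients) < 1 or len(pdxs) < 1:
        raise InsufficientDataError("need samples in both groups")
    log = np.log2(expr + 1.0)
    variances = log.var(axis=1, ddof=1)
    top = variances.nlargest(n_top).index
    sub = log.loc[top]
    if np.allclose(sub.to_numpy().std(axis=1), 0.0):
        raise PdxScreenError("selected gene set has zero variance")

    model_of = dict(zip(groups["sample_id"], groups["model_id"]))
    rows = []
    for _, prow in patients.iterrows():
        for _, xrow in pdxs.iterrows():
            ps, xs = prow["sample_id"], xrow["sample_id"]
            r, _p = pearsonr(sub[ps], sub[xs])
            rows.append({"patient": ps, "pdx": xs, "pearson_r": float(r),
                         "matched": model_of[ps] == model_of[xs]})
    return pd.DataFrame(rows)


def linkage_to_newick(linkage: np.ndarray,
                      leaf_names: Sequence[str]) -> str:
    """Render a scipy linkage matrix as a Newick tree string."""
    tree = hierarchy.to_tree(linkage)

    def walk(node) -> str:
        if node.is_leaf():
            return leaf_names[node.id]
        left, right = node.get_left(), node.get_right()
        ld = node.dist - left.dist
        rd = node.dist - right.dist
        return f"({walk(left)}:{ld:.6g},{walk(right)}:{rd:.6g})"

    return walk(tree) + ";"
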