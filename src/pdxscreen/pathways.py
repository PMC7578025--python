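"""Single-sample GSEA scoring and the pharmaco-transcriptomic screen.

The ssGSEA enrichment score follows the rank-weighted formulation: for
each sample, genes are ordered by descending expression (ties broken by
stable gene-identifier order); walking down the ordered list, the score is
the running sum of the difference between the weighted in-set cumulative
distribution (weights = rank ** alpha, where the top gene has rank N) and
the unweighted out-of-set cumulative distribution.  No final
normalization by the set-size range is applied -- scores are z-normalized
per pathway across samples afterwards, so only relative values matter and
absolute ES magnitudes are not comparable across implementations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import pearsonr

from .errors import InsufficientDataError, PdxScreenError

__all__ = [
    "read_gmt", "write_gmt", "PathwayScoreMatrix",
    "ssgsea_score", "rank_consistency", "correlate_drug_features",
]


# ---------------------------------------------------------------------------
# GMT
# ---------------------------------------------------------------------------

def read_gmt(path) -> Dict[str, List[str]]:
    """Parse a GMT file into {set name: member genes}."""
    sets: Dict[str, List[str]] = {}
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise PdxScreenError(
                    f"{path}:{line_no}: GMT rows need name, description, "
                    "and >= 1 gene")
            name = parts[0]
            if name in sets:
                raise PdxScreenError(f"{path}:{line_no}: duplicate set "
                                     f"{name!r}")
            sets[name] = [g for g in parts[2:] if g]
    return sets


def write_gmt(sets: Dict[str, Sequence[str]], path,
              descriptions: Optional[Dict[str, str]] = None) -> None:
    with open(path, "w") as fh:
        for name, genes in sets.items():
            desc = (descriptions or {}).get(name, "na")
            fh.write("\t".join([name, desc, *genes]) + "\n")


# ---------------------------------------------------------------------------
# ssGSEA
# ---------------------------------------------------------------------------

@dataclass
class PathwayScoreMatrix:
    """Gene sets x samples enrichment scores, raw and z-normalized."""

    raw: pd.DataFrame
    z: pd.DataFrame = field(default=None)
    row_sd: pd.Series = field(default=None)

    def __post_init__(self):
        if self.z is None:
            sd = self.raw.std(axis=1, ddof=1)
            mean = self.raw.mean(axis=1)
            z = self.raw.sub(mean, axis=0)
            with np.errstate(invalid="ignore", divide="ignore"):
                z = z.div(sd.replace(0.0, np.nan), axis=0)
            self.z = z.fillna(0.0)
            self.row_sd = sd


def _sample_es(expr_col: np.ndarray, member_mask_list, alpha: float):
    """ES for every gene set on one sample's expression vector."""
    n = expr_col.size
    # descending expression, ties broken by gene position (stable)
    order = np.lexsort((np.arange(n), -expr_col))
    ranks = np.arange(n, 0, -1, dtype=float)  # top gene gets rank N
    weights = ranks ** alpha
    out = []
    for mask in member_mask_list:
        in_ordered = mask[order]
        w = np.where(in_ordered, weights, 0.0)
        cum_in = np.cumsum(w)
        total_in = cum_in[-1]
        n_out = n - int(mask.sum())
        cum_out = np.cumsum(~in_ordered) / n_out if n_out else np.zeros(n)
        out.append(float(np.sum(cum_in / total_in - cum_out)))
    return out


def ssgsea_score(expr: pd.DataFrame, sets: Dict[str, Sequence[str]],
                 alpha: float = 0.25) -> PathwayScoreMatrix:
    """ssGSEA enrichment scores for every (gene set, sample) pair.

    ``expr`` is genes x samples and must be non-negative.  Sets are
    intersected with the matrix's genes; empty intersections are dropped
    with a warning, as are sets covering every gene (no out-of-set
    distribution exists).  Samples with all-equal expression fall back to
    the deterministic gene-order tie rule (with a warning).
    """
    if (expr.to_numpy() < 0).any():
        raise PdxScreenError("expression must be non-negative")
    gene_pos = {g: i for i, g in enumerate(expr.index)}
    kept_names, masks = [], []
    for name, genes in sets.items():
        idx = [gene_pos[g] for g in genes if g in gene_pos]
        if not idx:
            warnings.warn(f"gene set {name!r} has no genes in the matrix; "
                          "dropped", stacklevel=2)
            continue
        if len(set(idx)) == expr.shape[0]:
            warnings.warn(f"gene set {name!r} covers all genes; dropped",
                          stacklevel=2)
            continue
        mask = np.zeros(expr.shape[0], dtype=bool)
        mask[idx] = True
        kept_names.append(name)
        masks.append(mask)
    if not kept_names:
        raise InsufficientDataError("no usable gene sets after intersection")

    values = np.empty((len(kept_names), expr.shape[1]))
    arr = expr.to_numpy(float)
    for j, sample in enumerate(expr.columns):
        col = arr[:, j]
        if np.all(col == col[0]):
            warnings.warn(f"sample {sample!r} has all-equal expression; "
                          "ranking by gene order", stacklevel=2)
        values[:, j] = _sample_es(col, masks, alpha)
    raw = pd.DataFrame(values, index=kept_names, columns=expr.columns)
    raw.index.name = "gene_set"
    return PathwayScoreMatrix(raw=raw)


def rank_consistency(scores: PathwayScoreMatrix, set_name: str) -> dict:
    """Cross-sample consistency of one pathway's activity.

    Reports the set's mean raw score and its SD across samples, plus the
    rank of that mean among all sets (1 = most active).  Consistently
    active means a high mean with a low SD.
    """
    if scores.raw.shape[1] < 2:
        raise InsufficientDataError("need >= 2 samples")
    if set_name not in scores.raw.index:
        raise KeyError(set_name)
    means = scores.raw.mean(axis=1)
    ranks = means.rank(ascending=False, method="min")
    return {
        "set": set_name,
        "mean_score": float(means[set_name]),
        "sd_score": float(scores.raw.loc[set_name].std(ddof=1)),
        "rank_of_mean": int(ranks[set_name]),
        "n_sets": int(scores.raw.shape[0]),
    }


# ---------------------------------------------------------------------------
# correlation screen
# ---------------------------------------------------------------------------

def correlate_drug_features(auc_column: pd.Series, features: pd.DataFrame,
                            r_min: float = 0.70, alpha: float = 0.05,
                            log2_transform: bool = False) -> pd.DataFrame:
    """Pearson screen of one drug's AUC against feature rows.

    ``features`` is features x samples (pathway scores, or a TPM
    expression matrix with ``log2_transform=True`` for single-gene mode).
    A feature passes when p < alpha and |r| >= r_min.  Zero-variance
    features are reported with note ``"undefined"`` rather than NaN
    propagation.
    """
    shared = [s for s in features.columns if s in auc_column.index]
    y = auc_column.loc[shared].to_numpy(float)
    keep = np.isfinite(y)
    y = y[keep]
    shared = [s for s, k in zip(shared, keep) if k]
    if len(shared) < 3:
        raise InsufficientDataError("need >= 3 paired observations")
    mat = features[shared]
    if log2_transform:
        mat = np.log2(mat + 1.0)
    if np.std(y) == 0:
        raise PdxScreenError("AUC vector has zero variance")
    rows = []
    for feat, vals in mat.iterrows():
        v = vals.to_numpy(float)
        if np.std(v) == 0:
            rows.append({"feature": feat, "pearson_r": np.nan, "p": np.nan,
                         "passes": False, "note": "undefined"})
            continue
        r, p = pearsonr(v, y)
        rows.append({"feature": feat, "pearson_r": float(r), "p": float(p),
                     "passes": bool(p < alpha and abs(r) >= r_min),
                     "note": "ok"})
    return pd.DataFrame(rows).set_index("feature")
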