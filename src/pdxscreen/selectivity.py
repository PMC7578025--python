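"""Subtype-selective drug detection and pharmacogenomic association.

Per drug, a one-way ANOVA of AUC across molecular subtypes (groups below
``min_n`` observations excluded, mirroring the exclusion of the singleton
IM/UNS classes) flags subtype-selective compounds at the omnibus p < alpha.
Mutation associations are two-group F-tests of AUC by carrier status with
a Sidak family-wise correction, ``p_sidak = 1 - (1 - p) ** m``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import f as f_dist

from .errors import InsufficientDataError, PdxScreenError

__all__ = [
    "SelectivityResult", "PharmacogenomicResult",
    "one_way_anova", "subtype_anova", "sidak", "mutation_association",
]


@dataclass
class SelectivityResult:
    drug_id: str
    groups: List[str]
    group_n: Dict[str, int]
    group_mean_auc: Dict[str, float]
    f_stat: float
    p: float
    significant: bool


@dataclass
class PharmacogenomicResult:
    drug_id: str
    gene: str
    n_carrier: int
    n_noncarrier: int
    mean_auc_carrier: float
    mean_auc_noncarrier: float
    f_stat: float
    p_unadjusted: float
    p_sidak: float


def one_way_anova(groups: Sequence[np.ndarray]):
    """One-way fixed-effects ANOVA; returns (F, p).

    Zero within-group variance is handled exactly: F is 0 with p = 1 when
    the group means coincide, infinite with p = 0 when they differ.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise InsufficientDataError("ANOVA needs >= 2 groups")
    if any(g.size < 1 for g in groups):
        raise InsufficientDataError("empty group")
    n_total = sum(g.size for g in groups)
    grand = np.concatenate(groups).mean()
    ss_between = sum(g.size * (g.mean() - grand) ** 2 for g in groups)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups)
    df_between = len(groups) - 1
    df_within = n_total - len(groups)
    if df_within <= 0:
        raise InsufficientDataError("no residual degrees of freedom")
    if ss_within == 0.0:
        if ss_between == 0.0:
            return 0.0, 1.0
        return float("inf"), 0.0
    f_stat = (ss_between / df_between) / (ss_within / df_within)
    p = float(f_dist.sf(f_stat, df_between, df_within))
    return float(f_stat), p


def subtype_anova(matrix: pd.DataFrame, subtypes: pd.Series,
                  exclude: Sequence[str] = ("IM", "UNS"),
                  alpha: float = 0.05,
                  min_n: int = 2) -> List[SelectivityResult]:
    """Per-drug one-way ANOVA of AUC by subtype.

    ``exclude`` removes named subtypes up front; any remaining group with
    fewer than ``min_n`` models is also dropped.  Results are sorted by
    descending F.
    """
    keep = [m for m in matrix.index
            if m in subtypes.index and subtypes[m] not in set(exclude)]
    sub = matrix.loc[keep]
    labels = subtypes.loc[keep]
    counts = labels.value_counts()
    retained = [s for s in counts.index if counts[s] >= min_n]
    if len(retained) < 2:
        raise PdxScreenError(
            "fewer than 2 subtype groups retained; check exclusions")
    results = []
    for drug in sub.columns:
        col = sub[drug]
        groups, names, g_n, g_mean = [], [], {}, {}
        for s in sorted(retained):
            vals = col[labels == s].dropna().to_numpy(float)
            if vals.size >= min_n:
                groups.append(vals)
                names.append(s)
                g_n[s] = int(vals.size)
                g_mean[s] = float(vals.mean())
        if len(groups) < 2:
            continue
        f_stat, p = one_way_anova(groups)
        results.append(SelectivityResult(
            drug_id=drug, groups=names, group_n=g_n, group_mean_auc=g_mean,
            f_stat=f_stat, p=p, significant=bool(p < alpha)))
    results.sort(key=lambda r: -r.f_stat)
    return results


def sidak(p: float, m: int) -> float:
    """Sidak family-wise correction, 1 - (1 - p)^m."""
    if not (0.0 <= p <= 1.0):
        raise ValueError(f"p={p} outside [0, 1]")
    if m < 1:
        raise ValueError("family size must be >= 1")
    return float(-np.expm1(m * np.log1p(-p))) if p < 1.0 else 1.0


def mutation_association(matrix: pd.DataFrame, mutations: pd.DataFrame,
                         gene: str, drug_id: Optional[str] = None,
                         family_size: Optional[int] = None,
                         ) -> List[PharmacogenomicResult]:
    """AUC versus mutation status, per drug, with Sidak correction.

    Two-group one-way ANOVA (equivalently an F-test) of each drug's AUC
    between carriers and non-carriers of ``gene``.  ``family_size``
    defaults to the number of drugs tested for the gene.
    """
    if gene not in mutations.columns:
        raise PdxScreenError(f"gene {gene!r} not in mutation table")
    shared = [m for m in matrix.index if m in mutations.index]
    status = mutations.loc[shared, gene]
    drugs = [drug_id] if drug_id is not None else list(matrix.columns)
    m_family = family_size if family_size is not None else len(drugs)
    results = []
    for drug in drugs:
        col = matrix.loc[shared, drug]
        carrier = col[status == 1].dropna().to_numpy(float)
        noncarrier = col[status == 0].dropna().to_numpy(float)
        if carrier.size < 2 or noncarrier.size < 2:
            raise InsufficientDataError(
                f"{gene}/{drug}: need >= 2 models per carrier class")
        f_stat, p = one_way_anova([carrier, noncarrier])
        results.append(PharmacogenomicResult(
            drug_id=drug, gene=gene,
            n_carrier=int(carrier.size), n_noncarrier=int(noncarrier.size),
            mean_auc_carrier=float(carrier.mean()),
            mean_auc_noncarrier=float(noncarrier.mean()),
            f_stat=f_stat, p_unadjusted=p, p_sidak=sidak(p, m_family)))
    return results
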