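"""Paired tumour-normal fold changes and ordered-group statistics.

Matched tumour/normal expression is summarized per patient and gene as

    FC_ij = log2((T_ij + 1) / (N_ij + 1)),

displayed as a heat map with rows ordered by decreasing variance and
columns grouped by subtype, then by increasing mean fold change within
each group. Monotone trends across ordered groups (e.g. tumour grade)
are tested with the Jonckheere-Terpstra statistic — the sum of pairwise
Mann-Whitney counts over ordered group pairs — and matched pairs with
the Wilcoxon signed-rank test. Both tests are exact (complete
enumeration) for small samples and switch to a tie-corrected normal
approximation above a configurable size cutoff.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PairedExpression",
    "OrderedGroups",
    "paired_log2_fc",
    "order_heatmap",
    "jonckheere_terpstra",
    "wilcoxon_signed_rank",
]


@dataclass
class PairedExpression:
    """Matched tumour (T) and normal (N) expression, genes x patients."""

    gene_ids: List[str]
    patient_ids: List[str]
    T: np.ndarray
    N: np.ndarray
    subtype: Dict[str, str] = field(default_factory=dict)
    FC: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.T = np.asarray(self.T, dtype=float)
        self.N = np.asarray(self.N, dtype=float)
        shape = (len(self.gene_ids), len(self.patient_ids))
        if self.T.shape != shape or self.N.shape != shape:
            raise ValueError(
                f"T {self.T.shape} and N {self.N.shape} must both be genes x patients {shape}"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("duplicate gene_ids")
        if len(set(self.patient_ids)) != len(self.patient_ids):
            raise ValueError("duplicate patient_ids")
        # patients without an assignment are kept, labelled "unknown"
        self.subtype = {p: self.subtype.get(p, "unknown") for p in self.patient_ids}

    def fc_frame(self) -> pd.DataFrame:
        if self.FC is None:
            raise ValueError("FC not computed; call paired_log2_fc first")
        return pd.DataFrame(self.FC, index=self.gene_ids, columns=self.patient_ids)


@dataclass
class OrderedGroups:
    """Observations partitioned into groups with a hypothesized order."""

    groups: List[Tuple[str, np.ndarray]]
    alternative: str = "two-sided"

    def __post_init__(self) -> None:
        if len(self.groups) < 2:
            raise ValueError("need >= 2 ordered groups")
        self.groups = [(lbl, np.asarray(v, dtype=float)) for lbl, v in self.groups]
        for lbl, v in self.groups:
            if v.size == 0:
                raise ValueError(f"group {lbl!r} is empty")
        if self.alternative not in ("increasing", "decreasing", "two-sided"):
            raise ValueError(f"alternative must be increasing/decreasing/two-sided, got {self.alternative!r}")


def paired_log2_fc(pe: PairedExpression) -> PairedExpression:
    """FC_ij = log2((T_ij + 1)/(N_ij + 1)); the unit pseudocount keeps
    zero pairs well-defined (FC = 0)."""
    if np.any(pe.T < 0) or np.any(pe.N < 0):
        raise ValueError("expression values must be non-negative")
    pe.FC = np.log2((pe.T + 1.0) / (pe.N + 1.0))
    return pe


def order_heatmap(
    pe: PairedExpression,
    gene_panel: Sequence[str],
    subtype_order: Sequence[str] = (),
) -> Tuple[List[str], List[str]]:
    """Display orders for a fold-change heat map.

    Rows: panel genes by decreasing FC variance (sample variance across
    patients). Columns: patients grouped by subtype in the given order
    (labels missing from the order follow, alphabetically), then by
    increasing mean FC over the panel within each group. All ties break
    by identifier lexicographic order.
    """
    if not gene_panel:
        raise ValueError("gene_panel is empty")
    fc = pe.fc_frame()
    missing = [g for g in gene_panel if g not in fc.index]
    if missing:
        raise KeyError(f"panel genes absent: {missing}")
    panel = fc.loc[list(gene_panel)]
    variances = panel.var(axis=1, ddof=1)
    row_order = sorted(panel.index, key=lambda g: (-variances[g], g))
    rank = {lbl: i for i, lbl in enumerate(subtype_order)}
    extra = sorted({s for s in pe.subtype.values() if s not in rank})
    rank.update({lbl: len(subtype_order) + i for i, lbl in enumerate(extra)})
    mean_fc = panel.mean(axis=0)
    col_order = sorted(
        pe.patient_ids, key=lambda p: (rank[pe.subtype[p]], mean_fc[p], p)
    )
    return row_order, col_order


# ---------------------------------------------------------------------
# Jonckheere-Terpstra


def _jt_statistic(groups: List[np.ndarray]) -> float:
    jt = 0.0
    for a in range(len(groups)):
        for b in range(a + 1, len(groups)):
            x, y = groups[a][:, None], groups[b][None, :]
            jt += np.sum(x < y) + 0.5 * np.sum(x == y)
    return float(jt)


@lru_cache(maxsize=128)
def _assignment_labels(sizes: Tuple[int, ...]) -> np.ndarray:
    """All distinct assignments of n pooled positions to groups of the
    given sizes, as an (n_assignments, n) int8 label matrix."""
    n = sum(sizes)
    out: List[Tuple[int, ...]] = []
    counts = list(sizes)

    def rec(prefix: List[int]) -> None:
        if len(prefix) == n:
            out.append(tuple(prefix))
            return
        for g in range(len(counts)):
            if counts[g]:
                counts[g] -= 1
                prefix.append(g)
                rec(prefix)
                prefix.pop()
                counts[g] += 1

    rec([])
    return np.array(out, dtype=np.int8)


def _jt_exact_null(values: np.ndarray, sizes: Tuple[int, ...]) -> np.ndarray:
    """Null distribution of JT over all equally likely assignments of
    the pooled values to groups (handles ties exactly)."""
    L = _assignment_labels(sizes)
    W = (values[:, None] < values[None, :]) + 0.5 * (values[:, None] == values[None, :])
    mask = L[:, :, None] < L[:, None, :]
    return np.einsum("ast,st->a", mask, W.astype(float))


def jonckheere_terpstra(og: OrderedGroups, exact_limit: int = 12) -> Tuple[float, float, str]:
    """Jonckheere-Terpstra trend test across ordered groups.

    JT sums, over ordered group pairs (a earlier than b), the counts
    #{x in a, y in b : x < y} plus half the ties. With total n at or
    below ``exact_limit`` the p-value comes from complete enumeration of
    value-to-group assignments; otherwise from a normal approximation
    with tie-corrected variance. Two-sided p doubles the smaller tail,
    capped at 1.

    Returns ``(statistic, p, method)`` with method "exact" or "normal".
    """
    values = [v for _, v in og.groups]
    sizes = tuple(v.size for v in values)
    n = sum(sizes)
    obs = _jt_statistic(values)
    eps = 1e-9
    if n <= exact_limit:
        null = _jt_exact_null(np.concatenate(values), sizes)
        p_ge = float(np.mean(null >= obs - eps))
        p_le = float(np.mean(null <= obs + eps))
        method = "exact"
    else:
        pooled = np.concatenate(values)
        N = float(n)
        ni = np.array(sizes, dtype=float)
        _, tie_counts = np.unique(pooled, return_counts=True)
        t = tie_counts.astype(float)
        mean = (N**2 - np.sum(ni**2)) / 4.0
        term1 = (
            N * (N - 1) * (2 * N + 5)
            - np.sum(ni * (ni - 1) * (2 * ni + 5))
            - np.sum(t * (t - 1) * (2 * t + 5))
        ) / 72.0
        term2 = (
            np.sum(ni * (ni - 1) * (ni - 2))
            * np.sum(t * (t - 1) * (t - 2))
            / (36.0 * N * (N - 1) * (N - 2))
        )
        term3 = np.sum(ni * (ni - 1)) * np.sum(t * (t - 1)) / (8.0 * N * (N - 1))
        var = term1 + term2 + term3
        if var <= 0:
            p_ge = p_le = 1.0
        else:
            z = (obs - mean) / np.sqrt(var)
            p_ge = float(stats.norm.sf(z))
            p_le = float(stats.norm.cdf(z))
        method = "normal"
    if og.alternative == "increasing":
        p = p_ge
    elif og.alternative == "decreasing":
        p = p_le
    else:
        p = min(1.0, 2.0 * min(p_ge, p_le))
    return obs, p, method


# ---------------------------------------------------------------------
# Wilcoxon signed-rank


def _signed_rank_null_counts(ranks2: np.ndarray) -> np.ndarray:
    """Counts of each achievable doubled W+ over all 2^n sign patterns,
    by polynomial convolution."""
    total = int(ranks2.sum())
    counts = np.zeros(total + 1, dtype=float)
    counts[0] = 1.0
    for r in ranks2:
        new = counts.copy()
        new[r:] += counts[: counts.size - r]
        counts = new
    return counts


def wilcoxon_signed_rank(
    pairs: Sequence[Tuple[float, float]],
    exact_limit: int = 20,
    alternative: str = "two-sided",
) -> Tuple[float, float, str]:
    """Wilcoxon signed-rank test on matched pairs.

    Zero differences are dropped; ranks of the absolute differences use
    midranks for ties; the statistic is W+ (sum of ranks of positive
    differences). Exact p by enumeration of the 2^n sign patterns when
    the effective n is at or below ``exact_limit``, else a normal
    approximation with tie correction and continuity correction.
    Two-sided p doubles the smaller tail, capped at 1.
    """
    if alternative not in ("two-sided", "greater", "less"):
        raise ValueError(f"invalid alternative {alternative!r}")
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("pairs must be a sequence of (a, b) tuples")
    d = arr[:, 0] - arr[:, 1]
    d = d[d != 0]
    n = d.size
    if n == 0:
        raise ValueError("all paired differences are zero; no information")
    ranks = stats.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    eps = 1e-9
    if n <= exact_limit:
        ranks2 = np.round(2 * ranks).astype(int)  # midranks are multiples of 1/2
        counts = _signed_rank_null_counts(ranks2)
        total = 2.0**n
        obs2 = 2 * w_plus
        sums = np.arange(counts.size)
        p_ge = float(counts[sums >= obs2 - eps].sum() / total)
        p_le = float(counts[sums <= obs2 + eps].sum() / total)
        method = "exact"
    else:
        mu = n * (n + 1) / 4.0
        _, tie_counts = np.unique(np.abs(d), return_counts=True)
        t = tie_counts.astype(float)
        var = n * (n + 1) * (2 * n + 1) / 24.0 - np.sum(t**3 - t) / 48.0
        sd = np.sqrt(var)
        z_ge = (w_plus - mu - 0.5) / sd
        z_le = (w_plus - mu + 0.5) / sd
        p_ge = float(stats.norm.sf(z_ge))
        p_le = float(stats.norm.cdf(z_le))
        method = "normal"
    if alternative == "greater":
        p = p_ge
    elif alternative == "less":
        p = p_le
    else:
        p = min(1.0, 2.0 * min(p_ge, p_le))
    return w_plus, p, method
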