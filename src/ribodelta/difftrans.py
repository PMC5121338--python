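"""Differential translational-efficiency inference.

For every gene the pipeline computes a per-replicate polyribosomal
enrichment score

    E = log2((polysome + pseudocount) / (total + pseudocount))

on size-factor-normalized abundances, tests the per-condition mean score
against zero, converts the p-values to Storey q-values, and finally
classifies genes by where the between-line difference in the
treatment-induced shift,

    d = [E_mean(treated) - E_mean(untreated)]_responsive
      - [E_mean(treated) - E_mean(untreated)]_control,

falls relative to a band of ``band_multiplier`` standard deviations
around the center (median by default) of the d distribution. Genes
passing the q gate in at least one condition AND lying outside the band
are selected; the sign of d - center labels them positive (translation
up with the transition in the responsive line) or negative regulators.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy import special, stats

from .config import PipelineConfig
from .io import CountMatrix, ValidationError
from .normalization import apply_factors, spike_size_factors, total_count_factors

__all__ = [
    "EnrichmentTable",
    "StoreyFit",
    "enrichment_scores",
    "condition_pvalues",
    "storey_qvalues",
    "band_classifier",
    "run_diff_translation",
    "ZERO_VARIANCE_P",
]

#: Sentinel p-value for a nonzero mean with zero replicate variance: the
#: t statistic is formally infinite, so we report the smallest positive
#: normal float rather than an exact zero.
ZERO_VARIANCE_P = float(np.finfo(float).tiny)

Condition = Tuple[str, str]


def _cond_label(c: Condition) -> str:
    return f"{c[0]}.{c[1]}"


@dataclass
class StoreyFit:
    """Diagnostics of the null-proportion estimate behind the q-values."""

    lambda_: Tuple[float, ...]
    pi0: float
    m: int

    def __post_init__(self) -> None:
        if not 0.0 < self.pi0 <= 1.0:
            raise ValueError(f"pi0 must lie in (0, 1], got {self.pi0}")


@dataclass
class EnrichmentTable:
    """Per-gene enrichment scores and classification results.

    ``E[c]`` is a genes x replicates array of log2 enrichment scores for
    condition ``c``; ``summary`` accumulates per-gene statistics as the
    stages run (E_mean per condition, dE per line, d, p/q per condition,
    q_min, selected, class).
    """

    gene_ids: List[str]
    conditions: List[Condition]
    E: Dict[Condition, np.ndarray]
    summary: pd.DataFrame
    storey_fits: Dict[Condition, StoreyFit] = field(default_factory=dict)
    band_center: Optional[float] = None
    band_spread: Optional[float] = None

    def condition_labels(self) -> List[str]:
        return [_cond_label(c) for c in self.conditions]

    def to_frame(self) -> pd.DataFrame:
        out = self.summary.reset_index().rename(columns={"index": "gene_id"})
        return out


def enrichment_scores(
    normalized: np.ndarray,
    counts: CountMatrix,
    pseudocount: float = 0.5,
) -> EnrichmentTable:
    """Per-replicate log2 polysome/total enrichment on normalized abundances.

    Polysome and total libraries of a condition are paired by replicate
    index; spike rows are dropped. Raises if a condition lacks a
    fraction or the replicate indices of the two fractions differ.
    """
    if pseudocount < 0:
        raise ValueError(f"pseudocount must be >= 0, got {pseudocount}")
    normalized = np.asarray(normalized, dtype=float)
    if normalized.shape != counts.counts.shape:
        raise ValueError("normalized matrix shape does not match counts")
    keep = ~counts.spike_mask
    gene_ids = [g for g, k in zip(counts.gene_ids, keep) if k]
    conditions = counts.conditions()
    E: Dict[Condition, np.ndarray] = {}
    summary = pd.DataFrame(index=pd.Index(gene_ids, name="gene_id"))
    for cond in conditions:
        by_frac: Dict[str, Dict[int, int]] = {"total": {}, "polysome": {}}
        for j, s in enumerate(counts.samples):
            if s.condition == cond:
                if s.replicate in by_frac[s.fraction]:
                    raise ValidationError(
                        f"condition {cond}: duplicate replicate {s.replicate} in fraction {s.fraction}"
                    )
                by_frac[s.fraction][s.replicate] = j
        for frac in ("total", "polysome"):
            if not by_frac[frac]:
                raise ValidationError(f"condition {cond} lacks {frac} libraries")
        if set(by_frac["total"]) != set(by_frac["polysome"]):
            raise ValidationError(
                f"condition {cond}: unpaired replicate indices "
                f"(total {sorted(by_frac['total'])}, polysome {sorted(by_frac['polysome'])})"
            )
        reps = sorted(by_frac["total"])
        if len(reps) < 2:
            raise ValidationError(f"condition {cond}: need >= 2 replicates, have {len(reps)}")
        p_cols = [by_frac["polysome"][r] for r in reps]
        t_cols = [by_frac["total"][r] for r in reps]
        P = normalized[np.ix_(keep.nonzero()[0], p_cols)]
        T = normalized[np.ix_(keep.nonzero()[0], t_cols)]
        e = np.log2((P + pseudocount) / (T + pseudocount))
        E[cond] = e
        summary[f"E_mean.{_cond_label(cond)}"] = e.mean(axis=1)
    # per-line treatment-induced shift in mean enrichment
    lines = sorted({c[0] for c in conditions})
    for line in lines:
        tr, un = (line, "treated"), (line, "untreated")
        if tr in E and un in E:
            summary[f"dE.{line}"] = (
                summary[f"E_mean.{_cond_label(tr)}"] - summary[f"E_mean.{_cond_label(un)}"]
            )
    return EnrichmentTable(gene_ids=gene_ids, conditions=conditions, E=E, summary=summary)


def _trigamma_inverse(y: float, iters: int = 50) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration."""
    if y <= 0:
        raise ValueError("trigamma inverse requires y > 0")
    x = 0.5 + 1.0 / y
    for _ in range(iters):
        tri = special.polygamma(1, x)
        step = (tri - y) / special.polygamma(2, x)
        x = max(x - step, 1e-8)
        if abs(step) < 1e-10 * x:
            break
    return float(x)


def _moderated_pvalues(mean: np.ndarray, s2: np.ndarray, n: int) -> np.ndarray:
    """Empirical-Bayes variance-moderated one-sample t-test.

    Gene-wise sample variances are shrunk toward a prior variance s0^2
    with prior degrees of freedom d0 estimated from the scale of the
    log sample variances (method of moments on the scaled F model, as
    in moderated differential-expression analysis); the t statistic
    then has d0 + (n - 1) degrees of freedom. With only two residual
    degrees of freedom per gene this borrowing of strength across
    genes is what makes replicate-level inference workable.
    """
    d1 = n - 1
    ok = s2 > 0
    if ok.sum() < 2:
        # nothing to pool; degenerate fall-through handled by caller
        raise ValidationError("too few genes with positive variance to moderate")
    z = np.log(s2[ok])
    e = z - special.digamma(d1 / 2.0) + np.log(d1 / 2.0)
    evar = float(np.var(e, ddof=1))
    rhs = evar - float(special.polygamma(1, d1 / 2.0))
    if rhs > 0:
        d0 = 2.0 * _trigamma_inverse(rhs)
        s02 = float(np.exp(np.mean(e) + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
        df = d1 + d0
        s2_post = (d0 * s02 + d1 * s2) / (d0 + d1)
    else:
        # variances are consistent across genes: infinite prior df
        s02 = float(np.exp(np.mean(e)))
        df = np.inf
        s2_post = np.full_like(s2, s02)
    t = mean / np.sqrt(s2_post / n)
    if np.isfinite(df):
        return 2.0 * stats.t.sf(np.abs(t), df=df)
    return 2.0 * stats.norm.sf(np.abs(t))


def condition_pvalues(table: EnrichmentTable, moderated: bool = True) -> EnrichmentTable:
    """Two-sided one-sample test of mean log2 enrichment = 0, per gene
    and condition.

    By default the gene-wise variance is moderated across genes
    (empirical Bayes, see :func:`_moderated_pvalues`); with
    ``moderated=False`` the plain t-test on the n - 1 replicate degrees
    of freedom is used. Degenerate replicate sets are resolved
    deterministically: p = 1 when every replicate score is exactly 0,
    and (in the unmoderated test) p = ``ZERO_VARIANCE_P`` when the mean
    is nonzero but the replicate variance is zero.
    """
    for cond in table.conditions:
        e = table.E[cond]
        n = e.shape[1]
        if n < 2:
            raise ValidationError(f"condition {cond}: need >= 2 replicates for testing")
        mean = e.mean(axis=1)
        sd = e.std(axis=1, ddof=1)
        if moderated:
            p = _moderated_pvalues(mean, sd**2, n)
            p[(sd == 0) & (mean == 0)] = 1.0
        else:
            p = np.ones(e.shape[0])
            ok = sd > 0
            with np.errstate(divide="ignore", invalid="ignore"):
                t = mean[ok] / (sd[ok] / np.sqrt(n))
            p[ok] = 2.0 * stats.t.sf(np.abs(t), df=n - 1)
            degen = (~ok) & (mean != 0)
            p[degen] = ZERO_VARIANCE_P
        table.summary[f"p.{_cond_label(cond)}"] = p
    return table


def storey_qvalues(
    p: Sequence[float],
    lambda_: Union[float, Sequence[float]] = 0.5,
    pi0: Optional[float] = None,
) -> Tuple[np.ndarray, StoreyFit]:
    """Storey q-values with a point (or grid-averaged) pi0 estimate.

    pi0 is estimated as ``#{p_i > lambda} / (m (1 - lambda))``, capped
    at 1 and floored at 1/m so it stays positive; with a grid the
    estimates are averaged. q-values are the step-up tail minima
    ``q_(i) = min_{j >= i} pi0 * m * p_(j) / j`` on sorted p-values,
    clipped to [0, 1], with the input order restored. Forcing
    ``pi0=1`` recovers the Benjamini-Hochberg adjusted values.
    """
    p = np.asarray(p, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("p must be a non-empty 1-d vector")
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    lams = (float(lambda_),) if isinstance(lambda_, (int, float)) else tuple(float(l) for l in lambda_)
    if any(not 0.0 < l < 1.0 for l in lams):
        raise ValueError(f"lambda values must lie in (0, 1), got {lams}")
    if pi0 is None:
        ests = [np.mean(p > l) / (1.0 - l) for l in lams]
        pi0_hat = float(np.mean(ests))
        pi0_hat = min(1.0, max(pi0_hat, 1.0 / m))
    else:
        if not 0.0 < pi0 <= 1.0:
            raise ValueError(f"pi0 must lie in (0, 1], got {pi0}")
        pi0_hat = float(pi0)
    order = np.argsort(p, kind="mergesort")
    ranks = np.arange(1, m + 1)
    q_sorted = pi0_hat * m * p[order] / ranks
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q_sorted = np.clip(q_sorted, 0.0, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q, StoreyFit(lambda_=lams, pi0=pi0_hat, m=m)


def band_classifier(table: EnrichmentTable, config: PipelineConfig) -> EnrichmentTable:
    """Select regulated genes by the q gate plus the two-s.d. band on d.

    Requires dE columns for both the responsive and control line and a
    ``q_min`` column. Populates ``d``, ``selected`` and ``class``.
    """
    resp, ctrl = config.responsive_line, config.control_line
    for line in (resp, ctrl):
        if f"dE.{line}" not in table.summary.columns:
            raise ValidationError(
                f"cell line {line!r} missing from enrichment table "
                f"(have: {[c for c in table.summary.columns if c.startswith('dE.')]})"
            )
    if "q_min" not in table.summary.columns:
        raise ValidationError("q_min not computed; run the q-value stage first")
    d = (table.summary[f"dE.{resp}"] - table.summary[f"dE.{ctrl}"]).to_numpy()
    center = float(np.median(d)) if config.band_center == "median" else float(np.mean(d))
    spread = float(np.std(d, ddof=1)) if d.size > 1 else 0.0
    table.band_center = center
    table.band_spread = spread
    table.summary["d"] = d
    if spread == 0.0:
        warnings.warn("d distribution has zero spread; no gene can be selected")
        selected = np.zeros(d.size, dtype=bool)
    else:
        gate = table.summary["q_min"].to_numpy() < config.q_threshold
        outside = np.abs(d - center) >= config.band_multiplier * spread
        selected = gate & outside
    cls = np.where(selected & (d - center > 0), "positive",
                   np.where(selected & (d - center < 0), "negative", "none"))
    table.summary["selected"] = selected
    table.summary["class"] = cls
    return table


def selection_counts(summary: pd.DataFrame) -> Dict[str, int]:
    """Class sizes of a classified table: positive, negative, and their
    combined total of selected mRNAs."""
    if "class" not in summary.columns:
        raise ValidationError("table has no 'class' column; run the classifier first")
    pos = int((summary["class"] == "positive").sum())
    neg = int((summary["class"] == "negative").sum())
    return {"positive": pos, "negative": neg, "total": pos + neg}


def run_diff_translation(counts: CountMatrix, config: PipelineConfig) -> EnrichmentTable:
    """Full inference chain: normalize, score, test, adjust, classify.

    Size factors come from the spike-in rows when at least three spikes
    are usable, otherwise from non-spike library totals. q-values are
    computed within each condition separately. Deterministic given the
    inputs and config.
    """
    try:
        factors = spike_size_factors(counts)
    except ValidationError as exc:
        warnings.warn(f"spike normalization unavailable ({exc}); using library totals")
        factors = total_count_factors(counts)
    normalized = apply_factors(counts, factors)
    table = enrichment_scores(normalized, counts, pseudocount=config.pseudocount)
    table = condition_pvalues(table, moderated=config.moderated_test)
    q_cols = []
    for cond in table.conditions:
        lbl = _cond_label(cond)
        q, fit = storey_qvalues(
            table.summary[f"p.{lbl}"].to_numpy(),
            lambda_=config.storey_lambda,
            pi0=config.pi0,
        )
        table.summary[f"q.{lbl}"] = q
        table.storey_fits[cond] = fit
        q_cols.append(f"q.{lbl}")
    table.summary["q_min"] = table.summary[q_cols].min(axis=1)
    return band_classifier(table, config)
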