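"""qPCR and reporter quantification formulas.

Calculators for cycle-threshold (Ct) based quantification:

* RIP-qPCR chain — input-normalized ΔCt, percent input, and fold
  enrichment over a non-specific antibody control;
* −ΔΔCt relative expression against a reference gene (e.g. TBP);
* dual-reporter normalizations — flow-cytometry tRFP/tGFP fold change
  with the twofold hit call, and Renilla/Firefly luciferase ratios.

The input dilution factor is the reciprocal fraction of lysate reserved
as input: saving 10% of the lysate means factor 10, which subtracts
log2(10) cycles from the input Ct so it represents the full lysate.
Replicate Ct values are averaged on the Ct (cycle) scale before the
exponentiation steps.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, List, Sequence, Tuple

import numpy as np
import pandas as pd

__all__ = [
    "QpcrRecord",
    "ReporterSummary",
    "rip_normalized_dct",
    "rip_percent_input",
    "rip_fold_enrichment",
    "ddct_fold_change",
    "reporter_fold",
    "dual_luciferase_ratio",
    "summarize_rip_table",
]

ROLES = ("rip", "input", "nonspecific", "sample", "reference")


@dataclass(frozen=True)
class QpcrRecord:
    """One Ct measurement with its role in the quantification."""

    target: str
    role: str
    ct: float
    dilution_factor: float = 1.0
    replicate: int = 1

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ValueError(f"role must be one of {ROLES}, got {self.role!r}")
        if not math.isfinite(self.ct):
            raise ValueError(f"Ct must be finite, got {self.ct}")
        if self.role == "input" and self.dilution_factor < 1:
            raise ValueError(
                f"input dilution_factor must be >= 1 (reciprocal input fraction), got {self.dilution_factor}"
            )
        if self.dilution_factor <= 0:
            raise ValueError(f"dilution_factor must be > 0, got {self.dilution_factor}")


@dataclass(frozen=True)
class ReporterSummary:
    """Median fluorescence intensities of a dual-fluorescent reporter."""

    mfi_rfp_treated: float
    mfi_gfp_treated: float
    mfi_rfp_untreated: float
    mfi_gfp_untreated: float

    def __post_init__(self) -> None:
        for name in ("mfi_rfp_treated", "mfi_gfp_treated", "mfi_rfp_untreated", "mfi_gfp_untreated"):
            v = getattr(self, name)
            if not (math.isfinite(v) and v > 0):
                raise ValueError(f"{name} must be a positive finite MFI, got {v}")


def rip_normalized_dct(ct_rip: float, ct_input: float, dilution_factor: float) -> float:
    """ΔCt(normalized RIP) = Ct(RIP) − (Ct(Input) − log2(dilution factor))."""
    if dilution_factor <= 0:
        raise ValueError(f"dilution_factor must be > 0, got {dilution_factor}")
    return ct_rip - (ct_input - math.log2(dilution_factor))


def rip_percent_input(dct_normalized: float) -> float:
    """Percent input = 100 × 2^(−ΔCt(normalized RIP)).

    Values above 100% are arithmetically valid but experimentally
    implausible; they are returned with a warning.
    """
    pct = 100.0 * 2.0 ** (-dct_normalized)
    if pct > 100.0:
        warnings.warn(f"percent input {pct:.3g} exceeds 100%; check Ct values")
    return pct


def rip_fold_enrichment(dct_specific: float, dct_nonspecific: float) -> float:
    """Fold enrichment = 2^(−ΔΔCt) with ΔΔCt = ΔCt(RIP) − ΔCt(NS)."""
    return 2.0 ** (dct_nonspecific - dct_specific)


def ddct_fold_change(
    ct_target_cond: float,
    ct_ref_cond: float,
    ct_target_base: float,
    ct_ref_base: float,
) -> float:
    """Relative expression by the −ΔΔCt method.

    2^(−[(Ct_target − Ct_ref)_condition − (Ct_target − Ct_ref)_baseline]).
    """
    ddct = (ct_target_cond - ct_ref_cond) - (ct_target_base - ct_ref_base)
    return 2.0 ** (-ddct)


def reporter_fold(summary: ReporterSummary, fold_cutoff: float = 2.0) -> Tuple[float, bool]:
    """tGFP-normalized tRFP fold change, treated over untreated.

    Returns ``(fold, hit)`` where a hit is a fold at or above the
    cutoff (>= twofold by default).
    """
    if fold_cutoff <= 0:
        raise ValueError(f"fold_cutoff must be > 0, got {fold_cutoff}")
    fold = (summary.mfi_rfp_treated / summary.mfi_gfp_treated) / (
        summary.mfi_rfp_untreated / summary.mfi_gfp_untreated
    )
    return fold, fold >= fold_cutoff


def dual_luciferase_ratio(
    renilla: float, firefly: float, renilla_ctrl: float, firefly_ctrl: float
) -> float:
    """Firefly-normalized Renilla activity relative to a control construct."""
    for name, v in (("renilla", renilla), ("firefly", firefly),
                    ("renilla_ctrl", renilla_ctrl), ("firefly_ctrl", firefly_ctrl)):
        if not v > 0:
            raise ValueError(f"{name} must be positive, got {v}")
    return (renilla / firefly) / (renilla_ctrl / firefly_ctrl)


def summarize_rip_table(records: Iterable[QpcrRecord]) -> pd.DataFrame:
    """Per-target RIP quantification from a flat record set.

    For each target, technical replicates are averaged on the Ct scale
    within each role; the table reports the normalized ΔCt of the
    specific and non-specific pulldowns, percent input of the specific
    pulldown, and fold enrichment over the non-specific antibody.
    """
    df = pd.DataFrame(
        [
            {"target": r.target, "role": r.role, "ct": r.ct, "dilution_factor": r.dilution_factor}
            for r in records
        ]
    )
    if df.empty:
        raise ValueError("no qPCR records supplied")
    rows: List[dict] = []
    for target, grp in df.groupby("target", sort=True):
        mean_ct = grp.groupby("role")["ct"].mean()
        for role in ("rip", "input", "nonspecific"):
            if role not in mean_ct.index:
                raise ValueError(f"target {target!r}: missing role {role!r}")
        dil = grp.loc[grp["role"] == "input", "dilution_factor"].iloc[0]
        dct_rip = rip_normalized_dct(mean_ct["rip"], mean_ct["input"], dil)
        dct_ns = rip_normalized_dct(mean_ct["nonspecific"], mean_ct["input"], dil)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            pct = rip_percent_input(dct_rip)
        rows.append(
            {
                "target": target,
                "dct_rip": dct_rip,
                "dct_nonspecific": dct_ns,
                "percent_input": pct,
                "fold_enrichment": rip_fold_enrichment(dct_rip, dct_ns),
            }
        )
    return pd.DataFrame(rows)
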