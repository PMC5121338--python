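"""GU-rich-element scanning and exhaustive k-mer enrichment.

The motif of interest is the GU-rich element (GRE), an alternating G/T
run (GTGTGTGTGT on the DNA strand) in 3'-UTRs. Two deterministic tools
replace probabilistic motif discovery:

* :func:`find_gre_runs` reports maximal alternating-G/T runs of at
  least ``min_run`` nucleotides as 0-based half-open intervals;
* :func:`kmer_enrichment` tests every k-mer of widths 6-10 observed in
  either of two UTR sets for over-representation (presence/absence per
  sequence, one-sided hypergeometric) in the first set, with
  Benjamini-Hochberg adjustment within each width and dinucleotide
  repeats collapsed to a repeat class (all substrings of (GT)inf are
  "GT-repeat").

Presence per sequence, not total occurrence count, is the enrichment
unit; occurrence totals are reported separately by
:func:`count_occurrences`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .io import UTRSet

__all__ = [
    "MotifOccurrence",
    "find_gre_runs",
    "scan_utrs",
    "count_occurrences",
    "kmer_enrichment",
    "repeat_class",
    "collapse_repeat_classes",
    "top_repeat_class",
]

GRE_MOTIF = "GTGTGTGTGT"


@dataclass(frozen=True)
class MotifOccurrence:
    """A motif hit on the sense strand, 0-based half-open."""

    gene_id: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError(f"invalid interval [{self.start}, {self.end})")

    @property
    def matched_width(self) -> int:
        return self.end - self.start


def find_gre_runs(seq: str, min_run: int = 10, gene_id: str = "") -> List[MotifOccurrence]:
    """Maximal alternating G/T runs of length >= ``min_run``.

    A run is a substring in which every adjacent pair is GT or TG, i.e.
    a substring of (GT)inf or (TG)inf. Maximal runs never overlap, so a
    12-nt GTGTGTGTGTGT stretch is one occurrence, not three sliding
    10-mers.
    """
    if min_run < 1:
        raise ValueError(f"min_run must be >= 1, got {min_run}")
    out: List[MotifOccurrence] = []
    n = len(seq)
    i = 0
    while i < n:
        if seq[i] not in "GT":
            i += 1
            continue
        j = i + 1
        while j < n and seq[j] in "GT" and seq[j] != seq[j - 1]:
            j += 1
        if j - i >= min_run:
            out.append(MotifOccurrence(gene_id=gene_id, start=i, end=j))
        i = j
    return out


def scan_utrs(utrs: UTRSet, min_run: int = 10) -> List[MotifOccurrence]:
    """GRE runs across a UTR set, gene order preserved."""
    occs: List[MotifOccurrence] = []
    for gid, seq in utrs.entries.items():
        occs.extend(find_gre_runs(seq, min_run=min_run, gene_id=gid))
    return occs


def count_occurrences(utrs: UTRSet, motif: str, overlapping: bool = True) -> Dict[str, int]:
    """Substring occurrence counts per gene.

    Overlapping counting slides by one position; non-overlapping is
    left-greedy (each match consumes its characters).
    """
    if not motif:
        raise ValueError("motif must be non-empty")
    counts: Dict[str, int] = {}
    for gid, seq in utrs.entries.items():
        if overlapping:
            n = 0
            start = seq.find(motif)
            while start != -1:
                n += 1
                start = seq.find(motif, start + 1)
            counts[gid] = n
        else:
            counts[gid] = seq.count(motif)
    return counts


def repeat_class(kmer: str) -> Optional[str]:
    """Canonical repeat label for a k-mer, or None.

    Perfect dinucleotide repeats (substrings of (XY)inf with X != Y) map
    to the alphabetically ordered pair, e.g. GTGTGT and TGTGTG are both
    "GT-repeat"; homopolymers map to e.g. "A-homopolymer".
    """
    bases = set(kmer)
    if len(bases) == 1:
        return f"{kmer[0]}-homopolymer"
    if len(bases) == 2:
        a, b = kmer[0], kmer[1]
        if a != b and all(kmer[i] == (a if i % 2 == 0 else b) for i in range(len(kmer))):
            return f"{''.join(sorted((a, b)))}-repeat"
    return None


def _presence_sets(utrs: UTRSet, width: int) -> List[set]:
    sets = []
    for seq in utrs.entries.values():
        sets.append({seq[i : i + width] for i in range(len(seq) - width + 1)})
    return sets


def kmer_enrichment(
    pos: UTRSet,
    neg: UTRSet,
    width_range: Tuple[int, int] = (6, 10),
) -> pd.DataFrame:
    """Exhaustive k-mer over-representation screen, positive vs negative set.

    For every k-mer of each width observed in either set, counts the
    sequences containing it at least once, then computes the one-sided
    hypergeometric probability of drawing at least ``pos_with`` carriers
    when sampling ``pos_total`` sequences from the pooled universe.
    Rows carry a BH-adjusted q within each width and are sorted by p,
    then lexicographically by k-mer.

    Returns a DataFrame with columns kmer, width, pos_with, pos_total,
    neg_with, neg_total, p, q, repeat_class.
    """
    lo, hi = width_range
    if not (2 <= lo <= hi <= 12):
        raise ValueError(f"widths must satisfy 2 <= lo <= hi <= 12, got {width_range}")
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("both UTR sets must be non-empty")
    pos_total, neg_total = len(pos), len(neg)
    M = pos_total + neg_total
    frames = []
    for width in range(lo, hi + 1):
        pos_sets = _presence_sets(pos, width)
        neg_sets = _presence_sets(neg, width)
        universe = sorted(set().union(*pos_sets, *neg_sets))
        if not universe:
            continue
        pos_with = np.array([sum(k in s for s in pos_sets) for k in universe])
        neg_with = np.array([sum(k in s for s in neg_sets) for k in universe])
        K = pos_with + neg_with
        p = hypergeom.sf(pos_with - 1, M, K, pos_total)
        _, q, _, _ = multipletests(p, method="fdr_bh")
        frames.append(
            pd.DataFrame(
                {
                    "kmer": universe,
                    "width": width,
                    "pos_with": pos_with,
                    "pos_total": pos_total,
                    "neg_with": neg_with,
                    "neg_total": neg_total,
                    "p": p,
                    "q": q,
                    "repeat_class": [repeat_class(k) or "none" for k in universe],
                }
            )
        )
    if not frames:
        return pd.DataFrame(
            columns=[
                "kmer", "width", "pos_with", "pos_total",
                "neg_with", "neg_total", "p", "q", "repeat_class",
            ]
        )
    out = pd.concat(frames, ignore_index=True)
    out = out.sort_values(["p", "kmer"], kind="mergesort").reset_index(drop=True)
    return out


def collapse_repeat_classes(rows: pd.DataFrame) -> pd.DataFrame:
    """One representative (best p) row per repeat class; non-repeat
    k-mers kept as-is. Preserves the overall p ranking."""
    is_rep = rows["repeat_class"] != "none"
    reps = rows[is_rep].drop_duplicates(subset="repeat_class", keep="first")
    out = pd.concat([reps, rows[~is_rep]], ignore_index=False)
    return out.sort_index().reset_index(drop=True)


def top_repeat_class(rows: pd.DataFrame) -> Optional[str]:
    """Repeat class of the best-ranked row that belongs to one."""
    hits = rows[rows["repeat_class"] != "none"]
    if hits.empty:
        return None
    return str(hits.iloc[0]["repeat_class"])


def carrier_fraction(n_carriers: int, n_total: int) -> float:
    """Percentage of sequences carrying a motif, to one decimal place."""
    if n_total <= 0:
        raise ValueError(f"n_total must be > 0, got {n_total}")
    if not 0 <= n_carriers <= n_total:
        raise ValueError(f"n_carriers must lie in [0, {n_total}], got {n_carriers}")
    return round(100.0 * n_carriers / n_total, 1)
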