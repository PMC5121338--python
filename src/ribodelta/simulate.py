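"""Seeded synthetic-data generators with ground truth.

Every input the pipeline consumes can be generated here with known
truth labels, so each stage is testable end to end without any external
download:

* a polysome-profiling count experiment — two cell lines x two
  treatments x paired total/polysome libraries in triplicate, with
  negative-binomial counts around log-normal baselines, spike-in rows
  at constant nominal level, and translational effects implanted only
  in the responsive line's treated condition (an effect common to both
  lines could not mark the differential response, so none is planted);
* 3'-UTR sequences with GU-repeat elements implanted at a high rate in
  the positive class and at a low background rate elsewhere;
* qPCR Ct tables constructed to invert exactly through the RIP formula
  chain before noise;
* a paired tumour/normal cohort with subtype labels and ordered groups
  carrying a linear location trend.

Each generator draws from its own RNG stream, derived from the master
seed by stable hashing of the generator name, so adding one generator
never perturbs the draws of another. Repeated calls with the same
config are byte-identical.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np

from .config import PAM50_ORDER
from .io import CountMatrix, SampleMeta, UTRSet
from .qpcr import QpcrRecord
from .trends import OrderedGroups, PairedExpression

__all__ = [
    "SimConfig",
    "GeneTruth",
    "SimTruth",
    "simulate_polysome_experiment",
    "simulate_utrs",
    "simulate_qpcr",
    "simulate_paired_cohort",
]

# Approximate PAM50 subtype frequencies in breast-cancer cohorts.
SUBTYPE_PROBS = {
    "LumA": 0.42,
    "LumB": 0.20,
    "Her2": 0.10,
    "Basal": 0.16,
    "Normal": 0.06,
    "unknown": 0.06,
}


@dataclass
class SimConfig:
    """Study conditions for the synthetic experiment.

    Defaults mirror the profiled design: 3 replicates per fraction and
    condition, two cell lines of which one responds to treatment,
    library depth of one million expected counts, and a moderate
    negative-binomial dispersion typical of bulk RNA-seq biological
    replicates. Motif implantation places one (GT)_r run (r >= 5, i.e.
    >= 10 nt) per carrier UTR.
    """

    n_genes: int = 2000
    n_positive: int = 25
    n_negative: int = 25
    effect_size: float = 4.0  # |log2 shift| in the responsive treated polysome
    depth: float = 1e6  # expected non-spike counts per library
    dispersion: float = 0.01  # NB: var = mu + dispersion * mu^2
    replicates: int = 3
    implant_min_mean: float = 50.0  # expected total counts for implant-eligible genes
    n_spikes: int = 30
    spike_fraction: float = 0.02  # share of library mass in spike rows
    depth_jitter_sd: float = 0.15  # log-normal sd of per-sample depth factors
    gre_implant_rate: float = 0.3
    utr_length_range: Tuple[int, int] = (200, 1000)
    background_gt_rate: float = 0.01
    gre_min_run: int = 10
    ct_noise_sd: float = 0.2
    n_patients: int = 111
    n_cohort_genes: int = 20
    cohort_noise_sd: float = 0.25  # sd of per-cell log2 noise in the cohort
    trend_group_sizes: Tuple[int, ...] = (10, 53, 13)  # e.g. T1N0/T2N>0/T3N>0 cohort sizes
    trend_shift: float = 1.0
    responsive_line: str = "MCF10A"
    control_line: str = "MCF7"
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_positive + self.n_negative > self.n_genes:
            raise ValueError("n_positive + n_negative must not exceed n_genes")
        for name in ("gre_implant_rate", "background_gt_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.replicates < 2:
            raise ValueError("need >= 2 replicates per condition")
        if self.depth <= 0 or self.dispersion < 0:
            raise ValueError("depth must be > 0 and dispersion >= 0")
        lo, hi = self.utr_length_range
        if not 1 <= lo <= hi:
            raise ValueError(f"invalid utr_length_range {self.utr_length_range}")
        if lo < self.gre_min_run:
            raise ValueError("UTRs must be at least gre_min_run long to host an implant")
        if self.n_patients < 4:
            raise ValueError("n_patients must be >= 4")
        if self.ct_noise_sd < 0 or self.cohort_noise_sd < 0:
            raise ValueError("noise s.d. values must be >= 0")


@dataclass
class GeneTruth:
    true_class: str = "none"  # positive / negative / none
    true_dE_responsive: float = 0.0
    true_dE_control: float = 0.0
    has_gre: bool = False


@dataclass
class SimTruth:
    """Per-gene ground truth of the implanted effects."""

    genes: Dict[str, GeneTruth]

    def ids_of_class(self, cls: str) -> List[str]:
        return [g for g, t in self.genes.items() if t.true_class == cls]


def _stream(cfg: SimConfig, name: str) -> np.random.Generator:
    """Independent RNG stream per generator, derived from the master seed."""
    return np.random.default_rng([cfg.rng_seed & 0x7FFFFFFF, zlib.crc32(name.encode())])


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    mean = np.maximum(mean, 1e-12)
    if dispersion <= 0:
        return rng.poisson(mean)
    n = 1.0 / dispersion
    p = n / (n + mean)
    return rng.negative_binomial(n, p)


def simulate_polysome_experiment(cfg: SimConfig) -> Tuple[CountMatrix, SimTruth]:
    """Generate the full count experiment with implanted effects.

    Baseline gene abundances are log-normal; total-fraction counts are
    NB around ``depth x relative abundance x sample depth factor``;
    polysome-fraction means are additionally scaled by ``2^E`` where
    E = +/- effect_size for implanted genes in the responsive line's
    treated condition and 0 everywhere else. Spike rows keep a constant
    nominal level, scaled only by the per-sample depth factor.
    """
    rng = _stream(cfg, "polysome")
    gene_ids = [f"gene{i:05d}" for i in range(cfg.n_genes)]
    spike_ids = [f"ERCC-{i:04d}" for i in range(cfg.n_spikes)]
    rel = rng.lognormal(mean=0.0, sigma=1.5, size=cfg.n_genes)
    rel = rel / rel.sum() * (1.0 - cfg.spike_fraction)
    spike_rel = rng.lognormal(mean=0.0, sigma=1.0, size=cfg.n_spikes)
    spike_rel = spike_rel / spike_rel.sum() * cfg.spike_fraction
    base_mu = np.concatenate([rel, spike_rel]) * cfg.depth

    # implant effects only into detectably expressed genes: a polysomal
    # shift in a gene with single-digit expected counts is not
    # recoverable by any analysis, and the profiled candidates were by
    # construction detected transcripts
    eligible = np.flatnonzero(base_mu[: cfg.n_genes] >= cfg.implant_min_mean)
    if eligible.size < cfg.n_positive + cfg.n_negative:
        raise ValueError(
            f"only {eligible.size} genes reach implant_min_mean={cfg.implant_min_mean}; "
            "lower the floor or raise depth"
        )
    implant = rng.permutation(eligible)[: cfg.n_positive + cfg.n_negative]
    pos_set = {gene_ids[i] for i in implant[: cfg.n_positive]}
    neg_set = {gene_ids[i] for i in implant[cfg.n_positive :]}

    truth = SimTruth(genes={g: GeneTruth() for g in gene_ids + spike_ids})
    e_implant = np.zeros(cfg.n_genes)
    for i, g in enumerate(gene_ids):
        if g in pos_set:
            truth.genes[g] = GeneTruth("positive", cfg.effect_size, 0.0)
            e_implant[i] = cfg.effect_size
        elif g in neg_set:
            truth.genes[g] = GeneTruth("negative", -cfg.effect_size, 0.0)
            e_implant[i] = -cfg.effect_size

    samples: List[SampleMeta] = []
    columns: List[np.ndarray] = []
    mix_cycle = ("mix1", "mix2")
    for line in (cfg.responsive_line, cfg.control_line):
        for treatment in ("untreated", "treated"):
            for fraction in ("total", "polysome"):
                for rep in range(1, cfg.replicates + 1):
                    sid = f"{line}.{treatment}.{fraction}.r{rep}"
                    samples.append(
                        SampleMeta(
                            sample_id=sid,
                            cell_line=line,
                            treatment=treatment,
                            fraction=fraction,
                            replicate=rep,
                            spike_mix=mix_cycle[rep % 2],
                        )
                    )
                    depth_factor = rng.lognormal(mean=0.0, sigma=cfg.depth_jitter_sd)
                    mu = base_mu.copy()
                    if (
                        fraction == "polysome"
                        and line == cfg.responsive_line
                        and treatment == "treated"
                    ):
                        mu[: cfg.n_genes] = mu[: cfg.n_genes] * 2.0**e_implant
                    columns.append(_nb_draw(rng, mu * depth_factor, cfg.dispersion))
    counts = np.column_stack(columns)
    cm = CountMatrix(
        gene_ids=gene_ids + spike_ids,
        samples=samples,
        counts=counts,
        spike_ids=frozenset(spike_ids),
    )
    return cm, truth


def simulate_utrs(truth: SimTruth, cfg: SimConfig) -> UTRSet:
    """Random-background UTRs with GU-repeat implants.

    Positive-class genes receive one (GT)_r run (2r >= gre_min_run nt)
    with probability ``gre_implant_rate``; all other genes with the low
    ``background_gt_rate``. Implantation is recorded in
    ``truth.genes[g].has_gre``.
    """
    rng = _stream(cfg, "utrs")
    lo, hi = cfg.utr_length_range
    entries: Dict[str, str] = {}
    bases = np.array(list("ACGT"))
    for gid, gt in truth.genes.items():
        if gid.startswith("ERCC-"):
            continue
        length = int(rng.integers(lo, hi + 1))
        seq = rng.choice(bases, size=length)
        rate = cfg.gre_implant_rate if gt.true_class == "positive" else cfg.background_gt_rate
        gt.has_gre = bool(rng.random() < rate)
        if gt.has_gre:
            repeats = int(rng.integers(cfg.gre_min_run // 2, cfg.gre_min_run + 1))
            run = np.array(list("GT" * repeats))
            if run.size > length:
                run = run[:length]
            start = int(rng.integers(0, length - run.size + 1))
            seq[start : start + run.size] = run
        entries[gid] = "".join(seq)
    return UTRSet(entries)


def simulate_qpcr(true_fold: float, cfg: SimConfig) -> List[QpcrRecord]:
    """Ct records whose noiseless RIP chain returns ``true_fold`` exactly.

    Input Ct is fixed at 20 cycles with a dilution factor of 10 (10% of
    lysate reserved); the non-specific pulldown sits 8 cycles above the
    dilution-adjusted input and the specific pulldown log2(true_fold)
    cycles below that. Gaussian noise of sd ``ct_noise_sd`` is added per
    replicate.
    """
    if true_fold <= 0:
        raise ValueError(f"true_fold must be > 0, got {true_fold}")
    rng = _stream(cfg, "qpcr")
    ct_input, dilution = 20.0, 10.0
    adj_input = ct_input - np.log2(dilution)
    dct_ns = 8.0
    dct_rip = dct_ns - np.log2(true_fold)
    records: List[QpcrRecord] = []
    for rep in range(1, cfg.replicates + 1):
        noise = rng.normal(0.0, cfg.ct_noise_sd, size=3) if cfg.ct_noise_sd > 0 else np.zeros(3)
        records.append(
            QpcrRecord("target", "rip", float(adj_input + dct_rip + noise[0]), 1.0, rep)
        )
        records.append(
            QpcrRecord("target", "input", float(ct_input + noise[1]), dilution, rep)
        )
        records.append(
            QpcrRecord("target", "nonspecific", float(adj_input + dct_ns + noise[2]), 1.0, rep)
        )
    return records


def simulate_paired_cohort(
    cfg: SimConfig,
    true_log2fc: Optional[np.ndarray] = None,
) -> Tuple[PairedExpression, OrderedGroups]:
    """Matched tumour/normal cohort plus ordered groups with a trend.

    Normal-tissue expression is log-normal; tumour expression satisfies
    ``T + 1 = (N + 1) * 2^(fc_g + eps)`` with per-cell Gaussian log2
    noise, so the per-gene mean fold change recovers ``fc_g``. When
    ``true_log2fc`` is not given, gene effects are drawn N(0, 1).
    Ordered-group values are N(trend_shift * group_index, 1).
    """
    rng = _stream(cfg, "cohort")
    n_g, n_p = cfg.n_cohort_genes, cfg.n_patients
    gene_ids = [f"cg{i:03d}" for i in range(n_g)]
    patient_ids = [f"patient{i:03d}" for i in range(n_p)]
    if true_log2fc is None:
        fc = rng.normal(0.0, 1.0, size=n_g)
    else:
        fc = np.asarray(true_log2fc, dtype=float)
        if fc.shape != (n_g,):
            raise ValueError(f"true_log2fc must have shape ({n_g},), got {fc.shape}")
    N = rng.lognormal(mean=3.0, sigma=1.0, size=(n_g, n_p))
    eps = rng.normal(0.0, cfg.cohort_noise_sd, size=(n_g, n_p))
    T = np.maximum((N + 1.0) * 2.0 ** (fc[:, None] + eps) - 1.0, 0.0)
    labels = list(SUBTYPE_PROBS)
    probs = np.array(list(SUBTYPE_PROBS.values()))
    assign = rng.choice(len(labels), size=n_p, p=probs / probs.sum())
    subtype = {p: labels[a] for p, a in zip(patient_ids, assign)}
    pe = PairedExpression(gene_ids=gene_ids, patient_ids=patient_ids, T=T, N=N, subtype=subtype)

    groups = []
    for i, size in enumerate(cfg.trend_group_sizes):
        groups.append((f"group{i + 1}", rng.normal(cfg.trend_shift * i, 1.0, size=size)))
    og = OrderedGroups(groups=groups, alternative="two-sided")
    return pe, og
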