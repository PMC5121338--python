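"""Pipeline configuration.

All numeric gates of the analysis live here so that a run is fully
described by one small, serializable object: the per-condition q-value
threshold, the band multiplier and center used to call translationally
regulated genes, the pseudocount applied before the log-ratio, the
Storey pi0 tuning parameter, the motif-search width window, the minimum
GU-repeat run length, and the reporter fold cutoff.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Tuple, Union

import yaml

__all__ = ["PipelineConfig", "PAM50_ORDER"]

# Conventional display order for PAM50 intrinsic subtypes; patients with
# no assignment sort last.
PAM50_ORDER: Tuple[str, ...] = (
    "LumA",
    "LumB",
    "Her2",
    "Basal",
    "Normal",
    "unknown",
)


@dataclass
class PipelineConfig:
    """Knobs controlling every analysis stage.

    Parameters
    ----------
    q_threshold:
        Per-gene significance gate: a gene must reach a Storey q-value
        below this level in at least one of the four (cell line,
        treatment) conditions.
    band_multiplier:
        How many standard deviations from the band center the between-
        line difference ``d`` must lie for a gene to be selected.
    band_center:
        Whether the band is centered on the median (default) or mean of
        the ``d`` distribution.
    pseudocount:
        Added to both polysome and total normalized abundances before
        the log2 ratio, so zero counts stay finite.
    moderated_test:
        Moderate the per-gene replicate variance across genes
        (empirical Bayes) in the per-condition test; with False a plain
        one-sample t-test on n-1 degrees of freedom is used.
    storey_lambda:
        Tuning value(s) in (0, 1) for the pi0 estimate. A scalar uses
        the single-lambda estimator; a sequence averages the estimate
        over the grid.
    pi0:
        Optional override of the estimated null proportion (e.g. force
        1.0 to reduce the q-value to plain Benjamini-Hochberg).
    motif_width_range:
        Inclusive k-mer width window for the motif enrichment screen.
    gre_min_run:
        Minimum length (nt) of an alternating G/T run reported as a
        GU-rich element.
    reporter_fold_cutoff:
        Fold change at or above which a reporter construct is called a
        hit.
    responsive_line / control_line:
        Which cell line undergoes the transition upon treatment and
        which serves as the non-responding comparator. The between-line
        difference is ``d = dE(responsive) - dE(control)``.
    subtype_order:
        Display order for patient subtype groups in heat-map column
        ordering.
    rng_seed:
        Master seed; every stochastic step derives its stream from it.
    """

    q_threshold: float = 0.03
    band_multiplier: float = 2.0
    band_center: str = "median"
    pseudocount: float = 0.5
    moderated_test: bool = True
    storey_lambda: Union[float, Sequence[float]] = 0.5
    pi0: Optional[float] = None
    motif_width_range: Tuple[int, int] = (6, 10)
    gre_min_run: int = 10
    reporter_fold_cutoff: float = 2.0
    responsive_line: str = "MCF10A"
    control_line: str = "MCF7"
    subtype_order: Tuple[str, ...] = PAM50_ORDER
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.q_threshold <= 1.0:
            raise ValueError(f"q_threshold must be in (0, 1], got {self.q_threshold}")
        if self.band_multiplier <= 0:
            raise ValueError(f"band_multiplier must be > 0, got {self.band_multiplier}")
        if self.band_center not in ("median", "mean"):
            raise ValueError(f"band_center must be 'median' or 'mean', got {self.band_center!r}")
        if self.pseudocount < 0:
            raise ValueError(f"pseudocount must be >= 0, got {self.pseudocount}")
        lams = self.lambda_grid()
        if not lams or any(not 0.0 < l < 1.0 for l in lams):
            raise ValueError(f"storey_lambda values must lie in (0, 1), got {self.storey_lambda}")
        if self.pi0 is not None and not 0.0 < self.pi0 <= 1.0:
            raise ValueError(f"pi0 override must be in (0, 1], got {self.pi0}")
        lo, hi = self.motif_width_range
        if not (2 <= lo <= hi <= 12):
            raise ValueError(f"motif_width_range must satisfy 2 <= lo <= hi <= 12, got {self.motif_width_range}")
        if self.gre_min_run < 1:
            raise ValueError(f"gre_min_run must be >= 1, got {self.gre_min_run}")
        if self.reporter_fold_cutoff <= 0:
            raise ValueError(f"reporter_fold_cutoff must be > 0, got {self.reporter_fold_cutoff}")

    def lambda_grid(self) -> Tuple[float, ...]:
        """storey_lambda as a tuple, whether given as scalar or grid."""
        if isinstance(self.storey_lambda, (int, float)):
            return (float(self.storey_lambda),)
        return tuple(float(l) for l in self.storey_lambda)

    # -- serialization -------------------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["motif_width_range"] = list(self.motif_width_range)
        d["subtype_order"] = list(self.subtype_order)
        if not isinstance(self.storey_lambda, (int, float)):
            d["storey_lambda"] = list(self.lambda_grid())
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "motif_width_range" in d:
            d["motif_width_range"] = tuple(d["motif_width_range"])
        if "subtype_order" in d:
            d["subtype_order"] = tuple(d["subtype_order"])
        if isinstance(d.get("storey_lambda"), list):
            d["storey_lambda"] = tuple(d["storey_lambda"])
        return cls(**d)

    def save(self, path: Union[str, Path]) -> None:
        path = Path(path)
        text = yaml.safe_dump(self.to_dict(), sort_keys=True)
        path.write_text(text)

    @classmethod
    def load(cls, path: Union[str, Path]) -> "PipelineConfig":
        path = Path(path)
        if path.suffix == ".json":
            d = json.loads(path.read_text())
        else:
            d = yaml.safe_load(path.read_text())
        if not isinstance(d, dict):
            raise ValueError(f"config file {path} does not contain a mapping")
        return cls.from_dict(d)
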