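"""Domain types and file I/O.

The pipeline consumes gene-level count tables (TSV with a sample-id
header and a sidecar metadata table), 3'-UTR sequences (FASTA), and
emits flat TSV result tables. Everything read is validated on load and
every error names the offending record.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "SampleMeta",
    "CountMatrix",
    "UTRSet",
    "read_counts",
    "write_counts",
    "read_fasta",
    "write_fasta",
    "write_table",
    "read_table",
    "ValidationError",
]

TREATMENTS = ("untreated", "treated")
FRACTIONS = ("total", "polysome")
SPIKE_MIXES = ("mix1", "mix2", "none")

#: Float precision used by write_table; declared in the file header.
TABLE_FLOAT_SIGFIGS = 9


class ValidationError(ValueError):
    """An input file or in-memory object violates a contract."""


@dataclass(frozen=True)
class SampleMeta:
    """Metadata for one sequencing library.

    ``(cell_line, treatment)`` pairs define the experiment's conditions;
    ``fraction`` distinguishes the polysome-associated library from the
    matched total-mRNA library, paired by ``replicate`` index.
    """

    sample_id: str
    cell_line: str
    treatment: str
    fraction: str
    replicate: int
    spike_mix: str = "none"

    def __post_init__(self) -> None:
        if not self.sample_id:
            raise ValidationError("sample_id must be non-empty")
        if self.treatment not in TREATMENTS:
            raise ValidationError(
                f"sample {self.sample_id!r}: treatment must be one of {TREATMENTS}, got {self.treatment!r}"
            )
        if self.fraction not in FRACTIONS:
            raise ValidationError(
                f"sample {self.sample_id!r}: fraction must be one of {FRACTIONS}, got {self.fraction!r}"
            )
        if int(self.replicate) != self.replicate or self.replicate < 1:
            raise ValidationError(
                f"sample {self.sample_id!r}: replicate must be a positive integer, got {self.replicate!r}"
            )
        if self.spike_mix not in SPIKE_MIXES:
            raise ValidationError(
                f"sample {self.sample_id!r}: spike_mix must be one of {SPIKE_MIXES}, got {self.spike_mix!r}"
            )

    @property
    def condition(self) -> Tuple[str, str]:
        return (self.cell_line, self.treatment)


@dataclass
class CountMatrix:
    """Gene x sample matrix of non-negative integer counts.

    ``spike_ids`` flags rows that are external spike-in controls; they
    participate in normalization but are excluded from inference.
    """

    gene_ids: List[str]
    samples: List[SampleMeta]
    counts: np.ndarray
    spike_ids: frozenset = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        self.gene_ids = list(self.gene_ids)
        self.samples = list(self.samples)
        self.counts = np.asarray(self.counts)
        self.spike_ids = frozenset(self.spike_ids)
        n_g, n_s = len(self.gene_ids), len(self.samples)
        if self.counts.shape != (n_g, n_s):
            raise ValidationError(
                f"counts shape {self.counts.shape} does not match {n_g} genes x {n_s} samples"
            )
        seen: Dict[str, int] = {}
        for i, g in enumerate(self.gene_ids):
            if g in seen:
                raise ValidationError(f"duplicate gene_id {g!r} (rows {seen[g]} and {i})")
            seen[g] = i
        sids = [s.sample_id for s in self.samples]
        if len(set(sids)) != len(sids):
            dup = sorted({x for x in sids if sids.count(x) > 1})
            raise ValidationError(f"duplicate sample_id(s): {dup}")
        if not np.issubdtype(self.counts.dtype, np.integer):
            frac, _ = np.modf(self.counts.astype(float))
            if np.any(frac != 0):
                g, s = np.argwhere(frac != 0)[0]
                raise ValidationError(
                    f"non-integer count at gene {self.gene_ids[g]!r}, sample {sids[s]!r}: "
                    f"{self.counts[g, s]}"
                )
            self.counts = self.counts.astype(np.int64)
        if np.any(self.counts < 0):
            g, s = np.argwhere(self.counts < 0)[0]
            raise ValidationError(
                f"negative count at gene {self.gene_ids[g]!r}, sample {sids[s]!r}: {self.counts[g, s]}"
            )
        missing = self.spike_ids - set(self.gene_ids)
        if missing:
            raise ValidationError(f"spike_ids not present among gene_ids: {sorted(missing)}")

    @property
    def sample_ids(self) -> List[str]:
        return [s.sample_id for s in self.samples]

    @property
    def spike_mask(self) -> np.ndarray:
        return np.array([g in self.spike_ids for g in self.gene_ids], dtype=bool)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.gene_ids, columns=self.sample_ids)

    def conditions(self) -> List[Tuple[str, str]]:
        """Distinct (cell_line, treatment) pairs in first-seen order."""
        out: List[Tuple[str, str]] = []
        for s in self.samples:
            if s.condition not in out:
                out.append(s.condition)
        return out


@dataclass
class UTRSet:
    """Gene-keyed 3'-UTR sequences over the DNA alphabet {A,C,G,T,N}."""

    entries: Dict[str, str]

    VALID = frozenset("ACGTN")

    def __post_init__(self) -> None:
        self.entries = dict(self.entries)
        for gid, seq in self.entries.items():
            if not gid:
                raise ValidationError("empty gene_id in UTRSet")
            if not seq:
                raise ValidationError(f"empty sequence for gene {gid!r}")
            bad = set(seq) - self.VALID
            if bad:
                raise ValidationError(
                    f"gene {gid!r}: invalid characters {sorted(bad)} (alphabet is A/C/G/T/N)"
                )

    def __len__(self) -> int:
        return len(self.entries)

    def __getitem__(self, gid: str) -> str:
        return self.entries[gid]

    def __contains__(self, gid: str) -> bool:
        return gid in self.entries

    def subset(self, gene_ids: Sequence[str]) -> "UTRSet":
        missing = [g for g in gene_ids if g not in self.entries]
        if missing:
            raise KeyError(f"gene_ids absent from UTRSet: {missing}")
        return UTRSet({g: self.entries[g] for g in gene_ids})


# ---------------------------------------------------------------------
# counts + metadata TSV


def _read_metadata(metadata_path: Union[str, Path]) -> Dict[str, SampleMeta]:
    df = pd.read_csv(metadata_path, sep="\t", dtype=str)
    required = {"sample_id", "cell_line", "treatment", "fraction", "replicate"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"metadata file missing columns: {sorted(missing)}")
    metas: Dict[str, SampleMeta] = {}
    for _, row in df.iterrows():
        sid = row["sample_id"]
        if sid in metas:
            raise ValidationError(f"duplicate sample_id {sid!r} in metadata")
        try:
            rep = int(row["replicate"])
        except (TypeError, ValueError):
            raise ValidationError(
                f"sample {sid!r}: replicate must be an integer, got {row['replicate']!r}"
            ) from None
        metas[sid] = SampleMeta(
            sample_id=sid,
            cell_line=row["cell_line"],
            treatment=row["treatment"],
            fraction=row["fraction"],
            replicate=rep,
            spike_mix=row.get("spike_mix", "none") if "spike_mix" in df.columns else "none",
        )
    return metas


def read_counts(
    path: Union[str, Path],
    metadata_path: Union[str, Path],
    spike_prefix: str = "ERCC-",
) -> CountMatrix:
    """Load a counts TSV plus its sample-metadata sidecar.

    The counts file has a header row of sample ids and a first column of
    gene ids. Rows whose gene id starts with ``spike_prefix`` are
    flagged as spike-in controls. Gene order is preserved.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    gene_ids = [str(g) for g in df.index]
    dup = df.index[df.index.duplicated()].unique()
    if len(dup):
        raise ValidationError(f"duplicate gene_id {str(dup[0])!r} in counts file {path}")
    metas = _read_metadata(metadata_path)
    samples: List[SampleMeta] = []
    for sid in df.columns:
        if sid not in metas:
            raise ValidationError(f"sample {sid!r} in counts file has no metadata entry")
        samples.append(metas[sid])
    values = df.to_numpy()
    if not np.issubdtype(values.dtype, np.number):
        # locate the first non-numeric cell for the error message
        for g in gene_ids:
            for sid in df.columns:
                try:
                    float(df.loc[g, sid])
                except (TypeError, ValueError):
                    raise ValidationError(
                        f"non-numeric count at gene {g!r}, sample {sid!r}: {df.loc[g, sid]!r}"
                    ) from None
        raise ValidationError(f"non-numeric values in counts file {path}")
    spikes = frozenset(g for g in gene_ids if g.startswith(spike_prefix))
    return CountMatrix(gene_ids=gene_ids, samples=samples, counts=values, spike_ids=spikes)


def write_counts(cm: CountMatrix, path: Union[str, Path], metadata_path: Union[str, Path]) -> None:
    """Write a CountMatrix back to counts + metadata TSVs."""
    cm.to_frame().to_csv(path, sep="\t", index_label="gene_id")
    meta = pd.DataFrame(
        [
            {
                "sample_id": s.sample_id,
                "cell_line": s.cell_line,
                "treatment": s.treatment,
                "fraction": s.fraction,
                "replicate": s.replicate,
                "spike_mix": s.spike_mix,
            }
            for s in cm.samples
        ]
    )
    meta.to_csv(metadata_path, sep="\t", index=False)


# ---------------------------------------------------------------------
# FASTA


def read_fasta(path: Union[str, Path]) -> UTRSet:
    """Load UTR sequences from FASTA.

    The header token up to the first whitespace is the gene id. Input is
    uppercased and U (RNA) is mapped to T, so UTRs supplied in mRNA
    alphabet are accepted.
    """
    entries: Dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        gid = rec.id
        if gid in entries:
            raise ValidationError(f"duplicate FASTA header token {gid!r} in {path}")
        seq = str(rec.seq).upper().replace("U", "T")
        if not seq:
            raise ValidationError(f"empty sequence for FASTA record {gid!r} in {path}")
        bad = set(seq) - UTRSet.VALID
        if bad:
            raise ValidationError(
                f"FASTA record {gid!r}: invalid characters {sorted(bad)} "
                "(allowed: A/C/G/T/U/N, any case)"
            )
        entries[gid] = seq
    return UTRSet(entries)


def write_fasta(utrs: UTRSet, path: Union[str, Path], width: int = 70) -> None:
    records = [
        SeqRecord(Seq(seq), id=gid, description="") for gid, seq in utrs.entries.items()
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


# ---------------------------------------------------------------------
# generic result tables


def write_table(records: pd.DataFrame, path: Union[str, Path]) -> None:
    """Write a result table as TSV with deterministic column order and
    fixed float precision (stated in a header comment)."""
    df = records.copy()
    with open(path, "w") as fh:
        fh.write(f"# floats at {TABLE_FLOAT_SIGFIGS} significant digits\n")
        df.to_csv(fh, sep="\t", index=False, float_format=f"%.{TABLE_FLOAT_SIGFIGS}g")


def read_table(path: Union[str, Path]) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")
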