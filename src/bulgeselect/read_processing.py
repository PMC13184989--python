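"""Merged amplicon reads -> genotype count table with CPM normalization.

Stages: optional primer clipping, orientation against the reference
scaffold, fixed-position matching with variable-position extraction, and
counting of unique genotypes normalized to counts per million
(count x 1e6 / total reads).
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq

from bulgeselect.library_model import BASES, DegenerateLibrarySpec

CPM_SCALE = 1_000_000


class EmptyInputError(ValueError):
    pass


@dataclass
class ProcessingReport:
    """Bookkeeping for a read-processing run; rejections sum with passes."""

    n_input: int = 0
    n_oriented: int = 0
    n_scaffold_pass: int = 0
    n_rejected_by_reason: dict[str, int] = field(default_factory=dict)

    def reject(self, reason: str) -> None:
        self.n_rejected_by_reason[reason] = self.n_rejected_by_reason.get(reason, 0) + 1

    @property
    def n_rejected(self) -> int:
        return sum(self.n_rejected_by_reason.values())

    def is_consistent(self) -> bool:
        return self.n_input == self.n_scaffold_pass + self.n_rejected

    def to_json(self) -> str:
        return json.dumps(
            {
                "n_input": self.n_input,
                "n_oriented": self.n_oriented,
                "n_scaffold_pass": self.n_scaffold_pass,
                "n_rejected_by_reason": dict(sorted(self.n_rejected_by_reason.items())),
            },
            indent=2,
        )


@dataclass
class GenotypeCountTable:
    """Unique genotypes with read counts and CPM for one selection arm.

    Rows are retrievable sorted by count descending, ties broken
    lexicographically by genotype (deterministic "most abundant" choice).
    """

    arm_label: str
    counts: dict[str, int]
    total_reads: int

    def __post_init__(self) -> None:
        if self.total_reads != sum(self.counts.values()):
            raise ValueError("total_reads does not match the sum of counts")
        if any(c < 0 for c in self.counts.values()):
            raise ValueError("negative read count")

    @classmethod
    def from_counts(cls, counts: dict[str, int], arm_label: str) -> "GenotypeCountTable":
        return cls(arm_label=arm_label, counts=dict(counts), total_reads=sum(counts.values()))

    def cpm(self, genotype: str) -> float:
        return self.counts[genotype] * CPM_SCALE / self.total_reads

    def __len__(self) -> int:
        return len(self.counts)

    def __contains__(self, genotype: str) -> bool:
        return genotype in self.counts

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {"genotype": list(self.counts.keys()), "count": list(self.counts.values())}
        )
        df["cpm"] = df["count"] * CPM_SCALE / self.total_reads
        df = df.sort_values(
            ["count", "genotype"], ascending=[False, True], kind="mergesort"
        ).reset_index(drop=True)
        return df

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path, arm_label: str | None = None) -> "GenotypeCountTable":
        df = pd.read_csv(path, sep="\t", dtype={"genotype": str, "count": int})
        label = arm_label if arm_label is not None else Path(path).stem
        return cls.from_counts(dict(zip(df["genotype"], df["count"])), arm_label=label)


# -- per-read operations ---------------------------------------------------


def _fixed_mismatches(read: str, spec: DegenerateLibrarySpec, offset: int = 0) -> int:
    n = 0
    for i, ref in enumerate(spec.reference_core):
        if ref == "X":
            continue
        if read[offset + i] != ref:
            n += 1
    return n


def reverse_complement(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def orient_read(
    read: str, spec: DegenerateLibrarySpec, max_fixed_mismatches: int = 0
) -> str | None:
    """Return the read in forward orientation, or None if unresolvable.

    The orientation whose fixed scaffold positions match the reference with
    fewer mismatches wins; ties and double budget failures are rejected.
    Only full-core-length reads are oriented here (clip primers first).
    """
    if len(read) != spec.core_length:
        return None
    fwd = _fixed_mismatches(read, spec)
    rc = reverse_complement(read)
    rev = _fixed_mismatches(rc, spec)
    if fwd == rev:
        return None
    best, seq = (fwd, read) if fwd < rev else (rev, rc)
    if best > max_fixed_mismatches:
        return None
    return seq


def match_and_extract(
    read: str, spec: DegenerateLibrarySpec, max_fixed_mismatches: int = 0
) -> tuple[str | None, str]:
    """Extract the genotype from an oriented read window.

    Returns ``(genotype, "ok")`` on success or ``(None, reason)`` where the
    reason is one of ``length_mismatch``, ``scaffold_mismatch``,
    ``ambiguous_variable_base``.
    """
    if len(read) < spec.core_length:
        return None, "length_mismatch"
    best_offset, best_mm = None, None
    for offset in range(len(read) - spec.core_length + 1):
        mm = _fixed_mismatches(read, spec, offset)
        if best_mm is None or mm < best_mm:
            best_offset, best_mm = offset, mm
            if mm == 0:
                break
    assert best_offset is not None and best_mm is not None
    if best_mm > max_fixed_mismatches:
        return None, "scaffold_mismatch"
    genotype = "".join(
        read[best_offset + p - 1] for p in spec.variable_positions
    )
    if any(sym not in BASES for sym in genotype):
        return None, "ambiguous_variable_base"
    return genotype, "ok"


def _find_with_mismatches(read: str, primer: str, max_mm: int, from_end: bool) -> int | None:
    """Leftmost (or rightmost) offset where primer matches within budget."""
    span = range(len(read) - len(primer) + 1)
    offsets = reversed(span) if from_end else span
    for off in offsets:
        mm = sum(1 for a, b in zip(read[off : off + len(primer)], primer) if a != b)
        if mm <= max_mm:
            return off
    return None


def clip_primers(
    read: str, fwd_primer: str, rev_primer: str, max_mismatches: int = 0
) -> str | None:
    """Remove the flanking primers and return the insert, or None."""
    if not fwd_primer or not rev_primer:
        raise ValueError("primers must be non-empty")
    f = _find_with_mismatches(read, fwd_primer, max_mismatches, from_end=False)
    if f is None:
        return None
    start = f + len(fwd_primer)
    tail = read[start:]
    r = _find_with_mismatches(tail, rev_primer, max_mismatches, from_end=True)
    if r is None:
        return None
    return tail[:r]


# -- stream-level operations ----------------------------------------------


def count_and_normalize(genotypes: Iterable[str], arm_label: str) -> GenotypeCountTable:
    """Count unique genotypes from a stream and normalize to CPM."""
    counts = Counter(genotypes)
    if not counts:
        raise EmptyInputError("no genotypes to count")
    return GenotypeCountTable.from_counts(dict(counts), arm_label=arm_label)


def iter_reads(path: str | Path, fmt: str | None = None) -> Iterator[str]:
    """Yield read sequences from a FASTA or FASTQ file (format by suffix)."""
    path = Path(path)
    if fmt is None:
        suffix = path.suffix.lower()
        fmt = "fastq" if suffix in {".fastq", ".fq"} else "fasta"
    for record in SeqIO.parse(str(path), fmt):
        yield str(record.seq).upper()


def process_reads(
    reads: Iterable[str],
    spec: DegenerateLibrarySpec,
    arm_label: str,
    max_fixed_mismatches: int = 0,
    fwd_primer: str | None = None,
    rev_primer: str | None = None,
    primer_max_mismatches: int = 0,
) -> tuple[GenotypeCountTable, ProcessingReport]:
    """Full per-read pipeline: clip (optional), orient, match, count."""
    report = ProcessingReport()
    genotypes: list[str] = []
    for read in reads:
        report.n_input += 1
        if fwd_primer is not None and rev_primer is not None:
            clipped = clip_primers(read, fwd_primer, rev_primer, primer_max_mismatches)
            if clipped is None:
                report.reject("primer_not_found")
                continue
            read = clipped
        oriented = orient_read(read, spec, max_fixed_mismatches)
        if oriented is None:
            report.reject("orientation_failed")
            continue
        report.n_oriented += 1
        genotype, reason = match_and_extract(oriented, spec, max_fixed_mismatches)
        if genotype is None:
            report.reject(reason)
            continue
        report.n_scaffold_pass += 1
        genotypes.append(genotype)
    if not genotypes:
        raise EmptyInputError("no reads passed processing")
    return count_and_normalize(genotypes, arm_label), report
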