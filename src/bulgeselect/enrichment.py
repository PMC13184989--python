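"""Two-arm comparison: inner merge on common genotypes, log2 CPM-ratio
specificity score, and CPM-distribution summaries."""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from bulgeselect.read_processing import CPM_SCALE, GenotypeCountTable

#: CPM threshold used for "high-abundance" analyses
DEFAULT_HIGH_CPM = 10.0


def specificity_score(cpm_a: float, cpm_b: float) -> float:
    """log2(cpm_a / cpm_b); positive means the genotype prefers arm A."""
    if cpm_a <= 0 or cpm_b <= 0:
        raise ValueError("specificity score requires strictly positive CPM values")
    return math.log2(cpm_a / cpm_b)


@dataclass
class MergedSpecificityTable:
    """Genotypes present in both arms, with both CPMs and the score.

    ``exclusive_a`` / ``exclusive_b`` list arm-exclusive genotypes (kept out
    of the score table; a display pseudocount is applied only on export).
    """

    frame: pd.DataFrame  # columns: genotype, cpm_a, cpm_b, score
    arm_a_label: str
    arm_b_label: str
    exclusive_a: tuple[str, ...] = ()
    exclusive_b: tuple[str, ...] = ()

    @property
    def n_common(self) -> int:
        return len(self.frame)

    def genotypes(self) -> list[str]:
        return self.frame["genotype"].tolist()

    def to_tsv(self, path: str | Path) -> None:
        self.frame.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(
        cls, path: str | Path, arm_a_label: str = "A", arm_b_label: str = "B"
    ) -> "MergedSpecificityTable":
        df = pd.read_csv(path, sep="\t", dtype={"genotype": str})
        return cls(frame=df, arm_a_label=arm_a_label, arm_b_label=arm_b_label)

    def scatter_frame(self) -> pd.DataFrame:
        """Common plus exclusive genotypes for scatter export.

        Exclusive genotypes get a display-only pseudocount of half the
        minimum observed CPM on their missing axis, and a flag column.
        """
        df = self.frame.copy()
        df["exclusive"] = "common"
        pieces = [df]
        if len(df):
            pseudo_a = df["cpm_a"].min() / 2
            pseudo_b = df["cpm_b"].min() / 2
        else:
            pseudo_a = pseudo_b = 0.5
        if self.exclusive_a:
            pieces.append(
                pd.DataFrame(
                    {
                        "genotype": list(self.exclusive_a),
                        "cpm_a": np.nan,
                        "cpm_b": pseudo_b,
                        "score": np.nan,
                        "exclusive": self.arm_a_label,
                    }
                )
            )
        if self.exclusive_b:
            pieces.append(
                pd.DataFrame(
                    {
                        "genotype": list(self.exclusive_b),
                        "cpm_a": pseudo_a,
                        "cpm_b": np.nan,
                        "score": np.nan,
                        "exclusive": self.arm_b_label,
                    }
                )
            )
        return pd.concat(pieces, ignore_index=True)


def merge_common(a: GenotypeCountTable, b: GenotypeCountTable) -> MergedSpecificityTable:
    """Inner join of two arms on genotype; score = log2(cpm_a / cpm_b).

    An empty intersection yields an empty table, not an exception.
    """
    common = sorted(set(a.counts) & set(b.counts))
    cpm_a = np.array([a.counts[g] for g in common], dtype=float) * CPM_SCALE / a.total_reads
    cpm_b = np.array([b.counts[g] for g in common], dtype=float) * CPM_SCALE / b.total_reads
    frame = pd.DataFrame(
        {
            "genotype": common,
            "cpm_a": cpm_a,
            "cpm_b": cpm_b,
            "score": np.log2(cpm_a / cpm_b) if common else np.array([]),
        }
    )
    return MergedSpecificityTable(
        frame=frame,
        arm_a_label=a.arm_label,
        arm_b_label=b.arm_label,
        exclusive_a=tuple(sorted(set(a.counts) - set(b.counts))),
        exclusive_b=tuple(sorted(set(b.counts) - set(a.counts))),
    )


@dataclass
class EnrichmentSummary:
    """Per-arm CPM distribution descriptors and enrichment counts."""

    arm_label: str
    quantiles: dict[float, float]
    threshold_counts: dict[float, int]
    n_enriched: int
    enrichment_factor: float
    n_exclusive: int


def enrichment_summary(
    post: GenotypeCountTable,
    pre: GenotypeCountTable | None = None,
    thresholds: Sequence[float] = (1.0, 10.0, 100.0),
    quantile_probs: Sequence[float] = (0.5, 0.9, 0.99),
    enrichment_factor: float = 2.0,
    pool_size: int | None = None,
) -> EnrichmentSummary:
    """Summarize one arm's CPM distribution against its round-0 state.

    When no round-0 table is supplied, the pre-selection CPM defaults to
    the equimolar expectation 1e6 / pool_size (pool_size defaults to the
    number of distinct genotypes in ``post``).
    """
    df = post.to_frame()
    cpm = df["cpm"].to_numpy()
    quantiles = {float(q): float(np.quantile(cpm, q)) for q in quantile_probs}
    threshold_counts = {float(t): int((cpm >= t).sum()) for t in thresholds}

    if pre is not None:
        pre_cpm = {
            g: c * CPM_SCALE / pre.total_reads for g, c in pre.counts.items()
        }
        n_enriched = 0
        n_exclusive = 0
        for g, c in post.counts.items():
            post_cpm = c * CPM_SCALE / post.total_reads
            if g not in pre_cpm:
                n_exclusive += 1
                continue
            if post_cpm / pre_cpm[g] > enrichment_factor:
                n_enriched += 1
    else:
        n = pool_size if pool_size is not None else len(post)
        expected = CPM_SCALE / n
        n_enriched = int((cpm / expected > enrichment_factor).sum())
        n_exclusive = 0
    return EnrichmentSummary(
        arm_label=post.arm_label,
        quantiles=quantiles,
        threshold_counts=threshold_counts,
        n_enriched=n_enriched,
        enrichment_factor=enrichment_factor,
        n_exclusive=n_exclusive,
    )


def top_sequence(table: GenotypeCountTable) -> str:
    """Most abundant genotype; count ties broken lexicographically."""
    if not table.counts:
        raise ValueError("empty count table")
    return min(table.counts, key=lambda g: (-table.counts[g], g))
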