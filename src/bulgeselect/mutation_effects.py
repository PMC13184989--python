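"""Per-position stratification of specificity scores.

For each variable position the merged table is partitioned by the base at
that position; the effect statistic is the range (max - min) of per-base
median scores, calibrated against a permutation null when needed. Medians
are robust to the heavy-tailed CPM skew; a CPM-weighted mean is reported
alongside.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from bulgeselect.enrichment import DEFAULT_HIGH_CPM, MergedSpecificityTable
from bulgeselect.library_model import BASES, DegenerateLibrarySpec

DEFAULT_MIN_N = 10


@dataclass
class PositionEffectSummary:
    position: int
    per_base: pd.DataFrame  # index: base; columns: n, median, mean, weighted_mean
    effect_range: float

    def to_row(self) -> dict:
        row: dict = {"position": self.position, "effect_range": self.effect_range}
        for base in BASES:
            if base in self.per_base.index:
                row[f"n_{base}"] = int(self.per_base.loc[base, "n"])
                row[f"median_{base}"] = self.per_base.loc[base, "median"]
            else:
                row[f"n_{base}"] = 0
                row[f"median_{base}"] = np.nan
        return row


def _position_column(
    m: MergedSpecificityTable, spec: DegenerateLibrarySpec, position: int
) -> pd.Series:
    idx = spec.position_index(position)
    return m.frame["genotype"].str[idx]


def stratify_by_position(
    m: MergedSpecificityTable, spec: DegenerateLibrarySpec, position: int
) -> dict[str, pd.DataFrame]:
    """Partition the merged rows by the base at one variable position."""
    col = _position_column(m, spec, position)
    return {base: m.frame[col == base] for base in BASES}


def _effect_summary(
    frame: pd.DataFrame, base_col: pd.Series, min_n: int, position: int
) -> PositionEffectSummary:
    rows = []
    for base in BASES:
        sub = frame[base_col == base]
        if len(sub) == 0:
            continue
        weights = np.maximum(sub["cpm_a"], sub["cpm_b"])
        rows.append(
            {
                "base": base,
                "n": len(sub),
                "median": float(sub["score"].median()),
                "mean": float(sub["score"].mean()),
                "weighted_mean": float(np.average(sub["score"], weights=weights)),
            }
        )
    per_base = pd.DataFrame(rows).set_index("base") if rows else pd.DataFrame(
        columns=["n", "median", "mean", "weighted_mean"]
    )
    eligible = per_base[per_base["n"] >= min_n] if len(per_base) else per_base
    if len(eligible) >= 2:
        effect_range = float(eligible["median"].max() - eligible["median"].min())
    else:
        effect_range = 0.0
    return PositionEffectSummary(position=position, per_base=per_base, effect_range=effect_range)


def position_effect(
    m: MergedSpecificityTable,
    spec: DegenerateLibrarySpec,
    position: int,
    min_cpm: float = DEFAULT_HIGH_CPM,
    min_n: int = DEFAULT_MIN_N,
) -> PositionEffectSummary:
    frame = m.frame[np.maximum(m.frame["cpm_a"], m.frame["cpm_b"]) >= min_cpm]
    base_col = frame["genotype"].str[spec.position_index(position)]
    return _effect_summary(frame, base_col, min_n, position)


def rank_positions_by_effect(
    m: MergedSpecificityTable,
    spec: DegenerateLibrarySpec,
    min_cpm: float = DEFAULT_HIGH_CPM,
    min_n: int = DEFAULT_MIN_N,
) -> list[PositionEffectSummary]:
    """All variable positions ranked by effect_range, descending.

    Rows are first filtered to max(cpm_a, cpm_b) >= min_cpm; per-base
    strata below min_n rows are excluded from the range. Ties break by
    position index (ascending), deterministically.
    """
    frame = m.frame[np.maximum(m.frame["cpm_a"], m.frame["cpm_b"]) >= min_cpm]
    summaries = []
    for position in spec.variable_positions:
        base_col = frame["genotype"].str[spec.position_index(position)]
        summaries.append(_effect_summary(frame, base_col, min_n, position))
    summaries.sort(key=lambda s: (-s.effect_range, s.position))
    return summaries


def effects_frame(summaries: list[PositionEffectSummary]) -> pd.DataFrame:
    return pd.DataFrame([s.to_row() for s in summaries])


def variant_specificity(
    m: MergedSpecificityTable, variants: list[str]
) -> pd.DataFrame:
    """CPM pair and score for named variants; absent ones flagged, not errors."""
    indexed = m.frame.set_index("genotype")
    rows = []
    for g in variants:
        if g in indexed.index:
            r = indexed.loc[g]
            rows.append(
                {
                    "genotype": g,
                    "present": True,
                    "cpm_a": float(r["cpm_a"]),
                    "cpm_b": float(r["cpm_b"]),
                    "score": float(r["score"]),
                }
            )
        else:
            rows.append(
                {
                    "genotype": g,
                    "present": False,
                    "cpm_a": np.nan,
                    "cpm_b": np.nan,
                    "score": np.nan,
                }
            )
    return pd.DataFrame(rows)


def permutation_null_effect_range(
    m: MergedSpecificityTable,
    spec: DegenerateLibrarySpec,
    position: int,
    n_perm: int = 200,
    seed: int | None = None,
    min_cpm: float = DEFAULT_HIGH_CPM,
    min_n: int = DEFAULT_MIN_N,
    quantiles: tuple[float, ...] = (0.5, 0.95, 0.99),
) -> dict[float, float]:
    """Null distribution of effect_range under score-column shuffles.

    Only the score column is permuted, so per-base stratum sizes are
    unchanged; returns the requested null quantiles.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be at least 100")
    rng = np.random.default_rng(seed)
    frame = m.frame[np.maximum(m.frame["cpm_a"], m.frame["cpm_b"]) >= min_cpm].reset_index(
        drop=True
    )
    base_col = frame["genotype"].str[spec.position_index(position)]
    ranges = np.empty(n_perm)
    shuffled = frame.copy()
    for k in range(n_perm):
        shuffled["score"] = rng.permutation(frame["score"].to_numpy())
        # weighted mean uses cpm columns which stay aligned with genotypes
        ranges[k] = _effect_summary(shuffled, base_col, min_n, position).effect_range
    return {float(q): float(np.quantile(ranges, q)) for q in quantiles}
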