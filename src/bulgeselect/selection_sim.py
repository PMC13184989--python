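"""Synthetic single-step selection: ground-truth landscape, enrichment,
multinomial read sampling.

A genotype's reaction probability is a logistic function of an additive
(optionally epistatic) score per substrate; one selection round enriches
each genotype proportionally to that probability; reads are a multinomial
draw from the post-selection pool. This reproduces the statistical
structure the downstream analysis assumes: many low-count sequences, few
high-count ones, and arm-dependent enrichment.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy.special import expit

from bulgeselect.library_model import (
    BASES,
    DegenerateLibrarySpec,
    default_bulge_spec,
    library_size,
    sample_genotypes,
)
from bulgeselect.read_processing import GenotypeCountTable

SUBSTRATE_A = "A"
SUBSTRATE_B = "B"

_BASE_INDEX = {b: i for i, b in enumerate(BASES)}


class DegenerateSelectionError(ValueError):
    """All reacted fractions are zero: selection output is undefined."""


@dataclass
class ActivityLandscape:
    """Ground-truth genotype -> per-substrate reaction probability.

    additive_effects: (position, base, substrate) -> real
    epistatic_effects: ((pos_i, base_i), (pos_j, base_j), substrate) -> real
    pairing_bonus: added once per satisfied pair constraint
    intercept: substrate -> real
    The link is logistic: reacted fraction = expit(score).
    """

    spec: DegenerateLibrarySpec
    additive_effects: dict[tuple[int, str, str], float] = field(default_factory=dict)
    epistatic_effects: dict[
        tuple[tuple[int, str], tuple[int, str], str], float
    ] = field(default_factory=dict)
    pairing_bonus: float = 0.0
    intercept: dict[str, float] = field(default_factory=dict)

    def substrates(self) -> tuple[str, ...]:
        subs = set(self.intercept)
        subs |= {s for (_, _, s) in self.additive_effects}
        subs |= {s for (_, _, s) in self.epistatic_effects}
        return tuple(sorted(subs))

    def score(self, genotype: str, substrate: str) -> float:
        spec = self.spec
        total = self.intercept.get(substrate, 0.0)
        for p, sym in zip(spec.variable_positions, genotype):
            total += self.additive_effects.get((p, sym, substrate), 0.0)
        for ((pi, bi), (pj, bj), s), eff in self.epistatic_effects.items():
            if s != substrate:
                continue
            if (
                genotype[spec.position_index(pi)] == bi
                and genotype[spec.position_index(pj)] == bj
            ):
                total += eff
        if self.pairing_bonus:
            from bulgeselect.library_model import DEFAULT_PAIRED_DUPLETS

            for pc in spec.pair_constraints:
                b5 = genotype[spec.position_index(pc.pos5)]
                b3 = genotype[spec.position_index(pc.pos3)]
                if (b5, b3) in DEFAULT_PAIRED_DUPLETS:
                    total += self.pairing_bonus
        return total

    def score_many(self, genotypes: Sequence[str], substrate: str) -> np.ndarray:
        """Vectorized :meth:`score` over a genotype list."""
        spec = self.spec
        n = len(genotypes)
        codes = np.frombuffer(
            "".join(genotypes).encode("ascii"), dtype=np.uint8
        ).reshape(n, spec.n_variable)
        idx = np.zeros_like(codes, dtype=np.int64)
        for b, i in _BASE_INDEX.items():
            idx[codes == ord(b)] = i
        effect = np.zeros((spec.n_variable, len(BASES)))
        for (p, b, s), v in self.additive_effects.items():
            if s == substrate:
                effect[spec.position_index(p), _BASE_INDEX[b]] += v
        total = np.full(n, float(self.intercept.get(substrate, 0.0)), dtype=np.float64)
        for j in range(spec.n_variable):
            total += effect[j, idx[:, j]]
        for ((pi, bi), (pj, bj), s), eff in self.epistatic_effects.items():
            if s != substrate:
                continue
            mask = (idx[:, spec.position_index(pi)] == _BASE_INDEX[bi]) & (
                idx[:, spec.position_index(pj)] == _BASE_INDEX[bj]
            )
            total += eff * mask
        if self.pairing_bonus:
            for pc in spec.pair_constraints:
                i5 = idx[:, spec.position_index(pc.pos5)]
                i3 = idx[:, spec.position_index(pc.pos3)]
                paired = np.zeros(n, dtype=bool)
                from bulgeselect.library_model import DEFAULT_PAIRED_DUPLETS

                for b5, b3 in DEFAULT_PAIRED_DUPLETS:
                    paired |= (i5 == _BASE_INDEX[b5]) & (i3 == _BASE_INDEX[b3])
                total += self.pairing_bonus * paired
        return total

    def reacted_fraction_many(self, genotypes: Sequence[str], substrate: str) -> np.ndarray:
        return expit(self.score_many(genotypes, substrate))

    # -- serialization -----------------------------------------------------

    def to_json(self) -> str:
        return json.dumps(
            {
                "additive_effects": [
                    [p, b, s, v] for (p, b, s), v in sorted(self.additive_effects.items())
                ],
                "epistatic_effects": [
                    [pi, bi, pj, bj, s, v]
                    for ((pi, bi), (pj, bj), s), v in sorted(self.epistatic_effects.items())
                ],
                "pairing_bonus": self.pairing_bonus,
                "intercept": dict(sorted(self.intercept.items())),
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str, spec: DegenerateLibrarySpec) -> "ActivityLandscape":
        d = json.loads(text)
        return cls(
            spec=spec,
            additive_effects={(p, b, s): v for p, b, s, v in d["additive_effects"]},
            epistatic_effects={
                ((pi, bi), (pj, bj), s): v
                for pi, bi, pj, bj, s, v in d["epistatic_effects"]
            },
            pairing_bonus=d["pairing_bonus"],
            intercept=d["intercept"],
        )


def reacted_fraction(genotype: str, substrate: str, truth: ActivityLandscape) -> float:
    """Reaction probability in [0, 1] for one genotype on one substrate."""
    return float(expit(truth.score(genotype, substrate)))


# -- pool / selection / sampling ------------------------------------------


def simulate_pool(
    spec: DegenerateLibrarySpec,
    n_distinct: int,
    concentration: float = 50.0,
    seed: int | np.random.Generator | None = None,
) -> dict[str, float]:
    """Pre-selection pool: unique genotypes with Dirichlet-skewed frequencies.

    Large ``concentration`` approaches equimolar; small values produce a
    skewed pool.
    """
    if n_distinct > library_size(spec):
        raise ValueError("n_distinct exceeds the encoded sequence space")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    genotypes: dict[str, None] = {}
    while len(genotypes) < n_distinct:
        need = n_distinct - len(genotypes)
        for g in sample_genotypes(spec, int(need * 1.1) + 8, rng):
            if g not in genotypes:
                genotypes[g] = None
                if len(genotypes) == n_distinct:
                    break
    names = list(genotypes)
    freqs = rng.dirichlet(np.full(n_distinct, concentration))
    return dict(zip(names, freqs.tolist()))


def simulate_selection(
    pool: Mapping[str, float], truth: ActivityLandscape, substrate: str
) -> dict[str, float]:
    """One selection round: post(g) proportional to pre(g) x reacted fraction."""
    names = list(pool)
    pre = np.array([pool[g] for g in names])
    rf = truth.reacted_fraction_many(names, substrate)
    mass = pre * rf
    total = mass.sum()
    if total <= 0:
        raise DegenerateSelectionError("no genotype reacted; selection output undefined")
    post = mass / total
    return dict(zip(names, post.tolist()))


def sample_reads(
    freqs: Mapping[str, float],
    depth: int,
    seed: int | np.random.Generator | None = None,
    arm_label: str = "reads",
) -> GenotypeCountTable:
    """Multinomial draw of ``depth`` reads from a frequency map."""
    if depth <= 0:
        raise ValueError("depth must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    names = list(freqs)
    p = np.array([freqs[g] for g in names], dtype=float)
    p = p / p.sum()
    counts = rng.multinomial(depth, p)
    nz = counts > 0
    table = {g: int(c) for g, c in zip(names, counts) if c > 0}
    del nz
    return GenotypeCountTable.from_counts(table, arm_label=arm_label)


def write_reads_fastq(
    table: GenotypeCountTable,
    spec: DegenerateLibrarySpec,
    path: str | Path,
    quality_char: str = "I",
    reverse_complement_odd: bool = False,
) -> int:
    """Emit one FASTQ record per read via genotype embedding; returns #records.

    With ``reverse_complement_odd`` every second record is emitted on the
    opposite strand, exercising the orientation step downstream.
    """
    from bulgeselect.library_model import embed_in_core
    from bulgeselect.read_processing import reverse_complement

    n = 0
    with open(path, "w") as fh:
        for genotype, count in sorted(table.counts.items()):
            seq = embed_in_core(genotype, spec)
            for i in range(count):
                out = seq
                if reverse_complement_odd and n % 2 == 1:
                    out = reverse_complement(seq)
                fh.write(f"@read{n}\n{out}\n+\n{quality_char * len(out)}\n")
                n += 1
    return n


# -- benchmark registry ----------------------------------------------------

SCENARIOS = ("additive", "epistatic", "specificity-planted", "imbalanced")

#: positions whose substrate effects differ in the planted scenario
PLANTED_POSITIONS = (20, 21, 33, 34)


@dataclass
class SimulatedSelection:
    """A complete simulated experiment with its serialized ground truth."""

    scenario: str
    seed: int
    spec: DegenerateLibrarySpec
    truth: ActivityLandscape
    pool: dict[str, float]
    pre_counts: GenotypeCountTable
    post_counts: dict[str, GenotypeCountTable]

    def true_scores(self, genotypes: Sequence[str]) -> np.ndarray:
        """Planted specificity: score(A) - score(B), in log-odds units."""
        return self.truth.score_many(genotypes, SUBSTRATE_A) - self.truth.score_many(
            genotypes, SUBSTRATE_B
        )

    def true_post_cpm(self, genotypes: Sequence[str], substrate: str) -> np.ndarray:
        """Noise-free expected post-selection CPM for pool members."""
        names = list(self.pool)
        pre = np.array([self.pool[g] for g in names])
        rf = self.truth.reacted_fraction_many(names, substrate)
        post = pre * rf / (pre * rf).sum()
        lookup = dict(zip(names, post * 1e6))
        return np.array([lookup[g] for g in genotypes])

    def write_ground_truth(self, path: str | Path) -> None:
        Path(path).write_text(self.truth.to_json())


def _centered_effects(rng: np.random.Generator, scale: float) -> dict[str, float]:
    vals = rng.normal(0.0, scale, size=len(BASES))
    vals -= vals.mean()
    return dict(zip(BASES, vals.tolist()))


def _build_landscape(scenario: str, rng: np.random.Generator, spec: DegenerateLibrarySpec) -> ActivityLandscape:
    additive: dict[tuple[int, str, str], float] = {}
    epistatic: dict[tuple[tuple[int, str], tuple[int, str], str], float] = {}
    pairing_bonus = 0.0

    if scenario == "additive":
        # intercept keeps scores below the logistic knee for almost all
        # genotypes, so log reacted fraction is additive in the effects;
        # pair-constrained positions stay neutral -- their duplet coupling
        # would otherwise make per-position marginal statistics inconsistent
        intercept = {SUBSTRATE_A: -5.0, SUBSTRATE_B: -5.0}
        constrained = spec.constrained_positions()
        for p in spec.variable_positions:
            if p in constrained:
                continue
            eff = _centered_effects(rng, 0.8)
            for b, v in eff.items():
                additive[(p, b, SUBSTRATE_A)] = v
                additive[(p, b, SUBSTRATE_B)] = v
    elif scenario == "epistatic":
        intercept = {SUBSTRATE_A: -5.0, SUBSTRATE_B: -5.0}
        for p in spec.variable_positions:
            eff = _centered_effects(rng, 0.5)
            for b, v in eff.items():
                additive[(p, b, SUBSTRATE_A)] = v
                additive[(p, b, SUBSTRATE_B)] = v
        positions = list(spec.variable_positions)
        for _ in range(6):
            pi, pj = sorted(rng.choice(len(positions), size=2, replace=False))
            for bi in BASES:
                for bj in BASES:
                    v = float(rng.normal(0.0, 1.0))
                    key = ((positions[pi], bi), (positions[pj], bj))
                    epistatic[(key[0], key[1], SUBSTRATE_A)] = (
                        epistatic.get((key[0], key[1], SUBSTRATE_A), 0.0) + v
                    )
                    epistatic[(key[0], key[1], SUBSTRATE_B)] = (
                        epistatic.get((key[0], key[1], SUBSTRATE_B), 0.0) + v
                    )
        pairing_bonus = 1.0
    elif scenario == "specificity-planted":
        intercept = {SUBSTRATE_A: -5.0, SUBSTRATE_B: -5.0}
        for p in spec.variable_positions:
            eff = _centered_effects(rng, 0.8)
            for b, v in eff.items():
                additive[(p, b, SUBSTRATE_A)] = v
                additive[(p, b, SUBSTRATE_B)] = v
        # substrate-B deviates only at the planted positions; deltas are a
        # shuffled fixed pattern so every planted position carries a
        # guaranteed differential magnitude
        for p in PLANTED_POSITIONS:
            pattern = np.array([2.5, -2.5, 1.0, -1.0])
            delta = dict(zip(BASES, rng.permutation(pattern).tolist()))
            for b, v in delta.items():
                additive[(p, b, SUBSTRATE_B)] = additive[(p, b, SUBSTRATE_A)] + v
    elif scenario == "imbalanced":
        # arm A: strong, concentrated enrichment; arm B: near-neutral, so
        # arm-A membership is detection-limited at the default depths
        intercept = {SUBSTRATE_A: -10.0, SUBSTRATE_B: -4.0}
        for p in spec.variable_positions:
            eff_a = _centered_effects(rng, 2.5)
            eff_b = _centered_effects(rng, 0.1)
            for b in BASES:
                additive[(p, b, SUBSTRATE_A)] = eff_a[b]
                additive[(p, b, SUBSTRATE_B)] = eff_b[b]
    else:
        raise ValueError(f"unknown scenario {scenario!r}; known: {SCENARIOS}")

    return ActivityLandscape(
        spec=spec,
        additive_effects=additive,
        epistatic_effects=epistatic,
        pairing_bonus=pairing_bonus,
        intercept=intercept,
    )


def make_benchmark(
    scenario: str,
    seed: int,
    n_distinct: int | None = None,
    depth: int | Mapping[str, int] | None = None,
    spec: DegenerateLibrarySpec | None = None,
    concentration: float = 50.0,
) -> SimulatedSelection:
    """Build a registered benchmark: pool, ground truth, pre/post read tables.

    Defaults: 1e5 distinct genotypes at 1e6 reads per arm. The
    "imbalanced" scenario defaults to a broader pool (2e5 genotypes) read
    shallowly on arm A (2e5 reads) and deeply on arm B (6e5 reads), so
    arm-A membership is detection-limited -- the mechanism behind the
    positive-score skew of the merged table. ``depth`` may be a single
    integer or a per-substrate mapping.
    """
    if scenario not in SCENARIOS:
        raise ValueError(f"unknown scenario {scenario!r}; known: {SCENARIOS}")
    if n_distinct is None:
        n_distinct = 200_000 if scenario == "imbalanced" else 100_000
    if depth is None:
        depth = (
            {SUBSTRATE_A: 200_000, SUBSTRATE_B: 600_000}
            if scenario == "imbalanced"
            else 1_000_000
        )
    depths = (
        dict(depth)
        if isinstance(depth, Mapping)
        else {SUBSTRATE_A: int(depth), SUBSTRATE_B: int(depth)}
    )
    spec = spec if spec is not None else default_bulge_spec()
    rng = np.random.default_rng(seed)
    truth = _build_landscape(scenario, rng, spec)
    pool = simulate_pool(spec, n_distinct, concentration=concentration, seed=rng)
    pre_counts = sample_reads(pool, depths[SUBSTRATE_A], seed=rng, arm_label="round0")
    post_counts: dict[str, GenotypeCountTable] = {}
    for substrate in (SUBSTRATE_A, SUBSTRATE_B):
        post = simulate_selection(pool, truth, substrate)
        post_counts[substrate] = sample_reads(
            post, depths[substrate], seed=rng, arm_label=f"arm_{substrate}"
        )
    return SimulatedSelection(
        scenario=scenario,
        seed=seed,
        spec=spec,
        truth=truth,
        pool=pool,
        pre_counts=pre_counts,
        post_counts=post_counts,
    )
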