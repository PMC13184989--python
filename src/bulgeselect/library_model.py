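"""Degenerate bulge-library model: genotype space and exact combinatorics.

The library is described by a template over a fixed-length core: most
variable positions carry an independent IUPAC degeneracy code, while
designated position pairs are jointly constrained to purine-pyrimidine
(R-Y) or pyrimidine-purine (Y-R) duplets. Coordinates are 1-based over
the core sequence.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterator, Mapping, Sequence

import numpy as np

BASES = ("A", "C", "G", "T")

IUPAC_CODES: Mapping[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

#: duplets (5'-base, 3'-base) counted as base-paired: Watson-Crick plus G-T/T-G wobble
DEFAULT_PAIRED_DUPLETS = frozenset(
    [("A", "T"), ("T", "A"), ("C", "G"), ("G", "C"), ("G", "T"), ("T", "G")]
)

#: hard ceiling for exhaustive enumeration
ENUMERATION_SAFETY_BOUND = 10**7


class InvalidIUPACError(ValueError):
    """Raised for a symbol outside the IUPAC nucleotide alphabet."""


def expand_iupac(code: str) -> frozenset[str]:
    """Return the set of bases encoded by a single IUPAC symbol."""
    try:
        return IUPAC_CODES[code.upper()]
    except (KeyError, AttributeError):
        raise InvalidIUPACError(f"not an IUPAC nucleotide code: {code!r}") from None


def _orientation_duplets(orientation: str) -> frozenset[tuple[str, str]]:
    if orientation == "R-Y":
        first, second = IUPAC_CODES["R"], IUPAC_CODES["Y"]
    elif orientation == "Y-R":
        first, second = IUPAC_CODES["Y"], IUPAC_CODES["R"]
    else:
        raise ValueError(f"unknown pair orientation: {orientation!r}")
    return frozenset(itertools.product(sorted(first), sorted(second)))


@dataclass(frozen=True)
class PairConstraint:
    """A jointly constrained position pair.

    By default the allowed duplets are the union over ``allowed_orientations``
    of R x Y (for "R-Y") and Y x R (for "Y-R"). Passing ``duplets`` overrides
    the orientation expansion with an explicit duplet set.
    """

    pos5: int
    pos3: int
    allowed_orientations: tuple[str, ...] = ("R-Y", "Y-R")
    duplets: frozenset[tuple[str, str]] | None = None

    def __post_init__(self) -> None:
        if self.pos5 >= self.pos3:
            raise ValueError(f"pos5 ({self.pos5}) must be < pos3 ({self.pos3})")
        if self.duplets is None:
            if not self.allowed_orientations:
                raise ValueError("allowed_orientations must be non-empty")
            for o in self.allowed_orientations:
                _orientation_duplets(o)  # validates
        else:
            if not self.duplets:
                raise ValueError("explicit duplet set must be non-empty")
            for b5, b3 in self.duplets:
                if b5 not in BASES or b3 not in BASES:
                    raise ValueError(f"duplet {(b5, b3)} not over A/C/G/T")

    def allowed_duplets(self) -> frozenset[tuple[str, str]]:
        if self.duplets is not None:
            return frozenset(self.duplets)
        out: set[tuple[str, str]] = set()
        for o in self.allowed_orientations:
            out |= _orientation_duplets(o)
        return frozenset(out)


@dataclass(frozen=True)
class PairingRule:
    """Which duplets count as base-paired (used by :func:`pairing_fraction`)."""

    paired_duplets: frozenset[tuple[str, str]] = DEFAULT_PAIRED_DUPLETS

    def __post_init__(self) -> None:
        for b5, b3 in self.paired_duplets:
            if b5 not in BASES or b3 not in BASES:
                raise ValueError(f"duplet {(b5, b3)} not over A/C/G/T")


@dataclass(frozen=True)
class DegenerateLibrarySpec:
    """Template + paired-position constraints defining the genotype space.

    ``reference_core`` is a length-``core_length`` string over {A,C,G,T,X}
    with ``X`` exactly at the variable positions. A genotype is the string
    of bases at the variable positions, in ``variable_positions`` order.
    """

    core_length: int
    variable_positions: tuple[int, ...]
    position_codes: Mapping[str, str] | Mapping[int, str]
    pair_constraints: tuple[PairConstraint, ...]
    reference_core: str

    def __post_init__(self) -> None:
        vp = self.variable_positions
        if list(vp) != sorted(set(vp)):
            raise ValueError("variable_positions must be strictly increasing")
        if vp and (vp[0] < 1 or vp[-1] > self.core_length):
            raise ValueError("variable_positions out of core range")
        if len(self.reference_core) != self.core_length:
            raise ValueError(
                f"reference_core length {len(self.reference_core)} != core_length {self.core_length}"
            )
        vset = set(vp)
        for i, ch in enumerate(self.reference_core, start=1):
            if i in vset and ch != "X":
                raise ValueError(f"reference_core position {i} is variable but not 'X'")
            if i not in vset and ch not in BASES:
                raise ValueError(f"reference_core position {i}: invalid fixed base {ch!r}")
        constrained: list[int] = []
        for pc in self.pair_constraints:
            constrained.extend([pc.pos5, pc.pos3])
        if len(constrained) != len(set(constrained)):
            raise ValueError("a position appears in more than one pair constraint")
        for p in constrained:
            if p not in vset:
                raise ValueError(f"pair-constrained position {p} is not a variable position")
        for p in vp:
            if p in set(constrained):
                continue
            code = self._code_for(p)
            expand_iupac(code)  # validates

    def _code_for(self, position: int) -> str:
        codes = self.position_codes
        if position in codes:  # type: ignore[operator]
            return codes[position]  # type: ignore[index]
        return codes.get(str(position), "N")  # type: ignore[union-attr]

    # -- derived structure -------------------------------------------------

    @property
    def n_variable(self) -> int:
        return len(self.variable_positions)

    def position_index(self, position: int) -> int:
        """Index of a core position within the genotype string."""
        try:
            return self.variable_positions.index(position)
        except ValueError:
            raise ValueError(f"position {position} is not a variable position") from None

    def constrained_positions(self) -> frozenset[int]:
        out: set[int] = set()
        for pc in self.pair_constraints:
            out |= {pc.pos5, pc.pos3}
        return frozenset(out)

    def unconstrained_base_sets(self) -> dict[int, frozenset[str]]:
        """Map unconstrained variable position -> allowed base set."""
        cons = self.constrained_positions()
        return {
            p: expand_iupac(self._code_for(p))
            for p in self.variable_positions
            if p not in cons
        }


DEFAULT_VARIABLE_POSITIONS = (16, 17, 20, 21, 22, 23, 33, 34, 35, 36, 37, 40, 41, 42)

# Placeholder scaffold: the study's core sequence is not public, and every
# combinatorial quantity computed here is independent of the fixed bases.
_PLACEHOLDER_CORE = (
    "GGTAAGCTTGGCACT"  # 1-15
    "XX"  # 16-17 (paired with 42 / 40)
    "GA"  # 18-19
    "XXXX"  # 20-23
    "TCCGAGCCG"  # 24-32
    "XXXXX"  # 33-37
    "CT"  # 38-39
    "XXX"  # 40-42
    "GTCAG"  # 43-47
)


def default_bulge_spec(reference_core: str | None = None) -> DegenerateLibrarySpec:
    """The 47-nt bulge library: 10 N positions plus the 16-42 and 17-40 pairs.

    ``reference_core`` may supply the true fixed scaffold; it must carry
    'X' at the 14 variable positions.
    """
    return DegenerateLibrarySpec(
        core_length=47,
        variable_positions=DEFAULT_VARIABLE_POSITIONS,
        position_codes={p: "N" for p in (20, 21, 22, 23, 33, 34, 35, 36, 37, 41)},
        pair_constraints=(
            PairConstraint(pos5=16, pos3=42),
            PairConstraint(pos5=17, pos3=40),
        ),
        reference_core=reference_core if reference_core is not None else _PLACEHOLDER_CORE,
    )


# -- combinatorics ---------------------------------------------------------


def library_size(spec: DegenerateLibrarySpec) -> int:
    """Exact number of distinct genotypes encoded by the spec."""
    size = 1
    for bases in spec.unconstrained_base_sets().values():
        size *= len(bases)
    for pc in spec.pair_constraints:
        size *= len(pc.allowed_duplets())
    return size


def pairing_fraction(
    spec: DegenerateLibrarySpec, rule: PairingRule | None = None
) -> float:
    """Fraction of genotypes whose every constrained duplet is base-paired.

    Unconstrained positions factor out, so this is the product over pair
    constraints of |allowed and paired| / |allowed|.
    """
    rule = rule if rule is not None else PairingRule()
    frac = 1.0
    for pc in spec.pair_constraints:
        allowed = pc.allowed_duplets()
        frac *= len(allowed & rule.paired_duplets) / len(allowed)
    return frac


def _position_choices(spec: DegenerateLibrarySpec):
    """Per-genotype-index choice structure for enumeration/sampling.

    Returns a list aligned with variable_positions; each element is either
    ("free", sorted bases), ("pair5", constraint), or ("pair3", constraint).
    """
    free = spec.unconstrained_base_sets()
    pos5_of = {pc.pos5: pc for pc in spec.pair_constraints}
    pos3_of = {pc.pos3: pc for pc in spec.pair_constraints}
    out = []
    for p in spec.variable_positions:
        if p in free:
            out.append(("free", tuple(sorted(free[p]))))
        elif p in pos5_of:
            out.append(("pair5", pos5_of[p]))
        else:
            out.append(("pair3", pos3_of[p]))
    return out


def enumerate_genotypes(
    spec: DegenerateLibrarySpec,
    limit: int | None = None,
    safety_bound: int = ENUMERATION_SAFETY_BOUND,
) -> Iterator[str]:
    """Lazily yield genotypes in lexicographic order.

    ``limit=None`` enumerates the whole space and refuses if its size
    exceeds ``safety_bound``; otherwise at most ``limit`` genotypes are
    yielded.
    """
    if limit is None and library_size(spec) > safety_bound:
        raise ValueError(
            f"library size {library_size(spec)} exceeds safety bound {safety_bound}; "
            "pass an explicit limit or use sample_genotypes"
        )
    choices = _position_choices(spec)
    n = len(choices)
    budget = [limit]

    def rec(i: int, prefix: list[str], chosen5: dict[int, str]) -> Iterator[str]:
        if budget[0] is not None and budget[0] <= 0:
            return
        if i == n:
            if budget[0] is not None:
                budget[0] -= 1
            yield "".join(prefix)
            return
        kind, payload = choices[i][0], choices[i][1]
        if kind == "free":
            options = payload
        elif kind == "pair5":
            options = tuple(sorted({b5 for b5, _ in payload.allowed_duplets()}))
        else:
            b5 = chosen5[payload.pos5]
            options = tuple(
                sorted({b3 for a5, b3 in payload.allowed_duplets() if a5 == b5})
            )
        for b in options:
            if kind == "pair5":
                chosen5[payload.pos5] = b
            prefix.append(b)
            yield from rec(i + 1, prefix, chosen5)
            prefix.pop()

    yield from rec(0, [], {})


def sample_genotypes(
    spec: DegenerateLibrarySpec,
    n: int,
    seed: int | np.random.Generator | None = None,
) -> list[str]:
    """Draw ``n`` i.i.d. uniform genotypes from the encoded space."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    choices = _position_choices(spec)
    columns: dict[int, np.ndarray] = {}
    pair_draws: dict[int, np.ndarray] = {}
    for i, (kind, payload) in enumerate(choices):
        if kind == "free":
            columns[i] = rng.choice(np.array(payload), size=n)
        elif kind == "pair5":
            duplets = sorted(payload.allowed_duplets())
            idx = rng.integers(0, len(duplets), size=n)
            pair_draws[payload.pos3] = np.array([duplets[j][1] for j in idx])
            columns[i] = np.array([duplets[j][0] for j in idx])
    for i, (kind, payload) in enumerate(choices):
        if kind == "pair3":
            columns[i] = pair_draws[payload.pos3]
    cols = [columns[i] for i in range(len(choices))]
    if not cols:
        return [""] * n
    stacked = np.stack(cols, axis=1)
    return ["".join(row) for row in stacked]


# -- embedding / extraction ------------------------------------------------


def embed_in_core(genotype: str, spec: DegenerateLibrarySpec) -> str:
    """Place a genotype into the reference core, replacing the X positions."""
    if len(genotype) != spec.n_variable:
        raise ValueError(
            f"genotype length {len(genotype)} != {spec.n_variable} variable positions"
        )
    core = list(spec.reference_core)
    for sym, p in zip(genotype, spec.variable_positions):
        if sym not in BASES:
            raise ValueError(f"genotype symbol {sym!r} not in A/C/G/T")
        core[p - 1] = sym
    return "".join(core)


def extract_variable_positions(core_seq: str, spec: DegenerateLibrarySpec) -> str:
    """Inverse of :func:`embed_in_core` for a full-length core sequence."""
    if len(core_seq) != spec.core_length:
        raise ValueError(f"sequence length {len(core_seq)} != core length {spec.core_length}")
    return "".join(core_seq[p - 1] for p in spec.variable_positions)


def orientation_sublibraries(
    spec: DegenerateLibrarySpec,
) -> dict[tuple[str, ...], DegenerateLibrarySpec]:
    """Decompose into sub-specs with one orientation fixed per constraint.

    For the default two-pair spec this yields the four synthesis
    sublibraries (R-Y/R-Y, R-Y/Y-R, Y-R/R-Y, Y-R/Y-R); their genotype sets
    are disjoint and their sizes sum to the full library size.
    """
    per_pair = [tuple(pc.allowed_orientations) for pc in spec.pair_constraints]
    out: dict[tuple[str, ...], DegenerateLibrarySpec] = {}
    for combo in itertools.product(*per_pair):
        constraints = tuple(
            PairConstraint(pc.pos5, pc.pos3, allowed_orientations=(o,))
            for pc, o in zip(spec.pair_constraints, combo)
        )
        out[combo] = DegenerateLibrarySpec(
            core_length=spec.core_length,
            variable_positions=spec.variable_positions,
            position_codes=dict(spec.position_codes),
            pair_constraints=constraints,
            reference_core=spec.reference_core,
        )
    return out


def spec_to_dict(spec: DegenerateLibrarySpec) -> dict:
    """Plain-dict form of a spec for structured config files."""
    return {
        "core_length": spec.core_length,
        "variable_positions": list(spec.variable_positions),
        "position_codes": {str(k): v for k, v in dict(spec.position_codes).items()},
        "pair_constraints": [
            {
                "pos5": pc.pos5,
                "pos3": pc.pos3,
                "allowed_orientations": list(pc.allowed_orientations),
            }
            for pc in spec.pair_constraints
        ],
        "reference_core": spec.reference_core,
    }


def spec_from_dict(d: Mapping) -> DegenerateLibrarySpec:
    return DegenerateLibrarySpec(
        core_length=int(d["core_length"]),
        variable_positions=tuple(int(p) for p in d["variable_positions"]),
        position_codes={int(k): v for k, v in d.get("position_codes", {}).items()},
        pair_constraints=tuple(
            PairConstraint(
                pos5=int(pc["pos5"]),
                pos3=int(pc["pos3"]),
                allowed_orientations=tuple(pc.get("allowed_orientations", ("R-Y", "Y-R"))),
            )
            for pc in d.get("pair_constraints", [])
        ),
        reference_core=d["reference_core"],
    )


def genotype_satisfies_pairs(
    genotype: str, spec: DegenerateLibrarySpec, rule: PairingRule | None = None
) -> bool:
    """True iff every constrained duplet of the genotype is base-paired."""
    rule = rule if rule is not None else PairingRule()
    for pc in spec.pair_constraints:
        b5 = genotype[spec.position_index(pc.pos5)]
        b3 = genotype[spec.position_index(pc.pos3)]
        if (b5, b3) not in rule.paired_duplets:
            return False
    return True
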