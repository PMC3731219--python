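"""The design objective: seed detection, dG_kin, dG_str, and gate scoring.

Two terms, both minimized, score a candidate set of sequences against a
gate specification:

* dG_kin = max(dG, dG_sat) + min(alpha, alpha_sat) * G_p combines the free
  energy of formation of a reaction with the length alpha of its seed
  (nucleation site).  G_p = -1.28 kcal/mol is the average energetic
  contribution of one paired nucleotide; dG_sat = -15 kcal/mol and
  alpha_sat = 6 are saturation levels past which no further credit accrues.
  Reactions that must occur contribute dG_kin directly; reactions that must
  not occur contribute max(-dG_kin, 0).

* dG_str = -G_p * d rescales the Hamming distance d between an observed
  dot-bracket structure and its target (or target mask) into kcal/mol.

The total objective is the weighted sum over all terms of a gate; sequences
forming strong homodimers are excluded with an infinite score.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

from .energy_model import (
    FoldResult,
    NucleotideSequence,
    ReferenceEnergyModel,
    cofold,
    fold,
    is_wc_pair,
)
from .errors import SpecError, StructureError

#: structure-target alphabet: '.' unpaired, '('/')' literal brackets,
#: '|' paired with either bracket, '*' not compared
TARGET_CHARS = ".()|*"

DEFAULT_HOMODIMER_THRESHOLD = -7.5


@dataclass(frozen=True)
class SeedRegion:
    """Longest contiguous complementary run available for nucleation.

    ``start_a``/``start_b`` are 0-based positions of the run in each
    partner (1-based in formatted reports); ``alpha`` is its length in nt.
    The run is Watson-Crick complementary in antiparallel orientation and
    unpaired in both partners' individual MFE structures.
    """

    start_a: int
    start_b: int
    alpha: int

    def report(self) -> str:
        return f"alpha={self.alpha} A@{self.start_a + 1} B@{self.start_b + 1}"


@dataclass(frozen=True)
class ObjectiveConfig:
    """Constants of the scoring model (kcal/mol unless noted)."""

    g_p: float = -1.28
    dg_sat: float = -15.0
    alpha_sat: int = 6
    rt: float = 0.61
    w_kin: float = 1.0
    w_str: float = 1.0
    seed_allow_gu: bool = False

    def __post_init__(self) -> None:
        if self.g_p >= 0:
            raise SpecError("G_p must be negative")
        if self.dg_sat >= 0:
            raise SpecError("dG_sat must be negative")
        if self.alpha_sat < 1:
            raise SpecError("alpha_sat must be >= 1")
        if self.w_kin < 0 or self.w_str < 0:
            raise SpecError("term weights must be non-negative")


@dataclass(frozen=True)
class ObjectiveTerm:
    """One term of a gate objective.

    kin terms score the reaction between species group ``a`` and group
    ``b`` (groups of more than one species are co-folded first) with sense
    'occur' or 'avoid'.  str terms compare the fold of ``a`` (single
    species or complex) against a ``target`` string over ``.()|*``.
    """

    kind: Literal["kin", "str"]
    a: tuple[str, ...]
    b: tuple[str, ...] = ()
    sense: Literal["occur", "avoid"] | None = None
    target: str | None = None
    weight: float = 1.0
    label: str = ""

    def __post_init__(self) -> None:
        if self.kind == "kin":
            if self.sense not in ("occur", "avoid"):
                raise SpecError("kin terms need sense 'occur' or 'avoid'")
            if not self.b:
                raise SpecError("kin terms need two participant groups")
        elif self.kind == "str":
            if self.target is None:
                raise SpecError("str terms need a target")
            if self.sense is not None:
                raise SpecError("occur/avoid applies to kin terms only")
            bad = set(self.target) - set(TARGET_CHARS)
            if bad:
                raise SpecError(f"invalid target symbols {sorted(bad)}")
        else:
            raise SpecError(f"unknown term kind {self.kind!r}")


@dataclass
class TermScore:
    term: ObjectiveTerm
    value: float
    delta_g: float | None = None
    alpha: int | None = None
    distance: int | None = None


@dataclass
class ObjectiveResult:
    total: float
    terms: list[TermScore] = field(default_factory=list)
    folds: dict[tuple[str, ...], FoldResult] = field(default_factory=dict)


def seed_length(fold_a: FoldResult, fold_b: FoldResult,
                allow_gu: bool = False) -> SeedRegion:
    """Longest antiparallel complementary run of mutually accessible bases.

    Accessibility is read off the individual MFE structures (individual
    folding completes before the strands meet).  Ties go to the smallest
    start in A, then in B.  Returns alpha = 0 when no complementary
    accessible pair exists.
    """

    def ok(x: str, y: str) -> bool:
        return is_wc_pair(x, y) or (allow_gu and {x, y} == {"G", "U"})

    best = SeedRegion(0, 0, 0)
    sym_a = fold_a.structure.residue_symbols
    sym_b = fold_b.structure.residue_symbols
    res_a = fold_a.residues
    res_b = fold_b.residues
    strand_a = [fold_a.structure.strand_of(i) for i in range(len(res_a))]
    strand_b = [fold_b.structure.strand_of(i) for i in range(len(res_b))]
    for i in range(len(res_a)):
        for j in range(len(res_b)):
            a = 0
            # antiparallel: A[i + t] pairs B[j - t]
            while (
                i + a < len(res_a)
                and j - a >= 0
                and sym_a[i + a] == "."
                and sym_b[j - a] == "."
                and strand_a[i + a] == strand_a[i]
                and strand_b[j - a] == strand_b[j]
                and ok(res_a[i + a], res_b[j - a])
            ):
                a += 1
            start_b = j - a + 1
            if a > best.alpha or (
                a == best.alpha
                and a > 0
                and (i, start_b) < (best.start_a, best.start_b)
            ):
                best = SeedRegion(i, start_b, a)
    return best


def dg_kin(delta_g: float, alpha: int, cfg: ObjectiveConfig) -> float:
    """Kinetic objective: saturated formation energy plus seed credit."""
    return max(delta_g, cfg.dg_sat) + min(alpha, cfg.alpha_sat) * cfg.g_p


def structure_distance(observed: str, target: str) -> int:
    """Hamming distance between dot-bracket strings over compared positions.

    ``target`` may contain '|' (any bracket matches) and '*' (skip).
    Strand separators are ignored on both sides.
    """
    obs = observed.replace("&", "")
    tgt = target.replace("&", "")
    if len(obs) != len(tgt):
        raise StructureError(
            f"observed length {len(obs)} != target length {len(tgt)}"
        )
    d = 0
    for o, t in zip(obs, tgt):
        if t == "*":
            continue
        if t == "|":
            if o not in "()":
                d += 1
        elif o != t:
            d += 1
    return d


def dg_str(observed: str, target: str, cfg: ObjectiveConfig) -> float:
    """Structural objective: -G_p times the Hamming distance (>= 0)."""
    return -cfg.g_p * structure_distance(observed, target)


def avoid_term(delta_g_kin: float) -> float:
    """Contribution of a must-not-occur reaction: max(-dG_kin, 0).

    Maximizing dG_kin equals minimizing -dG_kin; the floor at zero keeps
    already-inert pairs from dominating the weighted sum.
    """
    return max(-delta_g_kin, 0.0)


class FoldCache:
    """Memo for fold/cofold results keyed by residue strings.

    Accepts either the reference model (folded through this module's free
    functions) or an engine object exposing ``fold``/``cofold`` methods,
    such as the ViennaRNA adapter.
    """

    def __init__(self, model):
        self.model = model
        self._engine = hasattr(model, "fold")
        self._memo: dict[tuple[str, ...], FoldResult] = {}

    def group(self, seqs: Sequence[NucleotideSequence]) -> FoldResult:
        key = tuple(s.residues for s in seqs)
        hit = self._memo.get(key)
        if hit is None:
            if self._engine:
                hit = (self.model.fold(seqs[0]) if len(seqs) == 1
                       else self.model.cofold(list(seqs)))
            else:
                hit = fold(seqs[0], self.model) if len(seqs) == 1 else cofold(
                    list(seqs), self.model
                )
            self._memo[key] = hit
        return hit


def group_delta_g(
    fold_ab: FoldResult, fold_a: FoldResult, fold_b: FoldResult
) -> float:
    dg = fold_ab.free_energy - fold_a.free_energy - fold_b.free_energy
    return min(dg, 0.0)


def total_objective(
    sequences: Mapping[str, NucleotideSequence],
    gate,
    cfg: ObjectiveConfig,
    model: ReferenceEnergyModel,
    *,
    homodimer_threshold: float = DEFAULT_HOMODIMER_THRESHOLD,
    cache: FoldCache | None = None,
) -> ObjectiveResult:
    """Weighted sum of all gate terms for a candidate sequence set.

    Lower is better.  Candidates in which any species self-hybridizes below
    ``homodimer_threshold`` are excluded with an infinite total (homodimers
    would compete with every intended reaction).
    """
    if cache is None or cache.model is not model:
        cache = FoldCache(model)
    missing = [sp.name for sp in gate.species if sp.name not in sequences]
    if missing:
        raise SpecError(f"missing sequences for species: {missing}")

    result = ObjectiveResult(total=0.0)

    def resolve(group: tuple[str, ...]) -> FoldResult:
        key = tuple(group)
        if key not in result.folds:
            result.folds[key] = cache.group([sequences[n] for n in group])
        return result.folds[key]

    # homodimer exclusion
    for sp in gate.species:
        seq = sequences[sp.name]
        dg_self = group_delta_g(
            cache.group([seq, seq]), cache.group([seq]), cache.group([seq])
        )
        if dg_self < homodimer_threshold:
            result.total = math.inf
            result.terms.append(
                TermScore(
                    ObjectiveTerm("str", (sp.name,), target="*",
                                  label=f"homodimer:{sp.name}"),
                    math.inf,
                    delta_g=dg_self,
                )
            )
            return result

    for term in gate.terms:
        if term.kind == "kin":
            fa = resolve(term.a)
            fb = resolve(term.b)
            fab = resolve(term.a + term.b)
            dg = group_delta_g(fab, fa, fb)
            seed = seed_length(fa, fb, allow_gu=cfg.seed_allow_gu)
            kin = dg_kin(dg, seed.alpha, cfg)
            raw = kin if term.sense == "occur" else avoid_term(kin)
            score = cfg.w_kin * term.weight * raw
            result.terms.append(
                TermScore(term, score, delta_g=dg, alpha=seed.alpha)
            )
        else:
            observed = resolve(term.a).structure.symbols
            d = structure_distance(observed, term.target)
            score = cfg.w_str * term.weight * (-cfg.g_p) * d
            result.terms.append(TermScore(term, score, distance=d))
        result.total += score
    return result
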