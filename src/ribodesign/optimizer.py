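"""Monte Carlo Simulated Annealing over RNA sequence space.

The search starts from random sequences that already satisfy the structural
and subsequence constraints of the gate (target-structure stem partners are
sampled as Watson-Crick pairs, motifs are placed verbatim) and iterates a
mutation/selection loop under a geometric Metropolis temperature schedule.

Two mutation operators are used: a directed move that copies a word of
consecutive nucleotides from one species, reverse-complements it, and
writes it into designable positions of another species (guaranteeing the
proposal contributes to an intermolecular interaction), and a random point
replacement.  The word length starts at three and shrinks to one over the
run.  When a mutated nucleotide sits in a target-structure stem, its
partner is co-mutated to the Watson-Crick complement so the intended
structure is never disrupted.  Insertions and deletions are not considered:
RNA lengths stay constant.  Proposals creating homopolymer runs of four or
more identical nucleotides in evolved regions are resampled, and sequences
forming strong homodimers are excluded by the objective.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field, replace

import numpy as np

from .energy_model import (
    NucleotideSequence,
    RNA_ALPHABET,
    ReferenceEnergyModel,
    complement,
    is_wc_pair,
    reverse_complement,
)
from .errors import InitializationError, MoveError, SpecError
from .gates import GateSpec, SpeciesSpec, validate_spec
from .landscape import delta_g_mfe
from .objective import (
    DEFAULT_HOMODIMER_THRESHOLD,
    FoldCache,
    ObjectiveConfig,
    ObjectiveResult,
    structure_distance,
    total_objective,
)

#: runs of this many identical consecutive nucleotides are forbidden
FORBIDDEN_RUN_LENGTH = 4

#: designs within this many dot-bracket symbols (3 bp) of their structural
#: target are reported as satisfying it
STRUCTURE_TOLERANCE_SYMBOLS = 6


@dataclass(frozen=True)
class OptimizerConfig:
    iterations: int = 10_000
    t0: float = 5.0
    t_final: float = 0.05
    #: fraction-of-run thresholds for mutation word lengths 3 -> 2 -> 1
    word_schedule: tuple[tuple[float, int], ...] = (
        (1 / 3, 3), (2 / 3, 2), (1.0, 1),
    )
    p_word: float = 0.5
    rng_seed: int = 0
    harmonic_stiffness: float = 0.0
    homodimer_dg_threshold: float = DEFAULT_HOMODIMER_THRESHOLD
    forbidden_run_length: int = FORBIDDEN_RUN_LENGTH
    move_resample_budget: int = 50
    init_attempts: int = 2000
    record_trajectory: bool = True

    def __post_init__(self) -> None:
        if self.iterations < 1:
            raise SpecError("iterations must be >= 1")
        if self.t0 <= 0 or self.t_final <= 0:
            raise SpecError("temperatures must be > 0")
        if self.word_schedule[-1][0] < 1.0:
            raise SpecError("word schedule must cover the whole run")

    def word_len_at(self, iteration: int) -> int:
        frac = (iteration + 1) / self.iterations
        for threshold, w in self.word_schedule:
            if frac <= threshold:
                return w
        return self.word_schedule[-1][1]

    def temperature_at(self, iteration: int) -> float:
        if self.iterations == 1:
            return self.t0
        gamma = (self.t_final / self.t0) ** (1 / (self.iterations - 1))
        return self.t0 * gamma**iteration


@dataclass(frozen=True)
class TrajectoryRecord:
    iteration: int
    move: str
    delta_f: float
    accepted: bool
    objective: float


@dataclass
class DesignResult:
    sequences: dict[str, NucleotideSequence]
    objective: float
    breakdown: ObjectiveResult
    trajectory: list[TrajectoryRecord] = field(default_factory=list)
    best_iteration: int = 0
    n_accepted: int = 0
    n_move_failures: int = 0


def partner_map(sp: SpeciesSpec) -> dict[int, int]:
    pm: dict[int, int] = {}
    for i, j in sp.target_pairs():
        pm[i] = j
        pm[j] = i
    return pm


def effective_mask(sp: SpeciesSpec) -> tuple[bool, ...]:
    """Designable mask after freezing stem partners of fixed positions."""
    mask = list(sp.base_mask())
    pm = partner_map(sp)
    for p, q in pm.items():
        if not mask[p]:
            mask[q] = False
    return tuple(mask)


def run_violation(residues: str, mask: tuple[bool, ...], limit: int) -> bool:
    """True when a homopolymer run of >= limit touches a designable position.

    Runs entirely inside fixed motifs (e.g. an imposed poly(U) terminator
    tail) are specification, not evolution, and are allowed.
    """
    n = len(residues)
    i = 0
    while i < n:
        j = i
        while j < n and residues[j] == residues[i]:
            j += 1
        if j - i >= limit and any(mask[p] for p in range(i, j)):
            return True
        i = j
    return False


def _forced_bases(sp: SpeciesSpec) -> dict[int, str]:
    forced: dict[int, str] = {}
    if sp.fixed_sequence is not None:
        forced.update(enumerate(sp.fixed_sequence))
    for m in sp.motifs:
        for t, b in enumerate(m.sequence):
            forced[m.start + t] = b
    return forced


def _init_species(
    sp: SpeciesSpec, rng: np.random.Generator, attempts: int, run_limit: int
) -> NucleotideSequence:
    mask = effective_mask(sp)
    forced = _forced_bases(sp)
    pm = partner_map(sp)
    # stem partners of forced bases are forced to the complement
    for p, q in pm.items():
        if p in forced and q not in forced:
            forced[q] = complement(forced[p])
    for _ in range(attempts):
        chars: list[str | None] = [None] * sp.length
        for p, b in forced.items():
            chars[p] = b
        for i, j in sp.target_pairs():
            if chars[i] is None and chars[j] is None:
                chars[i] = rng.choice(list(RNA_ALPHABET))
                chars[j] = complement(chars[i])
            elif chars[i] is None:
                chars[i] = complement(chars[j])
            elif chars[j] is None:
                chars[j] = complement(chars[i])
        for p in range(sp.length):
            if chars[p] is None:
                chars[p] = rng.choice(list(RNA_ALPHABET))
        residues = "".join(chars)
        if not run_violation(residues, mask, run_limit):
            return NucleotideSequence(sp.name, residues, mask)
    raise InitializationError(
        f"{sp.name}: could not satisfy constraints in {attempts} attempts"
    )


def initialize(
    gate: GateSpec, rng: np.random.Generator, cfg: OptimizerConfig | None = None
) -> dict[str, NucleotideSequence]:
    """Random sequences satisfying structure, motif, and run constraints."""
    cfg = cfg or OptimizerConfig()
    return {
        sp.name: _init_species(sp, rng, cfg.init_attempts,
                               cfg.forbidden_run_length)
        for sp in gate.species
    }


def _stems_consistent(residues: list[str], pm: dict[int, int]) -> bool:
    return all(is_wc_pair(residues[p], residues[q])
               for p, q in pm.items() if p < q)


def mutate(
    state: dict[str, NucleotideSequence],
    gate: GateSpec,
    rng: np.random.Generator,
    word_len: int,
    cfg: OptimizerConfig | None = None,
) -> tuple[dict[str, NucleotideSequence], str]:
    """One mutation proposal; returns (new sequences, move descriptor).

    Sequence lengths never change; fixed positions are never touched;
    stem partners are co-mutated to the Watson-Crick complement; proposals
    creating forbidden homopolymer runs are resampled.
    """
    cfg = cfg or OptimizerConfig()
    designable = [sp for sp in gate.species if any(effective_mask(sp))]
    if not designable:
        raise MoveError("no designable positions in gate")
    names = [sp.name for sp in gate.species]
    by_name = gate.species_by_name()

    for _ in range(cfg.move_resample_budget):
        # at word length 1 the transplant degrades to a directed point move
        use_word = word_len >= 1 and rng.random() < cfg.p_word
        if use_word:
            src = names[rng.integers(len(names))]
            src_res = state[src].residues
            if len(src_res) < word_len:
                continue
            tgt_sp = designable[rng.integers(len(designable))]
            mask = effective_mask(tgt_sp)
            windows = [
                w for w in range(tgt_sp.length - word_len + 1)
                if all(mask[w + t] for t in range(word_len))
            ]
            if not windows:
                continue
            s0 = int(rng.integers(len(src_res) - word_len + 1))
            w0 = windows[int(rng.integers(len(windows)))]
            word = src_res[s0 : s0 + word_len]
            ins = reverse_complement(word)
            chars = list(state[tgt_sp.name].residues)
            written = list(range(w0, w0 + word_len))
            for t, p in enumerate(written):
                chars[p] = ins[t]
            desc = f"word{word_len}:{src}[{s0 + 1}]->{tgt_sp.name}[{w0 + 1}]"
        else:
            tgt_sp = designable[rng.integers(len(designable))]
            mask = effective_mask(tgt_sp)
            positions = [p for p in range(tgt_sp.length) if mask[p]]
            p = positions[int(rng.integers(len(positions)))]
            chars = list(state[tgt_sp.name].residues)
            others = [b for b in RNA_ALPHABET if b != chars[p]]
            chars[p] = others[int(rng.integers(3))]
            written = [p]
            desc = f"point:{tgt_sp.name}[{p + 1}]"

        pm = partner_map(by_name[tgt_sp.name])
        ok = True
        for p in written:
            q = pm.get(p)
            if q is None or q in written:
                continue
            if not mask[q]:
                ok = False
                break
            chars[q] = complement(chars[p])
        if not ok:
            continue
        if not _stems_consistent(chars, pm):
            continue
        residues = "".join(chars)
        if run_violation(residues, mask, cfg.forbidden_run_length):
            continue
        if residues == state[tgt_sp.name].residues:
            continue
        new_state = dict(state)
        new_state[tgt_sp.name] = state[tgt_sp.name].with_residues(residues)
        return new_state, desc
    raise MoveError(f"no legal move in {cfg.move_resample_budget} resamples")


def accept(delta_f: float, temperature: float, rng: np.random.Generator) -> bool:
    """Metropolis criterion: downhill always, uphill with exp(-dF/T)."""
    if math.isnan(delta_f):
        return False
    if delta_f <= 0:
        return True
    if math.isinf(delta_f):
        return False
    return bool(rng.random() < math.exp(-delta_f / temperature))


def homodimer_check(
    seq: NucleotideSequence,
    model: ReferenceEnergyModel,
    cfg: OptimizerConfig | None = None,
) -> bool:
    """True when the sequence self-hybridizes strongly enough to reject."""
    cfg = cfg or OptimizerConfig()
    return delta_g_mfe(seq, seq, model) < cfg.homodimer_dg_threshold


def _evaluate(
    seqs: dict[str, NucleotideSequence],
    gate: GateSpec,
    obj_cfg: ObjectiveConfig,
    model: ReferenceEnergyModel,
    cfg: OptimizerConfig,
    cache: FoldCache,
) -> ObjectiveResult:
    res = total_objective(
        seqs, gate, obj_cfg, model,
        homodimer_threshold=cfg.homodimer_dg_threshold, cache=cache,
    )
    if cfg.harmonic_stiffness > 0 and math.isfinite(res.total):
        for sp in gate.species:
            d = structure_distance(
                cache.group([seqs[sp.name]]).structure.symbols,
                sp.target_structure,
            )
            res.total += cfg.harmonic_stiffness * d * d
    return res


def run(
    gate: GateSpec,
    cfg: OptimizerConfig | None = None,
    model: ReferenceEnergyModel | None = None,
    obj_cfg: ObjectiveConfig | None = None,
) -> DesignResult:
    """Simulated-annealing design loop; returns the best candidate seen.

    Deterministic for a given ``cfg.rng_seed``: a single seeded generator
    drives initialization, move proposals, and Metropolis draws.
    """
    cfg = cfg or OptimizerConfig()
    model = model or ReferenceEnergyModel()
    obj_cfg = obj_cfg or ObjectiveConfig()
    validate_spec(gate)
    rng = np.random.default_rng(cfg.rng_seed)
    cache = FoldCache(model)

    current = initialize(gate, rng, cfg)
    cur_res = _evaluate(current, gate, obj_cfg, model, cfg, cache)
    best, best_res, best_iter = dict(current), cur_res, -1
    trajectory: list[TrajectoryRecord] = []
    n_accepted = 0
    n_failures = 0

    for k in range(cfg.iterations):
        temperature = cfg.temperature_at(k)
        word_len = cfg.word_len_at(k)
        try:
            proposal, desc = mutate(current, gate, rng, word_len, cfg)
        except MoveError:
            n_failures += 1
            continue
        prop_res = _evaluate(proposal, gate, obj_cfg, model, cfg, cache)
        delta_f = prop_res.total - cur_res.total
        if math.isinf(prop_res.total):
            delta_f = math.inf
        accepted = accept(delta_f, temperature, rng)
        if accepted:
            current, cur_res = proposal, prop_res
            n_accepted += 1
            if cur_res.total < best_res.total:
                best, best_res, best_iter = dict(current), cur_res, k
        if cfg.record_trajectory:
            trajectory.append(
                TrajectoryRecord(k, desc, delta_f, accepted, cur_res.total)
            )

    return DesignResult(
        sequences=best,
        objective=best_res.total,
        breakdown=best_res,
        trajectory=trajectory,
        best_iteration=best_iter,
        n_accepted=n_accepted,
        n_move_failures=n_failures,
    )


def exhaustive_search(
    gate: GateSpec,
    model: ReferenceEnergyModel | None = None,
    obj_cfg: ObjectiveConfig | None = None,
    cfg: OptimizerConfig | None = None,
    max_free: int = 10,
) -> tuple[dict[str, NucleotideSequence], float]:
    """Brute-force global optimum over all designable assignments.

    Only feasible for toy gates: stem-linked positions count once (the
    partner is the complement), and candidates violating the homopolymer
    rule are excluded exactly as in the annealer.  Serves as the
    independent oracle for the stochastic search.
    """
    model = model or ReferenceEnergyModel()
    obj_cfg = obj_cfg or ObjectiveConfig()
    cfg = cfg or OptimizerConfig()
    base: dict[str, list[str]] = {}
    free_vars: list[tuple[str, int]] = []
    linked: dict[tuple[str, int], tuple[str, int]] = {}
    for sp in gate.species:
        chars = list(sp.fixed_sequence) if sp.fixed_sequence else ["N"] * sp.length
        for p, b in _forced_bases(sp).items():
            chars[p] = b
        mask = effective_mask(sp)
        pm = partner_map(sp)
        for p, q in pm.items():
            if chars[p] != "N" and chars[q] == "N" and not mask[q]:
                chars[q] = complement(chars[p])
        for p in range(sp.length):
            if not mask[p] and chars[p] == "N":
                raise SpecError(
                    f"{sp.name}: non-designable position {p + 1} has no base; "
                    "provide fixed_sequence for toy exhaustive searches"
                )
        base[sp.name] = chars
        for p in range(sp.length):
            if not mask[p]:
                continue
            q = pm.get(p)
            if q is not None and q < p and mask[q]:
                linked[(sp.name, p)] = (sp.name, q)
            else:
                free_vars.append((sp.name, p))
    if len(free_vars) > max_free:
        raise SpecError(
            f"{len(free_vars)} free positions exceed the exhaustive limit "
            f"({max_free})"
        )
    cache = FoldCache(model)
    best_seqs: dict[str, NucleotideSequence] | None = None
    best_total = math.inf
    masks = {sp.name: effective_mask(sp) for sp in gate.species}
    for assignment in itertools.product(RNA_ALPHABET, repeat=len(free_vars)):
        chars = {name: list(seq) for name, seq in base.items()}
        for (name, p), b in zip(free_vars, assignment):
            chars[name][p] = b
        for (name, p), (_, q) in linked.items():
            chars[name][p] = complement(chars[name][q])
        bad = False
        seqs = {}
        for sp in gate.species:
            residues = "".join(chars[sp.name])
            if run_violation(residues, masks[sp.name],
                             cfg.forbidden_run_length):
                bad = True
                break
            seqs[sp.name] = NucleotideSequence(sp.name, residues,
                                               masks[sp.name])
        if bad:
            continue
        res = total_objective(
            seqs, gate, obj_cfg, model,
            homodimer_threshold=cfg.homodimer_dg_threshold, cache=cache,
        )
        if res.total < best_total:
            best_total = res.total
            best_seqs = seqs
    if best_seqs is None:
        raise SpecError("no feasible assignment")
    return best_seqs, best_total
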