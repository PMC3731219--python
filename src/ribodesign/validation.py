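"""Synthetic validation fixtures: mutant libraries, regression, design QC.

The experimental check of the scoring model is a library of point variants
of a working riboregulator whose measured expression fold changes are
regressed (on a log scale) against dG_kin.  This module emulates that
methodology end to end with synthetic data: it randomizes a trinucleotide
in the seed of a base sRNA/mRNA pair, scores every mutant with the same
machinery used for design, and draws "experimental" log folds from a known
linear model in dG_kin plus Gaussian noise.  Because the generating slope
is known, parameter recovery — not value matching — is the test.

It also hosts toy design problems small enough for brute-force search.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .energy_model import (
    NucleotideSequence,
    RNA_ALPHABET,
    ReferenceEnergyModel,
    reverse_complement,
)
from .errors import FitError, SpecError
from .gates import GateSpec, SpeciesSpec, TruthTableEntry
from .objective import (
    FoldCache,
    ObjectiveConfig,
    ObjectiveTerm,
    dg_kin,
    group_delta_g,
    seed_length,
    structure_distance,
)


@dataclass(frozen=True)
class MutantRecord:
    mutant_id: str
    srna: str
    mrna: str
    delta_g: float
    alpha: int
    delta_g_kin: float
    fold_change: float

    def __post_init__(self) -> None:
        if self.fold_change <= 0:
            raise SpecError("fold_change must be > 0")


@dataclass(frozen=True)
class RegressionFit:
    slope: float
    intercept: float
    r_squared: float


def default_base_pair() -> dict[str, NucleotideSequence]:
    """A deterministic synthetic repressor pair used as the library parent.

    The 30-nt 5' UTR carries the Shine-Dalgarno sequence AGGAGA eight nt
    upstream of AUG; the 12-nt sRNA is the reverse complement of the UTR
    window covering the SD, which blocks the RBS in the complex with a
    formation energy right at the saturation level while leaving the seed
    term unsaturated (so trinucleotide mutants spread in dG_kin).
    """
    mrna = "AUCAUCAUCAUCA" + "AGGAGA" + "CAACCAAC" + "AUG"
    srna = reverse_complement(mrna[11:23])
    return {
        "sRNA": NucleotideSequence("sRNA", srna),
        "mRNA": NucleotideSequence("mRNA", mrna),
    }


def score_pair(
    srna: NucleotideSequence,
    mrna: NucleotideSequence,
    model: ReferenceEnergyModel,
    cfg: ObjectiveConfig,
    cache: FoldCache | None = None,
) -> tuple[float, int, float]:
    """(dG, alpha, dG_kin) of one sRNA/mRNA pair under any folding engine."""
    cache = cache or FoldCache(model)
    fa, fb = cache.group([srna]), cache.group([mrna])
    dg = group_delta_g(cache.group([srna, mrna]), fa, fb)
    seed = seed_length(fa, fb, allow_gu=cfg.seed_allow_gu)
    return dg, seed.alpha, dg_kin(dg, seed.alpha, cfg)


def generate_library(
    base: Mapping[str, NucleotideSequence] | None = None,
    n_mutants: int = 11,
    positions: Sequence[int] | None = None,
    noise_sigma: float = 0.25,
    true_slope: float | None = None,
    intercept: float | None = None,
    rng: np.random.Generator | None = None,
    model: ReferenceEnergyModel | None = None,
    cfg: ObjectiveConfig | None = None,
) -> list[MutantRecord]:
    """Mutant library with a known exponential energy-fold relationship.

    A randomized trinucleotide is written at ``positions`` of the sRNA
    (default: the start of the parent's seed region, mirroring an NNN
    mutagenesis primer); each mutant's dG_kin is computed from its
    sequences and log(fold) is drawn as
    intercept + true_slope * dG_kin + Normal(0, noise_sigma).

    Defaults: eleven mutants (the size of a small sequenced clone
    selection), slope -1/RT (Boltzmann-consistent), and an intercept that
    puts the parent design at a 30-fold response.
    """
    base = base or default_base_pair()
    rng = rng if rng is not None else np.random.default_rng(0)
    model = model or ReferenceEnergyModel()
    cfg = cfg or ObjectiveConfig()
    slope = true_slope if true_slope is not None else -1.0 / cfg.rt
    cache = FoldCache(model)

    srna0, mrna0 = base["sRNA"], base["mRNA"]
    _, _, base_kin = score_pair(srna0, mrna0, model, cfg, cache)
    if intercept is None:
        intercept = math.log(30.0) - slope * base_kin
    if positions is None:
        seed = seed_length(cache.group([srna0]), cache.group([mrna0]),
                           allow_gu=cfg.seed_allow_gu)
        start = min(max(seed.start_a, 0), len(srna0) - 3)
        positions = [start, start + 1, start + 2]
    if len(positions) == 0:
        raise SpecError("need at least one mutated position")

    records = []
    for m in range(n_mutants):
        chars = list(srna0.residues)
        for p in positions:
            chars[p] = RNA_ALPHABET[int(rng.integers(4))]
        srna = srna0.with_residues("".join(chars))
        dg, alpha, kin = score_pair(srna, mrna0, model, cfg, cache)
        log_fold = intercept + slope * kin + (
            rng.normal(0.0, noise_sigma) if noise_sigma > 0 else 0.0
        )
        records.append(
            MutantRecord(
                mutant_id=f"m{m + 1:02d}",
                srna=srna.residues,
                mrna=mrna0.residues,
                delta_g=dg,
                alpha=alpha,
                delta_g_kin=kin,
                fold_change=math.exp(log_fold),
            )
        )
    if all(r.delta_g_kin == 0 for r in records):
        warnings.warn("degenerate library: no mutant interacts",
                      stacklevel=2)
    return records


def fit_log_linear(records: Sequence[MutantRecord]) -> RegressionFit:
    """OLS of log(fold change) on dG_kin."""
    if len(records) < 3:
        raise FitError("need at least 3 records")
    x = np.array([r.delta_g_kin for r in records])
    y = np.log([r.fold_change for r in records])
    if len(np.unique(x)) < 2 or np.ptp(x) == 0:
        raise FitError("zero variance in dG_kin")
    if len(np.unique(x)) < 3:
        raise FitError("need at least 3 distinct dG_kin values")
    res = stats.linregress(x, y)
    return RegressionFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
    )


def library_frame(records: Sequence[MutantRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "mutant_id": [r.mutant_id for r in records],
            "sRNA": [r.srna for r in records],
            "mRNA": [r.mrna for r in records],
            "delta_G": [r.delta_g for r in records],
            "alpha": [r.alpha for r in records],
            "delta_G_kin": [r.delta_g_kin for r in records],
            "fold_change": [r.fold_change for r in records],
        }
    )


@dataclass
class DesignReport:
    reactions: pd.DataFrame
    crosstalk: pd.DataFrame
    structures: pd.DataFrame

    def to_text(self) -> str:
        parts = []
        for title, frame in (
            ("# reactions", self.reactions),
            ("# cross-talk dG_kin matrix", self.crosstalk),
            ("# structural targets", self.structures),
        ):
            parts.append(title)
            parts.append(frame.to_csv(sep="\t", index=False,
                                      float_format="%.2f").rstrip())
        return "\n".join(parts) + "\n"


def evaluate_designs(
    designs: Mapping[str, NucleotideSequence],
    gate: GateSpec,
    model: ReferenceEnergyModel | None = None,
    cfg: ObjectiveConfig | None = None,
) -> DesignReport:
    """Post-design QC: per-reaction energetics, cross-talk, mask satisfaction.

    Cross-talk lists dG_kin for every species pair including unintended
    ones (a designed device should show near-zero dG_kin off target).
    """
    model = model or ReferenceEnergyModel()
    cfg = cfg or ObjectiveConfig()
    cache = FoldCache(model)
    names = [sp.name for sp in gate.species if sp.name in designs]

    rx_rows = []
    for a, b, sense in gate.reactions:
        if not all(n in designs for n in a + b):
            continue
        fa = cache.group([designs[n] for n in a])
        fb = cache.group([designs[n] for n in b])
        fab = cache.group([designs[n] for n in a + b])
        dg = min(fab.free_energy - fa.free_energy - fb.free_energy, 0.0)
        seed = seed_length(fa, fb, allow_gu=cfg.seed_allow_gu)
        rx_rows.append(
            {"reaction": f"{'+'.join(a)} : {'+'.join(b)}", "sense": sense,
             "delta_G": dg, "alpha": seed.alpha,
             "delta_G_kin": dg_kin(dg, seed.alpha, cfg)}
        )

    ct = pd.DataFrame(index=names, columns=names, dtype=float)
    for i, na in enumerate(names):
        for nb in names[i:]:
            if na == nb:
                dg, alpha, kin = score_pair(designs[na], designs[nb],
                                            model, cfg, cache)
            else:
                dg, alpha, kin = score_pair(designs[na], designs[nb],
                                            model, cfg, cache)
            ct.loc[na, nb] = kin
            ct.loc[nb, na] = kin
    crosstalk = ct.reset_index(names=["species"])

    st_rows = []
    for term in gate.terms:
        if term.kind != "str" or not all(n in designs for n in term.a):
            continue
        observed = cache.group([designs[n] for n in term.a]).structure.symbols
        d = structure_distance(observed, term.target)
        compared = sum(1 for c in term.target if c != "*")
        st_rows.append(
            {"state": "+".join(term.a), "label": term.label,
             "distance": d, "compared_positions": compared,
             "satisfied_fraction": 1.0 - d / compared if compared else 1.0}
        )
    return DesignReport(
        reactions=pd.DataFrame(rx_rows),
        crosstalk=crosstalk,
        structures=pd.DataFrame(st_rows),
    )


def toy_yes_gate() -> GateSpec:
    """A YES-style toy device with exactly eight free designable positions.

    The 16-nt mRNA carries a 3-bp stem that blocks a 3-nt RBS stand-in;
    its 4-nt loop is designable.  The 8-nt sRNA (4 designable positions)
    must open the stem by pairing the mRNA's 5' side.  Small enough for
    exhaustive search over all 4^8 assignments, which makes it the oracle
    problem for the annealer.
    """
    mrna_struct = ".." + "(((" + "...." + ")))" + "...."
    mrna_seq = "GA" + "GGC" + "ACGA" + "GCC" + "AAUC"
    rbs = [9, 10, 11]
    mrna = SpeciesSpec(
        name="mRNA", role="mRNA_5UTR", length=16,
        target_structure=mrna_struct,
        fixed_sequence=mrna_seq,
        designable_mask=tuple(p in (5, 6, 7, 8) for p in range(16)),
    )
    srna = SpeciesSpec(
        name="sRNA", role="sRNA", length=8,
        target_structure="." * 8,
        fixed_sequence="AACGGGUC",
        designable_mask=tuple(p in (2, 3, 4, 5) for p in range(8)),
    )

    def mask(char: str, offset: int, total: int) -> str:
        chars = ["*"] * total
        for p in rbs:
            chars[offset + p] = char
        return "".join(chars)

    entries = [
        TruthTableEntry(frozenset(), "RBS_blocked"),
        TruthTableEntry(frozenset({"sRNA"}), "RBS_accessible"),
    ]
    reactions = [(("sRNA",), ("mRNA",), "occur")]
    terms = [
        ObjectiveTerm("kin", ("sRNA",), ("mRNA",), sense="occur",
                      label="sRNA:mRNA must occur"),
        ObjectiveTerm("str", ("mRNA",), target=mask("|", 0, 16),
                      label="mRNA alone: RBS blocked"),
        ObjectiveTerm("str", ("sRNA", "mRNA"), target=mask(".", 8, 24),
                      label="complex: RBS released"),
    ]
    return GateSpec("YES", [srna, mrna], entries, reactions, terms,
                    meta={"rbs": rbs})
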