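# ribodesign

Energy-based design automation of multi-state small-RNA (sRNA) regulatory
devices: given the truth table of a logic gate, the target secondary
structures of its RNA species, and fixed motifs such as the Shine-Dalgarno
(SD) sequence, `ribodesign` evolves the actual nucleotide sequences by
Monte Carlo Simulated Annealing against a physicochemical objective.

It is written for synthetic biologists and RNA engineers who want to
solve the *inverse* riboregulation problem — find sequences that implement
a specified behaviour — rather than analyze the behaviour of given
sequences. The package designs:

* **NOT** gates — an sRNA pairs the SD region of an open 5' UTR and blocks
  ribosome docking (or drives the UTR into an SD-paired conformation);
* **YES** gates — the UTR is *cis*-repressed by an anti-SD stem and the
  sRNA releases it, or the sRNA disrupts an intrinsic terminator hairpin
  (anti-termination);
* **AND** gates — two sRNAs are inert alone, dimerize, and only the dimer
  opens the UTR;
* **OR / coupled YES-NOT** devices — by serial redesign with one species'
  sequence held fixed.

## The objective

Each truth-table entry contributes terms to a single scalar objective
(lower is better). For every reaction between species *A* and *B*:

```
ΔG_kin = max(ΔG, ΔG_sat) + min(α, α_sat) · G_p
```

where ΔG is the free energy of complex formation from the separately
folded species, α is the length of the seed (the longest contiguous
Watson-Crick complementary run that is unpaired in both partners' MFE
structures — the nucleation site that sets the association rate), and
G_p = −1.28 kcal/mol is the average energetic contribution of one paired
nucleotide. Saturation levels ΔG_sat = −15 kcal/mol and α_sat = 6 nt cap
the credit, so the best attainable value is −22.68 kcal/mol. Reactions
that must occur contribute ΔG_kin; reactions that must not occur
contribute max(−ΔG_kin, 0).

Structural requirements (RBS accessible/blocked, terminator
formed/disrupted, full species targets) are scored by

```
ΔG_str = −G_p · d
```

with *d* the Hamming distance between the observed dot-bracket structure
and the target (or target mask) — a distance rescaled into kcal/mol.

The annealer starts from random sequences that already satisfy the
structural and motif constraints, and proposes either point replacements
or a directed move that copies a word (3 → 2 → 1 nt over the run) from
one species and inserts its reverse complement into another. Stem
partners are co-mutated, homopolymer runs of four are rejected, and
sequences forming strong homodimers are excluded. Folding uses a
self-contained additive pair-energy model (GC −3, AU −2, GU −1 kcal/mol)
that is exhaustively verifiable; a ViennaRNA adapter
(`ribodesign.vienna`) provides Turner-parameter folding behind the same
interface.

## Worked example

`examples/` contains one narrative script per capability. Designing a
reduced NOT gate (`python examples/04_design_not_gate.py`) prints:

```
final objective: -22.68 (best at iteration 19067)
  kin sRNA:mRNA must occur               -22.68
  str mRNA alone: RBS accessible           0.00
  str complex: RBS blocked                 0.00
sRNA
  UUGGCGUCCUUUCUCGCCAA
  ((((((......)..))))) (-16.00)
mRNA
  AAAGGAGGAGAGGAGGAGAACGAAGAAAUG
  ....................(..(....)) (-5.00)
```

The kin term sits at the −22.68 kcal/mol floor (interaction saturated in
both energy and seed length), the lone mRNA leaves its SD region
unpaired (translation ON without input), and in the sRNA:mRNA complex
every SD position is paired (translation OFF with input) — exactly the
NOT truth table. The designed sRNA folds into its imposed hairpin and
carries the anti-SD loop that nucleates the interaction.

The same library surface drives the other capabilities: folding and
cofolding (`01`), reaction-coordinate landscapes G(r) with formation and
activation energies (`02`), pair scoring (`03`), synthetic mutant-library
regression that recovers the generating slope −1/RT (`05`), and the
mass-action association model with its quasi-steady-state reduction
(`06`). A thin CLI exposes the same operations:
`ribodesign design|score|landscape|kinetics|validate|fixtures`.

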