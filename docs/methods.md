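# Methods

## Scope and model

`ribodesign` treats riboregulation as a secondary-structure phenomenon:
an sRNA and the 5' UTR of a target mRNA (optionally a second sRNA) fold
individually, associate through a seed, and settle into a complex whose
structure decides whether the ribosome binding site (RBS) or an intrinsic
terminator is available. Design means choosing sequences so that every
entry of a gate's truth table maps to the right conformational outcome.
Pseudoknots, non-canonical pairs, RNA chaperones (Hfq), divalent-ion
effects, and 3D structure are outside the model; temperature is fixed at
37 °C, i.e. RT = 0.61 kcal/mol.

## Energy models

The default engine is a deliberately minimal additive model: each base
pair contributes a fixed energy (GC −3.0, AU −2.0, GU −1.0 kcal/mol; no
stacking or loop terms), structures are pseudoknot-free, intramolecular
pairs must close a loop of ≥ 3 nt, and intermolecular pairs are exempt
from that minimum. GU wobble is accepted within a strand but not between
strands (interactions are treated as Watson-Crick, which also defines the
reaction coordinate below). The virtue of this model is verifiability:
every MFE prediction, landscape, and probability matrix can be checked
against exhaustive enumeration at toy sizes, and the test suite does
exactly that. Complexes of two or three strands are folded as a
concatenation with strand separators, which restricts inter-strand
pairing to nested topologies; some three-strand arrangements are
therefore unreachable (a known limitation of the concatenation
approach). Ties in the dynamic program are broken by preferring to leave
the leftmost branching position unpaired, making every fold
deterministic.

`ribodesign.vienna` wraps the ViennaRNA Turner-parameter engine behind
the same fold/cofold surface for realistic energetics (two strands only).
It is an alternative engine, never the reference for the additive model's
tests.

## Association landscape

The reaction coordinate r counts intermolecular Watson-Crick pairs;
r = 0 is the pre-association state, whose energy is the sum of the two
individual MFEs. G(r) is the minimum energy over all joint structures
with exactly r such pairs, computed exactly by an r-resolved interval
dynamic program (default limit 24 nt combined, configurable; the limit
keeps the exhaustive cross-checks fast). The free energy of formation is
ΔG = G(r_hyb) − G(0) at the profile minimum; the activation energy is
the maximum of G over the path 1..r_hyb, so ΔG‡ ≥ ΔG by construction.
The partition function Z = Σ_r exp(−G(r)/RT) is reported for analysis
(with a log-space variant for small RT) but is not an optimization
target. Production scoring uses the MFE shortcut
ΔG = E(cofold) − E(fold A) − E(fold B), which the tests verify against
the profile on all enumerable instances.

## Objective

* **ΔG_kin = max(ΔG, ΔG_sat) + min(α, α_sat)·G_p** with defaults
  G_p = −1.28 kcal/mol, ΔG_sat = −15 kcal/mol, α_sat = 6 nt. α is the
  seed length: the longest contiguous antiparallel Watson-Crick run whose
  positions are unpaired in both partners' individual MFE structures
  (individual folding, at millisecond timescale, completes before
  association, at seconds-to-minutes). Saturation reflects that beyond
  these levels further stabilization no longer buys regulatory activity.
  The floor implied by the defaults is −22.68 kcal/mol.
* **Occur vs avoid.** Required reactions add ΔG_kin; forbidden ones add
  max(−ΔG_kin, 0). The clip at zero keeps already-inert pairs from
  dominating the weighted sum — without it, maximizing ΔG_kin for avoid
  terms would reward arbitrary non-interaction over actual design
  progress.
* **ΔG_str = −G_p·d**, the Hamming distance between observed and target
  dot-bracket strings rescaled into kcal/mol. Targets use the alphabet
  `.` (unpaired), `(`/`)` (literal), `|` (paired with either bracket —
  an RBS-blocked mask cares about pairedness, not partner identity), and
  `*` (not compared). Term weights default to w_kin = w_str = 1.
* **Homodimer exclusion.** Any candidate whose species self-cofolds
  below −7.5 kcal/mol (half of ΔG_sat) receives an infinite objective;
  self-dimers would compete with every intended reaction.

## Gate construction

Builders assemble species, truth tables, reactions, and terms. The SD
sequence AGGAGA is placed 8 nt upstream of the start codon. The
cis-repressed UTR pairs an upstream anti-SD hexamer to the SD across a
3-nt loop. The anti-termination UTR carries a ≥ 6-bp terminator stem
with a fixed poly(U) hexamer; "disrupted" in reports means ≥ 80 % of
stem positions unpaired in the complex (the objective itself just
minimizes stem pairedness). Constrained redesign (`constrain_gate`)
freezes a species' sequence, enabling coupled YES/NOT and OR devices by
serial design; after an OR design, cross-talk between the two sRNAs is
reported but not optimized. `validate_spec` rejects incomplete truth
tables, overlapping motifs, and target pairs whose two positions are
forced to non-complementary bases — in that case design cannot proceed.

## Optimizer

Monte Carlo Simulated Annealing with a geometric temperature schedule
(T0 = 5.0 objective units cooling to 0.05 over the run — the schedule is
a package choice; only the Metropolis rule itself is fundamental).
Initialization samples stem partners as Watson-Crick pairs, places
motifs verbatim, and resamples until no homopolymer run of ≥ 4 touches a
designable position (runs wholly inside fixed motifs, e.g. poly(U), are
specification rather than evolution and are allowed). Moves are 50 %
directed (reverse-complement word transplant between species, word
length 3 for the first third of the run, 2 for the second, 1 after —
at length 1 the transplant acts as a directed point mutation) and 50 %
random point replacements; stem partners are co-mutated with strict
Watson-Crick complements; no insertions or deletions, so lengths are
constant. An optional harmonic term (stiffness · d² per species) can
soften the structural constraints. The best-seen candidate is returned;
a single seeded generator drives everything, so runs replay exactly.
Designs within 6 dot-bracket symbols (3 bp) of a structural target are
reported as satisfying it.

For toy problems (≤ 10 free positions after motif placement and stem
linkage) `exhaustive_search` enumerates every assignment under the same
constraints and serves as the independent oracle: on the bundled
8-position toy YES gate the annealer at 3 000 iterations recovers the
global optimum in ≥ 18 of 20 seeded runs. Full-size devices use
10⁴–10⁵ iterations at the reduced gate sizes bundled here (30-nt UTR,
20-nt sRNA), a problem scale chosen so the whole validation suite runs
on one CPU in minutes.

## Kinetics

The mass-action scheme A + B ⇌ [A:B]‡ → A:B (rates k_on, k_off, k_hyb)
with first-order degradation δ1 of free species and δ2 of the final
complex (whether δ2 also hits the intermediate is configurable; default
it does not) is integrated with an adaptive stiff-capable solver
(LSODA, rtol 1e-8). When k_off + k_hyb ≫ δ1 the intermediate sits at
A·B/K_M with K_M = (k_off + k_hyb)/k_on; `qssa_intermediate` reports a
validity flag (ratio ≥ 10). k_on and k_hyb are parameterized as
c_on·exp(−α·G_p/RT) and c_hyb·exp(−ΔG/RT) with free prefactors — only
ratios of predictions are meaningful, and the predicted expression fold
scales as exp(−ΔG_kin/RT).

## Synthetic validation fixtures

The regression methodology — score a mutant library with ΔG_kin, regress
log fold change, check the exponential energy-fold relationship — is
reproduced with synthetic data because it must run without wet-lab
measurements. A deterministic parent pair (30-nt UTR, 12-nt anti-SD
sRNA, formation energy at the saturation level but seed unsaturated, so
mutants spread in ΔG_kin) is mutagenized at a seed trinucleotide
(mirroring an NNN primer); log folds are drawn from
intercept + slope·ΔG_kin + N(0, σ) with slope −1/RT
(Boltzmann-consistent) and σ = 0.25, chosen once as a plausible
replicate spread for fluorometry data. The default library size is 11
mutants, the size of a small sequenced clone selection; recovery studies
use n = 50. Because the generating slope is known, the test is
parameter *recovery* (slope within 10 % in ≥ 95 % of libraries,
R² = 1 when noiseless), not agreement with any measured value. What
passing shows: the scoring and fitting pipeline is consistent and
unbiased at realistic noise. What it cannot show: that real fold
changes follow the model — the fixtures have the exponential law built
in by construction.

## Numerical choices and limitations

* Energies are exact multiples of 0.5 kcal/mol under the reference
  model; comparisons use 1e-6 tolerances.
* Boltzmann sums shift by the minimum energy (probabilities) or use
  log-sum-exp (log Z) to avoid overflow at small RT.
* Seed ties resolve to the smallest start position in A, then B;
  profile ties to the smallest r.
* Coordinates are 0-based half-open internally, 1-based inclusive in
  every report and file format; energies print with 2 decimals.
* The additive model has no loop penalties, so it over-stabilizes
  lone pairs and under-ranks stacking effects relative to Turner
  energetics; designs intended for the bench should be re-screened
  through the ViennaRNA adapter.
* The annealer is iteration-bounded (no convergence criterion); a small
  fraction of seeds stall one seed-extension short of the ΔG_kin floor
  on the reduced NOT gate — rerunning with another seed or more
  iterations resolves this.
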