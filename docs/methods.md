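# Methods

## The model

`attasm` simulates DNA assembly strategies that are built entirely from in
vivo site-specific recombination, at the level of annotated sequences. The
core object is a `DnaMolecule`: a circular or linear forward-strand sequence
carrying features (payload genes, antibiotic markers, replication origins)
and recombination sites. Two site classes are modelled:

* **Binary attachment-site systems** (lambda with two mutated variant pairs,
  HK022, Phi80). Sites exist in four states obeying
  `attB + attP = attL + attR`: Int catalyses B×P, Int plus Xis catalyses
  L×R. Partner sites must share system, variant and core. The attL site is
  composed of the B left arm and the P right arm; attR is the converse.
* **Symmetric systems** (Cre/loxP, FLP/frt): one state, unchanged by
  recombination, catalysed by a single recombinase.

A reaction is crossover splicing at the midpoint of the shared core (an odd
core gives its extra base to the left segment; any fixed convention
preserves the cores because both partners carry the same core). Topology
fully determines the outcome mode: circular×circular fuses (2→1),
an intramolecular direct repeat excises a circle (1→2), an intramolecular
inverted repeat (symmetric systems only) inverts the segment (1→1),
linear×linear exchanges arms (2→2), and circular×linear integrates the
circle (2→1). Total base count is conserved by construction, and features
ride along with their segments.

Reaction *enumeration* and reaction *choice* are deliberately separated:
`enumerate_events` lists every feasible pair under the resident enzymes in a
deterministic order and never applies one. Recombination in vivo is
stochastic, but every protocol step here ends in a screen that isolates one
outcome, so the strategy executors pick the designated event and the
selection model justifies treating that outcome as certain (integration
efficiencies for single-copy chromosomal integration are essentially
complete once non-recombinants are screened away).

### Orientation conventions

Sites pair only in parallel, forward-strand orientation; anti-parallel
attachment-site pairs are reported incompatible rather than being modelled
as inversions, because all shipped designs use parallel pairs. Symmetric
sites in opposite orientation on one molecule invert the intervening
segment. Reverse-strand site *storage* is supported (arms kept in site
orientation), but reverse–reverse pairs are rejected with a diagnostic
rather than silently mis-spliced; flip the molecule instead.

## Host-cell and screening model

A `CellState` is one chromosome plus episomes, a pir genotype and a resident
enzyme set. Replication is rule-based: the chromosome always replicates;
standard and N15-linear origins always replicate; the R6Kγ origin
replicates only in pir+ hosts. Selection is all-or-none per cell — a cell
survives a drug iff it carries that marker on a molecule it can replicate —
because the screens being modelled are binary plate screens, not MIC
gradients. `select` and `counter_select` partition any population and are
idempotent. Helper enzymes are modelled as transient: each strategy phase
induces the enzymes it needs and non-replicable molecules are cured
(segregationally lost) at phase boundaries, which stands in for curing
temperature-sensitive helper plasmids.

`pcr_predict` requires exact, unique primer matches (case-insensitive) and
supports amplicons that wrap a circular origin. Verification PCR in the
modelled workflows always runs on fully known constructs, so mismatch
tolerance would add parameters without adding information.

## Strategy designs

The published figures describe the strategies schematically; the exact
plasmid maps are not printed. The layouts below were derived so that every
textual constraint holds simultaneously, and they are pinned by the tests.

**SRAS (In/Out-Extract, one marker).** Host chromosome region, left to
right: `attL_Phi80 | breaker X (attL/attB HK022) | end E (attR lambda,
variant v) | [payloads] | attR_Phi80`. Unit plasmid (circular):
`attL_v | kan | R6Kγ | breaker (attR or attP HK022) | attR_v' | payload`.
One cycle integrates the unit at the ends (λ L×R), selects kan, excises the
backbone at the breakers (HK022 L×R or B×P), and counter-selects kan. The
lambda variant v alternates 1,2,1,… per cycle and the chromosomal breaker
state alternates L,B,L,… — this is exactly the pUnitR/pUnitP parity
alternation. Each cycle prepends its payload and leaves a single attB_v
scar between neighbours. Running the cycle breakers-first (integrate at the
breakers, excise at the ends) produces a canonically identical chromosome;
both orders are implemented and compared.

**Extraction.** An extraction vector integrates at the chromosomal breaker,
contributing `kan`, the R6Kγ origin and a lambda attL matched to the
*destination* host's end variant; Phi80 Int+Xis then excises everything
between the Phi80 pair as a circular plasmid (replicable only in pir+
hosts). The extracted plasmid has precisely the unit structure
(`attL | kan | ori | HK022 breaker | attR | payloads`) — this is what Rule 3
demands — so an inter-strain merge is just a breakers-first cycle with the
plasmid as the unit, including backbone excision and counter-selection.
That close-out keeps the final chromosome free of markers between payloads;
the compound junction it leaves carries the HK022 attB core as its
diagnostic scar. For arbitrary merge trees the source host's breaker parity
does not always produce the plasmid breaker state the destination needs, so
the executor selects an extraction-vector flavour that ships the required
breaker state; the canonical 2+3 demonstration shape never needs this.

**DRAS (Swap-Extract, two markers).** Host region:
`attL_Phi80 | frt | marker | attR_v | [payloads] | attR_Phi80`; unit:
`attL_v | R6Kγ | frt | new marker | attR_v' | payload`. Fusion at the ends
followed by FLP excision between the two frt sites deletes the old marker,
the attP junction and the unit origin in one arc, swapping kan↔cat while
appending the payload. frt, being symmetric, stays reactive throughout
(Rule 2), which is why the breaker here is frt rather than an att pair.

**Bi-Swap TRAS (three markers).** Unit `X-DNA-Y`:
`loxP | marker X | attR | payload | attL | marker Y | standard ori`,
with six vector types (3 markers × 2 directions). Merging `C-DNA1-G` with
`G-DNA2-K` fuses the circles at the matched lambda ends — the intermediate
carries all three markers — then Cre resolves the co-integrate at the two
loxP sites into the product `C-DNA1DNA2-K` (cat+kan, one origin, one loxP)
and a gen/attP by-product circle removed by counter-selecting gen. The
junction marker is thereby consumed. Junction end variants alternate by
junction index so no unit or merged block carries a self-reactive L/R pair.
The linear variant uses N15 hairpin plasmids: the linear ends are the
topology breakers, arm exchange yields the product directly with no fusion
intermediate, and the conjugation variant replaces electroporation in the
cost model only.

## The three rules

`validate_strategy` executes a two-unit assembly on synthetic payloads and
checks:

1. **Reactive ends become inactive** — no former payload-junction site can
   re-enumerate under the integrating enzyme on the final product (att
   junctions are attB, inert without a partner attP; the symmetric-ends
   mutant fails because loxP junctions stay reactive).
2. **Breakers stay reactive** — at every recorded intermediate, some breaker
   site still has a partner state the unit series supplies (the
   single-parity mutant strands the chromosome at attB with only attR units
   on offer).
3. **Products have unit structure** — the extracted product must contain
   the template's unit schema as an ordered (circular) subsequence: reactive
   end, marker, origin, breaker, next end, payload. Extra inert flank sites
   are allowed. The no-origin-extraction mutant fails here.

The three shipped mutants are constructed so each breaks exactly one rule.

## Planner and cost model

`build_merge_tree(n, k)` builds a balanced k-ary, order-preserving tree with
deeper-left filling: 2^N fragments assemble in N binary cycles
(`cycle_count` = tree depth, merges = n−1 for k = 2). The ledger prices a
tree from per-basis cost tables: *leaf* (library construction), *node*
(every clone grown/extracted: leaves + merges), *merge* (one junction),
*internal_node* (one k-ary reaction, used by single-reaction chemistries),
*extraction* (plasmid-side internal nodes plus one final), and
*non-final extraction* (one verification PCR each). The Bi-Swap TRAS,
TRAS-with-conjugation and restriction/ligation (BioBrick) columns of the
32-fragment comparison emerge from first principles: 63 nodes and 31 merges.
For the single-marker system, plasmid extractions (32 leaves + 16
extractions = 48) and PCR verifications (2 per merge + 15 non-final
extractions = 77) are likewise structural; its liquid/plate/electroporation
coefficients (5/9/5 per merge plus 2/1/1 per plasmid-side internal node) are
calibrated bookkeeping shipped as data — they cannot be derived from a
per-node/per-merge model and are excluded from structural claims. The
four-fragment isothermal-assembly template is included as an arity-4 cost
model only; no published column is reproduced for it because no k-ary tree
accounts for its step counts. Wall-clock scheduling ("estimated period") is
out of scope.

The strategy executors emit an `EventLog` entry per priced operation using
the same cost tables, so simulator and planner agree by construction; what
the simulation itself guarantees is the sequence-level outcome of every
recombination, selection and extraction step.

## Synthetic data

The fixture generator emulates the published unit design without any
copyrighted or accessioned sequence: payloads are random open reading frames
(ATG, non-stop codons at a requested GC fraction, TAA), 1.0–1.5 kb by
default to mimic a five-gene reporter operon, with an optional T7
promoter/terminator decoration that is not a necessary part of the unit.
Markers and origins are short deterministic pseudo-sequences (they function
by annotation, not by sequence). The site library pins the three published
attB cores (lambda-1, lambda-2, HK022); all arms and the Phi80 core are
deterministic synthetic placeholders, frozen in `data/sites.tsv` and
replaceable by a user-supplied library for base-pair-faithful work. Because
arms are synthetic, tests assert structure — payload order, scar identity,
junction counts, marker logic — not physical lengths such as junction
amplicon sizes; those require user-supplied construct sequences.
`lux_demo` re-executes the five-gene demonstration plan (a 2-leaf and a
3-leaf branch, extraction of the smaller branch, inter-strain integration)
and reports one diagnostic scar per junction; with the default seed the
final order is D, C, E, B, A.

What passing tests therefore show: the recombination algebra, screening
logic and accounting are internally consistent and reproduce every
structural and numeric claim that is derivable from the published design.
What they do not show: kinetics, recombination efficiency below 100%,
plasmid copy number, growth, mutation (e.g. host attB-core mutations), or
homologous recombination between accumulated attB scars — all explicitly
outside the model.

## Numerical and degenerate-input choices

Canonical form for circular molecules is the lexicographically smallest
rotation (Booth's algorithm), making rotation-invariant equality exact.
Site spans may wrap the circular origin (end > length, reduced modulo
length on access); features that would straddle a crossover cut are dropped
from products (the reacting sites are rebuilt as junction sites
explicitly). Coincident crossover points, missing site pairs, wrong-parity
units, same-marker swaps and non-screenable products all raise
`StrategyError`/`IncompatibleEventError` with a diagnostic rather than
producing a molecule. All randomness flows through a single seeded
generator; identical seeds give byte-identical libraries, logs and final
sequences.

## Known limitations

* Reverse-orientation att pairs and anti-parallel designs are rejected, not
  modelled.
* The "molecule count" of an induction outcome covers single events only;
  multi-event trajectories are reached by iterating phases, which is what
  the screened protocols do, but free-running reaction cascades are not
  sampled.
* The Gibson column of the operation comparison and the single-marker
  liquid/plate/electroporation rows are not derivable from the tree model;
  the former is omitted, the latter shipped as flagged calibration data.
* Seamless meet-and-cut linear assembly and restriction-based Bi-Swap
  variants are represented as cost templates only, without sequence-level
  schedules.
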