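# attasm

Sequence-level simulation and planning of **parallel in vivo DNA assembly by
site-specific recombination**.

Building a synthetic operon from a library of gene-sized fragments usually
means many rounds of in vitro cloning. An alternative is to do the joining
inside *E. coli* itself, using phage attachment-site recombination: each
fragment is shipped as an *assembly unit* — payload flanked by *reactive
ends* (mutated lambda attL/attR pairs), plus a *topology breaker* (an HK022
att site or a loxP/frt site that keeps circular molecules from simply
fusing), an antibiotic marker and a conditional R6Kγ origin — and each merge
is an integrate/excise/screen cycle on the host chromosome, or a
marker-swap between unit plasmids. Because merges are pairwise and
independent, 2^N fragments assemble in N parallel cycles.

`attasm` is a simulator and planner for this family of strategies, for
synthetic biologists designing such workflows and for anyone who wants to
reason about recombination-based cloning in silico. It provides:

* a **recombination engine** implementing the binary att algebra
  `attB + attP = attL + attR` (Int catalyses B×P; Int+Xis catalyses L×R;
  Cre/loxP and FLP/frt stay symmetric) as exact crossover splicing at the
  core midpoint, with topology-aware outcomes (fusion, excision, inversion,
  linear arm exchange, integration into a linear replicon) and base-count
  conservation;
* a **host-cell model**: transformation/conjugation, pir-dependent R6Kγ
  replication, helper-enzyme induction, all-or-none selection and
  counter-selection, and exact-match PCR prediction;
* executable **strategies**: the single-marker In/Out-Extract system
  (SRAS), the two-marker Swap-Extract system (DRAS), the three-marker
  Bi-Swap system (TRAS) with circular, linear (N15 hairpin plasmid) and
  conjugative variants — plus a checker for the three design rules
  (reactive ends must become inactive after assembly; topology breakers
  must stay reactive throughout; products must retain unit structure);
* a **planner** that builds balanced merge trees and prices a whole
  assembly in ten wet-lab operation categories, reproducing the published
  32-fragment step-count comparison for the strategies whose accounting is
  structural;
* **GenBank/FASTA I/O** (sites as `misc_recomb` features with full
  qualifiers; bit-exact round trips), a deterministic synthetic
  unit-library generator, and an in silico re-execution of the five-gene
  (lux operon) demonstration.

## Worked example

```python
from attasm import build_merge_tree, count_ops, get_template, lux_demo, payload_order

cell, log, report = lux_demo(seed=42)
print(payload_order(cell.chromosome))
for r in report:
    print(f"{r.left} | {r.right}: att{r.state} ({r.system}) scar, core {r.core}")
```

prints

```
['LuxD', 'LuxC', 'LuxE', 'LuxB', 'LuxA']
LuxD | LuxC: attB (lambda) scar, core ACCACTTTGTACAAGAAAGCTGGGT
LuxC | LuxE: attB (HK022) scar, core AACCTTTTTCACCTAAAGTGCACC
LuxE | LuxB: attB (lambda) scar, core ACAAGTTTGTACAAAAAAGCAGGCT
LuxB | LuxA: attB (lambda) scar, core ACCACTTTGTACAAGAAAGCTGGGT
```

Five synthetic payloads were assembled the way the wet-lab demonstration
ran: C then D on one host strain (two In/Out cycles), A, B, E on a second,
extraction of the D–C region as a plasmid, and a final attP×attB
integration into the second strain — yielding the chosen non-natural gene
order D,C,E,B,A. Each merge leaves exactly one attB scar between
neighbouring payloads; the variant-2 lambda core sits between D and C, and
the inter-strain junction carries the HK022 attB core. No marker remains in
the assembled region.

Planning a 32-fragment build with the three-marker Bi-Swap strategy:

```python
tree = build_merge_tree(32)
print(count_ops(get_template("TRAS"), tree).to_tsv())
```

```
operation	count
Incubation (liquid)	63
Plasmid Extraction	63
Digestion	0
DNA Extraction	0
Ligation	0
Gibson Assembly	0
Conjugation	0
Electroporation	31
PCR Verification	31
Incubation (plate)	31
```

— 63 clones to grow and extract (32 leaves + 31 merge products) and 31
junction events, finished in `cycle_count(tree) == 5` parallel cycles.

The same functionality is available from the shell:

```sh
attasm --seed 42 --out run demo-lux
attasm plan --strategy TRAS --n 32
attasm check-rules --mutants
attasm --seed 7 --out lib fixtures --n-units 6 --strategy TRAS
attasm --seed 7 --out sim simulate --strategy SRAS --n-units 4
```

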