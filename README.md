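# pksmith

From a type I polyketide synthase (PKS) gene cluster to a predicted natural
product — as a tested, reusable pipeline.

Modular type I PKSs are assembly lines: each extension module condenses one
extender unit (malonyl-CoA "acetate", (2*S*)-methylmalonyl-CoA "propionate",
or rarer units such as (2*R*)-methoxymalonyl-ACP) onto the growing chain and
optionally reduces the new β-keto group (KR → β-hydroxyl, +DH → α,β-double
bond, +ER → full saturation).  Reading the domain complement and a handful of
sequence motifs off a cluster therefore predicts the linear polyketide it
makes — and comparing that prediction with the retrobiosynthetic decomposition
of an isolated metabolite (the *collinearity check*) links cluster to
compound.  `pksmith` implements this inference chain for polyether tetronate
clusters of the tetromadurin type, end-to-end:

* **cluster_model** — data model for genes, modules and domains; FASTA /
  GenBank / JSON readers, TSV annotation tables.
* **domain_annotator** — reference-anchored motif calls: KS catalytic C/Q
  (extension vs decarboxylating KS^Q), AT selectivity ((H/T/V/Y)AFH acetate,
  (Y/V/W)ASH propionate, HASH relaxed hybrid), DH YGP-tyrosine + catalytic
  aspartate, KR (L/V/I)DD + catalytic tyrosine + B1/B2/A typing with
  D/L stereo outcomes, ER key tyrosine.
* **chain_assembler** — assembles the module-predicted chain, parses a target
  decomposition, diffs them position-by-position, and emits molecular
  formulas and SMILES.
* **pathway_engine** — the post-PKS tailoring pathway (tetronate formation,
  exocyclic double bond, double epoxidation + tetrahydrofuran cascade, two
  [4+2] cyclisations, two P450 hydroxylations) as a reaction table with exact
  formula bookkeeping and gene-knockout simulation.
* **ms_adducts** — formula arithmetic, positive-mode adduct m/z, peak
  matching and Δ-mass diagnosis (16 Da = missing hydroxyl, ...).
* **genetics_design** — in-frame deletion validation, screening-amplicon
  prediction, primer location, start-codon revision.
* **synthetic_data** — seeded generators for every fixture: clusters with
  planted motifs and held-out ground truth, GC-rich screening templates,
  noisy peak lists.

## Worked example

```python
import pksmith as pk

# canonical synthetic cluster: 7 PKS proteins, 1 loading + 14 extension modules
bundle = pk.make_cluster(pk.mad_architecture(), seed=1)
target = pk.tetromadurin_decomposition()

calls = pk.annotate_cluster(bundle.cluster, target)
print(calls.extender_tally())
# Counter({'propionate': 8, 'acetate': 6, 'methoxymalonate': 1})

order = [m.module_index for m in bundle.cluster.pks_modules]
chain13 = pk.assemble_from_calls(calls.calls, order)     # from the modules
chain14 = pk.chain_from_target(target)                   # from the metabolite
print(chain13.backbone_carbons)                          # 31
diff = pk.compare_chains(chain13, chain14)
print(diff.verdict, diff.positions())
# near_collinear ['12']   <- the single discrepancy: module 12's inactive KR
#                            predicts a C7 ketone where the product has a
#                            D-hydroxyl (trans-acting KR candidate)

caps = pk.detect_capabilities(bundle.cluster)
pathway = pk.build_pathway(caps, chain14)
wt = pk.simulate(pathway, chain14, set(), cluster=bundle.cluster)
ko = pk.simulate(pathway, chain14, {"mad10"}, cluster=bundle.cluster)
print(wt.formula, wt.product_label)   # C42H64O12 tetromadurin (1)
print(ko.formula, ko.product_label)   # C42H64O11 T-17 candidate (15): ...
```

The knockout of the PyrE3-like [4+2] cyclase gene blocks the oxadecalin
step and everything downstream of it (tetrahydropyran formation and the
second P450 hydroxylation), so the simulated shunt product is exactly one
oxygen — a nominal 16 Da — lighter than the wild-type product, matching the
Δ-mass diagnosis of its observed adduct series:

```python
from pathlib import Path
data = Path(pk.__file__).parent / "data"
d = pk.diagnose_delta(pk.Formula.parse("C42H64O12"),
                      pk.PeakList.from_csv(data / "tetromadurin_ions.csv"),
                      pk.PeakList.from_csv(data / "t17_ions.csv"))
print(d.shift_nominal, d.interpretation, d.proposed_formula)
# -16 absent hydroxyl (-O) C42H64O11
```

A `pksmith` CLI wraps the same pipeline (`pksmith run --seed 1 --out out/`,
plus `read`, `annotate`, `assemble`, `compare`, `simulate`, `adducts`,
`diagnose`, `deletion`, `make-fixture`).

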