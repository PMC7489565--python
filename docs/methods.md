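# Methods

## Scope and model

`pksmith` models the inference chain from a sequenced type I PKS biosynthetic
gene cluster to a predicted polyether tetronate product and the phenotypes of
targeted gene knockouts.  Everything is rule-based and deterministic; there is
no statistical fitting.  The package works at three levels:

1. **Sequence level** — each catalytic domain is classified from a handful of
   residues read off an alignment to a reference scaffold.
2. **Chain level** — ordered module calls are folded into a linear polyketide
   intermediate (monomer states, not full 3-D structure) and compared with
   the retrobiosynthetic decomposition of the target metabolite.
3. **Formula level** — tailoring is bookkeeping on element counts; knockout
   phenotypes are predicted as blocked steps and a final molecular formula.

## Domain annotation

Reference scaffolds (one per domain kind) are synthetic consensus sequences
packaged with the repository; only their *anchor columns* carry meaning — the
positions a curator would read a motif off in a multiple alignment.  A domain
is globally aligned to its scaffold (BLOSUM62, gap open −11 / extend −1, the
standard protein defaults) and anchor residues are read through the column
map.  Ties in co-optimal alignments resolve to the first (high-road) path the
aligner enumerates, so output is deterministic.

Rules per kind:

| Kind | Anchors | Rule |
|------|---------|------|
| KS | C-H-H triad | C → extension; Q → KS^Q (decarboxylating loading KS); else inactive |
| AT | 4-residue window | exact HASH → relaxed hybrid; (H/T/V/Y)AFH → acetate; (Y/V/W)ASH → propionate; else unknown |
| DH | YGP tyrosine; aspartate of HPALLDAAL | active iff both present |
| KR | (L/V/I)DD in the NADPH window; catalytic Tyr; Tyr+2 | no Tyr or >50% gap over the NADPH window → inactive; Tyr + LDD → B1 (B2 if Pro at Tyr+2), D-hydroxyl (B1 also D α-methyl); Tyr without LDD → A-type, L-hydroxyl |
| ER | key tyrosine | present → L-configuring; absent → D-configuring |

Pattern priority in the AT caller is explicit (HASH before the acetate
pattern) so the hybrid motif is never swallowed.  Motif matching is anchored,
never a free regex over the domain, to avoid false positives on internal
repeats.  The A-type rule (no LDD ⇒ L-hydroxyl) extends the B1/inactive cases
actually exercised by the canonical cluster and follows the general
ketoreductase stereochemistry literature.  One convention conflict exists in
the source descriptions of the Tyr+2 proline (B2-type vs A-type marker); the
rule engine follows the B2 reading and records the alternative in call notes.

Tunable thresholds: alignment identity floor 0.20 (identical columns /
alignment columns; below it a domain is refused as unalignable rather than
called), NADPH-window gap threshold 0.5 ("a significant deletion" made
precise).  Both are keyword arguments with these defaults.

A cluster-level post-pass uses an optional target decomposition: a
relaxed-hybrid loading AT resolves to the target's starter (the hybrid motif
can accept both acetate and propionate; the absence of a desmethyl congener
argues the starter is fixed), and a propionate call is re-labelled
`methoxymalonate_override` where the cluster carries the full five-gene
methoxymalonate subcluster and the target demands that extender — selectivity
motifs for methoxymalonate are known to mimic methylmalonyl motifs, so
sequence alone cannot make that call.

## Chain assembly and comparison

Per extension, the reduction ladder maps domain calls to a β-state: no active
KR → ketone; KR only (or KR + inactive DH) → hydroxyl with the KR's stereo;
KR+DH → α,β-double bond; KR+DH+ER → methylene.  α-Methyl stereochemistry
comes from the ER (saturated positions) or from a B1 KR (hydroxyl positions).
A module whose KR is inactive but whose DH looks intact is recorded as a
ketone with an explanatory note (the DH has no β-hydroxyl substrate; an enoyl
state is conceivable if an adjacent module's KR acts in trans) — the
comparison engine reports the possibility rather than choosing.

Carbon numbering runs from the carboxy/tetronate end (C1 = carbonyl of the
last extension), matching how the compound family is drawn.  The starter's
carbons all count as main-chain carbons, which makes the canonical chain
(propionate starter + 14 extensions) 31 carbons.  Double bonds are recorded
at the α,β-position of the forming module; double-bond migration in the
mature rings is below the resolution of this positional model and is noted in
the packaged decomposition file.

Formulas are computed monomer-wise against a saturated fatty-acid baseline
(C_B H_2B O2): +CH2 per side methyl, +CH2O per methoxy, then per-position
deltas (hydroxyl +O, enoyl −2H, ketone +O−2H).  A SMILES writer builds the
same molecule independently; a property test asserts the two element counts
agree on hundreds of random chains.  D/L labels stay labels — converting to
R/S would need full substituent priorities for no downstream benefit.

## Tailoring pathway and knockouts

The reaction table (packaged YAML, user-overridable) encodes nine steps with
required genes, licensing capabilities, signed element deltas and
prerequisites: tetronate formation/chain release (+C3H2O2, the exact
difference fixed once so that chain + glycerate → endpoint bookkeeping is
closed), C41 acetylation (+C2H2O) and elimination (−C2H4O2), double
epoxidation (+2O), the formula-neutral tetrahydrofuran cascade, C36
hydroxylation (+O), the [4+2] oxadecalin step, a fused hydration +
tetrahydropyran composite (formula-neutral; which tautomer the second cyclase
uses is left open because the two routes are formula-identical), and C38
hydroxylation (+O).  Whether the final hydroxylation needs only the
oxadecalin or the finished tetrahydropyran is genuinely unsettled; it is a
build option (`c38_hydroxylation_after`, default the oxadecalin step).

Capabilities are detected purely from product-label counts (the five-gene
glycerate and methoxymalonate operons, the epoxidase/hydrolase pair, the
P450 count, the two cyclase families).  Precursor-supply steps are gates, not
reactions: knocking out any methoxymalonate-supply gene yields "no product
(extender unavailable)" for a chain that uses that extender.

Simulation applies steps in table order; a step is blocked by a knocked-out
required gene or a blocked prerequisite, so the blocked set grows
monotonically with the knockout set, and the final formula is independent of
the topological order chosen (both are property-tested).  Wild type ends at
C42H64O12; knocking out the PyrE3-like cyclase blocks the oxadecalin step and
its dependents, ending at C42H64O11 — a nominal 16 Da light, the signature of
one missing hydroxyl.  Timing subtleties (possibly PKS-bound tetrahydrofuran
formation; P450 ordering) do not change formulas and are deliberately ignored.

## Mass spectra

Adduct m/z is (mass(M+δ) − z·mₑ)/z with the electron mass kept for
correctness.  Average masses are the default: the observed values this is
compared against come from a unit-resolution ion trap and match neither
average nor monoisotopic masses exactly, so all comparisons to observed ions
use a tolerance (default 0.5 Da).  Peak matching is greedy best-first with
each peak used at most once.  Δ-mass diagnosis takes the modal rounded shift
across adduct assignments (ties toward smaller magnitude, at least two
adducts agreeing), maps it through a small loss table (±16 hydroxyl, −18
water, −14 methylene) and confirms the proposed formula by re-matching.  Note
that one packaged observed ion (the parent compound's water-loss value) is
internally inconsistent with its own protonated ion — 22 Da apart instead of
~18 — and cannot be reproduced by any water-loss arithmetic; it ships as
printed with a header note.

## Genetics arithmetic

In-frame checks, amplicon prediction (wild type − deletion) and primer
location are exact integer/string operations; primer matching is exact by
design (mismatch tolerance is a primer-design concern, out of scope).
Amplicon lengths include both primer footprints, the standard PCR product
definition.  The start-codon scanner walks upstream in frame, stops at the
first in-frame stop, and reports every ATG with the peptide it would prepend.
The packaged revised cyclase protein (482 aa) cross-checks against the
originally annotated 1404 nt frame as 3×(482−15+1).

## Synthetic data: what it emulates, what it does not

Fixtures are generated, never downloaded.  A cluster fixture starts from the
scaffolds, plants the architecture description's motif residues at anchor
columns, and substitutes a fraction (default 10%) of the remaining positions,
never touching an anchor or its 2-residue guard band, so ground truth stays
valid by construction.  The default rate emulates within-cluster divergence
of paralogous domains while staying far above the 20% identity floor.
NADPH-site deletions remove 12 of the 16 window columns.  Ground truth is
written separately from inputs so annotator tests run blind.

This emulation is deliberately easy in one respect: real domains diverge by
indels and long-branch substitution patterns, not uniform point substitution,
and real motif context can be degenerate.  Passing blind-recovery tests
therefore demonstrates the correctness of the rule engine and the alignment
anchoring, not field performance on arbitrary natural sequences.  A
degradation test raises the substitution rate and asserts the failure mode is
the explicit unalignable-domain error, never a silent wrong call; because
anchors and guard bands are preserved by the generator, alignment identity
can level off just above the floor at extreme rates, so the test also checks
a fully scrambled domain, which must always fail loudly.

Screening templates are seeded random sequences at 0.70 GC (actinomycete-like)
with primer sites planted exactly once (accidental duplicates are scrambled
away) and optional deletions between the sites.  Peak lists place one peak
per adduct at the computed m/z plus seeded Gaussian noise, with log-uniform
intensities.

## Problem sizes and determinism

The packaged canonical cluster is 32 genes / 15 modules / 60 called domains;
property suites run 100 random clusters (annotation recovery), 200 random
chains (formula conservation) and 20 noisy spectra (Δ-mass round trip) —
sizes chosen so the full suite completes in seconds while exercising every
vocabulary branch.  All generators take explicit seeds; identical inputs give
byte-identical outputs (hash-checked), and the CLI writes a config-hash
manifest so whole-pipeline reruns are comparable.

## Known limitations

* Trans-AT PKSs, NRPS condensation logic and profile-HMM domain detection in
  unsegmented proteins are out of scope; domains arrive pre-segmented via a
  module map or generator.
* The positional chain model does not place migrated double bonds, ring
  atoms, or R/S descriptors; SMILES output is stereochemistry-free.
* Tailoring is formula-level: mechanisms, kinetics and yields are not
  modelled, and production-level phenotypes (percent of wild type) are not
  predictable from sequence.
* Capability detection trusts product labels; it does not re-derive function
  from sequence for tailoring genes.
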