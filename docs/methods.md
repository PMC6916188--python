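# Methods

## Parsimony tallying of substitutions in genome triplets

The unit of inference is a codon-aware alignment of three sequences: two
closely related ingroup genomes and one outgroup. A codon column is
*resolved* when the outgroup codon is identical to at least one ingroup
codon; the shared state is the inferred ancestor of the two ingroups and
any difference in the other ingroup is a substitution on that terminal
branch. Columns where the outgroup matches neither ingroup, or where
both ingroups share a non-outgroup state (a change on the outgroup
lineage), are uninformative and excluded. Columns containing a gap or
ambiguity character in any sequence are skipped outright, as are columns
whose inferred ancestral codon is a stop.

Counting conventions:

* `b` — instances of a given ancestral→derived codon pair differing at
  exactly two positions; `a1`, `a2` — instances of its two intermediate
  single steps, the change at the 5′-most position listed first.
* `ANC` — ancestral-state opportunities. Every resolved column adds 2 to
  the ANC of its ancestral codon, one per ingroup lineage, because either
  branch could have produced an event; `count/ANC` is therefore a
  per-lineage frequency. (Counting per column instead of per branch
  would scale all frequencies by 2 and cancel from every ratio used
  here; per-branch was chosen so that `f(x)` is interpretable on its
  own.)
* Codons differing at all three positions are tallied for the dataset
  composition report only.

`DF = b/(a1+a2+b)` is undefined (reported as NaN) when no instances
exist. Combinations with a stop-codon *intermediate* carry the
`EXCLUDED_STOP` label and never enter the analysis; stop *endpoints* are
rejected as errors. The serine special case — both intermediates
non-synonymous yet the final codon synonymous, possible only between the
two disjoint serine codon series — gets its own `SER` label and stays
out of the main pipeline: no adjacent synonymous null with serine-like
base changes exists, so the matched-null contract cannot be honoured.

## Null models

The controls are pseudo-codons assembled from two adjacent real codons in
which both changes are synonymous by construction:

* `NM1_23` — constant second position of codon *i*; changes at the
  fourfold-degenerate third position of codon *i* and the twofold-
  degenerate first position of codon *ii*.
* `NM1_12` — the same change sites, the constant base taken from the
  second position of codon *ii*.
* `NM2` — changes at the fourfold third positions of codons *i* and
  *ii*; the first position of codon *ii* is the constant base between
  them.

Codon *i* must belong to a fourfold box (amino acids L, V, S, P, T, A,
R, G — note that one published description of this list prints Y, which
is twofold-degenerate; T is the eighth fourfold amino acid and is what
this package implements). For NM1, codon *ii* must encode leucine or
arginine — the only amino acids with a degenerate first position — and
carry a purine third position, without which the first-position change
cannot be synonymous. A window is scanned only when both its codon
columns are resolved and gap-free; windows never span gene boundaries.
On a given branch, a window contributes `b` when both null sites changed
synonymously, `a1`/`a2` when exactly one did, and nothing when a
non-synonymous change hit a null site or any other window position
changed on that branch. ANC counts every eligible resolved window, two
per window.

Null keys are `(configuration, ordered base changes, constant base)`.
Internally NM1 windows are grouped by the host-determined synonymous
target of the twofold site, so a key's ANC counts only windows where
that key's change pair is realisable — e.g. `C→T` at the twofold site is
a leucine-host key and arginine windows with first-position C must not
dilute its opportunity count.

Each codon combination maps to the null key with the same ordered
changes and the same unchanged context base, preserving adjacency:
changes at codon positions (2,3) → NM1_23, (1,2) → NM1_12, (1,3) → NM2.
Keys that no eligible window can generate under the code (checked by
exhaustive enumeration) are flagged unrealisable; such combinations have
no matched null and are excluded from per-combination testing. All 16
NS combinations are non-adjacent and map to realisable NM2 keys.

Intergenic alignments provide an additional, synonymy-free control: base
triplets are scanned as pseudo-codons in all three frames, and doubles
are stratified by adjacency of the changed positions so each codon class
can be compared to the matching stratum.

## Statistics

* **Per combination.** Fisher's exact test (two-sided) on
  `[[b_n, a1n+a2n], [b_s, a1s+a2s]]` against the matched null, corrected
  by Benjamini–Hochberg at α = 0.05 across the family of all pairs
  tested in one analysis invocation. Direction is read from the DF
  comparison; a pair with fewer than `min_total` (default 5) instances
  on either side is reported but called neutral with an insufficiency
  flag. The 5-instance default also gates which DF values enter the
  group distributions, since DF estimated from one or two instances is
  a 0/1 coin flip rather than a rate.
* **Group level.** Welch's t and the Wilcoxon rank-sum test between the
  per-combination DF values of a class and the per-key DF values of a
  null model, α = 0.01; both must agree for a group call.
* **Fast vs slow genes.** Genes are split at the median dN/dS; dN and
  dS are single-substitution events over Nei–Gojobori-style site counts
  on the resolved ancestral codons, without multiple-hit correction
  (the triplets are close). Ties go to slow; genes with dS = 0 are
  excluded. Per class, the per-combination DF values of the two gene
  sets are compared by paired t and Wilcoxon signed-rank tests over
  shared combination keys, α = 0.01.
* **Simultaneous double mutations.** Per null key,
  `DM = f(b) − f(a1)·f(a2)`; negative estimates are flagged as noise and
  excluded from per-key means. For the NS adjustment the pipeline uses
  the configuration-pooled estimator `(Σb − Σ a1·a2/ANC) / ΣANC` over
  NM2 keys instead: at realistic desk scales individual keys hold only a
  handful of doubles, the codon-to-null opportunity ratio is 3–10, and
  rectified per-key noise would routinely erase the codon's entire `b`.
  Pooling lets the noise cancel; the per-key form remains available.
  The estimator carries a small positive bias: the product of observed
  single frequencies conditions twice on the window being otherwise
  clean, so it understates the sequential double rate by roughly the
  per-window probability of a collateral change.
* **Adjusted DF.** `b′ = max(0, b − round(DM·ANC))`, defined only for
  NS and SS, whose doubles are synonymous end-to-end; a simultaneous
  double in an SN or NN combination is itself non-synonymous, so the
  synonymous DM estimate does not transfer and the call is refused.
  Adjusted NS DF is compared to the matched NM2 key DF by paired tests.
* **Neutral expectation for NS.** Under a neutral second step the
  expected codon double count is
  `b_exp = (a1n + a2n) · b_s/(a1s + a2s)` — the null's second-step rate
  scaled by the codon's observed single-substitution supply. In the
  extreme case of a lethal intermediate (`a2n = 0`, `a1n = a1s`) with a
  symmetric null (`a1s = a2s`) this reduces to
  `DF = (b_s/2)/(a1s + b_s/2)`, which is the closed form the general
  expression must reproduce.
* **DAS.** `DAS = S(o→f) − ½[S(o→i1) + S(o→i2)]` under a similarity or
  distance matrix; synonymous steps use the diagonal, so SS scores 0 and
  NS is non-negative under any similarity matrix with row-maximal
  diagonal. Regime groups are compared by rank-sum at α = 0.01, with the
  expected direction inverted for distance matrices. Two matrices ship
  with the package so everything runs offline: an identity similarity
  matrix and a synthetic two-property distance (Euclidean over z-scored
  Kyte–Doolittle hydropathy and residue molecular weight); AAindex flat
  files and 20×20 TSVs are accepted for external sweeps.

## The simulator

The generator emulates the study design rather than any particular
dataset: an ancestral genome of stop-free genes drawn from codon usage
weights (uniform by default) plus optional intergenic tracts, evolved
independently along an outgroup branch and two ingroup branches
(star topology; the ingroup branches are the "thick" branches on which
events are counted).

Mutations are sequential proposals, not a rate matrix, so simultaneous
doubles and state-dependent acceptance are exact by construction. Each
proposal is a single point mutation with probability 1 − δ or a
simultaneous change of two adjacent bases with probability δ (δ is the
defining parameter of the multi-nucleotide mutation process; non-adjacent
simultaneous events are not modelled, matching the adjacency rationale of
NM1). Base changes follow a κ-biased kernel (transition probability
κ/(κ+2)). Acceptance: intergenic and synonymous changes always fix;
changes creating a stop never fix; non-synonymous changes fix with the
gene's fitness weight `w_g`; a change restoring the ancestral amino acid
at a codon that currently differs always fixes.

**Reversion boost.** Per-proposal acceptance is capped at the synonymous
baseline of 1, and a process capped at neutral can never push the NS
second-step rate above its synonymous null — yet positive selection
means fixing *faster* than neutral. The boost therefore acts as directed
compensation: when a deleterious non-synonymous change fixes, with
probability `min(1, c·(1−w_g)/w_g)` (c = `reversion_prob`, default 0.05)
a kernel-weighted single-base change restoring the ancestral amino acid
fixes immediately on the same branch. The odds factor `(1−w_g)/w_g`
makes compensation intensity grow with the fitness deficit a gene
tolerates; because the supply of deleterious fixations scales as `w_g`,
the resulting NS double supply is nearly constant across gene classes
while the single-substitution denominators are not — which is what
separates NS DF between slow and fast genes, mirroring the observation
that NS double *frequencies* are similar where NS *DF* differs.

Defaults (the study conditions): 400 genes × 500 codons (2×10⁵ codons);
branch lengths 0.15 (outgroup) and 0.04 per ingroup, in expected
proposals per site, keeping ingroup divergence well below outgroup
divergence so parsimony stays reliable; κ = 2; δ = 0.05; two-point gene
fitness w = 0.5 (fast) / 0.1 (slow), half of genes each; reversion boost
on; intergenic tract totalling 10% of the coding length. Every accepted
event is logged (branch, position, bases, simultaneity, acceptance
reason), and replaying the log over the ancestor reproduces the tip
sequences exactly.

What the generator does **not** emulate: indels and alignment error,
recombination, demography, codon-usage selection, strand asymmetry,
context-dependent mutation beyond adjacency, and non-star topologies.
Passing tests therefore demonstrate correctness of the counting,
matching and testing machinery and the qualitative selection contrasts —
not calibration against any real genome collection, whose absolute
counts and per-combination significance depend on dataset size and
mutation spectra.

## Validation design and problem sizes

The suite validates the pipeline at three levels, with simulation sizes
chosen for statistical power:

* **Exactness.** The genetic-code census (16 NS, 8 SS, 8 NN with both
  intermediates synonymous to the final codon), the worked
  classification and null-matching examples, and the closed-form
  neutral-limit expectation are asserted exactly.
* **Oracle equivalence.** Tallies over 100 small simulated alignments
  are compared against a plain-Python column-by-column recount and
  against the simulation truth log on columns where the outgroup
  retains the true ancestral codon.
* **Statistical behaviour.** Type-I control uses 20 neutral replicates
  of 2×10⁵ codons (no selection, δ = 0): the fraction of non-neutral BH
  calls must sit within the α = 0.05 budget. Selection recovery uses
  3.2×10⁶ codons at uniform w = 0.2 with the boost on (group tests need
  hundreds of doubles per class), plus a 1.6×10⁶-codon two-point run
  for the paired fast/slow directions and the ≥90% fast/slow recovery
  check. DM recovery pools three replicates of 2.4×10⁶ codons at
  δ = 0.05 (≈2×10⁵ NM1 window opportunities each) and requires the
  pooled DM to match the truth-log rate of *visible* simultaneous
  doubles within 25%. "Visible" means the scan could have counted the
  event: the outgroup and the other ingroup still carry the ancestral
  window and the event branch carries exactly the event's two changes —
  the raw mutational census necessarily exceeds what any tip-based
  method can observe.

## Known limitations

* Parsimony misassigns ancestral states when the outgroup changes
  convergently; at the default branch lengths this is rare but not zero,
  and all frequencies are conditioned on resolved columns.
* The DM estimator's clean-window conditioning gives it a small positive
  bias (see above); at publication-scale counts this is negligible, at desk
  scale it is measurable and absorbed by the 25% recovery tolerance.
* Per-combination Fisher calls need dataset sizes far beyond desk-scale
  simulation to reject neutrality; group-level tests carry the signal
  at the scales used here.
* Only the standard genetic code (NCBI table 11 codon assignments) is
  supported; the table is pluggable but alternatives are untested.
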