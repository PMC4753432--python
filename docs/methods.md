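# Methods

This note documents the models, decision rules and numerical choices behind
`barcaudit`, and what its synthetic benchmarks do and do not demonstrate.

## Sequence vetting

Candidate barcodes are screened in three ways.

**Translation.** Sequences are translated under the invertebrate
mitochondrial genetic code (NCBI table 5). Only TAA and TAG are stops;
AGA/AGG encode serine. Codons containing ambiguity codes translate to X and
never count as stops, so a poor-quality read cannot masquerade as a
pseudogene. When the reading frame is unknown the frame with the fewest
stops is chosen, ties going to the lowest frame — for a genuine barcode
this recovers the amplicon frame; for a NUMT it is conservative (the
reported stop count is a lower bound). A mean amino-acid p-distance to a
consensus is exposed as a metric, deliberately without a pass/fail
threshold: "unusual amino-acid profile" is a judgement call we leave to the
curator.

**Compliance.** Defaults: minimum ungapped length 500 bp and ambiguity
fraction below 1%, mirroring the minimum standards barcode databases apply
to "barcode compliant" records; both are configurable. The ambiguity test
counts every non-ACGT IUPAC symbol, and the threshold is inclusive (1%
ambiguity fails).

**Indels.** Each record is globally aligned (affine gaps: match +1,
mismatch −1, open −5, extend −2; end gaps free so partial barcodes anchor
without penalty) and maximal gap runs are converted to events with 1-based
inclusive coordinates on the 658-site Folmer grid. An insertion between
reference positions p and p+1 of length L is reported as p+1..p+L in the
expanded frame, so a TTG insert after position 93 reads "94–96". Events
whose length is not a multiple of three raise a frameshift flag; 3k-bp
events pass QC, since frame-preserving length variants occur naturally in
some gastropod COI sequences.

Two choices here deserve emphasis. First, *indel placement is only sharply
defined against a close counterpart*: against a ~15% divergent reference, a
gap can slide to a score-equal position several sites away. The library
audit therefore locates each record's indels against the consensus of its
gap-free conspecifics when they exist (they share the Folmer grid, so
coordinates are unchanged), falling back to congeners and only then to the
global anchor. Second, *placement is left-normalized* (the leftmost
equivalent representation, as in VCF convention), making coordinates
deterministic in repetitive context. Alignment identity is measured over
the shorter sequence, not over aligned columns only — with free end gaps a
non-homologous query could otherwise "match" a tiny chance overlap; queries
under 50% identity are rejected as non-homologous.

## Distances

K2P distances use pairwise deletion: sites where either sequence has a gap
or ambiguity code are dropped for that pair only. Saturated pairs (the
logarithm's argument non-positive) are *undefined*, reported as NaN,
excluded from summaries with a warning, and treated as "beyond threshold"
in clustering — silently capping them would bias summary maxima, and two
specimens too diverged to measure are certainly not conspecific.

Rank summaries aggregate unordered pairs: within species; between
different species of one genus; between different genera of one family.
The mean is the simple mean over pairs and the quoted SE is the standard
error of that mean; values are in percent. Both the number of qualifying
pairs and the number with defined distances are recorded, since the two
can differ. Before species-level summaries the audit applies the standard
exclusions — open-nomenclature records (sp./cf./aff.), records without a
species-level name, and names supplied on an invalid-name list — which
otherwise contaminate intraspecific statistics. Species names are compared
as full strings, so subspecific trinomials form their own analysis units;
genus- and family-rank summaries group by the metadata columns as given.

## MOTU delimitation

Specimens are clustered as connected components of the graph joining pairs
with distance ≤ threshold (inclusive; default 2.2%). Single linkage is
transitive, so a chain of near-threshold pairs merges into one MOTU — a
property, not a bug: it is how threshold systems flag gradual variation.
MOTU ids are dense integers numbered by each cluster's first member in
input order, making labels deterministic. The full RESL algorithm refines
such clusters with Markov clustering; that refinement is not reproduced
here, and outputs are labelled "BIN-style", never "BIN".

## Concordance and review

Each MOTU is classified: singleton (one member), discordant (more than one
species-level name among members), else concordant. Open-nomenclature
members are carried but never counted toward discordance; instead, such
specimens can inherit their MOTU's name (`propagate_id`) when, after
review, exactly one accepted name remains among the other members and it
is genus-consistent. Discordant MOTUs are re-evaluated through a synonym
table (chains collapsed at load, cycles rejected): if all member names
resolve to one accepted name the MOTU is reclassified concordant, with the
triggering synonyms recorded; otherwise it is confirmed discordant. In
summary percentages singletons count as concordant by default (a
one-member MOTU cannot conflict with morphology); a switch reverses this,
since report conventions differ.

## Grading

Every morpho-species with own-project records receives one grade, decided
in the fixed precedence **E > C > A > B > D**:

* **E** if any own record shares a MOTU with a differently named
  (synonym-resolved) record, or if same-named external records exist but
  none co-cluster with ours;
* **C** if ≥3 own specimens occupy more than one MOTU;
* **A** if own records share a MOTU with same-named external records and
  every same-named record falls in that single MOTU;
* **B** if a single MOTU holds ≥3 own specimens and no external record of
  the species exists;
* **D** otherwise (1–2 specimens without an unambiguous external match,
  plus any residual ambiguous combination).

The precedence resolves combinations the grade definitions alone leave
open, and encodes two judgements: discordance is always fatal, and a
multi-MOTU species reads as possible genetic structure (C) even when some
external records match. Conversely, external concordance outranks sample
size: a species with 1–2 specimens that co-clusters cleanly with external
same-named records earns an A, because "insufficient data" (D) requires
that no matching sequence be available. The headline statistic — percent
of graded species scoring A or B — is carried at full precision; display
rounding (round-half-even, one decimal) is applied separately, because
published report roundings are not always internally consistent.

## Trees

Neighbor joining uses the standard Q-criterion agglomeration with ties
broken by the lowest index pair, so results are reproducible. Negative
branch lengths are clamped to zero with the deficit moved to the sister
edge (path lengths preserved); this can be disabled. The bootstrap
resamples alignment columns with replacement, rebuilds the K2P + NJ tree
per replicate, and scores each original bipartition by the percentage of
replicates containing it; replicates whose resampled matrix contains
undefined distances count as unsupportive. Bipartitions subtended by
(near-)zero-length internal edges are not counted as resolved — identical
sequences yield a star, not a fully supported arbitrary topology.

## Synthetic libraries

The generator emulates the structure a barcode audit assumes, with every
default set to a coastal-survey regime: 34 species, 1–10 specimens each,
658 bp, transition/transversion ratio κ = 2, intraspecific target 0.8%,
sister-species target 13.32%, cryptic splits in ~6% of species, ~1% of
records mislabeled, ~7% carrying a 3-bp indel, and roughly half the
records marked as external/published.

* **Species tree.** A pure-birth (Yule) topology is simulated forward.
  Node ages are then mapped onto substitution-space depths: sister-split
  depths are centred on half the interspecific target and deeper nodes
  grow only as the square root of relative age, with a floor at a quarter
  of the sister path. The compression is deliberate: real COI divergences
  flatten with depth (confamilial means sit near congeneric ones), a naive
  clock-scaled Yule tree would push deep pairs into saturation where the
  K2P correction diverges, and the floor keeps every between-species
  distance well above the clustering threshold so the simulated barcode
  gap is real.
* **Sequences.** Evolution follows the K2P substitution process using
  exact transition probabilities (matrix exponential of the rate matrix,
  cached per branch length) — matching the distance model being estimated,
  which is what makes parameter-recovery tests meaningful. A coding
  constraint resamples would-be stop codons (falling back to the parent
  codon), so clean simulated barcodes pass the translation screen. This
  slightly depresses realized divergence (~5–10% relative), visible in the
  calibration tests and well inside their tolerances.
* **Within species.** Star genealogies: each specimen hangs from its
  species (or cryptic-lineage) ancestor by half the intraspecific target,
  so expected within-species pairwise divergence equals the target. A full
  coalescent would add realism (shared polymorphism, skewed pair
  distances) but is unnecessary for controlling the quantities audited.
* **Complications.** Cryptic splits duplicate a species into two lineages
  separated by ~3x the clustering threshold, guaranteeing an observable
  split. Mislabels swap the full taxonomic label between records of
  different species. Indels insert or delete 3 bp at uniform positions,
  re-drawn until the result is stop-free; truth coordinates are
  left-normalized by brute-force search (independent of the detector's
  shift rule). Taxonomy is cut from the species tree at depths giving
  realistic genus:species and family:species ratios (21:34 and 16:34).

What passing the synthetic benchmarks shows: the pipeline's operations are
internally correct (distances match closed forms, clustering matches
brute-force components, NJ recovers additive trees, grades fire per their
definitions) and the audit recovers *known* structure under survey-like
divergences. What it does not show: robustness to heterotachy, selection,
heteroplasmy, alignment error in length-variable regions beyond simple
3-bp indels, or the messiness of real metadata — on real libraries the
review stages remain genuinely expert-in-the-loop.

## Problem sizes

Default test and acceptance runs use libraries of ~30–180 records
(simulation plus full audit takes seconds), 20-seed replicates for
stochastic properties, and 100+ injected indels for recovery rates; these
sizes give stable statistics while keeping the full suite fast.

## Known limitations

* Single-linkage at a fixed threshold is only a proxy for RESL/BIN
  assignment; concordance counts on real libraries will differ where the
  refinement stage would have re-cut clusters.
* The grading precedence is one defensible total ordering of rules that
  published descriptions leave partially ordered; alternatives (e.g. C
  outranking E) are arguable and would change counts on conflict-rich
  libraries.
* K2P with pairwise deletion is the field's convention, not the best
  available distance; saturated pairs are reported as undefined rather
  than modelled.
* The reference-match operation is a local identity search over a shared
  anchor alignment, a reproducible stand-in for online similarity
  services; it has no e-value model.
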