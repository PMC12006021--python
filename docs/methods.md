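# Methods

## Alignment model

Pairwise protein alignment uses a substitution matrix (BLOSUM62 by
default) with affine gap penalties: a gap of length L costs
`open + extend·(L−1)`, defaults open 11, extend 1. Both a global
(Needleman–Wunsch, terminal gaps penalized) and a local
(Smith–Waterman) optimum are computed by a three-state Gotoh dynamic
program with full backpointers. Tracebacks are deterministic under the
fixed tie order diagonal > up > left (match preferred over a gap in the
subject, preferred over a gap in the query); in local mode the
traceback stops at the first zero-valued cell, the Smith–Waterman
convention. `X` is treated as uninformative: it scores 0 against every
residue and never counts as identical.

Percent identity is `100 · identical columns / alignment columns`. In
global mode the denominator includes every column, internal and
terminal gaps alike; in local mode it is the local alignment length
(the BLAST `pident` convention). Both conventions are exposed through
`identity_mode`, defaulting to global.

Local scores carry a Karlin–Altschul expectation
`E = K·m·n·e^(−λS)` with the unaligned sequence lengths m, n and the
standard gapped BLOSUM62/11/1 parameters λ = 0.267, K = 0.041. The
parameters are part of the scoring scheme and are not re-estimated.

No heuristic seeding is used: at the problem sizes this package
targets, exact dynamic programming is affordable, and exactness is what
makes the enumeration-oracle tests meaningful. The bulk screening path
uses score-only kernels (JIT-compiled, linear memory) that the test
suite checks against the full traceback aligners.

## Screening

The screen is two-stage. A local alignment provides candidate discovery
with an E-value cutoff (default 1e-6); survivors are re-aligned
globally and called as off-target hits when identity exceeds the
similarity threshold **strictly** (default 30). All qualifying pairs
are kept, not best-hit-only: gene-level tallies count per protein,
while species-level summaries deduplicate downstream. "Identical"
requires 100% identity over the full length of both sequences. Function
concordance considers only hits strictly above the function threshold
(default 50) and flags exact annotation string equality; mappings onto
"hypothetical protein" are retained as discordant pairs rather than
dropped, since such mappings are themselves informative.

## Taxonomic aggregation

Lineages use GTDB-style rank prefixes (`d__;p__;...;s__`); absent ranks
may be omitted. Species are compared after normalization: lower-case,
collapsed whitespace, truncation to the binomial (strain suffixes
stripped). Hits from MAGs without a species rank are excluded from the
Venn overlap but tallied separately as "NA" (counted as unique MAGs,
since they have no species name to deduplicate on). GTDB/NCBI phylum
synonyms (Firmicutes/Bacillota, Actinobacteriota/Actinomycetota, ...)
are **not** merged by default; an explicit synonym map can be enabled,
because silently merging nomenclatures would hide which catalogue
dialect the data carried. Pathogenicity is a strict partition: in the
catalog → pathogenic, absent → non-pathogenic, no species rank → NA.

## Clinical comparison

"Normalized prevalence" of a symptom in a drug group is the fraction of
the group's drugs reporting it — the minimal definition that makes a
percent change well-posed; no prescription- or frequency-weighting is
applied. A drug linked to at least one affecting target counts in the
affecting group only (ANY rule, recorded in the output metadata).
Percent change is `100·(p_aff − p_non)/p_non`, computed with integer
arithmetic and a single final division so that boundary cases (a change
of exactly +10.0%) are exactly representable and the strict `> 10%`
filter behaves as stated. No multiple-testing correction is applied —
the screen is descriptive — but a seeded permutation null
(`permutation_null`, label shuffling) is available for calibration.

## Structural comparison

Contacts are protein/ligand heavy-atom pairs within a distance cutoff
(default 10.5 Å), classified into the 10 unordered element-pair classes
over {C, N, O, X}; hydrogens are excluded, and waters are dropped at
parse time. The affinity model is purely linear in the 10 counts.  The
shipped default weight set (`contacts_default`: small negative
kcal/mol-per-contact weights, polar pairs weighted above apolar,
intercept 0) is a synthetic package default intended as a placeholder;
fitted coefficients should be supplied via a key-value model file,
which the pipeline accepts through `affinity_model`. Binding-pocket
residues are those with any heavy atom within 5 Å of a ligand heavy
atom. Pocket projection aligns the reference chain sequence globally to
a homolog and classifies each pocket residue as identical, substituted,
or deleted; comparison-sequence residues inserted strictly between
pocket columns count as in-pocket insertions. Projections are refused
below 15% overall alignment identity, where column correspondence is no
longer meaningful. Homology modelling and docking are out of scope: the
module consumes already-posed complexes.

## Synthetic data

The generator emulates every input the pipeline reads, with planted
structure recorded in a truth file:

- **Background sequences** are i.i.d. draws from the Robinson–Robinson
  amino-acid frequencies — the null model underlying BLOSUM62 — at
  lengths 150–250. They carry no similarity to targets above chance;
  an empirical test confirms no background hit passes the screen in
  ≥ 99/100 seeds.
- **Planted homologs** are substitution-only: exactly
  `round((1−t/100)·L)` positions are substituted to uniformly drawn
  different residues. Because a score-optimal affine-gap alignment of a
  heavily mutated pair can trade gap cost for extra matches and drift
  above the planted identity, draws are resampled (deterministically
  under the seed) until the gapless alignment is score-optimal — a
  cheap check (gapless score equals the DP optimum) that pins the
  measured identity exactly to the planted value. An indel mode exists
  for stress-testing, whose truth records the realized rather than
  nominal identity.
- **Lineages** realize a specified three-set species Venn structure
  exactly: one homolog is planted per planted species, so the screen's
  species sets equal the planted sets. Exact copies of pathogen targets
  (two per biome by default) plant the identical-match counts, and one
  plant per biome sits on a genus-only lineage to exercise the NA path.
  Homologs are planted only on a leading fraction (60%) of targets so a
  non-affecting group always remains.
- **Side effects** are independent Bernoulli draws per drug and
  symptom, with group-specific prevalences. The default panel plants
  one strong enrichment (0.6 vs 0.2, expected +200% change), moderate
  enrichments, null symptoms, reverse enrichments, and one-sided
  (unique) symptoms, each with a MedDRA-style system-organ-class label.
- **Complexes** use toy residue geometry (backbone plus one sidechain
  atom): pocket residues on a ~4 Å shell around the ligand, all others
  far outside the contact cutoff. A separate constructor realizes an
  exact requested contact profile by placing one spatial station per
  contact class. The default bundle also writes a comparison sequence
  carrying a known pocket edit script (2 substitutions + 1 in-pocket
  insertion).

What the generator does *not* emulate: phylogenetic correlation among
background sequences, realistic domain architecture, annotation noise,
real MedDRA hierarchies, or physical protein geometry. Passing tests
therefore demonstrate that the statistics and thresholds are computed
correctly and recover planted signal under the stated noise models —
not that any particular real-world catalogue would yield particular
counts, which depend on database snapshots.

## Default scales and determinism

Defaults are sized for fast, repeatable runs: 20 targets of length 200,
200 metaproteome proteins per biome (600 total, 12,000 screened pairs),
100 drugs per group, and one 40-residue complex. Every random choice
routes through a single seed; regenerating a dataset from the same seed
is byte-identical, and rerunning the pipeline on identical inputs and
config reproduces identical output bytes (the manifest records the
config hash and input checksums; each table embeds the config hash in a
header comment).

## Known limitations

- Karlin–Altschul parameters are fixed per scheme, not estimated; with
  a user-supplied matrix the E-values are only as good as the supplied
  λ and K.
- The affinity weights are placeholders (above); predicted ΔG values
  are comparative, not calibrated, until a fitted model file is
  supplied.
- Pocket projection assumes the alignment's column correspondence is
  meaningful; between remote homologs (identity just above the 15%
  floor) substitution/insertion calls should be treated as qualitative.
- The clinical screen is descriptive: percent changes carry binomial
  noise of order `1/√n` per group and no significance adjustment.
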