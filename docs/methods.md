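# Methods

## The model

`coibayes` assigns a query DNA sequence to the reference taxon (genus or
family, the *trained rank*) that maximizes a naive Bayes score over the
query's k-mer words. Training counts, for every word *w* of length *k* and
every taxon *G*: *n(w)*, the number of reference sequences containing *w*
at least once; *N*, the total number of reference sequences; *M(G)*, the
sequences in *G*; and *m(w, G)*, the sequences in *G* containing *w*.
Scoring uses

- word prior: π(w) = (n(w) + 0.5) / (N + 1)
- conditional: P(w | G) = (m(w, G) + π(w)) / (M(G) + 1)
- score(G) = Σ_w log P(w | G) over the query's *deduplicated* word set.

The naive assumption is word independence; the prior π(w) doubles as a
smoothing floor, so unseen words contribute a finite penalty rather than
−∞. Counting containment per sequence (not occurrences) keeps
m(w, G) ≤ M(G), which the conditional requires to stay below 1.

Two modelling choices here were genuinely open and are worth stating:

- **Deduplicated words for scoring, multiset for the bootstrap.** Scoring
  on the word *set* prevents long homopolymer or repeat tracts from
  dominating the posterior; resampling from the word *multiset* keeps the
  bootstrap's notion of "the query's data" faithful to the read, so
  repeat-rich queries are not artificially confident.
- **Orientation.** Barcode reads arrive on either strand. Both orientations
  are scored and the better one used (`check_reverse_complement=True` by
  default); ties keep the given orientation.
- **Argmax ties** break lexicographically by taxon name and are logged.
  Exact ties occur with identical sequences shared across taxa and in tiny
  toy models; on realistic references they are vanishingly rare.

## Bootstrap confidence

Each of `n_bootstrap` (default 100) trials draws ⌈|words| / 8⌉ words
uniformly with replacement from the chosen orientation's word multiset and
re-runs the argmax. The support of taxon *x* at rank *r* is
100 × (trials whose winning taxon's lineage passes through *x*) /
`n_bootstrap`, reported as an integer. Because trials are counted through
lineages, support is non-decreasing from the trained rank toward the root
— the formal basis for rank summarization: `summarize_to_rank` reports the
taxon at a rank only when its support clears a cutoff, else
"unclassified". The resample fraction (1/8) is exposed as
`bootstrap_fraction`.

## Reference curation

`build_training_set` screens candidates with rules applied in a fixed
order — minimum length (default 500 nt), no N, no other ambiguity code, a
fully identified species name (tokens `sp.`, `nr.`, `aff.`, `cf.` mark
insufficient names; enforced for genus-trained sets, waived for
family-trained sets), and a named taxon at the trained rank — so a record
gets exactly one reject reason and reports are deterministic. Name-term
matching is token equality, not substring search, so a genus called
"Crispa" is not rejected by "sp.". Duplicate sequences for the same taxon
are retained unconditionally: they carry real information about
within-species variation, though they inflate leave-one-out accuracy (a
held-out duplicate still has an exact twin in the reference).

Missing intermediate ranks are filled with explicit placeholders named
`undef_<parentName>` (nesting when consecutive ranks are missing); a
placeholder *at the trained rank* means the record cannot be trained and is
rejected. Taxonomies are serialized as `taxid*name*parent*depth*rank`
lines with deterministic taxids (preorder, children in lexicographic
order), making training files diffable and the write→read round trip
byte-identical.

## Validation machinery

**LOOCV** removes each sequence's counts from the model (an exact
decremental update, verified bit-identical to a full retrain), classifies
it, and restores the counts. A taxon emptied by the removal is excluded
from the candidates for that query — which is why *singletons* (taxa with
one sequence) can never be correct at the trained rank under LOOCV;
accuracy and cutoff summaries therefore exclude singleton queries by
default, while error tables include them. Both are parameters.
Fragment-length testing classifies a single contiguous window (50, 100,
200 or 400 nt) at a uniformly random start per query.

**Error accounting** at a support cutoff *c* partitions queries at each
rank into type I (wrong, support ≥ *c*), type II (correct, support < *c*),
correct-retained and wrong-withheld, all as percentages of all queries, so
the four always sum to 100. **Cutoff calibration** scans the grid
{0, 5, …, 100} for the smallest cutoff whose retained accuracy reaches a
target (default 99%) with at least one query retained; no qualifying value
yields N/A, which conflates "never accurate enough" with "nothing left
retained" — both mean the cutoff cannot deliver the target at that length.
**Match tables** compare assignments to independent (e.g. morphological)
labels as match / nonmatch / not-classified. **Coverage summaries** divide
represented by described taxon counts per order, rounding percentages
half-up; the Total row is the ratio of column sums (described sums over
orders with estimates only; represented sums over all orders) and the
Average row is the mean of per-order percentages over orders with
estimates. A bundled TSV carries literature counts of described insect
families and genera per order for this purpose.

## Synthetic data

The generator emulates a curated barcode reference at desk scale: a root
ancestor drawn uniformly over {A,C,G,T} evolves down the taxonomy
(order → family → genus → species ancestors → leaf sequences) by
independent per-site substitution to a uniformly chosen different base — a
Jukes–Cantor-like model with no indels, adequate for an alignment-free
k-mer classifier whose curation rules exclude gapped and ambiguous
sequences anyway. Defaults: 5 orders × 2 families × 3 genera × 3 species ×
2 sequences (180 sequences), 650 nt (full-length COI scale), 12%
inter-genus, 2% intra-genus and 0.5% intra-species per-site divergence;
order- and family-level branches default to the inter-genus rate. These
sizes keep every simulation in the test suite and the acceptance script in
the seconds-to-a-minute range while leaving each genus multiply
represented.

Queries are fresh draws from species ancestors (never copies of training
sequences). Novel taxa are simulated as *extra* withheld orders rather
than by deleting reference taxa, so reference and query sets are
independently sized and a novel query is unrepresented at every rank below
class — the clean version of the field situation where a whole group is
missing from public databases.

What the generator does *not* emulate: codon structure and selection,
transition/transversion bias, indels and alignment artifacts, sequencing
error profiles, geographically structured sampling, and the extreme
imbalance of real databases (a handful of mega-genera, one-third
singletons). Passing tests on synthetic data therefore demonstrate the
correctness of the machinery and the qualitative behaviours (accuracy
rises with fragment length and falls with database incompleteness; cutoffs
trade retention for error), not the absolute accuracy figures achievable
on real COI references.

## Numerical and reproducibility choices

- All randomness flows from integer seeds through numpy `SeedSequence`
  spawning (one child per query), so runs are reproducible bit-for-bit and
  per-query results do not depend on batch composition.
- Scores are computed in log space as float64 column sums; the test suite
  cross-checks the argmax against an exact rational-arithmetic enumeration
  on small models (agreement up to exact ties, which floats cannot
  distinguish and which break lexicographically).
- Report percentages are rounded half-up to integers; raw values are kept
  internally.
- Degenerate inputs: a query shorter than *k* is an error; windows
  containing non-ACGT characters are dropped (and counted); a query whose
  words are all dropped scores 0 for every taxon and falls to the
  lexicographic tie-break; an empty training set is an error.

## Known limitations

- Species-rank assignment is out of scope; training stops at genus or
  family.
- The classifier assumes the true taxon is present in the reference; it is
  not a novelty detector. The novel-taxon machinery quantifies the damage
  (nonmatches) and the mitigation (cutoffs convert nonmatches to
  not-classified; they can never create matches), but flagging novelty is
  the user's responsibility.
- Word size 8 with presence/absence counting saturates for very long
  sequences (> a few kb), where most of the 65 536 words are present in
  every sequence; the method is tuned for barcode-length inputs.
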