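# Methods

## Data model

A survey is a long-format table of citation records, one row per
(interview, taxon, use-category).  Within an interview the taxa form a free
list: distinct taxa hold distinct, contiguous ranks 1..L reflecting the order
of spontaneous mention, and a taxon's rank is repeated on each of its
use-category rows.  Use categories are the seven non-exclusive modalities
E (food/drink), A (alcoholic beverages), M (medicinal), T (tool),
C (ceremonial), AF (animal feed) and O (other).  Validation enforces rank
contiguity, uniqueness of (interview, taxon, category) triples, a single area
per interview, and a controlled vocabulary for the plant part.

The **interview is the counting unit** everywhere: N is the number of
interviews in scope, not of individual informants.  Surveys occasionally
interview two people at once; treating the interview as the unit keeps every
denominator well defined and matches how per-questionnaire means are usually
reported.  Taxon identity is the canonicalized scientific-name string
(whitespace collapsed, genus capitalized); no synonym resolution is
attempted, since survey names are assumed pre-standardized.

## Filtering

Quantitative tables include only taxa cited by ≥ 2 interviews (configurable).
FC for the filter is computed on the pooled data; per-area tables are then
derived from the filtered set, so a taxon kept by a pooled count of 2 split
across areas appears in both area inventories.  Two properties of the filter
matter numerically:

* the interview roster is preserved, so N does not shrink if an interview
  loses all its records — RFC denominators refer to the survey as conducted;
* ranks are **not** renumbered and each interview's original list length L is
  carried along, so Smith's S computed after filtering equals S computed on
  the full data restricted to the surviving taxa.  The alternative reading —
  renumber the surviving ranks so L reflects the filtered list — is available
  via `renumber_ranks` / the `--filter-before-salience` CLI flag.

## Indices

Definitions are as in the README.  Implementation notes:

* Mentions are counted at the interview level: one interview citing a taxon
  under three categories contributes FC = 1 and UR = 3.  This keeps FC, UR
  and Fic mutually consistent (FC ≤ UR ≤ 7·FC).
* Smith's S uses each interview's own list length L_i; a single survey-wide
  L would make the rank weight meaningless across lists of very different
  length.  S ≤ RFC always, with equality only if every citing list opens
  with the taxon.
* CV's third factor Σ_u IUc_u/N equals UR/N, so CV = (uses/7)(FC/N)(UR/N);
  the saturation bound CV = 7 is reached when every interview reports the
  taxon in all seven categories.
* Fic is reported as NaN when a category has fewer than two use reports
  (the formula divides by n_ur − 1); such categories are excluded from
  summaries rather than forced to 0.
* Ranked tables sort by the index descending with an alphabetical tie-break,
  and display-round RFC to 2 decimals and S/CV to 3 (full precision is kept
  in all machine-readable outputs).

## Cross-area comparison

The Jaccard index is set-based: A and B are per-area taxon counts, C the
shared count, JI = 100·C/(A+B−C).  The top-k variant restricts both presence
sets to the k taxa with highest pooled FC (alphabetical tie-break); fractions
map to k by rounding half up, so 50% of 157 taxa is k = 79 and 20% is k = 31.
Per-use-category similarity defaults to the taxon-set form (taxa carrying the
category in each area).  An alternative "frequency" mode replaces counts of
taxa with counts of use reports, with the shared term Σ_taxon
min(reports_A, reports_B) — a multiset Jaccard that reduces to the set form
on 0/1 counts.  Group means (taxa per interview, distinct use categories per
taxon) are compared with Student's equal-variance two-sample t-test by
default; Welch's correction is a flag.  p-values print to 4 decimals, with
values below 0.001 rendered "p < 0.001".

## Synthetic survey generator

The generator emulates a two-municipality wild-plant survey and is the
test-bed for the whole pipeline.  Defaults describe the target design:

| parameter | default | meaning |
| --- | --- | --- |
| n_interviews_per_area | 30 | two balanced areas, 60 interviews |
| pool_size | 199 | taxa that exist regionally |
| shared_fraction | 0.70 | pool fraction known in both areas |
| list_length_means | (28.63, 21.67) | per-area free-list means |
| list_length_dispersion | 6.4 | negative-binomial r; SD ≈ 11 |
| list_length_range | (10, 76) | hard clip on drawn lengths |
| citation_skew | 1.0 | Zipf exponent of taxon popularity |
| area_bias_sigma | 0.5 | lognormal per-taxon area preference |
| category_probs | E .80, M .35, A .25, O .15, AF .10, T .05, C .03 | per-category inclusion given citation |

List lengths are negative binomial (variance m + m²/r); r = 6.4 gives a
between-interview SD near 11, back-derived from the reported t statistic of
the area contrast at n = 30 per group.  Clipping to [10, 76] raises the
realized means slightly (≈ +0.5–1 taxon, more for the shorter-listed area);
tests therefore compare realized lengths against a direct simulation of the
same clipped distribution rather than the nominal mean.  Each interview
samples its taxa without replacement with probability ∝ Zipf weight × area
bias, ranks them in draw order, then draws categories independently per
(interview, taxon) with E forced when none is drawn — so the E marginal
exceeds 0.80 by the no-category probability (≈ 0.07).  All randomness
descends from one `SeedSequence`; per-interview substreams are spawned
deterministically, making datasets byte-reproducible.

What the generator does **not** emulate: category assignment is independent
per interview, so a frequently cited taxon accumulates many distinct
categories across the survey (uses-per-taxon ≈ 3.5 at the default design,
versus ≈ 1.5 in field data where a taxon's uses are a stable cultural
property); taxon popularity is a smooth Zipf law with no covariance between
popularity and use profile; and informant-level heterogeneity (age, sex,
expertise) is absent.  Passing tests on synthetic data therefore demonstrate
correctness of the arithmetic and the statistical behaviour of the design,
not ecological realism of any particular index value.

Realized inventory overlap at the default design is JI ≈ 62%, below the
nominal shared fraction: with 30 interviews per area, tail taxa passing the
pooled FC ≥ 2 filter are often observed on one side only.  JI approaches
100% under a fully shared pool only as the interview count grows — the
parameter-recovery tests compare the generator against an independent
set-level simulation of the same design rather than against the nominal
fraction.

## Benchmark fixture

`benchmark_fixture()` assigns presence sets constructively — 109 shared,
38 + 10 area-private taxa with ≥ 2 citations (placed to make every pooled
count ≥ 2), and 42 singletons that the filter removes — then simulates
citation order and categories consistent with them.  This gives exact
filtered counts 147/119/109 (union 157, JI = 69.43%) without rejection
sampling, and the fixture is fully deterministic.

## Numerical and degenerate-input choices

* Empty scope or an unknown area label raises immediately rather than
  returning empty tables silently; an entirely empty dataset round-trips
  through CSV as a header-only file.
* Jaccard of two empty collections is an error, not 0.
* The t-test reports p = NaN for two degenerate constant groups of n = 2,
  and t = 0, p = 1 for identical groups.
* Tie-breaks (ranking, top-k selection) are alphabetical, making every
  output deterministic for a fixed input.

## Problem sizes

The default analyses run at the design scale (60 interviews, 199-taxon
pool).  Distributional checks use 200 seeds for parameter recovery, 300
simulated surveys against a 2000-replicate Monte-Carlo power oracle for the
t-test, 500 interviews per area for category marginals, and 12 seeds ×
150 interviews/area for the full-overlap limit — sizes chosen to hold
Monte-Carlo error well below the tolerances they are tested against.
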