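# Methods

## Scope and data model

`pgxbeacon` is a client-side toolkit for GA4GH Beacon v2 resources in the
style of the Progenetix ecosystem. A beacon organizes data into four
cross-referenced entities — individuals, biosamples, analyses, and genomic
variations — served over REST under `https://{domain}/{entry_point}/…` and
constrained by CURIE ontology filters (e.g. `NCIT:C3512` for lung
adenocarcinoma). The toolkit covers the full workflow: discovering filtering
terms, querying one or many beacons, flattening the nested JSON responses
into tables, reading/writing CNV segment files, and computing cohort CNV and
survival statistics.

## Query semantics

Queries are plain GET requests; multiple filters are comma-joined into one
`filters` parameter, which Beacon v2 servers combine with AND logic. Count
queries target the counted entity's endpoint with
`requestedGranularity=count`. Response granularity (boolean / count / record)
is preserved in the envelope rather than coerced: a boolean answer is
reported as `total_count ∈ {0, 1}` with `granularity="boolean"`.

Filtering-term keyword search uses case-insensitive substring matching over
both term id and label, OR-combined across patterns. This is a deliberate,
documented choice: the pattern `male` therefore matches the label `Female`.

Federation uses a thread pool (workers share no mutable state; results are
collected in domain order), so the merged table is invariant to the worker
count. Any per-domain failure — HTTP error, malformed JSON, timeout — is
captured in that domain's envelope; the federation path never raises.
Identical records returned by two domains are both kept, distinguished by the
`domain` provenance column; deduplication across resources is intentionally
not attempted. Transport defaults: 30 s timeout, 2 retries with exponential
backoff (0.5 s base), all tunable via `TransportPolicy`.

## JSON flattening

The mapping dialect is a tiny, auditable subset of JSONPath: dot-separated
keys with a `[]` marker for lists (`externalReferences[].id`). Resolution is
total — missing keys at any depth yield null, never an error. Four
cardinalities govern list handling: `scalar`, `first`, `join` (default
delimiter `;`, the common convention in tabular bioinformatics exports), and
`explode` (one output row per list element; at most one explode column per
config so row multiplication is unambiguous; an empty list still yields one
null row). Values keep their native JSON scalar types until file export,
where nulls become empty strings. Harmonization across domains takes the
ordered first-seen union of columns with null fill, and is idempotent.

The shipped per-entity configs are best-effort reconstructions of the column
sets a Progenetix-style beacon populates; they are data files and can be
replaced wholesale for beacons with different models.

## Segment formats and coordinates

All in-memory coordinates are interbase (0-based half-open), the convention
Beacon v2 itself uses for variant positions. `.seg` files (the circular
binary segmentation output dialect) are 1-based inclusive and are shifted on
read and re-shifted on export. `.pgxseg` files are read without shifting.
Header spellings vary across real exports, so the parser accepts
`biosample_id`/`sample_id`/`sample` for the sample column and
`log2`/`value`/`seg.mean` for the ratio column. Metadata lines follow
`#key=value;key=value` with a mandatory sample identifier; `#` lines without
one are preserved verbatim as file-level comments. Written files are
canonical — fixed header, segments sorted by (sample, chromosome 1–22/X/Y,
start) — so read∘write is the identity on canonical files, field-exact.

## CNV statistics

Segments are classified into a 3-state model (gain / loss / neutral).
An explicit recognized state label (including the EFO copy-number terms
`EFO:0030070`/`EFO:0030067` and their low/high-level children) wins over
thresholds; otherwise log2 ≥ +0.15 → gain and log2 ≤ −0.15 → loss. The
±0.15 thresholds are a widely used array-CNV convention, not a derived
quantity; both are parameters. High-level amplifications and homozygous
deletions are not distinguished from ordinary gains/losses.

The genome is tiled into fixed bins (default 1 Mb, Progenetix-style) that
exactly partition each chromosome; the last bin per chromosome may be short.
For each bin and state, cohort frequency is

    percent = 100 · #{samples with ≥1 overlapping segment of that state} / n_samples

with overlap of at least `min_overlap` bases (default 1 — any overlap
counts, the simplest rule consistent with per-base counting). A sample
counts at most once per bin per state, but a sample carrying both a gain and
a loss in one bin counts toward both frequencies. The denominator is the
full sample roster (metadata roster of a `.pgxseg` file, or an explicit
`samples=` argument), so CNV-free samples dilute frequencies. Consequently
every reported percentage is an integer multiple of 100/n_samples.

Per-sample CNV fractions merge overlapping same-state intervals before
summation (fractions are invariant to splitting segments) and divide by the
total genome length from the chromosome-length table (bundled hg38 sizes by
default; any assembly's table can be supplied).

Frequency plots mirror gains upward and losses downward on a ±100% axis;
the exact plotted coordinates are returned as a table so rendering is
testable without pixel comparison.

## Survival analysis

The Kaplan–Meier estimator is computed from its definition
S(t) = Π_{t_i ≤ t} (1 − d_i/n_i) over distinct event times, with the
standard tie convention: subjects censored at t remain in the risk set of an
event at t. Confidence intervals use the Greenwood variance with the
log(−log S) transform; they appear in plots but are omitted from tables by
default. The k-group log-rank test accumulates observed minus expected
events (expectation proportional to risk-set share) with the hypergeometric
variance–covariance; the statistic is (O−E)ᵀV⁻¹(O−E) over the first k−1
groups, referred to χ²(k−1). A singular variance matrix falls back to the
pseudoinverse. Time units are the caller's responsibility; no calendar
parsing is attempted.

`build_survival_records` bridges flattened individual tables to survival
input, mapping status text to the event indicator through a configurable
vocabulary (default: dead/deceased → event, alive/censored → censored) and
dropping — with a reported count — rows with null or unmappable fields.
Groups come from a metadata column, a numeric threshold on one, or a
callable.

## The synthetic cohort generator

The mock module exists so every other module is testable offline; its
defaults define the conditions under which the toolkit's guarantees are
verified.

* Entities mirror the Beacon v2 default-model field names at the depth the
  shipped mapping configs need, with full referential integrity (one
  biosample and analysis per individual; variants reference both).
* Each individual draws a sex term (50/50) and carries each configured CURIE
  independently with its stated probability; carried terms are stored as
  disease codes on the document, so server-side filter matching is purely
  structural and every response is reproducible by direct computation on the
  dataset.
* CNVs are drawn bin-wise on a toy genome of five 5 Mb chromosomes (25 bins
  at the default 1 Mb binning — large enough for cohort statistics, small
  enough that a literal per-base oracle is cheap). One uniform draw per
  (sample, bin) assigns gain with probability 0.30, else loss with
  probability 0.15, so the per-bin gain indicator is exactly
  Bernoulli(0.30); maximal same-state runs are merged into segments with a
  single log2 value (N(±0.5, 0.1)). These rates are deliberately high for a
  real tumor cohort; they give informative bin counts at n = 20.
* Survival times are exponential with a per-sex hazard (default 0.002/day
  for both sexes, i.e. no group effect unless configured) under independent
  exponential censoring (0.001/day).

What the generator does **not** emulate: realistic genome-wide CNV
landscapes (focal vs broad events, recurrent driver loci, wave artifacts),
inter-sample heterogeneity in CNV burden, non-exponential survival, ontology
hierarchies (a filter matches only its exact CURIE), and access-controlled
beacons beyond the granularity tag. Passing tests therefore demonstrate
protocol and algorithmic correctness, not performance on real tumor data.

A single `numpy.random.Generator` seeded from the spec drives everything:
identical specs give byte-identical fixture exports.

The mock server answers every request by recomputing the match on the
in-memory documents (no caching), honours limit/skip paging and count
granularity, and can inject deterministic faults (HTTP 500, malformed JSON,
or a stall) for the first n requests or all requests, which makes retry
logic testable without flakiness.

## Verification strategy and problem sizes

* CNV frequencies are checked for exact equality against a brute-force
  per-base counter (boolean occupancy arrays over every base) on 10 seeded
  cohorts of 20 samples × 5 chromosomes, and the recovered mean gain
  frequency must sit inside the 99% binomial interval around the generating
  30% for each of 10 seeds.
* Kaplan–Meier output is checked against hand-computed product-limit values
  on a 4-record example and against lifelines (an independent
  implementation) to 1e-9 on seeded random datasets; the log-rank statistic
  matches lifelines' multivariate test to 1e-6.
* Log-rank calibration: 500 replicates of a 2×50 equal-hazard exponential
  design must reject at α = 0.05 between 3% and 7% of the time.
* Segment round-trips are field-exact on empty, toy, and 1000-segment
  seeded files; a second write reproduces the file byte for byte.
* Beacon semantics (AND monotonicity, count/record consistency, OR term
  matching), federation worker-invariance, and partial-failure isolation are
  all verified against direct set computation on the generated dataset.

These sizes keep the whole suite under a minute on one CPU while leaving the
statistical checks well-powered. `scripts/acceptance.py` re-runs the same
checks from scratch and writes the measured quantities as JSON.

## Known limitations

* GET-only queries; POST query grammars, OAuth flows and Beacon v1 are out
  of scope.
* The flattening dialect is not full JSONPath; payloads are not validated
  against the official Beacon JSON Schemas.
* `cnv_frequency`/`cnv_fraction` matrices precomputed by a live Progenetix
  `services` endpoint are passed through as ordinary responses, not
  re-derived.
* No Cox regression or weighted log-rank variants.
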