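# Methods

## The federation model

`brapifed` treats a federation as an **ordered** list of backends, each
serving a subset of BrAPI v2.1 endpoints.  Backend order is part of the
contract: every merged result is the concatenation of per-backend results
in that order, with no re-sorting and no cross-backend deduplication.
Backends are assumed to be disjoint shards — two backends never hold the
same semantic record — which matches the intended deployment (one genotype
store per crop, one passport/phenotype store) and is the only reading under
which deterministic concatenation is well defined.

### List pagination

Pages are 0-based.  For a request `(page, pageSize)` the proxy computes the
global half-open window `[page·pageSize, page·pageSize + pageSize)` over
the virtual concatenation, probes each routed backend's `totalCount` with a
minimal request (page 0, pageSize 1), intersects the window with each
backend's span, and fetches only the local pages covering the
intersection.  Because a window of length ≤ pageSize can straddle at most
one local page boundary at the same pageSize, at most **two adjacent local
pages per backend** are ever fetched.  Offset-based subrequests are
deliberately avoided: BrAPI only guarantees `page`/`pageSize` semantics.

Probed totals are a best-effort snapshot cached with a short TTL (5 s by
default).  If a backend returns fewer items than its probed total implied,
the proxy re-probes and replans once; a second inconsistency yields a
truncated page carrying a warning status.  Consistency under concurrent
backend mutation is documented, not solved — the target backends are
read-mostly archives.

### Allele-matrix merging

The federated genotype matrix is block-diagonal: the global variant axis is
the concatenation of backend variant axes, likewise callsets, and a cell
pairing a variant from one backend with a callset from another is filled
with the configured `missingGenotype` string (default `.`, VCF convention)
because no backend can genotype another backend's samples.  Both axes are
paged independently with the same two-local-pages-per-axis planning as
lists.  Matrices are matched across backends by `dataMatrixName`; a matrix
present in only some backends is still emitted, fill-valued elsewhere.
Non-fill cells are copied byte-for-byte — genotype strings are never
reinterpreted by the proxy.

### Identifier namespacing

Identifier attributes are those whose name ends in `DbId` (or the plural
`DbIds`), at any nesting depth.  A backend's records are rewritten exactly
once on the response path, prepending `prefix + separator`.  Resolution on
the request path is by longest configured `prefix + separator` leading
match, never by splitting — the separator may legitimately occur inside
local ids.  Load-time validation guarantees the prefix set is prefix-free
and that at most one backend has the empty prefix (the fallback for
unprefixed identifiers), which makes resolution unambiguous and rendering
injective.

**Ownership scoping.**  A prefix is applied to an identifier attribute only
when the entity type it denotes is one the backend itself serves (a backend
serving `/allelematrix` is additionally considered the owner of variant and
callset identifiers, since they are the axes of its matrix).  An attribute
referring to an entity type held elsewhere in the federation — for example
a genotype backend's `sample.germplasmDbId` pointing into the passport
database — is an *external reference*: it already carries the
federation-wide identifier and passes through untouched, resolving via the
fallback backend.  Without this rule the callset → sample → germplasm →
observation linkage chain could never cross from a prefixed genotype
backend into the unprefixed passport backend: the reference would be
rewritten into the genotype backend's own namespace, where no germplasm
exist.  Identifier kinds with no known entity mapping (`referenceDbId` and
similar) default to backend-owned, preserving within-backend referential
integrity.  Filter routing applies the same rule in reverse: owned filter
values are resolved to local form (a backend owning none of the values is
skipped entirely), external-reference filters are broadcast verbatim, and
unresolvable values are dropped — they match nothing, per BrAPI's
match-based filter semantics.

### Server surface

The endpoint set the proxy advertises is derived from the configuration
(implemented ∧ served by ≥ 1 backend); the `serverinfo` calls list, the
OpenAPI 3 document and the live routing table are all generated from that
one set, so the three cannot disagree.  Authorization is a set of static
bearer tokens: with tokens configured every data route returns 401 without
a valid token; with none configured the proxy is open (public-phase mode).
`serverinfo` and the OpenAPI document stay open for discovery.  Per-backend
tokens are attached to outbound requests; user identity is not forwarded.
Retries: 3 attempts with jittered exponential backoff on network errors
and 5xx only — GETs are idempotent, 4xx are terminal.  The HTTP layer is
the standard library's WSGI stack (`wsgiref` server, `urllib` client); the
OpenAPI validator used in tests is a structural validator for the OpenAPI
3.0 object model implemented in `brapifed.openapi`.

## The synthetic federation

`generate_world(spec, seed)` is a pure function of its arguments.  It
emulates the statistical structure the validation workflow assumes:

| parameter | default | meaning |
|---|---|---|
| `crops` | barley, wheat | one genotype backend per crop |
| `germplasm_per_crop` | 60 | accessions with passport data (120 callsets total) |
| `observations_per_germplasm` | 2 | plant-height records per accession |
| `variants_per_crop` | 12 | SNVs spaced 1 kb apart on one chromosome per crop |
| `allele_freq_range` | U(0.1, 0.9) | per-variant alternate-allele frequency |
| `missing_rate` | 0.05 | fraction of reported matrix cells set to `.` |
| `mu`, `sigma` | 100 cm, 5 cm | trait baseline and observation noise SD |
| `beta` | 15 cm (= 3σ) | trait shift per alternate allele at the planted variant |

Genotypes follow Hardy–Weinberg proportions at the drawn frequency,
independently across variants and germplasm (no linkage disequilibrium),
drawn once per germplasm so all of its callsets agree.  Trait observations
are `μ + β·dosage + N(0, σ²)` where dosage is the alternate-allele count at
the single planted variant (0 for the other crop); missingness is applied
to *reported* cells only, never to the latent dosage.  The linkage chain is
closed by construction: every callset maps to a sample, every sample to a
germplasm, every observation to a germplasm and study.

What the generator does **not** emulate — and hence what passing tests do
not show about real data: linkage disequilibrium between variants (real
neighbours of a causal marker would be correlated, not independent),
multi-allelic variants, phased genotypes, population structure and kinship
confounding, observation-unit-level experimental design, and heterogeneous
trait distributions across genebanks.  Recovery rates measured on this
fixture are therefore a test of the *plumbing* (federation, linkage,
statistics), not a power analysis for any real panel.

## The validation workflow

Variant selection iterates all `/variants` pages and keeps variants on the
query chromosome within `|pos − position| ≤ windowHalfWidth` (default
half-width 5 kb; the demo worlds use 3 kb windows over 1 kb-spaced
variants).  Genotype classes are taken verbatim from matrix cells after
normalizing unphased order (`1/0` → `0/1`); missing cells contribute no
group membership but their observations are counted, as are observations of
germplasm with no genotyped callset, so that
`grouped + missing-cell + ungenotyped = total` observations holds exactly.
Dangling identifiers encountered on the chain become warnings naming the
offending id, never exceptions — on a federation of independently curated
stores they are findings.

The distribution comparison is a two-sided Wilcoxon rank-sum test of the
homozygous-reference class against the pooled alternate-carrying classes;
when the reference class is below the minimum group size (default 3
observations) but two alternate classes are eligible, those two are
compared instead.  The exact U null distribution is used below a combined
n of 20, the tie- and continuity-corrected normal approximation above; two
degenerate cases are pinned analytically (all values identical → p = 1).
When all three genotype classes are eligible a Kruskal–Wallis 3-class test
is reported alongside.  Raw p-values are primary; Bonferroni across the
window's tested variants is reported as well.  No kinship or structure
correction is attempted (out of scope for an interface-validation tool).

## Numerical and design choices

- Page index 0-based everywhere; separator default `-`.
- Backend calls within one federated request are issued sequentially in
  backend order; the output contract (identical to sequential execution)
  would also admit a concurrent implementation.
- `onBackendError: fail` (default) turns any backend failure into a
  federation error; `degrade` excludes the dead backend and annotates the
  response with a warning status.
- The acceptance study sizes — 200 random federations for the list-merge
  oracle, 20 for matrix tiling, 100 replicates for planted-effect recovery
  and 500 for null uniformity — keep the whole suite under half a minute
  while leaving the binomial/KS checks well powered; they are the package's
  own choices and can be scaled up freely.

## Known limitations

- BrAPI search-POST and write endpoints are not implemented; GET only.
- Backends serving overlapping semantic content are not deduplicated.
- Totals probing is racy under concurrent backend writes (documented
  eventual-consistency contract above).
- The mock backends implement the subset of BrAPI the proxy and workflow
  exercise, not the full specification.
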