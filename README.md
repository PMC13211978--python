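# brapifed — a federating proxy for BrAPI endpoints

Plant genetic-resources projects routinely split their data across
specialized stores: passport and phenotyping data in a relational database,
genotyping data (VCF-derived variant matrices) in one variant browser per
crop.  Each store can expose its own [BrAPI](https://brapi.org) v2.1
endpoints, but downstream tools want **one** standards-compliant endpoint.

`brapifed` is that proxy.  Given a configuration listing N backend BrAPI
base URLs, it serves a single merged interface that:

- **recomputes list pagination** across backends: a federated page
  `(page, pageSize)` is the item window `[page·pageSize, page·pageSize + pageSize)`
  of the virtual concatenation of the backend lists (in configured backend
  order), realized by fetching at most two adjacent local pages per
  overlapped backend and none at all from backends a filter rules out;
- **merges 2D-paged allele matrices**: the federated variants × callsets
  genotype matrix is the block-diagonal assembly of the backend matrices,
  with both axes paged independently and cross-backend cells filled with a
  configurable missing-genotype string (default `.`, the VCF missing call);
- **namespaces identifiers**: backend-local `DbId`s are prefixed
  (`bar-` + `V0001` → `bar-V0001`) on responses and resolved by
  longest-prefix match on requests, so identifiers that collide between
  backends stay globally unique; prefix sets are validated to be prefix-free
  at config load time;
- **routes filtered requests** to the owning backend only, enforces
  bearer-token auth when tokens are configured, aggregates `serverinfo`,
  and publishes an OpenAPI 3 document that always matches the live routes.

The package also ships two first-class companions:

- `brapifed.synthetic` + `brapifed.mock_backend`: a deterministic generator
  for a complete mock federation (germplasm with passport data, studies,
  trait observations, samples, variants, callsets, Hardy–Weinberg genotype
  matrices) with a *planted* marker–trait effect
  `value = μ + β·dosage + N(0, σ)`, served as one passport/phenotype
  backend plus one genotype backend per crop — in process or over HTTP;
- `brapifed.pipeline`: a client-side workflow that validates a marker–trait
  relationship through any BrAPI endpoint: select variants within a window
  of a genomic position, pull their genotype calls from `/allelematrix`,
  walk the linkage chain callset → sample → germplasm → observations,
  compare per-genotype trait distributions with a two-sided Wilcoxon
  rank-sum test (exact below a combined n of 20), and tabulate passport
  provenance (collecting institute, country of origin, observation year)
  for carriers of the alternate allele.

## Worked example

Run the validation workflow against an in-process synthetic federation
(two crops, 120 callsets, planted effect β = 15 cm at 6H:17005000):

```bash
brapifed validate-marker --demo-seed 11 --chromosome 6H --position 17005000 \
    --window 3000 --trait Plant_height
```

prints (abridged):

```
7 variant(s) within 3000 bp of 6H:17005000; status: ok
variantDbId  chromosome  position  compared          statistic  pValue   pBonferroni  groupSizes
bar-V0006    6H          17005000  0/0+alt-carriers  30.0       3.5e-20  2.45e-19     {"0/0": 58, "0/1": 56, "1/1": 4}
bar-V0009    6H          17008000  0/0+alt-carriers  174.0      0.483    1            {"0/1": 46, "1/1": 64, "0/0": 4}
...
best-supported variant: bar-V0006 (p = 3.5e-20, 30 alternate-carrier germplasm)
```

Each row is one variant inside the window; `compared` names the genotype
classes whose plant-height distributions were contrasted, `pValue` is the
two-sided rank-sum p and `groupSizes` counts trait observations per
genotype class.  The planted variant (`bar-V0006`, note the crop prefix
added by the proxy) is recovered with an overwhelming p-value while its
unlinked neighbours stay at null levels.

The same command runs unchanged against a live federated endpoint:

```bash
brapifed serve -c federation.yml                      # the proxy
brapifed validate-marker --endpoint http://host:8080 --token TOKEN \
    --chromosome 6H --position 17007008 --window 5000 --trait Plant_height
```

A federation config looks like:

```yaml
server:
  port: 8080
  tokens: ["${PROXY_TOKEN}"]
federation:
  separator: "-"
  missingGenotype: "."
backends:
  - name: agent          # passport + phenotype store, unprefixed fallback
    baseUrl: http://agent.example/brapi/v2
    prefix: ""
    endpoints: [germplasm, studies, observations, observationvariables]
  - name: barley
    baseUrl: http://divbrowse-barley.example/brapi/v2
    prefix: bar
    authToken: "${BARLEY_TOKEN}"
    endpoints: [samples, variants, callsets, allelematrix]
  - name: wheat
    baseUrl: http://divbrowse-wheat.example/brapi/v2
    prefix: whe
    endpoints: [samples, variants, callsets, allelematrix]
```

`brapifed serve-world --seed 1` spins up mock HTTP backends plus a proxy
over them for interactive exploration; `/openapi.json` on the proxy serves
the generated OpenAPI document.

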