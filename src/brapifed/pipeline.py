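"""Marker-trait validation client over any BrAPI endpoint.

Reusable implementation of the analysis workflow the federated interface
exists to support: select variants near a genomic position of interest,
pull their genotype calls from the allele matrix, walk the linkage chain
callset -> sample -> germplasm -> observations to attach trait values to
genotype classes, compare the per-class trait distributions with a rank-sum
test, and tabulate passport provenance for carriers of the alternate
allele.

The client only needs an object with ``get(path, params) -> payload``;
``HttpEndpoint`` talks to a live proxy, ``LocalEndpoint`` drives an
in-process ``FederationProxy``.  Dangling identifiers encountered while
walking the chain are recorded as data-integrity warnings, not raised: on a
federation of independently curated backends they are findings, not bugs in
the client.
"""

from __future__ import annotations

import json
import urllib.parse
import urllib.request
from collections import Counter
from dataclasses import dataclass, field
from typing import Any, Iterable, Iterator, Mapping, Protocol

from scipy import stats

from .errors import FederationError

_CHUNK = 50  # identifier-filter values per request (keeps URLs bounded)


class Endpoint(Protocol):
    def get(self, path: str, params: Mapping[str, Any]) -> dict:
        """GET a BrAPI path; return the decoded JSON body."""
        ...


class HttpEndpoint:
    """Live BrAPI endpoint over HTTP with optional bearer token."""

    def __init__(self, base_url: str, token: str | None = None, timeout: float = 30.0):
        self.base_url = base_url.rstrip("/")
        self.token = token
        self.timeout = timeout

    def get(self, path: str, params: Mapping[str, Any]) -> dict:
        query = urllib.parse.urlencode(
            [(k, v) for k, vs in params.items() for v in (vs if isinstance(vs, list) else [vs])]
        )
        url = f"{self.base_url}/{path.lstrip('/')}"
        if query:
            url = f"{url}?{query}"
        headers = {"Accept": "application/json"}
        if self.token:
            headers["Authorization"] = f"Bearer {self.token}"
        req = urllib.request.Request(url, headers=headers)
        with urllib.request.urlopen(req, timeout=self.timeout) as resp:
            return json.loads(resp.read().decode("utf-8"))


class LocalEndpoint:
    """Drive an in-process FederationProxy as if over HTTP."""

    def __init__(self, proxy, token: str | None = None):
        self.proxy = proxy
        self.token = token

    def get(self, path: str, params: Mapping[str, Any]) -> dict:
        query = {
            k: [str(v) for v in (vs if isinstance(vs, list) else [vs])]
            for k, vs in params.items()
        }
        headers = {"Authorization": f"Bearer {self.token}"} if self.token else {}
        status, body = self.proxy.dispatch("GET", path, query, headers)
        if status != 200:
            raise FederationError(f"GET {path} returned {status}: {body}")
        return body


def iterate_pages(
    endpoint: Endpoint, path: str, params: Mapping[str, Any], page_size: int = 200
) -> Iterator[dict]:
    """Yield every record of a paged list endpoint."""
    page = 0
    while True:
        body = endpoint.get(path, {**params, "page": page, "pageSize": page_size})
        data = body.get("result", {}).get("data", [])
        yield from data
        meta = body.get("metadata", {}).get("pagination", {})
        if page >= int(meta.get("totalPages", 0)) - 1 or not data:
            break
        page += 1


def _chunked(values: list[str], size: int = _CHUNK) -> Iterator[list[str]]:
    for i in range(0, len(values), size):
        yield values[i: i + size]


# -- domain types --------------------------------------------------------


@dataclass(frozen=True)
class MarkerQuery:
    """A marker position of interest plus the trait to interrogate."""

    chromosome: str
    position: int  # 1-based bp
    trait_name: str
    window_half_width: int = 5000  # bp

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError("position is 1-based and must be >= 1")
        if self.window_half_width < 0:
            raise ValueError("window half-width must be >= 0")


@dataclass
class TraitGroup:
    germplasm: set[str] = field(default_factory=set)
    values: list[float] = field(default_factory=list)
    n_observations: int = 0


@dataclass
class GenotypeGroupedTrait:
    """Per-variant trait values grouped by genotype class."""

    #: variantDbId -> genotype class -> TraitGroup
    groups: dict[str, dict[str, TraitGroup]]
    #: variantDbId -> variant record (chromosome/position metadata)
    variants: dict[str, dict]
    warnings: list[str]
    #: observations excluded because the cell genotype was missing
    n_obs_missing_genotype: dict[str, int]
    #: observations of germplasm without any genotyped callset
    n_obs_ungenotyped: int
    #: all trait observations seen for the trait
    n_obs_total: int


@dataclass
class VariantTraitResult:
    variant_db_id: str
    chromosome: str
    position: int
    statistic: float
    p_value: float
    group_sizes: dict[str, int]
    compared: tuple[str, str]
    p_bonferroni: float = 1.0
    kruskal_p: float | None = None


# -- pipeline steps ------------------------------------------------------


def find_variants_near(
    query: MarkerQuery, endpoint: Endpoint, page_size: int = 200
) -> list[dict]:
    """All variants on the query chromosome within the window, via paging."""
    hits = []
    for variant in iterate_pages(endpoint, "variants", {}, page_size):
        if variant.get("referenceName") != query.chromosome:
            continue
        pos = int(variant.get("start", -1))
        if abs(pos - query.position) <= query.window_half_width:
            hits.append(variant)
    return hits


def normalize_genotype(cell: str) -> str:
    """Canonical unphased form: allele order in a cell is not meaningful."""
    if "/" in cell:
        alleles = sorted(cell.split("/"))
        return "/".join(alleles)
    return cell


def fetch_genotype_calls(
    variant_ids: list[str],
    endpoint: Endpoint,
    variant_page_size: int = 50,
    callset_page_size: int = 200,
    missing: str = ".",
) -> tuple[list[str], dict[str, dict[str, str]]]:
    """Retrieve genotype calls for the variants by tiling the allele matrix.

    Returns (all callset ids seen, {variantDbId: {callSetDbId: genotype}});
    missing cells are kept (callers decide how to treat them).
    """
    calls: dict[str, dict[str, str]] = {v: {} for v in variant_ids}
    callsets_seen: list[str] = []
    v_page = 0
    while True:
        c_page = 0
        v_count = None
        while True:
            body = endpoint.get(
                "allelematrix",
                {
                    "variantDbId": variant_ids,
                    "dimensionVariantPage": v_page,
                    "dimensionVariantPageSize": variant_page_size,
                    "dimensionCallSetPage": c_page,
                    "dimensionCallSetPageSize": callset_page_size,
                },
            )
            result = body.get("result", {})
            vids = result.get("variantDbIds", [])
            cids = result.get("callSetDbIds", [])
            for cid in cids:
                if cid not in callsets_seen:
                    callsets_seen.append(cid)
            grid = None
            for dm in result.get("dataMatrices", []):
                if dm.get("dataMatrixName", "genotype") == "genotype":
                    grid = dm.get("dataMatrix")
                    break
            if grid is not None:
                for i, vid in enumerate(vids):
                    row = calls.setdefault(vid, {})
                    for j, cid in enumerate(cids):
                        row[cid] = grid[i][j]
            pag = {p["dimension"]: p for p in result.get("pagination", [])}
            v_count = pag.get("VARIANTS", {}).get("totalPages", 0)
            c_total_pages = pag.get("CALLSETS", {}).get("totalPages", 0)
            c_page += 1
            if c_page >= c_total_pages:
                break
        v_page += 1
        if v_count is None or v_page >= v_count:
            break
    return callsets_seen, calls


def link_trait_to_genotypes(
    variants: list[dict],
    trait_name: str,
    endpoint: Endpoint,
    missing: str = ".",
    page_size: int = 200,
) -> GenotypeGroupedTrait:
    """Walk allele matrix -> callsets -> samples -> germplasm -> observations.

    Observations of germplasm lacking genotyped callsets are excluded from
    the groups but counted; missing matrix cells contribute no group
    membership.  Dangling identifiers become warnings.
    """
    variant_ids = [v["variantDbId"] for v in variants]
    warnings: list[str] = []
    callset_ids, calls = fetch_genotype_calls(
        variant_ids, endpoint, callset_page_size=page_size, missing=missing
    )

    # callset -> sample
    callset_to_sample: dict[str, str] = {}
    for chunk in _chunked(callset_ids):
        for rec in iterate_pages(endpoint, "callsets", {"callSetDbId": chunk}, page_size):
            if rec.get("sampleDbId"):
                callset_to_sample[rec["callSetDbId"]] = rec["sampleDbId"]
    for cid in callset_ids:
        if cid not in callset_to_sample:
            warnings.append(f"callset {cid} has no resolvable sample")

    # sample -> germplasm
    sample_ids = sorted(set(callset_to_sample.values()))
    sample_to_germplasm: dict[str, str] = {}
    for chunk in _chunked(sample_ids):
        for rec in iterate_pages(endpoint, "samples", {"sampleDbId": chunk}, page_size):
            if rec.get("germplasmDbId"):
                sample_to_germplasm[rec["sampleDbId"]] = rec["germplasmDbId"]
    for sid in sample_ids:
        if sid not in sample_to_germplasm:
            warnings.append(f"sample {sid} has no resolvable germplasm")

    # verify germplasm exist in the passport data
    germplasm_ids = sorted(set(sample_to_germplasm.values()))
    known_germplasm: set[str] = set()
    for chunk in _chunked(germplasm_ids):
        for rec in iterate_pages(endpoint, "germplasm", {"germplasmDbId": chunk}, page_size):
            known_germplasm.add(rec["germplasmDbId"])
    for gid in germplasm_ids:
        if gid not in known_germplasm:
            warnings.append(f"germplasm {gid} not found in passport data")

    # trait observations per germplasm (for the whole trait, once)
    obs_by_germplasm: dict[str, list[float]] = {}
    n_obs_total = 0
    for rec in iterate_pages(
        endpoint, "observations", {"observationVariableName": trait_name}, page_size
    ):
        n_obs_total += 1
        try:
            value = float(rec["value"])
        except (KeyError, TypeError, ValueError):
            warnings.append(
                f"observation {rec.get('observationDbId')} has non-numeric value"
            )
            continue
        obs_by_germplasm.setdefault(rec["germplasmDbId"], []).append(value)

    genotyped_germplasm = set(germplasm_ids) & known_germplasm
    n_obs_ungenotyped = sum(
        len(vals) for gid, vals in obs_by_germplasm.items()
        if gid not in genotyped_germplasm
    )

    germplasm_of_callset = {
        cid: sample_to_germplasm.get(callset_to_sample.get(cid, ""), None)
        for cid in callset_ids
    }

    groups: dict[str, dict[str, TraitGroup]] = {}
    n_obs_missing: dict[str, int] = {}
    for vid in variant_ids:
        per_class: dict[str, TraitGroup] = {}
        missing_obs = 0
        # genotype class per germplasm (callsets of a germplasm should agree;
        # a non-missing call wins over a missing one)
        germplasm_class: dict[str, str] = {}
        for cid, cell in calls.get(vid, {}).items():
            gid = germplasm_of_callset.get(cid)
            if gid is None or gid not in known_germplasm:
                continue
            gt = normalize_genotype(cell)
            if gt == missing:
                continue
            prev = germplasm_class.get(gid)
            if prev is not None and prev != gt:
                warnings.append(
                    f"germplasm {gid} has conflicting calls at {vid}: {prev} vs {gt}"
                )
                continue
            germplasm_class[gid] = gt
        classified = set(germplasm_class)
        for gid in genotyped_germplasm - classified:
            # genotyped germplasm whose cell at this variant is missing
            missing_obs += len(obs_by_germplasm.get(gid, []))
        for gid, gt in germplasm_class.items():
            values = obs_by_germplasm.get(gid, [])
            group = per_class.setdefault(gt, TraitGroup())
            group.germplasm.add(gid)
            group.values.extend(values)
            group.n_observations += len(values)
        groups[vid] = per_class
        n_obs_missing[vid] = missing_obs

    return GenotypeGroupedTrait(
        groups=groups,
        variants={v["variantDbId"]: v for v in variants},
        warnings=warnings,
        n_obs_missing_genotype=n_obs_missing,
        n_obs_ungenotyped=n_obs_ungenotyped,
        n_obs_total=n_obs_total,
    )


# -- statistics ----------------------------------------------------------

REF_CLASS = "0/0"
EXACT_MAX_N = 20  # combined sample size up to which the exact null is used


def rank_sum_test(x: list[float], y: list[float]) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney U) comparison.

    Exact enumeration of the U null distribution below a combined n of
    ``EXACT_MAX_N``, normal approximation (tie-corrected, continuity-
    corrected) above.  Degenerate case: all values identical -> p = 1.
    """
    x = list(map(float, x))
    y = list(map(float, y))
    if len(set(x) | set(y)) == 1:
        return len(x) * len(y) / 2.0, 1.0
    method = "exact" if len(x) + len(y) < EXACT_MAX_N else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(min(res.pvalue, 1.0))


def test_marker_trait(
    grouped: GenotypeGroupedTrait, min_group_size: int = 3
) -> list[VariantTraitResult]:
    """Rank-sum comparison per variant, sorted by ascending p-value.

    Primary comparison: homozygous-reference class vs the pooled
    alternate-carrying classes.  When the reference class is below the
    minimum size but two alternate classes are eligible, those two classes
    are compared instead.  With all three classes present a Kruskal-Wallis
    3-class rank test is reported alongside.
    """
    results: list[VariantTraitResult] = []
    for vid, per_class in grouped.groups.items():
        sizes = {gt: len(g.values) for gt, g in per_class.items()}
        eligible = [gt for gt, n in sizes.items() if n >= min_group_size]
        if len([gt for gt in per_class if sizes[gt] > 0]) < 2:
            continue
        ref = per_class.get(REF_CLASS)
        alt_values = [
            v for gt, g in per_class.items() if gt != REF_CLASS for v in g.values
        ]
        if ref is not None and len(ref.values) >= min_group_size and len(alt_values) >= min_group_size:
            stat, p = rank_sum_test(ref.values, alt_values)
            compared = (REF_CLASS, "alt-carriers")
        else:
            alts = sorted(
                (gt for gt in eligible if gt != REF_CLASS),
                key=lambda gt: -sizes[gt],
            )
            if len(alts) < 2:
                continue
            stat, p = rank_sum_test(per_class[alts[0]].values, per_class[alts[1]].values)
            compared = (alts[0], alts[1])
        kruskal_p = None
        present = [g.values for gt, g in per_class.items() if len(g.values) >= min_group_size]
        if len(present) >= 3:
            try:
                kruskal_p = float(stats.kruskal(*present).pvalue)
            except ValueError:  # all values identical
                kruskal_p = 1.0
        variant = grouped.variants.get(vid, {})
        results.append(
            VariantTraitResult(
                variant_db_id=vid,
                chromosome=str(variant.get("referenceName", "")),
                position=int(variant.get("start", 0)),
                statistic=stat,
                p_value=p,
                group_sizes=sizes,
                compared=compared,
                kruskal_p=kruskal_p,
            )
        )
    k = len(results)
    for r in results:
        r.p_bonferroni = min(1.0, r.p_value * k)
    results.sort(key=lambda r: (r.p_value, r.variant_db_id))
    return results


# -- passport breakdown ---------------------------------------------------


def carriers_of_alternate(
    grouped: GenotypeGroupedTrait, variant_id: str
) -> set[str]:
    """Germplasm heterozygous or homozygous alternate at the variant."""
    carriers: set[str] = set()
    for gt, group in grouped.groups.get(variant_id, {}).items():
        if gt != REF_CLASS and any(a not in ("0", ".") for a in gt.split("/")):
            carriers |= group.germplasm
    return carriers


def passport_breakdown(
    carrier_germplasm: Iterable[str], endpoint: Endpoint, page_size: int = 200
) -> dict[str, Counter]:
    """Collecting institute, country of origin and observation year counts.

    Missing passport fields are counted under ``"unknown"``.  Year counts
    are per observation (via its study); institute/country counts are per
    carrier germplasm.
    """
    carrier_ids = sorted(set(carrier_germplasm))
    institutes: Counter = Counter()
    countries: Counter = Counter()
    years: Counter = Counter()
    seen: set[str] = set()
    for chunk in _chunked(carrier_ids):
        for rec in iterate_pages(endpoint, "germplasm", {"germplasmDbId": chunk}, page_size):
            seen.add(rec["germplasmDbId"])
            institutes[rec.get("instituteName") or "unknown"] += 1
            countries[rec.get("countryOfOriginCode") or "unknown"] += 1
    for gid in carrier_ids:
        if gid not in seen:
            institutes["unknown"] += 1
            countries["unknown"] += 1

    study_year: dict[str, Any] = {}
    for rec in iterate_pages(endpoint, "studies", {}, page_size):
        study_year[rec.get("studyDbId")] = rec.get("year", "unknown")
    for chunk in _chunked(carrier_ids):
        for rec in iterate_pages(endpoint, "observations", {"germplasmDbId": chunk}, page_size):
            years[study_year.get(rec.get("studyDbId"), "unknown")] += 1
    return {"institute": institutes, "country": countries, "year": years}


# -- end-to-end runner -----------------------------------------------------


def run_marker_validation(
    query: MarkerQuery,
    endpoint: Endpoint,
    min_group_size: int = 3,
    missing: str = ".",
) -> dict[str, Any]:
    """Full workflow: select variants, link trait values, test, tabulate.

    Returns a JSON-serializable report; ``results`` is sorted by ascending
    p-value and ``top`` names the best-supported variant (None when no
    variant had two eligible genotype classes).
    """
    variants = find_variants_near(query, endpoint)
    report: dict[str, Any] = {
        "query": {
            "chromosome": query.chromosome,
            "position": query.position,
            "windowHalfWidth": query.window_half_width,
            "trait": query.trait_name,
        },
        "n_variants_in_window": len(variants),
    }
    if not variants:
        report.update(results=[], warnings=[], top=None, status="no variants in window")
        return report
    grouped = link_trait_to_genotypes(variants, query.trait_name, endpoint, missing=missing)
    results = test_marker_trait(grouped, min_group_size=min_group_size)
    report["warnings"] = grouped.warnings
    report["counts"] = {
        "observations_total": grouped.n_obs_total,
        "observations_ungenotyped_germplasm": grouped.n_obs_ungenotyped,
    }
    report["results"] = [
        {
            "variantDbId": r.variant_db_id,
            "chromosome": r.chromosome,
            "position": r.position,
            "statistic": r.statistic,
            "pValue": r.p_value,
            "pBonferroni": r.p_bonferroni,
            "kruskalP": r.kruskal_p,
            "groupSizes": r.group_sizes,
            "compared": list(r.compared),
        }
        for r in results
    ]
    if results:
        top = results[0]
        report["top"] = top.variant_db_id
        carriers = carriers_of_alternate(grouped, top.variant_db_id)
        breakdown = passport_breakdown(carriers, endpoint)
        report["passport"] = {k: dict(v) for k, v in breakdown.items()}
        report["n_carriers"] = len(carriers)
        report["status"] = "ok"
    else:
        report["top"] = None
        report["status"] = "no variant with two eligible genotype classes"
    return report
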