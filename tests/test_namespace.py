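"""Identifier namespacing: rendering, resolution, routing."""

import pytest
from hypothesis import given, strategies as st

from brapifed.config import BackendConfig, FederationConfig
from brapifed.errors import UnresolvableIdError
from brapifed.namespace import (
    SKIP,
    namespace_record,
    render_id,
    resolve_id,
    route_filters,
)


def make_config(prefixes, endpoints=("germplasm", "variants", "callsets")):
    backends = tuple(
        BackendConfig(
            name=f"b{i}", base_url=f"mock://b{i}", prefix=p,
            endpoints=frozenset(endpoints),
        )
        for i, p in enumerate(prefixes)
    )
    return FederationConfig(backends=backends)


CFG = make_config(["", "bar", "whe"])
BAR = CFG.backends[1]


class TestNamespaceRecord:
    def test_scalar_id_prefixed_names_untouched(self):
        record = {"germplasmDbId": "G1", "germplasmName": "Alpha"}
        out = namespace_record(record, BAR, "-")
        assert out == {"germplasmDbId": "bar-G1", "germplasmName": "Alpha"}

    def test_list_valued_ids_prefixed(self):
        record = {"variantDbId": "V9", "callSetDbIds": ["C1", "C2"]}
        out = namespace_record(record, BAR, "-")
        assert out == {"variantDbId": "bar-V9", "callSetDbIds": ["bar-C1", "bar-C2"]}

    def test_empty_prefix_is_identity(self):
        record = {"germplasmDbId": "G1", "nested": {"studyDbId": "S1"}}
        assert namespace_record(record, CFG.backends[0], "-") == record

    def test_nested_ids_prefixed(self):
        record = {"callSetDbId": "C1", "extra": [{"variantDbId": "V1"}]}
        out = namespace_record(record, BAR, "-")
        assert out["extra"][0]["variantDbId"] == "bar-V1"

    def test_unserved_entity_reference_passes_through(self):
        """A reference to an entity type held by another backend keeps its
        federation-wide form (the linkage chain must cross backends)."""
        genotype_backend = BackendConfig(
            name="g", base_url="mock://g", prefix="bar",
            endpoints=frozenset({"samples", "callsets", "variants"}),
        )
        record = {"sampleDbId": "S1", "germplasmDbId": "ACC1"}
        out = namespace_record(record, genotype_backend, "-")
        assert out == {"sampleDbId": "bar-S1", "germplasmDbId": "ACC1"}

    def test_unknown_id_kind_stays_within_backend(self):
        out = namespace_record({"referenceDbId": "chr1"}, BAR, "-")
        assert out == {"referenceDbId": "bar-chr1"}

    def test_none_valued_id_untouched(self):
        assert namespace_record({"sampleDbId": None}, BAR, "-") == {"sampleDbId": None}


class TestResolveId:
    def test_longest_prefix_match(self):
        backend, local = resolve_id("bar-G1", CFG)
        assert (backend.name, local) == ("b1", "G1")

    def test_fallback_for_unprefixed(self):
        backend, local = resolve_id("G1", CFG)
        assert (backend.name, local) == ("b0", "G1")

    def test_unresolvable_without_fallback(self):
        cfg = make_config(["bar", "whe"])
        with pytest.raises(UnresolvableIdError):
            resolve_id("xyz-G1", cfg)

    def test_separator_inside_local_id(self):
        backend, local = resolve_id("bar-G-1-a", CFG)
        assert (backend.name, local) == ("b1", "G-1-a")


class TestRouteFilters:
    def test_single_owner_routing(self):
        routed = route_filters({"germplasmDbId": "bar-G1"}, CFG, "germplasm")
        assert routed["b0"] is SKIP
        assert routed["b1"] == {"germplasmDbId": "G1"}
        assert routed["b2"] is SKIP

    def test_non_identifier_broadcast(self):
        routed = route_filters({"studyType": "trial"}, CFG, "germplasm")
        assert all(r == {"studyType": "trial"} for r in routed.values())

    def test_list_partitioned_by_owner(self):
        routed = route_filters({"variantDbId": ["bar-V1", "whe-V2"]}, CFG, "variants")
        assert routed["b1"] == {"variantDbId": ["V1"]}
        assert routed["b2"] == {"variantDbId": ["V2"]}
        assert routed["b0"] is SKIP

    def test_unresolvable_values_dropped(self):
        cfg = make_config(["bar", "whe"])
        routed = route_filters({"variantDbId": ["zzz-V1"]}, cfg, "variants")
        assert all(r is SKIP for r in routed.values())

    def test_mixed_resolvable_and_not(self):
        routed = route_filters({"variantDbId": ["bar-V1", "zzz-V9"]}, CFG, "variants")
        assert routed["b1"] == {"variantDbId": ["V1"]}

    def test_capability_skip(self):
        routed = route_filters({}, CFG, "allelematrix")
        assert all(r is SKIP for r in routed.values())

    def test_external_reference_filter_forwarded_verbatim(self):
        geno = BackendConfig(
            name="g", base_url="mock://g", prefix="bar",
            endpoints=frozenset({"samples"}),
        )
        cfg = FederationConfig(backends=(geno,))
        routed = route_filters({"germplasmDbId": ["ACC1"]}, cfg, "samples")
        assert routed["g"] == {"germplasmDbId": ["ACC1"]}


# -- properties ----------------------------------------------------------

_local_ids = st.text(
    alphabet=st.characters(whitelist_categories=("Ll", "Nd")), min_size=1, max_size=8
)
_prefixes = st.lists(
    st.text(alphabet="abcdefgh", min_size=1, max_size=4),
    min_size=1, max_size=4, unique=True,
).filter(
    lambda ps: not any(
        i != j and q.startswith(p) for i, p in enumerate(ps) for j, q in enumerate(ps)
    )
)


@given(prefixes=_prefixes, local=_local_ids, data=st.data())
def test_roundtrip_property(prefixes, local, data):
    """resolve(render(prefix, local)) recovers the backend and local id."""
    cfg = make_config(prefixes)
    backend = data.draw(st.sampled_from(cfg.backends))
    rendered = render_id(backend.prefix, local, cfg.separator)
    resolved, got_local = resolve_id(rendered, cfg)
    assert resolved.name == backend.name
    assert got_local == local


@given(prefixes=_prefixes, locals_=st.lists(_local_ids, min_size=1, max_size=6, unique=True))
def test_injectivity_property(prefixes, locals_):
    """Distinct (backend, localId) pairs render to distinct namespaced ids."""
    cfg = make_config(prefixes)
    rendered = {
        render_id(b.prefix, lid, cfg.separator)
        for b in cfg.backends for lid in locals_
    }
    assert len(rendered) == len(cfg.backends) * len(locals_)
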