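"""Server surface: auth, routing, serverinfo/OpenAPI consistency, WSGI."""

import json

import pytest

from conftest import make_list_federation

from brapifed.mock_backend import serve_world
from brapifed.openapi import build_openapi, validate_openapi
from brapifed.proxy import FederationProxy, wsgi_app
from brapifed.synthetic import WorldSpec, generate_world


class TestAuth:
    def test_401_without_token(self, world_federation):
        _, config, transport = world_federation
        from brapifed.config import FederationConfig

        config = FederationConfig(
            backends=config.backends, server_tokens=frozenset({"open-sesame"})
        )
        proxy = FederationProxy(config, transport=transport)
        for route in ("/germplasm", "/variants", "/allelematrix", "/germplasm/BAR0001"):
            status, _ = proxy.dispatch("GET", route, {})
            assert status == 401, route
            status, _ = proxy.dispatch(
                "GET", route, {}, {"Authorization": "Bearer wrong"}
            )
            assert status == 401, route
        status, _ = proxy.dispatch(
            "GET", "/germplasm", {}, {"Authorization": "Bearer open-sesame"}
        )
        assert status == 200
        # serverinfo stays open for discovery
        status, _ = proxy.dispatch("GET", "/serverinfo", {})
        assert status == 200

    def test_open_when_no_tokens_configured(self, world_proxy):
        _, proxy = world_proxy
        status, _ = proxy.dispatch("GET", "/germplasm", {})
        assert status == 200


class TestRouting:
    def test_single_record_routed_and_namespaced(self, world_proxy):
        _, proxy = world_proxy
        status, body = proxy.dispatch("GET", "/callsets/bar-C0001", {})
        assert status == 200
        assert body["result"]["callSetDbId"] == "bar-C0001"
        assert body["result"]["sampleDbId"] == "bar-S0001"

    def test_single_record_unknown_prefix_404(self, world_proxy):
        _, proxy = world_proxy
        status, _ = proxy.dispatch("GET", "/callsets/C0001", {})
        # unprefixed id resolves to the passport backend, which has no callsets
        assert status == 404
        status, _ = proxy.dispatch("GET", "/germplasm/BAR9999", {})
        assert status == 404

    def test_unadvertised_endpoint_404(self):
        config, transport = make_list_federation([2])
        proxy = FederationProxy(config, transport=transport)
        status, _ = proxy.dispatch("GET", "/allelematrix", {})
        assert status == 404

    def test_brapi_v2_path_prefix_accepted(self, world_proxy):
        _, proxy = world_proxy
        status, _ = proxy.dispatch("GET", "/brapi/v2/germplasm", {})
        assert status == 200

    def test_commoncropnames_union(self, world_proxy):
        _, proxy = world_proxy
        status, body = proxy.dispatch("GET", "/commoncropnames", {})
        assert status == 200
        assert body["result"]["data"] == ["barley", "wheat"]

    def test_method_not_allowed(self, world_proxy):
        _, proxy = world_proxy
        status, _ = proxy.dispatch("POST", "/germplasm", {})
        assert status == 405


class TestInterfaceConsistency:
    def test_serverinfo_openapi_routing_agree(self, world_proxy):
        """The same endpoint set appears in serverinfo, the OpenAPI paths
        and the live routing table."""
        _, proxy = world_proxy
        advertised = proxy.advertised_endpoints()

        _, info = proxy.dispatch("GET", "/serverinfo", {})
        serverinfo_eps = {
            c["service"].split("/")[0] for c in info["result"]["calls"]
        }
        assert serverinfo_eps == advertised

        doc = proxy.openapi_document()
        openapi_eps = {p.strip("/").split("/")[0] for p in doc["paths"]}
        assert openapi_eps | {"serverinfo"} == advertised | {"serverinfo"}
        assert "serverinfo" in openapi_eps

        for ep in advertised:
            status, _ = proxy.dispatch("GET", f"/{ep}", {})
            assert status == 200, ep

    def test_endpoints_absent_without_genotype_backends(self):
        """A germplasm-only federation advertises no genotype endpoints."""
        config, transport = make_list_federation([3])
        proxy = FederationProxy(config, transport=transport)
        advertised = proxy.advertised_endpoints()
        assert "variants" not in advertised
        assert "allelematrix" not in advertised
        assert "serverinfo" in advertised
        doc = proxy.openapi_document()
        assert "/allelematrix" not in doc["paths"]
        status, _ = proxy.dispatch("GET", "/variants", {})
        assert status == 404

    def test_openapi_document_validates(self, world_proxy):
        _, proxy = world_proxy
        assert validate_openapi(proxy.openapi_document())

    def test_openapi_validator_rejects_broken_documents(self):
        doc = build_openapi({"serverinfo", "germplasm"})
        with pytest.raises(ValueError):
            validate_openapi({})
        broken = json.loads(json.dumps(doc))
        del broken["paths"]["/germplasm"]["get"]["responses"]
        with pytest.raises(ValueError, match="responses"):
            validate_openapi(broken)
        broken = json.loads(json.dumps(doc))
        broken["paths"]["/germplasm/{germplasmDbId}"]["get"]["parameters"] = []
        with pytest.raises(ValueError, match="path"):
            validate_openapi(broken)


class TestWsgiAndHttp:
    def test_wsgi_roundtrip(self, world_proxy):
        _, proxy = world_proxy
        app = wsgi_app(proxy)
        captured = {}

        def start_response(status, headers):
            captured["status"] = status

        body = b"".join(
            app(
                {
                    "REQUEST_METHOD": "GET",
                    "PATH_INFO": "/germplasm",
                    "QUERY_STRING": "pageSize=2",
                },
                start_response,
            )
        )
        assert captured["status"].startswith("200")
        payload = json.loads(body)
        assert len(payload["result"]["data"]) == 2

    def test_live_http_federation(self):
        """serve_world exposes mock backends over HTTP; the proxy federates
        them through the real urllib transport."""
        world = generate_world(
            WorldSpec(germplasm_per_crop=4, variants_per_crop=3,
                      planted_variant_index=0),
            seed=3,
        )
        config, handles = serve_world(world)
        try:
            proxy = FederationProxy(config)
            status, body = proxy.dispatch("GET", "/variants", {"pageSize": ["4"]})
            assert status == 200
            assert body["metadata"]["pagination"]["totalCount"] == 6
            assert body["result"]["data"][0]["variantDbId"].startswith("bar-")
        finally:
            for h in handles:
                h.shutdown()
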