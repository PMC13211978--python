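"""Block-diagonal allele-matrix merging with 2D pagination."""

from conftest import block_diagonal_oracle, make_matrix_federation

from brapifed.client import BackendClient
from brapifed.matrix_merge import plan_matrix_window
from brapifed.proxy import FederationProxy


def get_matrix(proxy, vp, vps, cp, cps, extra=None):
    query = {
        "dimensionVariantPage": [str(vp)],
        "dimensionVariantPageSize": [str(vps)],
        "dimensionCallSetPage": [str(cp)],
        "dimensionCallSetPageSize": [str(cps)],
    }
    query.update(extra or {})
    status, body = proxy.dispatch("GET", "/allelematrix", query)
    assert status == 200, body
    return body["result"]


class TestPlanMatrixWindow:
    def test_single_backend_full_window(self):
        plan = plan_matrix_window(0, 10, 0, 10, [4], [3])
        [win] = plan.windows
        assert win.variant_sub.local_slice == (0, 4)
        assert win.callset_sub.local_slice == (0, 3)

    def test_first_tile_spans_both_backends(self):
        """A 4x4 first tile over totals (2,3)x(2,2) takes 2x2 from backend 0
        and the first two variants x both callsets of backend 1."""
        plan = plan_matrix_window(0, 4, 0, 4, [2, 3], [2, 2])
        w0, w1 = plan.windows
        assert w0.variant_sub.local_slice == (0, 2)
        assert w0.callset_sub.local_slice == (0, 2)
        assert w1.variant_sub.local_slice == (0, 2)
        assert w1.callset_sub.local_slice == (0, 2)

    def test_window_inside_second_backend_only(self):
        plan = plan_matrix_window(1, 2, 1, 2, [2, 3], [2, 2])
        [w1] = plan.windows
        assert w1.backend is None or w1.backend.name != "geno0"
        assert w1.variant_sub.local_slice == (0, 2)  # global variants [2,4)
        assert w1.callset_sub.local_slice == (0, 2)  # global callsets [2,4)

    def test_at_most_two_pages_per_axis(self):
        for vp in range(3):
            plan = plan_matrix_window(vp, 3, 0, 5, [4, 5], [3, 3])
            for win in plan.windows:
                for sub in (win.variant_sub, win.callset_sub):
                    if sub is not None:
                        assert 1 <= len(sub.page_indices) <= 2


class TestAssembleViaProxy:
    def test_two_singleton_backends_form_diagonal(self):
        config, transport, blocks = make_matrix_federation([(1, 1), (1, 1)], seed=3)
        # overwrite cells for a fully determined expectation
        transport.apps["mock://geno0"].matrix[2]["genotype"][0][0] = "0/0"
        transport.apps["mock://geno1"].matrix[2]["genotype"][0][0] = "1/1"
        proxy = FederationProxy(config, transport=transport)
        result = get_matrix(proxy, 0, 2, 0, 2)
        assert result["variantDbIds"] == ["g0-V0", "g1-V0"]
        assert result["callSetDbIds"] == ["g0-C0", "g1-C0"]
        [dm] = result["dataMatrices"]
        assert dm["dataMatrix"] == [["0/0", "."], [".", "1/1"]]

    def test_single_backend_identity_with_namespacing(self):
        config, transport, blocks = make_matrix_federation([(3, 2)], seed=4)
        proxy = FederationProxy(config, transport=transport)
        result = get_matrix(proxy, 0, 10, 0, 10)
        vids, cids, grid = block_diagonal_oracle(config, blocks, ".")
        assert result["variantDbIds"] == vids
        assert result["callSetDbIds"] == cids
        assert result["dataMatrices"][0]["dataMatrix"] == grid

    def test_cross_backend_cells_equal_fill(self):
        config, transport, blocks = make_matrix_federation(
            [(2, 2), (2, 2)], fill="?/?", seed=5
        )
        proxy = FederationProxy(config, transport=transport)
        result = get_matrix(proxy, 0, 10, 0, 10)
        grid = result["dataMatrices"][0]["dataMatrix"]
        for i in range(4):
            for j in range(4):
                same_backend = (i < 2) == (j < 2)
                if not same_backend:
                    assert grid[i][j] == "?/?"

    def test_pagination_totals_are_sums(self):
        config, transport, _ = make_matrix_federation([(2, 3), (4, 1)], seed=6)
        proxy = FederationProxy(config, transport=transport)
        result = get_matrix(proxy, 0, 3, 0, 2)
        pag = {p["dimension"]: p for p in result["pagination"]}
        assert pag["VARIANTS"]["totalCount"] == 6
        assert pag["CALLSETS"]["totalCount"] == 4
        assert pag["VARIANTS"]["totalPages"] == 2
        assert pag["CALLSETS"]["totalPages"] == 2

    def test_malformed_backend_grid_maps_to_federation_error(self):
        config, transport, _ = make_matrix_federation([(2, 2)], seed=7)
        app = transport.apps["mock://geno0"]
        orig = app.get

        def corrupted(path, params):  # axis labels no longer match the grid
            status, body = orig(path, params)
            if path.strip("/") == "allelematrix" and body["result"]["variantDbIds"]:
                body["result"]["variantDbIds"] = body["result"]["variantDbIds"][:-1]
            return status, body

        app.get = corrupted
        proxy = FederationProxy(config, transport=transport)
        status, body = proxy.dispatch(
            "GET", "/allelematrix", {"dimensionVariantPageSize": ["10"]}
        )
        assert status == 502
        assert "geno0" in body["metadata"]["status"][0]["message"]


class TestFilteredMatrix:
    def test_filter_routes_to_single_backend(self):
        config, transport, blocks = make_matrix_federation([(3, 2), (3, 2)], seed=8)
        client = BackendClient(config, transport)
        proxy = FederationProxy(config, client=client)
        result = get_matrix(proxy, 0, 10, 0, 10, {"variantDbId": ["g0-V1"]})
        assert result["variantDbIds"] == ["g0-V1"]
        # wheat-analog backend contributes no variant axis entries
        assert all(not v.startswith("g1-") for v in result["variantDbIds"])
        assert all(c.backend != "geno1" for c in client.call_log)

    def test_filter_spanning_both_crops_fills_cross_cells(self):
        config, transport, blocks = make_matrix_federation([(3, 2), (3, 2)], seed=9)
        proxy = FederationProxy(config, transport=transport)
        result = get_matrix(
            proxy, 0, 10, 0, 10, {"variantDbId": ["g0-V0", "g1-V2"]}
        )
        assert result["variantDbIds"] == ["g0-V0", "g1-V2"]
        grid = result["dataMatrices"][0]["dataMatrix"]
        assert grid[0][2] == "." and grid[0][3] == "."
        assert grid[1][0] == "." and grid[1][1] == "."
        # same-backend cells preserved byte-for-byte
        assert grid[0][0] == blocks[0][2][0][0]
        assert grid[1][2] == blocks[1][2][2][0]

    def test_unresolvable_filter_yields_empty_axes(self):
        config, transport, _ = make_matrix_federation([(3, 2), (3, 2)], seed=10)
        proxy = FederationProxy(config, transport=transport)
        result = get_matrix(proxy, 0, 10, 0, 10, {"variantDbId": ["nope-V0"]})
        assert result["variantDbIds"] == []
        assert result["callSetDbIds"] == []
        pag = {p["dimension"]: p for p in result["pagination"]}
        assert pag["VARIANTS"]["totalCount"] == 0


def test_conservation_of_axis_totals():
    """Merged per-axis totalCount equals the sum over backends."""
    config, transport, blocks = make_matrix_federation([(5, 4), (2, 7)], seed=11)
    proxy = FederationProxy(config, transport=transport)
    result = get_matrix(proxy, 0, 1, 0, 1)
    pag = {p["dimension"]: p for p in result["pagination"]}
    assert pag["VARIANTS"]["totalCount"] == sum(len(b[0]) for b in blocks)
    assert pag["CALLSETS"]["totalCount"] == sum(len(b[1]) for b in blocks)
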