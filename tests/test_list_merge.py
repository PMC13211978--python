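"""Fetch planning and merged pagination over concatenated backend lists."""

import numpy as np
import pytest

from conftest import concatenation_oracle, iterate_proxy_pages, make_list_federation

from brapifed.client import BackendClient
from brapifed.list_merge import TotalsCache, compute_fetch_plan, probe_totals
from brapifed.model import total_pages
from brapifed.namespace import route_filters
from brapifed.proxy import FederationProxy


class TestComputeFetchPlan:
    def test_single_backend_passthrough(self):
        plan = compute_fetch_plan(0, 5, [10])
        assert plan.window == (0, 5)
        [sub] = plan.subrequests
        assert sub.page_indices == (0,)
        assert sub.local_slice == (0, 5)

    def test_window_straddles_second_backend(self):
        """Window [4, 8) of totals [3, 5] lies in backend 1 items [1, 5)."""
        plan = compute_fetch_plan(1, 4, [3, 5])
        assert plan.window == (4, 8)
        [sub] = plan.subrequests
        assert sub.local_slice == (1, 5)
        assert sub.page_indices == (0, 1)

    def test_window_beyond_total_is_empty(self):
        plan = compute_fetch_plan(2, 2, [2, 2])
        assert plan.subrequests == ()
        assert plan.total_count == 4
        assert total_pages(plan.total_count, 2) == 2

    def test_slices_cover_window_exactly(self):
        """Concatenated sub-slices always tile the global window."""
        rng = np.random.default_rng(5)
        for _ in range(200):
            totals = list(rng.integers(0, 40, size=rng.integers(1, 5)))
            ps = int(rng.integers(1, 12))
            page = int(rng.integers(0, 6))
            plan = compute_fetch_plan(page, ps, totals)
            start, end = plan.window
            assert sum(hi - lo for _, _, (lo, hi) in
                       ((s.backend, s.page_indices, s.local_slice)
                        for s in plan.subrequests)) == max(0, end - start)
            for sub in plan.subrequests:
                lo, hi = sub.local_slice
                assert 1 <= len(sub.page_indices) <= 2
                assert sub.page_indices[0] == lo // ps
                assert sub.page_indices[-1] == (hi - 1) // ps

    def test_invalid_paging_rejected(self):
        with pytest.raises(ValueError):
            compute_fetch_plan(-1, 5, [3])
        with pytest.raises(ValueError):
            compute_fetch_plan(0, 0, [3])


class TestProbeTotals:
    def test_reads_fixture_totals(self):
        config, transport = make_list_federation([3, 5])
        client = BackendClient(config, transport)
        routed = route_filters({}, config, "germplasm")
        probe = probe_totals("germplasm", routed, client, config)
        assert probe.totals == [3, 5]

    def test_skip_contributes_zero_without_call(self):
        config, transport = make_list_federation([3, 5], prefixes=["b1", "b2"])
        client = BackendClient(config, transport)
        routed = route_filters({"germplasmDbId": "b1-G0"}, config, "germplasm")
        probe = probe_totals("germplasm", routed, client, config)
        assert probe.totals == [1, 0]  # filter matches one record on backend 0
        assert all(c.backend != "backend1" for c in client.call_log)

    def test_degrade_policy_excludes_dead_backend(self):
        config, transport = make_list_federation([3, 5])
        def explode(path, params):
            raise ConnectionError("backend down")
        transport.fault_hooks[config.backends[1].base_url] = explode
        client = BackendClient(config, transport, max_attempts=2, sleep=lambda s: None)
        routed = route_filters({}, config, "germplasm")
        probe = probe_totals("germplasm", routed, client, config, policy="degrade")
        assert probe.totals == [3, 0]
        assert probe.excluded == {"backend1"}
        assert any("excluded" in w["message"] for w in probe.warnings)

    def test_fail_policy_raises(self):
        from brapifed.errors import BackendNetworkError

        config, transport = make_list_federation([3, 5])
        transport.fault_hooks[config.backends[1].base_url] = (
            lambda p, q: (_ for _ in ()).throw(ConnectionError("down"))
        )
        client = BackendClient(config, transport, max_attempts=2, sleep=lambda s: None)
        routed = route_filters({}, config, "germplasm")
        with pytest.raises(BackendNetworkError):
            probe_totals("germplasm", routed, client, config, policy="fail")

    def test_totals_cache_bounds_probe_traffic(self):
        config, transport = make_list_federation([4])
        client = BackendClient(config, transport)
        routed = route_filters({}, config, "germplasm")
        cache = TotalsCache(ttl=60.0)
        probe_totals("germplasm", routed, client, config, cache=cache)
        before = len(client.call_log)
        probe_totals("germplasm", routed, client, config, cache=cache)
        assert len(client.call_log) == before


class TestExecutePlanViaProxy:
    def test_merged_page_matches_slice_of_oracle(self):
        """Page 1 of size 4 over [3, 5] equals oracle items [4, 8)."""
        config, transport = make_list_federation([3, 5])
        proxy = FederationProxy(config, transport=transport)
        oracle = concatenation_oracle(config, transport)
        status, body = proxy.dispatch(
            "GET", "/germplasm", {"page": ["1"], "pageSize": ["4"]}
        )
        assert status == 200
        assert body["result"]["data"] == oracle[4:8]
        assert body["metadata"]["pagination"]["totalCount"] == 8

    def test_ids_are_namespaced_in_merged_output(self):
        config, transport = make_list_federation([2, 2])
        proxy = FederationProxy(config, transport=transport)
        records = iterate_proxy_pages(proxy, "germplasm", 3)
        assert [r["germplasmDbId"] for r in records] == ["G0", "G1", "b1-G0", "b1-G1"]

    def test_empty_page_keeps_full_total(self):
        config, transport = make_list_federation([2, 2])
        proxy = FederationProxy(config, transport=transport)
        status, body = proxy.dispatch(
            "GET", "/germplasm", {"page": ["5"], "pageSize": ["2"]}
        )
        assert status == 200
        assert body["result"]["data"] == []
        assert body["metadata"]["pagination"]["totalCount"] == 4

    def test_degrade_mode_serves_live_backends_with_warning(self):
        config, transport = make_list_federation([3, 5])
        from brapifed.config import FederationConfig

        config = FederationConfig(
            backends=config.backends, on_backend_error="degrade"
        )
        transport.fault_hooks[config.backends[0].base_url] = (
            lambda p, q: (_ for _ in ()).throw(ConnectionError("down"))
        )
        client = BackendClient(config, transport, max_attempts=1, sleep=lambda s: None)
        proxy = FederationProxy(config, client=client)
        status, body = proxy.dispatch("GET", "/germplasm", {"pageSize": ["10"]})
        assert status == 200
        ids = [r["germplasmDbId"] for r in body["result"]["data"]]
        assert ids == [f"b1-G{j}" for j in range(5)]
        assert any("excluded" in s["message"] for s in body["metadata"]["status"])

    def test_stale_totals_trigger_replan(self):
        """A backend shrinking between probe and fetch is re-probed once."""
        config, transport = make_list_federation([6, 4])
        proxy = FederationProxy(config, transport=transport, totals_ttl=1e9)
        # warm the totals cache, then shrink backend 0 behind the proxy's back
        proxy.dispatch("GET", "/germplasm", {"pageSize": ["2"]})
        app = transport.apps[config.backends[0].base_url]
        del app.tables["germplasm"][3:]
        status, body = proxy.dispatch(
            "GET", "/germplasm", {"page": ["1"], "pageSize": ["4"]}
        )
        assert status == 200
        # after replanning, the page reflects the fresh totals [3, 4]
        assert body["metadata"]["pagination"]["totalCount"] == 7
        ids = [r["germplasmDbId"] for r in body["result"]["data"]]
        assert ids == ["b1-G1", "b1-G2", "b1-G3"]
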