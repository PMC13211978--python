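"""In-process mock BrAPI backends built from a synthetic world.

One passport/phenotype backend serves germplasm, studies and observations
for all crops; one genotype backend per crop serves samples, variants,
callsets and the allele matrix — the test double for a relational
phenotyping database federated with per-crop variant browsers.

The mock application speaks the same envelope dialect the real backends
would: list endpoints with BrAPI pagination metadata and equality filters,
``/{entity}/{id}`` single-record forms, and ``/allelematrix`` with 2D
pagination and identifier filters.  ``serve_world`` additionally exposes the
mocks over real HTTP for end-to-end runs; the test suite talks to them
in-process via ``InProcessTransport``.
"""

from __future__ import annotations

import threading
from dataclasses import dataclass
from typing import Any
from wsgiref.simple_server import WSGIRequestHandler, make_server

from .client import InProcessTransport
from .config import BackendConfig, FederationConfig
from .model import ENTITY_ID_FIELD, PaginationMeta
from .synthetic import SyntheticWorld

_RELATIONAL_ENDPOINTS = frozenset(
    {"germplasm", "studies", "observations", "observationvariables",
     "commoncropnames", "serverinfo"}
)
_GENOTYPE_ENDPOINTS = frozenset(
    {"samples", "variants", "callsets", "allelematrix", "commoncropnames", "serverinfo"}
)


def _envelope(records: list, page: int, page_size: int, total: int) -> dict:
    meta = PaginationMeta.for_window(page, page_size, total)
    return {
        "metadata": {"pagination": meta.to_dict(), "status": [], "datafiles": []},
        "result": {"data": records},
    }


class MockBrapiBackend:
    """A minimal BrAPI v2.1 application over in-memory tables."""

    def __init__(
        self,
        name: str,
        crops: list[str],
        tables: dict[str, list[dict]],
        matrix: tuple[list[str], list[str], dict[str, list[list[str]]]] | None = None,
    ):
        self.name = name
        self.crops = list(crops)
        self.tables = tables
        self.matrix = matrix  # (variant_ids, callset_ids, {matrixName: grid})

    # -- request entry --------------------------------------------------

    def get(self, path: str, params: dict[str, list[str]]) -> tuple[int, dict]:
        parts = [p for p in path.strip("/").split("/") if p]
        if not parts:
            return 404, {"error": "no endpoint"}
        endpoint = parts[0].lower()
        if endpoint == "serverinfo":
            calls = sorted(set(self.tables) | ({"allelematrix"} if self.matrix else set()))
            return 200, {
                "metadata": _single_meta(),
                "result": {"calls": [{"service": c, "methods": ["GET"]} for c in calls]},
            }
        if endpoint == "commoncropnames":
            return 200, _envelope(self.crops, 0, max(len(self.crops), 1), len(self.crops))
        if endpoint == "allelematrix" and self.matrix is not None:
            return self._allelematrix(params)
        if endpoint in self.tables:
            if len(parts) == 1:
                return self._list(endpoint, params)
            if len(parts) == 2:
                return self._single(endpoint, parts[1])
        return 404, {"error": f"no such endpoint {path}"}

    # -- list endpoints --------------------------------------------------

    def _list(self, endpoint: str, params: dict[str, list[str]]) -> tuple[int, dict]:
        page = int(params.get("page", ["0"])[0])
        page_size = int(params.get("pageSize", ["1000"])[0])
        records = self.tables[endpoint]
        for key, values in params.items():
            if key in ("page", "pageSize"):
                continue
            wanted = set(values)
            records = [r for r in records if str(r.get(key)) in wanted]
        window = records[page * page_size: (page + 1) * page_size]
        return 200, _envelope(window, page, page_size, len(records))

    def _single(self, endpoint: str, local_id: str) -> tuple[int, dict]:
        id_field = ENTITY_ID_FIELD.get(endpoint)
        for record in self.tables[endpoint]:
            if record.get(id_field) == local_id:
                return 200, {"metadata": _single_meta(), "result": record}
        return 404, {"error": f"{local_id} not found"}

    # -- allele matrix ---------------------------------------------------

    def _callset_filter(self, params: dict[str, list[str]]) -> set[str] | None:
        """Callset ids admitted by callSetDbId/sampleDbId/germplasmDbId filters."""
        callsets = self.tables.get("callsets", [])
        samples = self.tables.get("samples", [])
        allowed: set[str] | None = None

        def restrict(ids: set[str]):
            nonlocal allowed
            allowed = ids if allowed is None else allowed & ids

        if "callSetDbId" in params:
            restrict(set(params["callSetDbId"]))
        if "sampleDbId" in params:
            wanted = set(params["sampleDbId"])
            restrict({c["callSetDbId"] for c in callsets if c["sampleDbId"] in wanted})
        if "germplasmDbId" in params:
            wanted = set(params["germplasmDbId"])
            sample_ids = {s["sampleDbId"] for s in samples if s["germplasmDbId"] in wanted}
            restrict({c["callSetDbId"] for c in callsets if c["sampleDbId"] in sample_ids})
        return allowed

    def _allelematrix(self, params: dict[str, list[str]]) -> tuple[int, dict]:
        assert self.matrix is not None
        variant_ids, callset_ids, grids = self.matrix
        v_page = int(params.get("dimensionVariantPage", ["0"])[0])
        v_size = int(params.get("dimensionVariantPageSize", ["100"])[0])
        c_page = int(params.get("dimensionCallSetPage", ["0"])[0])
        c_size = int(params.get("dimensionCallSetPageSize", ["100"])[0])

        v_keep = list(range(len(variant_ids)))
        if "variantDbId" in params:
            wanted = set(params["variantDbId"])
            v_keep = [i for i in v_keep if variant_ids[i] in wanted]
        c_keep = list(range(len(callset_ids)))
        allowed = self._callset_filter(params)
        if allowed is not None:
            c_keep = [j for j in c_keep if callset_ids[j] in allowed]

        v_win = v_keep[v_page * v_size: (v_page + 1) * v_size]
        c_win = c_keep[c_page * c_size: (c_page + 1) * c_size]
        data_matrices = [
            {
                "dataMatrixName": name,
                "dataType": "string",
                "dataMatrix": [[grid[i][j] for j in c_win] for i in v_win],
            }
            for name, grid in grids.items()
        ]
        pagination = [
            {
                "dimension": "VARIANTS",
                "page": v_page,
                "pageSize": v_size,
                "totalCount": len(v_keep),
                "totalPages": -(-len(v_keep) // v_size),
            },
            {
                "dimension": "CALLSETS",
                "page": c_page,
                "pageSize": c_size,
                "totalCount": len(c_keep),
                "totalPages": -(-len(c_keep) // c_size),
            },
        ]
        return 200, {
            "metadata": _single_meta(),
            "result": {
                "variantDbIds": [variant_ids[i] for i in v_win],
                "callSetDbIds": [callset_ids[j] for j in c_win],
                "dataMatrices": data_matrices,
                "pagination": pagination,
            },
        }


def _single_meta() -> dict:
    return {
        "pagination": {"currentPage": 0, "pageSize": 1, "totalCount": 1, "totalPages": 1},
        "status": [],
        "datafiles": [],
    }


# -- wiring a world into a federation ------------------------------------


def _crop_prefixes(crops: list[str]) -> dict[str, str]:
    prefixes: dict[str, str] = {}
    for crop in crops:
        base = crop[:3].lower()
        prefix = base
        n = 2
        while prefix in prefixes.values():
            prefix = f"{base}{n}"
            n += 1
        prefixes[crop] = prefix
    return prefixes


def world_backends(
    world: SyntheticWorld,
) -> tuple[list[BackendConfig], dict[str, MockBrapiBackend]]:
    """Backend configs plus in-process apps for a synthetic world."""
    configs: list[BackendConfig] = []
    apps: dict[str, MockBrapiBackend] = {}

    base = "mock://agent"
    configs.append(
        BackendConfig(
            name="agent", base_url=base, prefix="", endpoints=_RELATIONAL_ENDPOINTS
        )
    )
    apps[base] = MockBrapiBackend(
        "agent",
        list(world.spec.crops),
        {
            "germplasm": world.germplasm,
            "studies": world.studies,
            "observations": world.observations,
            "observationvariables": world.observation_variables,
        },
    )

    prefixes = _crop_prefixes(list(world.spec.crops))
    for crop in world.spec.crops:
        data = world.crops[crop]
        base = f"mock://{crop}"
        configs.append(
            BackendConfig(
                name=crop, base_url=base, prefix=prefixes[crop],
                endpoints=_GENOTYPE_ENDPOINTS,
            )
        )
        apps[base] = MockBrapiBackend(
            crop,
            [crop],
            {"samples": data.samples, "variants": data.variants, "callsets": data.callsets},
            matrix=(
                [v["variantDbId"] for v in data.variants],
                [c["callSetDbId"] for c in data.callsets],
                {"genotype": data.matrix},
            ),
        )
    return configs, apps


def federation_for_world(
    world: SyntheticWorld,
    tokens: tuple[str, ...] = (),
    separator: str = "-",
    missing_genotype: str = ".",
    on_backend_error: str = "fail",
) -> tuple[FederationConfig, InProcessTransport]:
    configs, apps = world_backends(world)
    config = FederationConfig(
        backends=tuple(configs),
        server_tokens=frozenset(tokens),
        separator=separator,
        missing_genotype=missing_genotype,
        on_backend_error=on_backend_error,
    )
    return config, InProcessTransport(apps)


@dataclass
class MockServerHandle:
    name: str
    base_url: str
    httpd: Any
    thread: threading.Thread

    def shutdown(self) -> None:
        self.httpd.shutdown()
        self.thread.join(timeout=5)
        self.httpd.server_close()


class _QuietHandler(WSGIRequestHandler):
    def log_message(self, fmt, *args):
        pass


def _wsgi_for(app: MockBrapiBackend):
    import json
    from urllib.parse import parse_qs

    def wsgi(environ, start_response):
        query = parse_qs(environ.get("QUERY_STRING", ""), keep_blank_values=True)
        status, body = app.get(environ.get("PATH_INFO", "/"), query)
        payload = json.dumps(body).encode("utf-8")
        reason = {200: "OK", 404: "Not Found"}.get(status, "Error")
        start_response(
            f"{status} {reason}",
            [("Content-Type", "application/json"), ("Content-Length", str(len(payload)))],
        )
        return [payload]

    return wsgi


def serve_world(
    world: SyntheticWorld, host: str = "127.0.0.1", ports: list[int] | None = None
) -> tuple[FederationConfig, list[MockServerHandle]]:
    """Serve the world's mock backends over HTTP.

    Returns the federation config rewritten with the live base URLs plus a
    handle per server (``shutdown()`` to stop).  Pass ``ports`` to pin port
    numbers; by default ephemeral ports are assigned by the OS.
    """
    configs, apps = world_backends(world)
    handles: list[MockServerHandle] = []
    live: list[BackendConfig] = []
    for i, cfg in enumerate(configs):
        app = apps[cfg.base_url]
        port = ports[i] if ports else 0
        httpd = make_server(host, port, _wsgi_for(app), handler_class=_QuietHandler)
        thread = threading.Thread(target=httpd.serve_forever, daemon=True)
        thread.start()
        base_url = f"http://{host}:{httpd.server_port}"
        handles.append(MockServerHandle(cfg.name, base_url, httpd, thread))
        live.append(
            BackendConfig(
                name=cfg.name, base_url=base_url, prefix=cfg.prefix,
                endpoints=cfg.endpoints,
            )
        )
    return FederationConfig(backends=tuple(live)), handles
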