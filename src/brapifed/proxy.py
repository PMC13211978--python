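"""The public federated BrAPI endpoint.

``FederationProxy`` owns the request pipeline: bearer-token authorization,
filter routing, totals probing, fetch planning, execution and response
enveloping.  It is transport-agnostic — ``dispatch`` takes and returns plain
Python structures — and ``wsgi_app``/``serve`` expose it over HTTP with the
standard library's WSGI stack.

Endpoint advertisement is config-driven: the proxy advertises exactly the
endpoints it implements AND at least one backend serves; the serverinfo
calls list, the OpenAPI document and live routing are generated from the
same set, so the three can never disagree.
"""

from __future__ import annotations

import json
import logging
import time
import uuid
from typing import Mapping
from wsgiref.simple_server import WSGIRequestHandler, make_server

from . import list_merge, matrix_merge
from .client import BackendClient, Transport, UrllibTransport
from .config import FederationConfig
from .errors import BackendError, FederationError, UnresolvableIdError
from .model import (
    ENTITY_ID_FIELD,
    LIST_ENDPOINTS,
    PaginationMeta,
    status_message,
)
from .namespace import namespace_record, resolve_id, route_filters
from .openapi import build_openapi, validate_openapi

logger = logging.getLogger("brapifed.proxy")

DEFAULT_PAGE_SIZE = 1000
DEFAULT_MATRIX_PAGE_SIZE = 100

#: routes that never require a token
_OPEN_ROUTES = {"serverinfo", "openapi.json", "docs"}


class FederationProxy:
    """Dispatch federated BrAPI requests over the configured backends."""

    def __init__(
        self,
        config: FederationConfig,
        transport: Transport | None = None,
        client: BackendClient | None = None,
        totals_ttl: float = 5.0,
    ):
        self.config = config
        if client is None:
            client = BackendClient(config, transport or UrllibTransport())
        self.client = client
        self.totals_cache = list_merge.TotalsCache(ttl=totals_ttl)

    # -- capability surface --------------------------------------------

    def advertised_endpoints(self) -> set[str]:
        """Endpoints implemented by the proxy and served by >= 1 backend."""
        served = {e for b in self.config.backends for e in b.endpoints}
        advertised = {"serverinfo"}
        for ep in (*LIST_ENDPOINTS, "allelematrix", "commoncropnames"):
            if ep in served:
                advertised.add(ep)
        return advertised

    def serverinfo_body(self) -> dict:
        calls = []
        for ep in sorted(self.advertised_endpoints()):
            calls.append(
                {
                    "service": ep,
                    "methods": ["GET"],
                    "versions": ["2.1"],
                    "contentTypes": ["application/json"],
                    "dataTypes": ["application/json"],
                }
            )
            if ep in LIST_ENDPOINTS:
                calls.append(
                    {
                        "service": f"{ep}/{{{ENTITY_ID_FIELD[ep]}}}",
                        "methods": ["GET"],
                        "versions": ["2.1"],
                        "contentTypes": ["application/json"],
                        "dataTypes": ["application/json"],
                    }
                )
        return {
            "metadata": _meta_single(),
            "result": {
                "calls": calls,
                "serverName": "brapifed federation proxy",
                "serverDescription": (
                    "Merged interface over "
                    + ", ".join(b.name for b in self.config.backends)
                ),
                "contactEmail": "",
                "documentationURL": "/openapi.json",
                "location": "",
                "organizationName": "",
                "organizationURL": "",
            },
        }

    def openapi_document(self) -> dict:
        doc = build_openapi(self.advertised_endpoints())
        validate_openapi(doc)
        return doc

    # -- request handling ----------------------------------------------

    def dispatch(
        self,
        method: str,
        path: str,
        query: Mapping[str, list[str]] | None = None,
        headers: Mapping[str, str] | None = None,
    ) -> tuple[int, dict]:
        """Handle one request; returns (HTTP status, JSON-serializable body)."""
        t0 = time.perf_counter()
        request_id = uuid.uuid4().hex[:8]
        query = {k: list(v) for k, v in (query or {}).items()}
        headers = {k.lower(): v for k, v in (headers or {}).items()}
        path = "/" + path.strip("/")
        if path.startswith("/brapi/v2"):
            path = path[len("/brapi/v2"):] or "/"
        parts = [p for p in path.split("/") if p]

        if method.upper() != "GET":
            return 405, _error_body(405, "only GET is supported")
        if not parts:
            return 404, _error_body(404, "no such endpoint")
        endpoint = parts[0].lower()

        if endpoint not in _OPEN_ROUTES and not self._authorized(headers):
            return 401, _error_body(401, "missing or invalid bearer token")

        try:
            status, body = self._route(endpoint, parts, query)
        except UnresolvableIdError as exc:
            status, body = 404, _error_body(404, str(exc))
        except BackendError as exc:
            status, body = 502, _error_body(502, f"federation error: {exc}")
        except FederationError as exc:
            status, body = 400, _error_body(400, str(exc))
        logger.info(
            "req=%s GET %s -> %d (%.1f ms, %d backend calls)",
            request_id,
            path,
            status,
            (time.perf_counter() - t0) * 1e3,
            len(self.client.call_log),
        )
        return status, body

    def _route(self, endpoint: str, parts: list[str], query: dict) -> tuple[int, dict]:
        if endpoint == "serverinfo" and len(parts) == 1:
            return 200, self.serverinfo_body()
        if endpoint == "openapi.json" and len(parts) == 1:
            return 200, self.openapi_document()
        if endpoint == "docs" and len(parts) == 1:
            return 200, {"documentationURL": "/openapi.json"}
        if endpoint not in self.advertised_endpoints():
            return 404, _error_body(404, f"no such endpoint: {endpoint}")
        if endpoint == "commoncropnames" and len(parts) == 1:
            return self._handle_crops(query)
        if endpoint == "allelematrix" and len(parts) == 1:
            return self._handle_allelematrix(query)
        if endpoint in LIST_ENDPOINTS:
            if len(parts) == 1:
                return self._handle_list(endpoint, query)
            if len(parts) == 2:
                return self._handle_single(endpoint, parts[1])
        return 404, _error_body(404, "no such endpoint")

    def _authorized(self, headers: Mapping[str, str]) -> bool:
        if not self.config.server_tokens:
            return True  # public phase: no tokens configured, open access
        auth = headers.get("authorization", "")
        if not auth.lower().startswith("bearer "):
            return False
        return auth[7:].strip() in self.config.server_tokens

    # -- endpoint handlers ---------------------------------------------

    def _handle_list(self, endpoint: str, query: dict) -> tuple[int, dict]:
        page = _int_param(query, "page", 0)
        page_size = _int_param(query, "pageSize", DEFAULT_PAGE_SIZE)
        if page < 0 or page_size < 1:
            return 400, _error_body(400, "page must be >= 0 and pageSize >= 1")
        params = {k: v for k, v in query.items() if k not in ("page", "pageSize")}
        routed = route_filters(params, self.config, endpoint)
        probe = list_merge.probe_totals(
            endpoint,
            routed,
            self.client,
            self.config,
            policy=self.config.on_backend_error,
            cache=self.totals_cache,
        )
        plan = list_merge.compute_fetch_plan(
            page, page_size, probe.totals, self.config.backends
        )
        merged = list_merge.execute_plan(
            plan, endpoint, routed, self.client, self.config,
            extra_status=probe.warnings,
        )
        return 200, merged.to_envelope()

    def _handle_single(self, endpoint: str, rendered_id: str) -> tuple[int, dict]:
        backend, local_id = resolve_id(rendered_id, self.config)
        if not backend.serves(endpoint):
            return 404, _error_body(
                404, f"backend {backend.name} does not serve {endpoint}"
            )
        record = self.client.fetch_record(backend, endpoint, local_id)
        if record is None:
            return 404, _error_body(404, f"{rendered_id} not found")
        return 200, {
            "metadata": _meta_single(),
            "result": namespace_record(record, backend, self.config.separator),
        }

    def _handle_allelematrix(self, query: dict) -> tuple[int, dict]:
        v_page = _int_param(query, "dimensionVariantPage", 0)
        v_size = _int_param(query, "dimensionVariantPageSize", DEFAULT_MATRIX_PAGE_SIZE)
        c_page = _int_param(query, "dimensionCallSetPage", 0)
        c_size = _int_param(query, "dimensionCallSetPageSize", DEFAULT_MATRIX_PAGE_SIZE)
        if min(v_page, c_page) < 0 or min(v_size, c_size) < 1:
            return 400, _error_body(400, "invalid 2D paging parameters")
        params = {
            k: v
            for k, v in query.items()
            if not k.startswith("dimension") and k not in ("page", "pageSize")
        }
        routed = route_filters(params, self.config, "allelematrix")
        merged = matrix_merge.filtered_matrix(
            params,
            v_page,
            v_size,
            c_page,
            c_size,
            routed,
            self.client,
            self.config,
            policy=self.config.on_backend_error,
        )
        return 200, merged.to_envelope()

    def _handle_crops(self, query: dict) -> tuple[int, dict]:
        page = _int_param(query, "page", 0)
        page_size = _int_param(query, "pageSize", DEFAULT_PAGE_SIZE)
        crops: list[str] = []
        for backend in self.config.backends_serving("commoncropnames"):
            fetched = self.client.fetch_page(
                backend, "commoncropnames", {}, page=0, page_size=DEFAULT_PAGE_SIZE
            )
            for crop in fetched.records:
                if crop not in crops:
                    crops.append(crop)
        window = crops[page * page_size: (page + 1) * page_size]
        meta = PaginationMeta.for_window(page, page_size, len(crops))
        return 200, {
            "metadata": {"pagination": meta.to_dict(), "status": [], "datafiles": []},
            "result": {"data": window},
        }


# -- helpers ------------------------------------------------------------


def _meta_single() -> dict:
    return {
        "pagination": {"currentPage": 0, "pageSize": 1, "totalCount": 1, "totalPages": 1},
        "status": [],
        "datafiles": [],
    }


def _error_body(status: int, message: str) -> dict:
    level = "ERROR" if status >= 400 else "INFO"
    return {
        "metadata": {
            "pagination": {"currentPage": 0, "pageSize": 0, "totalCount": 0, "totalPages": 0},
            "status": [status_message(message, level)],
            "datafiles": [],
        },
        "result": None,
    }


def _int_param(query: Mapping[str, list[str]], name: str, default: int) -> int:
    values = query.get(name)
    if not values:
        return default
    try:
        return int(values[0])
    except ValueError:
        raise FederationError(f"parameter {name} must be an integer") from None


# -- WSGI ----------------------------------------------------------------


def wsgi_app(proxy: FederationProxy):
    """Wrap a proxy in a WSGI callable."""
    from urllib.parse import parse_qs

    def app(environ, start_response):
        query = parse_qs(environ.get("QUERY_STRING", ""), keep_blank_values=True)
        headers = {}
        if environ.get("HTTP_AUTHORIZATION"):
            headers["authorization"] = environ["HTTP_AUTHORIZATION"]
        status, body = proxy.dispatch(
            environ.get("REQUEST_METHOD", "GET"),
            environ.get("PATH_INFO", "/"),
            query,
            headers,
        )
        payload = json.dumps(body).encode("utf-8")
        reasons = {200: "OK", 400: "Bad Request", 401: "Unauthorized",
                   404: "Not Found", 405: "Method Not Allowed", 502: "Bad Gateway"}
        start_response(
            f"{status} {reasons.get(status, 'Error')}",
            [("Content-Type", "application/json"),
             ("Content-Length", str(len(payload)))],
        )
        return [payload]

    return app


class _QuietHandler(WSGIRequestHandler):
    def log_message(self, fmt, *args):  # route access logs through logging
        logger.debug("%s %s", self.address_string(), fmt % args)


def serve(
    config: FederationConfig,
    port: int | None = None,
    host: str = "127.0.0.1",
    transport: Transport | None = None,
):  # pragma: no cover - exercised via CLI / manual runs
    """Serve the federation proxy over HTTP (blocking)."""
    proxy = FederationProxy(config, transport=transport)
    httpd = make_server(host, port if port is not None else config.port,
                        wsgi_app(proxy), handler_class=_QuietHandler)
    logger.info("serving federated BrAPI endpoint on %s:%d", host, httpd.server_port)
    httpd.serve_forever()
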