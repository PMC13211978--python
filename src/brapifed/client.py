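"""HTTP contract to underlying BrAPI backends.

``BackendClient`` builds requests, attaches per-backend bearer tokens,
retries transient failures (network errors and 5xx, with jittered
exponential backoff; 4xx are terminal since GETs are idempotent) and
validates response envelopes.  Every outbound attempt is appended to
``call_log`` so tests can assert minimal-fetch behaviour.

Two transports are provided: ``UrllibTransport`` for live HTTP and
``InProcessTransport``, which dispatches directly to in-process backend
applications (the test double used throughout the suite).
"""

from __future__ import annotations

import json
import random
import time
import urllib.error
import urllib.parse
import urllib.request
from dataclasses import dataclass
from typing import Any, Callable, Mapping, Protocol

from .config import BackendConfig, FederationConfig
from .errors import BackendHTTPError, BackendNetworkError, MalformedResponseError
from .model import (
    CALLSETS_DIM,
    VARIANTS_DIM,
    AlleleMatrixBlock,
    EntityPage,
    MatrixPagination,
    PaginationMeta,
)


@dataclass
class BackendCall:
    """One outbound request attempt, recorded for inspection."""

    backend: str
    endpoint: str
    params: dict[str, Any]
    attempt: int
    outcome: str  # ok | http-error(<status>) | network-error | malformed-body


class Transport(Protocol):
    def request(
        self,
        base_url: str,
        path: str,
        params: Mapping[str, Any],
        headers: Mapping[str, str],
        timeout: float,
    ) -> tuple[int, Any]:
        """Issue a GET; return (HTTP status, decoded JSON body).

        Raises ConnectionError for network-level failures.
        """
        ...


class UrllibTransport:
    """Live HTTP GET via the standard library."""

    def request(self, base_url, path, params, headers, timeout):
        query = urllib.parse.urlencode(
            [(k, v) for k, vs in params.items() for v in (vs if isinstance(vs, list) else [vs])]
        )
        url = f"{base_url}/{path.lstrip('/')}"
        if query:
            url = f"{url}?{query}"
        req = urllib.request.Request(url, headers=dict(headers), method="GET")
        try:
            with urllib.request.urlopen(req, timeout=timeout) as resp:
                body = resp.read()
                status = resp.status
        except urllib.error.HTTPError as exc:
            body = exc.read()
            status = exc.code
        except (urllib.error.URLError, TimeoutError, OSError) as exc:
            raise ConnectionError(str(exc)) from exc
        try:
            return status, json.loads(body.decode("utf-8"))
        except (ValueError, UnicodeDecodeError):
            return status, None


class InProcessTransport:
    """Dispatch to in-process mock backend applications, keyed by base URL.

    The application contract is ``app.get(path, params) -> (status, payload)``
    with ``params`` values normalized to lists of strings.
    """

    def __init__(self, apps: Mapping[str, Any] | None = None):
        self.apps = dict(apps or {})
        #: per-app callables tests may install to simulate outages
        self.fault_hooks: dict[str, Callable[[str, dict], None]] = {}

    def register(self, base_url: str, app: Any) -> None:
        self.apps[base_url] = app

    def request(self, base_url, path, params, headers, timeout):
        app = self.apps.get(base_url)
        if app is None:
            raise ConnectionError(f"no in-process app registered at {base_url}")
        norm = {
            k: [str(v) for v in (vs if isinstance(vs, list) else [vs])]
            for k, vs in params.items()
        }
        hook = self.fault_hooks.get(base_url)
        if hook is not None:
            hook(path, norm)  # may raise ConnectionError to fake an outage
        return app.get(path.lstrip("/"), norm)


class BackendClient:
    """Fetch pages and matrix blocks from configured backends."""

    def __init__(
        self,
        config: FederationConfig,
        transport: Transport,
        max_attempts: int = 3,
        backoff_base: float = 0.25,
        backoff_cap: float = 4.0,
        sleep: Callable[[float], None] = time.sleep,
        rng: random.Random | None = None,
    ):
        self.config = config
        self.transport = transport
        self.max_attempts = max_attempts
        self.backoff_base = backoff_base
        self.backoff_cap = backoff_cap
        self._sleep = sleep
        self._rng = rng or random.Random(0)
        self.call_log: list[BackendCall] = []

    # -- low level -----------------------------------------------------

    def _headers(self, backend: BackendConfig) -> dict[str, str]:
        headers = {"Accept": "application/json"}
        if backend.auth_token:
            headers["Authorization"] = f"Bearer {backend.auth_token}"
        return headers

    def _get(self, backend: BackendConfig, path: str, params: Mapping[str, Any]) -> Any:
        """GET with retry; returns the decoded JSON body."""
        last_exc: Exception | None = None
        for attempt in range(1, self.max_attempts + 1):
            call = BackendCall(backend.name, path, dict(params), attempt, "ok")
            try:
                status, body = self.transport.request(
                    backend.base_url, path, params, self._headers(backend), backend.timeout
                )
            except ConnectionError as exc:
                call.outcome = "network-error"
                self.call_log.append(call)
                last_exc = BackendNetworkError(backend.name, str(exc))
            else:
                if 200 <= status < 300:
                    self.call_log.append(call)
                    return body
                call.outcome = f"http-error({status})"
                self.call_log.append(call)
                if 400 <= status < 500:
                    raise BackendHTTPError(backend.name, status)
                last_exc = BackendHTTPError(backend.name, status)
            if attempt < self.max_attempts:
                delay = min(self.backoff_cap, self.backoff_base * (2 ** (attempt - 1)))
                self._sleep(delay * (0.5 + self._rng.random()))
        assert last_exc is not None
        raise last_exc

    # -- envelope parsing ----------------------------------------------

    @staticmethod
    def _parse_pagination(body: Any, backend: str) -> PaginationMeta:
        try:
            pag = body["metadata"]["pagination"]
            meta = PaginationMeta(
                currentPage=int(pag["currentPage"]),
                pageSize=int(pag["pageSize"]),
                totalCount=int(pag["totalCount"]),
                totalPages=int(pag["totalPages"]),
            )
            meta.validate()
            return meta
        except (KeyError, TypeError, ValueError) as exc:
            raise MalformedResponseError(backend, f"invalid pagination block: {exc}") from exc

    def fetch_page(
        self,
        backend: BackendConfig,
        endpoint: str,
        params: Mapping[str, Any],
        page: int,
        page_size: int,
    ) -> EntityPage:
        """Fetch one raw (un-namespaced) list page from a backend."""
        if not backend.serves(endpoint):
            # capability contract: no call, empty contribution
            return EntityPage(PaginationMeta.for_window(page, page_size, 0), [])
        merged = dict(params)
        merged["page"] = page
        merged["pageSize"] = page_size
        body = self._get(backend, endpoint, merged)
        if not isinstance(body, dict):
            raise MalformedResponseError(backend.name, "response body is not a JSON object")
        meta = self._parse_pagination(body, backend.name)
        data = body.get("result", {}).get("data")
        if not isinstance(data, list):
            raise MalformedResponseError(backend.name, "result.data missing or not a list")
        if len(data) > meta.pageSize:
            raise MalformedResponseError(
                backend.name, f"{len(data)} records exceed pageSize {meta.pageSize}"
            )
        status = body.get("metadata", {}).get("status") or []
        return EntityPage(meta, data, status)

    def fetch_record(self, backend: BackendConfig, endpoint: str, local_id: str) -> dict | None:
        """Fetch a single record via the /{endpoint}/{id} form; None if 404."""
        try:
            body = self._get(backend, f"{endpoint}/{local_id}", {})
        except BackendHTTPError as exc:
            if exc.status == 404:
                return None
            raise
        if not isinstance(body, dict) or not isinstance(body.get("result"), dict):
            raise MalformedResponseError(backend.name, "single-record result missing")
        return body["result"]

    def fetch_matrix(
        self,
        backend: BackendConfig,
        params: Mapping[str, Any],
        variant_page: int,
        variant_page_size: int,
        callset_page: int,
        callset_page_size: int,
    ) -> AlleleMatrixBlock:
        """Fetch one raw allele-matrix block (2D page) from a backend."""
        merged = dict(params)
        merged.update(
            dimensionVariantPage=variant_page,
            dimensionVariantPageSize=variant_page_size,
            dimensionCallSetPage=callset_page,
            dimensionCallSetPageSize=callset_page_size,
        )
        body = self._get(backend, "allelematrix", merged)
        if not isinstance(body, dict) or not isinstance(body.get("result"), dict):
            raise MalformedResponseError(backend.name, "allelematrix result missing")
        result = body["result"]
        try:
            pagination = {}
            for entry in result["pagination"]:
                mp = MatrixPagination(
                    dimension=str(entry["dimension"]).upper(),
                    page=int(entry["page"]),
                    pageSize=int(entry["pageSize"]),
                    totalCount=int(entry["totalCount"]),
                    totalPages=int(entry["totalPages"]),
                )
                pagination[mp.dimension] = mp
        except (KeyError, TypeError, ValueError) as exc:
            raise MalformedResponseError(backend.name, f"invalid 2D pagination: {exc}") from exc
        if set(pagination) != {VARIANTS_DIM, CALLSETS_DIM}:
            raise MalformedResponseError(
                backend.name, f"2D pagination must cover both dimensions, got {sorted(pagination)}"
            )
        block = AlleleMatrixBlock(
            variant_ids=list(result.get("variantDbIds", [])),
            callset_ids=list(result.get("callSetDbIds", [])),
            data_matrices=list(result.get("dataMatrices", [])),
            pagination=pagination,
            status=body.get("metadata", {}).get("status") or [],
        )
        block.validate(backend.name)
        return block
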