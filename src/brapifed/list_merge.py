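"""Merged pagination over concatenated backend lists.

The proxy presents the concatenation of N backend lists (in configured
backend order) as a single consistently paged list.  For a requested
``(page, pageSize)`` it computes the global item window
``[page*pageSize, page*pageSize + pageSize)``, intersects it with each
backend's span of the virtual concatenation, and fetches only the backend
pages (at the same pageSize) that cover the intersection — at most two
adjacent local pages per backend, since a window of length <= pageSize can
straddle at most one local page boundary.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field
from typing import Any, Mapping

from .client import BackendClient
from .config import BackendConfig, FederationConfig
from .errors import BackendError
from .model import EntityPage, PaginationMeta, status_message, tag_status
from .namespace import SKIP, namespace_record


@dataclass(frozen=True)
class Subrequest:
    """Pages to fetch from one backend and the slice of its items to keep."""

    backend: BackendConfig
    page_indices: tuple[int, ...]
    local_slice: tuple[int, int]  # half-open interval into the backend's items


@dataclass(frozen=True)
class FetchPlan:
    """The global window and the per-backend subrequests realizing it."""

    page: int
    page_size: int
    window: tuple[int, int]
    subrequests: tuple[Subrequest, ...]
    totals: tuple[int, ...]

    @property
    def total_count(self) -> int:
        return sum(self.totals)


@dataclass
class ProbeResult:
    """Per-backend outcome of the totals probe."""

    totals: list[int]
    warnings: list[dict[str, str]] = field(default_factory=list)
    excluded: set[str] = field(default_factory=set)


class TotalsCache:
    """Short-TTL cache of probed per-backend totals.

    Totals are a best-effort snapshot of read-mostly archives; the cache
    bounds probe traffic while iterating pages of one logical query.
    """

    def __init__(self, ttl: float = 5.0, clock=time.monotonic):
        self.ttl = ttl
        self._clock = clock
        self._entries: dict[Any, tuple[float, int]] = {}

    @staticmethod
    def _key(backend: str, endpoint: str, params: Mapping[str, Any]) -> tuple:
        return (
            backend,
            endpoint,
            tuple(sorted((k, tuple(v) if isinstance(v, list) else v) for k, v in params.items())),
        )

    def get(self, backend: str, endpoint: str, params: Mapping[str, Any]) -> int | None:
        key = self._key(backend, endpoint, params)
        hit = self._entries.get(key)
        if hit is None or self._clock() - hit[0] > self.ttl:
            return None
        return hit[1]

    def put(self, backend: str, endpoint: str, params: Mapping[str, Any], total: int) -> None:
        self._entries[self._key(backend, endpoint, params)] = (self._clock(), total)

    def invalidate(self) -> None:
        self._entries.clear()


def probe_totals(
    endpoint: str,
    routed: Mapping[str, Any],
    client: BackendClient,
    config: FederationConfig,
    policy: str = "fail",
    cache: TotalsCache | None = None,
) -> ProbeResult:
    """Read each backend's totalCount for the filtered query.

    A minimal probe request (page 0, pageSize 1) is issued per non-skipped
    backend; SKIP-marked backends contribute 0 without any call.  Under the
    ``degrade`` policy an unreachable backend is excluded with a warning
    instead of failing the federated request.
    """
    result = ProbeResult(totals=[])
    for backend in config.backends:
        params = routed.get(backend.name, SKIP)
        if params is SKIP or not backend.serves(endpoint):
            result.totals.append(0)
            continue
        cached = cache.get(backend.name, endpoint, params) if cache else None
        if cached is not None:
            result.totals.append(cached)
            continue
        try:
            page = client.fetch_page(backend, endpoint, params, page=0, page_size=1)
        except BackendError as exc:
            if policy == "degrade":
                result.totals.append(0)
                result.excluded.add(backend.name)
                result.warnings.append(
                    status_message(f"backend {backend.name} excluded: {exc}", "WARNING")
                )
                continue
            raise
        result.totals.append(page.pagination.totalCount)
        if cache:
            cache.put(backend.name, endpoint, params, page.pagination.totalCount)
    return result


def compute_fetch_plan(page: int, page_size: int, totals: list[int] | tuple[int, ...],
                       backends: tuple[BackendConfig, ...] | None = None) -> FetchPlan:
    """Translate a global (page, pageSize) into per-backend subrequests.

    ``backends`` (parallel to ``totals``) is attached to the subrequests when
    given; planning itself only needs the totals.
    """
    if page < 0:
        raise ValueError("page must be >= 0")
    if page_size < 1:
        raise ValueError("pageSize must be >= 1")
    totals = tuple(int(t) for t in totals)
    grand = sum(totals)
    start = page * page_size
    end = min(start + page_size, grand)
    subs: list[Subrequest] = []
    offset = 0
    for i, t in enumerate(totals):
        lo = max(start, offset) - offset
        hi = min(end, offset + t) - offset
        offset += t
        if hi <= lo:
            continue
        first_page = lo // page_size
        last_page = (hi - 1) // page_size
        backend = backends[i] if backends is not None else None
        subs.append(
            Subrequest(
                backend=backend,  # type: ignore[arg-type]
                page_indices=tuple(range(first_page, last_page + 1)),
                local_slice=(lo, hi),
            )
        )
    return FetchPlan(
        page=page,
        page_size=page_size,
        window=(start, end),
        subrequests=tuple(subs),
        totals=totals,
    )


def _fetch_slice(
    client: BackendClient,
    sub: Subrequest,
    endpoint: str,
    params: Mapping[str, Any],
    page_size: int,
) -> tuple[list[dict], list[dict]]:
    """Fetch the planned pages of one backend and cut out the local slice.

    Returns (records, status).  Raises ValueError when the backend returned
    fewer items than the probed total implied (stale totals).
    """
    lo, hi = sub.local_slice
    items: dict[int, dict] = {}
    status: list[dict] = []
    for p in sub.page_indices:
        page = client.fetch_page(sub.backend, endpoint, params, page=p, page_size=page_size)
        status.extend(tag_status(page.status, sub.backend.name))
        for j, rec in enumerate(page.records):
            items[p * page_size + j] = rec
    try:
        records = [items[k] for k in range(lo, hi)]
    except KeyError:
        raise ValueError(
            f"backend {sub.backend.name} returned fewer items than its probed total"
        ) from None
    return records, status


def execute_plan(
    plan: FetchPlan,
    endpoint: str,
    routed: Mapping[str, Any],
    client: BackendClient,
    config: FederationConfig,
    extra_status: list[dict] | None = None,
    _replanned: bool = False,
) -> EntityPage:
    """Fetch, slice, namespace and concatenate the planned subrequests.

    A backend serving fewer items than probed triggers one re-probe and
    replan; a second inconsistency yields a truncated page with a warning
    (documented eventual-consistency contract).
    """
    records: list[dict] = []
    status: list[dict] = list(extra_status or [])
    for sub in plan.subrequests:
        params = routed.get(sub.backend.name)
        assert params is not SKIP and params is not None
        try:
            got, sub_status = _fetch_slice(client, sub, endpoint, params, plan.page_size)
        except ValueError as exc:
            if not _replanned:
                probe = probe_totals(endpoint, routed, client, config, cache=None)
                fresh = compute_fetch_plan(
                    plan.page, plan.page_size, probe.totals, config.backends
                )
                return execute_plan(
                    fresh, endpoint, routed, client, config,
                    extra_status=extra_status, _replanned=True,
                )
            status.append(status_message(str(exc) + " (page truncated)", "WARNING"))
            continue
        records.extend(
            namespace_record(r, sub.backend, config.separator) for r in got
        )
        status.extend(sub_status)
    meta = PaginationMeta.for_window(plan.page, plan.page_size, plan.total_count)
    return EntityPage(meta, records, status)
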