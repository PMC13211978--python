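"""Block-diagonal merging of allele matrices with 2D pagination.

The federated allele matrix is the block-diagonal assembly of the backend
matrices: the global variant axis is the concatenation of backend variant
axes (in backend order), likewise the callset axis, and a cell pairing a
variant from one backend with a callset from another has no call — it is
filled with the configured missing-genotype string (VCF missing-call
convention, default ".").

Both axes are paged independently; each requested 2D page (a tile) is
realized by fetching, per backend, at most two adjacent local pages per
axis, exactly as in the 1D case.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Mapping

from .client import BackendClient
from .config import BackendConfig, FederationConfig
from .errors import BackendError
from .list_merge import Subrequest
from .model import (
    CALLSETS_DIM,
    VARIANTS_DIM,
    AlleleMatrixBlock,
    MatrixPagination,
    status_message,
    tag_status,
)
from .namespace import SKIP, render_id


@dataclass(frozen=True)
class BackendWindow:
    """One backend's contribution to a 2D tile: per-axis subrequests.

    Either axis may be absent (``None``) when the tile does not intersect
    the backend's span on that axis; the backend then contributes only the
    axis labels of the axis it does intersect (its cells lie outside the
    block diagonal and are fill-valued).
    """

    backend: BackendConfig
    variant_sub: Subrequest | None
    callset_sub: Subrequest | None


@dataclass(frozen=True)
class MatrixFetchPlan:
    variant_page: int
    variant_page_size: int
    callset_page: int
    callset_page_size: int
    variant_totals: tuple[int, ...]
    callset_totals: tuple[int, ...]
    windows: tuple[BackendWindow, ...]


@dataclass
class MergedMatrixPage:
    """One federated 2D page of the allele matrix."""

    variant_ids: list[str]
    callset_ids: list[str]
    data_matrices: list[dict[str, Any]]
    pagination: list[MatrixPagination]
    status: list[dict[str, str]] = field(default_factory=list)

    def to_envelope(self) -> dict[str, Any]:
        return {
            "metadata": {
                "pagination": {
                    "currentPage": 0,
                    "pageSize": 1,
                    "totalCount": 1,
                    "totalPages": 1,
                },
                "status": list(self.status),
                "datafiles": [],
            },
            "result": {
                "variantDbIds": list(self.variant_ids),
                "callSetDbIds": list(self.callset_ids),
                "dataMatrices": list(self.data_matrices),
                "pagination": [p.to_dict() for p in self.pagination],
            },
        }


def _axis_intersections(
    page: int, page_size: int, totals: tuple[int, ...]
) -> dict[int, tuple[tuple[int, ...], tuple[int, int]]]:
    """Backend index -> (local page indices, local slice) on one axis."""
    start = page * page_size
    end = min(start + page_size, sum(totals))
    out: dict[int, tuple[tuple[int, ...], tuple[int, int]]] = {}
    offset = 0
    for i, t in enumerate(totals):
        lo = max(start, offset) - offset
        hi = min(end, offset + t) - offset
        offset += t
        if hi <= lo:
            continue
        pages = tuple(range(lo // page_size, (hi - 1) // page_size + 1))
        out[i] = (pages, (lo, hi))
    return out


def plan_matrix_window(
    variant_page: int,
    variant_page_size: int,
    callset_page: int,
    callset_page_size: int,
    variant_totals: list[int] | tuple[int, ...],
    callset_totals: list[int] | tuple[int, ...],
    backends: tuple[BackendConfig, ...] | None = None,
) -> MatrixFetchPlan:
    """Intersect the requested 2D window with each backend's spans."""
    if variant_page_size < 1 or callset_page_size < 1:
        raise ValueError("page sizes must be >= 1")
    v_totals = tuple(int(t) for t in variant_totals)
    c_totals = tuple(int(t) for t in callset_totals)
    if len(v_totals) != len(c_totals):
        raise ValueError("variant and callset totals must cover the same backends")
    by_v = _axis_intersections(variant_page, variant_page_size, v_totals)
    by_c = _axis_intersections(callset_page, callset_page_size, c_totals)
    windows = []
    for i in range(len(v_totals)):
        v = by_v.get(i)
        c = by_c.get(i)
        if v is None and c is None:
            continue
        backend = backends[i] if backends is not None else None
        windows.append(
            BackendWindow(
                backend,  # type: ignore[arg-type]
                Subrequest(backend, v[0], v[1]) if v else None,  # type: ignore[arg-type]
                Subrequest(backend, c[0], c[1]) if c else None,  # type: ignore[arg-type]
            )
        )
    return MatrixFetchPlan(
        variant_page=variant_page,
        variant_page_size=variant_page_size,
        callset_page=callset_page,
        callset_page_size=callset_page_size,
        variant_totals=v_totals,
        callset_totals=c_totals,
        windows=tuple(windows),
    )


def fetch_matrix_blocks(
    plan: MatrixFetchPlan,
    routed: Mapping[str, Any],
    client: BackendClient,
) -> dict[str, AlleleMatrixBlock]:
    """Fetch each planned backend block (or axis labels) as one 2D request.

    The planned local pages per axis are contiguous (at most two adjacent
    pages), so a single backend request at a doubled page size covers them:
    page ``first//1`` at size ``pageSize`` when one page, else an aligned
    request per page.  For simplicity and strict BrAPI page semantics we
    fetch each (variant page x callset page) combination and stitch.
    """
    blocks: dict[str, AlleleMatrixBlock] = {}
    for win in plan.windows:
        params = routed.get(win.backend.name)
        if params is SKIP or params is None:
            continue
        v_pages = win.variant_sub.page_indices if win.variant_sub else (0,)
        c_pages = win.callset_sub.page_indices if win.callset_sub else (0,)
        v_ps = plan.variant_page_size if win.variant_sub else 1
        c_ps = plan.callset_page_size if win.callset_sub else 1
        fetched: dict[tuple[int, int], AlleleMatrixBlock] = {}
        for vp in v_pages:
            for cp in c_pages:
                fetched[(vp, cp)] = client.fetch_matrix(
                    win.backend, params, vp, v_ps, cp, c_ps
                )
        blocks[win.backend.name] = _stitch(fetched, v_pages, c_pages, v_ps, c_ps, win)
    return blocks


def _stitch(
    fetched: dict[tuple[int, int], AlleleMatrixBlock],
    v_pages: tuple[int, ...],
    c_pages: tuple[int, ...],
    v_ps: int,
    c_ps: int,
    win: BackendWindow,
) -> AlleleMatrixBlock:
    """Combine up to 2x2 fetched local tiles, then cut the planned slices."""
    # absolute local index -> label
    v_labels: dict[int, str] = {}
    c_labels: dict[int, str] = {}
    names: list[str] = []
    dtypes: dict[str, str] = {}
    cells: dict[str, dict[tuple[int, int], str]] = {}
    for (vp, cp), block in fetched.items():
        for r, vid in enumerate(block.variant_ids):
            v_labels[vp * v_ps + r] = vid
        for c, cid in enumerate(block.callset_ids):
            c_labels[cp * c_ps + c] = cid
        for dm in block.data_matrices:
            name = dm.get("dataMatrixName", "genotype")
            if name not in cells:
                cells[name] = {}
                names.append(name)
                dtypes[name] = dm.get("dataType", "string")
            for r, row in enumerate(dm.get("dataMatrix", [])):
                for c, value in enumerate(row):
                    cells[name][(vp * v_ps + r, cp * c_ps + c)] = value
    v_lo, v_hi = win.variant_sub.local_slice if win.variant_sub else (0, 0)
    c_lo, c_hi = win.callset_sub.local_slice if win.callset_sub else (0, 0)
    variant_ids = [v_labels[i] for i in range(v_lo, v_hi)]
    callset_ids = [c_labels[j] for j in range(c_lo, c_hi)]
    data_matrices = [
        {
            "dataMatrixName": name,
            "dataType": dtypes[name],
            "dataMatrix": [
                [cells[name].get((i, j)) for j in range(c_lo, c_hi)]
                for i in range(v_lo, v_hi)
            ],
        }
        for name in names
    ]
    pagination = next(iter(fetched.values())).pagination if fetched else {}
    status = [s for b in fetched.values() for s in b.status]
    return AlleleMatrixBlock(variant_ids, callset_ids, data_matrices, pagination, status)


def assemble_matrix(
    plan: MatrixFetchPlan,
    blocks: Mapping[str, AlleleMatrixBlock],
    fill: str,
    config: FederationConfig,
    extra_status: list[dict] | None = None,
) -> MergedMatrixPage:
    """Assemble fetched backend blocks into the federated 2D page.

    Same-backend (variant, callset) cells are copied byte-for-byte from the
    backend grid; cross-backend cells equal ``fill``.  A matrix name present
    in only some backends is still emitted, with fill for absent blocks.
    """
    variant_ids: list[str] = []
    callset_ids: list[str] = []
    row_spans: dict[str, tuple[int, int]] = {}
    col_spans: dict[str, tuple[int, int]] = {}
    status: list[dict] = list(extra_status or [])
    for win in plan.windows:
        block = blocks.get(win.backend.name)
        prefix, sep = win.backend.prefix, config.separator
        if win.variant_sub is not None and block is not None:
            r0 = len(variant_ids)
            variant_ids.extend(render_id(prefix, v, sep) for v in block.variant_ids)
            row_spans[win.backend.name] = (r0, len(variant_ids))
        if win.callset_sub is not None and block is not None:
            c0 = len(callset_ids)
            callset_ids.extend(render_id(prefix, c, sep) for c in block.callset_ids)
            col_spans[win.backend.name] = (c0, len(callset_ids))
        if block is not None:
            status.extend(tag_status(block.status, win.backend.name))

    names: list[str] = []
    dtypes: dict[str, str] = {}
    for win in plan.windows:
        block = blocks.get(win.backend.name)
        if block is None:
            continue
        for dm in block.data_matrices:
            name = dm.get("dataMatrixName", "genotype")
            if name not in names:
                names.append(name)
                dtypes[name] = dm.get("dataType", "string")

    merged_matrices = []
    for name in names:
        grid = [[fill] * len(callset_ids) for _ in range(len(variant_ids))]
        for win in plan.windows:
            block = blocks.get(win.backend.name)
            if block is None:
                continue
            rows = row_spans.get(win.backend.name)
            cols = col_spans.get(win.backend.name)
            if rows is None or cols is None:
                continue  # off-diagonal only: stays fill
            source = next(
                (dm for dm in block.data_matrices if dm.get("dataMatrixName", "genotype") == name),
                None,
            )
            if source is None:
                continue  # matrix absent in this backend: stays fill
            for r, row in enumerate(source["dataMatrix"]):
                for c, value in enumerate(row):
                    grid[rows[0] + r][cols[0] + c] = value
        merged_matrices.append(
            {"dataMatrixName": name, "dataType": dtypes[name], "dataMatrix": grid}
        )

    pagination = [
        MatrixPagination.for_window(
            VARIANTS_DIM, plan.variant_page, plan.variant_page_size, sum(plan.variant_totals)
        ),
        MatrixPagination.for_window(
            CALLSETS_DIM, plan.callset_page, plan.callset_page_size, sum(plan.callset_totals)
        ),
    ]
    return MergedMatrixPage(variant_ids, callset_ids, merged_matrices, pagination, status)


def probe_matrix_totals(
    routed: Mapping[str, Any],
    client: BackendClient,
    config: FederationConfig,
    policy: str = "fail",
) -> tuple[list[int], list[int], list[dict]]:
    """Per-backend (variantTotal, callSetTotal) for the filtered query."""
    v_totals: list[int] = []
    c_totals: list[int] = []
    warnings: list[dict] = []
    for backend in config.backends:
        params = routed.get(backend.name, SKIP)
        if params is SKIP or not backend.serves("allelematrix"):
            v_totals.append(0)
            c_totals.append(0)
            continue
        try:
            probe = client.fetch_matrix(backend, params, 0, 1, 0, 1)
        except BackendError as exc:
            if policy == "degrade":
                v_totals.append(0)
                c_totals.append(0)
                warnings.append(
                    status_message(f"backend {backend.name} excluded: {exc}", "WARNING")
                )
                continue
            raise
        v_totals.append(probe.pagination[VARIANTS_DIM].totalCount)
        c_totals.append(probe.pagination[CALLSETS_DIM].totalCount)
    return v_totals, c_totals, warnings


def filtered_matrix(
    params: Mapping[str, Any],
    variant_page: int,
    variant_page_size: int,
    callset_page: int,
    callset_page_size: int,
    routed: Mapping[str, Any],
    client: BackendClient,
    config: FederationConfig,
    policy: str = "fail",
) -> MergedMatrixPage:
    """Full federated allele-matrix request: probe, plan, fetch, assemble."""
    v_totals, c_totals, warnings = probe_matrix_totals(routed, client, config, policy)
    plan = plan_matrix_window(
        variant_page,
        variant_page_size,
        callset_page,
        callset_page_size,
        v_totals,
        c_totals,
        config.backends,
    )
    blocks = fetch_matrix_blocks(plan, routed, client)
    return assemble_matrix(
        plan, blocks, config.missing_genotype, config, extra_status=warnings
    )
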