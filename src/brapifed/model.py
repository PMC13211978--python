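"""Shared domain types: BrAPI response envelopes and pagination metadata.

BrAPI list responses wrap an ordered ``data`` list in a ``result`` object and
carry pagination plus status messages in ``metadata``.  Page indices are
0-based throughout (BrAPI convention).  The allele-matrix endpoint is the one
exception to the list shape: its result is a set of variants x callsets grids
with a two-entry pagination array, one entry per dimension.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Any, Iterable

from .errors import MalformedResponseError

#: List endpoints the proxy knows how to federate (plus their /{id} forms).
LIST_ENDPOINTS = (
    "germplasm",
    "samples",
    "studies",
    "observations",
    "observationvariables",
    "variants",
    "callsets",
)

#: All endpoints the proxy can expose.
ALL_ENDPOINTS = LIST_ENDPOINTS + ("allelematrix", "commoncropnames", "serverinfo")

#: Identifier-attribute stem -> the endpoint (entity type) it refers to.
#: Used both for /{entity}/{id} routing and for ownership-scoped namespacing:
#: a backend only qualifies identifiers of entity types it actually serves;
#: references to entity types held elsewhere keep their federation-wide form.
ID_FIELD_ENTITY = {
    "germplasmDbId": "germplasm",
    "sampleDbId": "samples",
    "studyDbId": "studies",
    "observationDbId": "observations",
    "observationVariableDbId": "observationvariables",
    "variantDbId": "variants",
    "callSetDbId": "callsets",
}

#: Singular identifier attribute of each entity endpoint.
ENTITY_ID_FIELD = {entity: stem for stem, entity in ID_FIELD_ENTITY.items()}

VARIANTS_DIM = "VARIANTS"
CALLSETS_DIM = "CALLSETS"


def total_pages(total_count: int, page_size: int) -> int:
    """Number of pages needed for ``total_count`` items (0 when empty)."""
    if page_size < 1:
        raise ValueError("pageSize must be >= 1")
    return math.ceil(total_count / page_size)


@dataclass(frozen=True)
class PaginationMeta:
    """BrAPI list pagination block (0-based ``currentPage``)."""

    currentPage: int
    pageSize: int
    totalCount: int
    totalPages: int

    @classmethod
    def for_window(cls, page: int, page_size: int, total_count: int) -> "PaginationMeta":
        return cls(
            currentPage=page,
            pageSize=page_size,
            totalCount=total_count,
            totalPages=total_pages(total_count, page_size),
        )

    def validate(self) -> None:
        if self.currentPage < 0 or self.totalCount < 0:
            raise ValueError("negative pagination fields")
        if self.pageSize < 1:
            raise ValueError("pageSize must be >= 1")
        if self.totalPages != total_pages(self.totalCount, self.pageSize):
            raise ValueError(
                f"totalPages {self.totalPages} inconsistent with "
                f"totalCount {self.totalCount} at pageSize {self.pageSize}"
            )

    def to_dict(self) -> dict[str, int]:
        return {
            "currentPage": self.currentPage,
            "pageSize": self.pageSize,
            "totalCount": self.totalCount,
            "totalPages": self.totalPages,
        }


@dataclass(frozen=True)
class MatrixPagination:
    """One dimension of the allele-matrix 2D pagination."""

    dimension: str  # VARIANTS or CALLSETS
    page: int
    pageSize: int
    totalCount: int
    totalPages: int

    @classmethod
    def for_window(
        cls, dimension: str, page: int, page_size: int, total_count: int
    ) -> "MatrixPagination":
        return cls(
            dimension=dimension,
            page=page,
            pageSize=page_size,
            totalCount=total_count,
            totalPages=total_pages(total_count, page_size),
        )

    def to_dict(self) -> dict[str, Any]:
        return {
            "dimension": self.dimension,
            "page": self.page,
            "pageSize": self.pageSize,
            "totalCount": self.totalCount,
            "totalPages": self.totalPages,
        }


# An EntityRecord is a plain (possibly nested) attribute map; identifier
# attributes are those whose name ends in "DbId" (or the plural "DbIds").
EntityRecord = dict[str, Any]


@dataclass
class EntityPage:
    """One BrAPI list response: pagination + ordered records + status."""

    pagination: PaginationMeta
    records: list[EntityRecord]
    status: list[dict[str, str]] = field(default_factory=list)

    def to_envelope(self) -> dict[str, Any]:
        return {
            "metadata": {
                "pagination": self.pagination.to_dict(),
                "status": list(self.status),
                "datafiles": [],
            },
            "result": {"data": list(self.records)},
        }


@dataclass
class AlleleMatrixBlock:
    """One backend's allele-matrix fragment.

    ``data_matrices`` entries are ``{"dataMatrixName", "dataType",
    "dataMatrix"}`` where ``dataMatrix`` is a rows-by-variants x
    columns-by-callsets grid of genotype strings.
    """

    variant_ids: list[str]
    callset_ids: list[str]
    data_matrices: list[dict[str, Any]]
    pagination: dict[str, MatrixPagination]  # keyed by dimension
    status: list[dict[str, str]] = field(default_factory=list)

    def validate(self, backend: str = "?") -> None:
        for dm in self.data_matrices:
            grid = dm.get("dataMatrix", [])
            if len(grid) != len(self.variant_ids):
                raise MalformedResponseError(
                    backend,
                    f"matrix {dm.get('dataMatrixName')!r} has {len(grid)} rows "
                    f"for {len(self.variant_ids)} variants",
                )
            for row in grid:
                if len(row) != len(self.callset_ids):
                    raise MalformedResponseError(
                        backend,
                        f"matrix {dm.get('dataMatrixName')!r} row width "
                        f"{len(row)} != {len(self.callset_ids)} callsets",
                    )


def status_message(message: str, message_type: str = "INFO") -> dict[str, str]:
    return {"message": message, "messageType": message_type}


def tag_status(status: Iterable[dict[str, str]], backend: str) -> list[dict[str, str]]:
    """Prefix backend provenance onto status messages from a sub-response."""
    return [
        {
            "message": f"[{backend}] {s.get('message', '')}",
            "messageType": s.get("messageType", "INFO"),
        }
        for s in status
    ]
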