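"""OpenAPI 3 document generation for the federated interface.

The document is generated from the set of endpoints the proxy actually
advertises, so the serverinfo calls list, the routing table and the OpenAPI
paths always agree.  ``validate_openapi`` is a structural validator for the
parts of the OpenAPI 3.0 object model the proxy emits.
"""

from __future__ import annotations

import re
from typing import Any, Iterable

from .model import CALLSETS_DIM, ENTITY_ID_FIELD, LIST_ENDPOINTS, VARIANTS_DIM

_PAGING_PARAMS = [
    {
        "name": "page",
        "in": "query",
        "required": False,
        "description": "0-based page index",
        "schema": {"type": "integer", "minimum": 0},
    },
    {
        "name": "pageSize",
        "in": "query",
        "required": False,
        "description": "items per page",
        "schema": {"type": "integer", "minimum": 1},
    },
]

_MATRIX_PARAMS = [
    {"name": name, "in": "query", "required": False, "schema": {"type": "integer"}}
    for name in (
        "dimensionVariantPage",
        "dimensionVariantPageSize",
        "dimensionCallSetPage",
        "dimensionCallSetPageSize",
    )
] + [
    {
        "name": name,
        "in": "query",
        "required": False,
        "schema": {"type": "array", "items": {"type": "string"}},
        "explode": True,
    }
    for name in ("variantDbId", "callSetDbId", "sampleDbId", "germplasmDbId")
]

_LIST_FILTERS: dict[str, list[str]] = {
    "germplasm": ["germplasmDbId", "germplasmName", "commonCropName"],
    "samples": ["sampleDbId", "germplasmDbId"],
    "studies": ["studyDbId", "studyType", "commonCropName"],
    "observations": ["observationDbId", "germplasmDbId", "studyDbId", "observationVariableName"],
    "observationvariables": ["observationVariableDbId", "observationVariableName"],
    "variants": ["variantDbId", "referenceName"],
    "callsets": ["callSetDbId", "sampleDbId"],
}


def _ok_response(description: str) -> dict[str, Any]:
    return {
        "200": {
            "description": description,
            "content": {"application/json": {"schema": {"type": "object"}}},
        },
        "401": {"description": "Missing or invalid bearer token"},
    }


def build_openapi(endpoints: Iterable[str], title: str = "Federated BrAPI endpoint") -> dict:
    """Build an OpenAPI 3.0 document covering exactly ``endpoints``."""
    endpoints = set(endpoints)
    paths: dict[str, Any] = {}
    if "serverinfo" in endpoints:
        paths["/serverinfo"] = {
            "get": {
                "summary": "Advertised calls and server metadata",
                "responses": _ok_response("Server info"),
            }
        }
    if "commoncropnames" in endpoints:
        paths["/commoncropnames"] = {
            "get": {
                "summary": "Union of crops across backends",
                "parameters": list(_PAGING_PARAMS),
                "responses": _ok_response("Crop names"),
            }
        }
    for ep in LIST_ENDPOINTS:
        if ep not in endpoints:
            continue
        filters = [
            {
                "name": f,
                "in": "query",
                "required": False,
                "schema": {"type": "array", "items": {"type": "string"}},
                "explode": True,
            }
            for f in _LIST_FILTERS.get(ep, [])
        ]
        paths[f"/{ep}"] = {
            "get": {
                "summary": f"Federated {ep} list",
                "parameters": list(_PAGING_PARAMS) + filters,
                "responses": _ok_response(f"Merged page of {ep}"),
            }
        }
        id_field = ENTITY_ID_FIELD[ep]
        paths[f"/{ep}/{{{id_field}}}"] = {
            "get": {
                "summary": f"Single {ep} record by federation-wide id",
                "parameters": [
                    {
                        "name": id_field,
                        "in": "path",
                        "required": True,
                        "schema": {"type": "string"},
                    }
                ],
                "responses": {
                    **_ok_response(f"One {ep} record"),
                    "404": {"description": "Unknown identifier"},
                },
            }
        }
    if "allelematrix" in endpoints:
        paths["/allelematrix"] = {
            "get": {
                "summary": (
                    f"Federated allele matrix with 2D pagination "
                    f"({VARIANTS_DIM} x {CALLSETS_DIM})"
                ),
                "parameters": list(_MATRIX_PARAMS),
                "responses": _ok_response("Merged allele-matrix page"),
            }
        }
    return {
        "openapi": "3.0.3",
        "info": {
            "title": title,
            "version": "2.1",
            "description": "Single BrAPI v2.1 interface federating multiple backend endpoints.",
        },
        "components": {
            "securitySchemes": {
                "bearerAuth": {"type": "http", "scheme": "bearer"}
            }
        },
        "security": [{"bearerAuth": []}],
        "paths": paths,
    }


def validate_openapi(doc: Any) -> bool:
    """Structurally validate an OpenAPI 3.0 document; raise ValueError if bad."""

    def fail(msg: str):
        raise ValueError(f"invalid OpenAPI document: {msg}")

    if not isinstance(doc, dict):
        fail("root is not an object")
    version = doc.get("openapi")
    if not isinstance(version, str) or not version.startswith("3."):
        fail("missing or unsupported 'openapi' version string")
    info = doc.get("info")
    if not isinstance(info, dict) or "title" not in info or "version" not in info:
        fail("'info' must be an object with title and version")
    paths = doc.get("paths")
    if not isinstance(paths, dict) or not paths:
        fail("'paths' must be a non-empty object")
    for path, item in paths.items():
        if not path.startswith("/"):
            fail(f"path {path!r} must start with '/'")
        if not isinstance(item, dict):
            fail(f"path item for {path!r} is not an object")
        for method, op in item.items():
            if method not in ("get", "put", "post", "delete", "patch", "options", "head"):
                fail(f"unknown method {method!r} on {path!r}")
            if not isinstance(op, dict) or not isinstance(op.get("responses"), dict):
                fail(f"operation {method} {path} lacks a responses object")
            if not op["responses"]:
                fail(f"operation {method} {path} has empty responses")
            for param in op.get("parameters", []):
                if not isinstance(param, dict) or "name" not in param or "in" not in param:
                    fail(f"malformed parameter on {method} {path}")
                if param["in"] not in ("query", "path", "header", "cookie"):
                    fail(f"parameter {param.get('name')!r} has invalid location")
                if param["in"] == "path" and not param.get("required"):
                    fail(f"path parameter {param['name']!r} must be required")
            # every templated path segment must be declared as a path parameter
            declared = {
                p["name"] for p in op.get("parameters", []) if p.get("in") == "path"
            }
            templated = set(re.findall(r"\{([^}]+)\}", path))
            if templated != declared:
                fail(
                    f"path template variables {sorted(templated)} do not match "
                    f"declared path parameters {sorted(declared)} on {path}"
                )
    return True
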