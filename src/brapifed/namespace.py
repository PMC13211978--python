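"""Identifier namespacing across backends.

Several independent backends may reuse the same local identifiers (two
variant browsers both serving a ``V0001``), so the proxy qualifies
identifiers with a per-backend prefix on the way out and strips it on the
way in.  Resolution is by longest configured ``prefix + separator`` leading
match — never by splitting on the separator, which may legitimately occur
inside local identifiers.

Ownership scoping
-----------------
A record's identifier attributes (names ending in ``DbId`` / ``DbIds``) are
qualified with the backend's prefix only when the entity type they denote is
one the backend itself serves.  An attribute referring to an entity type
held by another member of the federation (for example a genotype backend's
``germplasmDbId``, when germplasm live in the passport database) is an
external reference: it already carries the federation-wide form and is
passed through untouched, resolving via the fallback backend.  Identifier
attributes with no known entity mapping (``referenceDbId`` and similar
infrastructure ids) are treated as backend-owned, which preserves
within-backend referential integrity by construction.
"""

from __future__ import annotations

from typing import Any, Mapping

from .config import BackendConfig, FederationConfig
from .errors import UnresolvableIdError
from .model import ID_FIELD_ENTITY


class _Skip:
    """Marker: this backend receives no call for the routed request."""

    _instance = None

    def __new__(cls):
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return "SKIP"


SKIP = _Skip()


def render_id(prefix: str, local_id: str, separator: str) -> str:
    """Federation-wide form of a backend-local identifier."""
    if prefix == "":
        return local_id
    return f"{prefix}{separator}{local_id}"


def resolve_id(rendered_id: str, config: FederationConfig) -> tuple[BackendConfig, str]:
    """Find the unique backend owning ``rendered_id``; strip its prefix.

    Longest-prefix match over ``prefix + separator``; the prefix-free config
    invariant guarantees at most one non-empty prefix can match.  Unprefixed
    identifiers fall back to the empty-prefix backend when one exists.
    """
    best: tuple[BackendConfig, str] | None = None
    for backend in config.backends:
        if backend.prefix == "":
            continue
        lead = backend.prefix + config.separator
        if rendered_id.startswith(lead):
            local = rendered_id[len(lead):]
            if best is None or len(backend.prefix) > len(best[0].prefix):
                best = (backend, local)
    if best is not None:
        return best
    fallback = config.fallback
    if fallback is not None:
        return fallback, rendered_id
    raise UnresolvableIdError(rendered_id)


def _id_field_stem(key: str) -> str | None:
    """Return the singular stem for an identifier attribute name, else None."""
    if key.endswith("DbId"):
        return key
    if key.endswith("DbIds"):
        return key[:-1]
    return None


def _owned_field(stem: str, backend: BackendConfig) -> bool:
    entity = ID_FIELD_ENTITY.get(stem)
    if entity is None:
        return True  # unknown id kinds stay within the backend
    if backend.serves(entity):
        return True
    # a backend serving the allele matrix owns its axis identifiers even
    # when it does not expose the corresponding list endpoints
    return entity in ("variants", "callsets") and backend.serves("allelematrix")


def namespace_record(
    record: Mapping[str, Any], backend: BackendConfig, separator: str
) -> dict[str, Any]:
    """Return a copy of ``record`` with owned identifier attributes qualified.

    Applied exactly once on the response path; non-identifier attributes are
    returned unchanged.  With an empty prefix this is the identity.
    """
    if backend.prefix == "":
        return dict(record)

    def walk(obj: Any) -> Any:
        if isinstance(obj, Mapping):
            out = {}
            for key, value in obj.items():
                stem = _id_field_stem(key)
                if stem is not None and _owned_field(stem, backend):
                    out[key] = _prefix_value(value, backend.prefix, separator)
                else:
                    out[key] = walk(value)
            return out
        if isinstance(obj, list):
            return [walk(v) for v in obj]
        return obj

    return walk(dict(record))


def _prefix_value(value: Any, prefix: str, separator: str) -> Any:
    if value is None:
        return None
    if isinstance(value, str):
        return render_id(prefix, value, separator)
    if isinstance(value, list):
        return [_prefix_value(v, prefix, separator) for v in value]
    return value


def route_filters(
    params: Mapping[str, Any],
    config: FederationConfig,
    endpoint: str | None = None,
) -> dict[str, Any]:
    """Partition a query-parameter map across backends.

    Returns ``{backend name: localized params}`` with ``SKIP`` for backends
    that must receive no call.  For each backend:

    * identifier filters on entity types the backend serves are resolved to
      local form; if such a filter is present but none of its values belong
      to the backend, the backend is SKIPped;
    * identifier filters on entity types the backend does not serve are
      external references and forwarded verbatim (match-based semantics);
    * non-identifier filters are forwarded verbatim to all non-skipped
      backends;
    * when ``endpoint`` is given, backends not serving it are SKIPped.

    Unresolvable identifier values are dropped (they match nothing) rather
    than raised, per BrAPI filter semantics.
    """
    routed: dict[str, Any] = {}
    for backend in config.backends:
        if endpoint is not None and not backend.serves(endpoint):
            routed[backend.name] = SKIP
            continue
        localized: dict[str, Any] = {}
        skip = False
        for key, raw in params.items():
            stem = _id_field_stem(key)
            if stem is None or not _owned_field(stem, backend):
                localized[key] = raw
                continue
            values = raw if isinstance(raw, list) else [raw]
            mine: list[str] = []
            for value in values:
                try:
                    owner, local = resolve_id(str(value), config)
                except UnresolvableIdError:
                    continue  # matches nothing anywhere
                if owner.name == backend.name:
                    mine.append(local)
            if not mine:
                skip = True
                break
            localized[key] = mine if isinstance(raw, list) else mine[0]
        routed[backend.name] = SKIP if skip else localized
    return routed
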