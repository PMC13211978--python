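"""Federation configuration: backends, prefixes, tokens.

The configuration is a single human-editable YAML file::

    server:
      port: 8080
      tokens: ["${PROXY_TOKEN}"]
    federation:
      separator: "-"
      missingGenotype: "."
      onBackendError: fail        # or "degrade"
    backends:
      - name: agent
        baseUrl: http://agent.example/brapi/v2
        prefix: ""
        endpoints: [germplasm, studies, observations]
      - name: barley
        baseUrl: http://divbrowse-barley.example/brapi/v2
        prefix: bar
        authToken: "${BARLEY_TOKEN}"
        endpoints: [samples, variants, callsets, allelematrix]

``${VAR}`` in token strings is interpolated from the environment at load
time.  Backend order in the file defines the global concatenation order of
merged results and is stable across requests.

Prefix rules enforced at load time (not per request): all non-empty prefixes
are pairwise distinct and none is a prefix of another, so longest-match
resolution is unambiguous; at most one backend may carry the empty prefix
and becomes the fallback for unprefixed identifiers.
"""

from __future__ import annotations

import os
import re
from dataclasses import dataclass, replace
from typing import Any, Iterable, Optional

import yaml

from .errors import ConfigError
from .model import ALL_ENDPOINTS

_ENV_RE = re.compile(r"\$\{([A-Za-z_][A-Za-z0-9_]*)\}")


def _interpolate(value: str) -> str:
    return _ENV_RE.sub(lambda m: os.environ.get(m.group(1), ""), value)


@dataclass(frozen=True)
class BackendConfig:
    """One underlying BrAPI endpoint of the federation."""

    name: str
    base_url: str
    prefix: str = ""
    auth_token: Optional[str] = None
    endpoints: frozenset[str] = frozenset()
    timeout: float = 30.0

    def serves(self, endpoint: str) -> bool:
        return endpoint in self.endpoints


@dataclass(frozen=True)
class FederationConfig:
    """The full federation: ordered backends plus proxy-level settings."""

    backends: tuple[BackendConfig, ...]
    server_tokens: frozenset[str] = frozenset()
    separator: str = "-"
    missing_genotype: str = "."
    on_backend_error: str = "fail"  # "fail" | "degrade"
    port: int = 8080

    def __post_init__(self) -> None:
        validate_backends(self.backends)
        if self.on_backend_error not in ("fail", "degrade"):
            raise ConfigError(
                f"onBackendError must be 'fail' or 'degrade', got {self.on_backend_error!r}"
            )

    @property
    def fallback(self) -> Optional[BackendConfig]:
        """The backend accepting unprefixed identifiers, if any."""
        for b in self.backends:
            if b.prefix == "":
                return b
        return None

    def backends_serving(self, endpoint: str) -> list[BackendConfig]:
        return [b for b in self.backends if b.serves(endpoint)]

    def backend(self, name: str) -> BackendConfig:
        for b in self.backends:
            if b.name == name:
                return b
        raise KeyError(name)


def validate_backends(backends: Iterable[BackendConfig]) -> None:
    backends = list(backends)
    if not backends:
        raise ConfigError("at least one backend must be configured")
    names = [b.name for b in backends]
    if len(set(names)) != len(names):
        raise ConfigError("backend names must be unique")
    prefixes = [b.prefix for b in backends]
    empties = [p for p in prefixes if p == ""]
    if len(empties) > 1:
        raise ConfigError("at most one backend may have an empty prefix")
    nonempty = [p for p in prefixes if p]
    if len(set(nonempty)) != len(nonempty):
        raise ConfigError("non-empty prefixes must be pairwise distinct")
    for i, p in enumerate(nonempty):
        for j, q in enumerate(nonempty):
            if i != j and q.startswith(p):
                raise ConfigError(
                    f"prefix {p!r} is a prefix of {q!r}; the prefix set must be prefix-free"
                )
    unknown = {e for b in backends for e in b.endpoints if e not in ALL_ENDPOINTS}
    if unknown:
        raise ConfigError(f"unknown endpoint names in config: {sorted(unknown)}")


def _as_backend(entry: dict[str, Any]) -> BackendConfig:
    if not isinstance(entry, dict):
        raise ConfigError(f"backend entry must be a mapping, got {type(entry).__name__}")
    try:
        name = str(entry["name"])
        base_url = str(entry["baseUrl"])
    except KeyError as exc:
        raise ConfigError(f"backend entry missing required key {exc}") from exc
    token = entry.get("authToken")
    if token is not None:
        token = _interpolate(str(token))
    endpoints = entry.get("endpoints", [])
    if not isinstance(endpoints, list):
        raise ConfigError(f"backend {name!r}: endpoints must be a list")
    return BackendConfig(
        name=name,
        base_url=base_url.rstrip("/"),
        prefix=str(entry.get("prefix", "")),
        auth_token=token,
        endpoints=frozenset(str(e).lower() for e in endpoints),
        timeout=float(entry.get("timeout", 30.0)),
    )


def config_from_dict(doc: dict[str, Any]) -> FederationConfig:
    if not isinstance(doc, dict):
        raise ConfigError("config root must be a mapping")
    server = doc.get("server", {}) or {}
    fed = doc.get("federation", {}) or {}
    raw_backends = doc.get("backends")
    if not raw_backends:
        raise ConfigError("config must declare at least one backend")
    backends = tuple(_as_backend(e) for e in raw_backends)
    tokens = frozenset(_interpolate(str(t)) for t in (server.get("tokens") or []))
    return FederationConfig(
        backends=backends,
        server_tokens=tokens,
        separator=str(fed.get("separator", "-")),
        missing_genotype=str(fed.get("missingGenotype", ".")),
        on_backend_error=str(fed.get("onBackendError", "fail")),
        port=int(server.get("port", 8080)),
    )


def load_config(path: str | os.PathLike) -> FederationConfig:
    """Load and validate a federation config file.

    Prefix-rule violations are rejected here, at load time, never at
    request time.
    """
    try:
        with open(path, "r", encoding="utf-8") as fh:
            doc = yaml.safe_load(fh)
    except FileNotFoundError as exc:
        raise ConfigError(f"config file not found: {path}") from exc
    except yaml.YAMLError as exc:
        raise ConfigError(f"config file {path} is not valid YAML: {exc}") from exc
    return config_from_dict(doc)


def config_to_dict(config: FederationConfig) -> dict[str, Any]:
    """Serialize a config back to the file dialect (round-trips load_config)."""
    return {
        "server": {
            "port": config.port,
            "tokens": sorted(config.server_tokens),
        },
        "federation": {
            "separator": config.separator,
            "missingGenotype": config.missing_genotype,
            "onBackendError": config.on_backend_error,
        },
        "backends": [
            {
                "name": b.name,
                "baseUrl": b.base_url,
                "prefix": b.prefix,
                **({"authToken": b.auth_token} if b.auth_token is not None else {}),
                "endpoints": sorted(b.endpoints),
                "timeout": b.timeout,
            }
            for b in config.backends
        ],
    }


def dump_config(config: FederationConfig) -> str:
    return yaml.safe_dump(config_to_dict(config), sort_keys=False)


def with_backends(config: FederationConfig, backends: Iterable[BackendConfig]) -> FederationConfig:
    return replace(config, backends=tuple(backends))
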