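"""Error taxonomy for the federation layer.

Every failure surfaced by the proxy maps to one of these classes so the
server module can translate them to HTTP statuses uniformly.
"""

from __future__ import annotations


class FederationError(Exception):
    """Base class for all federation-level failures."""


class ConfigError(FederationError):
    """Invalid federation configuration (load-time rejection)."""


class UnresolvableIdError(FederationError):
    """A namespaced identifier matches no configured backend prefix and
    no fallback backend exists."""

    def __init__(self, rendered_id: str):
        self.rendered_id = rendered_id
        super().__init__(f"identifier {rendered_id!r} matches no configured backend")


class BackendError(FederationError):
    """Failure talking to a single underlying backend."""

    def __init__(self, backend: str, message: str):
        self.backend = backend
        super().__init__(f"[{backend}] {message}")


class BackendHTTPError(BackendError):
    """Backend returned a non-2xx HTTP status."""

    def __init__(self, backend: str, status: int, message: str = ""):
        self.status = status
        super().__init__(backend, message or f"HTTP status {status}")


class BackendNetworkError(BackendError):
    """Backend unreachable after the configured retry budget."""


class MalformedResponseError(BackendError):
    """Backend response body failed envelope or dimension validation."""
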