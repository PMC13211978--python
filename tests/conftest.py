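"""Shared fixtures: synthetic federations and randomized mock builders."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from brapifed.client import BackendClient, InProcessTransport
from brapifed.config import BackendConfig, FederationConfig
from brapifed.mock_backend import MockBrapiBackend, federation_for_world
from brapifed.namespace import render_id
from brapifed.pipeline import LocalEndpoint
from brapifed.proxy import FederationProxy
from brapifed.synthetic import WorldSpec, generate_world

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=60,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


# -- randomized list federations ----------------------------------------


def make_list_federation(
    sizes: list[int],
    prefixes: list[str] | None = None,
    endpoint: str = "germplasm",
    tokens: tuple[str, ...] = (),
) -> tuple[FederationConfig, InProcessTransport]:
    """A federation of simple list backends with ``sizes[i]`` records each.

    Records are ``{<id field>: "G<j>", "germplasmName": "<backend>-item-<j>"}``
    so local ids deliberately collide across backends.
    """
    if prefixes is None:
        prefixes = [""] + [f"b{i}" for i in range(1, len(sizes))]
    backends = []
    apps = {}
    for i, (n, prefix) in enumerate(zip(sizes, prefixes)):
        name = f"backend{i}"
        base = f"mock://{name}"
        records = [
            {"germplasmDbId": f"G{j}", "germplasmName": f"{name}-item-{j}"}
            for j in range(n)
        ]
        backends.append(
            BackendConfig(
                name=name, base_url=base, prefix=prefix,
                endpoints=frozenset({endpoint, "serverinfo"}),
            )
        )
        apps[base] = MockBrapiBackend(name, [], {endpoint: records})
    config = FederationConfig(backends=tuple(backends), server_tokens=frozenset(tokens))
    return config, InProcessTransport(apps)


def concatenation_oracle(config: FederationConfig, transport: InProcessTransport,
                         endpoint: str = "germplasm") -> list[dict]:
    """Independent expectation: namespace every backend's full list, concatenate."""
    from brapifed.namespace import namespace_record

    out = []
    for backend in config.backends:
        app = transport.apps[backend.base_url]
        for record in app.tables[endpoint]:
            out.append(namespace_record(record, backend, config.separator))
    return out


def iterate_proxy_pages(proxy: FederationProxy, endpoint: str, page_size: int,
                        params: dict | None = None) -> list[dict]:
    """Collect every record by walking all pages of a federated endpoint."""
    records = []
    page = 0
    while True:
        query = {**(params or {}), "page": [str(page)], "pageSize": [str(page_size)]}
        status, body = proxy.dispatch("GET", f"/{endpoint}", query)
        assert status == 200, body
        meta = body["metadata"]["pagination"]
        records.extend(body["result"]["data"])
        if page >= meta["totalPages"] - 1:
            break
        page += 1
    return records


# -- randomized matrix federations --------------------------------------


def make_matrix_federation(
    dims: list[tuple[int, int]],
    fill: str = ".",
    seed: int = 0,
) -> tuple[FederationConfig, InProcessTransport, list]:
    """Backends serving only an allele matrix of the given (variants, callsets)."""
    rng = np.random.default_rng(seed)
    genotypes = np.array(["0/0", "0/1", "1/1", "."])
    backends = []
    apps = {}
    blocks = []
    for i, (nv, nc) in enumerate(dims):
        name = f"geno{i}"
        base = f"mock://{name}"
        vids = [f"V{j}" for j in range(nv)]
        cids = [f"C{j}" for j in range(nc)]
        grid = [[str(genotypes[rng.integers(4)]) for _ in range(nc)] for _ in range(nv)]
        backends.append(
            BackendConfig(
                name=name, base_url=base, prefix=f"g{i}",
                endpoints=frozenset({"allelematrix", "serverinfo"}),
            )
        )
        apps[base] = MockBrapiBackend(name, [], {}, matrix=(vids, cids, {"genotype": grid}))
        blocks.append((vids, cids, grid))
    config = FederationConfig(
        backends=tuple(backends), missing_genotype=fill,
    )
    return config, InProcessTransport(apps), blocks


def block_diagonal_oracle(config: FederationConfig, blocks: list, fill: str):
    """Expected merged axes and grid: block-diagonal assembly."""
    variant_ids = []
    callset_ids = []
    spans = []
    for backend, (vids, cids, _) in zip(config.backends, blocks):
        r0, c0 = len(variant_ids), len(callset_ids)
        variant_ids += [render_id(backend.prefix, v, config.separator) for v in vids]
        callset_ids += [render_id(backend.prefix, c, config.separator) for c in cids]
        spans.append((r0, c0))
    grid = [[fill] * len(callset_ids) for _ in range(len(variant_ids))]
    for (r0, c0), (vids, cids, block) in zip(spans, blocks):
        for r, row in enumerate(block):
            for c, val in enumerate(row):
                grid[r0 + r][c0 + c] = val
    return variant_ids, callset_ids, grid


# -- synthetic-world fixtures -------------------------------------------


@pytest.fixture(scope="session")
def small_world():
    return generate_world(WorldSpec(germplasm_per_crop=12, variants_per_crop=6), seed=7)


@pytest.fixture(scope="session")
def world_federation(small_world):
    config, transport = federation_for_world(small_world)
    return small_world, config, transport


@pytest.fixture()
def world_proxy(world_federation):
    world, config, transport = world_federation
    client = BackendClient(config, transport, sleep=lambda s: None)
    return world, FederationProxy(config, client=client)


@pytest.fixture()
def world_endpoint(world_proxy):
    world, proxy = world_proxy
    return world, LocalEndpoint(proxy)


def planted_global_id(world, config: FederationConfig) -> str:
    """Federation-wide id of the planted variant."""
    crop = world.spec.crops[0]
    backend = config.backend(crop)
    return render_id(backend.prefix, world.planted_variant_id, config.separator)
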