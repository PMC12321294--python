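"""Beacon v2 REST client: query construction, execution, federation.

A Beacon v2 service exposes the default-model entities (individuals,
biosamples, analyses, g_variants) plus the informational /filtering_terms
endpoint under ``https://{domain}/{entry_point}/``.  Queries are expressed as
GET parameters; multiple CURIE filters are comma-joined and combined with AND
semantics by the server.  Responses arrive as standard envelopes
(``meta`` + ``responseSummary`` + ``response.resultSets[].results``) whose
granularity may be boolean, count, or record depending on what the resource
grants.

Federation never raises across the network path: per-domain failures are
captured in that domain's :class:`BeaconResponseEnvelope` and partial results
are returned.
"""

from __future__ import annotations

import concurrent.futures
import json
import re
import time
import urllib.error
import urllib.parse
import urllib.request
import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping, Protocol, Sequence

import pandas as pd

from . import mapping as _mapping

__all__ = [
    "BeaconQuery",
    "BeaconResponseEnvelope",
    "FilteringTerm",
    "RequestDescriptor",
    "Transport",
    "UrllibTransport",
    "FixtureTransport",
    "TransportPolicy",
    "build_request",
    "fetch_entity",
    "fetch_counts",
    "fetch_filtering_terms",
    "fetch_multi_domain",
]

ENTITIES = ("individuals", "biosamples", "analyses", "g_variants")
ENTITY_TYPES = ENTITIES + ("filtering_terms", "counts")

_CURIE_RE = re.compile(r"^[A-Za-z_][A-Za-z0-9._-]*:\S+$")


@dataclass(frozen=True)
class BeaconQuery:
    """One user request against one or more Beacon domains."""

    entity_type: str
    filters: tuple[str, ...] = ()
    biosample_ids: tuple[str, ...] = ()
    individual_ids: tuple[str, ...] = ()
    domains: tuple[str, ...] = ()
    entry_points: tuple[str, ...] = ()
    limit: int = 0
    skip: int = 0
    count_entity: str = "biosamples"

    def __post_init__(self) -> None:
        if self.entity_type not in ENTITY_TYPES:
            raise ValueError(
                f"unknown entity_type {self.entity_type!r}; "
                f"valid: {', '.join(ENTITY_TYPES)}"
            )
        object.__setattr__(self, "filters", tuple(self.filters))
        object.__setattr__(self, "biosample_ids", tuple(self.biosample_ids))
        object.__setattr__(self, "individual_ids", tuple(self.individual_ids))
        object.__setattr__(self, "domains", tuple(self.domains))
        object.__setattr__(self, "entry_points", tuple(self.entry_points))
        for f in self.filters:
            if not f or not f.strip():
                raise ValueError("filters must be nonempty strings")
            if not _CURIE_RE.match(f):
                warnings.warn(f"filter {f!r} is not CURIE-shaped (prefix:suffix)")
        if self.domains and self.entry_points and len(self.domains) != len(self.entry_points):
            raise ValueError(
                f"domains ({len(self.domains)}) and entry_points "
                f"({len(self.entry_points)}) must be parallel lists"
            )
        if self.limit < 0 or self.skip < 0:
            raise ValueError("limit and skip must be non-negative")
        if self.entity_type == "counts" and not (
            self.filters or self.biosample_ids or self.individual_ids
        ):
            raise ValueError("entity_type='counts' requires at least one filter or id")
        if self.count_entity not in ENTITIES:
            raise ValueError(f"count_entity must be one of {ENTITIES}")

    def domain_pairs(self) -> list[tuple[str, str]]:
        entry_points = self.entry_points or ("beacon",) * len(self.domains)
        return list(zip(self.domains, entry_points))


@dataclass(frozen=True)
class RequestDescriptor:
    url: str
    params: Mapping[str, str]

    @property
    def full_url(self) -> str:
        if not self.params:
            return self.url
        return self.url + "?" + urllib.parse.urlencode(dict(self.params))


@dataclass
class BeaconResponseEnvelope:
    """Normalized per-domain response: records or a count or an error."""

    domain: str
    entity_type: str = ""
    granularity: str = "record"
    total_count: int | None = None
    records: list[dict] = field(default_factory=list)
    error: str | None = None
    elapsed: float = 0.0

    @property
    def ok(self) -> bool:
        return self.error is None


@dataclass(frozen=True)
class FilteringTerm:
    id: str
    label: str = ""
    scope: str | None = None
    type: str | None = None


@dataclass(frozen=True)
class TransportPolicy:
    timeout: float = 30.0
    retries: int = 2
    backoff: float = 0.5  # seconds, doubled per retry


class Transport(Protocol):
    def get(self, url: str, params: Mapping[str, str], timeout: float) -> str:
        """Return the response body for a GET, raising on transport failure."""


class UrllibTransport:
    """Plain stdlib HTTP transport with retry/backoff."""

    def __init__(self, policy: TransportPolicy = TransportPolicy()):
        self.policy = policy

    def get(self, url: str, params: Mapping[str, str], timeout: float) -> str:
        full = url + ("?" + urllib.parse.urlencode(dict(params)) if params else "")
        last: Exception | None = None
        for attempt in range(self.policy.retries + 1):
            try:
                with urllib.request.urlopen(full, timeout=timeout) as resp:
                    return resp.read().decode("utf-8")
            except Exception as exc:  # URLError, HTTPError, socket.timeout
                last = exc
                if attempt < self.policy.retries:
                    time.sleep(self.policy.backoff * (2**attempt))
        raise last  # type: ignore[misc]


class FixtureTransport:
    """Serves canned JSON responses from a fixture directory (offline mode).

    File layout matches :func:`pgxbeacon.mock.export_fixture_files`: one JSON
    per endpoint, named ``{entity}.json`` under ``{directory}/{domain}/``.
    Filters/paging are ignored — fixtures are point snapshots of one query.
    """

    def __init__(self, directory: str):
        self.directory = directory

    def get(self, url: str, params: Mapping[str, str], timeout: float) -> str:
        from pathlib import Path

        parsed = urllib.parse.urlparse(url)
        endpoint = parsed.path.rstrip("/").rsplit("/", 1)[-1]
        path = Path(self.directory) / parsed.netloc / f"{endpoint}.json"
        if not path.exists():
            raise FileNotFoundError(f"no fixture for {url} at {path}")
        return path.read_text(encoding="utf-8")


def build_request(
    query: BeaconQuery, domain: str, entry_point: str = "beacon"
) -> RequestDescriptor:
    """Build the GET request for one domain.

    ``counts`` targets the counted entity's endpoint with
    ``requestedGranularity=count``; filters are comma-joined (the Beacon v2
    GET convention — the server applies AND logic).
    """
    if not domain:
        raise ValueError("domain must be nonempty")
    endpoint = query.count_entity if query.entity_type == "counts" else query.entity_type
    scheme = "http" if domain.startswith(("localhost", "127.0.0.1")) else "https"
    url = f"{scheme}://{domain}/{entry_point.strip('/')}/{endpoint}"
    params: dict[str, str] = {}
    if query.filters:
        params["filters"] = ",".join(query.filters)
    if query.biosample_ids:
        params["biosampleIds"] = ",".join(query.biosample_ids)
    if query.individual_ids:
        params["individualIds"] = ",".join(query.individual_ids)
    if query.entity_type == "counts":
        params["requestedGranularity"] = "count"
    if query.limit:
        params["limit"] = str(query.limit)
    if query.skip:
        params["skip"] = str(query.skip)
    return RequestDescriptor(url=url, params=params)


def _parse_envelope(domain: str, entity_type: str, body: str) -> BeaconResponseEnvelope:
    doc = json.loads(body)
    meta = doc.get("meta", {})
    granularity = meta.get("returnedGranularity", "record")
    summary = doc.get("responseSummary", {})
    total = summary.get("numTotalResults")
    if total is None and "exists" in summary:
        granularity = granularity if granularity == "boolean" else "boolean"
        total = 1 if summary["exists"] else 0
    records: list[dict] = []
    response = doc.get("response", {})
    for result_set in response.get("resultSets", []):
        records.extend(result_set.get("results", []))
    if granularity != "record":
        records = []
    if total is None and granularity == "record":
        total = len(records)
    return BeaconResponseEnvelope(
        domain=domain,
        entity_type=entity_type,
        granularity=granularity,
        total_count=None if total is None else int(total),
        records=records,
    )


def fetch_entity(
    query: BeaconQuery,
    domain: str,
    entry_point: str = "beacon",
    transport: Transport | None = None,
    policy: TransportPolicy = TransportPolicy(),
) -> BeaconResponseEnvelope:
    """Execute one query against one domain; failures land in the envelope."""
    transport = transport or UrllibTransport(policy)
    started = time.perf_counter()
    try:
        request = build_request(query, domain, entry_point)
        body = transport.get(request.url, request.params, policy.timeout)
        envelope = _parse_envelope(domain, query.entity_type, body)
    except Exception as exc:
        envelope = BeaconResponseEnvelope(
            domain=domain,
            entity_type=query.entity_type,
            granularity="record",
            total_count=None,
            records=[],
            error=f"{type(exc).__name__}: {exc}",
        )
    envelope.elapsed = time.perf_counter() - started
    return envelope


def fetch_counts(
    query: BeaconQuery,
    transport: Transport | None = None,
    policy: TransportPolicy = TransportPolicy(),
    num_workers: int = 1,
) -> pd.DataFrame:
    """Record counts per domain: a (domain, entity, count) table.

    Failed domains yield a null count plus a warning; an all-fail federation
    returns an empty-count table, never an exception.
    """
    count_query = query if query.entity_type == "counts" else replace(
        query, entity_type="counts",
        count_entity=query.entity_type if query.entity_type in ENTITIES else "biosamples",
    )
    envelopes = _run_federated(count_query, transport, policy, num_workers)
    rows = []
    for env in envelopes:
        if env.ok:
            rows.append({"domain": env.domain, "entity": count_query.count_entity,
                         "count": env.total_count})
        else:
            warnings.warn(f"count query failed for {env.domain}: {env.error}")
            rows.append({"domain": env.domain, "entity": count_query.count_entity,
                         "count": None})
    table = pd.DataFrame(rows, columns=["domain", "entity", "count"], dtype=object)
    return table.where(pd.notna(table), None)


def fetch_filtering_terms(
    domain: str,
    entry_point: str = "beacon",
    patterns: Sequence[str] = (),
    transport: Transport | None = None,
    policy: TransportPolicy = TransportPolicy(),
) -> list[FilteringTerm]:
    """Filtering terms advertised by a domain, optionally pattern-matched.

    A term matches when ANY pattern is a case-insensitive substring of its id
    or label (so the pattern ``male`` matches the label ``Female``); an empty
    pattern list returns every term in server order.
    """
    transport = transport or UrllibTransport(policy)
    scheme = "http" if domain.startswith(("localhost", "127.0.0.1")) else "https"
    url = f"{scheme}://{domain}/{entry_point.strip('/')}/filtering_terms"
    try:
        body = transport.get(url, {}, policy.timeout)
        doc = json.loads(body)
    except Exception as exc:
        raise RuntimeError(f"filtering terms unsupported on {domain}: {exc}") from exc
    raw = doc.get("response", {}).get("filteringTerms")
    if raw is None:
        raise RuntimeError(f"filtering terms unsupported on {domain}: no term list in response")
    terms = [
        FilteringTerm(
            id=str(t.get("id", "")),
            label=str(t.get("label", "")),
            scope=t.get("scope"),
            type=t.get("type"),
        )
        for t in raw
        if t.get("id")
    ]
    if not patterns:
        return terms
    lowered = [p.lower() for p in patterns]
    return [
        t for t in terms
        if any(p in t.id.lower() or p in t.label.lower() for p in lowered)
    ]


def _flatten_envelope(
    envelope: BeaconResponseEnvelope, config: _mapping.MappingConfig
) -> pd.DataFrame:
    return _mapping.flatten_records(envelope.records, config, domain=envelope.domain)


def _run_federated(
    query: BeaconQuery,
    transport: Transport | None,
    policy: TransportPolicy,
    num_workers: int,
) -> list[BeaconResponseEnvelope]:
    pairs = query.domain_pairs()
    if not pairs:
        raise ValueError("query has no domains")
    if num_workers < 1:
        raise ValueError("num_workers must be >= 1")
    if num_workers == 1 or len(pairs) == 1:
        return [fetch_entity(query, d, e, transport, policy) for d, e in pairs]
    with concurrent.futures.ThreadPoolExecutor(max_workers=num_workers) as pool:
        futures = [
            pool.submit(fetch_entity, query, d, e, transport, policy) for d, e in pairs
        ]
        return [f.result() for f in futures]  # preserves domain order


def fetch_multi_domain(
    query: BeaconQuery,
    num_workers: int = 1,
    transport: Transport | None = None,
    policy: TransportPolicy = TransportPolicy(),
    config: _mapping.MappingConfig | None = None,
) -> tuple[list[BeaconResponseEnvelope], pd.DataFrame]:
    """Query every domain of *query* concurrently and merge the tables.

    Returns the per-domain envelopes (in domain order) plus the row-wise union
    of the flattened per-domain tables with a ``domain`` provenance column.
    The merged table is invariant to ``num_workers``; a failing domain
    contributes an error envelope and no rows.  Identical records returned by
    different domains are kept (deduplication is deliberately not attempted —
    provenance makes them distinguishable).
    """
    if query.entity_type not in ENTITIES:
        raise ValueError(f"fetch_multi_domain needs a record entity, not {query.entity_type!r}")
    envelopes = _run_federated(query, transport, policy, num_workers)
    config = config or _mapping.default_mapping(query.entity_type)
    tables = [_flatten_envelope(env, config) for env in envelopes if env.ok]
    merged = (
        _mapping.harmonize_tables(tables)
        if tables
        else pd.DataFrame(columns=["domain"] + config.column_names)
    )
    return envelopes, merged
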