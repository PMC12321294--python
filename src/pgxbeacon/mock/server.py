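"""A local Beacon-v2-shaped HTTP server over a generated cohort.

Serves ``/{entry_point}/{entity}`` and ``/{entry_point}/filtering_terms``
with standard envelopes (meta + responseSummary + response.resultSets),
honouring multi-filter AND semantics, ``limit``/``skip`` paging,
``requestedGranularity=count``, and ``/{entity}/{id}`` lookups.  Every answer
is computed on demand from the in-memory dataset, so server responses are
always reproducible by direct computation on the documents.

A fault plan makes failure modes deterministic for retry testing: the first
``n`` requests (or all, when ``n`` is None) return HTTP 500, malformed JSON,
or stall past the client timeout.
"""

from __future__ import annotations

import json
import threading
import time
import urllib.parse
from dataclasses import dataclass
from http.server import BaseHTTPRequestHandler, ThreadingHTTPServer

from .generate import MockDataset

__all__ = ["FaultPlan", "MockBeaconServer", "serve_mock"]

_ENTITIES = ("individuals", "biosamples", "analyses", "g_variants")


@dataclass
class FaultPlan:
    """mode: 'http500' | 'malformed' | 'timeout'; first_n=None means every request."""

    mode: str
    first_n: int | None = None
    delay: float = 2.0  # seconds to stall in 'timeout' mode

    def __post_init__(self) -> None:
        if self.mode not in ("http500", "malformed", "timeout"):
            raise ValueError(f"unknown fault mode {self.mode!r}")


def _envelope(granularity: str, total: int, results: list[dict] | None) -> dict:
    doc = {
        "meta": {
            "beaconId": "org.pgxbeacon.mock",
            "apiVersion": "v2.0",
            "returnedGranularity": granularity,
        },
        "responseSummary": {"exists": total > 0, "numTotalResults": total},
    }
    if granularity == "record":
        doc["response"] = {
            "resultSets": [
                {
                    "id": "mock",
                    "setType": "dataset",
                    "exists": total > 0,
                    "resultsCount": len(results or []),
                    "results": results or [],
                }
            ]
        }
    return doc


class _Handler(BaseHTTPRequestHandler):
    server: "MockBeaconServer.._Server"  # type: ignore[name-defined]

    def log_message(self, *args) -> None:  # silence request logging in tests
        pass

    def do_GET(self) -> None:  # noqa: N802 (http.server API)
        owner: MockBeaconServer = self.server.owner  # type: ignore[attr-defined]
        owner.request_count += 1
        fault = owner.fault
        if fault is not None and (fault.first_n is None or owner.request_count <= fault.first_n):
            if fault.mode == "http500":
                self.send_error(500, "injected fault")
                return
            if fault.mode == "malformed":
                self._send(200, "{this is not json", "application/json")
                return
            if fault.mode == "timeout":
                time.sleep(fault.delay)
                self.send_error(504, "injected stall")
                return
        try:
            status, body = owner.answer(self.path)
        except Exception as exc:  # pragma: no cover - defensive
            status, body = 500, json.dumps({"error": str(exc)})
        self._send(status, body, "application/json")

    def _send(self, status: int, body: str, ctype: str) -> None:
        data = body.encode("utf-8")
        self.send_response(status)
        self.send_header("Content-Type", ctype)
        self.send_header("Content-Length", str(len(data)))
        self.end_headers()
        self.wfile.write(data)


class MockBeaconServer:
    """Threaded local beacon; use as a context manager or call start()/stop()."""

    def __init__(
        self,
        dataset: MockDataset,
        entry_point: str = "beacon",
        port: int = 0,
        fault: FaultPlan | None = None,
    ):
        self.dataset = dataset
        self.entry_point = entry_point.strip("/")
        self.fault = fault
        self.request_count = 0
        try:
            self._server = ThreadingHTTPServer(("127.0.0.1", port), _Handler)
        except OSError as exc:
            raise RuntimeError(f"cannot bind mock beacon to port {port}: {exc}") from exc
        self._server.owner = self  # type: ignore[attr-defined]
        self._thread: threading.Thread | None = None

    @property
    def port(self) -> int:
        return self._server.server_address[1]

    @property
    def domain(self) -> str:
        return f"localhost:{self.port}"

    def start(self) -> "MockBeaconServer":
        self._thread = threading.Thread(target=self._server.serve_forever, daemon=True)
        self._thread.start()
        return self

    def stop(self) -> None:
        self._server.shutdown()
        self._server.server_close()
        if self._thread is not None:
            self._thread.join(timeout=5)

    def __enter__(self) -> "MockBeaconServer":
        return self.start()

    def __exit__(self, *exc) -> None:
        self.stop()

    # -- request answering (pure function of dataset + path) ------------------

    def answer(self, raw_path: str) -> tuple[int, str]:
        parsed = urllib.parse.urlparse(raw_path)
        parts = [p for p in parsed.path.split("/") if p]
        params = {k: v[0] for k, v in urllib.parse.parse_qs(parsed.query).items()}
        entry = self.entry_point.split("/")
        if parts[: len(entry)] != entry:
            return 404, json.dumps({"error": f"unknown entry point in {parsed.path}"})
        parts = parts[len(entry):]
        if not parts:
            return 404, json.dumps({"error": "no endpoint"})
        endpoint, rest = parts[0], parts[1:]

        if endpoint == "filtering_terms":
            terms = [
                {"id": t.id, "label": t.label, "scope": t.scope, "type": t.type}
                for t in self.dataset.filtering_terms
            ]
            return 200, json.dumps(
                {
                    "meta": {"beaconId": "org.pgxbeacon.mock", "returnedGranularity": "record"},
                    "response": {"filteringTerms": terms},
                }
            )
        if endpoint not in _ENTITIES:
            return 404, json.dumps({"error": f"unknown endpoint {endpoint!r}"})

        if rest:  # /{entity}/{id}
            wanted = rest[0]
            hits = [r for r in self.dataset.entity(endpoint) if r.get("id") == wanted]
            return 200, json.dumps(_envelope("record", len(hits), hits))

        filters = [f for f in params.get("filters", "").split(",") if f]
        records = self.dataset.matching_records(endpoint, filters)
        if params.get("biosampleIds"):
            wanted_bs = set(params["biosampleIds"].split(","))
            records = [
                r
                for r in records
                if (r.get("id") if endpoint == "biosamples" else r.get("biosampleId"))
                in wanted_bs
            ]
        if params.get("individualIds"):
            wanted_ind = set(params["individualIds"].split(","))
            records = [
                r
                for r in records
                if self.dataset.individual_of(r, endpoint) in wanted_ind
            ]
        total = len(records)
        if params.get("requestedGranularity") == "count":
            return 200, json.dumps(_envelope("count", total, None))
        skip = int(params.get("skip", 0))
        limit = int(params.get("limit", 0))
        page = records[skip:] if limit == 0 else records[skip : skip + limit]
        return 200, json.dumps(_envelope("record", total, page))


def serve_mock(
    dataset: MockDataset,
    port: int = 0,
    entry_point: str = "beacon",
    fault: FaultPlan | None = None,
) -> MockBeaconServer:
    """Start a mock beacon; returns the running server (caller stops it)."""
    return MockBeaconServer(dataset, entry_point=entry_point, port=port, fault=fault).start()
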