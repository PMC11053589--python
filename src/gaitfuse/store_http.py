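"""Thin HTTP binding for the metrics store (stdlib only).

Routes mirror the store semantics: ``GET /<endpoint>?<filters>`` returns
a JSON array of records, ``POST /<endpoint>`` with a JSON array body
inserts a batch. All filter/validation semantics live in
:mod:`gaitfuse.store`; this layer only translates HTTP. No TLS, no
authentication.
"""

from __future__ import annotations

import json
import threading
from http.server import BaseHTTPRequestHandler, ThreadingHTTPServer
from urllib.parse import urlsplit

from gaitfuse.errors import GaitFuseError, SchemaError
from gaitfuse.store import MetricsStore

__all__ = ["make_server", "serve_forever"]


def _make_handler(store: MetricsStore, lock: threading.Lock):
    class Handler(BaseHTTPRequestHandler):
        def log_message(self, *args):  # keep test output quiet
            pass

        def _send(self, code: int, payload) -> None:
            body = json.dumps(payload).encode()
            self.send_response(code)
            self.send_header("Content-Type", "application/json")
            self.send_header("Content-Length", str(len(body)))
            self.end_headers()
            self.wfile.write(body)

        def do_GET(self):
            parts = urlsplit(self.path)
            endpoint = parts.path.strip("/")
            try:
                with lock:
                    records = store.query(endpoint, parts.query)
                self._send(200, records)
            except SchemaError as exc:
                self._send(404, {"error": str(exc)})
            except GaitFuseError as exc:
                self._send(400, {"error": str(exc)})

        def do_POST(self):
            endpoint = urlsplit(self.path).path.strip("/")
            length = int(self.headers.get("Content-Length", 0))
            try:
                payload = json.loads(self.rfile.read(length) or b"null")
                if not isinstance(payload, list):
                    raise ValueError("request body must be a JSON array of objects")
                with lock:
                    count = store.insert(endpoint, payload)
                self._send(200, {"inserted": count})
            except SchemaError as exc:
                self._send(404, {"error": str(exc)})
            except (GaitFuseError, ValueError, json.JSONDecodeError) as exc:
                self._send(400, {"error": str(exc)})

    return Handler


def make_server(store: MetricsStore, host: str = "127.0.0.1", port: int = 0):
    """Create (but do not start) an HTTP server bound to the store."""
    return ThreadingHTTPServer((host, port), _make_handler(store, threading.Lock()))


def serve_forever(db_path: str, host: str, port: int) -> None:
    store = MetricsStore(db_path)
    server = make_server(store, host, port)
    try:
        server.serve_forever()
    finally:
        server.server_close()
        store.close()
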