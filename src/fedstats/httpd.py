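"""Thin HTTP+JSON transport over the in-process gateway.

A standard-library ``http.server`` wrapper exposing the four middleware
calls with their canonical verbs::

    POST  /connection     {"user", "secret"}          -> {"token"}
    GET   /microservice   X-Token header              -> descriptor
    PATCH /data           {"site", "csv"}             -> receipt
    GET   /result         ?expression=... + X-Token   -> result envelope

This is a development transport: deployment concerns (TLS, VPN, firewalls,
certificate management) are explicitly out of scope and belong to the
hosting environment.
"""

from __future__ import annotations

import json
import threading
import urllib.parse
import urllib.request
from http.server import BaseHTTPRequestHandler, ThreadingHTTPServer

from .federation import AuthError, Gateway
from .expression import ParseError, PolicyError
from .table import IngestionError


def _handler_for(gateway: Gateway):
    class Handler(BaseHTTPRequestHandler):
        def log_message(self, fmt, *args):  # gateway keeps its own log
            pass

        def _reply(self, status: int, payload: dict) -> None:
            body = json.dumps(payload).encode()
            self.send_response(status)
            self.send_header("Content-Type", "application/json")
            self.send_header("Content-Length", str(len(body)))
            self.end_headers()
            self.wfile.write(body)

        def _body(self) -> dict:
            n = int(self.headers.get("Content-Length", 0) or 0)
            if n == 0:
                return {}
            return json.loads(self.rfile.read(n).decode())

        def _token(self) -> str:
            return self.headers.get("X-Token", "")

        def _dispatch(self, method: str) -> None:
            path = urllib.parse.urlparse(self.path)
            try:
                if method == "POST" and path.path == "/connection":
                    token = gateway.request_connection(self._body())
                    self._reply(200, {"token": token})
                elif method == "GET" and path.path == "/microservice":
                    self._reply(200, gateway.request_microservice(self._token()))
                elif method == "PATCH" and path.path == "/data":
                    body = self._body()
                    receipt = gateway.upload_data(
                        self._token(), body.get("csv", ""), body.get("site"))
                    self._reply(200, receipt)
                elif method == "GET" and path.path == "/result":
                    q = urllib.parse.parse_qs(path.query)
                    expr = q.get("expression", [""])[0]
                    self._reply(200, gateway.request_result(self._token(), expr))
                else:
                    self._reply(404, {"error": "unknown endpoint"})
            except AuthError as exc:
                self._reply(401, {"error": str(exc)})
            except PolicyError as exc:
                self._reply(403, {"error": str(exc)})
            except (IngestionError, ParseError, KeyError, ValueError) as exc:
                self._reply(400, {"error": str(exc)})

        def do_POST(self):
            self._dispatch("POST")

        def do_GET(self):
            self._dispatch("GET")

        def do_PATCH(self):
            self._dispatch("PATCH")

    return Handler


def serve(gateway: Gateway, host: str = "127.0.0.1", port: int = 0
          ) -> ThreadingHTTPServer:
    """Start the HTTP transport on a background thread; returns the server
    (``server.server_address`` carries the bound port)."""
    server = ThreadingHTTPServer((host, port), _handler_for(gateway))
    thread = threading.Thread(target=server.serve_forever, daemon=True)
    thread.start()
    return server


# -- minimal client used by the CLI -----------------------------------------

class Client:
    def __init__(self, base_url: str) -> None:
        self.base_url = base_url.rstrip("/")
        self.token = ""

    def _call(self, method: str, path: str, body: dict | None = None,
              query: dict | None = None) -> dict:
        url = self.base_url + path
        if query:
            url += "?" + urllib.parse.urlencode(query)
        data = json.dumps(body).encode() if body is not None else None
        req = urllib.request.Request(url, data=data, method=method)
        req.add_header("Content-Type", "application/json")
        if self.token:
            req.add_header("X-Token", self.token)
        try:
            with urllib.request.urlopen(req) as resp:
                return json.loads(resp.read().decode())
        except urllib.error.HTTPError as exc:
            detail = exc.read().decode()
            raise RuntimeError(f"HTTP {exc.code}: {detail}") from exc

    def connect(self, user: str, secret: str) -> str:
        self.token = self._call("POST", "/connection",
                                {"user": user, "secret": secret})["token"]
        return self.token

    def microservice(self) -> dict:
        return self._call("GET", "/microservice")

    def upload(self, csv_text: str, site: str | None = None) -> dict:
        return self._call("PATCH", "/data", {"csv": csv_text, "site": site})

    def result(self, expression: str) -> dict:
        return self._call("GET", "/result", query={"expression": expression})
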