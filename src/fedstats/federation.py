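"""Three-node cluster simulator and the four-call researcher gateway.

The middleware contract has exactly four calls: request a connection
(POST), request the microservice descriptor (GET), upload data (PATCH) and
request a result (GET).  Uploads are parsed against the agreed data
dictionary, secret-shared, and the per-party share arrays are distributed to
the three compute nodes; the plaintext buffer is wiped.  Results flow back
only as aggregate envelopes.

Roles are separated per the study's access concept: a *site-uploader* may
only upload its own site's data; a *researcher* may only evaluate agreed
statistics.  Authentication itself is a stub credential check — transport
security (VPN, TLS, firewalls) belongs to deployment, not to this simulator,
and the transport is pluggable (in-process here, a thin HTTP wrapper in
``fedstats.httpd``).

Structured request logs carry metadata only; payload values never enter a
log line.
"""

from __future__ import annotations

import json
import secrets
import time
from dataclasses import dataclass, field

import numpy as np
import yaml

from . import ring as R
from .dictionary import default_dictionary
from .expression import Evaluator, ParseError, PolicyError
from .stats import AggregateResult, SecureStats
from .table import DataDictionary, IngestionError, PrivateTable, ingest_csv

ROLE_UPLOADER = "site-uploader"
ROLE_RESEARCHER = "researcher"

STATISTICS = ("freq", "mean", "median", "quantile", "min", "max", "length",
              "survival_table")


class AuthError(PermissionError):
    pass


class ClusterConfigError(ValueError):
    pass


@dataclass
class ClusterConfig:
    """Three compute nodes, the agreed dictionary, SDC threshold, seeds."""

    node_names: tuple = ("node-1", "node-2", "node-3")
    sdc_threshold: int = 0
    dictionary: DataDictionary | None = None
    seed: int | None = None  # None: OS entropy (production); int: test mode

    def __post_init__(self) -> None:
        if len(self.node_names) != 3:
            raise ClusterConfigError(
                f"exactly three compute nodes are required, got "
                f"{len(self.node_names)}")
        if self.dictionary is None:
            self.dictionary = default_dictionary()

    @classmethod
    def from_yaml(cls, text: str) -> "ClusterConfig":
        d = yaml.safe_load(text) or {}
        dictionary = None
        if "dictionary" in d:
            dictionary = DataDictionary.from_dict(d["dictionary"])
        return cls(
            node_names=tuple(d.get("node_names", ("node-1", "node-2", "node-3"))),
            sdc_threshold=int(d.get("sdc_threshold", 0)),
            dictionary=dictionary,
            seed=d.get("seed"),
        )


@dataclass
class ComputeNode:
    """One compute party: holds exactly one share of every cell."""

    name: str
    index: int
    shares: dict = field(default_factory=dict)  # table label -> {col: array}

    def store(self, label: str, table: PrivateTable) -> None:
        self.shares[label] = {
            name: col.values.party_share(self.index)
            for name, col in table.columns.items()
        }

    def state_arrays(self):
        """Everything this node knows — for privacy state inspection."""
        for tab in self.shares.values():
            yield from tab.values()


class Cluster:
    """The three-party computation cluster (single-process simulator)."""

    def __init__(self, config: ClusterConfig | None = None) -> None:
        self.config = config or ClusterConfig()
        self.nodes = [ComputeNode(n, i) for i, n in enumerate(self.config.node_names)]
        seed = self.config.seed
        self.store = R.TripleStore(seed=None if seed is None else seed + 1)
        self.input_rng = np.random.default_rng(seed)
        self.engine = SecureStats(self.store,
                                  sdc_threshold=self.config.sdc_threshold)
        self.tables: dict[str, PrivateTable] = {}

    def ingest(self, label: str, csv_text: str) -> PrivateTable:
        table = ingest_csv(csv_text, self.config.dictionary,
                           site_label=label, rng=self.input_rng)
        self.tables[label] = table
        for node in self.nodes:
            node.store(label, table)
        return table


@dataclass
class SessionToken:
    token: str
    user: str
    role: str
    issued_at: float


class Gateway:
    """Researcher/uploader-facing middleware over one cluster.

    Default accounts: ``munich``/``rome`` (site-uploaders) and ``analyst``
    (researcher), all with the stub secret ``"demo"`` unless configured.
    """

    def __init__(self, cluster: Cluster | None = None,
                 accounts: dict | None = None) -> None:
        self.cluster = cluster or Cluster()
        self.accounts = accounts or {
            "munich": {"secret": "demo", "role": ROLE_UPLOADER},
            "rome": {"secret": "demo", "role": ROLE_UPLOADER},
            "analyst": {"secret": "demo", "role": ROLE_RESEARCHER},
        }
        self.sessions: dict[str, SessionToken] = {}
        self.session_env: dict[str, dict] = {}
        self.log: list[str] = []

    # -- logging (metadata only, never payloads) -----------------------------

    def _log(self, method: str, path: str, user: str, status: int,
             **meta) -> None:
        entry = {"ts": round(time.time(), 3), "method": method, "path": path,
                 "user": user, "status": status, **meta}
        self.log.append(json.dumps(entry))

    # -- the four calls ------------------------------------------------------

    def request_connection(self, credentials: dict) -> str:
        """POST /connection — authenticate and issue a session token."""
        user = credentials.get("user", "")
        acct = self.accounts.get(user)
        if acct is None or acct["secret"] != credentials.get("secret"):
            self._log("POST", "/connection", user, 401)
            raise AuthError("unknown user or bad secret")
        token = secrets.token_hex(16)
        self.sessions[token] = SessionToken(token=token, user=user,
                                            role=acct["role"],
                                            issued_at=time.time())
        self.session_env[token] = {}
        self._log("POST", "/connection", user, 200, role=acct["role"])
        return token

    def _session(self, token: str, required_role: str | None = None
                 ) -> SessionToken:
        sess = self.sessions.get(token)
        if sess is None:
            raise AuthError("invalid or expired session token")
        if required_role is not None and sess.role != required_role:
            raise AuthError(
                f"role {sess.role!r} may not perform this call "
                f"(requires {required_role!r})")
        return sess

    def request_microservice(self, token: str) -> dict:
        """GET /microservice — the service descriptor."""
        sess = self._session(token)
        self._log("GET", "/microservice", sess.user, 200)
        return {
            "microservices": ["import_csv"],
            "statistics": list(STATISTICS),
            "dictionary_version": self.cluster.config.dictionary.version,
            "nodes": [n.name for n in self.cluster.nodes],
        }

    def upload_data(self, token: str, csv_payload: str,
                    site_label: str | None = None) -> dict:
        """PATCH /data — ingest one site's CSV into secret shares.

        The payload is parsed, shared across the three nodes and wiped; the
        receipt names the stored table label and its public shape only.
        """
        sess = self._session(token, required_role=ROLE_UPLOADER)
        label = site_label or sess.user
        try:
            table = self.cluster.ingest(label, csv_payload)
        except IngestionError as exc:
            self._log("PATCH", "/data", sess.user, 400,
                      table=label, error=type(exc).__name__)
            raise
        # drop the only reference to the plaintext payload
        del csv_payload
        self._log("PATCH", "/data", sess.user, 200, table=label,
                  n_rows=table.n_rows, n_columns=len(table.columns))
        return {"table": label, "n_rows": table.n_rows,
                "n_columns": len(table.columns),
                "dictionary_version": table.dictionary.version}

    def request_result(self, token: str, expression: str) -> dict:
        """GET /result — evaluate one statement of the session language."""
        sess = self._session(token, required_role=ROLE_RESEARCHER)
        evaluator = Evaluator(self.cluster.tables, self.cluster.engine,
                              env=self.session_env[token])
        try:
            result = evaluator.evaluate(expression)
        except (ParseError, PolicyError, KeyError) as exc:
            status = 403 if isinstance(exc, PolicyError) else 400
            self._log("GET", "/result", sess.user, status,
                      error=type(exc).__name__)
            raise
        self._log("GET", "/result", sess.user, 200,
                  kind=(result.statistic if isinstance(result, AggregateResult)
                        else "assignment"))
        envelope = {
            "request": expression,
            "server": "+".join(n.name for n in self.cluster.nodes),
        }
        if isinstance(result, AggregateResult):
            envelope["result"] = result.to_dict()
        else:
            envelope["result"] = result  # assignment acknowledgement
        return envelope
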