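"""Federation middleware: the four-call protocol, role separation, the
restricted expression language, log hygiene and node-state privacy."""

import json

import numpy as np
import pytest

from fedstats.dictionary import single_column_dictionary
from fedstats.expression import ParseError, PolicyError, parse
from fedstats.federation import (AuthError, Cluster, ClusterConfig,
                                 ClusterConfigError, Gateway)
from fedstats.table import IngestionError

from conftest import CONFORMANCE_AGES

TOY_DICT_YAML = """
sdc_threshold: 0
seed: 17
dictionary:
  version: toy
  columns:
    - {name: flag, kind: categorical, categories: ["no", "yes"]}
    - {name: x, kind: metric, categories: []}
"""


@pytest.fixture
def toy_gateway() -> Gateway:
    return Gateway(Cluster(ClusterConfig.from_yaml(TOY_DICT_YAML)))


def connect(gw, user):
    return gw.request_connection({"user": user, "secret": "demo"})


class TestClusterConfig:
    def test_exactly_three_nodes_required(self):
        with pytest.raises(ClusterConfigError):
            ClusterConfig(node_names=("a", "b"))
        with pytest.raises(ClusterConfigError):
            ClusterConfig(node_names=("a", "b", "c", "d"))

    def test_yaml_roundtrip(self):
        cfg = ClusterConfig.from_yaml(TOY_DICT_YAML)
        assert cfg.sdc_threshold == 0 and cfg.seed == 17
        assert cfg.dictionary.names == ["flag", "x"]


class TestFourCallProtocol:
    def test_end_to_end_toy_freq_matches_plaintext(self, toy_gateway):
        gw = toy_gateway
        up = connect(gw, "munich")
        assert "import_csv" in gw.request_microservice(up)["microservices"]
        gw.upload_data(up, "flag,x\nyes,1\nno,2\nyes,3\n", "site_a")
        up2 = connect(gw, "rome")
        gw.upload_data(up2, "flag,x\nyes,4\nno,5\nno,6\n", "site_b")
        rs = connect(gw, "analyst")
        gw.request_result(rs, 'a <- load("DS1", "site_a")')
        gw.request_result(rs, 'b <- load("DS1", "site_b")')
        res = gw.request_result(rs, "freq(c(a$flag, b$flag))")
        assert res["result"]["payload"] == {"no": 3, "yes": 3}

    def test_session_uses_exactly_four_call_types(self, toy_gateway):
        gw = toy_gateway
        up = connect(gw, "munich")
        gw.request_microservice(up)
        gw.upload_data(up, "flag,x\nyes,1\n", "s")
        rs = connect(gw, "analyst")
        gw.request_result(rs, 't <- load("DS1", "s")')
        gw.request_result(rs, "length(t$x)")
        seen = {(json.loads(l)["method"], json.loads(l)["path"])
                for l in gw.log}
        assert seen == {("POST", "/connection"), ("GET", "/microservice"),
                        ("PATCH", "/data"), ("GET", "/result")}

    def test_invalid_token_is_auth_error_without_state_change(self, toy_gateway):
        gw = toy_gateway
        with pytest.raises(AuthError):
            gw.upload_data("bogus-token", "flag,x\nyes,1\n")
        assert gw.cluster.tables == {}

    def test_role_separation(self, toy_gateway):
        gw = toy_gateway
        uploader = connect(gw, "munich")
        researcher = connect(gw, "analyst")
        with pytest.raises(AuthError):
            gw.request_result(uploader, "length(t$x)")
        with pytest.raises(AuthError):
            gw.upload_data(researcher, "flag,x\nyes,1\n")

    def test_malformed_csv_diagnostics(self, toy_gateway):
        gw = toy_gateway
        up = connect(gw, "munich")
        with pytest.raises(IngestionError, match="row 1"):
            gw.upload_data(up, "flag,x\nyes,notanumber\n", "s")

    def test_raw_column_request_is_policy_refusal(self, toy_gateway):
        gw = toy_gateway
        up = connect(gw, "munich")
        gw.upload_data(up, "flag,x\nyes,1\nno,2\n", "s")
        rs = connect(gw, "analyst")
        gw.request_result(rs, 't <- load("DS1", "s")')
        with pytest.raises(PolicyError):
            gw.request_result(rs, "t$x")
        with pytest.raises(PolicyError):
            gw.request_result(rs, "subset(t, flag == yes)")


class TestLogAndStateHygiene:
    UPLOAD = "flag,x\nyes,123.456\nno,789.25\n"

    def test_logs_contain_no_payload_values(self, toy_gateway):
        gw = toy_gateway
        up = connect(gw, "munich")
        gw.upload_data(up, self.UPLOAD, "s")
        rs = connect(gw, "analyst")
        gw.request_result(rs, 't <- load("DS1", "s")')
        gw.request_result(rs, "mean(t$x)")
        for line in gw.log:
            for needle in ("123.456", "789.25", "yes,", "flag,x"):
                assert needle not in line

    def test_no_plaintext_reachable_from_single_node(self, toy_gateway):
        """After upload, each node holds one uniform share per cell; no
        node's state decodes to the uploaded values."""
        gw = toy_gateway
        up = connect(gw, "munich")
        gw.upload_data(up, self.UPLOAD, "s")
        uploaded = {123.456, 789.25, 0.0, 1.0}
        ring = gw.cluster.tables["s"].column("x").values.ring
        for node in gw.cluster.nodes:
            for arr in node.state_arrays():
                decoded = set(np.round(ring.decode_fixed(arr), 3))
                assert not (decoded & uploaded)


class TestExpressionLanguage:
    def test_parse_error_carries_position(self):
        with pytest.raises(ParseError) as err:
            parse("freq(t$$x)")
        assert "position" in str(err.value)

    def test_unknown_function_rejected(self):
        with pytest.raises(ParseError):
            parse("drop(t$x)")

    def test_grammar_accepts_transcript_shapes(self):
        for text in (
            'tm <- load("DS1", "munich_production")',
            "quantile(tm$age)",
            "freq(c(tm$gender, tr$gender))",
            "length(c(tm$age, tr$age))",
            "freq(subset(tm, event_death == 0 & ecog_status == 0)$gender)",
        ):
            parse(text)

    def test_transcript_lengths_and_quantiles(self, site_csvs, rng):
        """24 + 24 rows pool to 48, and the conformance ages reproduce the
        printed single-site five-number summary through the session."""
        gw = Gateway(Cluster(ClusterConfig(
            dictionary=single_column_dictionary("age", "years"), seed=5)))
        ages_csv = "age\n" + "\n".join(str(v) for v in CONFORMANCE_AGES) + "\n"
        other_csv = "age\n" + "\n".join(
            str(float(v)) for v in np.linspace(40, 80, 24)) + "\n"
        up = connect(gw, "munich")
        gw.upload_data(up, ages_csv, "munich_production")
        up2 = connect(gw, "rome")
        gw.upload_data(up2, other_csv, "rome_production")
        rs = connect(gw, "analyst")
        gw.request_result(rs, 'tm <- load("DS1", "munich_production")')
        gw.request_result(rs, 'tr <- load("DS1", "rome_production")')
        assert gw.request_result(rs, "length(tm$age)")["result"]["payload"] == 24
        assert gw.request_result(rs, "length(tr$age)")["result"]["payload"] == 24
        assert gw.request_result(
            rs, "length(c(tm$age, tr$age))")["result"]["payload"] == 48
        q = gw.request_result(rs, "quantile(tm$age)")["result"]["payload"]
        assert q == [38.0, 62.5, 66.0, 72.25, 91.0]

    def test_masked_mean_matches_plaintext(self, toy_gateway):
        gw = toy_gateway
        up = connect(gw, "munich")
        gw.upload_data(up, "flag,x\nyes,1\nno,2\nyes,6\nno,10\n", "s")
        rs = connect(gw, "analyst")
        gw.request_result(rs, 't <- load("DS1", "s")')
        res = gw.request_result(rs, "mean(subset(t, flag == yes)$x)")
        assert res["result"]["payload"] == pytest.approx(3.5, abs=2**-10)


class TestHTTPTransport:
    def test_four_calls_over_http(self):
        from fedstats.httpd import Client, serve
        gw = Gateway(Cluster(ClusterConfig.from_yaml(TOY_DICT_YAML)))
        server = serve(gw, port=0)
        try:
            host, port = server.server_address
            base = f"http://{host}:{port}"
            up = Client(base)
            up.connect("munich", "demo")
            assert "import_csv" in up.microservice()["microservices"]
            receipt = up.upload("flag,x\nyes,1\nno,2\n", site="s")
            assert receipt["n_rows"] == 2
            rs = Client(base)
            rs.connect("analyst", "demo")
            rs.result('t <- load("DS1", "s")')
            res = rs.result("freq(t$flag)")
            assert res["result"]["payload"] == {"no": 1, "yes": 1}
            with pytest.raises(RuntimeError, match="401"):
                Client(base).connect("munich", "wrong")
        finally:
            server.shutdown()
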