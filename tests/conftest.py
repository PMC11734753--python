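"""Shared fixtures: in-process cohort servers and federated pools.

A "federation" here is several fully wired servers (datastore + access
control + profiles + sessions behind the WSGI REST layer) each holding
one synthetic cohort, plus a researcher pool connected to all of them
through in-process transports — the whole protocol without sockets.
"""

from __future__ import annotations

import pandas as pd
import pytest

from fedshield.client import WSGITransport, connect
from fedshield.server import ArmadilloServer, RestApi, ServerConfig
from fedshield.synthetic import demo_network

ADMIN = "admin@example.org"
RESEARCHER = "alice@example.org"


class Node:
    """One wired server with an admin and a granted researcher."""

    def __init__(self, tmp_path, label: str, clock=None):
        kwargs = {"clock": clock} if clock else {}
        self.label = label
        self.server = ArmadilloServer(
            ServerConfig(storage_root=str(tmp_path / label)), **kwargs
        )
        self.app = RestApi(self.server)
        self.transport = WSGITransport(self.app)
        self.server.access.register_user(ADMIN, is_admin=True)
        self.server.access.register_user(RESEARCHER)
        self.admin_token = self.server.access.issue_token(ADMIN).raw
        self.researcher_token = self.server.access.issue_token(RESEARCHER).raw

    def request(self, method, path, body=None, token=None):
        return self.transport.request(method, path, body, token)

    def publish(self, project: str, folder: str, name: str, df: pd.DataFrame,
                grant: bool = True):
        """Admin-side: create project, store a table, grant the researcher."""
        if not self.server.datastore.project_exists(project):
            self.server.datastore.create_project(project)
        ref = self.server.datastore.upload_table(project, folder, name, df, fmt="pandas")
        if grant:
            self.server.access.grant(self.admin_token, RESEARCHER, project)
        return ref

    def node_spec(self) -> dict:
        return {"label": self.label, "transport": self.transport,
                "token": self.researcher_token}


@pytest.fixture
def node(tmp_path) -> Node:
    return Node(tmp_path, "solo")


@pytest.fixture(scope="session")
def demo_tables():
    return demo_network(seed=2024)


@pytest.fixture
def federation(tmp_path, demo_tables):
    """Three demo cohorts, each on its own server, tables published."""
    tables, truth = demo_tables
    nodes = []
    for label, df in tables.items():
        n = Node(tmp_path, label)
        n.publish("demo", "core", "tbl", df)
        nodes.append(n)
    return nodes, tables, truth


@pytest.fixture
def pool(federation):
    nodes, _, _ = federation
    p = connect([n.node_spec() for n in nodes])
    p.assign_load("D", "demo", "core", "tbl")
    yield p
    p.close()


def concatenated(tables: dict) -> pd.DataFrame:
    return pd.concat(tables.values(), ignore_index=True)
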