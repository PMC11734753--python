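"""REST interface over the server modules.

A plain WSGI application (servable with ``wsgiref`` or any WSGI
container) exposing the data-management, access, profile and session
endpoints. Requests and responses are JSON; authentication is a bearer
token in the ``Authorization`` header. Table upload takes the CSV text
(or base64 parquet bytes) inside the JSON body.

The app is also directly callable in-process (see
:class:`fedshield.client.WSGITransport`), which is how a multi-node
federation is exercised without network sockets.
"""

from __future__ import annotations

import base64
import json
import re
import time
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .access_control import AccessControl, AuditLog, LocalTokenIssuer, Metrics
from .datastore import DataStore, SubsetManifest
from .disclosure_stats import PACKAGE_CATALOG
from .errors import FedShieldError, ForbiddenError, ValidationError
from .profiles import ProfileRegistry
from .session_engine import SessionManager


@dataclass
class ServerConfig:
    storage_root: str
    secret: str = "local-dev-secret"
    port: int = 8080
    token_ttl_seconds: float = 12 * 3600
    origin_allow_list: list[str] | None = None
    preview_cap: int = 10
    default_profile: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "ServerConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)


class ArmadilloServer:
    """Wires datastore, access control, profiles and sessions together."""

    def __init__(self, config: ServerConfig, clock=time.time):
        self.config = config
        root = Path(config.storage_root)
        self.datastore = DataStore(root / "data", preview_cap=config.preview_cap)
        issuer = LocalTokenIssuer(config.secret, config.token_ttl_seconds, clock)
        audit = AuditLog(root / "audit.jsonl", clock)
        self.access = AccessControl(
            issuer,
            audit,
            project_exists=self.datastore.project_exists,
            origin_allow_list=set(config.origin_allow_list)
            if config.origin_allow_list else None,
        )
        self.profiles = ProfileRegistry(PACKAGE_CATALOG, root / "profiles.json")
        self.sessions = SessionManager(
            self.datastore, self.access, self.profiles, root / "workspaces", clock
        )
        self.metrics = Metrics(clock, self.sessions.active_count)
        spec = dict(config.default_profile) or {
            "packages": {"base-stats"},
            "whitelist": {"base-stats"},
        }
        profile = self.profiles.create("default", **spec)
        self.profiles.start(profile.name)


# -- routing ---------------------------------------------------------

_ROUTES: list[tuple[str, re.Pattern, str]] = []


def route(method: str, pattern: str):
    compiled = re.compile("^" + pattern + "$")

    def wrap(fn):
        _ROUTES.append((method, compiled, fn.__name__))
        return fn

    return wrap


class RestApi:
    """Maps HTTP routes onto server operations; WSGI callable."""

    def __init__(self, server: ArmadilloServer):
        self.server = server

    # -- WSGI plumbing ----------------------------------------------

    def __call__(self, environ, start_response):
        method = environ["REQUEST_METHOD"]
        path = environ.get("PATH_INFO", "/")
        query = environ.get("QUERY_STRING", "")
        token = None
        auth = environ.get("HTTP_AUTHORIZATION", "")
        if auth.startswith("Bearer "):
            token = auth[len("Bearer "):]
        try:
            length = int(environ.get("CONTENT_LENGTH") or 0)
        except ValueError:
            length = 0
        raw = environ["wsgi.input"].read(length) if length else b""
        body = {}
        if raw:
            try:
                body = json.loads(raw)
            except json.JSONDecodeError:
                return self._respond(start_response, 400,
                                     {"error": "validation", "message": "invalid JSON body"})
        status, payload = self.dispatch(method, path, query, token, body)
        return self._respond(start_response, status, payload)

    @staticmethod
    def _respond(start_response, status: int, payload) -> list[bytes]:
        reasons = {200: "OK", 400: "Bad Request", 401: "Unauthorized",
                   403: "Forbidden", 404: "Not Found", 409: "Conflict",
                   503: "Service Unavailable", 500: "Internal Server Error"}
        data = json.dumps(payload).encode()
        start_response(
            f"{status} {reasons.get(status, 'OK')}",
            [("Content-Type", "application/json"),
             ("Content-Length", str(len(data)))],
        )
        return [data]

    def dispatch(self, method: str, path: str, query: str, token, body):
        for verb, pattern, fn_name in _ROUTES:
            if verb != method:
                continue
            match = pattern.match(path)
            if match:
                self.server.metrics.count(f"{verb} {pattern.pattern.strip('^$')}")
                try:
                    payload = getattr(self, fn_name)(token, body, query, **match.groupdict())
                    return 200, payload
                except FedShieldError as exc:
                    return exc.http_status, exc.to_payload()
        return 404, {"error": "not-found", "message": f"no route for {method} {path}"}

    # -- helpers -----------------------------------------------------

    def _admin(self, token) -> None:
        user = self.server.access.resolve(token)
        if user is None or not user.is_admin:
            subject = user.subject_id if user else "anonymous"
            self.server.access.audit.append(subject, "admin-api", "-", "denied")
            raise ForbiddenError("administrator role required")

    # -- auth --------------------------------------------------------

    @route("POST", "/auth/token")
    def issue_token(self, token, body, query):
        access_token = self.server.access.issue_token(
            body.get("subject_id", ""), body.get("origin_id", "")
        )
        return {"token": access_token.raw, "expires_at": access_token.expires_at}

    @route("PUT", r"/access/(?P<project>[^/]+)/(?P<subject>[^/]+)")
    def grant(self, token, body, query, project, subject):
        user = self.server.access.grant(token, subject, project)
        return {"subject_id": user.subject_id, "grants": sorted(user.grants)}

    @route("DELETE", r"/access/(?P<project>[^/]+)/(?P<subject>[^/]+)")
    def revoke(self, token, body, query, project, subject):
        user = self.server.access.revoke(token, subject, project)
        return {"subject_id": user.subject_id, "grants": sorted(user.grants)}

    @route("GET", "/audit")
    def read_audit(self, token, body, query):
        since = 0
        for part in query.split("&"):
            if part.startswith("since="):
                since = int(part.split("=", 1)[1] or 0)
        events = self.server.access.read_audit(token, since)
        return {"events": [e.to_payload() for e in events]}

    @route("GET", "/metrics")
    def read_metrics(self, token, body, query):
        self._admin(token)
        return self.server.metrics.snapshot()

    # -- projects & objects ------------------------------------------

    @route("PUT", r"/projects/(?P<project>[^/]+)")
    def create_project(self, token, body, query, project):
        self._admin(token)
        created = self.server.datastore.create_project(project)
        return {"name": created.name, "created_at": created.created_at}

    @route("GET", "/projects")
    def list_projects(self, token, body, query):
        self._admin(token)
        return {"projects": self.server.datastore.list_projects()}

    @route("DELETE", r"/projects/(?P<project>[^/]+)")
    def delete_project(self, token, body, query, project):
        self._admin(token)
        self.server.datastore.delete_project(project)
        return {"status": "deleted"}

    @route("POST", r"/projects/(?P<project>[^/]+)/objects")
    def upload_object(self, token, body, query, project):
        self._admin(token)
        fmt = body.get("format", "csv")
        if fmt == "csv":
            payload = body.get("payload", "")
        elif fmt == "parquet":
            payload = base64.b64decode(body.get("payload", ""))
        else:
            raise ValidationError(f"unsupported upload format {fmt!r}")
        ref = self.server.datastore.upload_table(
            project, body.get("folder", ""), body.get("name", ""),
            payload, fmt=fmt, overwrite=bool(body.get("overwrite", False)),
        )
        return ref.to_payload()

    @route("GET", r"/projects/(?P<project>[^/]+)/objects")
    def list_objects(self, token, body, query, project):
        # researchers with a grant may list names/schemas, never contents
        user = self.server.access.require(token, project, "list")
        assert user is not None
        return {"objects": [r.to_payload() for r in
                            self.server.datastore.list_objects(project)]}

    @route("GET", r"/projects/(?P<project>[^/]+)/objects/(?P<folder>[^/]+)/(?P<name>[^/]+)/preview")
    def preview(self, token, body, query, project, folder, name):
        self._admin(token)  # researchers never see previews
        return {"rows": self.server.datastore.preview(project, folder, name)}

    @route("DELETE", r"/projects/(?P<project>[^/]+)/objects/(?P<folder>[^/]+)/(?P<name>[^/]+)")
    def delete_object(self, token, body, query, project, folder, name):
        self._admin(token)
        self.server.datastore.delete_object(project, folder, name)
        return {"status": "deleted"}

    @route("POST", r"/projects/(?P<project>[^/]+)/subsets")
    def create_subsets(self, token, body, query, project):
        self._admin(token)
        manifest = SubsetManifest.from_csv(body.get("manifest", ""))
        refs = self.server.datastore.create_subsets_from_manifest(
            project, manifest, body.get("target_folder", "subsets"),
            overwrite=bool(body.get("overwrite", False)),
        )
        return {"tables": [r.to_payload() for r in refs]}

    # -- profiles ----------------------------------------------------

    @route("GET", "/profiles")
    def list_profiles(self, token, body, query):
        self._admin(token)
        return {"profiles": [p.to_payload() for p in self.server.profiles.list()]}

    @route("PUT", r"/profiles/(?P<name>[^/]+)")
    def create_profile(self, token, body, query, name):
        self._admin(token)
        profile = self.server.profiles.create(
            name,
            packages=set(body.get("packages", [])),
            whitelist=set(body.get("whitelist", [])),
            blacklist=set(body.get("blacklist", [])),
            options=body.get("options"),
        )
        return profile.to_payload()

    @route("DELETE", r"/profiles/(?P<name>[^/]+)")
    def delete_profile(self, token, body, query, name):
        self._admin(token)
        self.server.profiles.delete(name)
        return {"status": "deleted"}

    @route("POST", r"/profiles/(?P<name>[^/]+)/start")
    def start_profile(self, token, body, query, name):
        self._admin(token)
        profile, already = self.server.profiles.start(name)
        payload = profile.to_payload()
        if already:
            payload["warning"] = "profile already running"
        return payload

    @route("POST", r"/profiles/(?P<name>[^/]+)/stop")
    def stop_profile(self, token, body, query, name):
        self._admin(token)
        return self.server.profiles.stop(name).to_payload()

    # -- sessions ----------------------------------------------------

    @route("POST", "/sessions")
    def create_session(self, token, body, query):
        session = self.server.sessions.create_session(
            token, body.get("profile", "default")
        )
        return {"session_id": session.id, "profile": session.profile_name,
                "symbols": []}

    @route("DELETE", r"/sessions/(?P<sid>[^/]+)")
    def destroy_session(self, token, body, query, sid):
        self.server.sessions.destroy_session(sid, token)
        return {"status": "deleted"}

    @route("GET", r"/sessions/(?P<sid>[^/]+)/symbols")
    def list_symbols(self, token, body, query, sid):
        return self.server.sessions.list_symbols(sid, token)

    @route("POST", r"/sessions/(?P<sid>[^/]+)/symbols/(?P<symbol>[^/]+)")
    def assign(self, token, body, query, sid, symbol):
        op = body.get("op")
        if op == "load":
            return self.server.sessions.assign_load(
                sid, token, symbol,
                body.get("project", ""), body.get("folder", ""), body.get("name", ""),
            )
        if op == "expr":
            return self.server.sessions.assign_expr(
                sid, token, symbol, body.get("expression", {})
            )
        raise ValidationError("assign op must be 'load' or 'expr'")

    @route("POST", r"/sessions/(?P<sid>[^/]+)/aggregate")
    def aggregate(self, token, body, query, sid):
        return self.server.sessions.aggregate(
            sid, token, body.get("function", ""), body.get("args", {})
        )

    @route("POST", r"/sessions/(?P<sid>[^/]+)/workspaces/(?P<name>[^/]+)")
    def save_workspace(self, token, body, query, sid, name):
        ref = self.server.sessions.save_workspace(sid, token, name)
        return ref.to_payload()

    @route("POST", r"/workspaces/(?P<name>[^/]+)/restore")
    def restore_workspace(self, token, body, query, name):
        session = self.server.sessions.restore_workspace(
            token, name, body.get("profile", "default")
        )
        return {"session_id": session.id, "profile": session.profile_name,
                "symbols": sorted(session.symbols)}

    @route("GET", "/workspaces")
    def list_workspaces(self, token, body, query):
        return {"workspaces": self.server.sessions.list_workspaces(token)}


def create_app(config: ServerConfig, clock=time.time) -> RestApi:
    """Build a ready-to-serve WSGI app from a config."""
    return RestApi(ArmadilloServer(config, clock))


def serve(config: ServerConfig):  # pragma: no cover - interactive entry point
    from wsgiref.simple_server import make_server

    app = create_app(config)
    with make_server("", config.port, app) as httpd:
        print(f"fedshield server listening on port {config.port}")
        httpd.serve_forever()
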