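"""Authentication, project-level authorization and the audit trail.

The identity provider is pluggable: the shipped :class:`LocalTokenIssuer`
signs compact HMAC-SHA256 tokens with a server secret (standing in for
an external OpenID Connect provider), and any object implementing
``verify(token) -> claims`` can replace it. Authorization is a fixed
decision table — administrators manage data, granted researchers may
only analyse — and every decision is appended to an immutable audit log.

An optional origin allow-list reproduces the jump-host pattern where
data servers only accept connections from a whitelisted central analysis
server rather than from individual researcher machines.
"""

from __future__ import annotations

import base64
import hashlib
import hmac
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

from .errors import AuthError, ForbiddenError, NotFoundError, ValidationError

#: actions a granted researcher may perform on a granted project
RESEARCHER_ACTIONS = frozenset({"analyse", "list"})

#: all actions known to the server (anything else is denied by default)
ALL_ACTIONS = frozenset(
    {"upload", "preview", "grant", "analyse", "read_audit", "list", "delete", "manage_profiles"}
)


@dataclass
class User:
    subject_id: str
    email: str = ""
    is_admin: bool = False
    grants: set[str] = field(default_factory=set)


@dataclass(frozen=True)
class AccessToken:
    subject_id: str
    issued_at: float
    expires_at: float
    origin_id: str
    raw: str = ""


@dataclass(frozen=True)
class AuditEvent:
    seq: int
    timestamp: float
    subject_id: str
    action: str
    target: str
    outcome: str  # allowed | denied | error

    def to_payload(self) -> dict:
        return {
            "seq": self.seq,
            "timestamp": self.timestamp,
            "subject_id": self.subject_id,
            "action": self.action,
            "target": self.target,
            "outcome": self.outcome,
        }


def _b64(data: bytes) -> str:
    return base64.urlsafe_b64encode(data).rstrip(b"=").decode()


def _unb64(text: str) -> bytes:
    pad = "=" * (-len(text) % 4)
    return base64.urlsafe_b64decode(text + pad)


class LocalTokenIssuer:
    """Compact signed bearer tokens: ``base64(claims).base64(hmac)``.

    ``clock`` is injectable so expiry is testable without sleeping.
    """

    def __init__(self, secret: str, ttl_seconds: float = 12 * 3600, clock=time.time):
        self._key = secret.encode()
        self.ttl = float(ttl_seconds)
        self.clock = clock

    def issue(self, subject_id: str, origin_id: str = "") -> AccessToken:
        now = self.clock()
        claims = {
            "sub": subject_id,
            "iat": now,
            "exp": now + self.ttl,
            "origin": origin_id,
        }
        body = _b64(json.dumps(claims, sort_keys=True).encode())
        sig = _b64(hmac.new(self._key, body.encode(), hashlib.sha256).digest())
        raw = f"{body}.{sig}"
        return AccessToken(subject_id, now, claims["exp"], origin_id, raw=raw)

    def verify(self, token: str) -> dict:
        try:
            body, sig = token.split(".")
            expected = _b64(hmac.new(self._key, body.encode(), hashlib.sha256).digest())
            if not hmac.compare_digest(sig, expected):
                raise AuthError("invalid token signature")
            claims = json.loads(_unb64(body))
        except AuthError:
            raise
        except Exception:
            raise AuthError("malformed token")
        if claims.get("exp", 0) <= self.clock():
            raise AuthError("token expired")
        return claims


class AuditLog:
    """Append-only audit trail, persisted as JSON lines (one event/line)."""

    def __init__(self, path=None, clock=time.time):
        self.path = Path(path) if path else None
        self.clock = clock
        self._events: list[AuditEvent] = []
        if self.path and self.path.exists():
            for line in self.path.read_text().splitlines():
                if line.strip():
                    d = json.loads(line)
                    self._events.append(AuditEvent(**d))

    @property
    def next_seq(self) -> int:
        return self._events[-1].seq + 1 if self._events else 1

    def append(self, subject_id: str, action: str, target: str, outcome: str) -> AuditEvent:
        event = AuditEvent(
            seq=self.next_seq,
            timestamp=self.clock(),
            subject_id=subject_id,
            action=action,
            target=target,
            outcome=outcome,
        )
        self._events.append(event)
        if self.path:
            with self.path.open("a") as fh:
                fh.write(json.dumps(event.to_payload()) + "\n")
        return event

    def read(self, since_seq: int = 0) -> list[AuditEvent]:
        return [e for e in self._events if e.seq > since_seq]


class AccessControl:
    """User registry, permission grants and the authorization choke point."""

    def __init__(
        self,
        issuer: LocalTokenIssuer,
        audit: AuditLog,
        project_exists=lambda name: True,
        origin_allow_list: set[str] | None = None,
    ):
        self.issuer = issuer
        self.audit = audit
        self.project_exists = project_exists
        self.origin_allow_list = set(origin_allow_list) if origin_allow_list else None
        self._users: dict[str, User] = {}

    # -- registry ----------------------------------------------------

    def register_user(self, subject_id: str, email: str = "", is_admin: bool = False) -> User:
        if not subject_id:
            raise ValidationError("subject_id must be non-empty")
        if subject_id in self._users:
            raise ValidationError(f"subject {subject_id!r} already registered")
        user = User(subject_id, email, is_admin)
        self._users[subject_id] = user
        return user

    def get_user(self, subject_id: str) -> User:
        user = self._users.get(subject_id)
        if user is None:
            raise AuthError(f"unknown subject {subject_id!r}")
        return user

    # -- tokens ------------------------------------------------------

    def issue_token(self, subject_id: str, origin_id: str = "") -> AccessToken:
        self.get_user(subject_id)  # raises AuthError if unregistered
        if self.origin_allow_list is not None and origin_id not in self.origin_allow_list:
            self.audit.append(subject_id, "issue_token", origin_id, "denied")
            raise ForbiddenError(f"origin {origin_id!r} is not allow-listed")
        token = self.issuer.issue(subject_id, origin_id)
        self.audit.append(subject_id, "issue_token", origin_id, "allowed")
        return token

    def resolve(self, token: str | None) -> User | None:
        """Token -> user, or None for anonymous; AuthError if invalid/expired."""
        if not token:
            return None
        claims = self.issuer.verify(token)
        return self.get_user(claims["sub"])

    # -- grants ------------------------------------------------------

    def grant(self, admin_token: str, subject_id: str, project: str) -> User:
        self._require_admin(admin_token, "grant", f"{project}:{subject_id}")
        if not self.project_exists(project):
            raise NotFoundError(f"unknown project {project!r}")
        user = self.get_user(subject_id)
        user.grants.add(project)
        self.audit.append(subject_id, "granted", project, "allowed")
        return user

    def revoke(self, admin_token: str, subject_id: str, project: str) -> User:
        self._require_admin(admin_token, "revoke", f"{project}:{subject_id}")
        user = self.get_user(subject_id)
        user.grants.discard(project)
        self.audit.append(subject_id, "revoked", project, "allowed")
        return user

    # -- authorization -----------------------------------------------

    def decide(self, user: User | None, project: str, action: str) -> bool:
        """Pure decision-table lookup; deny-by-default for unknown actions."""
        if action not in ALL_ACTIONS:
            return False
        if user is None:
            return False
        if user.is_admin:
            return True
        return action in RESEARCHER_ACTIONS and project in user.grants

    def authorize(self, token: str | None, project: str, action: str) -> bool:
        """Audited decision; AuthError for invalid tokens (audited as denied)."""
        try:
            user = self.resolve(token)
        except AuthError:
            self.audit.append("?", action, project, "denied")
            raise
        allowed = self.decide(user, project, action)
        subject = user.subject_id if user else "anonymous"
        self.audit.append(subject, action, project, "allowed" if allowed else "denied")
        return allowed

    def require(self, token: str | None, project: str, action: str) -> User:
        if not self.authorize(token, project, action):
            raise ForbiddenError(f"action {action!r} on project {project!r} denied")
        return self.resolve(token)

    def _require_admin(self, token: str | None, action: str, target: str) -> User:
        try:
            user = self.resolve(token)
        except AuthError:
            self.audit.append("?", action, target, "denied")
            raise
        if user is None or not user.is_admin:
            subject = user.subject_id if user else "anonymous"
            self.audit.append(subject, action, target, "denied")
            raise ForbiddenError(f"action {action!r} requires an administrator")
        return user

    # -- audit & metrics ---------------------------------------------

    def read_audit(self, admin_token: str, since_seq: int = 0) -> list[AuditEvent]:
        self._require_admin(admin_token, "read_audit", "audit")
        return self.audit.read(since_seq)


class Metrics:
    """Server metrics snapshot: uptime, per-endpoint counts, live sessions."""

    def __init__(self, clock=time.time, active_sessions=lambda: 0):
        self.clock = clock
        self.started_at = clock()
        self.request_counts: dict[str, int] = {}
        self.active_sessions = active_sessions

    def count(self, endpoint: str) -> None:
        self.request_counts[endpoint] = self.request_counts.get(endpoint, 0) + 1

    def snapshot(self) -> dict:
        return {
            "uptime_seconds": self.clock() - self.started_at,
            "request_counts": dict(self.request_counts),
            "active_sessions": self.active_sessions(),
        }
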