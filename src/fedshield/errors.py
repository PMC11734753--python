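"""Error taxonomy shared by server and client.

Every error carries a machine-readable ``code`` so the researcher client
can branch on the failure class without parsing prose. The codes mirror
the protocol's failure modes: input problems, permission problems,
blocked functions, disclosure-control refusals, lifecycle state, and
missing objects.
"""

from __future__ import annotations


class FedShieldError(Exception):
    """Base class; ``code`` is the machine-readable error class."""

    code = "error"
    http_status = 500

    def __init__(self, message: str = "", **details):
        super().__init__(message or self.code)
        self.message = message or self.code
        self.details = details

    def to_payload(self) -> dict:
        payload = {"error": self.code, "message": self.message}
        if self.details:
            payload.update(self.details)
        return payload


class ValidationError(FedShieldError):
    code = "validation"
    http_status = 400


class IngestError(ValidationError):
    code = "ingest"
    http_status = 400


class ConflictError(FedShieldError):
    code = "conflict"
    http_status = 409


class NotFoundError(FedShieldError):
    code = "not-found"
    http_status = 404


class AuthError(FedShieldError):
    code = "auth"
    http_status = 401


class ForbiddenError(FedShieldError):
    code = "forbidden"
    http_status = 403


class ForbiddenFunctionError(FedShieldError):
    code = "forbidden-function"
    http_status = 403


class DisclosureError(FedShieldError):
    """An output was refused by a disclosure-control threshold.

    ``rule`` names the violated threshold (min_obs, min_cell,
    min_subset, glm_ratio) so clients and audits can report it.
    """

    code = "disclosure"
    http_status = 403

    def __init__(self, message: str = "", rule: str = "", **details):
        super().__init__(message, rule=rule, **details)
        self.rule = rule


class UnavailableError(FedShieldError):
    code = "unavailable"
    http_status = 503


class EstimationError(FedShieldError):
    """Client-side numerical failure (e.g. singular pooled information)."""

    code = "estimation"
    http_status = 500


ERROR_CODES = {
    cls.code: cls
    for cls in (
        ValidationError,
        IngestError,
        ConflictError,
        NotFoundError,
        AuthError,
        ForbiddenError,
        ForbiddenFunctionError,
        DisclosureError,
        UnavailableError,
        EstimationError,
    )
}


def from_payload(payload: dict) -> FedShieldError:
    """Rebuild a typed error from a serialized error body."""
    code = payload.get("error", "error")
    cls = ERROR_CODES.get(code, FedShieldError)
    message = payload.get("message", code)
    details = {k: v for k, v in payload.items() if k not in ("error", "message")}
    if cls is DisclosureError:
        rule = details.pop("rule", "")
        return DisclosureError(message, rule=rule, **details)
    err = cls(message, **details)
    return err
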