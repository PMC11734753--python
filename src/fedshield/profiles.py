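"""Analysis profiles: named environments gating what researchers may run.

A profile bundles the installed statistical "packages" (in-process
registries of aggregate/assign functions), a function whitelist, a
function blacklist that always wins, per-profile disclosure-control
thresholds, and a running/stopped lifecycle that emulates container
management: sessions can only be created on a running profile, and
stopping a profile terminates its sessions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

from .errors import ConflictError, NotFoundError, ValidationError


@dataclass(frozen=True)
class DisclosureOptions:
    """Statistical disclosure-control thresholds, snapshotted per session.

    min_cell:
        Minimum non-zero count in any released contingency-table cell.
    min_subset:
        Minimum surviving row count of a row filter (0 is allowed:
        an empty subset reveals nothing about individuals).
    min_obs:
        Minimum valid observations behind any released moment.
    glm_ratio:
        Maximum parameters-to-observations ratio for model fitting.
    """

    min_cell: int = 3
    min_subset: int = 3
    min_obs: int = 3
    glm_ratio: float = 0.2

    def __post_init__(self):
        for name in ("min_cell", "min_subset", "min_obs"):
            if int(getattr(self, name)) < 1:
                raise ValidationError(f"{name} must be >= 1")
        if not (0 < self.glm_ratio <= 1):
            raise ValidationError("glm_ratio must be in (0, 1]")


@dataclass
class Profile:
    name: str
    packages: set[str] = field(default_factory=set)
    whitelist: set[str] = field(default_factory=set)
    blacklist: set[str] = field(default_factory=set)
    options: DisclosureOptions = field(default_factory=DisclosureOptions)
    state: str = "stopped"  # stopped | running
    version: int = 1

    def to_payload(self) -> dict:
        d = asdict(self)
        d["packages"] = sorted(self.packages)
        d["whitelist"] = sorted(self.whitelist)
        d["blacklist"] = sorted(self.blacklist)
        return d


class ProfileRegistry:
    """Create, persist, start/stop profiles and answer callability queries.

    ``function_catalog`` maps package name -> set of function names that
    package provides (the in-process stand-in for installed analysis
    packages). ``session_counter(profile_name)`` reports live sessions
    and ``on_stop(profile_name)`` is invoked when a profile stops so the
    session engine can discard its sessions.
    """

    def __init__(self, function_catalog: dict[str, set[str]], store_path=None):
        self.catalog = {k: set(v) for k, v in function_catalog.items()}
        self.store_path = Path(store_path) if store_path else None
        self._profiles: dict[str, Profile] = {}
        self.session_counter = lambda name: 0
        self.on_stop = lambda name: None

    # -- CRUD --------------------------------------------------------

    def create(
        self,
        name: str,
        packages: set[str] | None = None,
        whitelist: set[str] | None = None,
        blacklist: set[str] | None = None,
        options: DisclosureOptions | dict | None = None,
    ) -> Profile:
        if not name:
            raise ValidationError("profile name must be non-empty")
        if name in self._profiles:
            raise ConflictError(f"profile {name!r} already exists")
        unknown = set(packages or ()) - set(self.catalog)
        if unknown:
            raise ValidationError(f"unknown packages: {', '.join(sorted(unknown))}")
        if isinstance(options, dict):
            options = DisclosureOptions(**options)
        profile = Profile(
            name=name,
            packages=set(packages or ()),
            whitelist=set(whitelist or ()),
            blacklist=set(blacklist or ()),
            options=options or DisclosureOptions(),
        )
        self._profiles[name] = profile
        self._persist()
        return profile

    def get(self, name: str) -> Profile:
        profile = self._profiles.get(name)
        if profile is None:
            raise NotFoundError(f"unknown profile {name!r}")
        return profile

    def list(self) -> list[Profile]:
        return [self._profiles[k] for k in sorted(self._profiles)]

    def update_options(self, name: str, **changes) -> Profile:
        """Edit thresholds; live sessions keep their snapshot (no races)."""
        profile = self.get(name)
        merged = {**asdict(profile.options), **changes}
        profile.options = DisclosureOptions(**merged)
        profile.version += 1
        self._persist()
        return profile

    def delete(self, name: str) -> None:
        profile = self.get(name)
        live = self.session_counter(name)
        if live:
            raise ConflictError(
                f"profile {name!r} has {live} live session(s); stop it first"
            )
        del self._profiles[profile.name]
        self._persist()

    # -- lifecycle ---------------------------------------------------

    def start(self, name: str) -> tuple[Profile, bool]:
        """Returns (profile, already_running_warning)."""
        profile = self.get(name)
        if profile.state == "running":
            return profile, True
        profile.state = "running"
        profile.version += 1
        self._persist()
        return profile, False

    def stop(self, name: str) -> Profile:
        profile = self.get(name)
        if profile.state == "running":
            profile.state = "stopped"
            profile.version += 1
            self.on_stop(name)
            self._persist()
        return profile

    # -- callability -------------------------------------------------

    def is_callable(self, profile: Profile | str, function_name: str) -> bool:
        """Blacklist always wins; otherwise the function must be provided
        by an installed package and be whitelisted (explicitly, or via a
        package-level whitelist entry covering its package)."""
        if isinstance(profile, str):
            profile = self.get(profile)
        if function_name in profile.blacklist:
            return False
        providing = {pkg for pkg in profile.packages if function_name in self.catalog.get(pkg, ())}
        if not providing:
            return False
        if function_name in profile.whitelist:
            return True
        return bool(providing & profile.whitelist)

    # -- persistence -------------------------------------------------

    def _persist(self) -> None:
        if not self.store_path:
            return
        payload = {name: p.to_payload() for name, p in self._profiles.items()}
        self.store_path.write_text(json.dumps(payload, indent=1))
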