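"""Scheme-addressed locations.

Every file and directory the engine touches is named by a URI of the form
``scheme://[user@]host[/path]`` — e.g. ``file:///data/run1/seqs.fa`` or
``mem://scratch/in/a.fa``.  The scheme selects the storage (or compute)
backend; nothing else in the system knows how bytes are actually stored.

Grammar (EBNF, see also docs/formats.md)::

    uri    = scheme "://" [ user "@" ] host [ path ]
    scheme = ALPHA { ALPHA | DIGIT | "+" | "-" | "." }
    user   = 1*( any character except "@" and "/" )
    host   = *( any character except "/" )
    path   = "/" ...                     ; absolute, "." / ".." forbidden

Parsing normalizes the path (collapsing duplicate slashes and trailing
slashes except for the root) and then ``render`` ↔ ``parse`` round-trips
exactly.
"""

from __future__ import annotations

import posixpath
import re
from dataclasses import dataclass, replace

from .errors import ValidationError

_URI_RE = re.compile(
    r"^(?P<scheme>[A-Za-z][A-Za-z0-9+.\-]*)://"
    r"(?:(?P<user>[^@/]+)@)?"
    r"(?P<host>[^/]*)"
    r"(?P<path>/.*)?$"
)


@dataclass(frozen=True)
class UriRef:
    """A parsed ``scheme://[user@]host/path`` reference."""

    scheme: str
    user: str | None = None
    host: str | None = None
    path: str = "/"

    @staticmethod
    def parse(text: str) -> "UriRef":
        m = _URI_RE.match(text)
        if not m:
            raise ValidationError(f"not a valid URI: {text!r}")
        scheme = m.group("scheme")
        user = m.group("user")
        host = m.group("host") or None
        path = m.group("path") or "/"
        return UriRef(scheme=scheme, user=user, host=host, path=_normalize(path))

    def render(self) -> str:
        userpart = f"{self.user}@" if self.user else ""
        return f"{self.scheme}://{userpart}{self.host or ''}{self.path}"

    # -- path helpers -------------------------------------------------
    @property
    def basename(self) -> str:
        return posixpath.basename(self.path)

    @property
    def parent(self) -> "UriRef":
        return replace(self, path=posixpath.dirname(self.path) or "/")

    def join(self, *names: str) -> "UriRef":
        for n in names:
            if "/" in n or n in (".", ".."):
                raise ValidationError(f"illegal path component: {n!r}")
        joined = posixpath.join(self.path, *names)
        return replace(self, path=_normalize(joined))

    def with_path(self, path: str) -> "UriRef":
        return replace(self, path=_normalize(path))

    def same_location(self, other: "UriRef") -> bool:
        return (self.scheme, self.host, self.path) == (
            other.scheme,
            other.host,
            other.path,
        )

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.render()


def _normalize(path: str) -> str:
    if not path.startswith("/"):
        raise ValidationError(f"URI path must be absolute: {path!r}")
    for seg in path.split("/"):
        if seg in (".", ".."):
            raise ValidationError(f"'.'/'..' segments forbidden in URI path: {path!r}")
    norm = posixpath.normpath(path)
    return norm if norm != "//" else "/"
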