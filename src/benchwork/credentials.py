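"""Encrypted credential vault with blocked-not-failed semantics.

Per-backend secrets are stored encrypted with AES-256-CTR under a key
derived from the user's password (PBKDF2-HMAC-SHA256, per-record random
salt), authenticated with HMAC-SHA256 over the full record
(encrypt-then-MAC).  The plaintext secret is never persisted anywhere: on
``unlock`` (login) the user's records are decrypted and held only in a RAM
cache, which is cleared on logout/shutdown and is never serialized.

When the engine asks for a credential that is not cached, :meth:`get`
raises :class:`~benchwork.errors.CredentialMissing` — a ``Blocked`` signal,
so the dependent task is placed in the resumable *blocked* state rather
than failing.
"""

from __future__ import annotations

import base64
import hashlib
import hmac
import os
import time
from dataclasses import dataclass

from ._aes import ctr_xor
from .errors import AuthenticationError, CredentialMissing

RECORD_VERSION = 1
DEFAULT_KDF_ITERATIONS = 200_000
_MAGIC = b"benchwork-credential-v1"


def _derive_keys(password: str, salt: bytes, iterations: int) -> tuple[bytes, bytes]:
    material = hashlib.pbkdf2_hmac(
        "sha256", password.encode("utf-8"), salt, iterations, dklen=64
    )
    return material[:32], material[32:]  # (AES key, MAC key)


def encrypt_secret(
    secret: bytes, password: str, iterations: int = DEFAULT_KDF_ITERATIONS
) -> dict:
    """Encrypt *secret* under *password*; returns a JSON-ready record."""
    if not password:
        raise ValueError("password must be non-empty")
    salt = os.urandom(16)
    nonce = os.urandom(16)
    enc_key, mac_key = _derive_keys(password, salt, iterations)
    ciphertext = ctr_xor(enc_key, nonce, secret)
    mac = hmac.new(
        mac_key,
        _MAGIC + salt + nonce + iterations.to_bytes(4, "big") + ciphertext,
        hashlib.sha256,
    ).digest()
    b64 = lambda b: base64.b64encode(b).decode("ascii")
    return {
        "version": RECORD_VERSION,
        "kdf": "pbkdf2-sha256",
        "iterations": iterations,
        "salt": b64(salt),
        "nonce": b64(nonce),
        "ciphertext": b64(ciphertext),
        "mac": b64(mac),
    }


def decrypt_secret(record: dict, password: str) -> bytes:
    """Recover the secret; raises :class:`AuthenticationError` on a wrong
    password or any ciphertext tampering (no plaintext is ever emitted in
    that case)."""
    if record.get("version") != RECORD_VERSION:
        raise AuthenticationError("unrecognized credential record version")
    b64 = base64.b64decode
    salt = b64(record["salt"])
    nonce = b64(record["nonce"])
    ciphertext = b64(record["ciphertext"])
    iterations = int(record["iterations"])
    enc_key, mac_key = _derive_keys(password, salt, iterations)
    expect = hmac.new(
        mac_key,
        _MAGIC + salt + nonce + iterations.to_bytes(4, "big") + ciphertext,
        hashlib.sha256,
    ).digest()
    if not hmac.compare_digest(expect, b64(record["mac"])):
        raise AuthenticationError("credential authentication failed")
    return ctr_xor(enc_key, nonce, ciphertext)


@dataclass
class _CacheEntry:
    secret: bytes


class CredentialCache:
    """Session-scoped RAM map (user, backend_id) -> plaintext secret."""

    def __init__(self):
        self._entries: dict[tuple[str, str], _CacheEntry] = {}

    def put(self, user: str, backend_id: str, secret: bytes) -> None:
        self._entries[(user, backend_id)] = _CacheEntry(secret)

    def get(self, user: str, backend_id: str) -> bytes | None:
        entry = self._entries.get((user, backend_id))
        return entry.secret if entry else None

    def clear(self, user: str | None = None) -> None:
        if user is None:
            self._entries.clear()
        else:
            for key in [k for k in self._entries if k[0] == user]:
                del self._entries[key]

    def __len__(self) -> int:
        return len(self._entries)


class CredentialVault:
    """Encrypted store + RAM cache.

    *records* is any object with the record-table contract implemented by
    :class:`benchwork.persistence.Store`: ``put_credential(user, backend_id,
    payload, expires_at)``, ``get_credential(user, backend_id)``,
    ``list_credentials(user)``, ``delete_credential(user, backend_id)``.
    """

    def __init__(self, records, kdf_iterations: int = DEFAULT_KDF_ITERATIONS, clock=time.time):
        self._records = records
        self._iterations = kdf_iterations
        self._clock = clock
        self.cache = CredentialCache()

    # -- storage ------------------------------------------------------
    def store_credential(
        self,
        user: str,
        backend_id: str,
        secret: bytes | str,
        password: str,
        ttl: float | None = None,
    ) -> dict:
        if isinstance(secret, str):
            secret = secret.encode("utf-8")
        record = encrypt_secret(secret, password, self._iterations)
        expires_at = (self._clock() + ttl) if ttl is not None else None
        self._records.put_credential(user, backend_id, record, expires_at)
        return record

    def remove(self, user: str, backend_id: str) -> None:
        self._records.delete_credential(user, backend_id)
        self.cache.clear(user)

    def list(self, user: str) -> list[str]:
        """Backend ids with a live (non-expired) stored credential."""
        now = self._clock()
        out = []
        for backend_id, _payload, expires_at in self._records.list_credentials(user):
            if expires_at is None or expires_at > now:
                out.append(backend_id)
        return sorted(out)

    def has(self, user: str, backend_id: str) -> bool:
        return backend_id in self.list(user)

    # -- session ------------------------------------------------------
    def unlock(self, user: str, password: str) -> int:
        """Decrypt and cache all of *user*'s live credentials.

        Returns the number cached.  A wrong password caches nothing and
        raises :class:`AuthenticationError` (explicit failure) when the
        user has stored credentials.
        """
        now = self._clock()
        rows = [
            (bid, payload)
            for bid, payload, expires_at in self._records.list_credentials(user)
            if expires_at is None or expires_at > now
        ]
        decrypted: list[tuple[str, bytes]] = []
        failures = 0
        for backend_id, payload in rows:
            try:
                decrypted.append((backend_id, decrypt_secret(payload, password)))
            except AuthenticationError:
                failures += 1
        if failures and not decrypted:
            raise AuthenticationError(f"wrong password for user {user!r}")
        for backend_id, secret in decrypted:
            self.cache.put(user, backend_id, secret)
        return len(decrypted)

    def lock(self, user: str | None = None) -> None:
        self.cache.clear(user)

    def get(self, user: str, backend_id: str) -> bytes:
        """Cached secret, or a Blocked signal mapped to task status *blocked*."""
        secret = self.cache.get(user, backend_id)
        if secret is None:
            raise CredentialMissing(
                f"no decrypted credential cached for user={user!r} backend={backend_id!r}"
            )
        return secret

    def resolver(self, user: str):
        """``backend_id -> secret`` callable for a storage router."""

        def _resolve(backend_id: str) -> bytes:
            return self.get(user, backend_id)

        return _resolve
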