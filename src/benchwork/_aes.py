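"""AES block cipher (FIPS 197) with CTR-mode keystream.

Self-contained implementation used by the credential vault; supports
128/192/256-bit keys.  Tables are generated at import time from the GF(2^8)
arithmetic rather than transcribed, and the implementation is checked in the
test suite against the FIPS-197 appendix known-answer vectors.

Performance note: this is pure Python and meant for small payloads
(credential secrets, at most a few KiB); bulk data never passes through it.
"""

from __future__ import annotations


def _xtime(a: int) -> int:
    a <<= 1
    return (a ^ 0x1B) & 0xFF if a & 0x100 else a


def _build_sbox() -> list[int]:
    # log/antilog tables over GF(2^8) with generator 3, then the affine map.
    exp = [0] * 255
    log = [0] * 256
    x = 1
    for i in range(255):
        exp[i] = x
        log[x] = i
        x ^= _xtime(x)  # multiply by generator 3 = x * (0x02 ^ 0x01)
    sbox = [0] * 256
    for a in range(256):
        b = 0 if a == 0 else exp[(255 - log[a]) % 255]
        s = b
        for _ in range(4):
            b = ((b << 1) | (b >> 7)) & 0xFF
            s ^= b
        sbox[a] = s ^ 0x63
    return sbox


_SBOX = _build_sbox()
_RCON = [0x00, 0x01, 0x02, 0x04, 0x08, 0x10, 0x20, 0x40, 0x80, 0x1B, 0x36]


def _expand_key(key: bytes) -> tuple[list[list[int]], int]:
    if len(key) not in (16, 24, 32):
        raise ValueError("AES key must be 16, 24 or 32 bytes")
    nk = len(key) // 4
    nr = nk + 6
    words = [list(key[4 * i : 4 * i + 4]) for i in range(nk)]
    for i in range(nk, 4 * (nr + 1)):
        t = list(words[i - 1])
        if i % nk == 0:
            t = t[1:] + t[:1]
            t = [_SBOX[b] for b in t]
            t[0] ^= _RCON[i // nk]
        elif nk > 6 and i % nk == 4:
            t = [_SBOX[b] for b in t]
        words.append([words[i - nk][j] ^ t[j] for j in range(4)])
    return words, nr


class AES:
    def __init__(self, key: bytes):
        self._words, self._nr = _expand_key(key)

    def encrypt_block(self, block: bytes) -> bytes:
        if len(block) != 16:
            raise ValueError("AES block must be 16 bytes")
        w = self._words
        # state[i] with i = row + 4*col (column-major, as in FIPS 197)
        s = list(block)
        s = [s[i] ^ w[i // 4][i % 4] for i in range(16)]
        for rnd in range(1, self._nr):
            s = [_SBOX[b] for b in s]
            s = [s[(i + 4 * (i % 4)) % 16] for i in range(16)]  # ShiftRows
            # MixColumns, one column at a time
            out = [0] * 16
            for c in range(4):
                a0, a1, a2, a3 = s[4 * c : 4 * c + 4]
                out[4 * c + 0] = _xtime(a0) ^ _xtime(a1) ^ a1 ^ a2 ^ a3
                out[4 * c + 1] = a0 ^ _xtime(a1) ^ _xtime(a2) ^ a2 ^ a3
                out[4 * c + 2] = a0 ^ a1 ^ _xtime(a2) ^ _xtime(a3) ^ a3
                out[4 * c + 3] = _xtime(a0) ^ a0 ^ a1 ^ a2 ^ _xtime(a3)
            s = [out[i] ^ w[4 * rnd + i // 4][i % 4] for i in range(16)]
        s = [_SBOX[b] for b in s]
        s = [s[(i + 4 * (i % 4)) % 16] for i in range(16)]
        s = [s[i] ^ w[4 * self._nr + i // 4][i % 4] for i in range(16)]
        return bytes(s)


def ctr_xor(key: bytes, nonce: bytes, data: bytes) -> bytes:
    """Encrypt/decrypt *data* with AES-CTR; *nonce* is the 16-byte initial counter."""
    if len(nonce) != 16:
        raise ValueError("CTR nonce must be 16 bytes")
    cipher = AES(key)
    counter = int.from_bytes(nonce, "big")
    out = bytearray()
    for off in range(0, len(data), 16):
        block = cipher.encrypt_block(
            ((counter + off // 16) % (1 << 128)).to_bytes(16, "big")
        )
        piece = data[off : off + 16]
        out.extend(x ^ y for x, y in zip(piece, block))
    return bytes(out)
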