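"""File-type matching and input pairing.

A tool parameter's *file type* is a unix-style filename glob (``*.fa``,
``seq_??.txt``, ``[abc]*.qual``).  Whether a file can satisfy a parameter is
decided purely by matching its basename against that glob, case-sensitively.

When a job has two batchable file parameters, each input file of one type
must be grouped with its counterpart of the other type (``s1.fa`` with
``s1.qual``).  The engine pairs the two groups so that the total Levenshtein
edit distance between paired names is minimal; ties between equally cheap
pairings are broken by lexicographic order of the pair list, so pairing is
fully deterministic.
"""

from __future__ import annotations

import fnmatch
import posixpath
from dataclasses import dataclass, field

from .errors import PatternError

#: exact assignment is used up to this group size; greedy above it
_EXACT_LIMIT = 12


def validate_glob(pattern: str) -> None:
    """Raise :class:`PatternError` if *pattern* is not a usable filename glob.

    Allowed metacharacters: ``*``, ``?`` and ``[...]`` character classes.
    A pattern must be non-empty, must not contain a path separator and every
    ``[`` must have a closing ``]``.
    """
    if not pattern:
        raise PatternError("empty file-type pattern")
    if "/" in pattern:
        raise PatternError(f"pattern must match basenames only (no '/'): {pattern!r}")
    i = 0
    while i < len(pattern):
        if pattern[i] == "[":
            j = i + 1
            if j < len(pattern) and pattern[j] == "!":
                j += 1
            if j < len(pattern) and pattern[j] == "]":
                j += 1
            j = pattern.find("]", j)
            if j < 0:
                raise PatternError(f"unclosed '[' in pattern: {pattern!r}")
            i = j
        i += 1


def match_files(filenames: list[str], pattern: str) -> list[str]:
    """Return the sublist of *filenames* whose basename matches *pattern*.

    Input order is preserved; matching is case-sensitive.
    """
    validate_glob(pattern)
    return [
        name
        for name in filenames
        if fnmatch.fnmatchcase(posixpath.basename(name), pattern)
    ]


def levenshtein(a: str, b: str) -> int:
    """Unit-cost edit distance (insert/delete/substitute each cost 1)."""
    if a == b:
        return 0
    if len(a) < len(b):
        a, b = b, a
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, start=1):
        cur = [i]
        for j, cb in enumerate(b, start=1):
            cur.append(
                min(
                    prev[j] + 1,  # delete from a
                    cur[j - 1] + 1,  # insert into a
                    prev[j - 1] + (ca != cb),  # substitute
                )
            )
        prev = cur
    return prev[-1]


@dataclass
class Pairing:
    """Result of pairing two input groups.

    ``pairs`` holds ``min(|A|, |B|)`` one-to-one pairs in lexicographic
    order; unpaired names from the larger group are *reported* in
    ``leftover_a`` / ``leftover_b``, never silently dropped.
    """

    pairs: list[tuple[str, str]]
    leftover_a: list[str] = field(default_factory=list)
    leftover_b: list[str] = field(default_factory=list)

    @property
    def total_cost(self) -> int:
        return sum(levenshtein(a, b) for a, b in self.pairs)


def pair_inputs(group_a: list[str], group_b: list[str]) -> Pairing:
    """Pair names across two groups minimizing total Levenshtein distance.

    For group sizes up to 12 the pairing is an exact minimum-cost assignment
    with deterministic lexicographic tie-breaking among optimal solutions;
    above that a greedy nearest-pair heuristic (same tie-break) is used.
    """
    if not group_a or not group_b:
        raise ValueError("pair_inputs requires two non-empty groups")
    a = list(group_a)
    b = list(group_b)
    if max(len(a), len(b)) <= _EXACT_LIMIT:
        pairs = _exact_pairs(a, b)
    else:
        pairs = _greedy_pairs(a, b)
    used_a = {i for i, _ in pairs}
    used_b = {j for _, j in pairs}
    result = sorted((a[i], b[j]) for i, j in pairs)
    return Pairing(
        pairs=result,
        leftover_a=[x for i, x in enumerate(a) if i not in used_a],
        leftover_b=[x for j, x in enumerate(b) if j not in used_b],
    )


def _cost_matrix(a: list[str], b: list[str]):
    import numpy as np

    return np.array([[levenshtein(x, y) for y in b] for x in a], dtype=float)


def _assignment_cost(cost) -> float:
    from scipy.optimize import linear_sum_assignment

    if cost.size == 0:
        return 0.0
    rows, cols = linear_sum_assignment(cost)
    return float(cost[rows, cols].sum())


def _exact_pairs(a: list[str], b: list[str]) -> list[tuple[int, int]]:
    # Fix pairs one at a time in lexicographic order of (name_a, name_b),
    # keeping only choices that preserve the optimal total cost.  This yields
    # the lexicographically smallest pairing among all minimum-cost ones.
    import numpy as np

    cost = _cost_matrix(a, b)
    free_a = list(range(len(a)))
    free_b = list(range(len(b)))
    target = _assignment_cost(cost)
    pairs: list[tuple[int, int]] = []
    n_pairs = min(len(a), len(b))
    while len(pairs) < n_pairs:
        candidates = sorted(
            ((a[i], b[j], i, j) for i in free_a for j in free_b),
            key=lambda t: (t[0], t[1]),
        )
        for _, _, i, j in candidates:
            rest_a = [x for x in free_a if x != i]
            rest_b = [y for y in free_b if y != j]
            sub = cost[np.ix_(rest_a, rest_b)] if rest_a and rest_b else cost[0:0, 0:0]
            if cost[i, j] + _assignment_cost(sub) == target:
                pairs.append((i, j))
                free_a = rest_a
                free_b = rest_b
                target -= cost[i, j]
                break
        else:  # pragma: no cover - assignment always has a consistent choice
            raise AssertionError("no consistent pair found")
    return pairs


def _greedy_pairs(a: list[str], b: list[str]) -> list[tuple[int, int]]:
    free_a = set(range(len(a)))
    free_b = set(range(len(b)))
    pairs: list[tuple[int, int]] = []
    dist = {(i, j): levenshtein(a[i], b[j]) for i in free_a for j in free_b}
    while free_a and free_b:
        best = min(
            ((dist[i, j], a[i], b[j], i, j) for i in free_a for j in free_b),
            key=lambda t: (t[0], t[1], t[2]),
        )
        _, _, _, i, j = best
        pairs.append((i, j))
        free_a.discard(i)
        free_b.discard(j)
    return pairs
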