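"""Independent brute-force oracles used to cross-check the implementation.

Everything here is written against the mathematical definitions directly
(plain Python, no shared code with the package kernels) so that agreement is
meaningful.
"""

from __future__ import annotations

from Bio.Align import substitution_matrices

_BLOSUM62 = substitution_matrices.load("BLOSUM62")


def sw_affine_bruteforce(query: str, subject: str, gap_open: int = 11, gap_extend: int = 1) -> int:
    """Best local affine-gap alignment score by explicit three-state DP.

    A gap of length L costs gap_open + L * gap_extend.
    """
    m, n = len(query), len(subject)
    neg = float("-inf")
    # M[i][j]: best alignment ending in a match/mismatch at (i, j)
    # X[i][j]: ending in a gap consuming query residue i (gap in subject)
    # Y[i][j]: ending in a gap consuming subject residue j (gap in query)
    M = [[neg] * (n + 1) for _ in range(m + 1)]
    X = [[neg] * (n + 1) for _ in range(m + 1)]
    Y = [[neg] * (n + 1) for _ in range(m + 1)]
    best = 0
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            s = _BLOSUM62[query[i - 1], subject[j - 1]]
            prev = max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1], 0)
            M[i][j] = prev + s
            X[i][j] = max(
                M[i - 1][j] - gap_open - gap_extend,
                X[i - 1][j] - gap_extend,
                Y[i - 1][j] - gap_open - gap_extend,
            )
            Y[i][j] = max(
                M[i][j - 1] - gap_open - gap_extend,
                Y[i][j - 1] - gap_extend,
                X[i][j - 1] - gap_open - gap_extend,
            )
            best = max(best, M[i][j], X[i][j], Y[i][j])
    return int(best)


def lcs_bruteforce(a: str, b: str) -> int:
    """Longest common subsequence length, classic quadratic DP."""
    prev = [0] * (len(b) + 1)
    for ch in a:
        cur = [0]
        for j, bh in enumerate(b, start=1):
            cur.append(prev[j - 1] + 1 if ch == bh else max(prev[j], cur[j - 1]))
        prev = cur
    return prev[-1]


def identity_over_shorter(a: str, b: str) -> float:
    return 100.0 * lcs_bruteforce(a, b) / min(len(a), len(b))


def first_fit_clusters(
    sequences: list[tuple[str, str]], threshold: float
) -> list[list[str]]:
    """First-fit greedy clustering with the same visiting order convention:
    descending length, ties by id; identity over the shorter sequence."""
    ordered = sorted(sequences, key=lambda item: (-len(item[1]), item[0]))
    clusters: list[list[str]] = []
    reps: list[str] = []
    for seq_id, seq in ordered:
        for k, rep in enumerate(reps):
            if identity_over_shorter(seq, rep) >= threshold:
                clusters[k].append(seq_id)
                break
        else:
            clusters.append([seq_id])
            reps.append(seq)
    return clusters


def rule_bruteforce(requirement_kind: str, k: int, member_roles: set[str], found: set[str]) -> bool:
    """Direct evaluation of a pathway requirement on a role subset."""
    n = len(found & member_roles)
    if requirement_kind == "ALL":
        return n == len(member_roles)
    if requirement_kind == "AT_LEAST_K":
        return n >= k
    if requirement_kind == "ANY":
        return n >= 1
    raise ValueError(requirement_kind)
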