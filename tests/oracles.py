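"""Independent brute-force oracles used only by the test suite.

These deliberately re-derive quantities by the most literal method possible
(plain dynamic programming, column counting, sliding windows) so they share
no code with the package implementation they check.
"""

from Bio.Align import substitution_matrices

_B62 = substitution_matrices.load("BLOSUM62")
NEG = float("-inf")


def gotoh_global(a: str, b: str, open_: float = 11.0, extend: float = 1.0) -> float:
    """Needleman-Wunsch with affine gaps (gap of length k costs open+(k-1)e),
    end gaps penalised."""
    n, m = len(a), len(b)
    M = [[NEG] * (m + 1) for _ in range(n + 1)]
    X = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in b (a consumed)
    Y = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in a
    M[0][0] = 0.0
    for i in range(1, n + 1):
        X[i][0] = -(open_ + (i - 1) * extend)
    for j in range(1, m + 1):
        Y[0][j] = -(open_ + (j - 1) * extend)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = _B62[a[i - 1], b[j - 1]]
            M[i][j] = max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1]) + s
            X[i][j] = max(M[i - 1][j] - open_, X[i - 1][j] - extend,
                          Y[i - 1][j] - open_)
            Y[i][j] = max(M[i][j - 1] - open_, Y[i][j - 1] - extend,
                          X[i][j - 1] - open_)
    return max(M[n][m], X[n][m], Y[n][m])


def gotoh_local(a: str, b: str, open_: float = 11.0, extend: float = 1.0) -> float:
    """Smith-Waterman with affine gaps; empty alignment scores 0."""
    n, m = len(a), len(b)
    M = [[0.0] * (m + 1) for _ in range(n + 1)]
    X = [[NEG] * (m + 1) for _ in range(n + 1)]
    Y = [[NEG] * (m + 1) for _ in range(n + 1)]
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = _B62[a[i - 1], b[j - 1]]
            M[i][j] = max(0.0,
                          M[i - 1][j - 1] + s, X[i - 1][j - 1] + s,
                          Y[i - 1][j - 1] + s)
            X[i][j] = max(M[i - 1][j] - open_, X[i - 1][j] - extend)
            Y[i][j] = max(M[i][j - 1] - open_, Y[i][j - 1] - extend)
            best = max(best, M[i][j])
    return best


STRONG = ["STA", "NEQK", "NHQK", "NDEQ", "QHRK", "MILV", "MILF", "HY", "FYW"]
WEAK = ["CSA", "ATV", "SAG", "STNK", "STPA", "SGND", "SNDEQK", "NDEQHK",
        "NEQHRK", "FVLIM", "HFY"]
_AA = "ACDEFGHIKLMNPQRSTVWY"


def count_identity(row_a: str, row_b: str, partial: bool = False):
    """Column-count identity/similarity with the longest-sequence denominator.

    Returns (pct_identity, pct_similarity, n_identical, n_similar, denom).
    """
    cols = list(zip(row_a, row_b))
    if partial:
        idx = [i for i, (x, y) in enumerate(cols) if x != "-" and y != "-"]
        cols = cols[idx[0]:idx[-1] + 1]
    n_id = n_sim = 0
    for x, y in cols:
        if x in _AA and y in _AA:
            if x == y:
                n_id += 1
            elif any(x in g and y in g for g in STRONG):
                n_sim += 1
            elif any(x in g and y in g for g in WEAK):
                n_sim += 1
    len_a = sum(1 for x, _ in cols if x != "-")
    len_b = sum(1 for _, y in cols if y != "-")
    denom = max(len_a, len_b)
    return (100.0 * n_id / denom, 100.0 * (n_id + n_sim) / denom,
            n_id, n_sim, denom)


def motif_scan_oracle(seq: str, pattern: str, max_mismatches: int):
    """Literal sliding-window wildcard scan; returns (start, [(pos, exp, obs)])."""
    out = []
    k = len(pattern)
    for i in range(len(seq) - k + 1):
        subs = []
        for j in range(k):
            if pattern[j].lower() == "x":
                continue
            if seq[i + j] != pattern[j].upper():
                subs.append((j + 1, pattern[j].upper(), seq[i + j]))
        if len(subs) <= max_mismatches:
            out.append((i + 1, subs))
    return out
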