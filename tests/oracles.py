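"""Independent reference implementations used only as test oracles.

Plain-Python exhaustive dynamic programming for local (Smith–Waterman) and
global (Needleman–Wunsch) alignment under affine gaps, written from the
recurrences and kept deliberately separate from the package's alignment
path.
"""

NEG = float("-inf")


def sw_score(a, b, score_fn, gap_open, gap_extend):
    """Optimal local alignment score; gap of length L costs open + L*extend."""
    n, m = len(a), len(b)
    H = [[0.0] * (m + 1) for _ in range(n + 1)]
    E = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in a (vertical)
    F = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in b (horizontal)
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i][j] = max(E[i - 1][j] - gap_extend,
                          H[i - 1][j] - gap_open - gap_extend)
            F[i][j] = max(F[i][j - 1] - gap_extend,
                          H[i][j - 1] - gap_open - gap_extend)
            diag = H[i - 1][j - 1] + score_fn(a[i - 1], b[j - 1])
            H[i][j] = max(0.0, diag, E[i][j], F[i][j])
            best = max(best, H[i][j])
    return best


def nw_score(a, b, score_fn, gap_open, gap_extend):
    """Optimal global alignment score with end gaps penalized."""
    n, m = len(a), len(b)
    H = [[NEG] * (m + 1) for _ in range(n + 1)]
    E = [[NEG] * (m + 1) for _ in range(n + 1)]
    F = [[NEG] * (m + 1) for _ in range(n + 1)]
    H[0][0] = 0.0
    for i in range(1, n + 1):
        E[i][0] = -gap_open - i * gap_extend
        H[i][0] = E[i][0]
    for j in range(1, m + 1):
        F[0][j] = -gap_open - j * gap_extend
        H[0][j] = F[0][j]
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i][j] = max(E[i - 1][j] - gap_extend,
                          H[i - 1][j] - gap_open - gap_extend)
            F[i][j] = max(F[i][j - 1] - gap_extend,
                          H[i][j - 1] - gap_open - gap_extend)
            diag = H[i - 1][j - 1] + score_fn(a[i - 1], b[j - 1])
            H[i][j] = max(diag, E[i][j], F[i][j])
    return H[n][m]


def enumerate_greedy_matching(weighted_pairs, e_cutoff):
    """Direct transcription of the one-to-one matching rule for tiny inputs:
    sort admissible (evalue, -bit, a, b) candidates and accept while both
    partners are unused.
    """
    cands = sorted(
        (ev, -bit, a, b) for (a, b, ev, bit) in weighted_pairs if ev <= e_cutoff
    )
    used_a, used_b, out = set(), set(), []
    for ev, nbit, a, b in cands:
        if a not in used_a and b not in used_b:
            used_a.add(a)
            used_b.add(b)
            out.append((a, b))
    return out
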