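"""Brute-force oracles: naive loop re-implementations of the recurrence
measures, kept deliberately independent of the package's vectorised code."""

import numpy as np


def oracle_recurrence(dist, eps, theiler):
    T = len(dist)
    R = [[False] * T for _ in range(T)]
    for i in range(T):
        for j in range(T):
            if abs(i - j) > theiler and dist[i][j] <= eps:
                R[i][j] = True
    return R


def oracle_rqa(dist, eps, theiler, l_min=2):
    """RR / DET / LAM / mean diagonal line length by explicit enumeration."""
    T = len(dist)
    R = oracle_recurrence(dist, eps, theiler)
    n_elig = n_rec = 0
    for i in range(T):
        for j in range(T):
            if abs(i - j) > theiler:
                n_elig += 1
                if R[i][j]:
                    n_rec += 1
    rr = n_rec / n_elig
    if n_rec == 0:
        return rr, float("nan"), float("nan"), float("nan")

    diag_lines = []
    for off in range(theiler + 1, T):
        run = 0
        for i in range(T - off):
            if R[i][i + off]:
                run += 1
            elif run:
                diag_lines.append(run)
                run = 0
        if run:
            diag_lines.append(run)
    long_d = [l for l in diag_lines if l >= l_min]
    det = sum(long_d) / sum(diag_lines) if diag_lines else float("nan")
    mean_line = sum(long_d) / len(long_d) if long_d else float("nan")

    vert_lines = []
    for j in range(T):
        run = 0
        for i in range(T):
            if R[i][j]:
                run += 1
            elif run:
                vert_lines.append(run)
                run = 0
        if run:
            vert_lines.append(run)
    long_v = [l for l in vert_lines if l >= l_min]
    lam = sum(long_v) / sum(vert_lines) if vert_lines else float("nan")
    return rr, det, lam, mean_line


def oracle_strengths(dist, eps, theiler):
    """Strength centrality as per-row sums of linear similarity weights."""
    T = len(dist)
    R = oracle_recurrence(dist, eps, theiler)
    out = []
    for i in range(T):
        s = 0.0
        for j in range(T):
            if R[i][j]:
                s += 1.0 - dist[i][j] / eps
        out.append(s)
    return out
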