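"""Independent brute-force oracles used only by the test suite.

Each oracle re-derives a quantity from first principles with the simplest
possible algorithm, deliberately sharing no code with the implementation
it checks."""

from __future__ import annotations

import itertools
import math

from Bio.Align import substitution_matrices
from Bio.Data.CodonTable import standard_dna_table

_B62 = substitution_matrices.load("BLOSUM62")
_TABLE = standard_dna_table.forward_table
_STOPS = set(standard_dna_table.stop_codons)
_NEG = float("-inf")


def sw_score_oracle(a: str, b: str, gap_open: float = 11.0,
                    gap_extend: float = 1.0) -> float:
    """Quadratic-space Gotoh local-alignment DP; returns the optimal score."""
    n, m = len(a), len(b)
    h = [[0.0] * (m + 1) for _ in range(n + 1)]
    e = [[_NEG] * (m + 1) for _ in range(n + 1)]   # gap in a (consume b)
    f = [[_NEG] * (m + 1) for _ in range(n + 1)]   # gap in b (consume a)
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            e[i][j] = max(e[i][j - 1] - gap_extend,
                          h[i][j - 1] - gap_open - gap_extend)
            f[i][j] = max(f[i - 1][j] - gap_extend,
                          h[i - 1][j] - gap_open - gap_extend)
            s = float(_B62[a[i - 1], b[j - 1]])
            h[i][j] = max(0.0, h[i - 1][j - 1] + s, e[i][j], f[i][j])
            if h[i][j] > best:
                best = h[i][j]
    return best


def ng86_oracle(cds_a: str, cds_b: str):
    """Pathway-enumeration Nei-Gojobori estimate on an aligned codon pair."""
    assert len(cds_a) == len(cds_b) and len(cds_a) % 3 == 0

    def syn_sites(codon):
        aa = _TABLE[codon]
        syn = 0
        for pos in range(3):
            for base in "ACGT":
                if base == codon[pos]:
                    continue
                alt = codon[:pos] + base + codon[pos + 1:]
                if alt not in _STOPS and _TABLE[alt] == aa:
                    syn += 1
        return syn / 3.0

    S = N = Sd = Nd = 0.0
    for k in range(0, len(cds_a), 3):
        ca, cb = cds_a[k:k + 3], cds_b[k:k + 3]
        if ca in _STOPS or cb in _STOPS or set(ca + cb) - set("ACGT"):
            continue
        S += (syn_sites(ca) + syn_sites(cb)) / 2.0
        N += 3.0 - (syn_sites(ca) + syn_sites(cb)) / 2.0
        diff = [i for i in range(3) if ca[i] != cb[i]]
        if not diff:
            continue
        paths = []
        for order in itertools.permutations(diff):
            cur, sd, nd, ok = ca, 0, 0, True
            for pos in order:
                nxt = cur[:pos] + cb[pos] + cur[pos + 1:]
                if nxt in _STOPS:
                    ok = False
                    break
                if _TABLE[cur] == _TABLE[nxt]:
                    sd += 1
                else:
                    nd += 1
                cur = nxt
            if ok:
                paths.append((sd, nd))
        if not paths:        # all pathways blocked: fall back to all orders
            for order in itertools.permutations(diff):
                cur, sd, nd = ca, 0, 0
                for pos in order:
                    nxt = cur[:pos] + cb[pos] + cur[pos + 1:]
                    same = (cur not in _STOPS and nxt not in _STOPS
                            and _TABLE.get(cur) == _TABLE.get(nxt))
                    sd, nd = sd + (1 if same else 0), nd + (0 if same else 1)
                    cur = nxt
                paths.append((sd, nd))
        Sd += sum(p[0] for p in paths) / len(paths)
        Nd += sum(p[1] for p in paths) / len(paths)
    ps = Sd / S if S else None
    ks = None if ps is None or ps >= 0.75 else -0.75 * math.log(1 - 4 * ps / 3)
    return {"S": S, "N": N, "Sd": Sd, "Nd": Nd, "ps": ps, "ks": ks}


def wilcoxon_exact_oracle(x, y) -> float:
    """Two-sided exact rank-sum p by enumerating every group labeling."""
    pooled = list(x) + list(y)
    n1 = len(x)

    def u_stat(xs, ys):
        return sum((xi > yi) + 0.5 * (xi == yi) for xi in xs for yi in ys)

    u_obs = u_stat(list(x), list(y))
    us = []
    idx_all = range(len(pooled))
    for comb in itertools.combinations(idx_all, n1):
        chosen = set(comb)
        xs = [pooled[i] for i in comb]
        ys = [pooled[i] for i in idx_all if i not in chosen]
        us.append(u_stat(xs, ys))
    n = len(us)
    cdf = sum(u <= u_obs for u in us) / n
    sf = sum(u >= u_obs for u in us) / n
    return min(1.0, 2.0 * min(cdf, sf))


def chain_oracle(anchors, max_gap: int) -> int:
    """Longest gap-bounded monotone chain by exhaustive recursion.

    ``anchors`` are (rank_a, rank_b) pairs; the chain must be strictly
    increasing on the first axis and strictly monotone on the second, with
    both gaps <= max_gap."""
    best = 0
    for orient in (1, -1):
        pts = sorted((ra, orient * rb) for ra, rb in anchors)

        def extend(last, remaining):
            top = 0
            for k, (ra, rb) in enumerate(remaining):
                if last is None or (
                        last[0] < ra <= last[0] + max_gap
                        and last[1] < rb <= last[1] + max_gap):
                    top = max(top, 1 + extend((ra, rb), remaining[k + 1:]))
            return top

        best = max(best, extend(None, pts))
    return best
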