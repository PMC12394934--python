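"""Independent brute-force oracles used only by the test suite.

Each oracle derives the expected answer from first principles by a route
independent of the library implementation (substring enumeration for
digestion, full rank-assignment enumeration for the exact Mann-Whitney
p-value, single-site summation for charge).
"""

from itertools import combinations


def brute_force_digest(protein, p1_residues, max_missed, min_len=1, max_len=10**9):
    """Every substring that starts and ends at a cleavage boundary and
    spans at most ``max_missed`` internal uncut sites, with multiplicity
    (one emission per (start, end) pair)."""
    n = len(protein)
    sites = {i for i in range(n - 1) if protein[i] in p1_residues}
    out = []
    for a in range(n):
        if not (a == 0 or (a - 1) in sites):
            continue
        for b in range(a + 1, n + 1):
            if not (b == n or (b - 1) in sites):
                continue
            internal = sum(1 for i in sites if a <= i <= b - 2)
            if internal <= max_missed and min_len <= b - a <= max_len:
                out.append(protein[a:b])
    return sorted(out)


def exact_mwu_pvalue(x, y):
    """Exact two-sided Mann-Whitney p by enumerating all rank assignments
    (tie-free samples only): the fraction of label assignments whose U
    deviates from its mean at least as much as observed."""
    pooled = sorted(x + y)
    assert len(set(pooled)) == len(pooled), "oracle requires tie-free samples"
    nx, ny = len(x), len(y)
    u_obs = sum(1 for xi in x for yj in y if xi > yj)
    mean = nx * ny / 2.0
    count = total = 0
    idx = range(nx + ny)
    for xs in combinations(idx, nx):
        xs_set = set(xs)
        u = sum(1 for i in xs_set for j in idx if j not in xs_set and pooled[i] > pooled[j])
        total += 1
        if abs(u - mean) >= abs(u_obs - mean) - 1e-12:
            count += 1
    return count / total


def single_site_charge(sequence, pH, pka):
    """Net charge as an explicit per-site list summation."""
    sites = [("pos", pka.n_term), ("neg", pka.c_term)]
    side = {"H": "pos", "K": "pos", "R": "pos",
            "D": "neg", "E": "neg", "C": "neg", "Y": "neg"}
    for aa in sequence:
        if aa in side:
            sites.append((side[aa], pka.side_chains[aa]))
    total = 0.0
    for kind, k in sites:
        if kind == "pos":
            total += 1.0 / (1.0 + 10.0 ** (pH - k))
        else:
            total -= 1.0 / (1.0 + 10.0 ** (k - pH))
    return total
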