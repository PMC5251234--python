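"""Independent from-definition oracles, free of the package's numerics.

The multi-scale similarity oracle re-implements the whole pipeline —
characteristic annotation, step encoding, linear resampling, the Haar
pyramid, per-level Pearson — with plain Python loops and the textbook
formulas, sharing no transform code with the package.
"""

import math

# step map restated independently (base, paired) -> three vertical steps
ORACLE_STEPS = {
    ("A", False): (1, 1, 1),
    ("A", True): (-1, -1, 1),
    ("U", False): (1, -1, 1),
    ("U", True): (-1, 1, 1),
    ("G", False): (1, -1, -1),
    ("G", True): (1, 1, -1),
    ("C", False): (-1, 1, -1),
    ("C", True): (-1, -1, -1),
}


def oracle_signal(seq, dotbracket, kind="cumulative"):
    """Steps or cumulative ordinates via direct rule application."""
    paired = [False] * len(seq)
    stack = []
    for i, ch in enumerate(dotbracket):
        if ch == "(":
            stack.append(i)
        elif ch == ")":
            j = stack.pop()
            paired[i] = paired[j] = True
    steps = []
    for base, p in zip(seq, paired):
        steps.extend(ORACLE_STEPS[(base, p)])
    if kind == "steps":
        return [float(s) for s in steps]
    out, total = [], 0
    for s in steps:
        total += s
        out.append(float(total))
    return out


def oracle_resample(signal, target_len):
    """Linear interpolation on a uniform [0, 1] grid, by hand."""
    n = len(signal)
    if n == target_len:
        return list(signal)
    out = []
    for k in range(target_len):
        t = k / (target_len - 1) * (n - 1)
        lo = min(int(math.floor(t)), n - 2)
        frac = t - lo
        out.append(signal[lo] * (1 - frac) + signal[lo + 1] * frac)
    return out


def oracle_haar(signal, levels):
    """Plain orthonormal Haar pyramid: a=(even+odd)/sqrt2, d=(even-odd)/sqrt2.

    Returns (approx, [d_1 .. d_L]) with d_1 the finest level.
    """
    approx = list(signal)
    details = []
    for _ in range(levels):
        nxt, det = [], []
        for i in range(0, len(approx), 2):
            nxt.append((approx[i] + approx[i + 1]) / math.sqrt(2))
            det.append((approx[i] - approx[i + 1]) / math.sqrt(2))
        details.append(det)
        approx = nxt
    return approx, details


def oracle_pearson(u, v):
    """Textbook Pearson with the shared zero-variance convention."""
    u_const = all(x == u[0] for x in u)
    v_const = all(x == v[0] for x in v)
    if u_const or v_const:
        return 1.0 if (u_const and v_const and list(u) == list(v)) else 0.0
    n = len(u)
    mu = sum(u) / n
    mv = sum(v) / n
    cov = sum((a - mu) * (b - mv) for a, b in zip(u, v))
    su = math.sqrt(sum((a - mu) ** 2 for a in u))
    sv = math.sqrt(sum((b - mv) ** 2 for b in v))
    return cov / (su * sv)


def oracle_multiscale_similarity(seq_a, db_a, seq_b, db_b, levels=4,
                                 kind="cumulative", weights=None):
    """Straight-line re-computation of the weighted multi-scale similarity."""
    sig_a = oracle_signal(seq_a, db_a, kind)
    sig_b = oracle_signal(seq_b, db_b, kind)
    target = 2
    while target < max(len(sig_a), len(sig_b)):
        target *= 2
    sig_a = oracle_resample(sig_a, target)
    sig_b = oracle_resample(sig_b, target)
    levels = min(levels, int(math.log2(target)))
    approx_a, det_a = oracle_haar(sig_a, levels)
    approx_b, det_b = oracle_haar(sig_b, levels)
    if weights is None:
        weights = [1.0 / (levels + 1)] * (levels + 1)
    corr = [oracle_pearson(approx_a, approx_b)]
    corr += [oracle_pearson(det_a[j], det_b[j]) for j in range(levels)]
    return math.fsum(w * c for w, c in zip(weights, corr))


def oracle_upgma_merges(labels, matrix):
    """Brute-force UPGMA that re-averages raw leaf entries every round.

    Returns the merge history as (leafset_a, leafset_b, height) with
    the same tie-break: smallest distance, then lexicographically
    smallest (min-label, partner-label) cluster pair.
    """
    index = {lab: i for i, lab in enumerate(labels)}
    clusters = [frozenset([lab]) for lab in labels]
    merges = []
    while len(clusters) > 1:
        best = None
        for a in clusters:
            for b in clusters:
                if min(a) >= min(b):
                    continue
                d = sum(matrix[index[x]][index[y]] for x in a for y in b) / (
                    len(a) * len(b)
                )
                cand = (d, min(a), min(b))
                if best is None or cand < best:
                    best = cand
                    best_pair = (a, b)
        a, b = best_pair
        merges.append((tuple(sorted(a)), tuple(sorted(b)), best[0] / 2.0))
        clusters = [c for c in clusters if c not in (a, b)] + [a | b]
    return merges
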