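"""Independent brute-force oracles used by the test suite.

Everything here is deliberately naive: explicit loops, exhaustive
enumeration and exact rational arithmetic, sharing no code with the package
implementations they check.
"""

from __future__ import annotations

import itertools
from fractions import Fraction

HOM_REF, HET, HOM_ALT, MISSING = 0, 1, 2, -1


# ---------------------------------------------------------------------------
# ROH caller: materialize every window and per-site proportion explicitly
# ---------------------------------------------------------------------------

def brute_force_segments(calls, positions, params):
    """Reference windowed ROH caller for one individual-chromosome.

    Returns (start_pos, end_pos, n_snp, n_het) tuples.  O(n * window) —
    usable only on small instances.
    """
    n = len(calls)
    w = params.window_snp
    windows = []
    for a in range(0, n - w + 1):
        block = calls[a : a + w]
        hets = sum(1 for c in block if c == HET)
        missing = sum(1 for c in block if c == MISSING)
        windows.append(hets <= params.window_het and missing <= params.window_missing)

    in_state = []
    for s in range(n):
        covering = [
            windows[a] for a in range(len(windows)) if a <= s <= a + w - 1
        ]
        if not covering:
            in_state.append(False)
        else:
            frac = sum(covering) / len(covering)
            in_state.append(frac >= params.window_threshold - 1e-12)

    # maximal runs of in-state sites, split at large physical gaps
    runs = []
    current = None
    for s in range(n):
        if not in_state[s]:
            if current is not None:
                runs.append(current)
                current = None
            continue
        if current is None:
            current = [s, s]
        else:
            if positions[s] - positions[current[1]] > params.max_gap_kb * 1000:
                runs.append(current)
                current = [s, s]
            else:
                current[1] = s
    if current is not None:
        runs.append(current)

    segments = []
    for a, b in runs:
        while a <= b and calls[a] in (HET, MISSING):
            a += 1
        while b >= a and calls[b] in (HET, MISSING):
            b -= 1
        if a > b:
            continue
        n_snp = b - a + 1
        length = positions[b] - positions[a] + 1
        if n_snp < params.min_snp_final:
            continue
        if length < params.min_kb_final * 1000:
            continue
        if n_snp / (length / 1000) < 1 / params.density_kb_per_snp:
            continue
        n_het = sum(1 for c in calls[a : b + 1] if c == HET)
        segments.append((int(positions[a]), int(positions[b]), n_snp, n_het))
    return segments


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact test
# ---------------------------------------------------------------------------

def hwe_oracle_formula(n_het, n_hom_ref, n_hom_alt):
    """Exact two-sided HWE p via rational arithmetic on the conditional pmf."""
    n = n_het + n_hom_ref + n_hom_alt
    n_a = 2 * min(n_hom_ref, n_hom_alt) + n_het
    if n_a == 0:
        return Fraction(1)
    probs = {}
    for k in range(n_a % 2, n_a + 1, 2):
        aa = (n_a - k) // 2
        bb = n - aa - k
        if bb < 0:
            continue
        num = Fraction(2**k)
        # multinomial coefficient n! / (aa! k! bb!)
        from math import factorial

        num *= Fraction(factorial(n), factorial(aa) * factorial(k) * factorial(bb))
        probs[k] = num
    total = sum(probs.values())
    p_obs = probs[n_het]
    return sum(p for p in probs.values() if p <= p_obs) / total


def hwe_oracle_enumeration(n_het, n_hom_ref, n_hom_alt, allele_freq=Fraction(1, 3)):
    """HWE p for tiny cohorts by exhaustive genotype-assignment enumeration.

    Enumerates every assignment of {hom_ref, het, hom_alt} to the n
    individuals under HWE with an arbitrary rational allele frequency,
    conditions on the observed allele count, and sums the conditional
    probabilities of het counts no more likely than the observed one.  The
    conditional distribution is frequency-free, so any 0 < p < 1 works.
    """
    n = n_het + n_hom_ref + n_hom_alt
    q = allele_freq
    geno_p = {0: (1 - q) ** 2, 1: 2 * q * (1 - q), 2: q**2}
    alt_count = 2 * n_hom_alt + n_het
    cond = {}
    for assignment in itertools.product((0, 1, 2), repeat=n):
        if sum(assignment) != alt_count:
            continue
        prob = Fraction(1)
        for g in assignment:
            prob *= geno_p[g]
        k = sum(1 for g in assignment if g == 1)
        cond[k] = cond.get(k, Fraction(0)) + prob
    total = sum(cond.values())
    p_obs = cond[n_het] / total
    return sum(p for p in cond.values() if p / total <= p_obs) / total


# ---------------------------------------------------------------------------
# Mann-Whitney-Wilcoxon exact enumeration
# ---------------------------------------------------------------------------

def mww_oracle(a, b):
    """Exact two-sided rank-sum p by enumerating all label assignments.

    Midranks handle ties; the two-sided p counts assignments whose U deviates
    from its permutation mean at least as much as the observed U (the U
    permutation distribution is symmetric, so this equals doubled-tail
    counting for tie-free data).
    """
    a, b = list(a), list(b)
    pooled = a + b
    n = len(pooled)
    n_a = len(a)
    order = sorted(range(n), key=lambda i: pooled[i])
    ranks = [0.0] * n
    i = 0
    while i < n:
        j = i
        while j + 1 < n and pooled[order[j + 1]] == pooled[order[i]]:
            j += 1
        mid = (i + j) / 2 + 1
        for k in range(i, j + 1):
            ranks[order[k]] = mid
        i = j + 1
    offset = n_a * (n_a + 1) / 2
    mean_u = n_a * len(b) / 2
    dev_obs = abs(sum(ranks[:n_a]) - offset - mean_u)
    count = total = 0
    for idx in itertools.combinations(range(n), n_a):
        u = sum(ranks[i] for i in idx) - offset
        if abs(u - mean_u) >= dev_obs - 1e-12:
            count += 1
        total += 1
    return count / total


# ---------------------------------------------------------------------------
# ep: direct summation over all qualifying segments
# ---------------------------------------------------------------------------

def ep_oracle(segments, min_mb=1.0):
    """Unbinned mean per-segment het fraction x 100 over segments >= min_mb.

    ``segments`` is a sequence of (length_bp, n_snp, n_het) triples.
    Returns None when no segment qualifies.
    """
    fractions = [
        n_het / n_snp
        for length_bp, n_snp, n_het in segments
        if length_bp / 1e6 >= min_mb
    ]
    if not fractions:
        return None
    return 100.0 * sum(fractions) / len(fractions)
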