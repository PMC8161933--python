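"""Independent brute-force re-implementations used only as test oracles.

Everything here is written from scratch in plain Python (dicts, loops) and
deliberately shares no code with the package: matrix literals, observation
probabilities, per-base scores and window statistics are all re-derived.
"""

from __future__ import annotations

BASES = "ACGT"

# bisulfite substitution scores for the original-top strand, (ref, read) -> score
OT = {}
_rows = {
    "A": [6, -18, -18, -18, -25],
    "C": [-18, 6, -18, 3, -25],
    "G": [-18, -18, 6, -18, -25],
    "T": [-18, -18, -18, 3, -25],
    "N": [-25, -25, -25, -25, 25],
}
for _ref, _vals in _rows.items():
    for _read, _v in zip("ACGTN", _vals):
        OT[(_ref, _read)] = _v

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}
OB = {(r, q): OT[(_COMP[r], _COMP[q])] for r in "ACGTN" for q in "ACGTN"}


def matrix(strand):
    return OT if strand == "OT" else OB


def row_total(strand, gs):
    tbl = matrix(strand)
    return sum(tbl[(gs, b)] for b in BASES)


def obs_prob(mk, gs, snp, m_cpg, m_ch, strand="OT", context=0):
    """P(Mk | Gs) by explicit enumeration of the observation cases."""
    if mk == "N" or gs == "N":
        return 0.25
    special = "C" if strand == "OT" else "G"
    converted = "T" if strand == "OT" else "A"
    row = {b: (1.0 - snp if b == gs else snp / 3.0) for b in BASES}
    if gs == special and context in (1, 2):
        m = m_cpg if context == 1 else m_ch
        row[special] = (1.0 - snp) * m
        row[converted] = snp / 3.0 + (1.0 - snp) * (1.0 - m)
    total = sum(row.values())
    return row[mk] / total


def eq4(mk, gs, snp, m_cpg, m_ch, strand="OT", context=0):
    p = obs_prob(mk, gs, snp, m_cpg, m_ch, strand, context)
    sc = matrix(strand)[(gs, mk)]
    return p * sc + (1.0 - p) * (row_total(strand, gs) - sc)


def eq5(mk, ult, eps_k, eps_lt, mode="corrected"):
    both = eps_lt + eps_k - eps_lt * eps_k
    if mode == "corrected":
        return 1.0 - both if mk == ult else both
    return both if mk == ult else 1.0 - both


def eq67(mk, stack, eps_k, strand="OT", mode="corrected"):
    """Mean over (ult, eps_lt) pairs of the per-unique-read weighted score."""
    tbl = matrix(strand)
    acc = 0.0
    for ult, eps_lt in stack:
        p = eq5(mk, ult, eps_k, eps_lt, mode)
        sc = tbl[(ult, mk)]
        acc += p * sc + (1.0 - p) * (row_total(strand, ult) - sc)
    return acc / len(stack)


def context_at(ref, pos):
    """1 = CpG, 2 = CH at C/G sites, 0 elsewhere; linear re-derivation."""
    b = ref[pos]
    if b == "C":
        return 1 if pos + 1 < len(ref) and ref[pos + 1] == "G" else 2
    if b == "G":
        return 1 if pos > 0 and ref[pos - 1] == "C" else 2
    return 0


def eq8(ref, read, start, strand, unique_reads, snp, m_cpg, m_ch, mode="corrected",
        read_eps=None):
    """Full-enumeration candidate score for a gapless read.

    ``unique_reads``: list of (start, bases, eps_list); overlap is found by
    linear scan per locus.
    """
    total = 0.0
    for k, mk in enumerate(read):
        pos = start + k
        gs = ref[pos]
        ctx = context_at(ref, pos)
        s_ref = eq4(mk, gs, snp, m_cpg, m_ch, strand, ctx)
        stack = []
        eps_k = read_eps[k] if read_eps is not None else 1e-4
        for ustart, ubases, ueps in unique_reads:
            t = pos - ustart
            if 0 <= t < len(ubases):
                stack.append((ubases[t], ueps[t]))
        s_uni = eq67(mk, stack, eps_k, strand, mode) if stack else s_ref
        total += (s_ref + s_uni) / 2.0
    return total


def eq9(a):
    n = len(a)
    x_bar = sum(a) / n
    return sum((x - x_bar) ** 2 for x in a) / n


def eq1(p, r):
    return 0.0 if p + r == 0 else 2.0 * p * r / (p + r)


def eq23(n_random, n_our):
    tot = n_random + n_our
    return n_random / tot, n_our / tot
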