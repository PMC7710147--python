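"""Independent brute-force oracles, kept deliberately naive.

These recompute expected results by exhaustive enumeration or direct
arithmetic, without touching the implementation paths they check.
"""

RESIDUE_MASSES = {
    "G": 57.021464, "A": 71.037114, "S": 87.032028, "P": 97.052764,
    "V": 99.068414, "T": 101.047678, "C": 103.009185, "L": 113.084064,
    "I": 113.084064, "N": 114.042927, "D": 115.026943, "Q": 128.058578,
    "K": 128.094963, "E": 129.042593, "M": 131.040485, "H": 137.058912,
    "F": 147.068414, "R": 156.101111, "Y": 163.063329, "W": 186.079313,
}


def mass_sum(sequence, mod_deltas=()):
    total = 18.010565 + sum(RESIDUE_MASSES[aa] for aa in sequence)
    return total + sum(mod_deltas)


def naive_sites(seq, residues, side="C", restrict_before_proline=False):
    """1-based bond positions, recomputed by direct rule application."""
    sites = []
    for p in range(1, len(seq)):
        if side == "C":
            hit = seq[p - 1] in residues
            if hit and restrict_before_proline and seq[p] == "P":
                hit = False
        else:
            hit = seq[p] in residues
        if hit:
            sites.append(p)
    return sites


def brute_force_digest(seq, sites, max_missed, min_len, max_len):
    """All (start, end) spans passing the specific/missed/length predicate."""
    site_set = set(sites)
    n = len(seq)
    out = set()
    for s in range(1, n + 1):
        if not (s == 1 or (s - 1) in site_set):
            continue
        for e in range(s, n + 1):
            if not (e == n or e in site_set):
                continue
            if not min_len <= e - s + 1 <= max_len:
                continue
            if sum(1 for p in sites if s <= p < e) <= max_missed:
                out.add((s, e))
    return out


def brute_force_semi(seq, sites, max_missed, min_len, max_len, max_ext):
    """Spans with exactly one specific terminus, trim distance <= max_ext."""
    site_set = set(sites)
    n = len(seq)
    boundaries = sorted({0, n} | site_set)
    out = set()
    for s in range(1, n + 1):
        for e in range(s, n + 1):
            ns = s == 1 or (s - 1) in site_set
            cs = e == n or e in site_set
            if ns == cs:
                continue
            if not min_len <= e - s + 1 <= max_len:
                continue
            if sum(1 for p in sites if s <= p < e) > max_missed:
                continue
            if not ns:
                trim = (s - 1) - max(b for b in boundaries if b <= s - 1)
                if trim > max_ext:
                    continue
            if not cs:
                trim = min(b for b in boundaries if b >= e) - e
                if trim > max_ext:
                    continue
            out.add((s, e))
    return out


def brute_force_align(query, reference, il_equivalent):
    """(best_start, best_mismatches) by sliding-window scan; ties → smallest."""
    def fold(s):
        return s.replace("L", "I") if il_equivalent else s

    q, r = fold(query), fold(reference)
    best = None
    for start in range(len(r) - len(q) + 1):
        mm = sum(1 for a, b in zip(q, r[start : start + len(q)]) if a != b)
        if best is None or mm < best[1]:
            best = (start + 1, mm)
    return best
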