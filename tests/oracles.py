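"""Independent brute-force oracles used to pin down the contracts of the
optimised implementations. Each oracle shares only the primitive energy /
matching definitions with the code under test, never its search strategy."""

from __future__ import annotations

from lagenome.energy import EnergyModel
from lagenome.fold import pairable, structure_energy
from lagenome.sequences import reverse_complement


# ---------------------------------------------------------------------------
# folding


def enumerate_all_hairpins(seq: str, model: EnergyModel, max_two_loop: int | None = None):
    """Every nested single-hairpin structure (as a pair chain) with its
    energy, by direct recursive enumeration."""
    cap = model.max_loop if max_two_loop is None else min(model.max_loop, max_two_loop)
    n = len(seq)
    min_span = model.min_hairpin_loop + 1
    out = []

    def extend(chain):
        i, j = chain[-1]
        out.append((list(chain), structure_energy(seq, chain, model)))
        for k in range(i + 1, min(i + cap + 1, j - min_span) + 1):
            b5 = k - i - 1
            for l in range(max(k + min_span, j - 1 - (cap - b5)), j):
                if pairable(seq[k], seq[l]):
                    extend(chain + [(k, l)])

    for i in range(n):
        for j in range(i + min_span, n):
            if pairable(seq[i], seq[j]):
                extend([(i, j)])
    return out


def brute_force_mfe(seq: str, model: EnergyModel):
    """(energy, pairs) of the best structure, or (0.0, None) if none < 0."""
    best_e, best_pairs = 0.0, None
    for pairs, e in enumerate_all_hairpins(seq, model):
        if e < best_e - 1e-12:
            best_e, best_pairs = e, pairs
    return best_e, best_pairs


# ---------------------------------------------------------------------------
# exact matching


def brute_force_maximal_matches(a: str, b: str, min_len: int):
    """All maximal exact matches >= min_len between a and b, by scanning
    every diagonal for runs of equality. Returns (start_a, start_b, length)
    triples, 0-based."""
    out = []
    for diag in range(-(len(a) - 1), len(b)):
        i = max(0, -diag)
        j = i + diag
        run = 0
        while i <= len(a) and j <= len(b):
            if i < len(a) and j < len(b) and a[i] == b[j]:
                run += 1
            else:
                if run >= min_len:
                    out.append((i - run, j - run, run))
                run = 0
            i += 1
            j += 1
    return sorted(out)


def brute_force_palindromes(seq: str, min_arm: int, max_loop: int, max_mismatch: int):
    """All (start, end, arm, loop, mismatches) hits (1-based inclusive span)
    where the left arm pairs the right arm in reverse complement with at
    most max_mismatch substitutions, the outermost arm position matches,
    and the arms cannot be extended outward within the mismatch budget."""
    n = len(seq)
    hits = []
    for loop in range(max_loop + 1):
        for mid in range(n):
            right = mid + loop
            max_arm = min(mid, n - right)
            mism_at = []
            for arm in range(1, max_arm + 1):
                l, r = seq[mid - arm], seq[right + arm - 1]
                mism_at.append(reverse_complement(l) != r)
            best = None
            for arm in range(min_arm, max_arm + 1):
                m = sum(mism_at[:arm])
                if m <= max_mismatch and not mism_at[arm - 1]:
                    best = (arm, m)
            if best:
                arm, m = best
                hits.append((mid - arm + 1, right + arm, arm, loop, m))
    # non-redundant: drop spans contained in a kept longer span
    kept = []
    for h in sorted(hits, key=lambda h: -(h[1] - h[0])):
        if any(k[0] <= h[0] and h[1] <= k[1] and k != h for k in kept):
            continue
        kept.append(h)
    return sorted(kept)


# ---------------------------------------------------------------------------
# phylogenetics


def three_taxon_branch_lengths(d_ab: float, d_ac: float, d_bc: float):
    """Closed-form unrooted star for three taxa."""
    a = (d_ab + d_ac - d_bc) / 2
    b = (d_ab + d_bc - d_ac) / 2
    c = (d_ac + d_bc - d_ab) / 2
    return a, b, c
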