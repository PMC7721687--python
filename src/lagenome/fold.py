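"""Minimum-free-energy folding of single RNA hairpins.

The cis signals of LA genomes (frameshift, packaging, replication stem
loops) are all simple hairpins, so the folding search space is restricted
to nested single-hairpin structures: one helix, possibly interrupted by
bulges and internal loops (each <= 30 nt), closed by a hairpin loop of
>= 3 unpaired bases. Pseudoknots and multiloops are out of scope.

The search is an exact dynamic programme over closing pairs; an exhaustive
structure enumeration serves as its oracle in the test suite. Energies are
kcal/mol; ``dG_kJ`` converts by the exact factor 4.184 because the source
publications for these genomes print kJ/mol.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .energy import EnergyModel, INF, KCAL_TO_KJ, PAIRS, default_model

MAX_FOLD_LEN = 200


class FoldingError(ValueError):
    pass


def to_rna(seq: str) -> str:
    s = seq.upper().replace("T", "U")
    bad = set(s) - set("ACGUN")
    if bad:
        raise FoldingError(f"bad alphabet: {sorted(bad)}")
    return s


def pairable(a: str, b: str) -> bool:
    return a + b in PAIRS


@dataclass(frozen=True)
class Hairpin:
    """A folded stem loop on the input sequence (0-based indices)."""

    pairs: tuple[tuple[int, int], ...]  # outermost first, strictly nested
    dG_kcal: float
    sequence: str  # RNA alphabet

    def __post_init__(self) -> None:
        for (i, j), (k, l) in zip(self.pairs, self.pairs[1:]):
            if not (i < k < l < j):
                raise FoldingError("pairs are not strictly nested")

    @property
    def dG_kJ(self) -> float:
        return self.dG_kcal * KCAL_TO_KJ

    @property
    def span(self) -> tuple[int, int]:
        i, j = self.pairs[0]
        return (i, j)

    @property
    def loop(self) -> tuple[int, int]:
        """0-based half-open interval of the unpaired hairpin loop."""
        i, j = self.pairs[-1]
        return (i + 1, j)

    @property
    def loop_seq(self) -> str:
        a, b = self.loop
        return self.sequence[a:b]

    @property
    def n_stem_pairs(self) -> int:
        return len(self.pairs)

    def dot_bracket(self) -> str:
        chars = ["."] * len(self.sequence)
        for i, j in self.pairs:
            chars[i], chars[j] = "(", ")"
        return "".join(chars)


def structure_energy(seq: str, pairs: list[tuple[int, int]], model: EnergyModel) -> float:
    """Free energy of an explicit nested single-hairpin structure.

    Shared by the dynamic programme and the exhaustive oracle so that both
    score candidate structures identically.
    """
    if not pairs:
        return 0.0
    e = model.au_penalty(seq[pairs[0][0]] + seq[pairs[0][1]])
    for (i, j), (k, l) in zip(pairs, pairs[1:]):
        e += model.two_loop_energy(
            seq[i] + seq[j], seq[k] + seq[l], k - i - 1, j - l - 1
        )
    i, j = pairs[-1]
    e += model.hairpin_loop_energy(seq[i] + seq[j], j - i - 1, seq[i + 1], seq[j - 1])
    return e


def _dp_tables(seq: str, model: EnergyModel, max_two_loop: int | None = None):
    """V[i][j]: MFE of a hairpin whose outermost pair is (i, j), without the
    exterior terminal-AU term. *max_two_loop* optionally tightens the
    bulge/interior size bound below the model's cap (used by genome scans
    for speed; MFE hairpins essentially never use large interior loops)."""
    n = len(seq)
    cap = model.max_loop if max_two_loop is None else min(model.max_loop, max_two_loop)
    V = [[INF] * n for _ in range(n)]
    min_span = model.min_hairpin_loop + 1
    for span in range(min_span, n):
        for i in range(0, n - span):
            j = i + span
            if not pairable(seq[i], seq[j]):
                continue
            best = model.hairpin_loop_energy(
                seq[i] + seq[j], j - i - 1, seq[i + 1], seq[j - 1]
            )
            outer = seq[i] + seq[j]
            kmax = min(i + cap + 1, j - min_span)
            for k in range(i + 1, kmax + 1):
                b5 = k - i - 1
                lmin = max(k + min_span, j - 1 - (cap - b5))
                for l in range(lmin, j):
                    vkl = V[k][l]
                    if vkl == INF:
                        continue
                    e = model.two_loop_energy(outer, seq[k] + seq[l], b5, j - l - 1) + vkl
                    if e < best:
                        best = e
            V[i][j] = best
    return V


def _traceback(seq: str, V, i: int, j: int, model: EnergyModel,
               max_two_loop: int | None = None) -> list[tuple[int, int]]:
    cap = model.max_loop if max_two_loop is None else min(model.max_loop, max_two_loop)
    pairs = [(i, j)]
    min_span = model.min_hairpin_loop + 1
    while True:
        target = V[i][j]
        hp = model.hairpin_loop_energy(seq[i] + seq[j], j - i - 1, seq[i + 1], seq[j - 1])
        if math.isclose(hp, target, abs_tol=1e-9):
            return pairs
        outer = seq[i] + seq[j]
        found = False
        kmax = min(i + cap + 1, j - min_span)
        for k in range(i + 1, kmax + 1):
            b5 = k - i - 1
            lmin = max(k + min_span, j - 1 - (cap - b5))
            for l in range(lmin, j):
                if V[k][l] == INF:
                    continue
                e = model.two_loop_energy(outer, seq[k] + seq[l], b5, j - l - 1) + V[k][l]
                if math.isclose(e, target, abs_tol=1e-9):
                    pairs.append((k, l))
                    i, j = k, l
                    found = True
                    break
            if found:
                break
        if not found:  # pragma: no cover - would indicate a DP/table mismatch
            raise FoldingError("traceback failed")


def fold_hairpin(seq: str, model: EnergyModel | None = None,
                 max_two_loop: int | None = None) -> Hairpin | None:
    """MFE single hairpin of *seq* (DNA or RNA), or None if no structure
    with negative free energy exists. Unpaired flanking bases are free."""
    model = model or default_model()
    rna = to_rna(seq)
    if len(rna) < 5:
        raise FoldingError("sequence shorter than 5 nt cannot form a hairpin")
    if len(rna) > MAX_FOLD_LEN:
        raise FoldingError(
            f"sequence longer than {MAX_FOLD_LEN} nt: use enumerate on windows"
        )
    V = _dp_tables(rna, model, max_two_loop)
    n = len(rna)
    best, best_ij = 0.0, None
    for i in range(n):
        for j in range(i + 1, n):
            if V[i][j] == INF:
                continue
            e = V[i][j] + model.au_penalty(rna[i] + rna[j])
            if e < best - 1e-12 or (
                best_ij is not None
                and math.isclose(e, best, abs_tol=1e-9)
                and (j - i, i) < (best_ij[1] - best_ij[0], best_ij[0])
            ):
                best, best_ij = e, (i, j)
    if best_ij is None or best >= 0:
        return None
    pairs = _traceback(rna, V, best_ij[0], best_ij[1], model, max_two_loop)
    return Hairpin(pairs=tuple(pairs), dG_kcal=best, sequence=rna)


def enumerate_hairpins(
    seq: str,
    model: EnergyModel | None = None,
    suboptimality_percent: float = 5.0,
    max_count: int = 50,
    max_two_loop: int | None = None,
) -> list[Hairpin]:
    """Distinct hairpins with dG within *suboptimality_percent* of the MFE,
    best first (ties: smaller span, then 5'-most), capped at *max_count*."""
    model = model or default_model()
    rna = to_rna(seq)
    mfe_hp = fold_hairpin(rna, model, max_two_loop)
    if mfe_hp is None:
        return []
    threshold = mfe_hp.dG_kcal * (1 - suboptimality_percent / 100.0) + 1e-9
    V = _dp_tables(rna, model, max_two_loop)
    n = len(rna)
    out: list[Hairpin] = []
    cap = model.max_loop if max_two_loop is None else min(model.max_loop, max_two_loop)
    min_span = model.min_hairpin_loop + 1

    def emit(i, j, acc, pairs):
        """Enumerate completions of a structure whose innermost pair so far
        is (i, j), with accumulated exterior+loop energy *acc*."""
        hp = model.hairpin_loop_energy(rna[i] + rna[j], j - i - 1, rna[i + 1], rna[j - 1])
        if acc + hp <= threshold:
            out.append(Hairpin(pairs=tuple(pairs), dG_kcal=acc + hp, sequence=rna))
        outer = rna[i] + rna[j]
        kmax = min(i + cap + 1, j - min_span)
        for k in range(i + 1, kmax + 1):
            b5 = k - i - 1
            lmin = max(k + min_span, j - 1 - (cap - b5))
            for l in range(lmin, j):
                if V[k][l] == INF:
                    continue
                e = model.two_loop_energy(outer, rna[k] + rna[l], b5, j - l - 1)
                if acc + e + V[k][l] <= threshold:
                    emit(k, l, acc + e, pairs + [(k, l)])

    for i in range(n):
        for j in range(i + min_span, n):
            if V[i][j] == INF:
                continue
            au = model.au_penalty(rna[i] + rna[j])
            if au + V[i][j] <= threshold:
                emit(i, j, au, [(i, j)])

    out.sort(key=lambda h: (h.dG_kcal, h.span[1] - h.span[0], h.span[0]))
    return out[:max_count]
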