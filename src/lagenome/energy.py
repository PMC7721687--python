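"""Nearest-neighbor free-energy model for hairpin folding.

Free energies are the published Turner 2004 RNA parameters at 37 degC in
1 M NaCl, shipped as TSV data files: helix stacks (Watson-Crick and GU
wobble), loop-size initiation penalties for hairpin/bulge/internal loops
(sizes capped at 30, mirroring the MFOLD settings used for these genomes),
hairpin-loop terminal mismatches, the 0.5 kcal/mol terminal-AU/GU penalty
and the Ninio asymmetry term. Interior and bulge loops carry no mismatch
terms: their omitted first-mismatch bonuses and AU-closure penalties are
of similar magnitude and opposite sign, so the simpler model stays within
the tolerances used throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources

INF = math.inf
KCAL_TO_KJ = 4.184

PAIRS = {"AU", "UA", "CG", "GC", "GU", "UG"}


def _read_tsv(name: str) -> list[list[str]]:
    text = resources.files("lagenome.data").joinpath(name).read_text()
    rows = []
    for line in text.splitlines():
        if not line or line.startswith("#"):
            continue
        rows.append(line.split("\t"))
    return rows


def _f(x: str) -> float:
    return INF if x == "inf" else float(x)


@dataclass(frozen=True)
class EnergyModel:
    """Free-energy tables (kcal/mol, 37 degC) for single-hairpin folding."""

    stack: dict = field(repr=False)
    hairpin_init: dict = field(repr=False)
    bulge_init: dict = field(repr=False)
    internal_init: dict = field(repr=False)
    hairpin_mismatch: dict = field(repr=False)
    terminal_au_penalty: float = 0.5
    asymmetry_per_nt: float = 0.6
    asymmetry_max: float = 3.0
    max_loop: int = 30
    min_hairpin_loop: int = 3
    temperature_c: float = 37.0

    # ---- term accessors -------------------------------------------------
    def stack_energy(self, outer: str, inner: str) -> float:
        return self.stack.get((outer, inner), INF)

    def hairpin_initiation(self, size: int) -> float:
        return self.hairpin_init.get(size, INF)

    def bulge_initiation(self, size: int) -> float:
        return self.bulge_init.get(size, INF)

    def internal_initiation(self, size: int) -> float:
        return self.internal_init.get(size, INF)

    def hairpin_terminal_mismatch(self, pair: str, x: str, y: str) -> float:
        return self.hairpin_mismatch.get((pair, x, y), 0.0)

    def au_penalty(self, pair: str) -> float:
        """0.5 kcal/mol helix-terminus penalty for AU/UA/GU/UG pairs."""
        return self.terminal_au_penalty if pair in ("AU", "UA", "GU", "UG") else 0.0

    # ---- composite loop energies ---------------------------------------
    def hairpin_loop_energy(self, pair: str, size: int, x: str, y: str) -> float:
        """Closing *pair* around a loop of *size* unpaired bases whose first
        and last bases are *x* and *y*."""
        if size < self.min_hairpin_loop or size > self.max_loop:
            return INF
        e = self.hairpin_initiation(size)
        if size >= 4:
            e += self.hairpin_terminal_mismatch(pair, x, y)
        else:
            e += self.au_penalty(pair)
        return e

    def two_loop_energy(self, outer: str, inner: str, b5: int, b3: int) -> float:
        """Stack (0/0), bulge (b/0) or internal loop (b5/b3) between two pairs."""
        if b5 == 0 and b3 == 0:
            return self.stack_energy(outer, inner)
        size = b5 + b3
        if size > self.max_loop:
            return INF
        if b5 == 0 or b3 == 0:
            e = self.bulge_initiation(size)
            if size == 1:
                e += self.stack_energy(outer, inner)  # helix stacking persists
            else:
                e += self.au_penalty(outer) + self.au_penalty(inner)
            return e
        e = self.internal_initiation(size)
        e += min(self.asymmetry_per_nt * abs(b5 - b3), self.asymmetry_max)
        return e


def _load_default() -> EnergyModel:
    stack_rows = _read_tsv("turner2004_stack.tsv")
    header = stack_rows[0][1:]
    stack = {}
    for row in stack_rows[1:]:
        outer = row[0]
        for inner, val in zip(header, row[1:]):
            stack[(outer, inner)] = _f(val)

    loops = _read_tsv("turner2004_loops.tsv")
    hp, bu, it = {}, {}, {}
    for row in loops[1:]:
        size = int(row[0])
        hp[size], bu[size], it[size] = _f(row[1]), _f(row[2]), _f(row[3])

    mm_rows = _read_tsv("turner2004_hairpin_mismatch.tsv")
    cols = mm_rows[0][2:]
    mm = {}
    for row in mm_rows[1:]:
        pair, x = row[0], row[1]
        for y, val in zip(cols, row[2:]):
            mm[(pair, x, y)] = _f(val)

    return EnergyModel(
        stack=stack, hairpin_init=hp, bulge_init=bu, internal_init=it, hairpin_mismatch=mm
    )


_DEFAULT: EnergyModel | None = None


def default_model() -> EnergyModel:
    global _DEFAULT
    if _DEFAULT is None:
        _DEFAULT = _load_default()
    return _DEFAULT
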