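"""Region-resolved identity matrices, conserved-residue panels and
neighbor-joining phylograms for sets of LA genomes.

Identity is ClustalW-style: identical columns divided by columns where
both sequences are non-gap, from a single global pairwise alignment
(nucleotide: +5/-4, gap 10/0.5; protein: BLOSUM62, gap 10/0.5). Pairwise
alignments rather than an MSA drive the matrices, which keeps results
independent of input order. Trees are neighbor-joining on d = 1 - id/100.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices


class CompareError(ValueError):
    pass


class Region(Enum):
    GENOME_NT = "GENOME_NT"
    CANONICAL_NT = "CANONICAL_NT"
    GAGPOL_AA = "GAGPOL_AA"
    GAG_AA = "GAG_AA"
    POL_AA = "POL_AA"
    RDRP_THIRD_AA = "RDRP_THIRD_AA"
    VAR19_AA = "VAR19_AA"
    VAR44_AA = "VAR44_AA"


@dataclass(frozen=True)
class RegionSpec:
    """A named region with its interval on an annotated reference.

    *reference_coords* is a 1-based inclusive interval in the reference's
    own space (nucleotide for *_NT regions, residue for *_AA regions);
    None means the full sequence.
    """

    name: Region
    reference_coords: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        if self.name is Region.VAR44_AA and self.reference_coords:
            lo, hi = self.reference_coords
            if hi - lo + 1 != 44:
                raise CompareError("VAR44 interval must span 44 residues")
        if self.name is Region.VAR19_AA and self.reference_coords:
            lo, hi = self.reference_coords
            if hi - lo + 1 != 19:
                raise CompareError("VAR19 interval must span 19 residues")


@dataclass(frozen=True)
class IdentityMatrix:
    labels: tuple[str, ...]
    values: np.ndarray  # symmetric, percent
    region: RegionSpec
    aligner_settings: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        v = self.values
        if v.shape != (len(self.labels), len(self.labels)):
            raise CompareError("matrix shape does not match labels")
        finite = ~np.isnan(v)
        if not np.allclose(v[finite], v.T[finite]):
            raise CompareError("matrix not symmetric")
        if not np.allclose(np.diag(v), 100.0):
            raise CompareError("diagonal must be 100")
        if np.nanmin(v) < 0 or np.nanmax(v) > 100:
            raise CompareError("identities outside [0, 100]")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    def min_offdiag(self) -> float:
        mask = ~np.eye(len(self.labels), dtype=bool)
        return float(np.nanmin(self.values[mask]))


@dataclass(frozen=True)
class ConservedResiduePanel:
    h154: bool
    cap_residues: dict  # reference residue position -> bool
    rdrp_motifs: dict  # motif name -> percent identity to reference


@dataclass(frozen=True)
class Phylogram:
    newick: str
    distance_basis: str = "1 - identity/100"
    method: str = "neighbor-joining"
    negative_branches_clamped: int = 0


# ---------------------------------------------------------------------------
# alignment


def _aligner(kind: str) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    if kind == "NT":
        aligner.match_score = 5
        aligner.mismatch_score = -4
    else:
        aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -10
    aligner.extend_gap_score = -0.5
    return aligner


def aligner_settings(kind: str) -> dict:
    if kind == "NT":
        return {"kind": "NT", "match": 5, "mismatch": -4, "gap_open": 10, "gap_extend": 0.5}
    return {"kind": "AA", "matrix": "BLOSUM62", "gap_open": 10, "gap_extend": 0.5}


def _align_pair(a: str, b: str, kind: str):
    if not a or not b:
        raise CompareError("empty sequence")
    return _aligner(kind).align(a, b)[0]


def pairwise_identity(a: str, b: str, kind: str = "NT") -> float:
    """Percent identity over non-gap-pair columns of one global alignment,
    rounded to 1 decimal."""
    aln = _align_pair(a, b, kind)
    a_blocks, b_blocks = aln.aligned
    ncols = 0
    matches = 0
    for (As, Ae), (Bs, _) in zip(a_blocks, b_blocks):
        for k in range(Ae - As):
            ncols += 1
            if a[As + k] == b[Bs + k]:
                matches += 1
    if ncols == 0:
        return 0.0
    return round(100.0 * matches / ncols, 1)


def extract_region(target: str, reference: str, region: RegionSpec, kind: str = "AA") -> str:
    """Target subsequence aligned to the reference interval of *region*.

    The interval is projected through a global pairwise alignment; on the
    reference itself this returns exactly the reference interval.
    """
    if region.reference_coords is None:
        return target
    lo, hi = region.reference_coords
    if not (1 <= lo <= hi <= len(reference)):
        raise CompareError(f"region {region.name.value} outside reference")
    if target == reference:
        return reference[lo - 1: hi]
    aln = _align_pair(reference, target, kind)
    ref_blocks, tgt_blocks = aln.aligned
    t_lo = t_hi = None
    for (rs, re), (ts, _) in zip(ref_blocks, tgt_blocks):
        for k in range(re - rs):
            rpos = rs + k  # 0-based reference
            if lo - 1 <= rpos <= hi - 1:
                tpos = ts + k
                if t_lo is None:
                    t_lo = tpos
                t_hi = tpos
    if t_lo is None:
        raise CompareError(f"region {region.name.value} lost in alignment")
    return target[t_lo: t_hi + 1]


def rdrp_third(pol_protein: str) -> str:
    """Central third of the Pol domain by residue count."""
    n = len(pol_protein)
    return pol_protein[n // 3: n - n // 3]


def identity_matrix(
    seqs: dict[str, str],
    region: RegionSpec,
    reference_label: str | None = None,
    kind: str | None = None,
) -> IdentityMatrix:
    """All pairwise identities over the extracted region; symmetric with a
    100 diagonal. Extraction failures are recorded as NaN with a warning."""
    if len(seqs) < 2:
        raise CompareError("need at least two sequences")
    kind = kind or ("NT" if region.name.value.endswith("_NT") else "AA")
    labels = tuple(seqs)
    extracted = {}
    reference = seqs[reference_label] if reference_label else next(iter(seqs.values()))
    for label, s in seqs.items():
        try:
            extracted[label] = extract_region(s, reference, region, kind)
        except CompareError as exc:
            warnings.warn(f"{label}: {exc}")
            extracted[label] = None
    n = len(labels)
    values = np.full((n, n), np.nan)
    np.fill_diagonal(values, 100.0)
    for i in range(n):
        for j in range(i + 1, n):
            a, b = extracted[labels[i]], extracted[labels[j]]
            if a is None or b is None:
                continue
            values[i, j] = values[j, i] = pairwise_identity(a, b, kind)
    return IdentityMatrix(
        labels=labels, values=values, region=region,
        aligner_settings=aligner_settings(kind),
    )


# ---------------------------------------------------------------------------
# conserved residues

# Gag positions on the classical ScV-LA reference protein: the His required
# for cap-snatching and the four cap-recognition residues.
H154_POSITION = 154
CAP_RESIDUES = {150: "Y", 152: "D", 452: "Y", 538: "Y"}


def check_conserved_residues(
    gagpol: str,
    reference: str,
    h_position: int = H154_POSITION,
    cap_residues: dict[int, str] | None = None,
    motif_intervals: dict[str, tuple[int, int]] | None = None,
) -> ConservedResiduePanel:
    """Check cap-snatching His and cap-recognition residues at
    reference-aligned positions, and per-motif identity for the RdRp
    motifs A-D (intervals given in reference residue coordinates)."""
    cap_residues = cap_residues if cap_residues is not None else CAP_RESIDUES
    aln = _align_pair(reference, gagpol, "AA")
    ref_blocks, tgt_blocks = aln.aligned
    if len(ref_blocks) == 0:
        raise CompareError("unalignable")

    def residue_at(ref_pos_1based: int) -> str | None:
        rp = ref_pos_1based - 1
        for (rs, re), (ts, _) in zip(ref_blocks, tgt_blocks):
            if rs <= rp < re:
                return gagpol[ts + (rp - rs)]
        return None

    h_ok = residue_at(h_position) == "H"
    cap = {pos: residue_at(pos) == aa for pos, aa in cap_residues.items()}
    motifs = {}
    for name, (lo, hi) in (motif_intervals or {}).items():
        spec = RegionSpec(Region.RDRP_THIRD_AA, (lo, hi))
        try:
            sub = extract_region(gagpol, reference, spec, "AA")
            motifs[name] = pairwise_identity(reference[lo - 1: hi], sub, "AA")
        except CompareError:
            motifs[name] = float("nan")
    return ConservedResiduePanel(h154=h_ok, cap_residues=cap, rdrp_motifs=motifs)


# ---------------------------------------------------------------------------
# phylogram


def nj_phylogram(m: IdentityMatrix) -> Phylogram:
    """Neighbor-joining tree on d = 1 - identity/100.

    Deterministic given the matrix (labels sorted before tree building);
    negative branch lengths are clamped to zero with a warning.
    """
    from skbio import DistanceMatrix
    from skbio.tree import nj

    if len(m.labels) < 3:
        raise CompareError("too few taxa")
    if np.isnan(m.values).any():
        raise CompareError("matrix contains missing identities")
    order = sorted(range(len(m.labels)), key=lambda i: m.labels[i])
    labels = [m.labels[i] for i in order]
    d = 1.0 - m.values[np.ix_(order, order)] / 100.0
    d = (d + d.T) / 2.0
    np.fill_diagonal(d, 0.0)
    tree = nj(DistanceMatrix(d, ids=labels))
    clamped = 0
    for node in tree.traverse():
        if node.length is not None and node.length < 0:
            node.length = 0.0
            clamped += 1
    if clamped:
        warnings.warn(f"{clamped} negative NJ branch lengths clamped to 0")
    return Phylogram(newick=str(tree).strip(), negative_branches_clamped=clamped)
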