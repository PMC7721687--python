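"""End-to-end workflow: characterise each genome, compare the set, and
analyse the extra sequences; write GFF3/TSV/Newick/JSON artifacts."""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

from .sequences import ViralSequence, read_fasta
from .partition import GenomePartition, partition_genome, partition_report
from .orfs import AnnotationError, build_gagpol_model
from .signals import find_signal_stemloops
from .extras import find_self_identity, find_shared_stretches, palindrome_scan, match_host_sequences
from .compare import Region, RegionSpec, identity_matrix, nj_phylogram
from .gff import gff3_document
from .partition import Zone

log = logging.getLogger("lagenome")


class PipelineError(RuntimeError):
    pass


@dataclass
class PipelineConfig:
    input_fastas: list = field(default_factory=list)  # paths or ViralSequence lists
    host_fasta: str | None = None
    anchors: dict = field(default_factory=dict)  # id -> (anchor_5, anchor_3)
    default_anchor_5: str = "GAAAAA"
    default_anchor_3: str = "CCATATGC"
    min_self_identity_len: int = 13
    palindrome_min_arm: int = 8
    palindrome_max_loop: int = 8
    palindrome_max_mismatch: int = 2
    regions: tuple = (Region.CANONICAL_NT, Region.GAGPOL_AA)
    output_dir: str | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.min_self_identity_len, self.palindrome_min_arm) < 1:
            raise ValueError("thresholds must be positive")


@dataclass
class AnnotationReport:
    per_virus: dict
    matrices: dict  # region name -> IdentityMatrix
    newick: str | None
    provenance: dict

    def summary_json(self) -> str:
        out = {
            "provenance": self.provenance,
            "viruses": self.per_virus,
            "newick": self.newick,
            "matrices": {
                name: {"labels": list(m.labels), "values": m.values.tolist()}
                for name, m in self.matrices.items()
            },
        }
        return json.dumps(out, indent=2)


def _load_inputs(cfg: PipelineConfig) -> list[ViralSequence]:
    seqs: list[ViralSequence] = []
    for item in cfg.input_fastas:
        if isinstance(item, ViralSequence):
            seqs.append(item)
        elif isinstance(item, (list, tuple)):
            seqs.extend(item)
        else:
            if not Path(item).exists():
                raise PipelineError(f"parse error: input file {item} not found")
            seqs.extend(read_fasta(item))
    if not seqs:
        raise PipelineError("parse error: no input sequences")
    return seqs


def run_pipeline(cfg: PipelineConfig) -> AnnotationReport:
    """Characterise -> compare -> extra-sequence analysis.

    Deterministic given inputs and config; artifacts are written under
    ``cfg.output_dir`` when set. Stage errors are aggregated per virus.
    """
    import lagenome

    seqs = _load_inputs(cfg)
    host_db = read_fasta(cfg.host_fasta) if cfg.host_fasta else None
    outdir = Path(cfg.output_dir) if cfg.output_dir else None
    if outdir:
        outdir.mkdir(parents=True, exist_ok=True)

    per_virus: dict = {}
    partitions: dict[str, GenomePartition] = {}
    gagpols: dict = {}
    errors: list[str] = []
    for vs in seqs:
        entry: dict = {}
        a5, a3 = cfg.anchors.get(vs.id, (cfg.default_anchor_5, cfg.default_anchor_3))
        try:
            part = partition_genome(vs, anchor_5=a5, anchor_3=a3)
            partitions[vs.id] = part
            entry["partition"] = partition_report(part)
        except Exception as exc:
            errors.append(f"{vs.id}/partition: {exc}")
            per_virus[vs.id] = {"error": str(exc)}
            continue
        gp = None
        try:
            gp = build_gagpol_model(part)
            gagpols[vs.id] = gp
            entry["gagpol"] = {
                "gag": (gp.gag.start, gp.gag.end),
                "pol": (gp.pol.start, gp.pol.end),
                "slippery": (gp.slippery.position, gp.slippery.heptamer),
                "reinit_codons": list(gp.reinit_codons),
                "fusion_len": len(gp.fusion_protein),
            }
        except AnnotationError as exc:
            errors.append(f"{vs.id}/gagpol: {exc}")
            entry["gagpol"] = {"error": str(exc)}
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            signals = find_signal_stemloops(part, gp)
        entry["signals"] = [
            {
                "kind": s.kind.value,
                "span": (s.start, s.end),
                "note": s.note,
                "dot_bracket": s.hairpin.dot_bracket() if s.hairpin else None,
                "dG_kJ": round(s.hairpin.dG_kJ, 2) if s.hairpin else None,
            }
            for s in signals
        ]
        if part.five_extra_len or part.three_extra_len:
            matches = find_self_identity(part, min_len=cfg.min_self_identity_len)
            entry["self_identity"] = [
                {"span": m.paper_string(part), "length": m.length} for m in matches
            ]
            pal_region = part.sequence.residues[: part.five_extra_len + 60]
            hits = palindrome_scan(
                pal_region, cfg.palindrome_min_arm,
                cfg.palindrome_max_loop, cfg.palindrome_max_mismatch,
            )
            entry["palindromes_5p"] = [asdict(hh) for hh in hits]
            if host_db:
                entry["host_hits"] = [
                    asdict(hh)
                    for z in (Zone.FIVE_EXTRA, Zone.THREE_EXTRA)
                    for hh in match_host_sequences(part, z, host_db)
                ]
        per_virus[vs.id] = entry
        if outdir:
            (outdir / f"{vs.id}.gff3").write_text(gff3_document(part, gp, signals))

    # shared stretches across 5' extras
    shared = []
    ids = [i for i in partitions if partitions[i].five_extra_len >= cfg.min_self_identity_len]
    for i, a in enumerate(ids):
        for bid in ids[i + 1:]:
            for s in find_shared_stretches(
                partitions[a], partitions[bid], min_len=cfg.min_self_identity_len
            ):
                shared.append(
                    {"virus_a": s.virus_a, "virus_b": s.virus_b,
                     "stretch": s.stretch, "length": s.length}
                )

    matrices = {}
    newick = None
    if len(gagpols) >= 2:
        for region in cfg.regions:
            if region is Region.CANONICAL_NT:
                data = {i: partitions[i].canonical_seq for i in gagpols}
            elif region is Region.GAGPOL_AA:
                data = {i: gagpols[i].fusion_protein for i in gagpols}
            elif region is Region.GAG_AA:
                data = {i: gagpols[i].gag.protein for i in gagpols}
            elif region is Region.POL_AA:
                data = {i: gagpols[i].pol.protein for i in gagpols}
            elif region is Region.RDRP_THIRD_AA:
                from .compare import rdrp_third

                data = {i: rdrp_third(gagpols[i].pol.protein) for i in gagpols}
            elif region is Region.GENOME_NT:
                data = {i: partitions[i].sequence.residues for i in gagpols}
            else:
                continue
            m = identity_matrix(data, RegionSpec(region))
            matrices[region.value] = m
            if outdir:
                m.to_frame().to_csv(outdir / f"identity_{region.value}.tsv", sep="\t")
        if len(gagpols) >= 3 and Region.GAGPOL_AA.value in matrices:
            newick = nj_phylogram(matrices[Region.GAGPOL_AA.value]).newick
            if outdir:
                (outdir / "phylogram.nwk").write_text(newick + "\n")

    report = AnnotationReport(
        per_virus=per_virus,
        matrices=matrices,
        newick=newick,
        provenance={
            "version": lagenome.__version__,
            "seed": cfg.seed,
            "anchors": {"default": [cfg.default_anchor_5, cfg.default_anchor_3],
                        **{k: list(v) for k, v in cfg.anchors.items()}},
            "thresholds": {
                "min_self_identity_len": cfg.min_self_identity_len,
                "palindrome": [cfg.palindrome_min_arm, cfg.palindrome_max_loop,
                               cfg.palindrome_max_mismatch],
            },
            "shared_stretches": shared,
            "errors": errors,
        },
    )
    if outdir:
        (outdir / "report.json").write_text(report.summary_json())
    if errors:
        log.warning("pipeline completed with stage errors: %s", "; ".join(errors))
    return report
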