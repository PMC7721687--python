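"""Optional GenBank accession support.

The published analyses of these genomes rest on deposited accessions
(MW174758-MW174763, J04692.1, JN819511.1, ...). Network fetching is OFF by
default: analyses read FASTA from a local directory (``data/accessions``
by default), and :func:`fetch_accessions` populates that directory
explicitly when a network connection exists.
"""

from __future__ import annotations

from pathlib import Path

from .sequences import ViralSequence, read_fasta, write_fasta

STUDY_ACCESSIONS = {
    "MW174763": "TdV-LAbarr1",
    "MW174760": "ScV-LA1-EX231",
    "MW174759": "ScV-LA2-EX1125",
    "MW174761": "ScV-LAlus1-EX436",
    "MW174762": "ScV-LAlusA-EX1160",
    "MW174758": "ScV-LAlus4-EX229",
    "J04692.1": "ScV-LA1-original",
    "JN819511.1": "ScV-L-A-lus",
}

DEFAULT_DIR = Path("data/accessions")


class MissingAccessionError(FileNotFoundError):
    pass


def accession_path(accession: str, directory: str | Path = DEFAULT_DIR) -> Path:
    return Path(directory) / f"{accession}.fasta"


def load_accession(accession: str, directory: str | Path = DEFAULT_DIR) -> ViralSequence:
    """Load one accession from the local directory; raises
    :class:`MissingAccessionError` with fetch instructions if absent."""
    path = accession_path(accession, directory)
    if not path.exists():
        raise MissingAccessionError(
            f"{accession} not found at {path}. Run "
            f"`python scripts/fetch_accessions.py` (network required) or place "
            f"a FASTA for {accession} there."
        )
    records = read_fasta(path)
    if not records:
        raise MissingAccessionError(f"{path} contains no records")
    return records[0]


def fetch_accessions(
    accessions: list[str] | None = None,
    directory: str | Path = DEFAULT_DIR,
    email: str = "anonymous@example.org",
) -> list[Path]:
    """Download accessions from NCBI (explicit opt-in; requires network)."""
    from Bio import Entrez, SeqIO

    accessions = accessions or list(STUDY_ACCESSIONS)
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    Entrez.email = email
    written = []
    for acc in accessions:
        path = accession_path(acc, directory)
        if path.exists():
            written.append(path)
            continue
        with Entrez.efetch(db="nuccore", id=acc, rettype="fasta", retmode="text") as handle:
            rec = SeqIO.read(handle, "fasta")
        vs = ViralSequence(
            id=acc, residues=str(rec.seq).upper().replace("U", "T"),
            description=rec.description,
        )
        write_fasta([vs], path)
        written.append(path)
    return written
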