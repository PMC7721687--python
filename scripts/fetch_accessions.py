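#!/usr/bin/env python
"""Download the study's GenBank accessions into data/accessions/ (opt-in;
requires network access). The test suite and pipeline read the FASTA files
from that directory and never touch the network themselves."""

import sys

from lagenome.accessions import STUDY_ACCESSIONS, fetch_accessions


def main() -> int:
    accs = sys.argv[1:] or list(STUDY_ACCESSIONS)
    try:
        paths = fetch_accessions(accs)
    except Exception as exc:  # DNS failure, no network, etc.
        print(f"fetch failed: {exc}", file=sys.stderr)
        return 1
    for p in paths:
        print(p)
    return 0


if __name__ == "__main__":
    raise SystemExit(main())
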