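"""Optional NCBI retrieval helper (never exercised by the test suite).

The analysis of the original 19 tomato heat-shock transcripts needs
their mRNA records; this downloads them by accession via Entrez efetch.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Sequence

#: The 19 tomato heat-shock-protein transcript accessions of the study corpus.
STUDY_ACCESSIONS: Sequence[str] = (
    "XM_010327263.3", "NM_001309248.1", "NM_001321563.1", "NM_001246851.2",
    "NM_001247296.2", "NM_001320262.1", "NM_001321450.1", "XM_026032687.1",
    "XM_010326728.3", "XM_026032686.1", "XM_026032685.1", "NM_001247047.2",
    "NM_001247134.1", "XM_015230190.2", "XM_027919128.1", "XM_027919127.1",
    "XM_015208371.2", "XM_027913778.1", "NM_001247342.2",
)


def fetch_accessions(
    accessions: Iterable[str],
    out_path: str | Path,
    email: str,
) -> int:
    """Fetch nucleotide FASTA records by accession; returns the record count."""
    from Bio import Entrez, SeqIO

    Entrez.email = email
    handle = Entrez.efetch(
        db="nuccore",
        id=",".join(accessions),
        rettype="fasta",
        retmode="text",
    )
    records = list(SeqIO.parse(handle, "fasta"))
    handle.close()
    if not records:
        raise RuntimeError("no records returned by NCBI")
    SeqIO.write(records, str(out_path), "fasta")
    return len(records)
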