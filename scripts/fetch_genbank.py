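"""One-time helper: download the deposited control-region sequences.

Fetches accessions ON470395-ON470439 from NCBI efetch and writes them,
uppercased, to data/genbank_ON470395-ON470439.fasta.  The package never
requires this file; only the deposited-haplotype acceptance check uses it.

Run on a machine with internet access:
    python scripts/fetch_genbank.py
"""

from __future__ import annotations

import urllib.request
from pathlib import Path

ACCESSIONS = [f"ON{470395 + i}" for i in range(45)]
URL = (
    "https://eutils.ncbi.nlm.nih.gov/entrez/eutils/efetch.fcgi"
    "?db=nuccore&rettype=fasta&retmode=text&id=" + ",".join(ACCESSIONS)
)
OUT = Path(__file__).resolve().parent.parent / "data" / (
    "genbank_ON470395-ON470439.fasta"
)


def main() -> None:
    print(f"fetching {len(ACCESSIONS)} records from NCBI ...")
    with urllib.request.urlopen(URL, timeout=60) as resp:
        text = resp.read().decode()
    OUT.parent.mkdir(parents=True, exist_ok=True)
    OUT.write_text(text)
    n = text.count(">")
    print(f"wrote {n} records to {OUT}")
    if n != len(ACCESSIONS):
        raise SystemExit(f"expected {len(ACCESSIONS)} records, got {n}")


if __name__ == "__main__":
    main()
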