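#!/usr/bin/env python
"""Fetch the vespid Antigen 5 family from UniProt for a real-data run.

Downloads the 19 UniProtKB entries of the cross-reactive vespid Antigen 5
family (Vespula, Vespa, Dolichovespula, Polistes and Polybia members,
including the Polybia scutellaris hypoallergen candidate Q7Z156 and the
Ves v 5 template Q05110), trims signal peptides using the CHAIN feature
annotation when present, writes the mature sequences to FASTA and, if mafft
is on PATH, aligns them into ``family_aligned.fasta`` ready for the
pipeline config.

Requires network access; the analysis itself never downloads anything.

Usage:
    python scripts/fetch_family.py --out data/ag5
"""

from __future__ import annotations

import argparse
import re
import shutil
import subprocess
import urllib.request
from pathlib import Path

ACCESSIONS = [
    "P35783", "Q05110", "P35760", "P35784", "P35785", "P35787", "P35786",
    "P35782", "P35781", "P81657", "P10736", "Q05108", "P10737", "P35759",
    "Q05109", "P35780", "P81656", "P83377", "Q7Z156",
]

UNIPROT_URL = "https://rest.uniprot.org/uniprotkb/{acc}.txt"


def fetch_entry(acc: str) -> str:
    with urllib.request.urlopen(UNIPROT_URL.format(acc=acc), timeout=30) as fh:
        return fh.read().decode()


def mature_sequence(entry_text: str) -> str:
    """Sequence of the mature CHAIN when annotated, else the full sequence."""
    seq_lines = []
    in_seq = False
    for line in entry_text.splitlines():
        if line.startswith("SQ"):
            in_seq = True
            continue
        if in_seq:
            if line.startswith("//"):
                break
            seq_lines.append(re.sub(r"[^A-Z]", "", line.upper()))
    seq = "".join(seq_lines)
    m = re.search(r"^FT\s+CHAIN\s+(\d+)\.\.(\d+)", entry_text, re.MULTILINE)
    if m:
        start, end = int(m.group(1)), int(m.group(2))
        return seq[start - 1 : end]
    return seq


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--out", type=Path, default=Path("data/ag5"))
    args = parser.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    fasta = args.out / "family_mature.fasta"
    with open(fasta, "w") as fh:
        for acc in ACCESSIONS:
            print(f"fetching {acc} ...")
            seq = mature_sequence(fetch_entry(acc))
            fh.write(f">{acc}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")
    print(f"wrote {fasta}")

    if shutil.which("mafft"):
        aligned = args.out / "family_aligned.fasta"
        with open(aligned, "w") as out_fh:
            subprocess.run(
                ["mafft", "--auto", str(fasta)], stdout=out_fh, check=True,
                stderr=subprocess.DEVNULL,
            )
        print(f"wrote {aligned} (point the pipeline config at this file; "
              "the published analysis used a manually adjusted alignment, so "
              "inspect insertions around the N-terminal region before trusting "
              "residue numbering)")
    else:
        print("mafft not found: align family_mature.fasta with your aligner "
              "of choice before running the pipeline")


if __name__ == "__main__":
    main()
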