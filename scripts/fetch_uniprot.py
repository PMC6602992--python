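#!/usr/bin/env python
"""Fetch the tobacco LHC antenna sequences from UniProt (one-time, online).

Downloads the canonical sequence and the annotated chloroplast
transit-peptide span for each accession and writes a single FASTA with
``[transit=1..N]`` header tags to data/uniprot/tobacco_lhc.fasta.
Entries without an annotated transit peptide (e.g. A0A076L1Y1) are
written untagged; supply their span via a sidecar TSV if needed.

Usage:  python scripts/fetch_uniprot.py [--out data/uniprot/tobacco_lhc.fasta]
"""

from __future__ import annotations

import argparse
import json
import sys
import urllib.request
from pathlib import Path

ACCESSIONS = [
    ("lhcb1.1", "P27496"),
    ("lhcb1.2", "P27493"),
    ("lhcb1.3", "P27495"),
    ("lhcb1.4", "P27491"),
    ("lhcb1.5", "P27492"),
    ("lhcb2.1", "P27494"),
    ("lhcb3.1", "A0A076L1Y1"),
    ("CP29", "Q0PWS7"),
    ("CP26", "Q0PWS5"),
    ("CP24", "Q0PWS6"),
    ("PsbS", "Q9SMB4"),
]

API = "https://rest.uniprot.org/uniprotkb/{acc}.json"


def fetch_entry(acc: str) -> tuple[str, int | None]:
    with urllib.request.urlopen(API.format(acc=acc), timeout=30) as fh:
        data = json.load(fh)
    seq = data["sequence"]["value"]
    transit_end = None
    for feat in data.get("features", []):
        if feat.get("type") == "Transit peptide":
            loc = feat["location"]
            if loc["start"]["value"] == 1:
                transit_end = loc["end"]["value"]
    return seq, transit_end


def main() -> int:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument(
        "--out", default="data/uniprot/tobacco_lhc.fasta", type=Path
    )
    args = ap.parse_args()
    args.out.parent.mkdir(parents=True, exist_ok=True)
    lines = []
    for name, acc in ACCESSIONS:
        try:
            seq, transit_end = fetch_entry(acc)
        except Exception as exc:  # noqa: BLE001 - report and continue
            print(f"FAILED {acc} ({name}): {exc}", file=sys.stderr)
            continue
        tag = f" [transit=1..{transit_end}]" if transit_end else ""
        lines.append(f">{acc} {name}{tag}")
        lines.extend(seq[i : i + 60] for i in range(0, len(seq), 60))
        print(f"fetched {acc} ({name}): {len(seq)} aa, transit={transit_end}")
    if not lines:
        print("nothing fetched", file=sys.stderr)
        return 1
    args.out.write_text("\n".join(lines) + "\n")
    print(f"wrote {args.out}")
    return 0


if __name__ == "__main__":
    raise SystemExit(main())
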