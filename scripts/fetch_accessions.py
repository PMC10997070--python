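#!/usr/bin/env python
"""Download the published plastome panel from NCBI (network required).

Fetches the GenBank flat files of the 20-genome comparison panel into
data/real-plastomes/, where the real-data acceptance checks look for
them.  The core library never requires network access; this helper
exists only to populate the optional real-data inputs.

Usage:
    python scripts/fetch_accessions.py [--email you@example.org]
"""

from __future__ import annotations

import argparse
import time
import urllib.parse
import urllib.request
from pathlib import Path

ACCESSIONS = [
    "MZ571477", "PP069562", "OR098702", "KM014691", "MK593157",
    "MT001880", "PP475539", "OK138594", "OM990831", "OP715666",
    "OP715674", "MT740331", "MT254070", "MH251636", "MK593164",
    "MK593167", "KT626943", "OK274247", "OK448493", "MW201731",
]

EUTILS = "https://eutils.ncbi.nlm.nih.gov/entrez/eutils/efetch.fcgi"


def fetch(accession: str, out_dir: Path, email: str) -> None:
    params = urllib.parse.urlencode(
        {
            "db": "nuccore",
            "id": accession,
            "rettype": "gbwithparts",
            "retmode": "text",
            "email": email,
            "tool": "plastmark",
        }
    )
    with urllib.request.urlopen(f"{EUTILS}?{params}", timeout=120) as resp:
        (out_dir / f"{accession}.gb").write_bytes(resp.read())


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--email", default="anonymous@example.org")
    parser.add_argument(
        "--out",
        type=Path,
        default=Path(__file__).resolve().parent.parent
        / "data"
        / "real-plastomes",
    )
    args = parser.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)
    for accession in ACCESSIONS:
        target = args.out / f"{accession}.gb"
        if target.exists():
            print(f"{accession}: already present")
            continue
        print(f"fetching {accession} ...")
        fetch(accession, args.out, args.email)
        time.sleep(0.4)  # NCBI rate limit
    print(f"done; records in {args.out}")


if __name__ == "__main__":
    main()
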