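#!/usr/bin/env python
"""Download the deposited crystal structures used by the structural checks.

Fetches 4DRX (tubulin-D1 complex), 4DUI (free D1), 5EYL (free TM-3) and
5EYP (tubulin-A-C2 complex) from the RCSB into data/structures/.  Requires
network access; the files are multi-megabyte and are therefore not bundled
with the package.
"""

from __future__ import annotations

import pathlib
import urllib.request

ENTRIES = ("4drx", "4dui", "5eyl", "5eyp")
TARGET = pathlib.Path(__file__).resolve().parent.parent / "data" / "structures"


def main() -> None:
    TARGET.mkdir(parents=True, exist_ok=True)
    for pdb_id in ENTRIES:
        dest = TARGET / f"{pdb_id}.pdb"
        if dest.exists():
            print(f"{dest} already present")
            continue
        url = f"https://files.rcsb.org/download/{pdb_id.upper()}.pdb"
        print(f"fetching {url} ...")
        with urllib.request.urlopen(url, timeout=60) as response:
            dest.write_bytes(response.read())
        print(f"  wrote {dest} ({dest.stat().st_size // 1024} kB)")


if __name__ == "__main__":
    main()
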