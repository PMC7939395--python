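#!/usr/bin/env python
"""Fetch deposited SAS-6 head-domain structures and store CA-only snapshots.

Downloads the deposited coordinates used for cross-species head-domain
comparison — 6Z4A (human SAS-6 N-terminal domain), 3Q0Y (C. reinhardtii),
3PYI and 4G79 (C. elegans), 2Y3V (D. rerio) — and writes compact CA-only
PDB files (first model, first chain) under data/pdb/, which the structure
comparison tests and the acceptance script pick up when present.

Usage:  python scripts/fetch_pdb.py [--out data/pdb]
Requires network access to files.rcsb.org.
"""

from __future__ import annotations

import argparse
import sys
import urllib.request
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from sas6screen.structures import Structure, read_structures, write_structure  # noqa: E402

ENTRIES = ["6Z4A", "3Q0Y", "3PYI", "4G79", "2Y3V"]


def fetch_ca(pdb_id: str) -> Structure:
    url = f"https://files.rcsb.org/download/{pdb_id}.pdb"
    with urllib.request.urlopen(url, timeout=60) as resp:
        text = resp.read().decode()
    model = read_structures(text)[0]
    chain = sorted(model.chains)[0]
    ca = [a for a in model.atoms if a.chain_id == chain and a.name == "CA" and not a.hetatm]
    if not ca:
        raise RuntimeError(f"{pdb_id}: no CA atoms on chain {chain}")
    return Structure(atoms=ca)


def main() -> int:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--out", default="data/pdb", type=Path)
    args = parser.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)
    for pdb_id in ENTRIES:
        dest = args.out / f"{pdb_id.lower()}_ca.pdb"
        try:
            s = fetch_ca(pdb_id)
        except Exception as exc:
            print(f"FAILED {pdb_id}: {exc}", file=sys.stderr)
            return 1
        dest.write_text(write_structure(s))
        print(f"{pdb_id}: {len(s.atoms)} CA atoms -> {dest}")
    return 0


if __name__ == "__main__":
    raise SystemExit(main())
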