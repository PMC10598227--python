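#!/usr/bin/env python
"""Download the deposited 20-model NMR ensemble (PDB 8U27) and compute its
pairwise-RMSD statistics with noetools.

Network access is required for the download; the library itself never
fetches anything.  The deposited ensemble statistics to compare against
are a mean pairwise backbone RMSD of 0.56 Å and heavy-atom RMSD of 1.29 Å
over residues 10–31 and 47–176.

Usage:
    python scripts/fetch_8u27.py [--dest scratch/8u27.pdb]
"""

from __future__ import annotations

import argparse
import urllib.request
from pathlib import Path

from noetools.geometry import Selection
from noetools.io import read_structure
from noetools.validation import region_rmsd_table

URL = "https://files.rcsb.org/download/8U27.pdb"


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--dest", type=Path, default=Path("scratch/8u27.pdb"))
    parser.add_argument(
        "--selection", default="A:10-31,47-176",
        help="residue selection for the RMSD table",
    )
    args = parser.parse_args()

    if not args.dest.exists():
        args.dest.parent.mkdir(parents=True, exist_ok=True)
        print(f"downloading {URL} ...")
        urllib.request.urlretrieve(URL, args.dest)
    ensemble = read_structure(args.dest)
    print(f"{len(ensemble)} models, {ensemble[0].n_atoms} atoms each")
    sel = Selection.parse(args.selection)
    table = region_rmsd_table(ensemble, {"structured region": sel})
    print(table.to_string(index=False))


if __name__ == "__main__":
    main()
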