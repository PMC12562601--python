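#!/usr/bin/env python
"""Convergence check against the deposited NMR ensemble (PDB 9U9N).

Downloads the 20-model ws-PSCA ensemble from the PDB (requires network —
run manually, not part of the automated suite) and computes the backbone
ensemble RMSD over the ordered-core regions Leu1–Ile33, Val41–Cys50 and
Asn63–Ala74 under both conventions.  The expected value for the
deposited ensemble is about 0.71 Å.

Usage:
    python scripts/check_deposited_ensemble.py [--pdb local_copy.pdb]
"""

from __future__ import annotations

import argparse
import sys
import urllib.request

from ifscreen.structmodel import RegionSpec, ensemble_rmsd, read_structure

URL = "https://files.rcsb.org/download/9U9N.pdb"
REGIONS = "{c}:1-33,{c}:41-50,{c}:63-74"


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--pdb", default=None,
                    help="local copy of the 9U9N PDB file (skips download)")
    args = ap.parse_args()

    if args.pdb:
        path = args.pdb
    else:
        path = "9u9n_downloaded.pdb"
        print(f"downloading {URL} ...")
        urllib.request.urlretrieve(URL, path)

    st = read_structure(path)
    print(f"models: {st.n_models}, chains: {st.chain_ids}")
    chain = st.chain_ids[0]
    region = RegionSpec.from_string(REGIONS.format(c=chain))
    for mode in ("mean_pairwise", "to_mean"):
        for atoms in ("backbone", "backbone_o"):
            val = ensemble_rmsd(st, region, mode, atoms)
            print(f"  {mode:<14} {atoms:<11} {val:.3f} A")
    print("expected for the deposited ensemble: ~0.71 A")
    return 0


if __name__ == "__main__":
    sys.exit(main())
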