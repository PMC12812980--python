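#!/usr/bin/env python
"""Environment–community permutation correlations.

Tests each chemistry variable against the phytoplankton and bacterial
Bray–Curtis matrices with the distance-based permutation correlation, and
runs partial Mantel tests of each community against chemistry distance
controlling for the other community.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from trophonet import io
from trophonet.stats import env_community_correlation, partial_mantel

HERE = Path(__file__).resolve().parent.parent
VARS = ("tn", "tp", "chl_a", "secchi")


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--data", type=Path, default=HERE / "results" / "data")
    ap.add_argument("--out", type=Path, default=HERE / "results")
    ap.add_argument("--n-perm", type=int, default=999)
    ap.add_argument("--seed", type=int, default=1)
    args = ap.parse_args()

    records = io.read_chemistry(args.data / "chemistry.csv")
    chem = pd.DataFrame(
        [{"site_id": r.site_id, "tn": r.tn, "tp": r.tp,
          "chl_a": r.chl_a, "secchi": r.secchi} for r in records]
    ).set_index("site_id")
    dists = {
        "phytoplankton": io.read_distance_matrix(args.out / "bray_curtis_phyto.csv"),
        "bacteria": io.read_distance_matrix(args.out / "bray_curtis_bact.csv"),
    }

    report = {}
    print(f"permutation correlations ({args.n_perm} permutations):")
    for kingdom, dmat in dists.items():
        sites = [s for s in dmat.index if s in chem.index]
        d = dmat.loc[sites, sites].to_numpy()
        report[kingdom] = {}
        for i, var in enumerate(VARS):
            res = env_community_correlation(
                chem.loc[sites, var].to_numpy(), d,
                n_perm=args.n_perm, seed=args.seed * 100 + i,
            )
            report[kingdom][var] = {"r": res.r, "p": res.p}
            star = " *" if res.p < 0.05 else ""
            print(f"  {kingdom:14s} ~ {var:6s}: r = {res.r: .3f}, p = {res.p:.3f}{star}")

    # partial Mantel: community vs chemistry distance, controlling the other
    sites = [s for s in dists["phytoplankton"].index if s in chem.index]
    z = (chem.loc[sites, list(VARS)] - chem.loc[sites, list(VARS)].mean()) / chem.loc[
        sites, list(VARS)
    ].std()
    d_chem = squareform(pdist(z.to_numpy()))
    dp = dists["phytoplankton"].loc[sites, sites].to_numpy()
    db = dists["bacteria"].loc[sites, sites].to_numpy()
    for name, d1, dc in (("phytoplankton", dp, db), ("bacteria", db, dp)):
        res = partial_mantel(d1, d_chem, dc, n_perm=args.n_perm, seed=args.seed)
        report[f"partial_{name}"] = {"r": res.r, "p": res.p}
        print(f"  partial Mantel {name} ~ chemistry | other kingdom: "
              f"r = {res.r: .3f}, p = {res.p:.3f}")

    io.write_json(report, args.out / "env_associations.json")


if __name__ == "__main__":
    main()
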