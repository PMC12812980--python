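#!/usr/bin/env python
"""Score every site's Trophic State Index and classify it.

Reads the chemistry table written by 01_simulate.py, computes the four
component indices and the weighted composite, classifies each site on the
oligotrophic→hyper-eutrophic scale, and writes the per-site table and the
summary (median TSI, eutrophic fraction, class counts) under results/.
"""

import argparse
from pathlib import Path

from trophonet import io
from trophonet.trophic import assess_sites

HERE = Path(__file__).resolve().parent.parent


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--data", type=Path, default=HERE / "results" / "data")
    ap.add_argument("--out", type=Path, default=HERE / "results")
    args = ap.parse_args()

    records = io.read_chemistry(args.data / "chemistry.csv")
    assessments, summary = assess_sites(records)
    io.write_assessments(assessments, records, args.out / "assessments.csv")
    io.write_json(io.summary_to_dict(summary), args.out / "trophic_summary.json")

    print(f"assessed {summary.n_samples} sites")
    print(f"composite TSI: median {summary.tsi_median:.2f}, "
          f"mean {summary.tsi_mean:.2f} ± {summary.tsi_sd:.2f}, "
          f"range [{summary.tsi_min:.1f}, {summary.tsi_max:.1f}]")
    print(f"eutrophic (TSI > 50): {summary.fraction_eutrophic:.1f}% of sites")
    for label, n in summary.counts.items():
        if n:
            print(f"  {label}: {n}")


if __name__ == "__main__":
    main()
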