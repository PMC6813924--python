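#!/usr/bin/env python
"""Kinship QC on the simulated discovery cohort: estimate pairwise phi with
the KING-robust estimator, compare against pedigree expectation, and report
samples recommended for exclusion (the planted sample swap F05_C1 should be
the single hit).

Reads results/data/discovery.* (run 01_simulate_cohort.py first); writes
results/kinship.tsv and results/kinship_exclusions.json.
"""

import argparse
import json
import sys
from pathlib import Path

from hbocprio.io_formats import read_ped, read_vcf
from hbocprio.kinship import flag_pedigree_discordance, kinship_table


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--data", type=Path, default=Path("results/data"))
    parser.add_argument("--out", type=Path, default=Path("results"))
    args = parser.parse_args()

    vcf = args.data / "discovery.vcf"
    if not vcf.exists():
        sys.exit("discovery cohort not found; run analysis/01_simulate_cohort.py first")
    records, samples = read_vcf(vcf)
    pedigrees = read_ped(args.data / "discovery.ped")
    pedigrees.mark_sequenced(samples)

    kin = kinship_table(records, samples)
    report = flag_pedigree_discordance(kin, pedigrees)

    args.out.mkdir(parents=True, exist_ok=True)
    kin.to_csv(args.out / "kinship.tsv", sep="\t", index=False, float_format="%.6g")
    (args.out / "kinship_exclusions.json").write_text(
        json.dumps({"excluded_samples": report.exclusions}, indent=2) + "\n"
    )
    print(f"{len(kin)} pairs estimated over {kin.n_sites_used.max()} sites")
    for p in report.discordant_pairs:
        print(f"discordant: {p.sample_i} vs {p.sample_j} "
              f"(expected phi {p.expected_phi:.3f}, observed {p.observed_phi:.3f})")
    print(f"recommended exclusions: {report.exclusions}")


if __name__ == "__main__":
    main()
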