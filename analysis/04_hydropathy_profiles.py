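#!/usr/bin/env python
"""Hydropathy characterization of the selected candidates.

Computes Kyte-Doolittle profiles (window 19) for the final candidates of
03_prioritize_candidates.py, flags prominent hydrophobic domains (any
window mean > 1.6, the classic membrane-stretch cutoff) and writes the
profile table under results/.  Algal MLDP-type LB proteins are expected
NOT to carry such a domain, in contrast to seed-plant oleosins.
"""

import argparse
from pathlib import Path

import pandas as pd

from lbproteome import hydrophobic_domain_flag, kd_profile
from lbproteome import io as lio


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--data", type=Path, default=Path("results/synthetic"))
    parser.add_argument("--report", type=Path, default=Path("results/decision_report.tsv"))
    parser.add_argument("--out", type=Path, default=Path("results"))
    parser.add_argument("--window", type=int, default=19)
    args = parser.parse_args()

    catalog = lio.read_fasta(args.data / "catalog.fasta")
    report = lio.read_report(args.report, "tsv")
    candidates = list(report["protein_id"])

    frames, flags = [], {}
    for pid in candidates:
        profile = kd_profile(catalog[pid], args.window, protein_id=pid)
        frames.append(profile.to_frame())
        flags[pid] = hydrophobic_domain_flag(profile)
    table = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=["protein_id", "position", "score"]
    )
    args.out.mkdir(parents=True, exist_ok=True)
    table.to_csv(args.out / "hydropathy_profiles.tsv", sep="\t", index=False)

    n_domain = sum(flags.values())
    print(f"profiled {len(candidates)} candidates at window {args.window}")
    print(f"{n_domain} carry a prominent hydrophobic domain (score > 1.6):")
    for pid, flag in flags.items():
        if flag:
            print(f"  {pid}")


if __name__ == "__main__":
    main()
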