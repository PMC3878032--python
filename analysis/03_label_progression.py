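#!/usr/bin/env python
"""Label each visit for significant progression and write the labels CSV.

Applies the composite definition (validated >= 3 dB MD loss from
baseline, or an upward severity-stage shift) and its two single-clause
variants, and reports the per-definition prevalence.

    python analysis/03_label_progression.py --cohort results/cohort.csv --out results/
"""

import argparse
from pathlib import Path

import numpy as np

from kfprog.cohort import read_cohort
from kfprog.progression import label_cohort, labels_to_frame


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--cohort", type=Path, default=Path("results/cohort.csv"))
    parser.add_argument("--definition", default="composite",
                        choices=["composite", "md_only", "hap_only"])
    parser.add_argument("--out", type=Path, default=Path("results"))
    args = parser.parse_args()

    cohort = read_cohort(args.cohort)
    args.out.mkdir(parents=True, exist_ok=True)
    for definition in ("composite", "md_only", "hap_only"):
        labels = label_cohort(cohort, definition=definition)
        values = np.concatenate([lab.labels for lab in labels.values()])
        print(f"{definition:10s}: prevalence {np.nanmean(values):.3f} "
              f"({int(np.nansum(values))} positive visits)")
        if definition == args.definition:
            frame = labels_to_frame(labels)
            frame.to_csv(args.out / "labels.csv", index=False)
            print(f"wrote {args.out / 'labels.csv'} ({args.definition})")


if __name__ == "__main__":
    main()
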