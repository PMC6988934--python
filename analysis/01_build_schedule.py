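#!/usr/bin/env python
"""Build and validate the default two-day schedule.

Constructs the full protocol for one participant, checks every ordering
constraint and printed per-phase count, and writes the trial list plus a
count summary.  Expected outcome: zero violations; 1546 + 1580 = 3126
trials, 2248 field trials, 544 generalization channel probes (34 distinct
probes x 16 repetitions).
"""

import argparse
import os

import pandas as pd

from curladapt.protocol import build_schedule, validate_schedule


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--participant", type=int, default=0)
    ap.add_argument("--out", default="results")
    args = ap.parse_args()

    sched = build_schedule(seed=args.seed, participant_index=args.participant)
    report = validate_schedule(sched)

    os.makedirs(args.out, exist_ok=True)
    sched.to_csv(os.path.join(args.out, "schedule.csv"))
    counts = pd.DataFrame(
        sorted(report.counts.items()), columns=["quantity", "count"]
    )
    counts.to_csv(os.path.join(args.out, "schedule_counts.csv"), index=False)

    print(f"schedule: {len(sched)} trials, counterbalanced={sched.counterbalanced}")
    print(counts.to_string(index=False))
    if report.ok:
        print("all ordering constraints and per-phase counts satisfied")
    else:
        print(f"{len(report.violations)} violations:")
        for v in report.violations[:10]:
            print(" -", v)


if __name__ == "__main__":
    main()
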