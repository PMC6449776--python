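"""PVC sensitivity experiment: does correction rescue small-region effects?

Replicated phantom cohorts carry a marginal carrier-vs-non-carrier
decline confined to the two small atrophying regions (amygdala,
caudate).  Each replicate is analysed twice — with and without partial
volume correction — and the regions flagged by the mixed model are
compared between the two arms.
"""

import argparse
import json
from pathlib import Path

from fdglong.experiments import pvc_sensitivity_experiment

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main(seed: int = 0, n_replicates: int = 6) -> None:
    RESULTS.mkdir(exist_ok=True)
    table, summary = pvc_sensitivity_experiment(n_replicates=n_replicates, base_seed=seed)
    table.to_csv(RESULTS / "pvc_sensitivity.csv", index=False)
    with open(RESULTS / "pvc_sensitivity_summary.json", "w") as fh:
        json.dump(summary, fh, indent=2)

    print(f"replicates: {summary['n_replicates']}")
    print(f"non-PVC flags contained in PVC flags: {summary['n_superset']}"
          f"/{summary['n_replicates']} (strictly more with PVC: "
          f"{summary['n_strict_superset']})")
    print(f"total small-region flags: PVC {summary['total_flags_pvc']}, "
          f"non-PVC {summary['total_flags_nopvc']}")
    print(f"wrote {RESULTS/'pvc_sensitivity.csv'} and summary JSON")


if __name__ == "__main__":
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--n-replicates", type=int, default=6)
    args = ap.parse_args()
    main(args.seed, args.n_replicates)
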