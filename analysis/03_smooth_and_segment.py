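"""Apply the interruption-smoothing rule (1-3-sample runs flanked by >= 1 h
of consistent state), quantify its impact on the activity budget, verify
that every injected interruption is reverted, and extract bouts."""

import json
import pickle

import pandas as pd

from common import results_dir, scratch_dir
from ursactive.bout_segmentation import (
    extract_bouts,
    mean_bout_lengths,
    smooth_states,
    smoothing_impact,
)
from ursactive.io_formats import write_bouts


def main():
    with open(scratch_dir() / "classified.pkl", "rb") as fh:
        labelled = pickle.load(fh)
    with open(scratch_dir() / "simulation.pkl", "rb") as fh:
        truth = pickle.load(fh)["truth"]

    smoothed = smooth_states(labelled)
    impact = smoothing_impact(labelled, smoothed)

    sm = smoothed.set_index(["bear_id", "timestamp"])
    true = truth.true_states.set_index(["bear_id", "timestamp"])
    idx = pd.MultiIndex.from_frame(truth.interruptions[["bear_id", "timestamp"]])
    idx = idx.intersection(sm.index)
    recovery = (sm.loc[idx, "state"].to_numpy() == true.loc[idx, "state"].to_numpy()).mean()

    bouts = extract_bouts(smoothed)
    write_bouts(bouts, scratch_dir() / "bouts.csv")  # full table is bulky
    mean_bout_lengths(bouts).to_csv(results_dir() / "mean_bout_lengths.csv", index=False)
    with open(scratch_dir() / "smoothed.pkl", "wb") as fh:
        pickle.dump(smoothed, fh)
    summary = {**{k: round(v, 4) for k, v in impact.items()},
               "interruption_recovery_pct": round(100 * recovery, 2),
               "n_bouts": len(bouts)}
    (results_dir() / "smoothing_impact.json").write_text(json.dumps(summary, indent=2))

    print(f"smoothing flipped {impact['n_flipped']:,} samples: "
          f"+{impact['pct_inactive_added']:.2f}% inactive time, "
          f"+{impact['pct_active_added']:.2f}% active time, "
          f"net {impact['net_activity_change_pct']:+.2f}% active time")
    print(f"injected interruptions reverted: {100 * recovery:.1f}% of {len(idx):,}")
    print(f"extracted {len(bouts):,} bouts "
          f"({(~bouts['truncated']).sum():,} with uncensored durations)")


if __name__ == "__main__":
    main()
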