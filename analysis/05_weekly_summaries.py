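"""Aggregate to complete bear-weeks (the sampling unit of the seasonal
models) and to per-bear activity proportions by season and daily period."""

import pickle

from common import results_dir, scratch_dir
from ursactive.bout_segmentation import extract_bouts
from ursactive.io_formats import write_summaries
from ursactive.temporal_stratification import period_proportions, weekly_aggregate


def main():
    with open(scratch_dir() / "annotated.pkl", "rb") as fh:
        annotated = pickle.load(fh)

    retained = annotated[annotated["season"] != "excluded"]
    bouts = extract_bouts(annotated)
    weekly = weekly_aggregate(retained, bouts)
    write_summaries(weekly, results_dir() / "weekly_summaries.csv")

    props = period_proportions(retained)
    write_summaries(props, results_dir() / "period_proportions.csv")

    n_f = (weekly["sex"] == "F").sum()
    n_m = (weekly["sex"] == "M").sum()
    print(f"complete bear-weeks: {n_f} female, {n_m} male")
    print("mean hours active per day (complete weeks):")
    print(weekly.groupby(["season", "sex"])["hours_active_per_day"]
          .mean().round(2).to_string())
    grand = props.groupby("period")["proportion_active"].mean()
    print("grand mean proportion of time active by daily period:")
    print((100 * grand).round(1).to_string())


if __name__ == "__main__":
    main()
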