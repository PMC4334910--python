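"""Annotate each sample with its solar daily period (six periods bounded by
sunrise/sunset and the civil/nautical twilights) and the civil-daylight
covariate, and re-derive seasons from the per-bear berry windows."""

import pickle

from common import STUDY_LAT, STUDY_LON, STUDY_TZ, scratch_dir
from ursactive.io_formats import read_metadata_table
from ursactive.solar_time import annotate_periods
from ursactive.temporal_stratification import assign_season, calendar_from_metadata


def main():
    with open(scratch_dir() / "smoothed.pkl", "rb") as fh:
        smoothed = pickle.load(fh)

    metadata = read_metadata_table(scratch_dir() / "data" / "metadata.csv")
    calendars = calendar_from_metadata(metadata)
    annotated = assign_season(smoothed, calendars)
    annotated = annotate_periods(annotated, STUDY_LAT, STUDY_LON, STUDY_TZ)
    with open(scratch_dir() / "annotated.pkl", "wb") as fh:
        pickle.dump(annotated, fh)

    by_season = annotated.groupby("season").size()
    print("samples per season (excluded = outside the 22 May - 22 Oct guards):")
    for season, n in by_season.items():
        print(f"  {season:>10}: {n:,}")
    daylight = annotated.groupby(annotated["timestamp"].dt.normalize())[
        "daylight_civil_hours"].first()
    print(f"civil daylight spans {daylight.min():.2f}-{daylight.max():.2f} h/day "
          f"over the record")


if __name__ == "__main__":
    main()
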