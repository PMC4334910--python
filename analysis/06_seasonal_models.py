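"""Fit the seasonal mixed-effects models: weekly hours active and bout
lengths (daylight + sex + season + sex:season, random intercept per bear)
and the period x season model on arcsine activity proportions."""

import json
import warnings

import pandas as pd

from common import results_dir
from ursactive.summaries_models import fit_period_lmm, fit_weekly_lmm


def main():
    weekly = pd.read_csv(results_dir() / "weekly_summaries.csv")
    props = pd.read_csv(results_dir() / "period_proportions.csv")

    fits = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for response in ("hours_active", "active_bout", "inactive_bout"):
            fits[f"weekly_{response}"] = fit_weekly_lmm(
                weekly.dropna(subset=["active_bout_h", "inactive_bout_h"]), response)
        fits["period_season"] = fit_period_lmm(props)

    (results_dir() / "model_fits.json").write_text(
        json.dumps({k: f.to_dict() for k, f in fits.items()}, indent=2))

    hours = fits["weekly_hours_active"]
    berry = hours.coef("season[T.berry]")
    print(f"berry vs herb-bulb, hours active/day: "
          f"beta = {berry['estimate']:.2f} (SE {berry['se']:.2f}, p = {berry['pvalue']:.2g})")
    sexm = hours.coef("sex[T.M]")
    print(f"male vs female: beta = {sexm['estimate']:.2f} (SE {sexm['se']:.2f})")
    ab = fits["weekly_active_bout"].coef("season[T.berry]")
    print(f"berry vs herb-bulb, active bout length: beta = {ab['estimate']:.2f} h "
          f"(SE {ab['se']:.2f})")
    night = fits["period_season"].coef("period[T.night]")
    print(f"night vs day, arcsine proportion active: beta = {night['estimate']:.2f} "
          f"(SE {night['se']:.2f}, p = {night['pvalue']:.2g})")
    print(f"full coefficient tables: {results_dir() / 'model_fits.json'}")


if __name__ == "__main__":
    main()
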