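#!/usr/bin/env python
"""Change-point segmentation and mixed-effects inference per sub-band.

PELT/MBIC change points on each grand timecourse, average power per
interval per session, random-intercept LME vs. null by chi-squared LRT,
and Tukey pairwise contrasts.  Writes results/04_change_points_lme.csv
and results/04_tukey_pairwise.csv, and reports the recovered beta ERD
onset lead relative to consonant movement onset.
"""

import json

import numpy as np
import pandas as pd

from _common import RESULTS, get_bundle
from speechbeta.inference import last_pre_onset_change_point


def main() -> None:
    bundle, config = get_bundle()
    fs = bundle.sample_rate_hz
    onset = bundle.grand["beta_h"].boundaries[0]
    rows, tukey_frames = [], []
    for band, res in bundle.change_points.items():
        rows.append(
            {
                "band": band,
                "change_points": json.dumps(res.change_points.tolist()),
                "n_intervals": res.n_intervals,
                "chi2": round(res.lme.chi2, 2),
                "df": res.lme.df,
                "p": res.lme.p_value,
            }
        )
        tk = res.tukey.copy()
        tk.insert(0, "band", band)
        tukey_frames.append(tk)
    df = pd.DataFrame(rows)
    tukey = pd.concat(tukey_frames, ignore_index=True)
    tukey["p_bonferroni_bands"] = np.minimum(tukey.p_tukey * len(rows), 1.0)
    RESULTS.mkdir(exist_ok=True)
    df.to_csv(RESULTS / "04_change_points_lme.csv", index=False)
    tukey.to_csv(RESULTS / "04_tukey_pairwise.csv", index=False)

    print(df.to_string(index=False))
    cps = bundle.change_points["beta_h"].change_points
    last = last_pre_onset_change_point(cps, onset)
    lead = (onset - last) / fs * 1000.0
    truth = config.sim.band_envelope_params["beta_h"].lead_s * 1000.0
    print(
        f"\nbeta_h: last change point before consonant onset sits {lead:.0f} ms "
        f"ahead of movement (generator ground truth: {truth:.0f} ms) -- the "
        "pre-movement beta decline is recovered from the segmentation."
    )
    n_sig = int((tukey.p_bonferroni_bands < 0.05).sum())
    print(f"{n_sig}/{len(tukey)} Tukey contrasts significant after the "
          "across-band Bonferroni stage.")


if __name__ == "__main__":
    main()
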