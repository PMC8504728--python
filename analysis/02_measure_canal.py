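"""Pelvimetry stage: landmarks -> canal measurements -> consensus per specimen.

Reads results/landmarks.csv (written by 01), measures every
(specimen, observer, replicate) landmark set, averages the fuzzy outlet ML
replicates within each observer, then averages observers into a consensus
table merged with the cohort covariates.  Writes
results/canal_measurements_raw.csv and results/analysis_cohort.csv.
"""

from pathlib import Path

import pandas as pd

from pelvimetrics.morphometry import FIELD_ORDER, CanalMeasurements, measure_all, read_landmarks_csv
from pelvimetrics.reliability import average_fuzzy_replicates

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    lm_sets = read_landmarks_csv(OUT / "landmarks.csv")
    meas = measure_all(lm_sets)
    meas.to_csv(OUT / "canal_measurements_raw.csv", index=False, float_format="%.10g")
    print(f"measured {len(meas)} landmark sets "
          f"({meas.specimen_id.nunique()} specimens x "
          f"{meas.observer_id.nunique()} observers x "
          f"{meas.replicate_id.nunique()} replicates)")

    rows = []
    for (spec, obs), grp in meas.groupby(["specimen_id", "observer_id"]):
        reps = [
            CanalMeasurements(**{f: r[f] for f in FIELD_ORDER})
            for _, r in grp.sort_values("replicate_id").iterrows()
        ]
        merged = average_fuzzy_replicates(reps)
        rows.append(dict(specimen_id=spec, observer_id=obs, **merged.as_dict()))
    per_obs = pd.DataFrame(rows)
    consensus = per_obs.drop(columns="observer_id").groupby("specimen_id", as_index=False).mean()

    cohort = pd.read_csv(OUT / "cohort.csv")
    analysis = cohort[["specimen_id", "sex", "body_weight_kg", "stature_m",
                       "gut_volume_cc"]].merge(consensus, on="specimen_id")
    analysis.to_csv(OUT / "analysis_cohort.csv", index=False, float_format="%.10g")
    print("consensus canal measurements (mm / deg), cohort means:")
    print(analysis.groupby("sex")[list(FIELD_ORDER)].mean().round(2).to_string())
    print(f"\nwrote {OUT / 'analysis_cohort.csv'}")


if __name__ == "__main__":
    main()
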