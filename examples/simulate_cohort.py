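"""Generate a synthetic 24-h ambulatory cohort and inspect its moments.

The generator emulates an ambulatory BP monitoring protocol: readings every
30 min from 08:00-20:00 and hourly overnight, with reference SBP/DBP drawn
from a between-subject + circadian + nocturnal-dip + AR(1) model and seven
wearable features linked linearly to SBP.
"""

from conformalbp import synth
from conformalbp.schema import DAYTIME, NIGHTTIME

config = synth.CohortConfig(n_subjects=500, seed=1)
cohort = synth.generate_cohort(config)

day, night = config.n_slots()
print(f"records: {len(cohort)}  ({day} daytime + {night} nighttime slots/subject)")
print(f"SBP  mean {cohort.sbp_ref.mean():6.2f}  SD {cohort.sbp_ref.std(ddof=1):5.2f}  "
      f"(population target 123.48 +/- 20.04 mmHg)")
print(f"DBP  mean {cohort.dbp_ref.mean():6.2f}  SD {cohort.dbp_ref.std(ddof=1):5.2f}  "
      f"(population target  75.80 +/- 14.47 mmHg)")

by_phase = cohort.groupby("phase")["sbp_ref"].agg(["mean", "std"])
dip = by_phase.loc[DAYTIME, "mean"] - by_phase.loc[NIGHTTIME, "mean"]
print(f"daytime-minus-nighttime SBP mean: {dip:.1f} mmHg (nocturnal dip)")
print(f"night/day SBP SD ratio: "
      f"{by_phase.loc[NIGHTTIME,'std']/by_phase.loc[DAYTIME,'std']:.2f} "
      f"(> 1: nights are more variable)")
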