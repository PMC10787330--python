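# workmode

Estimate **per-minute probability of being in work mode** from passively
logged smartphone data, and segment each day into office work, breaks at
the worksite, off-work time and remote work.

Traditional work-hour measurement equates working with being at the
worksite. That misses two things a location trace cannot see: breaks
taken *at* the worksite and work done *away* from it. `workmode` targets
both by combining two streams a logging app can collect without user
effort:

* **screen events** — timestamps of notifications, screen on/off events
  and active-app labels (1-s resolution);
* **GPS fixes** — one fix per 600 s, compared against up to 5 registered
  workplace locations.

GPS provides automatic labels through a dwell rule (on-working after the
device stays within 1 km of a workplace for 1800 s; off-working after
1800 s without such a detection). A per-participant two-stage model —
gradient boosted trees over 5-features-per-app 1800-s windows, followed
by a 1-D convolutional network that smooths the provisional probability
sequence into next-minute probabilities — then learns to recognize the
*behavioral* signature of work, so that minutes at the worksite with
off-work behavior surface as breaks and minutes off-site with work
behavior surface as remote work:

| probability > 0.5 | at worksite | state |
|---|---|---|
| yes | yes | office working |
| no  | yes | break at worksite |
| yes | no  | remote working |
| no  | no  | off work |

Because no public dataset of paired screen-event/GPS logs exists, the
package ships a first-class synthetic-data module that simulates
participants (Poisson notifications, log-normal reaction times and usage
episodes, schedules with commutes, breaks, evening remote work and
holidays, noisy GPS tracks) with known minute-level ground truth; the
whole pipeline is validated against it. See `docs/methods.md` for the
model, conventions and limitations.

Intended users: researchers in digital phenotyping / occupational health
who want to prototype or stress-test geofence-plus-behavior work-hour
estimation without access to a real cohort.

## Worked example

```python
import numpy as np
from workmode import generate_participant, simulate_days
from workmode.pipeline import run_participant
from workmode.segmentation import classify_minutes, summarize_day

profile = generate_participant(1)            # deterministic synthetic user
events, gps, truth = simulate_days(profile, 30, seed=1)

res = run_participant(profile.participant_id, events, gps,
                      profile.workplaces, seed=1)
print(f"stage-1 AUC {res.stage1_auc:.3f} -> final AUC {res.final_auc:.3f}")

day = next(d for d in res.heldout_days if res.days[d].day_class == "typical")
seg = classify_minutes(res.final[day], res.days[day].minute_state)
print({k: round(v, 2) for k, v in summarize_day(seg).items()})
```

Output:

```
stage-1 AUC 0.932 -> final AUC 0.941
{'office_h': 9.73, 'break_at_work_h': 0.77, 'off_h': 5.05, 'remote_h': 2.7,
 'prob_work_h': 12.43, 'gps_work_h': 10.5}
```

Reading it: on 30 simulated days the boosted-tree stage alone separates
on/off-working minutes with AUC 0.932 on held-out days (transition
minutes around GPS switches excluded); the temporal CNN raises that to
0.941. On the first typical held-out day the model finds 9.7 h of office
work and 0.8 h of breaks inside the 10.5 h the geofence calls work, plus
2.7 h of evening remote work — so behavior-defined work (12.4 h) exceeds
GPS-defined work, driven by remote time, matching how the day was
actually scheduled by the simulator.

The same flow is available from the shell:

```
workmode --config run.yaml demo      # simulate -> label -> featurize ->
                                     # train -> segment -> evaluate
```

which writes `events.csv`, `gps.csv`, `truth.csv`, `workhours.csv`,
`features.csv`, `prob.csv`, `segmentation.csv`, `summary.csv` and
`report.json` into the configured output directory (column dictionaries
in `src/workmode/ingest_io.py`).

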