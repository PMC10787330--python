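"""End-to-end per-participant pipeline.

Orchestrates: GPS day labeling -> window featurization -> stage-1 boosted
trees (day-blocked 5-fold CV) -> per-minute provisional probabilities ->
stage-2 temporal CNN -> final probabilities -> segmentation -> evaluation.

Bridging convention (1800-s windows vs per-minute output): the provisional
probability at minute t comes from the 1800-s feature window *ending* at t,
slid at a 60-s stride.  Stage-1 training still uses non-overlapping
1800-s windows; stage-2 training inputs use out-of-fold provisional
probabilities (each day is scored by the fold model that never saw it) so
the smoother is not trained on leaked stage-1 fits.

Day budget: the last ``holdout_fraction`` of calendar days (all day
classes) is held out for evaluation; training uses the typical workdays of
the remaining span.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .gps_labeling import PipelineConfig, label_days
from .featurization import WindowFeaturizer, build_training_set, feature_names
from .stage1_gbt import Stage1Config, Stage1Model, train_stage1, predict_proba
from .stage2_cnn import CnnConfig, Stage2Model, make_sequences, train_stage2, predict_series
from .segmentation import classify_minutes, summarize_day
from . import evaluation as ev


@dataclass
class ParticipantResult:
    participant_id: str
    days: dict                               # date -> DayRecord
    train_days: list
    heldout_days: list
    vocab: list
    stage1: Stage1Model
    stage2: Stage2Model
    window_oof_auc: float | None             # stage-1 CV AUC on training windows
    provisional: dict = field(default_factory=dict)   # date -> (1095,) array
    final: dict = field(default_factory=dict)
    stage1_auc: float | None = None          # held-out, masked, pooled
    final_auc: float | None = None
    day_metrics: pd.DataFrame | None = None
    summaries: pd.DataFrame | None = None


def _minute_provisional(model: Stage1Model, fz: WindowFeaturizer, date,
                        fold: int | None) -> np.ndarray:
    X = pd.DataFrame(fz.minute_matrix(date), columns=model.feature_names)
    return predict_proba(model, X, fold=fold)


def run_participant(participant_id: str, events: pd.DataFrame, gps: pd.DataFrame,
                    workplaces, cfg: PipelineConfig | None = None,
                    s1cfg: Stage1Config | None = None,
                    cnn_cfg: CnnConfig | None = None,
                    seed: int = 0, holdout_fraction: float = 0.3,
                    k_folds: int = 5) -> ParticipantResult:
    """Train and evaluate the two-stage model for one participant."""
    cfg = cfg or PipelineConfig()
    s1cfg = s1cfg or Stage1Config()
    cnn_cfg = cnn_cfg or CnnConfig(seed=seed)

    days = label_days(gps, workplaces, cfg)
    dates = sorted(days)
    n_hold = max(1, int(round(holdout_fraction * len(dates)))) if holdout_fraction > 0 else 0
    heldout = dates[len(dates) - n_hold:] if n_hold else []
    train_dates = [d for d in dates[:len(dates) - n_hold]
                   if days[d].day_class == "typical"]
    if len(train_dates) < cfg.min_typical_days:
        raise ValueError(
            f"{participant_id}: only {len(train_dates)} typical workdays available "
            f"for training; at least {cfg.min_typical_days} are required")

    train_records = {d: days[d] for d in train_dates}
    X, y, meta, vocab = build_training_set(train_records, events, cfg)
    day_ids = meta["date"].to_numpy()
    stage1, oof = train_stage1(X, y, day_ids, k=k_folds, seed=seed, cfg=s1cfg)
    window_oof_auc = ev.participant_auc(oof, y)

    events_by_date = dict(tuple(events.groupby(events["timestamp"].map(lambda t: t.date()))))
    empty_events = events.iloc[0:0]

    # per-minute provisional series: out-of-fold on training days,
    # final refit model on held-out days
    prov, gps_minutes = {}, {}
    for d in dates:
        fz = WindowFeaturizer(events_by_date.get(d, empty_events), vocab, cfg)
        fold = stage1.day_fold.get(d)
        prov[d] = _minute_provisional(stage1, fz, d, fold)
        gps_minutes[d] = days[d].minute_state.astype(int)

    # stage 2 trained on the training days' out-of-fold provisional series
    pairs_X, pairs_y, pair_days = make_sequences([prov[d] for d in train_dates],
                                                 [gps_minutes[d] for d in train_dates],
                                                 cnn_cfg.lookback)
    stage2 = train_stage2(pairs_X, pairs_y, cnn_cfg, groups=pair_days)

    final = {d: predict_series(stage2, prov[d]) for d in dates}

    res = ParticipantResult(participant_id, days, train_dates, heldout, vocab,
                            stage1, stage2, window_oof_auc, prov, final)

    eval_dates = heldout if heldout else dates
    rows, summaries = [], []
    pooled_p1, pooled_pf, pooled_y, pooled_m = [], [], [], []
    for d in eval_dates:
        g = gps_minutes[d]
        mask = ev.transition_mask(g, cfg.transition_exclusion_min)
        acc = ev.day_accuracy(final[d], g, mask, cfg.prob_threshold)
        ref = ev.reference_accuracy_9to5(g)
        sens, spec = ev.sensitivity_specificity(final[d], g, mask, cfg.prob_threshold)
        seg = classify_minutes(final[d], g, cfg.prob_threshold)
        s = summarize_day(seg)
        s.update(participant_id=participant_id, date=str(d))
        summaries.append(s)
        rows.append({"participant_id": participant_id, "date": str(d),
                     "day_class": days[d].day_class, "accuracy": acc,
                     "reference_accuracy": ref, "sensitivity": sens,
                     "specificity": spec})
        pooled_p1.append(prov[d])
        pooled_pf.append(final[d])
        pooled_y.append(g)
        pooled_m.append(mask)
    p1 = np.concatenate(pooled_p1)
    pf = np.concatenate(pooled_pf)
    yy = np.concatenate(pooled_y)
    mm = np.concatenate(pooled_m)
    res.stage1_auc = ev.participant_auc(p1, yy, mm)
    res.final_auc = ev.participant_auc(pf, yy, mm)
    res.day_metrics = pd.DataFrame(rows)
    res.summaries = pd.DataFrame(summaries)
    return res


def run_cohort(events: pd.DataFrame, gps: pd.DataFrame, workplaces_by_pid: dict,
               cfg: PipelineConfig | None = None,
               s1cfg: Stage1Config | None = None,
               cnn_cfg: CnnConfig | None = None,
               seed: int = 0, holdout_fraction: float = 0.3) -> dict:
    """Run every participant; returns {participant_id: ParticipantResult}.

    Participants whose data cannot support training (too few typical days)
    are skipped with a console note, mirroring cohort-selection criteria.
    """
    out = {}
    for i, (pid, wp) in enumerate(sorted(workplaces_by_pid.items())):
        e = events[events["participant_id"] == pid].reset_index(drop=True)
        g = gps[gps["participant_id"] == pid].reset_index(drop=True)
        cnn = cnn_cfg or CnnConfig(seed=seed + i)
        if cnn_cfg is not None:
            cnn = CnnConfig(**{**cnn_cfg.__dict__, "seed": seed + i})
        try:
            out[pid] = run_participant(pid, e, g, wp, cfg, s1cfg, cnn,
                                       seed=seed + i,
                                       holdout_fraction=holdout_fraction)
        except ValueError as exc:
            print(f"skipping {pid}: {exc}")
    return out


def cohort_report(results: dict, cfg: PipelineConfig | None = None) -> dict:
    """Cohort-level metrics in the shape of the study's results section."""
    cfg = cfg or PipelineConfig()
    pids = sorted(results)
    s1 = np.array([results[p].stage1_auc for p in pids], dtype=float)
    fin = np.array([results[p].final_auc for p in pids], dtype=float)
    day_metrics = pd.concat([results[p].day_metrics for p in pids], ignore_index=True)
    summaries = pd.concat([results[p].summaries for p in pids], ignore_index=True)
    acc, ref = day_metrics["accuracy"], day_metrics["reference_accuracy"]
    report = {
        "n_participants": len(pids),
        "stage1_auc_mean": float(np.nanmean(s1)),
        "stage1_auc_sd": float(np.nanstd(s1, ddof=1)) if len(s1) > 1 else 0.0,
        "final_auc_mean": float(np.nanmean(fin)),
        "final_auc_sd": float(np.nanstd(fin, ddof=1)) if len(fin) > 1 else 0.0,
        "frac_auc_above_floor": float(np.mean(fin > cfg.auc_floor)),
        "accuracy_mean": float(acc.mean()),
        "reference_accuracy_mean": float(ref.mean()),
        "per_participant": {p: {"stage1_auc": results[p].stage1_auc,
                                "final_auc": results[p].final_auc,
                                "window_oof_auc": results[p].window_oof_auc,
                                "n_train_days": len(results[p].train_days),
                                "n_heldout_days": len(results[p].heldout_days)}
                            for p in pids},
    }
    if len(s1) >= 2 and np.isfinite(s1).all() and np.isfinite(fin).all():
        t, p2, df = ev.paired_t(fin, s1)
        report["stage2_gain_t"] = t
        report["stage2_gain_p_one_sided"] = p2 / 2.0 if t > 0 else 1.0 - p2 / 2.0
        report["stage2_gain_df"] = df
    if len(day_metrics) >= 2 and acc.std(ddof=1) + ref.std(ddof=1) > 0:
        t, p2, df = ev.paired_t(acc.to_numpy(), ref.to_numpy())
        report["accuracy_vs_reference_t"] = t
        report["accuracy_vs_reference_p"] = p2
    report["mean_hours"] = {
        k: float(summaries[k].mean())
        for k in ("office_h", "break_at_work_h", "off_h", "remote_h",
                  "prob_work_h", "gps_work_h")
    }
    return report
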