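"""End-to-end orchestration: sessions → MAD tables → statistics → files.

The pipeline mirrors the study design: compute three epoch MADs per bout
per device, compare devices by Bland-Altman, validate the intensity
pattern against heart rate, fit per-device cut-points, and score
classification against both the fitted and the universal adult
cut-points.  Every run writes a manifest capturing the configuration,
seed and library versions so reruns are byte-stable.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as mio
from .agreement import bland_altman, pair_bout_mads, threshold_bias
from .cutpoints import (
    ADULT_UNIVERSAL_CUTS,
    CutPointSet,
    classify,
    compare_cutpoint_sets,
    evaluate,
    fit_cutpoints,
)
from .hr_validity import (
    CorrelationSummary,
    UndefinedCorrelationError,
    bout_mean_hr,
    pooled_correlation,
    subject_correlation,
)
from .signal_core import bout_three_epoch_mads, choose_epoch_spec
from .synthetic import SessionDataset, generate_cohort

logger = logging.getLogger("madaccel")

__all__ = [
    "PipelineConfig",
    "activity_misclassification_count",
    "cohort_hr_validity",
    "extract_bout_mads",
    "heart_rate_table",
    "run_pipeline",
]

EPOCH_SLOTS = ("start", "middle", "end")


def extract_bout_mads(
    sessions: list[SessionDataset], target_duration_s: float = 5.0
) -> pd.DataFrame:
    """Three-epoch bout MADs for every (participant, device, bout).

    Each device uses its own power-of-two epoch length nearest the target
    duration.  Returns a tidy table with one row per epoch slot.
    """
    rows = []
    for session in sessions:
        for device_id, rec in session.recordings.items():
            spec = choose_epoch_spec(rec.sampling_rate_hz, target_duration_s)
            for i, bout in enumerate(session.bouts):
                mads = bout_three_epoch_mads(rec, bout, spec)
                for slot, mad in zip(EPOCH_SLOTS, mads):
                    rows.append(
                        {
                            "participant": session.participant_id,
                            "device": device_id,
                            "bout_index": i,
                            "label": bout.label,
                            "intensity_class": bout.intensity_class,
                            "epoch_slot": slot,
                            "mad_mg": mad,
                        }
                    )
    return pd.DataFrame(rows, columns=mio.MAD_TABLE_COLS)


def heart_rate_table(sessions: list[SessionDataset]) -> pd.DataFrame:
    rows = [
        {
            "participant": s.participant_id,
            "bout_label": o.bout_label,
            "hr_start_bpm": o.hr_start_bpm,
            "hr_1min_bpm": o.hr_1min_bpm,
            "hr_2min_bpm": o.hr_2min_bpm,
        }
        for s in sessions
        for o in s.heart_rate
    ]
    return pd.DataFrame(rows, columns=mio.HR_TABLE_COLS)


def cohort_hr_validity(
    mad_table: pd.DataFrame, hr_table: pd.DataFrame, device: str
) -> CorrelationSummary:
    """Per-subject HR-vs-MAD correlations for one device, Fisher-pooled.

    Bout MAD is the mean of the bout's three epoch MADs; bout heart rate
    is the mean of the 1-min and 2-min readings.  Sedentary bouts are
    excluded inside :func:`subject_correlation`; subjects with fewer than
    three usable bouts are excluded and listed.
    """
    dev = mad_table[mad_table["device"] == device]
    bout_mad = (
        dev.groupby(["participant", "label", "intensity_class"], as_index=False)
        ["mad_mg"].mean()
    )
    hr = hr_table.copy()
    hr["hr_bpm"] = [
        bout_mean_hr(r.hr_1min_bpm, r.hr_2min_bpm)
        for r in hr.itertuples(index=False)
    ]
    merged = bout_mad.merge(
        hr[["participant", "bout_label", "hr_bpm"]],
        left_on=["participant", "label"],
        right_on=["participant", "bout_label"],
    )
    per_subject: dict[str, float] = {}
    excluded: list[str] = []
    n_used = 0
    for pid, grp in merged.groupby("participant"):
        try:
            r = subject_correlation(
                grp["mad_mg"].to_numpy(),
                grp["hr_bpm"].to_numpy(),
                grp["intensity_class"].to_numpy(),
            )
        except UndefinedCorrelationError as exc:
            logger.warning("hr_validity: subject %s excluded (%s)", pid, exc)
            excluded.append(str(pid))
            continue
        per_subject[str(pid)] = r
        n_used += int((grp["intensity_class"] > 0).sum())
    return CorrelationSummary(
        per_subject_r=per_subject,
        pooled_r=pooled_correlation(per_subject),
        n_bouts_used=n_used,
        excluded_subjects=tuple(excluded),
    )


def activity_misclassification_count(
    mad_table: pd.DataFrame, device: str, cuts: CutPointSet
) -> int:
    """Number of activities whose majority-vote epoch class is wrong.

    Each bout contributes one activity; its predicted class is the
    majority vote of its three epoch classifications (a three-way tie
    resolves to the median class).
    """
    dev = mad_table[mad_table["device"] == device]
    wrong = 0
    for (_, _), grp in dev.groupby(["participant", "bout_index"]):
        pred = np.sort(classify(grp["mad_mg"].to_numpy(), cuts))
        vote = int(pred[len(pred) // 2])  # median = majority when one exists
        if vote != int(grp["intensity_class"].iloc[0]):
            wrong += 1
    return wrong


@dataclass
class PipelineConfig:
    """Configuration for a full analysis run.

    Exactly one input source is used: synthetic generation (requires a
    seed) or files (a recordings manifest plus a protocol table).
    """

    output_dir: str = "madaccel_out"
    # synthetic source
    synthetic: bool = True
    n_participants: int = 20
    seed: int | None = None
    # file source
    recordings: list[dict] = field(default_factory=list)
    protocol_path: str | None = None
    heart_rate_path: str | None = None
    # analysis parameters
    epoch_target_s: float = 5.0
    agreement_level: str = "bout"
    agreement_threshold_mg: float = 700.0
    reference_cuts: tuple[float, float, float] = (
        ADULT_UNIVERSAL_CUTS.cut1_mg,
        ADULT_UNIVERSAL_CUTS.cut2_mg,
        ADULT_UNIVERSAL_CUTS.cut3_mg,
    )
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.synthetic and self.recordings:
            raise ValueError("choose one input source: synthetic or files")
        if self.synthetic and self.seed is None:
            raise ValueError("synthetic mode requires an explicit seed")
        if not self.synthetic and not self.recordings:
            raise ValueError("file mode requires a recordings manifest")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "reference_cuts" in raw:
            raw["reference_cuts"] = tuple(raw["reference_cuts"])
        return cls(**raw)


def _load_file_sessions(config: PipelineConfig) -> list[SessionDataset]:
    bouts_by_pid = mio.read_bout_protocol(config.protocol_path)
    recs: dict[str, dict] = {}
    for entry in config.recordings:
        rec = mio.read_raw_recording(
            entry["path"],
            device_id=entry["device"],
            dynamic_range_mg=entry["dynamic_range_mg"],
            sampling_rate_hz=entry.get("sampling_rate_hz"),
        )
        recs.setdefault(str(entry["participant"]), {})[entry["device"]] = rec
    hr_by_pid: dict[str, list] = {}
    if config.heart_rate_path:
        from .synthetic import HeartRateObservation

        hr_df = mio.read_heart_rate_table(config.heart_rate_path)
        for row in hr_df.itertuples(index=False):
            hr_by_pid.setdefault(str(row.participant), []).append(
                HeartRateObservation(
                    row.bout_label, row.hr_start_bpm, row.hr_1min_bpm,
                    row.hr_2min_bpm,
                )
            )
    sessions = []
    for pid, devices in recs.items():
        if pid not in bouts_by_pid:
            raise ValueError(f"participant {pid} has recordings but no protocol")
        sessions.append(
            SessionDataset(
                participant_id=pid,
                recordings=devices,
                bouts=tuple(bouts_by_pid[pid]),
                heart_rate=tuple(hr_by_pid.get(pid, ())),
            )
        )
    return sessions


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and write the result bundle to ``config.output_dir``.

    Returns a summary dict (also written as ``manifest.json``).  Output
    files: ``mad_epochs.csv``, ``agreement_pairs.csv``,
    ``agreement_summary.json``, ``hr_validity.csv``, ``cutpoints.json``,
    ``classification_report.csv``, ``manifest.json``.
    """
    logging.basicConfig(level=config.log_level)
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    if config.synthetic:
        logger.info("stage=simulate n=%d seed=%s", config.n_participants, config.seed)
        sessions = generate_cohort(config.n_participants, seed=config.seed)
    else:
        logger.info("stage=load n_recordings=%d", len(config.recordings))
        sessions = _load_file_sessions(config)

    logger.info("stage=mad")
    mad_table = extract_bout_mads(sessions, config.epoch_target_s)
    mio.write_mad_table(mad_table, out / "mad_epochs.csv")
    devices = sorted(mad_table["device"].unique())

    summary: dict = {"devices": devices, "n_participants": len(sessions)}

    if len(devices) >= 2:
        logger.info("stage=agree devices=%s", devices[:2])
        dev_a, dev_b = devices[0], devices[1]
        paired = pair_bout_mads(
            mad_table[mad_table["device"] == dev_a],
            mad_table[mad_table["device"] == dev_b],
            level=config.agreement_level,
        )
        for row in paired.unmatched.itertuples(index=False):
            logger.warning("agree: unmatched key %s", tuple(row))
        ba = bland_altman(paired.mad_a, paired.mad_b)
        tb = threshold_bias(paired.mad_a, paired.mad_b,
                            config.agreement_threshold_mg)
        paired.pairs.to_csv(out / "agreement_pairs.csv", index=False)
        summary["agreement"] = {
            "device_a": dev_a,
            "device_b": dev_b,
            "level": config.agreement_level,
            "bias_mg": ba.bias,
            "loa_lower_mg": ba.loa_lower,
            "loa_upper_mg": ba.loa_upper,
            "threshold_mg": tb.threshold_mg,
            "bias_below_mg": tb.bias_below,
            "bias_above_mg": tb.bias_above,
        }
        with open(out / "agreement_summary.json", "w") as fh:
            json.dump(summary["agreement"], fh, indent=2)

    hr_table = heart_rate_table(sessions)
    if len(hr_table):
        logger.info("stage=validate-hr")
        hr_rows = []
        summary["hr_validity"] = {}
        for device in devices:
            cs = cohort_hr_validity(mad_table, hr_table, device)
            summary["hr_validity"][device] = {
                "pooled_r": cs.pooled_r,
                "n_bouts_used": cs.n_bouts_used,
                "excluded_subjects": list(cs.excluded_subjects),
            }
            hr_rows += [
                {"device": device, "participant": pid, "r": r}
                for pid, r in cs.per_subject_r.items()
            ]
            hr_rows.append(
                {"device": device, "participant": "POOLED", "r": cs.pooled_r}
            )
        pd.DataFrame(hr_rows).to_csv(out / "hr_validity.csv", index=False)

    logger.info("stage=cutpoints")
    summary["cutpoints"] = {}
    report_frames = []
    reference = CutPointSet(*config.reference_cuts)
    for device in devices:
        dev = mad_table[mad_table["device"] == device]
        fit, cuts = fit_cutpoints(
            dev["mad_mg"].to_numpy(),
            dev["intensity_class"].to_numpy(),
            dev["participant"].to_numpy(),
        )
        rep_fitted = evaluate(dev["mad_mg"].to_numpy(),
                              dev["intensity_class"].to_numpy(), cuts)
        rep_ref = evaluate(dev["mad_mg"].to_numpy(),
                           dev["intensity_class"].to_numpy(), reference)
        comparison = compare_cutpoint_sets(
            rep_fitted, rep_ref, names=("fitted", "reference")
        )
        comparison.insert(0, "device", device)
        report_frames.append(comparison)
        summary["cutpoints"][device] = {
            "cut1_mg": cuts.cut1_mg,
            "cut2_mg": cuts.cut2_mg,
            "cut3_mg": cuts.cut3_mg,
            "methods": [t.method for t in fit.thresholds],
            "misclassification_pct_fitted": rep_fitted.misclassification_pct,
            "misclassification_pct_reference": rep_ref.misclassification_pct,
            "activities_misclassified_fitted": activity_misclassification_count(
                mad_table, device, cuts
            ),
            "activities_misclassified_reference": activity_misclassification_count(
                mad_table, device, reference
            ),
        }
    with open(out / "cutpoints.json", "w") as fh:
        json.dump(summary["cutpoints"], fh, indent=2)
    pd.concat(report_frames, ignore_index=True).to_csv(
        out / "classification_report.csv", index=False
    )

    import statsmodels

    manifest = {
        "config": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in vars(config).items()
        },
        "versions": {
            "numpy": np.__version__,
            "pandas": pd.__version__,
            "statsmodels": statsmodels.__version__,
        },
        "summary": summary,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return summary
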