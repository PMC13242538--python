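"""Readers, writers and preprocessing for screening-visit tables.

The canonical on-disk form is long format, matching how surveillance data
arrive: one row per retained visit with columns ``subject_id, visit_time,
observed_state`` (states 1 = healthy, 2 = precursor, 3 = cancer), plus a
subject table carrying the censoring summary (delta, interval), covariates
and — for simulated cohorts — the latent progression times.  Round-trips
are lossless.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .simulate import SimulatedCohort, SubjectHistory, VisitDesign
from .transitions import ThreeStateSpec

__all__ = [
    "cohort_to_frames",
    "histories_from_frames",
    "write_cohort",
    "read_cohort",
    "apply_reference_age",
    "StudyConfig",
    "write_manifest",
]


def cohort_to_frames(cohort: SimulatedCohort):
    """Long visit table + subject table for a simulated cohort."""
    vrows = []
    srows = []
    p = cohort.histories[0].covariates.size if cohort.histories else 0
    for i, h in enumerate(cohort.histories):
        for j, v in enumerate(h.visits):
            last = j == h.visits.size - 1
            state = h.delta if (last and h.delta != 1) else 1
            vrows.append({"subject_id": h.subject_id, "visit_time": v,
                          "observed_state": state})
        row = {"subject_id": h.subject_id, "delta": h.delta,
               "interval_left": h.interval_left, "interval_right": h.interval_right,
               "latent_x": cohort.latent_x[i], "latent_t": cohort.latent_t[i]}
        for k in range(p):
            row[f"z{k+1}"] = h.covariates[k]
        srows.append(row)
    return pd.DataFrame(vrows), pd.DataFrame(srows)


def histories_from_frames(visits: pd.DataFrame, subjects: pd.DataFrame | None = None,
                          covariate_columns=()) -> list[SubjectHistory]:
    """Parse a long visit table into subject histories.

    Each subject's rows must be time-ordered healthy visits optionally
    followed by a single terminal state-2 or state-3 visit.  Malformed
    records (non-increasing times, unknown states, events before the end,
    missing covariates) are rejected with the subject id in the message.
    """
    required = {"subject_id", "visit_time", "observed_state"}
    if not required.issubset(visits.columns):
        raise ValueError(f"visit table must have columns {sorted(required)}")
    cov = None
    if covariate_columns:
        if subjects is None:
            raise ValueError("covariate columns requested but no subject table given")
        missing = [c for c in covariate_columns if c not in subjects.columns]
        if missing:
            raise ValueError(f"subject table lacks covariate columns {missing}")
        if subjects[list(covariate_columns)].isna().any().any():
            bad = subjects.loc[subjects[list(covariate_columns)].isna().any(axis=1),
                               "subject_id"].tolist()
            raise ValueError(f"missing covariates for subjects {bad}")
        cov = subjects.set_index("subject_id")[list(covariate_columns)]
    histories = []
    for sid, g in visits.groupby("subject_id", sort=True):
        g = g.sort_index()
        times = g["visit_time"].to_numpy(dtype=float)
        states = g["observed_state"].to_numpy()
        if np.any(np.diff(times) <= 0):
            raise ValueError(f"subject {sid}: visit times not strictly increasing")
        if not np.isin(states, [1, 2, 3]).all():
            raise ValueError(f"subject {sid}: unknown observed_state values")
        if np.any(states[:-1] != 1):
            raise ValueError(f"subject {sid}: event state before the final visit "
                             "(follow-up should stop at detection)")
        delta = int(states[-1])
        left = 0.0 if times.size == 1 else float(times[-2])
        right = float(times[-1])
        if delta == 1:
            left = 0.0
        z = cov.loc[sid].to_numpy(dtype=float) if cov is not None else np.empty(0)
        histories.append(SubjectHistory(subject_id=sid, visits=times, delta=delta,
                                        interval_left=left, interval_right=right,
                                        covariates=z))
    return histories


def write_cohort(cohort: SimulatedCohort, directory) -> Path:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    visits, subjects = cohort_to_frames(cohort)
    visits.to_csv(directory / "visits.csv", index=False, float_format="%.17g")
    subjects.to_csv(directory / "subjects.csv", index=False, float_format="%.17g")
    meta = {"dgp": cohort.dgp.to_dict(), "design": cohort.design.to_dict(),
            "seed": cohort.seed, "n": cohort.n}
    (directory / "cohort.json").write_text(json.dumps(meta, indent=2))
    return directory


def read_cohort(directory) -> SimulatedCohort:
    directory = Path(directory)
    visits = pd.read_csv(directory / "visits.csv", float_precision="round_trip")
    subjects = pd.read_csv(directory / "subjects.csv", float_precision="round_trip")
    meta = json.loads((directory / "cohort.json").read_text())
    cov_cols = [c for c in subjects.columns if c.startswith("z")]
    histories = histories_from_frames(visits, subjects, cov_cols)
    order = {h.subject_id: h for h in histories}
    histories = [order[sid] for sid in subjects["subject_id"]]
    return SimulatedCohort(
        histories=histories,
        latent_x=subjects["latent_x"].to_numpy(dtype=float),
        latent_t=subjects["latent_t"].to_numpy(dtype=float),
        dgp=ThreeStateSpec.from_dict(meta["dgp"]),
        design=VisitDesign.from_dict(meta["design"]),
        seed=meta["seed"])


def apply_reference_age(visits: pd.DataFrame, reference_age: float):
    """Shift visit ages so the assumed healthy-at ``reference_age`` becomes
    process time 0.

    Returns ``(shifted, report)``: subjects with any visit at or before the
    reference age are dropped and listed in the report.  The shift is
    recorded in ``shifted.attrs["reference_age"]`` for back-transforming CIF
    time axes (add the reference age back to fitted quantiles).
    """
    bad = visits.loc[visits["visit_time"] <= reference_age, "subject_id"].unique()
    report = {"reference_age": reference_age,
              "n_rejected": len(bad), "rejected_subjects": list(bad)}
    keep = ~visits["subject_id"].isin(bad)
    shifted = visits.loc[keep].copy()
    shifted["visit_time"] = shifted["visit_time"] - reference_age
    shifted.attrs["reference_age"] = reference_age
    return shifted, report


@dataclass
class StudyConfig:
    """Serializable description of a full simulation study run."""

    dgp: dict = field(default_factory=lambda: {"family": "weibull", "p": 0})
    cells: list = field(default_factory=list)
    methods: list = field(default_factory=lambda: ["exp-ml", "weibull-ml"])
    design: dict = field(default_factory=dict)
    priors: dict = field(default_factory=dict)
    estimator_options: dict = field(default_factory=dict)
    seed: int = 0
    out_dir: str = "study_out"

    def to_yaml(self, path):
        Path(path).write_text(yaml.safe_dump(self.__dict__, sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        data = yaml.safe_load(Path(path).read_text())
        return cls(**data)

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.__dict__, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


def write_manifest(directory, config=None, seed=None, extra=None) -> Path:
    """Reproducibility manifest: config hash, seed, package version."""
    from . import __version__

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest = {"package": "tristate", "version": __version__, "seed": seed}
    if config is not None:
        manifest["config_digest"] = config.digest()
        manifest["config"] = config.__dict__
    if extra:
        manifest.update(extra)
    path = directory / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, default=str))
    return path
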