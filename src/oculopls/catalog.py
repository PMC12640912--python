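"""Registry of oculomotor parameters and the eye-tracking task each belongs to.

Five standard tasks are covered: fixation, pro-saccade, anti-saccade,
smooth pursuit and optokinetic nystagmus (OKN). The default catalog holds
199 parameters, the size of the feature space the analysis pipeline screens.
Column names follow a ``<TASKPREFIX>_<metric>`` convention so catalogs can be
inferred from a cohort header when no sidecar catalog file is supplied.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import pandas as pd

TASKS = ("fixation", "pro_saccade", "anti_saccade", "smooth_pursuit", "okn")

#: header-prefix naming convention used when inferring a catalog
TASK_PREFIXES = {
    "FIX_": "fixation",
    "PS_": "pro_saccade",
    "AS_": "anti_saccade",
    "SP_": "smooth_pursuit",
    "OKN_": "okn",
}

_PREFIX_OF_TASK = {task: prefix for prefix, task in TASK_PREFIXES.items()}

# Metric stems per task; crossed with summary-statistic suffixes to build
# parameter names. The per-task totals below sum to 199.
_STEMS = {
    "fixation": [
        "bcea_68", "bcea_95", "gaze_dispersion", "drift_velocity",
        "microsaccade_rate", "microsaccade_amplitude", "intrusion_rate",
        "blink_rate", "stability_index", "slow_drift_amplitude",
    ],
    "pro_saccade": [
        "latency", "peak_velocity", "mean_velocity", "gain", "duration",
        "endpoint_error", "undershoot_rate", "multistep_rate",
        "velocity_asymmetry", "peak_acceleration", "deceleration_time",
        "express_rate", "q_ratio", "curvature", "direction_error_rate",
    ],
    "anti_saccade": [
        "latency", "error_rate", "correction_latency", "peak_velocity",
        "gain", "duration", "endpoint_error", "corrected_error_rate",
        "express_rate", "velocity_asymmetry", "antisaccade_cost",
        "amplitude", "direction_cost",
    ],
    "smooth_pursuit": [
        "gain", "catchup_saccade_rate", "catchup_amplitude", "rmse",
        "phase_lag", "velocity_error", "saccade_proportion",
        "anticipatory_rate", "latency",
    ],
    "okn": [
        "slow_phase_velocity", "fast_phase_rate", "fast_phase_amplitude",
        "gain", "asymmetry_index", "beat_frequency",
    ],
}

_SUFFIXES = ("mean", "sd", "median", "cv")

#: per-task parameter counts of the default catalog (totals 199)
DEFAULT_TASK_COUNTS = {
    "fixation": 30,
    "pro_saccade": 60,
    "anti_saccade": 50,
    "smooth_pursuit": 35,
    "okn": 24,
}


@dataclass(frozen=True)
class ParameterCatalog:
    """Ordered mapping parameter name -> oculomotor task."""

    names: tuple[str, ...]
    tasks: tuple[str, ...] = field(repr=False)

    def __post_init__(self) -> None:
        if len(self.names) != len(self.tasks):
            raise ValueError("names and tasks must have equal length")
        if len(set(self.names)) != len(self.names):
            raise ValueError("parameter names must be unique")
        unknown = set(self.tasks) - set(TASKS)
        if unknown:
            raise ValueError(f"unknown tasks: {sorted(unknown)}")

    def __len__(self) -> int:
        return len(self.names)

    def __contains__(self, name: str) -> bool:
        return name in self.task_of

    @property
    def task_of(self) -> dict[str, str]:
        return dict(zip(self.names, self.tasks))

    def parameters_for(self, task: str) -> list[str]:
        return [n for n, t in zip(self.names, self.tasks) if t == task]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"parameter": self.names, "task": self.tasks})

    def write_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_pairs(cls, pairs) -> "ParameterCatalog":
        names, tasks = zip(*pairs) if pairs else ((), ())
        return cls(tuple(names), tuple(tasks))

    @classmethod
    def read_csv(cls, path) -> "ParameterCatalog":
        frame = pd.read_csv(path, dtype=str)
        missing = {"parameter", "task"} - set(frame.columns)
        if missing:
            raise ValueError(f"catalog file lacks columns: {sorted(missing)}")
        return cls(tuple(frame["parameter"]), tuple(frame["task"]))

    @classmethod
    def from_columns(cls, columns) -> "ParameterCatalog":
        """Infer a catalog from column names via the task-prefix convention."""
        pairs = []
        for col in columns:
            for prefix, task in TASK_PREFIXES.items():
                if col.startswith(prefix):
                    pairs.append((col, task))
                    break
            else:
                raise ValueError(
                    f"column {col!r} has no recognized task prefix "
                    f"({', '.join(TASK_PREFIXES)})"
                )
        return cls.from_pairs(pairs)


def make_catalog(task_counts: dict[str, int]) -> ParameterCatalog:
    """Build a catalog with the given number of parameters per task."""
    pairs = []
    for task in TASKS:
        count = int(task_counts.get(task, 0))
        prefix = _PREFIX_OF_TASK[task]
        names = [
            f"{prefix}{stem}_{suffix}"
            for stem, suffix in itertools.product(_STEMS[task], _SUFFIXES)
        ]
        # numbered spillover if more parameters are requested than named combos
        names += [f"{prefix}extra_{i:03d}" for i in range(max(0, count - len(names)))]
        pairs.extend((name, task) for name in names[:count])
    return ParameterCatalog.from_pairs(pairs)


def default_catalog() -> ParameterCatalog:
    """The 199-parameter catalog spanning all five oculomotor tasks."""
    catalog = make_catalog(DEFAULT_TASK_COUNTS)
    assert len(catalog) == 199
    return catalog
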