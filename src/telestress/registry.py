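"""Weekly feature registry.

The registry is the single source of truth for which weekly features the
pipeline computes, in which order, from which daily/weekly source variable,
and under which reporting category (sleep / activity / work / questionnaire).
The default registry has exactly 50 entries spanning every collected stream;
it can be replaced wholesale from a YAML file.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator

import yaml

from .errors import ConfigurationError

#: Aggregations that map a week of daily values (or weekly series) to one number.
AGGREGATIONS = (
    "weekly_mean",       # mean over present daily values (missing iff 0 present)
    "weekly_sd",         # unbiased SD over present daily values (missing iff <2 present)
    "weekly_count",      # weekly count/ratio variables (worked days, outings, ...)
    "weekly_sum",        # sum over present daily values (missing iff 0 present)
    "baseline_deviation",  # |weekly mean - participant's all-week baseline mean|
    "weekly_delta",      # week-over-week change of a weekly base feature
)

CATEGORIES = ("sleep", "activity", "work", "questionnaire")


@dataclass(frozen=True)
class RegistryEntry:
    name: str
    source: str
    aggregation: str
    category: str

    def __post_init__(self) -> None:
        if self.aggregation not in AGGREGATIONS:
            raise ConfigurationError(
                f"unknown aggregation {self.aggregation!r} for feature {self.name!r}"
            )
        if self.category not in CATEGORIES:
            raise ConfigurationError(
                f"unknown category {self.category!r} for feature {self.name!r}"
            )


class FeatureRegistry:
    """Ordered, name-unique collection of :class:`RegistryEntry`."""

    def __init__(self, entries: Iterable[RegistryEntry]):
        self.entries: list[RegistryEntry] = list(entries)
        names = [e.name for e in self.entries]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise ConfigurationError(f"duplicate feature names in registry: {dupes}")
        self._by_name = {e.name: e for e in self.entries}

    @property
    def names(self) -> list[str]:
        return [e.name for e in self.entries]

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self) -> Iterator[RegistryEntry]:
        return iter(self.entries)

    def __contains__(self, name: str) -> bool:
        return name in self._by_name

    def __getitem__(self, name: str) -> RegistryEntry:
        try:
            return self._by_name[name]
        except KeyError:
            raise ConfigurationError(f"unknown feature {name!r}") from None

    def category_of(self, name: str) -> str:
        return self[name].category

    @classmethod
    def from_yaml(cls, path) -> "FeatureRegistry":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(RegistryEntry(**row) for row in raw)

    def to_yaml(self, path) -> None:
        rows = [
            {"name": e.name, "source": e.source,
             "aggregation": e.aggregation, "category": e.category}
            for e in self.entries
        ]
        with open(path, "w") as fh:
            yaml.safe_dump(rows, fh, sort_keys=False)


# Daily source variables and their categories.
_MEAN_SD_SOURCES = [
    ("sleep_duration", "sleep"),
    ("sleep_efficiency", "sleep"),
    ("sleep_start", "sleep"),
    ("sleep_end", "sleep"),
    ("steps", "activity"),
    ("distance", "activity"),
    ("floors", "activity"),
    ("calories", "activity"),
    ("hr_mean", "activity"),
    ("hr_sd", "activity"),
    ("working_hours", "work"),
    ("work_start", "work"),
    ("work_end", "work"),
    ("working_hour_gap", "work"),
    ("scheduled_hours", "work"),
]

_COUNT_SOURCES = [
    ("worked_days", "work"),
    ("wfh_days", "work"),
    ("absence_days", "work"),
    ("telework_rate_week", "work"),
    ("outings", "questionnaire"),
    ("lunches_skipped", "questionnaire"),
]

_SUM_SOURCES = [
    ("steps", "activity"),
    ("distance", "activity"),
    ("floors", "activity"),
    ("calories", "activity"),
]

_BASELINE_DEV_SOURCES = [
    ("hr_mean_mean", "activity"),
    ("calories_mean", "activity"),
    ("sleep_duration_mean", "sleep"),
    ("work_start_mean", "work"),
    ("steps_mean", "activity"),
]

_DELTA_SOURCES = [
    ("sleep_duration_mean", "sleep"),
    ("steps_sum", "activity"),
    ("hr_mean_mean", "activity"),
    ("working_hours_mean", "work"),
    ("k6_total", "questionnaire"),
]


def default_registry(include_prior_k6: bool = True) -> FeatureRegistry:
    """The default 50-feature registry.

    Weekly mean and unbiased SD of 15 daily variables (30), six weekly
    count/ratio variables, four weekly sums, five absolute deviations of a
    weekly mean from the participant's own study-long baseline, and five
    week-over-week changes.

    ``include_prior_k6=False`` drops the ``k6_total_delta`` predictor (the
    week-over-week change in the distress score itself), which uses the
    previous weeks' questionnaire answers and is therefore the one entry a
    user may consider too close to the label.
    """
    entries: list[RegistryEntry] = []
    for src, cat in _MEAN_SD_SOURCES:
        entries.append(RegistryEntry(f"{src}_mean", src, "weekly_mean", cat))
        entries.append(RegistryEntry(f"{src}_sd", src, "weekly_sd", cat))
    for src, cat in _COUNT_SOURCES:
        entries.append(RegistryEntry(src, src, "weekly_count", cat))
    for src, cat in _SUM_SOURCES:
        entries.append(RegistryEntry(f"{src}_sum", src, "weekly_sum", cat))
    for src, cat in _BASELINE_DEV_SOURCES:
        base = src.removesuffix("_mean")
        entries.append(RegistryEntry(f"{base}_baseline_dev", src, "baseline_deviation", cat))
    for src, cat in _DELTA_SOURCES:
        if src == "k6_total" and not include_prior_k6:
            continue
        entries.append(RegistryEntry(f"{src}_delta", src, "weekly_delta", cat))
    return FeatureRegistry(entries)
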