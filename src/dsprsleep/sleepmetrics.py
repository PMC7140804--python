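"""Sleep/activity phenotypes from minute-binned activity traces.

Sleep is defined as a run of at least 5 consecutive minutes with zero beam
breaks.  For each fly, each 24 h day, and each 12 h phase (light/dark) we
derive four quantities:

* **sleep time** — sleeping minutes in the phase (bouts spanning a phase
  boundary are split minute-wise, so a phase holds at most 720 min);
* **bout number** — sleep bouts assigned to the phase of their onset minute
  (``bout_phase_rule="onset"``, the default) or counted in every phase they
  touch (``"split"``);
* **mean bout length** — mean full length of the phase's bouts;
* **waking activity** — total beam breaks over the awake minutes of the
  phase.

Trait codes: ``LST/DST`` light/dark sleep time, ``LWA/DWA`` waking activity,
``LBN/DBN`` bout number, ``LBL/DBL`` bout length.  Per-fly values are
averaged over days, genotype means over flies; bout-length traits get a
log10 companion column used for mapping (their among-fly variance grows
with the mean).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

TRAITS = ("LST", "DST", "LWA", "DWA", "LBN", "DBN", "LBL", "DBL")
MINUTES_PER_DAY = 1440
MINUTES_PER_PHASE = 720


class SleepMetricsError(ValueError):
    pass


@dataclass(frozen=True)
class Photoperiod:
    """12h:12h light:dark cycle; phases are protocol-defined."""

    lights_on: str = "08:00"
    light_minutes: int = MINUTES_PER_PHASE

    @property
    def lights_on_minute(self) -> int:
        hh, mm = (int(x) for x in self.lights_on.split(":"))
        return hh * 60 + mm

    def is_light(self, minute_of_day: np.ndarray) -> np.ndarray:
        rel = (np.asarray(minute_of_day) - self.lights_on_minute) % MINUTES_PER_DAY
        return rel < self.light_minutes


@dataclass(frozen=True)
class SleepBout:
    """A maximal run of >= ``min_sleep`` zero-count minutes.

    ``start`` is the 0-based offset of the first sleeping minute within the
    trace; ``length`` is in minutes.
    """

    start: int
    length: int

    @property
    def stop(self) -> int:  # exclusive
        return self.start + self.length


def find_bouts(minute_counts: Sequence[int] | np.ndarray, min_sleep: int = 5) -> list[SleepBout]:
    """Maximal runs of consecutive zero-count minutes with length >= ``min_sleep``."""
    counts = np.asarray(minute_counts)
    if counts.size and counts.min() < 0:
        raise SleepMetricsError("negative activity counts")
    if min_sleep < 1:
        raise SleepMetricsError("min_sleep must be >= 1")
    zero = np.concatenate([[0], (counts == 0).astype(np.int8), [0]])
    d = np.diff(zero)
    starts = np.flatnonzero(d == 1)
    stops = np.flatnonzero(d == -1)
    return [
        SleepBout(int(s), int(e - s))
        for s, e in zip(starts, stops)
        if e - s >= min_sleep
    ]


def sleeping_mask(n: int, bouts: Sequence[SleepBout]) -> np.ndarray:
    mask = np.zeros(n, dtype=bool)
    for b in bouts:
        mask[b.start : b.stop] = True
    return mask


def phase_metrics(
    fly_trace: np.ndarray,
    photoperiod: Photoperiod = Photoperiod(),
    trace_start: str | None = None,
    bout_phase_rule: str = "onset",
    min_sleep: int = 5,
) -> pd.DataFrame:
    """Per-(day, phase) metrics for one fly.

    ``trace_start`` is the clock time of the first minute; by default the
    trace is assumed to begin at lights-on (the assay convention).  The
    trace length must be a whole number of days.
    """
    trace = np.asarray(fly_trace)
    t = len(trace)
    if t == 0 or t % MINUTES_PER_DAY:
        raise SleepMetricsError("trace length must be a positive multiple of 1440")
    if bout_phase_rule not in ("onset", "split"):
        raise SleepMetricsError(f"unknown bout_phase_rule {bout_phase_rule!r}")
    start_min = (
        photoperiod.lights_on_minute
        if trace_start is None
        else int(trace_start.split(":")[0]) * 60 + int(trace_start.split(":")[1])
    )
    minute_of_day = (start_min + np.arange(t)) % MINUTES_PER_DAY
    light = photoperiod.is_light(minute_of_day)
    day = np.arange(t) // MINUTES_PER_DAY

    bouts = find_bouts(trace, min_sleep=min_sleep)
    asleep = sleeping_mask(t, bouts)

    n_days = t // MINUTES_PER_DAY
    rows = []
    for d in range(n_days):
        for phase, sel_phase in (("light", light), ("dark", ~light)):
            sel = (day == d) & sel_phase
            sleep_min = int((asleep & sel).sum())
            waking = int(trace[~asleep & sel].sum())
            if bout_phase_rule == "onset":
                in_phase = [
                    b for b in bouts if sel[b.start]
                ]
            else:  # split: a bout counts in every (day, phase) cell it touches
                in_phase = [b for b in bouts if sel[b.start : b.stop].any()]
            rows.append(
                {
                    "day": d,
                    "phase": phase,
                    "sleep_min": sleep_min,
                    "bout_n": len(in_phase),
                    "mean_bout_len": (
                        float(np.mean([b.length for b in in_phase]))
                        if in_phase
                        else np.nan
                    ),
                    "waking_activity": waking,
                }
            )
    return pd.DataFrame(rows)


def fly_trait_values(per_day: pd.DataFrame) -> dict[str, float]:
    """Collapse one fly's per-(day, phase) metrics to the 8 traits (mean over
    days; bout length averaged over days with at least one bout)."""
    out = {}
    for code, phase, col in (
        ("LST", "light", "sleep_min"),
        ("DST", "dark", "sleep_min"),
        ("LWA", "light", "waking_activity"),
        ("DWA", "dark", "waking_activity"),
        ("LBN", "light", "bout_n"),
        ("DBN", "dark", "bout_n"),
        ("LBL", "light", "mean_bout_len"),
        ("DBL", "dark", "mean_bout_len"),
    ):
        vals = per_day.loc[per_day["phase"] == phase, col]
        out[code] = float(vals.mean()) if vals.notna().any() else np.nan
    return out


@dataclass
class PhenotypeTable:
    """Genotype means (long format) plus the per-fly records behind them."""

    genotype_means: pd.DataFrame  # genotype, subpop, trait, mean, n_flies
    per_fly: pd.DataFrame  # genotype, subpop, fly, trait, value

    @classmethod
    def from_per_fly(
        cls,
        per_fly: pd.DataFrame,
        transform_spec: Sequence[str] = ("LBL", "DBL"),
        log_offset: float | None = None,
    ) -> "PhenotypeTable":
        """Aggregate per-fly values to genotype means.

        Traits named in ``transform_spec`` additionally get a
        ``<trait>_log10`` companion row per genotype, computed on the
        genotype mean; a mean <= 0 is a hard error unless ``log_offset`` is
        provided (and added before the log).
        """
        required = {"genotype", "subpop", "fly", "trait", "value"}
        if missing := required - set(per_fly.columns):
            raise SleepMetricsError(f"per-fly table missing columns {sorted(missing)}")
        grouped = (
            per_fly.dropna(subset=["value"])
            .groupby(["genotype", "subpop", "trait"], sort=True, as_index=False)
            .agg(mean=("value", "mean"), n_flies=("value", "size"))
        )
        extra = []
        for trait in transform_spec:
            sub = grouped[grouped["trait"] == trait]
            if sub.empty:
                continue
            vals = sub["mean"].to_numpy(dtype=float)
            if log_offset is not None:
                vals = vals + log_offset
            if np.any(vals <= 0):
                raise SleepMetricsError(
                    f"log10 transform of {trait}: non-positive genotype mean "
                    "(pass log_offset to shift)"
                )
            ex = sub.copy()
            ex["trait"] = trait + "_log10"
            ex["mean"] = np.log10(vals)
            extra.append(ex)
        if extra:
            grouped = pd.concat([grouped] + extra, ignore_index=True)
        grouped = grouped.sort_values(["trait", "genotype"]).reset_index(drop=True)
        return cls(genotype_means=grouped, per_fly=per_fly.reset_index(drop=True))

    @property
    def traits(self) -> list[str]:
        return sorted(self.genotype_means["trait"].unique())

    def trait_means(self, trait: str) -> pd.Series:
        sub = self.genotype_means[self.genotype_means["trait"] == trait]
        if sub.empty:
            raise SleepMetricsError(f"no trait {trait!r} in table")
        return sub.set_index("genotype")["mean"]

    def subpop_of(self) -> pd.Series:
        return (
            self.genotype_means.groupby("genotype", sort=True)["subpop"].first()
        )

    def write_csv(self, path) -> Path:
        path = Path(path)
        self.genotype_means.to_csv(path, index=False, float_format="%.8g")
        return path

    @classmethod
    def read_csv(cls, means_path, per_fly_path=None) -> "PhenotypeTable":
        means = pd.read_csv(means_path)
        per_fly = (
            pd.read_csv(per_fly_path)
            if per_fly_path is not None
            else pd.DataFrame(columns=["genotype", "subpop", "fly", "trait", "value"])
        )
        return cls(genotype_means=means, per_fly=per_fly)


def aggregate(
    per_day_metrics: pd.DataFrame,
    transform_spec: Sequence[str] = ("LBL", "DBL"),
    log_offset: float | None = None,
) -> PhenotypeTable:
    """PhenotypeTable from a per-fly, per-day metrics table.

    Expects columns genotype, subpop, fly, day, phase, sleep_min, bout_n,
    mean_bout_len, waking_activity (the output of :func:`phase_metrics`
    annotated with fly identity).
    """
    rows = []
    for (genotype, subpop, fly), sub in per_day_metrics.groupby(
        ["genotype", "subpop", "fly"], sort=True
    ):
        for trait, value in fly_trait_values(sub).items():
            rows.append(
                {
                    "genotype": genotype,
                    "subpop": subpop,
                    "fly": fly,
                    "trait": trait,
                    "value": value,
                }
            )
    if not rows:
        raise SleepMetricsError("no per-day metrics to aggregate")
    return PhenotypeTable.from_per_fly(
        pd.DataFrame(rows), transform_spec=transform_spec, log_offset=log_offset
    )


def extract_from_dam(
    matrices: Sequence,
    channel_map,
    genotype_subpop: dict[str, int],
    photoperiod: Photoperiod = Photoperiod(),
    bout_phase_rule: str = "onset",
    min_sleep: int = 5,
    transform_spec: Sequence[str] = ("LBL", "DBL"),
    log_offset: float | None = None,
    drop_dead: bool = False,
) -> PhenotypeTable:
    """Run the extractor over clipped DAM matrices using a channel map.

    ``drop_dead`` excludes flies with zero activity over the final 24 h
    (off by default).
    """
    by_monitor = {m.monitor: m for m in matrices}
    rows = []
    for rec in channel_map.table.itertuples(index=False):
        matrix = by_monitor.get(rec.monitor)
        if matrix is None:
            raise SleepMetricsError(f"no DAM data for monitor {rec.monitor!r}")
        trace = matrix.channel(int(rec.channel))
        if drop_dead and trace[-MINUTES_PER_DAY:].sum() == 0:
            continue
        per_day = phase_metrics(
            trace,
            photoperiod=photoperiod,
            bout_phase_rule=bout_phase_rule,
            min_sleep=min_sleep,
        )
        per_day["genotype"] = rec.genotype
        per_day["subpop"] = genotype_subpop[rec.genotype]
        per_day["fly"] = rec.fly
        rows.append(per_day)
    if not rows:
        raise SleepMetricsError("no flies extracted")
    return aggregate(
        pd.concat(rows, ignore_index=True),
        transform_spec=transform_spec,
        log_offset=log_offset,
    )
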