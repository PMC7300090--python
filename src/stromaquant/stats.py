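"""Group statistics and report generation.

Parametric comparisons use Student's t-test for two groups and one-way ANOVA
with Tukey HSD post-hoc pairwise tests for three or more; non-parametric
distribution comparisons (in :mod:`stromaquant.fibers`) use the two-sample
Kolmogorov-Smirnov test.  Significance level alpha = 0.05; all p-values are
reported, never thresholded away.
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass, field
from typing import Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from stromaquant.errors import InsufficientDataError

__all__ = [
    "GroupSummary",
    "PairwiseResult",
    "StatResult",
    "MeanSem",
    "compare_groups",
    "mean_sem",
    "build_report",
]


@dataclass
class GroupSummary:
    label: str
    n: int
    mean: float
    sem: float


@dataclass
class PairwiseResult:
    group_a: str
    group_b: str
    mean_diff: float
    p_adj: float
    ci_lo: float
    ci_hi: float
    reject: bool


@dataclass
class StatResult:
    """Outcome of a hypothesis test with per-group summaries."""

    test: str
    groups: list[GroupSummary]
    statistic: float
    p_value: float
    pairwise: list[PairwiseResult] = field(default_factory=list)
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0 or np.isnan(self.p_value)):
            raise ValueError(f"p-value {self.p_value} outside [0, 1]")


class MeanSem(NamedTuple):
    mean: float
    sem: float
    n: int
    sem_defined: bool


def mean_sem(values: Sequence[float]) -> MeanSem:
    """Mean and standard error (sd with ddof=1 over sqrt(n)).

    A single value has an undefined SEM; it is reported as 0 with
    ``sem_defined=False`` so downstream plots can flag it.
    """
    arr = np.asarray(values, dtype=np.float64)
    if arr.size == 0:
        raise InsufficientDataError("mean_sem requires at least one value")
    if arr.size == 1:
        return MeanSem(float(arr[0]), 0.0, 1, False)
    sem = float(np.std(arr, ddof=1) / np.sqrt(arr.size))
    return MeanSem(float(arr.mean()), sem, int(arr.size), True)


def _summaries(groups: Mapping[str, Sequence[float]]) -> list[GroupSummary]:
    out = []
    for label, vals in groups.items():
        ms = mean_sem(vals)
        out.append(GroupSummary(label, ms.n, ms.mean, ms.sem))
    return out


def compare_groups(
    groups: Mapping[str, Sequence[float]],
    paired: bool = False,
    welch: bool = False,
) -> StatResult:
    """Compare named groups of measurements.

    Two groups are compared with Student's t-test (equal variances by
    default; ``welch=True`` switches to Welch's unequal-variance form,
    ``paired=True`` to the paired test).  Three or more groups use one-way
    ANOVA followed by Tukey HSD pairwise comparisons.
    """
    if len(groups) < 2:
        raise InsufficientDataError("compare_groups requires at least two groups")
    arrays = {k: np.asarray(v, dtype=np.float64) for k, v in groups.items()}
    for label, arr in arrays.items():
        if arr.size < 2:
            raise InsufficientDataError(
                f"group {label!r} has n={arr.size} < 2; cannot test"
            )
    labels = list(arrays)
    if len(labels) == 2:
        a, b = arrays[labels[0]], arrays[labels[1]]
        if paired:
            if a.size != b.size:
                raise InsufficientDataError("paired test requires equal group sizes")
            res = sps.ttest_rel(a, b)
            name = "paired t-test"
        else:
            res = sps.ttest_ind(a, b, equal_var=not welch)
            name = "Welch t-test" if welch else "Student t-test"
        return StatResult(name, _summaries(arrays), float(res.statistic), float(res.pvalue))
    f_res = sps.f_oneway(*arrays.values())
    values = np.concatenate(list(arrays.values()))
    tags = np.concatenate([[lab] * arrays[lab].size for lab in labels])
    tukey = pairwise_tukeyhsd(values, tags, alpha=0.05)
    pairwise = []
    for row in tukey.summary().data[1:]:
        g1, g2, meandiff, p_adj, lo, hi, reject = row
        pairwise.append(
            PairwiseResult(str(g1), str(g2), float(meandiff), float(p_adj),
                           float(lo), float(hi), bool(reject))
        )
    return StatResult(
        "one-way ANOVA + Tukey HSD",
        _summaries(arrays),
        float(f_res.statistic),
        float(f_res.pvalue),
        pairwise=pairwise,
    )


# ---------------------------------------------------------------------------
# report generation


def _to_jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _to_jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, dict):
        return {str(k): _to_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_jsonable(v) for v in obj]
    if isinstance(obj, pd.DataFrame):
        return obj.to_dict(orient="records")
    return obj


def _flatten(obj, prefix=""):
    out = {}
    plain = _to_jsonable(obj)
    if isinstance(plain, dict):
        for k, v in plain.items():
            out.update(_flatten(v, f"{prefix}{k}." if prefix else f"{k}."))
    elif isinstance(plain, list):
        out[prefix.rstrip(".")] = json.dumps(plain)
    else:
        out[prefix.rstrip(".")] = plain
    return out


def build_report(
    results: Mapping[str, object],
    out_dir: str | os.PathLike,
    plots: bool = False,
) -> list[str]:
    """Write one JSON and one CSV per analysis under ``out_dir``.

    ``results`` maps analysis names (e.g. ``"fibers"``, ``"hue"``) to result
    objects (dataclasses, DataFrames, dicts).  Regenerating on the same
    inputs produces byte-identical files.  With ``plots=True`` a bar chart
    of every scalar result is written per analysis.
    """
    out_dir = os.fspath(out_dir)
    os.makedirs(out_dir, exist_ok=True)
    written: list[str] = []
    for name in sorted(results):
        obj = results[name]
        json_path = os.path.join(out_dir, f"{name}.json")
        with open(json_path, "w") as fh:
            json.dump(_to_jsonable(obj), fh, indent=2, sort_keys=True)
            fh.write("\n")
        written.append(json_path)
        csv_path = os.path.join(out_dir, f"{name}.csv")
        if isinstance(obj, pd.DataFrame):
            obj.to_csv(csv_path, index=False, float_format="%.8g", lineterminator="\n")
        else:
            flat = _flatten(obj)
            pd.DataFrame([flat]).to_csv(
                csv_path, index=False, float_format="%.8g", lineterminator="\n"
            )
        written.append(csv_path)
        if plots:
            written.append(_plot_scalars(name, obj, out_dir))
    return written


def _plot_scalars(name: str, obj, out_dir: str) -> str:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    flat = _flatten(obj)
    scalars = {k: v for k, v in flat.items() if isinstance(v, (int, float))}
    fig, ax = plt.subplots(figsize=(max(4, 0.5 * len(scalars)), 3.5))
    if scalars:
        ax.bar(range(len(scalars)), list(scalars.values()))
        ax.set_xticks(range(len(scalars)))
        ax.set_xticklabels(list(scalars), rotation=90, fontsize=6)
    ax.set_title(name)
    fig.tight_layout()
    path = os.path.join(out_dir, f"{name}.png")
    fig.savefig(path, dpi=100)
    plt.close(fig)
    return path
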