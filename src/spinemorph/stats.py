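"""Group-comparison statistics for the two study designs.

Two designs are supported, mirroring how such immobilisation experiments
are analysed:

* ``critical_timings`` — all groups harvested at the same stage; a single
  pooled control is compared against each immobilised group with a one-way
  ANOVA followed by Tukey's HSD post-hoc test, separately at every vertebral
  location (or metric).
* ``ontogenetic`` — one immobilised group followed over stages; at each
  stage and location the immobilised group is compared to its age-matched
  control with a two-tailed unpaired (pooled-variance Student) t-test.

Significance is flagged at alpha = 0.05 with no correction across
locations: per-location inference is reported as-is, which the caller must
keep in mind when reading a profile of p-values.
"""

from __future__ import annotations

import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "ALPHA",
    "one_way_anova",
    "tukey_hsd",
    "t_test_unpaired",
    "per_location_comparison",
    "pooled_control_anova",
]

ALPHA = 0.05


def _clean_groups(samples: Mapping[str, Sequence[float]]) -> dict[str, np.ndarray]:
    usable: dict[str, np.ndarray] = {}
    for name, values in samples.items():
        arr = np.asarray(values, dtype=float)
        arr = arr[~np.isnan(arr)]
        if arr.size < 2:
            warnings.warn(f"group {name!r} has < 2 values, excluded", stacklevel=3)
            continue
        usable[name] = arr
    return usable


def one_way_anova(samples: Mapping[str, Sequence[float]]) -> tuple[float, float]:
    """Classical one-way ANOVA F statistic and p-value across named groups.

    Groups with fewer than two values are excluded with a warning. Fully
    degenerate input (no variance between or within groups) returns
    F = 0, p = 1.
    """
    groups = _clean_groups(samples)
    if len(groups) < 2:
        raise ValueError("insufficient groups: ANOVA needs >= 2 groups with >= 2 values")
    arrays = list(groups.values())
    grand = np.concatenate(arrays)
    if np.ptp(grand) == 0.0:
        return 0.0, 1.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        f_stat, p = sps.f_oneway(*arrays)
    if np.isnan(f_stat):  # zero within-group variance, unequal means
        return float("inf"), 0.0
    return float(f_stat), float(p)


def tukey_hsd(samples: Mapping[str, Sequence[float]]) -> pd.DataFrame:
    """Tukey HSD pairwise comparisons (studentized-range family at 0.05).

    Returns one row per unordered pair with the mean difference statistic and
    the family-wise adjusted p-value. With exactly two groups this reduces to
    the pooled-variance t-test.
    """
    groups = _clean_groups(samples)
    if len(groups) < 2:
        raise ValueError("insufficient groups: Tukey needs >= 2 groups with >= 2 values")
    names = list(groups)
    arrays = [groups[n] for n in names]
    if np.ptp(np.concatenate(arrays)) == 0.0:
        rows = [
            {"group_a": names[i], "group_b": names[j], "statistic": 0.0, "p_adj": 1.0}
            for i in range(len(names))
            for j in range(i + 1, len(names))
        ]
        return pd.DataFrame(rows)
    res = sps.tukey_hsd(*arrays)
    rows = []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            rows.append(
                {
                    "group_a": names[i],
                    "group_b": names[j],
                    "statistic": float(res.statistic[i, j]),
                    "p_adj": float(res.pvalue[i, j]),
                }
            )
    return pd.DataFrame(rows)


def t_test_unpaired(a: Sequence[float], b: Sequence[float]) -> tuple[float, float]:
    """Two-tailed unpaired Student t-test (pooled variance).

    Zero pooled variance is handled explicitly: equal means give p = 1,
    unequal means give p = 0 with a warning.
    """
    xa = np.asarray(a, dtype=float)
    xb = np.asarray(b, dtype=float)
    xa, xb = xa[~np.isnan(xa)], xb[~np.isnan(xb)]
    if xa.size < 2 or xb.size < 2:
        raise ValueError("each sample needs >= 2 values")
    if np.ptp(xa) == 0.0 and np.ptp(xb) == 0.0:
        if xa.mean() == xb.mean():
            return 0.0, 1.0
        warnings.warn("zero pooled variance with unequal means; p = 0", stacklevel=2)
        return float("inf") if xa.mean() > xb.mean() else float("-inf"), 0.0
    t, p = sps.ttest_ind(xa, xb, equal_var=True)
    return float(t), float(p)


def _location_values(frame: pd.DataFrame, mask, location: str) -> np.ndarray:
    vals = frame.loc[mask & (frame["label"] == location), "value"]
    return vals.to_numpy(dtype=float)


def per_location_comparison(
    profiles: pd.DataFrame,
    design: str,
    control_group: str = "control",
    alpha: float = ALPHA,
) -> pd.DataFrame:
    """Compare groups at every vertebral location (or metric name).

    ``profiles`` is long-format with columns ``specimen_id, group, stage,
    label, value``. For ``critical_timings``, an ANOVA + Tukey is run per
    label across the pooled control and every immobilised group (all
    harvested at one stage); pairwise rows against the control are emitted.
    For ``ontogenetic``, a per-label t-test is run between the immobilised
    group and the age-matched control at each stage.

    Locations where more than half the specimens of either group carry no
    value are skipped with a warning.
    """
    required = {"specimen_id", "group", "stage", "label", "value"}
    if not required.issubset(profiles.columns):
        raise ValueError(f"profiles frame needs columns {sorted(required)}")
    if design not in ("critical_timings", "ontogenetic"):
        raise ValueError(f"unknown design {design!r}")
    rows: list[dict] = []

    def _usable(mask, label) -> bool:
        sub = profiles[mask]
        n_spec = sub["specimen_id"].nunique()
        n_val = sub[(sub["label"] == label) & sub["value"].notna()]["specimen_id"].nunique()
        return n_spec > 0 and n_val >= 0.5 * n_spec

    labels = list(dict.fromkeys(profiles["label"]))
    if design == "critical_timings":
        treat_groups = [g for g in dict.fromkeys(profiles["group"]) if g != control_group]
        for label in labels:
            masks = {control_group: profiles["group"] == control_group}
            masks.update({g: profiles["group"] == g for g in treat_groups})
            skipped = [g for g, m in masks.items() if not _usable(m, label)]
            if skipped:
                warnings.warn(f"location {label} skipped: sparse in {skipped}", stacklevel=2)
                continue
            samples = {g: _location_values(profiles, m, label) for g, m in masks.items()}
            try:
                f_stat, p = one_way_anova(samples)
                pairs = tukey_hsd(samples)
            except ValueError as err:
                warnings.warn(f"location {label} skipped: {err}", stacklevel=2)
                continue
            rows.append(
                {
                    "location": label,
                    "stage": None,
                    "test": "anova",
                    "comparison": "omnibus",
                    "statistic": f_stat,
                    "p_value": p,
                    "significant": p < alpha,
                }
            )
            for _, pr in pairs.iterrows():
                if control_group not in (pr["group_a"], pr["group_b"]):
                    continue
                other = pr["group_b"] if pr["group_a"] == control_group else pr["group_a"]
                rows.append(
                    {
                        "location": label,
                        "stage": None,
                        "test": "tukey",
                        "comparison": f"{control_group}|{other}",
                        "statistic": pr["statistic"],
                        "p_value": pr["p_adj"],
                        "significant": pr["p_adj"] < alpha,
                    }
                )
    else:  # ontogenetic
        treat_groups = [g for g in dict.fromkeys(profiles["group"]) if g != control_group]
        for stage in sorted(profiles["stage"].unique()):
            ctl_mask = (profiles["group"] == control_group) & (profiles["stage"] == stage)
            for group in treat_groups:
                im_mask = (profiles["group"] == group) & (profiles["stage"] == stage)
                if not im_mask.any() or not ctl_mask.any():
                    continue
                for label in labels:
                    if not (_usable(ctl_mask, label) and _usable(im_mask, label)):
                        warnings.warn(
                            f"location {label} at E{stage} skipped: sparse", stacklevel=2
                        )
                        continue
                    a = _location_values(profiles, im_mask, label)
                    b = _location_values(profiles, ctl_mask, label)
                    try:
                        t, p = t_test_unpaired(a, b)
                    except ValueError as err:
                        warnings.warn(
                            f"location {label} at E{stage} skipped: {err}", stacklevel=2
                        )
                        continue
                    rows.append(
                        {
                            "location": label,
                            "stage": stage,
                            "test": "t_test",
                            "comparison": f"{control_group}|{group}",
                            "statistic": t,
                            "p_value": p,
                            "significant": p < alpha,
                        }
                    )
    return pd.DataFrame(
        rows,
        columns=["location", "stage", "test", "comparison", "statistic", "p_value", "significant"],
    )


def pooled_control_anova(
    profiles: pd.DataFrame, day_col: str = "treatment_day"
) -> pd.DataFrame:
    """Descriptive per-location ANOVA across control treatment-day subgroups.

    Supports the decision to pool controls treated on different days into a
    single group: a profile of non-significant F tests across the subgroups
    is the expected outcome. Descriptive only — no equivalence test is made.
    """
    if day_col not in profiles.columns:
        raise ValueError(f"profiles frame needs a {day_col!r} column")
    rows = []
    for label in dict.fromkeys(profiles["label"]):
        sub = profiles[profiles["label"] == label]
        samples = {
            str(day): grp["value"].to_numpy(dtype=float)
            for day, grp in sub.groupby(day_col)
        }
        try:
            f_stat, p = one_way_anova(samples)
        except ValueError:
            continue
        rows.append({"location": label, "statistic": f_stat, "p_value": p})
    return pd.DataFrame(rows, columns=["location", "statistic", "p_value"])
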