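"""Hemispheric laterality of the task-evoked HbO2 response.

LI = (L - R) / (L + R), where L and R are the mean band-passed HbO2
concentration changes over the left and right channels of a region
(prefrontal or motor) during the 60 s task window.  LI >= 0.1 is
left-lateralized, LI <= -0.1 right-lateralized, anything between is
symmetric.  Subjects whose denominator is near zero or negative are
recorded as undefined and excluded from group statistics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._groupcompare import omnibus_with_posthoc
from .clinstats import fdr_bh
from .preprocess import HemoglobinSeries
from .probe import GROUPS, ProbeLayout, TaskParadigm, extract_task_window

REGIONS = ("prefrontal", "motor")
CLASSES = ("left", "right", "symmetric", "undefined")


def laterality_index(L: float, R: float, floor: float = 1e-3) -> float:
    """LI = (L - R)/(L + R); NaN (undefined) when L + R <= floor.

    A negative or near-zero denominator would flip or explode the sign, so
    such records are flagged undefined rather than misclassified.
    """
    denom = L + R
    if denom <= floor:
        return math.nan
    return (L - R) / denom


def classify_li(li: float, threshold: float = 0.1) -> str:
    """left if LI >= threshold, right if LI <= -threshold, else symmetric;
    NaN maps to undefined."""
    if not np.isfinite(li):
        return "undefined"
    if li >= threshold:
        return "left"
    if li <= -threshold:
        return "right"
    return "symmetric"


@dataclass(frozen=True)
class LateralityRecord:
    subject_id: str
    group: str
    region: str
    L_hbo2: float
    R_hbo2: float
    li: float
    classification: str


def compute_laterality(
    hemo: HemoglobinSeries,
    layout: ProbeLayout,
    paradigm: TaskParadigm,
    subject_id: str,
    group: str,
    li_threshold: float = 0.1,
    floor: float = 1e-3,
) -> list[LateralityRecord]:
    """Per-region laterality records for one subject from processed HbO2."""
    task = extract_task_window(hemo.hbo2, paradigm, axis=-1)
    records = []
    for region in REGIONS:
        left = layout.region_indices(region, "left")
        right = layout.region_indices(region, "right")
        L = float(task[left].mean())
        R = float(task[right].mean())
        li = laterality_index(L, R, floor=floor)
        records.append(
            LateralityRecord(
                subject_id=subject_id,
                group=group,
                region=region,
                L_hbo2=L,
                R_hbo2=R,
                li=li,
                classification=classify_li(li, li_threshold),
            )
        )
    return records


def records_to_frame(records: list[LateralityRecord]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in records])


def lateralization_ratio(records: pd.DataFrame) -> pd.DataFrame:
    """Proportions of left/right/symmetric subjects per group and region.

    Undefined records are excluded from the denominator; their count is
    reported.  Proportions sum to 1 over classified subjects.
    """
    rows = []
    for (group, region), sub in records.groupby(["group", "region"], sort=True):
        classified = sub[sub["classification"] != "undefined"]
        n = len(classified)
        n_undef = len(sub) - n
        if n == 0:
            raise ValueError(f"all records undefined for {group}/{region}")
        counts = classified["classification"].value_counts()
        rows.append(
            {
                "group": group,
                "region": region,
                "left": counts.get("left", 0) / n,
                "right": counts.get("right", 0) / n,
                "symmetric": counts.get("symmetric", 0) / n,
                "n_classified": n,
                "n_undefined": n_undef,
            }
        )
    return pd.DataFrame(rows)


def group_li_compare(records: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Per-region one-way ANOVA of LI across groups, with Welch post hoc.

    The two omnibus p-values (prefrontal, motor) form the FDR family;
    post hoc contrasts are FDR-corrected within region.
    """
    rows = []
    for region in REGIONS:
        sub = records[(records["region"] == region) & np.isfinite(records["li"])]
        groups = {
            g: sub.loc[sub["group"] == g, "li"].to_numpy()[:, None]
            for g in GROUPS
            if (sub["group"] == g).sum() >= 2
        }
        if len(groups) < 2:
            raise ValueError(f"insufficient defined LI data in region {region!r}")
        res = omnibus_with_posthoc(groups, alpha=alpha)
        row = {"region": region, "F": float(res["F"][0]), "p": float(res["p"][0])}
        for pair in res["posthoc_p"]:
            row[f"p_{pair[0]}_vs_{pair[1]}"] = float(res["posthoc_p"][pair][0])
        rows.append(row)
    out = pd.DataFrame(rows)
    q, reject = fdr_bh(out["p"].to_numpy(), alpha)
    out["q"] = q
    out["significant"] = reject
    return out
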