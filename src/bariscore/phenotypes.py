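"""Weight-response phenotype derivation.

From each patient's weight trajectory we derive the nadir (lowest
postoperative weight, earliest year on ties), percent total weight loss
(%TWL), percent excess weight loss (%EWL, excess relative to the weight at
BMI 25 kg/m^2) and weight regain as a percent of maximum weight lost
(%WR), both at the nadir and at the end of follow-up (year 6 by default,
taken from the closest visit within a window). Patients who cannot
contribute a phenotype are flagged with an explicit exclusion reason rather
than silently dropped.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import InsufficientDataError, InvalidArgumentError
from .simulate import WeightTrajectory, trajectories_to_frame

IDEAL_BMI = 25.0

EXCL_NO_BASELINE = "no year-0 weight"
EXCL_NO_POSTOP = "no postoperative weight"
EXCL_NO_WINDOW = "no follow-up weight in window"


def find_nadir(trajectory: WeightTrajectory) -> tuple[float, int]:
    """Lowest postoperative weight and its visit year (earliest on ties)."""
    post = trajectory.years >= 1
    if not np.any(post):
        raise InsufficientDataError(
            f"{trajectory.patient_id}: no postoperative weight record"
        )
    years = trajectory.years[post]
    weights = trajectory.weights[post]
    order = np.lexsort((years, weights))  # weight first, year breaks ties
    i = order[0]
    return float(weights[i]), int(years[i])


def compute_weight_metrics(
    w0: float, wt: float, nadir: float, height: float
) -> tuple[float, float, float]:
    """(%TWL, %EWL, %WR) for a weight ``wt`` given baseline, nadir and height.

    %TWL = 100 (w0 - wt) / w0
    %EWL = 100 (w0 - wt) / (w0 - 25 h^2)
    %WR  = 100 (wt - nadir) / (w0 - nadir)
    """
    if w0 <= 0 or height <= 0:
        raise InvalidArgumentError("w0 and height must be positive")
    ideal = IDEAL_BMI * height * height
    twl = 100.0 * (w0 - wt) / w0
    if w0 <= ideal:
        raise InvalidArgumentError(
            f"baseline weight {w0:.1f} kg not above ideal weight {ideal:.1f} kg; %EWL undefined"
        )
    ewl = 100.0 * (w0 - wt) / (w0 - ideal)
    if w0 == nadir:
        raise InvalidArgumentError("baseline equals nadir weight; %WR undefined")
    wr = 100.0 * (wt - nadir) / (w0 - nadir)
    return twl, ewl, wr


def _followup_visit(
    years: np.ndarray, weights: np.ndarray, followup_year: int, window: float
) -> tuple[float, int] | None:
    """Weight at the visit closest to ``followup_year`` within the window.

    Ties in distance go to the later visit.
    """
    in_win = (years >= 1) & (np.abs(years - followup_year) <= window)
    if not np.any(in_win):
        return None
    ys = years[in_win]
    ws = weights[in_win]
    # sort by (distance, -year): later visit wins distance ties
    order = np.lexsort((-ys, np.abs(ys - followup_year)))
    i = order[0]
    return float(ws[i]), int(ys[i])


def derive_phenotype_table(
    trajectories: list[WeightTrajectory] | pd.DataFrame,
    covariates: pd.DataFrame,
    followup_year: int = 6,
    window: float = 1.0,
) -> pd.DataFrame:
    """Per-patient phenotype table indexed by patient id.

    Nadir phenotypes are computed from all postoperative visits; end-of-
    follow-up phenotypes from the visit closest to ``followup_year`` within
    ``+/- window`` years (missing-window patients keep their nadir
    phenotypes and get NaN year-6 columns). Binary codings use strict
    inequalities: ``ewl6y_gt50 = ewl_6y > 50`` and ``wr_gt20 = wr_mwl > 20``.
    """
    if isinstance(trajectories, pd.DataFrame):
        frame = trajectories
    else:
        frame = trajectories_to_frame(trajectories)
    frame = frame.sort_values(["patient_id", "visit_year"])

    rows = []
    grouped = dict(tuple(frame.groupby("patient_id", sort=False)))
    for pid in covariates.index:
        height = float(covariates.loc[pid, "height"])
        rec: dict[str, object] = {"patient_id": pid}
        grp = grouped.get(pid)
        years = grp["visit_year"].to_numpy() if grp is not None else np.empty(0, int)
        weights = grp["weight_kg"].to_numpy() if grp is not None else np.empty(0)

        base = years == 0
        if not np.any(base):
            rec.update(_empty_metrics(), included=False, exclusion_reason=EXCL_NO_BASELINE)
            rows.append(rec)
            continue
        w0 = float(weights[base][0])
        rec["w0"] = w0
        if not np.any(years >= 1):
            rec.update(_empty_metrics(skip=("w0",)), included=False,
                       exclusion_reason=EXCL_NO_POSTOP)
            rows.append(rec)
            continue

        traj = WeightTrajectory(patient_id=str(pid), years=years, weights=weights)
        nadir_w, nadir_y = find_nadir(traj)
        ideal = IDEAL_BMI * height * height
        excess = w0 - ideal  # may be <= 0 on degenerate data; %EWL then undefined
        max_loss = w0 - nadir_w  # zero when no weight was lost; %WR then undefined
        twl_n = 100.0 * (w0 - nadir_w) / w0
        ewl_n = 100.0 * (w0 - nadir_w) / excess if excess > 0 else np.nan
        rec.update(
            nadir_weight=nadir_w, nadir_year=nadir_y, twl_nadir=twl_n, ewl_nadir=ewl_n
        )

        visit = _followup_visit(years, weights, followup_year, window)
        if visit is None:
            rec.update(
                w6=np.nan, w6_year=pd.NA, twl_6y=np.nan, ewl_6y=np.nan, wr_mwl=np.nan,
                ewl6y_gt50=pd.NA, wr_gt20=pd.NA,
                included=False, exclusion_reason=EXCL_NO_WINDOW,
            )
        else:
            w6, w6_year = visit
            twl6 = 100.0 * (w0 - w6) / w0
            ewl6 = 100.0 * (w0 - w6) / excess if excess > 0 else np.nan
            wr = 100.0 * (w6 - nadir_w) / max_loss if max_loss > 0 else np.nan
            rec.update(
                w6=w6, w6_year=w6_year, twl_6y=twl6, ewl_6y=ewl6, wr_mwl=wr,
                ewl6y_gt50=bool(ewl6 > 50.0) if np.isfinite(ewl6) else pd.NA,
                wr_gt20=bool(wr > 20.0) if np.isfinite(wr) else pd.NA,
                included=True, exclusion_reason="",
            )
        rows.append(rec)

    table = pd.DataFrame(rows).set_index("patient_id")
    order = [
        "w0", "nadir_weight", "nadir_year", "w6", "w6_year",
        "twl_nadir", "ewl_nadir", "twl_6y", "ewl_6y", "wr_mwl",
        "ewl6y_gt50", "wr_gt20", "included", "exclusion_reason",
    ]
    return table[order]


def _empty_metrics(skip: tuple[str, ...] = ()) -> dict[str, object]:
    cols = {
        "w0": np.nan, "nadir_weight": np.nan, "nadir_year": pd.NA,
        "w6": np.nan, "w6_year": pd.NA,
        "twl_nadir": np.nan, "ewl_nadir": np.nan,
        "twl_6y": np.nan, "ewl_6y": np.nan, "wr_mwl": np.nan,
        "ewl6y_gt50": pd.NA, "wr_gt20": pd.NA,
    }
    return {k: v for k, v in cols.items() if k not in skip}


def exclusions_log(table: pd.DataFrame) -> pd.DataFrame:
    """Excluded patients and their reasons (one row each)."""
    excl = table.loc[~table["included"].astype(bool), ["exclusion_reason"]]
    return excl.reset_index()
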