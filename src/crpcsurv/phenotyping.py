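"""Identify metastatic castration-resistant prostate cancer from raw tables.

Two detection methods, mirroring clinical practice when no diagnosis code for
the condition exists:

* **treatment**: the patient receives cytotoxic chemotherapy, secondary
  hormone therapy, or immune-modulatory therapy on or after the start of a
  (first-line) hormone-therapy episode;
* **psa_rise**: two consecutive strict increases in serum PSA — a triple
  v1 < v2 < v3 of consecutive measurements — during a hormone-therapy
  episode.

Patients without any hormone-therapy episode, or with fewer than three PSA
values dated within their episodes, are excluded from the PSA method with a
named reason. Hormone-therapy episodes are reconstructed from dispense
records by merging refills whose gaps do not exceed ``gap_days`` (dispense
coverage of intermittent therapy is incomplete in practice, hence the
tolerance).

Conventions: an "increase" is strict (ties do not count); same-day duplicate
PSA values are collapsed to their maximum, which makes results independent of
input row order; episode membership is inclusive of both endpoints.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

HORMONE = "hormone"
SECOND_LINE_CLASSES = ("chemo", "secondary_hormone", "immunomodulatory")

METHOD_NONE = "none"
EXCL_NO_HORMONE = "no_hormone_therapy"
EXCL_FEW_PSA = "fewer_than_3_psa"
EXCL_NOT_DETECTED = "not_detected"
EXCL_NONE = "none"


def build_therapy_episodes(medications: pd.DataFrame, gap_days: int = 90) -> pd.DataFrame:
    """Merge hormone dispenses into episodes; gaps <= gap_days are bridged.

    Returns one row per episode with the set of co-occurring (overlapping)
    non-hormone drug classes, sorted by (patient_id, start_date).
    """
    cols = ["patient_id", "start_date", "end_date", "drug_classes_present"]
    if medications.empty:
        return pd.DataFrame(columns=cols)
    meds = medications.copy()
    meds["start_date"] = pd.to_datetime(meds["start_date"])
    meds["end_date"] = pd.to_datetime(meds["end_date"])
    if (meds["start_date"] > meds["end_date"]).any():
        raise ValueError("medication row with start_date after end_date")

    horm = meds[meds["drug_class"] == HORMONE].sort_values(
        ["patient_id", "start_date", "end_date"], kind="stable"
    )
    other = meds[meds["drug_class"] != HORMONE]
    other_by_pid = dict(tuple(other.groupby("patient_id"))) if len(other) else {}
    rows = []
    for pid, grp in horm.groupby("patient_id", sort=True):
        cur_start = cur_end = None
        spans = []
        for s, e in zip(grp["start_date"], grp["end_date"]):
            if cur_start is None:
                cur_start, cur_end = s, e
            elif (s - cur_end).days <= gap_days:
                cur_end = max(cur_end, e)
            else:
                spans.append((cur_start, cur_end))
                cur_start, cur_end = s, e
        spans.append((cur_start, cur_end))
        oth = other_by_pid.get(pid)
        for s, e in spans:
            if oth is None:
                present: tuple = ()
            else:
                overlap = oth[(oth["start_date"] <= e) & (oth["end_date"] >= s)]
                present = tuple(sorted(set(overlap["drug_class"])))
            rows.append((pid, s, e, present))
    return pd.DataFrame(rows, columns=cols)


def _empty_result(patient_ids) -> pd.DataFrame:
    pids = sorted(set(patient_ids))
    return pd.DataFrame({
        "patient_id": pids,
        "is_crpc": False,
        "method": METHOD_NONE,
        "crpc_date": pd.Series([pd.NaT] * len(pids), dtype="datetime64[ns]"),
        "exclusion_reason": EXCL_NO_HORMONE,
    })


def _fill_result(res: pd.DataFrame, flags, methods, dates, reasons) -> pd.DataFrame:
    if flags:
        res.loc[list(flags), "is_crpc"] = True
    if methods:
        res.loc[list(methods), "method"] = pd.Series(methods)
    if dates:
        res.loc[list(dates), "crpc_date"] = pd.Series(dates)
    if reasons:
        res.loc[list(reasons), "exclusion_reason"] = pd.Series(reasons)
    return res.reset_index()


def phenotype_treatment(episodes: pd.DataFrame, medications: pd.DataFrame,
                        patient_ids) -> pd.DataFrame:
    """Method 1: second-line therapy starting on/after a hormone episode start.

    The CRPC index date is the earliest qualifying second-line start date.
    """
    res = _empty_result(patient_ids).set_index("patient_id")
    meds = medications.copy()
    if len(meds):
        meds["start_date"] = pd.to_datetime(meds["start_date"])
    second = meds[meds["drug_class"].isin(SECOND_LINE_CLASSES)] if len(meds) else meds
    second_by_pid = dict(tuple(second.groupby("patient_id"))) if len(second) else {}
    ep_starts = episodes.groupby("patient_id")["start_date"].min() if len(episodes) else pd.Series(dtype="datetime64[ns]")
    flags, methods, dates, reasons = {}, {}, {}, {}
    for pid in res.index:
        if pid not in ep_starts.index:
            continue  # stays excluded: no hormone therapy
        reasons[pid] = EXCL_NOT_DETECTED
        cand = second_by_pid.get(pid)
        if cand is None:
            continue
        cand = cand[cand["start_date"] >= ep_starts.loc[pid]]
        if len(cand):
            flags[pid] = True
            methods[pid] = "treatment"
            dates[pid] = cand["start_date"].min()
            reasons[pid] = EXCL_NONE
    return _fill_result(res, flags, methods, dates, reasons)


def _dedup_psa(labs: pd.DataFrame) -> pd.DataFrame:
    psa = labs[labs["analyte"] == "PSA"].copy()
    psa["date"] = pd.to_datetime(psa["date"])
    # same-day duplicates: keep the maximum (deterministic, order-independent)
    return psa.groupby(["patient_id", "date"], as_index=False)["value"].max()


def phenotype_psa(episodes: pd.DataFrame, labs: pd.DataFrame, patient_ids) -> pd.DataFrame:
    """Method 2: two consecutive strict PSA increases within a hormone episode.

    The CRPC index date is the date of the third value of the earliest
    qualifying triple.
    """
    res = _empty_result(patient_ids).set_index("patient_id")
    psa = _dedup_psa(labs).sort_values(["patient_id", "date"], kind="stable")
    psa_by_pid = dict(tuple(psa.groupby("patient_id"))) if len(psa) else {}
    eps_by_pid = dict(tuple(episodes.groupby("patient_id"))) if len(episodes) else {}
    flags, methods, dates, reasons = {}, {}, {}, {}
    for pid in res.index:
        pep = eps_by_pid.get(pid)
        if pep is None:
            continue  # no hormone therapy
        pv = psa_by_pid.get(pid)
        in_ep_total = 0
        best_date = None
        if pv is not None:
            d_all = pv["date"].to_numpy()
            v_all = pv["value"].to_numpy()
            for s, e in zip(pep["start_date"], pep["end_date"]):
                inside = (d_all >= np.datetime64(s)) & (d_all <= np.datetime64(e))
                v = v_all[inside]
                dts = d_all[inside]
                in_ep_total += len(v)
                if len(v) >= 3:
                    rising = (v[:-2] < v[1:-1]) & (v[1:-1] < v[2:])
                    hits = np.where(rising)[0]
                    if len(hits):
                        d = dts[hits[0] + 2]
                        if best_date is None or d < best_date:
                            best_date = d
        if in_ep_total < 3:
            reasons[pid] = EXCL_FEW_PSA
        elif best_date is not None:
            flags[pid] = True
            methods[pid] = "psa_rise"
            dates[pid] = pd.Timestamp(best_date)
            reasons[pid] = EXCL_NONE
        else:
            reasons[pid] = EXCL_NOT_DETECTED
    return _fill_result(res, flags, methods, dates, reasons)


def combine_phenotypes(r1: pd.DataFrame, r2: pd.DataFrame) -> pd.DataFrame:
    """OR-combine the two detection methods; index date = earliest candidate."""
    a = r1.set_index("patient_id").sort_index()
    b = r2.set_index("patient_id").sort_index()
    if not a.index.equals(b.index):
        raise ValueError("phenotype results cover different patient sets")
    is_crpc = a["is_crpc"].astype(bool) | b["is_crpc"].astype(bool)
    method = pd.Series(METHOD_NONE, index=a.index)
    method[a["is_crpc"].astype(bool) & ~b["is_crpc"].astype(bool)] = "treatment"
    method[~a["is_crpc"].astype(bool) & b["is_crpc"].astype(bool)] = "psa_rise"
    method[a["is_crpc"].astype(bool) & b["is_crpc"].astype(bool)] = "both"
    dates = pd.concat([
        pd.to_datetime(a["crpc_date"]).where(a["is_crpc"].astype(bool)),
        pd.to_datetime(b["crpc_date"]).where(b["is_crpc"].astype(bool)),
    ], axis=1)
    crpc_date = dates.min(axis=1)

    def _reason(row_a, row_b, flagged):
        if flagged:
            return EXCL_NONE
        reasons = {row_a, row_b}
        if EXCL_NOT_DETECTED in reasons:
            return EXCL_NOT_DETECTED
        if EXCL_FEW_PSA in reasons:
            return EXCL_FEW_PSA
        return EXCL_NO_HORMONE

    reason = [
        _reason(ra, rb, f)
        for ra, rb, f in zip(a["exclusion_reason"], b["exclusion_reason"], is_crpc)
    ]
    return pd.DataFrame({
        "patient_id": a.index,
        "is_crpc": is_crpc.to_numpy(),
        "method": method.to_numpy(),
        "crpc_date": crpc_date.to_numpy(),
        "exclusion_reason": reason,
    })


def phenotype_cohort(tables, gap_days: int = 90) -> pd.DataFrame:
    """Run both methods over a cohort and combine them."""
    pids = tables.demographics["patient_id"].tolist()
    episodes = build_therapy_episodes(tables.medications, gap_days=gap_days)
    r1 = phenotype_treatment(episodes, tables.medications, pids)
    r2 = phenotype_psa(episodes, tables.labs, pids)
    return combine_phenotypes(r1, r2)


def format_prevalence(n_flagged: int, n_total: int) -> str:
    """Report-style prevalence, rounded to one decimal (e.g. ``'3.0%'``)."""
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    return f"{100.0 * n_flagged / n_total:.1f}%"
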