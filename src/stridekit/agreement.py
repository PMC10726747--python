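"""Stride-by-stride agreement between the IMU pipeline and the reference.

Events from the two systems are paired one-to-one by greedy nearest-neighbour
matching within a time window; matched strides inherit the pairing of their
defining initial contacts.  Summary statistics are the mean difference,
sample SD and Bland-Altman limits of agreement at mean +/- 1.96 SD, plus
Bland-Altman point sets (per stride and per trial) and per-trial CoV pairs.
All differences are signed IMU minus reference.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ParameterError
from .spatial import StrideTable, summarize_trial

STRIDE_PARAMS = ("stride_time", "stride_length", "stride_velocity")


@dataclass
class EventMatch:
    imu_time: float
    ref_time: float
    diff_ms: float  # IMU - reference, milliseconds
    event_type: str = ""
    side: str = ""


@dataclass
class MatchResult:
    matches: list = field(default_factory=list)
    n_imu_unmatched: int = 0
    n_ref_unmatched: int = 0

    @property
    def diffs_ms(self) -> np.ndarray:
        return np.array([m.diff_ms for m in self.matches], dtype=float)


@dataclass
class AgreementReport:
    """Agreement summary: per event type / parameter statistics and the raw
    Bland-Altman point sets, plus per-trial CoV pairs."""

    events: dict = field(default_factory=dict)  # type -> stats dict
    parameters: dict = field(default_factory=dict)  # param -> stats dict
    bland_altman: dict = field(default_factory=dict)  # param -> {stride, trial}
    cov: dict = field(default_factory=dict)  # param -> {imu, ref, diff}
    matching_window_s: float = 0.0
    unmatched: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "matching_window_s": self.matching_window_s,
            "events": self.events,
            "parameters": self.parameters,
            "bland_altman": self.bland_altman,
            "cov": self.cov,
            "unmatched": self.unmatched,
        }


def default_matching_window(ref_event_times: np.ndarray) -> float:
    """Half the median reference stride time (s)."""
    t = np.sort(np.asarray(ref_event_times, dtype=float))
    if t.size < 2:
        return 0.5
    return 0.5 * float(np.median(np.diff(t)))


def match_events(
    imu_times: np.ndarray,
    ref_times: np.ndarray,
    window: float,
    event_type: str = "",
    side: str = "",
) -> MatchResult:
    """Greedy nearest-neighbour one-to-one matching within +/- window.

    Candidate pairs are taken in order of increasing absolute time
    difference; each event participates in at most one match.  Unmatched
    events are counted, never fabricated.
    """
    imu = np.asarray(imu_times, dtype=float)
    ref = np.asarray(ref_times, dtype=float)
    result = MatchResult()
    if imu.size == 0 or ref.size == 0:
        result.n_imu_unmatched = imu.size
        result.n_ref_unmatched = ref.size
        return result
    diffs = np.abs(imu[:, None] - ref[None, :])
    cand = np.argwhere(diffs <= window)
    order = np.argsort(diffs[cand[:, 0], cand[:, 1]], kind="stable")
    used_imu: set = set()
    used_ref: set = set()
    pairs = []
    for i, j in cand[order]:
        if i in used_imu or j in used_ref:
            continue
        used_imu.add(int(i))
        used_ref.add(int(j))
        pairs.append((int(i), int(j)))
    pairs.sort(key=lambda p: p[1])
    for i, j in pairs:
        result.matches.append(
            EventMatch(
                imu_time=float(imu[i]),
                ref_time=float(ref[j]),
                diff_ms=float((imu[i] - ref[j]) * 1000.0),
                event_type=event_type,
                side=side,
            )
        )
    result.n_imu_unmatched = imu.size - len(pairs)
    result.n_ref_unmatched = ref.size - len(pairs)
    return result


def match_strides(
    imu: StrideTable, ref: StrideTable, window: float
) -> dict:
    """Pair strides via their defining (start) IC matches.

    Returns per-parameter arrays of signed differences (IMU - reference) and
    the paired value arrays for Bland-Altman use.
    """
    imu_recs = imu.valid_records()
    ref_recs = ref.valid_records()
    imu_ics = np.array([r.ic_start for r in imu_recs])
    ref_ics = np.array([r.ic_start for r in ref_recs])
    res = match_events(imu_ics, ref_ics, window)
    out: dict = {"n_pairs": len(res.matches)}
    idx_imu = {round(r.ic_start, 9): k for k, r in enumerate(imu_recs)}
    idx_ref = {round(r.ic_start, 9): k for k, r in enumerate(ref_recs)}
    for param in STRIDE_PARAMS:
        iv, rv = [], []
        for m in res.matches:
            iv.append(getattr(imu_recs[idx_imu[round(m.imu_time, 9)]], param))
            rv.append(getattr(ref_recs[idx_ref[round(m.ref_time, 9)]], param))
        iv = np.array(iv, dtype=float)
        rv = np.array(rv, dtype=float)
        out[param] = {"imu": iv, "ref": rv, "diff": iv - rv}
    return out


def mean_sd_loa(diffs) -> tuple[float, float, float, float]:
    """Mean, sample SD and limits of agreement (mean +/- 1.96 SD)."""
    d = np.asarray(diffs, dtype=float)
    if d.size < 2:
        raise ParameterError(f"need >= 2 differences, got {d.size}")
    mean = float(np.mean(d))
    sd = float(np.std(d, ddof=1))
    return mean, sd, mean - 1.96 * sd, mean + 1.96 * sd


def bland_altman_points(
    imu_values, ref_values, level: str = "stride", trial_ids=None
) -> np.ndarray:
    """Bland-Altman point set: x = (imu + ref)/2, y = imu - ref.

    ``level='trial'`` first averages paired values within each trial
    (``trial_ids`` groups the pairs; a single trial is assumed when omitted).
    """
    iv = np.asarray(imu_values, dtype=float)
    rv = np.asarray(ref_values, dtype=float)
    if iv.shape != rv.shape:
        raise ParameterError("imu and ref value lists differ in length")
    if level == "trial":
        ids = np.zeros(len(iv), dtype=int) if trial_ids is None else np.asarray(trial_ids)
        xs, ys = [], []
        for t in np.unique(ids):
            sel = ids == t
            mi, mr = float(np.mean(iv[sel])), float(np.mean(rv[sel]))
            xs.append((mi + mr) / 2.0)
            ys.append(mi - mr)
        return np.column_stack([xs, ys])
    if level != "stride":
        raise ParameterError(f"unknown level {level!r}")
    return np.column_stack([(iv + rv) / 2.0, iv - rv])


def cov_comparison(imu: StrideTable, ref: StrideTable) -> dict:
    """Per-parameter CoV (%) of each method and their difference
    (IMU - reference)."""
    s_imu = summarize_trial(imu)
    s_ref = summarize_trial(ref)
    out = {}
    for param in STRIDE_PARAMS:
        ci = s_imu[param]["cov_pct"]
        cr = s_ref[param]["cov_pct"]
        out[param] = {"imu": ci, "ref": cr, "diff": ci - cr}
    return out


def build_agreement_report(
    imu_events: dict,
    ref_events: dict,
    imu_strides: dict,
    ref_strides: dict,
    window: float | None = None,
) -> AgreementReport:
    """Assemble the full agreement report for one trial.

    ``imu_events``/``ref_events`` map side -> event-set objects exposing
    ``times('ic'|'tc')``; stride dicts map side -> StrideTable.
    """
    ref_ic_all = np.concatenate(
        [ev.times("ic") for ev in ref_events.values()] or [np.array([])]
    )
    if window is None:
        window = default_matching_window(np.sort(ref_ic_all))
    report = AgreementReport(matching_window_s=float(window))

    for etype in ("ic", "tc"):
        all_diffs = []
        n_unmatched = 0
        for side in ("left", "right"):
            res = match_events(
                imu_events[side].times(etype),
                ref_events[side].times(etype),
                window,
                event_type=etype,
                side=side,
            )
            all_diffs.append(res.diffs_ms)
            n_unmatched += res.n_imu_unmatched + res.n_ref_unmatched
        d = np.concatenate(all_diffs)
        if d.size >= 2:
            mean, sd, lo, hi = mean_sd_loa(d)
            report.events[etype] = {
                "n": int(d.size),
                "mean_ms": mean,
                "sd_ms": sd,
                "loa_low_ms": lo,
                "loa_high_ms": hi,
            }
        report.unmatched[etype] = n_unmatched

    merged: dict = {p: {"imu": [], "ref": []} for p in STRIDE_PARAMS}
    for side in ("left", "right"):
        pairs = match_strides(imu_strides[side], ref_strides[side], window)
        for p in STRIDE_PARAMS:
            merged[p]["imu"].append(pairs[p]["imu"])
            merged[p]["ref"].append(pairs[p]["ref"])
    for p in STRIDE_PARAMS:
        iv = np.concatenate(merged[p]["imu"])
        rv = np.concatenate(merged[p]["ref"])
        if iv.size >= 2:
            mean, sd, lo, hi = mean_sd_loa(iv - rv)
            report.parameters[p] = {
                "n": int(iv.size),
                "mean": mean,
                "sd": sd,
                "loa_low": lo,
                "loa_high": hi,
            }
            report.bland_altman[p] = {
                "stride": bland_altman_points(iv, rv, "stride"),
                "trial": bland_altman_points(iv, rv, "trial"),
            }

    imu_all = StrideTable(
        records=[r for t in imu_strides.values() for r in t.records],
        provenance="imu",
    )
    ref_all = StrideTable(
        records=[r for t in ref_strides.values() for r in t.records],
        provenance="omcs",
    )
    try:
        report.cov = cov_comparison(imu_all, ref_all)
    except ParameterError:
        report.cov = {}
    return report
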