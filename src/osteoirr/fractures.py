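"""Hospitalized fragility-fracture identification and deduplication.

Fractures are identified from ICD-10 diagnosis codes (principal, related,
or associated position) and procedure codes on hospital stays.  Each stay
yields at most one raw event per anatomical site, dated at admission.
Sequential same-site events are counted as *independent* only when separated
by at least 90 days from the previous independent same-site event with no
fracture of another site in between.

Events belong to overlapping site groups: hip; vertebral; wrist/forearm; and
non-hip/nonvertebral (wrist/forearm, humerus, clavicle, ribs, pelvis, leg) —
a wrist fracture counts in both the wrist/forearm and the
non-hip/nonvertebral groups.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

SITES = ("hip", "vertebral", "wrist_forearm", "humerus", "clavicle",
         "ribs", "pelvis", "leg")

GROUPS = ("hip", "vertebral", "wrist_forearm", "nonhip_nonvertebral")

NONHIP_NONVERTEBRAL_SITES = frozenset(
    {"wrist_forearm", "humerus", "clavicle", "ribs", "pelvis", "leg"})

INDEPENDENCE_GAP_DAYS = 90

#: Default diagnosis-code prefixes per site.  This is an editable stand-in
#: for a full national code list: ICD-10 S72 hip, S22.0/S32.0/T08 vertebral,
#: S52 wrist/forearm, S42.0 clavicle, S42 (other) humerus, S22.3/S22.4 ribs,
#: S32 (other) pelvis, S82 leg.  Longest matching prefix wins, so "S220"
#: (vertebral) takes precedence over a generic "S22" entry.
DEFAULT_CODE_MAP: dict[str, str] = {
    "S72": "hip",
    "S220": "vertebral",
    "S320": "vertebral",
    "T08": "vertebral",
    "S52": "wrist_forearm",
    "S420": "clavicle",
    "S42": "humerus",
    "S22": "ribs",
    "S32": "pelvis",
    "S82": "leg",
}

DEFAULT_POSITIONS = frozenset({"principal", "related", "associated"})


@dataclass(frozen=True)
class FractureCodeMap:
    """Maps diagnosis/procedure code prefixes to anatomical sites.

    ``prefixes`` maps a code prefix to exactly one site; the longest prefix
    matching a code decides its site.  ``positions`` is the set of accepted
    diagnosis positions in the discharge summary.
    """

    prefixes: dict = field(default_factory=lambda: dict(DEFAULT_CODE_MAP))
    positions: frozenset = DEFAULT_POSITIONS

    def __post_init__(self):
        bad = {p: s for p, s in self.prefixes.items() if s not in SITES}
        if bad:
            raise ValueError(f"unknown site(s) in code map: {bad}")

    def site_of(self, code: str) -> str | None:
        code = str(code).replace(".", "").upper()
        best = None
        for prefix, site in self.prefixes.items():
            if code.startswith(prefix) and (best is None or
                                            len(prefix) > len(best[0])):
                best = (prefix, site)
        return best[1] if best else None


def identify_raw_events(stays: pd.DataFrame,
                        code_map: FractureCodeMap | None = None
                        ) -> pd.DataFrame:
    """One raw fracture event per (stay, site), dated at admission.

    Multiple codes of the same site on one stay collapse to a single event.
    Codes in positions outside ``code_map.positions`` are ignored.
    """
    code_map = code_map or FractureCodeMap()
    if stays.empty:
        return pd.DataFrame(columns=["person_id", "event_date", "site"])
    df = stays[stays["position"].isin(code_map.positions)].copy()
    df["site"] = df["code"].map(code_map.site_of)
    df = df.dropna(subset=["site"])
    events = (df.groupby(["person_id", "stay_id", "site"], as_index=False)
                .agg(event_date=("admission_date", "min")))
    events = events[["person_id", "event_date", "site"]].drop_duplicates(
        ["person_id", "event_date", "site"])
    return events.sort_values(["person_id", "event_date", "site"],
                              kind="stable", ignore_index=True)


def dedup_flags(dates: np.ndarray, sites: np.ndarray,
                gap_days: int = INDEPENDENCE_GAP_DAYS) -> np.ndarray:
    """Independence flags for one person's date-sorted events."""
    flags = np.zeros(len(dates), dtype=bool)
    last_indep: dict[str, int] = {}
    for k in range(len(dates)):
        d, s = int(dates[k]), sites[k]
        prev = last_indep.get(s)
        if prev is None:
            ok = True
        elif d - prev < gap_days:
            ok = False
        else:
            between = (dates > prev) & (dates < d) & (sites != s)
            ok = not between.any()
        if ok:
            flags[k] = True
            last_indep[s] = d
    return flags


def deduplicate(events: pd.DataFrame,
                gap_days: int = INDEPENDENCE_GAP_DAYS) -> pd.DataFrame:
    """Flag independent events under the 90-day same-site rule.

    The first event of each site is independent.  A later same-site event is
    independent iff it falls at least ``gap_days`` after the previous
    *independent* same-site event and no event of any other site occurred
    strictly between the two dates.  Non-independent events are retained,
    flagged ``independent=False``, for audit.
    """
    if events.empty:
        out = events.copy()
        out["independent"] = pd.Series(dtype=bool)
        return out
    events = events.sort_values(["person_id", "event_date", "site"],
                                kind="stable", ignore_index=True)
    flags = np.zeros(len(events), dtype=bool)
    for pid, grp in events.groupby("person_id", sort=False):
        flags[grp.index] = dedup_flags(
            grp["event_date"].to_numpy(dtype=np.int64),
            grp["site"].to_numpy(), gap_days)
    out = events.copy()
    out["independent"] = flags
    return out


def assign_groups(site: str) -> frozenset:
    """Site-group memberships for one event site (groups overlap)."""
    if site == "hip":
        return frozenset({"hip"})
    if site == "vertebral":
        return frozenset({"vertebral"})
    if site == "wrist_forearm":
        return frozenset({"wrist_forearm", "nonhip_nonvertebral"})
    if site in NONHIP_NONVERTEBRAL_SITES:
        return frozenset({"nonhip_nonvertebral"})
    raise ValueError(f"unmapped site: {site!r}")


def events_by_group(events: pd.DataFrame) -> pd.DataFrame:
    """Explode events to one row per (event, site-group) membership."""
    if events.empty:
        out = events.copy()
        out["site_group"] = pd.Series(dtype=object)
        return out
    rows = []
    for group in GROUPS:
        member = events["site"].map(lambda s: group in assign_groups(s))
        sub = events[member].copy()
        sub["site_group"] = group
        rows.append(sub)
    return pd.concat(rows, ignore_index=True)


def find_fracture_events(stays: pd.DataFrame,
                         code_map: FractureCodeMap | None = None
                         ) -> pd.DataFrame:
    """Identify, deduplicate, and group fracture events in one call."""
    return deduplicate(identify_raw_events(stays, code_map))
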