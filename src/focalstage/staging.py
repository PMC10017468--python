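"""G/F classification: global Centiloid status x focal regional involvement.

Participants are classified by two axes:

* global status -- dcCL at or above the global cutoff (default 25.11 CL);
* focal status -- number of the ten composite regions whose SUVR exceeds the
  ligand- and region-specific cutoff (strict ``>``).

Groups: ``G-F-`` (global-negative, no involved region), ``G-F+``
(global-negative with >= 1 involved region) and ``G+`` (global-positive).
The subtype distinguishes focal involvement (1-9 regions) from the
whole-brain pattern (all 10); a global-positive scan with zero involved
regions is possible in principle and carries ``discordant_flag``.

Boundary conventions (regional strict ``>``, global ``>=``) are exposed as
parameters because they are conventions, not derivable facts.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from .centiloid import GlobalThreshold, LigandCalibration, is_global_positive, suvr_to_cl
from .cutoffs import RegionalCutoffs
from .regions import REGIONS, RegionalProfile

GROUPS = ("G-F-", "G-F+", "G+")
SUBTYPES = ("none", "focal", "whole_brain")


@dataclass
class StagingResult:
    """Classification of one participant."""

    participant_id: str
    ligand: str
    global_cl: float
    global_positive: bool
    region_flags: dict[str, bool]
    n_involved: int
    group: str
    subtype: str
    discordant_flag: bool

    def __post_init__(self) -> None:
        if self.n_involved != sum(self.region_flags.values()):
            raise ValueError("n_involved inconsistent with region_flags")
        expected_group = (
            "G+" if self.global_positive else ("G-F+" if self.n_involved else "G-F-")
        )
        if self.group != expected_group:
            raise ValueError(f"group {self.group!r} inconsistent; expected {expected_group!r}")
        expected_subtype = (
            "none" if self.n_involved == 0
            else "whole_brain" if self.n_involved == len(REGIONS)
            else "focal"
        )
        if self.subtype != expected_subtype:
            raise ValueError(
                f"subtype {self.subtype!r} inconsistent; expected {expected_subtype!r}"
            )


def flag_regions(
    profile: RegionalProfile,
    cutoffs: RegionalCutoffs,
    *,
    inclusive: bool = False,
) -> dict[str, bool]:
    """Regional positivity flags; strict ``SUVR > cutoff`` by default."""
    if profile.ligand != cutoffs.ligand:
        raise ValueError(
            f"ligand mismatch: profile {profile.ligand} vs cutoffs {cutoffs.ligand}"
        )
    if inclusive:
        return {r: profile.region_suvr[r] >= cutoffs.cutoff(r) for r in REGIONS}
    return {r: profile.region_suvr[r] > cutoffs.cutoff(r) for r in REGIONS}


def classify(
    profile: RegionalProfile,
    cutoffs: RegionalCutoffs,
    calib: LigandCalibration,
    thr: GlobalThreshold,
    *,
    regional_inclusive: bool = False,
    global_inclusive: bool = True,
) -> StagingResult:
    """Stage one participant from their regional profile."""
    cl = suvr_to_cl(profile.global_suvr, calib)
    global_positive = is_global_positive(cl, thr, inclusive=global_inclusive)
    flags = flag_regions(profile, cutoffs, inclusive=regional_inclusive)
    n_involved = sum(flags.values())
    group = "G+" if global_positive else ("G-F+" if n_involved else "G-F-")
    subtype = (
        "none" if n_involved == 0
        else "whole_brain" if n_involved == len(REGIONS)
        else "focal"
    )
    return StagingResult(
        participant_id=profile.participant_id,
        ligand=profile.ligand,
        global_cl=cl,
        global_positive=global_positive,
        region_flags=flags,
        n_involved=n_involved,
        group=group,
        subtype=subtype,
        discordant_flag=global_positive and n_involved == 0,
    )


def stage_cohort(
    profiles: Sequence[RegionalProfile],
    cutoffs_by_ligand: Mapping[str, RegionalCutoffs],
    calibs_by_ligand: Mapping[str, LigandCalibration],
    thr: GlobalThreshold,
    **classify_kwargs,
) -> tuple[list[StagingResult], dict[str, int]]:
    """Stage every participant; returns results plus per-group counts."""
    results = []
    for p in profiles:
        if p.ligand not in cutoffs_by_ligand or p.ligand not in calibs_by_ligand:
            raise ValueError(
                f"participant {p.participant_id}: no cutoffs/calibration for "
                f"ligand {p.ligand!r}"
            )
        results.append(
            classify(p, cutoffs_by_ligand[p.ligand], calibs_by_ligand[p.ligand],
                     thr, **classify_kwargs)
        )
    counts = Counter(r.group for r in results)
    summary = {g: counts.get(g, 0) for g in GROUPS}
    return results, summary


def staging_to_frame(results: Sequence[StagingResult]) -> pd.DataFrame:
    """One row per participant; regional flags as 0/1 columns."""
    rows = [
        {
            "participant_id": r.participant_id,
            "ligand": r.ligand,
            "global_cl": r.global_cl,
            "global_positive": int(r.global_positive),
            **{f"flag_{reg}": int(r.region_flags[reg]) for reg in REGIONS},
            "n_involved": r.n_involved,
            "group": r.group,
            "subtype": r.subtype,
            "discordant_flag": int(r.discordant_flag),
        }
        for r in results
    ]
    columns = [
        "participant_id", "ligand", "global_cl", "global_positive",
        *(f"flag_{reg}" for reg in REGIONS),
        "n_involved", "group", "subtype", "discordant_flag",
    ]
    return pd.DataFrame(rows, columns=columns)
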