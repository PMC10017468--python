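"""Regional SUVR quantification: VOI means -> composite-region profiles.

Amyloid PET uptake is quantified as the standardized uptake value ratio
(SUVR): mean tracer uptake in a target volume of interest (VOI) divided by
mean uptake in a reference region (here the whole cerebellum). For focal
staging, lateralized AAL-style VOIs are pooled into ten composite regions --
five lobes (frontal, lateral temporal, parietal, cingulate, striatum) in
each hemisphere -- and a global cortical SUVR is computed over all cortical
(non-striatal) VOIs.

Pooling across the VOIs of a composite region is volume-weighted, which is
equivalent to averaging over the union of their voxels; with equal volumes
it degenerates to the unweighted mean.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from importlib import resources
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

LIGANDS = ("FBB", "FMM")

LOBES = ("frontal", "lateral_temporal", "parietal", "cingulate", "striatum")
CORTICAL_LOBES = ("frontal", "lateral_temporal", "parietal", "cingulate")
HEMISPHERES = ("left", "right")

#: The ten composite regions, as ``"<lobe>_<hemisphere>"`` keys.
REGIONS = tuple(f"{lobe}_{hemi}" for lobe in LOBES for hemi in HEMISPHERES)
CORTICAL_REGIONS = tuple(r for r in REGIONS if not r.startswith("striatum"))


def region_key(lobe: str, hemisphere: str) -> str:
    """Composite-region key for a (lobe, hemisphere) pair."""
    if lobe not in LOBES:
        raise ValueError(f"unknown lobe {lobe!r}; expected one of {LOBES}")
    if hemisphere not in HEMISPHERES:
        raise ValueError(f"unknown hemisphere {hemisphere!r}")
    return f"{lobe}_{hemisphere}"


@dataclass(frozen=True)
class VOIEntry:
    """One VOI's assignment to a composite region."""

    voi_name: str
    lobe: str
    hemisphere: str

    @property
    def region(self) -> str:
        return region_key(self.lobe, self.hemisphere)


@dataclass
class RegionMap:
    """Mapping from lateralized VOIs to the ten composite regions.

    Every VOI maps to exactly one composite region and all ten regions must
    be represented.
    """

    entries: list[VOIEntry]

    def __post_init__(self) -> None:
        names = [e.voi_name for e in self.entries]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise ValueError(f"duplicate VOI names in region map: {dupes}")
        for e in self.entries:
            region_key(e.lobe, e.hemisphere)  # validates lobe/hemisphere
        present = {e.region for e in self.entries}
        missing = [r for r in REGIONS if r not in present]
        if missing:
            raise ValueError(f"region map does not reach composite regions: {missing}")

    @property
    def voi_names(self) -> list[str]:
        return [e.voi_name for e in self.entries]

    def region_of(self, voi_name: str) -> str:
        for e in self.entries:
            if e.voi_name == voi_name:
                return e.region
        raise KeyError(voi_name)

    def vois_of(self, region: str) -> list[str]:
        return [e.voi_name for e in self.entries if e.region == region]

    def cortical_vois(self) -> list[str]:
        """All non-striatal VOI names (the default global cortical target)."""
        return [e.voi_name for e in self.entries if e.lobe != "striatum"]

    @classmethod
    def from_mapping(cls, spec: Mapping) -> "RegionMap":
        entries = [
            VOIEntry(str(d["voi"]), str(d["lobe"]), str(d["hemisphere"]))
            for d in spec["vois"]
        ]
        return cls(entries)

    @classmethod
    def from_yaml(cls, path) -> "RegionMap":
        with open(path) as fh:
            return cls.from_mapping(yaml.safe_load(fh))


@lru_cache(maxsize=1)
def default_region_map() -> RegionMap:
    """The packaged default map: 42 lateralized AAL VOIs -> 10 regions.

    Frontal: superior/middle frontal gyri, medial superior frontal,
    opercular and triangular inferior frontal, supplementary motor area and
    the three orbital parts; lateral temporal: superior/middle/inferior
    temporal gyri; parietal: superior/inferior parietal, supramarginal,
    angular and precuneus; cingulate: anterior and posterior cingulate;
    striatum: caudate and putamen -- each left and right.
    """
    ref = resources.files("focalstage").joinpath("data/region_map_default.yaml")
    return RegionMap.from_mapping(yaml.safe_load(ref.read_text()))


@dataclass(frozen=True)
class VOIMeasurement:
    """Mean uptake over one VOI together with its volume (voxels or mm^3)."""

    voi_name: str
    mean_uptake: float
    volume: float

    def __post_init__(self) -> None:
        if not math.isfinite(self.mean_uptake) or self.mean_uptake < 0:
            raise ValueError(f"{self.voi_name}: mean_uptake must be finite and >= 0")
        if not self.volume > 0:
            raise ValueError(f"{self.voi_name}: volume must be > 0")


@dataclass
class RegionalProfile:
    """One participant's ten composite-region SUVRs plus the global SUVR."""

    participant_id: str
    ligand: str
    region_suvr: dict[str, float]
    global_suvr: float

    def __post_init__(self) -> None:
        if self.ligand not in LIGANDS:
            raise ValueError(f"unknown ligand {self.ligand!r}; expected one of {LIGANDS}")
        missing = [r for r in REGIONS if r not in self.region_suvr]
        if missing:
            raise ValueError(f"profile {self.participant_id}: missing regions {missing}")
        values = list(self.region_suvr.values()) + [self.global_suvr]
        if not all(math.isfinite(v) and v >= 0 for v in values):
            raise ValueError(f"profile {self.participant_id}: SUVRs must be finite and >= 0")


def aggregate_profile(
    vois: Sequence[VOIMeasurement],
    reference: VOIMeasurement,
    region_map: RegionMap | None = None,
    global_vois: Sequence[str] | None = None,
    *,
    participant_id: str = "",
    ligand: str = "FBB",
) -> RegionalProfile:
    """Pool VOI means into composite-region and global SUVRs.

    Each composite region's SUVR is the volume-weighted mean uptake of its
    VOIs divided by the reference mean uptake; the global SUVR is computed
    identically over ``global_vois`` (default: all cortical VOIs of the map).
    """
    if region_map is None:
        region_map = default_region_map()
    if not reference.mean_uptake > 0:
        raise ValueError("reference mean uptake must be > 0")

    by_name: dict[str, VOIMeasurement] = {}
    for v in vois:
        if v.voi_name in by_name:
            raise ValueError(f"VOI {v.voi_name!r} supplied more than once")
        by_name[v.voi_name] = v

    def pooled_suvr(names: Iterable[str], what: str) -> float:
        tot_uptake = 0.0
        tot_volume = 0.0
        for name in names:
            if name not in by_name:
                raise ValueError(f"missing VOI {name!r} required for {what}")
            m = by_name[name]
            tot_uptake += m.mean_uptake * m.volume
            tot_volume += m.volume
        return tot_uptake / tot_volume / reference.mean_uptake

    region_suvr = {
        region: pooled_suvr(region_map.vois_of(region), f"region {region}")
        for region in REGIONS
    }
    if global_vois is None:
        global_vois = region_map.cortical_vois()
    global_suvr = pooled_suvr(global_vois, "the global cortical target")
    return RegionalProfile(participant_id, ligand, region_suvr, global_suvr)


def extract_voi_means(
    intensity_volume: np.ndarray,
    label_volume: np.ndarray,
    label_table: Mapping[int, str],
) -> list[VOIMeasurement]:
    """Per-label mean intensity and voxel count from a labeled image.

    Labels present in ``label_table`` but absent from ``label_volume`` are
    omitted from the result.
    """
    intensity = np.asarray(intensity_volume, dtype=float)
    labels = np.asarray(label_volume)
    if intensity.shape != labels.shape:
        raise ValueError(
            f"shape mismatch: intensity {intensity.shape} vs labels {labels.shape}"
        )
    for label in label_table:
        if label < 0:
            raise ValueError(f"negative label {label} in label table")
    out = []
    for label, name in label_table.items():
        mask = labels == label
        n = int(mask.sum())
        if n == 0:
            continue
        out.append(VOIMeasurement(name, float(intensity[mask].mean()), float(n)))
    return out


def voi_means_from_nifti(
    intensity_path, label_path, label_table: Mapping[int, str]
) -> list[VOIMeasurement]:
    """`extract_voi_means` over a NIfTI intensity/label volume pair."""
    import nibabel as nib

    intensity = np.asanyarray(nib.load(str(intensity_path)).dataobj, dtype=float)
    labels = np.asanyarray(nib.load(str(label_path)).dataobj)
    return extract_voi_means(intensity, np.rint(labels).astype(int), label_table)


# ---------------------------------------------------------------------------
# Tabular I/O

VOI_TABLE_COLUMNS = ("participant_id", "ligand", "voi_name", "mean_uptake", "volume")


def aggregate_profiles_from_table(
    voi_table: pd.DataFrame,
    reference_voi: str,
    region_map: RegionMap | None = None,
    global_vois: Sequence[str] | None = None,
) -> list[RegionalProfile]:
    """Build one profile per (participant, ligand) from a long VOI table.

    The table needs columns ``participant_id, ligand, voi_name, mean_uptake,
    volume`` and must contain a ``reference_voi`` row per participant.
    """
    missing = [c for c in VOI_TABLE_COLUMNS if c not in voi_table.columns]
    if missing:
        raise ValueError(f"VOI table is missing columns {missing}")
    profiles = []
    for (pid, ligand), grp in voi_table.groupby(["participant_id", "ligand"], sort=True):
        measurements = {}
        for row in grp.itertuples(index=False):
            measurements[row.voi_name] = VOIMeasurement(
                row.voi_name, float(row.mean_uptake), float(row.volume)
            )
        if reference_voi not in measurements:
            raise ValueError(f"participant {pid}: missing reference VOI {reference_voi!r}")
        reference = measurements.pop(reference_voi)
        profiles.append(
            aggregate_profile(
                list(measurements.values()),
                reference,
                region_map,
                global_vois,
                participant_id=str(pid),
                ligand=str(ligand),
            )
        )
    return profiles


def profiles_to_frame(profiles: Sequence[RegionalProfile]) -> pd.DataFrame:
    """Wide per-participant table: one column per composite region + global."""
    rows = [
        {
            "participant_id": p.participant_id,
            "ligand": p.ligand,
            **{r: p.region_suvr[r] for r in REGIONS},
            "global_suvr": p.global_suvr,
        }
        for p in profiles
    ]
    columns = ["participant_id", "ligand", *REGIONS, "global_suvr"]
    return pd.DataFrame(rows, columns=columns)


def profiles_from_frame(frame: pd.DataFrame) -> list[RegionalProfile]:
    missing = [c for c in ("participant_id", "ligand", "global_suvr", *REGIONS)
               if c not in frame.columns]
    if missing:
        raise ValueError(f"profile table is missing columns {missing}")
    return [
        RegionalProfile(
            str(row.participant_id),
            str(row.ligand),
            {r: float(getattr(row, r)) for r in REGIONS},
            float(row.global_suvr),
        )
        for row in frame.itertuples(index=False)
    ]
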