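"""Direct-comparison Centiloid (dcCL) conversion and global amyloid positivity.

The Centiloid scale maps tracer-specific SUVR onto a common axis anchored at
0 (mean SUVR of amyloid-negative young controls, ``SUVR_YC-0``) and 100
(mean SUVR of a typical amyloid-positive cognitively impaired anchor group,
``SUVR_ADCI-100``):

    CL = 100 * (SUVR_ind - SUVR_YC-0) / (SUVR_ADCI-100 - SUVR_YC-0)

The direct-comparison calibration uses per-ligand anchor means obtained from
head-to-head FBB/FMM scans; those means are configuration inputs here.
Global amyloid positivity is CL >= cutoff, with the default cutoff 25.11 CL
(a ROC-derived value); 20 and 40 CL are conventional sensitivity settings.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .regions import LIGANDS

#: Default global positivity cutoff on the dcCL scale.
DEFAULT_CL_CUTOFF = 25.11

#: Conventional sensitivity-analysis cutoffs ("at least moderate plaque
#: density" and "elevated amyloid").
SENSITIVITY_CL_CUTOFFS = (20.0, 40.0)


@dataclass(frozen=True)
class LigandCalibration:
    """Per-ligand dcCL anchor means (young-control and ADCI groups)."""

    ligand: str
    suvr_yc0: float
    suvr_adci100: float

    def __post_init__(self) -> None:
        if self.ligand not in LIGANDS:
            raise ValueError(f"unknown ligand {self.ligand!r}; expected one of {LIGANDS}")
        if not (self.suvr_yc0 > 0 and math.isfinite(self.suvr_yc0)):
            raise ValueError("suvr_yc0 must be finite and > 0")
        if not (self.suvr_adci100 > self.suvr_yc0 and math.isfinite(self.suvr_adci100)):
            raise ValueError("degenerate anchors: suvr_adci100 must exceed suvr_yc0")


@dataclass(frozen=True)
class GlobalThreshold:
    """Global amyloid-positivity cutoff in Centiloid units."""

    cl_cutoff: float = DEFAULT_CL_CUTOFF
    provenance: str = "configured"

    def __post_init__(self) -> None:
        if not math.isfinite(self.cl_cutoff):
            raise ValueError("cl_cutoff must be finite")
        if self.provenance not in ("configured", "roc_derived"):
            raise ValueError(f"unknown provenance {self.provenance!r}")


def suvr_to_cl(suvr, calib: LigandCalibration):
    """Affine SUVR -> Centiloid conversion; accepts scalars or arrays."""
    scale = 100.0 / (calib.suvr_adci100 - calib.suvr_yc0)
    out = (np.asarray(suvr, dtype=float) - calib.suvr_yc0) * scale
    return float(out) if np.isscalar(suvr) or out.ndim == 0 else out


def cl_to_suvr(cl, calib: LigandCalibration):
    """Inverse of :func:`suvr_to_cl`."""
    scale = (calib.suvr_adci100 - calib.suvr_yc0) / 100.0
    out = np.asarray(cl, dtype=float) * scale + calib.suvr_yc0
    return float(out) if np.isscalar(cl) or out.ndim == 0 else out


def youden_j(cl_values, truth_labels, threshold: float) -> float:
    """Sensitivity + specificity - 1 for the rule ``cl >= threshold``."""
    cl = np.asarray(cl_values, dtype=float)
    truth = np.asarray(truth_labels, dtype=bool)
    pred = cl >= threshold
    sens = np.mean(pred[truth]) if truth.any() else np.nan
    spec = np.mean(~pred[~truth]) if (~truth).any() else np.nan
    return float(sens + spec - 1.0)


def derive_cl_cutoff_roc(cl_values, truth_labels) -> GlobalThreshold:
    """ROC-optimal CL cutoff maximizing Youden's J.

    Candidate thresholds are the midpoints between consecutive distinct CL
    values (plus one below the minimum); classification is ``cl >= t`` and
    ties in J are broken toward the lower threshold.
    """
    cl = np.asarray(cl_values, dtype=float)
    truth = np.asarray(truth_labels, dtype=bool)
    if cl.shape != truth.shape or cl.ndim != 1:
        raise ValueError("cl_values and truth_labels must be equal-length 1-D")
    if truth.all() or not truth.any():
        raise ValueError("both classes must be present to derive a ROC cutoff")
    uniq = np.unique(cl)
    candidates = np.concatenate([[uniq[0] - 1.0], (uniq[:-1] + uniq[1:]) / 2.0])
    best_t, best_j = candidates[0], -np.inf
    for t in candidates:
        j = youden_j(cl, truth, t)
        if j > best_j:  # strict: ties keep the earlier (lower) threshold
            best_t, best_j = t, j
    return GlobalThreshold(float(best_t), provenance="roc_derived")


def is_global_positive(cl: float, thr: GlobalThreshold, *, inclusive: bool = True) -> bool:
    """Global positivity at the CL cutoff (boundary counted positive by default)."""
    return bool(cl >= thr.cl_cutoff) if inclusive else bool(cl > thr.cl_cutoff)
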