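"""Regional SUVR positivity cutoffs via iterative Tukey-fence outlier removal.

A cognitively unimpaired (CU) reference sample still contains amyloid-positive
individuals, so a simple upper percentile would be contaminated. The iterative
outlier method repeatedly computes the quartiles of the retained sample,
removes every value outside the Tukey inner fences
[Q1 - 1.5*IQR, Q3 + 1.5*IQR] (both tails each pass, removed values never
re-enter), and stops once no value is removed. The cutoff is then the maximum
of the outlier-free sample plus 2.5% of itself, i.e. ``max * 1.025``.

Applied per ligand and per composite region, this yields the focal-specific
SUVR positivity thresholds used by the staging step.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .regions import LIGANDS, REGIONS, RegionalProfile

#: Fewer CU values than this makes quartiles (hence fences) meaningless.
MIN_REFERENCE_N = 8

QUARTILE_METHODS = ("linear", "hinges")


def _quartiles(x: np.ndarray, method: str) -> tuple[float, float]:
    if method == "linear":
        q1, q3 = np.quantile(x, [0.25, 0.75])  # type-7 interpolation
        return float(q1), float(q3)
    if method == "hinges":
        # Tukey hinges: medians of the lower/upper halves, median included
        # in both halves when n is odd.
        s = np.sort(x)
        n = s.size
        half = (n + 1) // 2
        return float(np.median(s[:half])), float(np.median(s[n - half:]))
    raise ValueError(f"unknown quartile method {method!r}; expected {QUARTILE_METHODS}")


@dataclass(frozen=True)
class CutoffIteration:
    """One pass of the outlier loop (state before removal, then removal count)."""

    n_retained: int
    q1: float
    q3: float
    iqr: float
    lower_bound: float
    upper_bound: float
    n_removed: int


@dataclass
class CutoffTrace:
    """Full audit trail of one iterative-outlier cutoff derivation."""

    iterations: list[CutoffIteration]
    retained: np.ndarray
    final_max: float
    cutoff: float
    fence_multiplier: float = 1.5
    increment_fraction: float = 0.025
    quartile_method: str = "linear"

    def to_dict(self) -> dict:
        return {
            "iterations": [vars(it) for it in self.iterations],
            "retained_n": int(self.retained.size),
            "final_max": self.final_max,
            "cutoff": self.cutoff,
            "fence_multiplier": self.fence_multiplier,
            "increment_fraction": self.increment_fraction,
            "quartile_method": self.quartile_method,
        }


def iterative_outlier_cutoff(
    values: Sequence[float],
    fence_multiplier: float = 1.5,
    increment_fraction: float = 0.025,
    *,
    quartile_method: str = "linear",
    min_n: int = MIN_REFERENCE_N,
) -> CutoffTrace:
    """Derive a positivity cutoff from a reference sample.

    Repeats Tukey-fence removal on the retained set until no value falls
    outside the fences, then returns ``cutoff = (1 + increment_fraction) *
    max(retained)`` together with the per-iteration trace.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or x.size < min_n:
        raise ValueError(f"need at least {min_n} values in a 1-D sample, got {x.size}")
    if not np.isfinite(x).all():
        raise ValueError("values must all be finite")
    if fence_multiplier <= 0 or increment_fraction <= 0:
        raise ValueError("fence_multiplier and increment_fraction must be > 0")

    iterations: list[CutoffIteration] = []
    retained = x
    while True:
        q1, q3 = _quartiles(retained, quartile_method)
        iqr = q3 - q1
        lower = q1 - fence_multiplier * iqr
        upper = q3 + fence_multiplier * iqr
        keep = (retained >= lower) & (retained <= upper)
        n_removed = int(retained.size - keep.sum())
        iterations.append(
            CutoffIteration(int(retained.size), q1, q3, iqr, lower, upper, n_removed)
        )
        if n_removed == 0:
            break
        retained = retained[keep]
        if retained.size == 0:  # cannot occur with Tukey fences (quartiles are inside)
            raise AssertionError("outlier removal emptied the sample")

    final_max = float(retained.max())
    return CutoffTrace(
        iterations=iterations,
        retained=retained,
        final_max=final_max,
        cutoff=(1.0 + increment_fraction) * final_max,
        fence_multiplier=fence_multiplier,
        increment_fraction=increment_fraction,
        quartile_method=quartile_method,
    )


@dataclass
class RegionalCutoffs:
    """Per-ligand, per-composite-region SUVR positivity cutoffs with traces."""

    ligand: str
    per_region: dict[str, CutoffTrace]
    reference_n: int

    def __post_init__(self) -> None:
        if self.ligand not in LIGANDS:
            raise ValueError(f"unknown ligand {self.ligand!r}")
        missing = [r for r in REGIONS if r not in self.per_region]
        if missing:
            raise ValueError(f"cutoffs missing regions {missing}")
        bad = [r for r, t in self.per_region.items() if not t.cutoff > 0]
        if bad:
            raise ValueError(f"non-positive cutoffs for regions {bad}")

    def cutoff(self, region: str) -> float:
        return self.per_region[region].cutoff

    def as_series(self) -> dict[str, float]:
        return {r: self.per_region[r].cutoff for r in REGIONS}

    def to_json(self, path) -> None:
        payload = {
            "ligand": self.ligand,
            "reference_n": self.reference_n,
            "per_region": {r: t.to_dict() for r, t in self.per_region.items()},
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)


def derive_regional_cutoffs(
    cu_profiles: Sequence[RegionalProfile],
    ligand: str,
    **cutoff_kwargs,
) -> RegionalCutoffs:
    """Apply the iterative-outlier derivation to each region of a CU sample.

    All profiles must share ``ligand``; cutoffs are ligand-specific because
    the SUVR dynamic range differs between tracers.
    """
    if ligand not in LIGANDS:
        raise ValueError(f"unknown ligand {ligand!r}")
    mixed = sorted({p.ligand for p in cu_profiles} - {ligand})
    if mixed:
        raise ValueError(f"profiles with ligand(s) {mixed} passed to {ligand} derivation")
    if not cu_profiles:
        raise ValueError("no reference profiles supplied")
    per_region = {
        region: iterative_outlier_cutoff(
            [p.region_suvr[region] for p in cu_profiles], **cutoff_kwargs
        )
        for region in REGIONS
    }
    return RegionalCutoffs(ligand, per_region, reference_n=len(cu_profiles))
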