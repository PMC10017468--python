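"""Synthetic two-ligand amyloid-PET cohorts with planted group structure.

The generator emulates the statistical structure the staging pipeline
assumes, so every stage can be exercised end to end without clinical data:

* a cognitive-continuum cohort (CU / aMCI / dementia) scanned with one of
  two tracers (FBB or FMM), FBB having the higher baseline cortical SUVR;
* a latent amyloid state per participant -- none, focal (1-2 involved lobes
  with subthreshold global burden) or global-positive (a single severity
  factor loading onto all lobes, parietal strongest, striatum weakest) --
  drawn with diagnosis-dependent probabilities;
* regional SUVRs = ligand baseline + planted uplift + subject / lobe /
  hemisphere Gaussian noise, with the global SUVR the volume-weighted mean
  of the cortical regions;
* anchor samples (young controls and ADCI patients) whose means define the
  per-ligand dcCL calibration self-consistently;
* cognitive and morphometric outcomes (MMSE, SVLT delayed recall,
  hippocampal volume, ICV, AD-ROI cortical thickness) with planted
  group-level differences and an age confound, plus APOE4, sex, education
  and a visual-read field sampled per group.

Focal lobe patterns are allocated by largest-remainder rounding of the
calibrated pattern distribution (then randomly assigned), so the cohort
realizes its configured involvement frequencies -- with their ordering
parietal > frontal ~ temporal > cingulate > striatum -- at any seed.
Striatum-only patterns are excluded: striatal amyloid follows cortical
involvement, it does not lead it.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from functools import lru_cache

import numpy as np
import pandas as pd

from .centiloid import DEFAULT_CL_CUTOFF, GlobalThreshold, LigandCalibration
from .cutoffs import RegionalCutoffs, derive_regional_cutoffs
from .regions import (
    CORTICAL_LOBES,
    HEMISPHERES,
    LIGANDS,
    LOBES,
    REGIONS,
    RegionalProfile,
)
from .staging import StagingResult, stage_cohort

DIAGNOSES = ("CU", "aMCI", "dementia")

#: Relative volume of each cortical lobe within the global cortical target
#: (AAL-like proportions; each hemisphere carries half the lobe weight).
CORTICAL_LOBE_WEIGHTS = {
    "frontal": 0.34,
    "parietal": 0.27,
    "lateral_temporal": 0.26,
    "cingulate": 0.13,
}

#: Reference age used as the centering point of the planted age slopes.
AGE_CENTER = 71.6


@dataclass(frozen=True)
class OutcomeSpec:
    """Planted per-group means, noise SD, score bounds and age slope."""

    means: tuple[float, float, float]  # G-F-, G-F+, G+
    sd: float
    bounds: tuple[float, float] | None = None
    age_slope: float = 0.0


def _default_outcomes() -> dict[str, OutcomeSpec]:
    return {
        "mmse": OutcomeSpec((26.5, 24.5, 22.5), 4.5, (0.0, 30.0), -0.08),
        "svlt": OutcomeSpec((6.5, 4.5, 2.5), 2.5, (0.0, 12.0), -0.05),
        "hippocampal_volume": OutcomeSpec((3400.0, 3150.0, 2900.0), 450.0, None, -15.0),
        "icv": OutcomeSpec((1.45e6, 1.45e6, 1.45e6), 1.5e5, None, 0.0),
        "ad_roi_thickness": OutcomeSpec((3.05, 2.95, 2.75), 0.18, None, -0.005),
    }


@dataclass
class GeneratorConfig:
    """Study conditions of the synthetic cohort.

    Defaults reproduce the published cohort's composition: 968-scale
    diagnosis mix, per-diagnosis global-positivity gradient, the
    focal-positive share among global-negatives, lobar involvement
    proportions, and Table-2-style covariate distributions.
    """

    n_participants: int = 900
    seed: int = 42
    ligand_split: float = 0.515  # fraction FBB (498/968)
    diagnosis_mix: dict[str, float] = field(
        default_factory=lambda: {"CU": 0.236, "aMCI": 0.413, "dementia": 0.351}
    )
    g_plus_prob: dict[str, float] = field(
        default_factory=lambda: {"CU": 0.206, "aMCI": 0.568, "dementia": 0.847}
    )
    focal_prob_given_gneg: dict[str, float] = field(
        default_factory=lambda: {"CU": 0.088, "aMCI": 0.185, "dementia": 0.269}
    )
    # (baseline SUVR mean, total per-region SD); FBB baseline > FMM baseline
    ligand_scale: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {"FBB": (1.20, 0.046), "FMM": (1.10, 0.046)}
    )
    lobe_involvement_props: dict[str, float] = field(
        default_factory=lambda: {
            "parietal": 0.388,
            "frontal": 0.325,
            "lateral_temporal": 0.324,
            "cingulate": 0.261,
            "striatum": 0.130,
        }
    )
    focal_bilateral_prob: float = 0.7
    focal_cl_range: tuple[float, float] = (8.0, 20.0)
    focal_uplift_bounds: tuple[float, float] = (0.25, 0.55)
    #: Global-positive severity (floor, folded-normal mean, sd) by diagnosis.
    #: CU positives are early accumulators: a low graded continuum rather
    #: than the established burden of impaired positives.
    gplus_severity_by_diagnosis: dict[str, tuple[float, float, float]] = field(
        default_factory=lambda: {
            "CU": (0.18, 0.12, 0.12),
            "aMCI": (0.32, 0.18, 0.12),
            "dementia": (0.35, 0.25, 0.12),
        }
    )
    lobe_loadings: dict[str, float] = field(
        default_factory=lambda: {
            "parietal": 1.00,
            "frontal": 0.96,
            "lateral_temporal": 0.95,
            "cingulate": 0.90,
            "striatum": 0.60,
        }
    )
    #: Size of the dedicated CU reference sample used for cutoff derivation
    #: (split across ligands by ``ligand_split``).
    cu_reference_n: int = 445
    anchor_n: int = 20
    anchor_uplift: float = 1.0  # ADCI anchor mean SUVR sits this far above baseline
    anchor_sd: tuple[float, float] = (0.03, 0.08)  # young-control, ADCI
    effect_sizes: dict[str, OutcomeSpec] = field(default_factory=_default_outcomes)
    age_by_group: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "G-F-": (70.9, 8.1), "G-F+": (74.9, 6.6), "G+": (71.6, 8.3)
        }
    )
    female_prob: dict[str, float] = field(
        default_factory=lambda: {"G-F-": 0.506, "G-F+": 0.516, "G+": 0.587}
    )
    education_by_group: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "G-F-": (12.0, 4.9), "G-F+": (11.5, 5.4), "G+": (11.5, 4.8)
        }
    )
    apoe_freq_by_group: dict[str, float] = field(
        default_factory=lambda: {"G-F-": 0.158, "G-F+": 0.327, "G+": 0.605}
    )
    visual_read_prob: dict[str, float] = field(
        default_factory=lambda: {"G-F-": 0.041, "G-F+": 0.129, "G+": 0.931}
    )

    def __post_init__(self) -> None:
        if self.n_participants < 0:
            raise ValueError("n_participants must be >= 0")
        if not 0.0 <= self.ligand_split <= 1.0:
            raise ValueError("ligand_split must be in [0, 1]")
        for name, probs in (("diagnosis_mix", self.diagnosis_mix),):
            if abs(sum(probs.values()) - 1.0) > 1e-8:
                raise ValueError(f"{name} must sum to 1")
            if any(p < 0 for p in probs.values()):
                raise ValueError(f"{name} contains negative probabilities")
        for name, probs in (
            ("g_plus_prob", self.g_plus_prob),
            ("focal_prob_given_gneg", self.focal_prob_given_gneg),
            ("lobe_involvement_props", self.lobe_involvement_props),
            ("female_prob", self.female_prob),
            ("apoe_freq_by_group", self.apoe_freq_by_group),
            ("visual_read_prob", self.visual_read_prob),
        ):
            if any(not 0.0 <= p <= 1.0 for p in probs.values()):
                raise ValueError(f"{name} values must be in [0, 1]")
        for lig, (mean, sd) in self.ligand_scale.items():
            if lig not in LIGANDS:
                raise ValueError(f"unknown ligand {lig!r}")
            if mean <= 0 or sd <= 0:
                raise ValueError("ligand baselines and SDs must be > 0")
        if self.ligand_scale["FBB"][0] <= self.ligand_scale["FMM"][0]:
            raise ValueError("FBB baseline SUVR must exceed FMM baseline")
        if any(spec.sd <= 0 for spec in self.effect_sizes.values()):
            raise ValueError("outcome SDs must be > 0")

    def with_null_effects(self) -> "GeneratorConfig":
        """Copy with all planted group differences on outcomes removed.

        Each outcome keeps its marginal location, noise and age slope, but
        the three group means are equalized (to their unweighted mean), so
        any residual group association runs only through the age confound.
        """
        nulled = {
            name: replace(spec, means=(float(np.mean(spec.means)),) * 3)
            for name, spec in self.effect_sizes.items()
        }
        return replace(self, effect_sizes=nulled)


# ---------------------------------------------------------------------------
# Focal lobe-pattern calibration

#: Allowed focal patterns: single cortical lobes and all lobe pairs.
#: Striatum never appears alone (cortex-first spreading).
_FOCAL_PATTERNS: tuple[frozenset[str], ...] = tuple(
    [frozenset({lobe}) for lobe in CORTICAL_LOBES]
    + [frozenset(pair) for pair in itertools.combinations(LOBES, 2)]
)


@lru_cache(maxsize=8)
def _calibrate_focal_patterns(props_key: tuple[tuple[str, float], ...]) -> np.ndarray:
    """Pattern probabilities whose marginals match the target lobe proportions.

    Models lobe involvement as independent Bernoulli(q) restricted to the
    allowed patterns and solves for q by fixed-point iteration so that the
    restricted per-lobe marginals equal the configured proportions.
    """
    props = dict(props_key)
    target = np.array([props[lobe] for lobe in LOBES])
    q = target.copy()
    lobe_idx = {lobe: i for i, lobe in enumerate(LOBES)}
    membership = np.zeros((len(_FOCAL_PATTERNS), len(LOBES)))
    for p, pattern in enumerate(_FOCAL_PATTERNS):
        for lobe in pattern:
            membership[p, lobe_idx[lobe]] = 1.0

    for _ in range(500):
        # P(pattern) under independent Bernoulli(q), restricted + normalized
        raw = np.array(
            [
                np.prod(np.where(membership[p] > 0, q, 1.0 - q))
                for p in range(len(_FOCAL_PATTERNS))
            ]
        )
        pi = raw / raw.sum()
        marginal = membership.T @ pi
        if np.allclose(marginal, target, atol=1e-10):
            break
        q = np.clip(q * target / np.maximum(marginal, 1e-12), 1e-6, 1 - 1e-6)
    return pi


def _largest_remainder_counts(pi: np.ndarray, n: int) -> np.ndarray:
    """Integer allocation of n items to probabilities pi, sum preserved."""
    quota = pi * n
    counts = np.floor(quota).astype(int)
    short = n - counts.sum()
    if short > 0:
        order = np.argsort(-(quota - counts))
        counts[order[:short]] += 1
    return counts


# ---------------------------------------------------------------------------
# Cohort generation


@dataclass
class SyntheticCohort:
    """Generated cohort: covariate table, profiles, and hidden ground truth.

    ``truth`` (latent group, burden, planted lobe count) is ground truth for
    validation only and must not feed the staging pipeline.
    """

    cohort: pd.DataFrame
    profiles: list[RegionalProfile]
    truth: pd.DataFrame
    config: GeneratorConfig


def _truncated_normal(rng, mean, sd, lo, hi, size):
    mean = np.broadcast_to(np.asarray(mean, dtype=float), (size,))
    sd = np.broadcast_to(np.asarray(sd, dtype=float), (size,))
    out = rng.normal(mean, sd)
    bad = (out < lo) | (out > hi)
    while bad.any():  # redraw; bounds are several SDs out, so this is quick
        out[bad] = rng.normal(mean[bad], sd[bad])
        bad = (out < lo) | (out > hi)
    return out


def generate_cohort(config: GeneratorConfig | None = None) -> SyntheticCohort:
    """Generate a cohort deterministically from ``config.seed``."""
    cfg = config or GeneratorConfig()
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_participants

    region_lobe = np.array([r.rsplit("_", 1)[0] for r in REGIONS])
    lobe_of_region = {r: r.rsplit("_", 1)[0] for r in REGIONS}
    # Weight of each cortical region inside the global cortical target.
    w_region = np.array(
        [
            CORTICAL_LOBE_WEIGHTS.get(lobe_of_region[r], 0.0) / 2.0
            for r in REGIONS
        ]
    )

    if n == 0:
        cohort = pd.DataFrame(
            columns=["participant_id", "ligand", "diagnosis", "age", "sex",
                     "education", "apoe4", "mmse", "svlt", "hippocampal_volume",
                     "icv", "ad_roi_thickness", "visual_read"]
        )
        truth = pd.DataFrame(columns=["participant_id", "true_group",
                                      "latent_burden", "n_lobes_planted"])
        return SyntheticCohort(cohort, [], truth, cfg)

    pid = np.array([f"sub-{i:04d}" for i in range(n)])
    diagnosis = rng.choice(
        DIAGNOSES, size=n, p=[cfg.diagnosis_mix[d] for d in DIAGNOSES]
    )
    ligand = np.where(rng.random(n) < cfg.ligand_split, "FBB", "FMM")

    # Latent amyloid group with diagnosis-dependent probabilities.
    p_gplus = np.array([cfg.g_plus_prob[d] for d in diagnosis])
    p_focal = np.array([cfg.focal_prob_given_gneg[d] for d in diagnosis])
    u = rng.random(n)
    is_gplus = u < p_gplus
    is_focal = ~is_gplus & (rng.random(n) < p_focal)
    true_group = np.where(is_gplus, "G+", np.where(is_focal, "G-F+", "G-F-"))

    # --- regional uplift ----------------------------------------------------
    uplift = np.zeros((n, len(REGIONS)))
    latent_burden = np.zeros(n)
    n_lobes_planted = np.zeros(n, dtype=int)
    loadings = np.array([cfg.lobe_loadings[lobe] for lobe in region_lobe])

    # Global-positives: one severity factor loading onto every lobe.
    gp = np.flatnonzero(is_gplus)
    sev_params = np.array(
        [cfg.gplus_severity_by_diagnosis[d] for d in diagnosis[gp]]
    ).reshape(-1, 3)
    severity = sev_params[:, 0] + np.abs(
        rng.normal(sev_params[:, 1], sev_params[:, 2])
    )
    uplift[gp] = severity[:, None] * loadings[None, :]
    latent_burden[gp] = severity
    n_lobes_planted[gp] = len(LOBES)

    # Focal subjects: calibrated lobe patterns, subthreshold global burden.
    fc = np.flatnonzero(is_focal)
    if fc.size:
        pi = _calibrate_focal_patterns(
            tuple(sorted(cfg.lobe_involvement_props.items()))
        )
        counts = _largest_remainder_counts(pi, fc.size)
        pattern_ids = rng.permutation(np.repeat(np.arange(len(_FOCAL_PATTERNS)), counts))
        target_cl = rng.uniform(*cfg.focal_cl_range, size=fc.size)
        lo_up, hi_up = cfg.focal_uplift_bounds
        region_index = {r: j for j, r in enumerate(REGIONS)}
        for k, i in enumerate(fc):
            pattern = _FOCAL_PATTERNS[pattern_ids[k]]
            involved: list[str] = []
            for lobe in pattern:
                if rng.random() < cfg.focal_bilateral_prob:
                    involved += [f"{lobe}_left", f"{lobe}_right"]
                else:
                    involved.append(f"{lobe}_{HEMISPHERES[rng.integers(2)]}")
            w_cort = sum(w_region[region_index[r]] for r in involved)
            # Uplift sized so the global CL lands near its subthreshold target.
            delta = float(
                np.clip(target_cl[k] / 100.0 * cfg.anchor_uplift / max(w_cort, 1e-9),
                        lo_up, hi_up)
            )
            for r in involved:
                uplift[i, region_index[r]] = delta
            latent_burden[i] = delta * w_cort / cfg.anchor_uplift
            n_lobes_planted[i] = len(pattern)

    # --- SUVR synthesis -----------------------------------------------------
    baseline = np.array([cfg.ligand_scale[l][0] for l in ligand])
    total_sd = np.array([cfg.ligand_scale[l][1] for l in ligand])
    # Split the configured per-region SD into subject- (diffuse), lobe- and
    # hemisphere-level components (shares 0.65/0.54/0.54 in SD units).
    sd_subject, sd_lobe, sd_hemi = (
        0.65 * total_sd, 0.54 * total_sd, 0.54 * total_sd
    )
    subject_shift = rng.normal(0.0, 1.0, size=n) * sd_subject
    lobe_noise = rng.normal(0.0, 1.0, size=(n, len(LOBES))) * sd_lobe[:, None]
    hemi_noise = rng.normal(0.0, 1.0, size=(n, len(REGIONS))) * sd_hemi[:, None]
    lobe_pos = {lobe: i for i, lobe in enumerate(LOBES)}
    lobe_expand = np.array([lobe_pos[lobe] for lobe in region_lobe])

    suvr = (
        baseline[:, None]
        + subject_shift[:, None]
        + lobe_noise[:, lobe_expand]
        + hemi_noise
        + uplift
    )
    np.clip(suvr, 0.01, None, out=suvr)
    global_suvr = suvr @ w_region  # striatal weights are zero

    profiles = [
        RegionalProfile(
            participant_id=pid[i],
            ligand=str(ligand[i]),
            region_suvr={r: float(suvr[i, j]) for j, r in enumerate(REGIONS)},
            global_suvr=float(global_suvr[i]),
        )
        for i in range(n)
    ]

    # --- covariates and outcomes -------------------------------------------
    group_idx = {g: k for k, g in enumerate(("G-F-", "G-F+", "G+"))}
    gidx = np.array([group_idx[g] for g in true_group])

    age_mean = np.array([cfg.age_by_group[g][0] for g in true_group])
    age_sd = np.array([cfg.age_by_group[g][1] for g in true_group])
    age = _truncated_normal(rng, age_mean, age_sd, 55.0, 95.0, n)
    sex = np.where(
        rng.random(n) < np.array([cfg.female_prob[g] for g in true_group]), "F", "M"
    )
    edu_mean = np.array([cfg.education_by_group[g][0] for g in true_group])
    edu_sd = np.array([cfg.education_by_group[g][1] for g in true_group])
    education = np.round(_truncated_normal(rng, edu_mean, edu_sd, 0.0, 22.0, n))
    apoe4 = (
        rng.random(n) < np.array([cfg.apoe_freq_by_group[g] for g in true_group])
    ).astype(int)
    visual_read = (
        rng.random(n) < np.array([cfg.visual_read_prob[g] for g in true_group])
    ).astype(int)

    columns = {
        "participant_id": pid,
        "ligand": ligand,
        "diagnosis": diagnosis,
        "age": age,
        "sex": sex,
        "education": education,
        "apoe4": apoe4,
    }
    for name, spec in cfg.effect_sizes.items():
        means = np.array(spec.means)[gidx]
        vals = means + spec.age_slope * (age - AGE_CENTER) + rng.normal(0, spec.sd, n)
        if spec.bounds is not None:
            vals = np.clip(vals, *spec.bounds)
        columns[name] = vals
    columns["visual_read"] = visual_read

    cohort = pd.DataFrame(columns)
    truth = pd.DataFrame(
        {
            "participant_id": pid,
            "true_group": true_group,
            "latent_burden": latent_burden,
            "n_lobes_planted": n_lobes_planted,
        }
    )
    return SyntheticCohort(cohort, profiles, truth, cfg)


# ---------------------------------------------------------------------------
# Anchors and end-to-end convenience


@dataclass(frozen=True)
class AnchorSet:
    """Per-ligand anchor SUVR samples (young controls and ADCI patients)."""

    ligand: str
    young_control: np.ndarray
    adci: np.ndarray


def generate_anchor_sets(
    config: GeneratorConfig | None = None,
    *,
    anchor_sd_scale: float = 1.0,
    seed: int | None = None,
) -> dict[str, AnchorSet]:
    """Anchor samples per ligand; their means define the dcCL calibration.

    ``anchor_sd_scale`` rescales both anchor SDs (used by stability checks);
    ``seed`` overrides the anchor stream seed (default ``config.seed + 1``).
    """
    cfg = config or GeneratorConfig()
    rng = np.random.default_rng(cfg.seed + 1 if seed is None else seed)
    sd_yc, sd_adci = (s * anchor_sd_scale for s in cfg.anchor_sd)
    out = {}
    for lig in LIGANDS:
        base = cfg.ligand_scale[lig][0]
        yc = rng.normal(base, sd_yc, size=cfg.anchor_n)
        adci = rng.normal(base + cfg.anchor_uplift, sd_adci, size=cfg.anchor_n)
        out[lig] = AnchorSet(lig, yc, adci)
    return out


def calibration_from_anchors(anchors: AnchorSet) -> LigandCalibration:
    """dcCL calibration from anchor sample means (YC mean -> 0, ADCI -> 100)."""
    return LigandCalibration(
        anchors.ligand,
        float(np.mean(anchors.young_control)),
        float(np.mean(anchors.adci)),
    )


@dataclass
class StagedCohort:
    """A generated cohort run through the full staging pipeline."""

    sim: SyntheticCohort
    cutoffs_by_ligand: dict[str, RegionalCutoffs]
    calibs_by_ligand: dict[str, LigandCalibration]
    threshold: GlobalThreshold
    results: list[StagingResult]
    summary: dict[str, int]

    def table(self) -> pd.DataFrame:
        """Cohort covariates joined to staging results (a CohortTable)."""
        from .staging import staging_to_frame

        staged = staging_to_frame(self.results)
        return self.sim.cohort.merge(
            staged.drop(columns=["ligand"]), on="participant_id", validate="1:1"
        )


def make_cu_reference(
    config: GeneratorConfig | None = None,
    *,
    n: int | None = None,
    seed: int | None = None,
) -> SyntheticCohort:
    """A dedicated cognitively-unimpaired reference sample for cutoffs.

    Mirrors deriving thresholds from a standalone CU pool (445 subjects by
    default, split across both ligands) rather than from the study cohort
    itself. The reference keeps the configured CU amyloid-positivity rates:
    amyloid-positive CU are present, and removing them is the iterative
    outlier step's job.
    """
    cfg = config or GeneratorConfig()
    ref_cfg = replace(
        cfg,
        n_participants=cfg.cu_reference_n if n is None else n,
        seed=(cfg.seed + 2) if seed is None else seed,
        diagnosis_mix={"CU": 1.0, "aMCI": 0.0, "dementia": 0.0},
    )
    return generate_cohort(ref_cfg)


def stage_generated_cohort(
    sim: SyntheticCohort,
    cl_cutoff: float = DEFAULT_CL_CUTOFF,
    cu_reference: SyntheticCohort | None = None,
    **classify_kwargs,
) -> StagedCohort:
    """Run the staging pipeline on a generated cohort, as a study would.

    Regional cutoffs are derived per ligand from a dedicated CU reference
    sample (default: :func:`make_cu_reference` under the cohort's own
    config), and the dcCL calibration comes from the generator's anchor
    samples.
    """
    ref = cu_reference or make_cu_reference(sim.config)
    cutoffs_by_ligand = {
        lig: derive_regional_cutoffs(
            [p for p in ref.profiles if p.ligand == lig], lig
        )
        for lig in LIGANDS
    }
    calibs_by_ligand = {
        lig: calibration_from_anchors(a)
        for lig, a in generate_anchor_sets(sim.config).items()
    }
    thr = GlobalThreshold(cl_cutoff)
    results, summary = stage_cohort(
        sim.profiles, cutoffs_by_ligand, calibs_by_ligand, thr, **classify_kwargs
    )
    return StagedCohort(sim, cutoffs_by_ligand, calibs_by_ligand, thr, results, summary)
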