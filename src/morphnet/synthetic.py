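"""Synthetic cohorts: vertex-wise morphometry, covariates, behaviors.

The generator emulates what the method consumes, not cortical geometry:
each parcel is a bag of vertex values drawn from a positive distribution
(log-normal for volume and area, which are right-skewed; zero-truncated
normal for thickness).  Parcel pairs listed in the similarity plant share
a distribution template, so their histogram similarity is high by
construction; every parcel additionally gets multiplicative per-subject
jitter so matrices differ across subjects.

Behaviors follow the interaction model forward: covariates are drawn in
natural units (age uniform over 18-64 years, balanced sex, education and
intracranial volume from normals), network efficiency is computed by
RUNNING the real similarity / OMST / efficiency pipeline on the synthetic
morphometry, and the behavior is the linear combination of z-scored
variables plus the age x efficiency interaction plus Gaussian noise.

The default cohort is at desk-realistic adult-lifespan scale: 65 subjects
aged 18-64, the 32-parcel parcellation with its reference vertex counts
(every parcel >= 50 vertices), 30 histogram bins.  Default coefficients are on
the standardized scale and sized so the behavior has unit variance with
roughly half of it explained (R^2 ~ 0.47), making planted and fitted
standardized coefficients directly comparable.

``simulate_glm_cohort`` is a lightweight sibling for calibrating the
regression stage alone: efficiency is drawn directly as a standard normal
instead of being computed from images.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats as sps

from morphnet.efficiency import efficiency_profile
from morphnet.morphometry_io import Parcellation, SubjectMorphometry, filter_parcels
from morphnet.omst import absolutize, omst_select
from morphnet.similarity import build_similarity_matrix

# The 32-parcel functional parcellation surviving the 50-vertex filter,
# with per-parcel vertex counts on the fsaverage5 surface.
DEFAULT_PARCELS: tuple[tuple[str, int], ...] = (
    ("Vis(lh)", 1213),
    ("SomMot(lh)", 1590),
    ("DorsAttn_Post(lh)", 627),
    ("DorsAttn_FEF(lh)", 97),
    ("SalVentAttn_ParOper(lh)", 130),
    ("SalVentAttn_FrOper(lh)", 331),
    ("SalVentAttn_Med(lh)", 216),
    ("Limbic_OFC(lh)", 213),
    ("Limbic_TempPole(lh)", 331),
    ("Cont_Par(lh)", 151),
    ("Cont_PFCl(lh)", 291),
    ("Default_Par(lh)", 263),
    ("Default_Temp(lh)", 359),
    ("Default_PFC(lh)", 771),
    ("Default_PCC(lh)", 281),
    ("Vis(rh)", 1266),
    ("SomMot(rh)", 1612),
    ("DorsAttn_Post(rh)", 614),
    ("DorsAttn_FEF(rh)", 98),
    ("DorsAttn_PrCv(rh)", 50),
    ("SalVentAttn_TempOccPar(rh)", 208),
    ("SalVentAttn_FrOper(rh)", 313),
    ("SalVentAttn_Med(rh)", 242),
    ("Limbic_OFC(rh)", 237),
    ("Limbic_TempPole(rh)", 321),
    ("Cont_Par(rh)", 167),
    ("Cont_PFCl(rh)", 543),
    ("Default_Par(rh)", 183),
    ("Default_Temp(rh)", 269),
    ("Default_PFCv(rh)", 60),
    ("Default_PFCm(rh)", 461),
    ("Default_PCC(rh)", 225),
)

MEASURE_FAMILIES = {"volume": "lognormal", "area": "lognormal", "thickness": "truncnorm"}

# Per-vertex base scales: volume mm^3, area mm^2, thickness mm.  Volumes
# around 5-66 mm^3 per vertex, area around 9 mm^2 (a coarse standard
# surface vertex covers several mm^2), thickness around 2.5 mm.
_BASE_LOC = {"volume": np.log(25.0), "area": np.log(9.0), "thickness": 2.5}
_BASE_SCALE = {"volume": 0.40, "area": 0.30, "thickness": 0.50}


@dataclass(frozen=True)
class ParcelDistributionSpec:
    """Vertex-value distribution of one parcel, per measure.

    ``loc``/``scale`` are log-space mean/sd for log-normal measures and
    natural-unit mean/sd for the truncated normal.
    """

    label: str
    n_vertices: int
    loc: dict[str, float]
    scale: dict[str, float]

    def __post_init__(self) -> None:
        if self.n_vertices < 1:
            raise ValueError(f"{self.label}: n_vertices must be >= 1")
        for m, s in self.scale.items():
            if s <= 0:
                raise ValueError(f"{self.label}: scale for {m} must be > 0")


@dataclass(frozen=True)
class GlmCoefficients:
    """Forward-model coefficients on the standardized-variable scale."""

    age: float = 0.35
    eff: float = 0.30
    sex: float = 0.30
    edu: float = 0.25
    icv: float = 0.15
    morph_global: float = 0.15
    interaction: float = 0.35  # beta: the age x efficiency term
    intercept: float = 0.0


# Sum of squared coefficient contributions ~0.465 with unit-variance
# predictors; noise sd sqrt(1 - 0.465) puts Var(beh) at 1 and R^2 near 0.5.
DEFAULT_NOISE_SD = float(np.sqrt(1.0 - 0.465))


@dataclass(frozen=True)
class CohortSpec:
    """Everything needed to draw a cohort deterministically."""

    n_subjects: int = 65
    parcels: tuple[ParcelDistributionSpec, ...] = ()
    planted_pairs: tuple[tuple[str, str], ...] = ()
    age_range: tuple[float, float] = (18.0, 64.0)
    education_mean: float = 15.4
    education_sd: float = 3.2
    icv_mean: float = 1.45e6
    icv_sd: float = 1.5e5
    subject_jitter_sd: float = 0.05
    behaviors: tuple[tuple[str, GlmCoefficients], ...] = (
        ("beh", GlmCoefficients()),
        ("beh_null", GlmCoefficients(interaction=0.0)),
    )
    noise_sd: float = DEFAULT_NOISE_SD
    seed: int = 0


def default_cohort_spec(
    seed: int = 0,
    n_subjects: int = 65,
    parcels: tuple[tuple[str, int], ...] = DEFAULT_PARCELS,
    planted_pairs: tuple[tuple[str, str], ...] = (("Vis(lh)", "Vis(rh)"),),
    **overrides,
) -> CohortSpec:
    """Build a cohort spec with per-parcel distribution parameters.

    Each parcel's location/scale are drawn once (from ``seed``) around the
    base per-vertex values, so parcels differ from one another; parcels in
    ``planted_pairs`` copy the first member's parameters, so their
    distributions — and hence their histogram similarity — coincide up to
    subject jitter and sampling noise.
    """
    rng = np.random.default_rng([seed, 2**20])
    specs: dict[str, ParcelDistributionSpec] = {}
    for label, n_vertices in parcels:
        loc = {}
        scale = {}
        for m in ("volume", "area", "thickness"):
            spread = 0.25 if m != "thickness" else 0.15
            loc[m] = _BASE_LOC[m] + rng.normal(0.0, spread)
            scale[m] = _BASE_SCALE[m] * float(np.exp(rng.normal(0.0, 0.2)))
        specs[label] = ParcelDistributionSpec(label, n_vertices, loc, scale)
    labels = set(specs)
    for a, b in planted_pairs:
        if a not in labels or b not in labels:
            raise ValueError(f"planted pair ({a}, {b}) references unknown parcel")
        specs[b] = replace(specs[b], loc=dict(specs[a].loc), scale=dict(specs[a].scale))
    return CohortSpec(
        n_subjects=n_subjects,
        parcels=tuple(specs[label] for label, _n in parcels),
        planted_pairs=tuple(planted_pairs),
        seed=seed,
        **overrides,
    )


def _draw_values(
    family: str, loc: float, scale: float, n: int, rng: np.random.Generator
) -> np.ndarray:
    if family == "lognormal":
        return rng.lognormal(mean=loc, sigma=scale, size=n)
    if family == "truncnorm":
        a = (0.0 - loc) / scale  # truncate at zero
        return sps.truncnorm.rvs(a, np.inf, loc=loc, scale=scale, size=n, random_state=rng)
    raise ValueError(f"unknown distribution family {family!r}")


def simulate_subject_morphometry(spec: CohortSpec, subject_index: int) -> SubjectMorphometry:
    """Draw one subject's vertex values; deterministic in (seed, index)."""
    rng = np.random.default_rng([spec.seed, subject_index])
    values: dict[str, dict[str, np.ndarray]] = {}
    for ps in spec.parcels:
        per_measure = {}
        for m, family in MEASURE_FAMILIES.items():
            jitter = rng.normal(0.0, spec.subject_jitter_sd)
            loc = ps.loc[m] + jitter  # log-space shift == multiplicative jitter
            per_measure[m] = _draw_values(family, loc, ps.scale[m], ps.n_vertices, rng)
        values[ps.label] = per_measure
    labels = tuple(ps.label for ps in spec.parcels)
    return SubjectMorphometry(
        subject_id=f"sub-{subject_index:03d}",
        parcellation=Parcellation(labels),
        values=values,
    )


def _zscore(x: np.ndarray) -> np.ndarray:
    return (x - x.mean()) / x.std(ddof=1)


def _forward_behavior(
    cohort: pd.DataFrame,
    eff: np.ndarray,
    coef: GlmCoefficients,
    noise_sd: float,
    rng: np.random.Generator,
) -> np.ndarray:
    signal = (
        coef.age * _zscore(cohort["age"].to_numpy())
        + coef.eff * _zscore(eff)
        + coef.sex * cohort["sex"].to_numpy()
        + coef.edu * _zscore(cohort["edu"].to_numpy())
        + coef.icv * _zscore(cohort["icv"].to_numpy())
        + coef.morph_global * _zscore(cohort["morph_global"].to_numpy())
        + coef.interaction * _zscore(cohort["age"].to_numpy()) * _zscore(eff)
        + coef.intercept
    )
    return signal + rng.normal(0.0, noise_sd, size=len(cohort))


def simulate_cohort(
    spec: CohortSpec,
    measure: str = "area",
    n_bins: int = 30,
    min_vertices: int = 50,
) -> tuple[dict[str, SubjectMorphometry], pd.DataFrame, pd.DataFrame]:
    """Draw a full cohort and push it through the real network pipeline.

    Returns (subjects, cohort table, long-format efficiency table).  The
    cohort table holds covariates, the measure-matched global morphometry
    covariate, global efficiency ``e_global``, and one column per behavior
    generated by the forward model with efficiency = the pipeline's own
    ``e_global`` output — so integration bugs surface in recovery tests.
    """
    n = spec.n_subjects
    rng = np.random.default_rng([spec.seed, 2**21])
    lo, hi = spec.age_range
    age = rng.uniform(lo, hi, size=n)
    sex = rng.permutation(np.arange(n) % 2).astype(float)
    edu = np.clip(rng.normal(spec.education_mean, spec.education_sd, size=n), 8, 22)
    icv = rng.normal(spec.icv_mean, spec.icv_sd, size=n)

    subjects: dict[str, SubjectMorphometry] = {}
    eff_frames = []
    e_global = np.empty(n)
    morph_global = np.empty(n)
    for i in range(n):
        sm = filter_parcels(simulate_subject_morphometry(spec, i), min_vertices)
        subjects[sm.subject_id] = sm
        sim = build_similarity_matrix(sm, measure, n_bins=n_bins)
        bg, _diag = omst_select(absolutize(sim))
        prof = efficiency_profile(bg, subject_id=sm.subject_id, measure=measure)
        eff_frames.append(prof.to_frame())
        e_global[i] = prof.e_global
        morph_global[i] = sm.global_summary(measure)

    cohort = pd.DataFrame(
        {
            "subject_id": list(subjects),
            "age": age,
            "sex": sex,
            "edu": edu,
            "icv": icv,
            "morph_global": morph_global,
            "e_global": e_global,
        }
    )
    noise_rng = np.random.default_rng([spec.seed, 2**22])
    for name, coef in spec.behaviors:
        cohort[name] = _forward_behavior(cohort, e_global, coef, spec.noise_sd, noise_rng)
    return subjects, cohort, pd.concat(eff_frames, ignore_index=True)


def simulate_glm_cohort(
    n: int = 65,
    coefficients: GlmCoefficients = GlmCoefficients(),
    noise_sd: float = DEFAULT_NOISE_SD,
    seed: int = 0,
    behavior: str = "beh",
    efficiency_column: str = "e_global",
) -> pd.DataFrame:
    """Cohort table for calibrating the regression stage in isolation.

    All continuous variables (including efficiency) are drawn as standard
    normals, sex as a fair binary, and the behavior from the forward model
    — no imaging stages involved.  With ``noise_sd = 0`` the behavior is
    an exact linear function of the predictors and the fit interpolates.
    """
    rng = np.random.default_rng([seed, 2**23])
    cohort = pd.DataFrame(
        {
            "subject_id": [f"sub-{i:03d}" for i in range(n)],
            "age": rng.normal(size=n),
            "sex": rng.permutation(np.arange(n) % 2).astype(float),
            "edu": rng.normal(size=n),
            "icv": rng.normal(size=n),
            "morph_global": rng.normal(size=n),
            efficiency_column: rng.normal(size=n),
        }
    )
    eff = cohort[efficiency_column].to_numpy()
    cohort[behavior] = _forward_behavior(cohort, eff, coefficients, noise_sd, rng)
    return cohort
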