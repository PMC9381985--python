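"""Seeded synthetic first-ever-ASCVD cohort generator.

The generator emulates the structure of a hospital ASCVD admission cohort
(n = 5,597; age 63.02 +/- 11.44 y; 71.34% male; observed LDL-C
2.45 +/- 0.91 mmol/L; tendon xanthomata 0.11%; therapy mix
1,947/312/3,210/128 none/low/medium/high) as a two-component mixture:

* a **background** component calibrated to the DLCN-unlikely stratum of
  such a cohort (observed LDL-C 2.23 +/- 0.70, older, premature CHD 19%,
  no tendon xanthomata), and
* a small **FH-like** component (default weight 0.05): untreated LDL-C
  mean 4.8 / SD 1.5 mmol/L, younger (mean 50 y), premature CHD near
  certain, occasional tendon xanthomata — producing the expected risk
  gradient across DLCN levels.

LDL-C is drawn on the *untreated* scale per component and the observed
admission value is then attenuated by the therapy potency's reduction
fraction, so back-correction downstream recovers the component's own
bounds. The background's untreated LDL-C is bounded at 6.4 mmol/L and it
draws no tendon xanthomata or premature arcus, so no background record can
exceed 8 DLCN points: every DLCN-definite case comes from the FH-like
component.

Family-history prevalences follow the background stratum; the FH-like
component multiplies the premature-CHD and hypercholesterolemia
family-history odds by a configurable factor (default x8).

Everything is deterministic given the seed. The mixture models marginals
and the gradient only; within-stratum correlations beyond component
membership are not modelled.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml
from scipy import stats

from .cohort import DEFAULT_LDL_REDUCTION, DLCN_PREMATURE_AGE, PatientRecord

#: therapy-potency mix of the emulated cohort (none/low/medium/high)
THERAPY_COUNTS = (1947, 312, 3210, 128)


def _odds_scale(p: float, factor: float) -> float:
    odds = p / (1.0 - p) * factor
    return odds / (1.0 + odds)


@dataclass(frozen=True)
class ComponentSpec:
    """Marginal distributions of one mixture component."""

    age_mean: float
    age_sd: float
    ldl_untreated_mean: float  # mmol/L, therapy-naive scale
    ldl_untreated_sd: float
    ldl_lo: float
    ldl_hi: float
    hdl_mean: float = 0.97
    hdl_sd: float = 0.25
    # TC = LDL(observed) + HDL + remainder, keeping TC >= LDL + HDL
    tc_remainder_mean: float = 0.72
    tc_remainder_sd: float = 0.45
    tg_mean: float = 1.7
    tg_sd: float = 1.2
    bmi_mean: float = 25.4
    bmi_sd: float = 3.3
    male_p: float = 0.7134
    smoking_p: tuple[float, float, float] = (0.4404, 0.2431, 0.3165)
    drinking_p: tuple[float, float, float] = (0.6191, 0.0661, 0.3148)
    hyperlipemia_p: float = 0.3313
    diabetes_p: float = 0.3716
    hypertension_p: float = 0.6607
    premature_chd_p: float = 0.1909
    other_chd_p: float = 0.50  # non-premature CHD, conditional on no premature event
    stroke_p: float = 0.1093
    pvd_p: float = 0.03
    fh_chd_p: float = 0.0062
    fh_hyperlipemia_p: float = 0.0108
    fh_stroke_p: float = 0.1243
    fh_xanthomata_p: float = 0.0
    tendon_xanthomata_p: float = 0.0
    arcus_p: float = 0.0


@dataclass(frozen=True)
class CohortSpec:
    """Full generator specification (see module docstring for defaults)."""

    n: int
    fh_like_weight: float
    background: ComponentSpec
    fh_like: ComponentSpec
    therapy_p: tuple[float, float, float, float]
    lp_a_mean: float = 177.79  # mg/L, log-normal moment-matched
    lp_a_sd: float = 215.07
    age_bounds: tuple[int, int] = (18, 95)
    ldl_reduction: dict = field(default_factory=lambda: dict(DEFAULT_LDL_REDUCTION))
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.fh_like_weight <= 1.0:
            raise ValueError("fh_like_weight must be in [0, 1]")
        if self.n < 0:
            raise ValueError("n must be nonnegative")
        if abs(sum(self.therapy_p) - 1.0) > 1e-9:
            raise ValueError("therapy proportions must sum to 1")


def default_spec(n: int = 5597, fh_like_weight: float = 0.05,
                 fh_history_odds_factor: float = 8.0, seed: int = 0) -> CohortSpec:
    """The calibrated default cohort specification.

    Background marginals follow the DLCN-unlikely stratum of the emulated
    cohort; its age mean (63.7) is solved from the overall target
    (0.95 * m_bg + 0.05 * 50 = 63.02). Untreated LDL means are the observed
    component means divided by the cohort-average retention factor
    E[1 - r] ~ 0.778 under the default therapy mix and reduction fractions.
    """
    background = ComponentSpec(
        age_mean=63.7, age_sd=11.0,
        ldl_untreated_mean=2.87, ldl_untreated_sd=0.90,
        ldl_lo=0.5, ldl_hi=6.4,
    )
    fh_like = ComponentSpec(
        age_mean=50.0, age_sd=11.0,
        ldl_untreated_mean=4.8, ldl_untreated_sd=1.5,
        ldl_lo=0.8, ldl_hi=12.0,
        tc_remainder_mean=0.72, tg_mean=2.0,
        hyperlipemia_p=0.44, hypertension_p=0.60,
        premature_chd_p=0.95, other_chd_p=0.02,
        stroke_p=0.10, pvd_p=0.10,
        fh_chd_p=_odds_scale(0.0062, fh_history_odds_factor),
        fh_hyperlipemia_p=_odds_scale(0.0108, fh_history_odds_factor),
        fh_xanthomata_p=0.01,
        tendon_xanthomata_p=0.02,
        arcus_p=0.05,
    )
    total = sum(THERAPY_COUNTS)
    return CohortSpec(
        n=n, fh_like_weight=fh_like_weight,
        background=background, fh_like=fh_like,
        therapy_p=tuple(c / total for c in THERAPY_COUNTS),
        seed=seed,
    )


def _trunc_normal(rng, mean, sd, lo, hi, size):
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def _lognormal_moment_matched(rng, mean, sd, size):
    sigma2 = np.log1p((sd / mean) ** 2)
    mu = np.log(mean) - sigma2 / 2.0
    return rng.lognormal(mean=mu, sigma=np.sqrt(sigma2), size=size)


_THERAPY_LEVELS = ("none", "low", "medium", "high")
_SMOKING = ("never", "ex", "current")


def _onset_premature(rng, age: int, cutoff: int) -> int | None:
    """Uniform onset strictly below the premature cutoff (and <= age)."""
    hi = min(cutoff - 1, age)
    lo = min(25, hi)
    return int(rng.integers(lo, hi + 1))


def _component_draws(rng, comp: ComponentSpec, n: int, age_bounds) -> dict:
    """Vectorized continuous draws for one mixture component."""
    lo_age, hi_age = age_bounds
    return {
        "age": _trunc_normal(rng, comp.age_mean, comp.age_sd, lo_age, hi_age, n),
        "ldl": _trunc_normal(rng, comp.ldl_untreated_mean, comp.ldl_untreated_sd,
                             comp.ldl_lo, comp.ldl_hi, n),
        "hdl": _trunc_normal(rng, comp.hdl_mean, comp.hdl_sd, 0.3, 3.0, n),
        "rem": _trunc_normal(rng, comp.tc_remainder_mean, comp.tc_remainder_sd,
                             0.05, 3.0, n),
        "tg": _trunc_normal(rng, comp.tg_mean, comp.tg_sd, 0.2, 15.0, n),
        "bmi": _trunc_normal(rng, comp.bmi_mean, comp.bmi_sd, 14.0, 50.0, n),
    }


def generate(spec: CohortSpec, seed: int | None = None) -> list[PatientRecord]:
    """Draw a cohort of validated patient records; deterministic given seed."""
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    n = spec.n
    if n == 0:
        return []
    is_fh = rng.random(n) < spec.fh_like_weight
    therapy_idx = rng.choice(4, size=n, p=spec.therapy_p)
    lp_a = _lognormal_moment_matched(rng, spec.lp_a_mean, spec.lp_a_sd, n)
    draws = {
        False: _component_draws(rng, spec.background, n, spec.age_bounds),
        True: _component_draws(rng, spec.fh_like, n, spec.age_bounds),
    }

    records: list[PatientRecord] = []
    lo_age, hi_age = spec.age_bounds
    for i in range(n):
        fh = bool(is_fh[i])
        comp = spec.fh_like if fh else spec.background
        d = draws[fh]
        sex = "male" if rng.random() < comp.male_p else "female"
        age = int(round(float(d["age"][i])))
        age = min(max(age, lo_age), hi_age)
        ldl_untreated = float(d["ldl"][i])
        therapy = _THERAPY_LEVELS[therapy_idx[i]]
        r = spec.ldl_reduction[therapy]
        ldl_obs = ldl_untreated * (1.0 - r)
        hdl = float(d["hdl"][i])
        tc = ldl_obs + hdl + float(d["rem"][i])
        tg = float(d["tg"][i])
        bmi = float(d["bmi"][i])

        cut = DLCN_PREMATURE_AGE[sex]
        chd_onset = None
        if rng.random() < comp.premature_chd_p:
            chd_onset = _onset_premature(rng, age, cut)
        elif age >= cut and rng.random() < comp.other_chd_p:
            chd_onset = int(rng.integers(cut, age + 1))
        stroke_onset = None
        if rng.random() < comp.stroke_p:
            stroke_onset = int(rng.integers(min(30, age), age + 1))
        pvd_onset = None
        if rng.random() < comp.pvd_p:
            pvd_onset = int(rng.integers(min(35, age), age + 1))

        fh_chd_onset = fh_chd_sex = None
        if rng.random() < comp.fh_chd_p:  # relative's premature CHD
            fh_chd_sex = "male" if rng.random() < 0.5 else "female"
            fh_chd_onset = _onset_premature(rng, 95, DLCN_PREMATURE_AGE[fh_chd_sex])
        fh_stroke_onset = fh_stroke_sex = None
        if rng.random() < comp.fh_stroke_p:
            fh_stroke_sex = "male" if rng.random() < 0.5 else "female"
            fh_stroke_onset = int(rng.integers(35, 85))

        records.append(PatientRecord(
            id=f"P{i:05d}",
            age=age, sex=sex, bmi=round(bmi, 1),
            smoking=_SMOKING[rng.choice(3, p=comp.smoking_p)],
            drinking=_SMOKING[rng.choice(3, p=comp.drinking_p)],
            ldl_c=round(ldl_obs, 4), hdl_c=round(hdl, 2),
            tc=round(tc, 4), tg=round(tg, 2),
            lp_a=round(float(lp_a[i]), 1),
            tendon_xanthomata=bool(rng.random() < comp.tendon_xanthomata_p),
            arcus_cornealis=bool(rng.random() < comp.arcus_p),
            chd_onset_age=chd_onset,
            stroke_onset_age=stroke_onset,
            pvd_onset_age=pvd_onset,
            hyperlipemia=bool(rng.random() < comp.hyperlipemia_p),
            diabetes=bool(rng.random() < comp.diabetes_p),
            hypertension=bool(rng.random() < comp.hypertension_p),
            therapy_level=therapy,
            fh_chd_onset_age=fh_chd_onset,
            fh_chd_relative_sex=fh_chd_sex,
            fh_stroke_onset_age=fh_stroke_onset,
            fh_stroke_relative_sex=fh_stroke_sex,
            fh_hyperlipemia=bool(rng.random() < comp.fh_hyperlipemia_p),
            fh_xanthomata=bool(rng.random() < comp.fh_xanthomata_p),
            genetic_test="not_done",
        ))
    return records


# ---------------------------------------------------------------------------
# spec serialization (shareable fixtures)

def spec_to_yaml(spec: CohortSpec, path: str | Path) -> None:
    data = dataclasses.asdict(spec)
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)


def spec_from_yaml(path: str | Path) -> CohortSpec:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    for key in ("background", "fh_like"):
        comp = data[key]
        for tup in ("smoking_p", "drinking_p"):
            comp[tup] = tuple(comp[tup])
        data[key] = ComponentSpec(**comp)
    data["therapy_p"] = tuple(data["therapy_p"])
    data["age_bounds"] = tuple(data["age_bounds"])
    return CohortSpec(**data)
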