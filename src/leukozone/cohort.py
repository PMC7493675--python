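"""Two-group synthetic cohorts with planted statistical structure.

The ``"pilot"`` preset emulates a pilot cohort of older adults with
atrial fibrillation (AF, n = 17) and demographically matched non-AF
peers (n = 17): per-zone leukoaraiosis fractions with group means of
15.6 vs 10.8 % (periventricular), 2.1 vs 0.6 % (deep) and 0.72 vs
0.07 % (infracortical); head-size (TICV) variation; lobe cortical
thickness with a planted negative partial correlation (controlling
TICV) between temporal thickness and log total LA; strokes and lacunae
present only in the AF arm; and matched demographics.

Per-subject zone fractions are log-normal multipliers of the group mean
(LA loads are strongly right-skewed), **normalized to unit sample mean
within each group and zone** so that each arm's sample mean equals its
preset mean exactly. The cohort thus embodies the stated group-level
conditions, while between-subject dispersion remains log-normal; with
dispersion -> 0 every subject sits at the group mean.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from functools import lru_cache

import numpy as np
import pandas as pd

from .phantom import PhantomSpec, make_label_volume
from .zoning import ZoneParams, ZoneSet, zone_partition

ZONES = ("periventricular", "deep", "infracortical")


@dataclass
class GroupSpec:
    """One arm of the cohort."""

    name: str
    n: int
    zone_means_pct: dict[str, float]  # mean planted % of zonal WM per depth zone
    ticv_mean_mm3: float
    ticv_sd_mm3: float
    n_with_stroke: int = 0
    stroke_volume_mean_ml: float = 0.0
    n_with_lacunae: int = 0
    lacunae_volume_mean_ml: float = 0.0
    age_mean: float = 68.0
    age_sd: float = 6.0
    education_mean: float = 14.0
    education_sd: float = 2.5
    moca_mean: float = 26.0
    moca_sd: float = 2.5
    wtar_mean: float = 38.0
    wtar_sd: float = 9.0
    charlson_mean: float = 1.0
    charlson_sd: float = 0.7
    n_male: int | None = None  # defaults to ~2/3 of n

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("group size must be >= 2")
        if self.ticv_sd_mm3 <= 0:
            raise ValueError("TICV dispersion must be positive")


@dataclass
class CohortSpec:
    """Cohort-level generation parameters."""

    groups: tuple[GroupSpec, ...]
    zone_cv: float = 0.5  # log-normal coefficient of variation of per-subject fractions
    match_group_means: bool = True
    thickness_means_mm: dict[str, float] = field(
        default_factory=lambda: {"frontal": 2.55, "parietal": 2.35, "temporal": 2.75, "occipital": 2.10}
    )
    thickness_sd_mm: float = 0.12
    #: planted partial correlation (controlling TICV) between each lobe's
    #: thickness and log total LA
    thickness_partial_r: dict[str, float] = field(
        default_factory=lambda: {"frontal": 0.0, "parietal": 0.0, "temporal": -0.37, "occipital": 0.0}
    )
    ticv_thickness_r: float = 0.2  # mild head-size effect on thickness
    phantom: PhantomSpec = field(default_factory=PhantomSpec)
    zone_params: ZoneParams = field(default_factory=ZoneParams)

    def __post_init__(self) -> None:
        if self.zone_cv < 0:
            raise ValueError("zone_cv must be >= 0")
        if self.thickness_sd_mm <= 0:
            raise ValueError("thickness dispersion must be positive")


def pilot_preset() -> CohortSpec:
    """The AF vs non-AF pilot cohort preset (n = 17 per arm)."""
    af = GroupSpec(
        name="AF",
        n=17,
        zone_means_pct={"periventricular": 15.6, "deep": 2.1, "infracortical": 0.72},
        ticv_mean_mm3=1_615_269.0,
        ticv_sd_mm3=178_016.0,
        n_with_stroke=11,
        stroke_volume_mean_ml=28.4,
        n_with_lacunae=9,
        lacunae_volume_mean_ml=0.59,
        age_mean=67.7,
        age_sd=8.0,
        education_mean=13.5,
        education_sd=2.9,
        moca_mean=24.3,
        moca_sd=5.5,
        wtar_mean=37.6,
        wtar_sd=8.9,
        charlson_mean=1.8,
        charlson_sd=0.95,
        n_male=11,
    )
    non_af = GroupSpec(
        name="non-AF",
        n=17,
        zone_means_pct={"periventricular": 10.8, "deep": 0.6, "infracortical": 0.07},
        ticv_mean_mm3=1_605_508.0,
        ticv_sd_mm3=137_530.0,
        age_mean=68.2,
        age_sd=4.8,
        education_mean=14.4,
        education_sd=2.0,
        moca_mean=26.8,
        moca_sd=1.8,
        wtar_mean=38.6,
        wtar_sd=10.0,
        charlson_mean=0.24,
        charlson_sd=0.44,
        n_male=11,
    )
    return CohortSpec(groups=(af, non_af))


PRESETS = {"pilot": pilot_preset}


def get_preset(name: str) -> CohortSpec:
    try:
        return PRESETS[name]()
    except KeyError:
        raise KeyError(f"unknown cohort preset {name!r}; available: {sorted(PRESETS)}") from None


@lru_cache(maxsize=4)
def _reference_zones_cached(phantom_key, zone_key) -> tuple[ZoneSet, dict[str, float], float]:
    spec = PhantomSpec()
    labels = make_label_volume(spec)
    zones = zone_partition(labels, ZoneParams())
    return _weights_from(zones)


def _weights_from(zones: ZoneSet) -> tuple[ZoneSet, dict[str, float], float]:
    n_wm = int(zones.wm.data.sum())
    weights = {z: int(zones.by_name(z).data.sum()) / n_wm for z in ZONES}
    wm_mm3 = n_wm * zones.wm.voxel_volume_mm3
    return zones, weights, wm_mm3


def reference_zones(spec: CohortSpec) -> tuple[ZoneSet, dict[str, float], float]:
    """Zone masks, zone/WM volume weights and WM volume (mm³) of the
    cohort's shared phantom geometry."""
    if spec.phantom == PhantomSpec() and spec.zone_params == ZoneParams():
        return _reference_zones_cached(None, None)
    labels = make_label_volume(spec.phantom)
    return _weights_from(zone_partition(labels, spec.zone_params))


def _lognormal_multipliers(rng: np.random.Generator, n: int, cv: float, match_mean: bool) -> np.ndarray:
    """Unit-mean log-normal multipliers with coefficient of variation cv."""
    if cv == 0:
        return np.ones(n)
    sigma2 = math.log(1.0 + cv**2)
    m = rng.lognormal(mean=-sigma2 / 2.0, sigma=math.sqrt(sigma2), size=n)
    if match_mean:
        m = m / m.mean()
    return m


def simulate_cohort(spec: CohortSpec | None = None, seed: int = 0) -> pd.DataFrame:
    """Generate the planted (ground-truth) cohort table.

    One row per subject with planted zone fractions, derived total and
    anterior/posterior fractions (via the shared geometry's zone
    weights), TICV, lobe thickness, stroke/lacunae volumes and
    demographics. Deterministic for a fixed seed.
    """
    spec = spec or pilot_preset()
    rng = np.random.default_rng(seed)
    zones, weights, wm_mm3 = reference_zones(spec)

    # zone composition of the anterior/posterior compartments, used to
    # derive the expected planted anterior/posterior fractions
    ap_weights = {}
    for region in ("anterior", "posterior"):
        reg = zones.by_name(region).data
        n_reg = int(reg.sum())
        ap_weights[region] = {
            z: int((zones.by_name(z).data & reg).sum()) / n_reg for z in ZONES
        }

    rows = []
    sid = 0
    for grp in spec.groups:
        fracs = {}
        for z in ZONES:
            mult = _lognormal_multipliers(rng, grp.n, spec.zone_cv, spec.match_group_means)
            fracs[z] = np.clip(grp.zone_means_pct[z] * mult, 0.0, 100.0)
        ticv = rng.normal(grp.ticv_mean_mm3, grp.ticv_sd_mm3, size=grp.n)

        stroke = np.zeros(grp.n)
        if grp.n_with_stroke > 0:
            who = rng.choice(grp.n, size=grp.n_with_stroke, replace=False)
            per = _lognormal_multipliers(rng, grp.n_with_stroke, 1.0, spec.match_group_means)
            stroke[who] = per * grp.stroke_volume_mean_ml * grp.n / grp.n_with_stroke
        lac = np.zeros(grp.n)
        if grp.n_with_lacunae > 0:
            who = rng.choice(grp.n, size=grp.n_with_lacunae, replace=False)
            per = _lognormal_multipliers(rng, grp.n_with_lacunae, 1.0, spec.match_group_means)
            lac[who] = per * grp.lacunae_volume_mean_ml * grp.n / grp.n_with_lacunae

        n_male = grp.n_male if grp.n_male is not None else round(2 * grp.n / 3)
        sex = np.array(["M"] * n_male + ["F"] * (grp.n - n_male))

        for i in range(grp.n):
            total = sum(fracs[z][i] * weights[z] for z in ZONES)
            row = {
                "id": f"S{sid:03d}",
                "group": grp.name,
                "pv_pct": float(fracs["periventricular"][i]),
                "deep_pct": float(fracs["deep"][i]),
                "ic_pct": float(fracs["infracortical"][i]),
                "total_pct": float(total),
                "anterior_pct": float(
                    sum(fracs[z][i] * ap_weights["anterior"][z] for z in ZONES)
                ),
                "posterior_pct": float(
                    sum(fracs[z][i] * ap_weights["posterior"][z] for z in ZONES)
                ),
                "la_volume_mm3": float(total / 100.0 * wm_mm3),
                "wm_volume_mm3": float(wm_mm3),
                "ticv_mm3": float(ticv[i]),
                "stroke_volume_ml": float(stroke[i]),
                "lacunae_volume_ml": float(lac[i]),
                "age": float(rng.normal(grp.age_mean, grp.age_sd)),
                "education": float(rng.normal(grp.education_mean, grp.education_sd)),
                "moca": float(np.clip(rng.normal(grp.moca_mean, grp.moca_sd), 0, 30)),
                "wtar": float(np.clip(rng.normal(grp.wtar_mean, grp.wtar_sd), 0, 50)),
                "charlson": float(max(0.0, rng.normal(grp.charlson_mean, grp.charlson_sd))),
                "sex": str(sex[i]),
            }
            rows.append(row)
            sid += 1

    cohort = pd.DataFrame(rows)

    # lobe thickness: planted partial correlation with log total LA given TICV
    log_la = np.log(cohort["total_pct"].to_numpy() + 1.0)
    ticv_all = cohort["ticv_mm3"].to_numpy()
    z_std = (ticv_all - ticv_all.mean()) / ticv_all.std()
    x_res = log_la - log_la.mean()
    x_res = x_res - z_std * (x_res @ z_std) / (z_std @ z_std)
    x_res = x_res / x_res.std()
    for lobe, base in spec.thickness_means_mm.items():
        rho = spec.thickness_partial_r.get(lobe, 0.0)
        noise = rng.normal(0.0, 1.0, size=len(cohort))
        latent = rho * x_res + math.sqrt(max(0.0, 1.0 - rho**2)) * noise
        cohort[f"thickness_{lobe}"] = (
            base + spec.thickness_sd_mm * latent + spec.ticv_thickness_r * spec.thickness_sd_mm * z_std
        )
    return cohort
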