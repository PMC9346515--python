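"""Seeded synthetic cohort generator for the myotubular-myopathy mouse study.

The generator runs the analysis model forwards: per-mouse log body weight is
linear in the square root of age (weeks) with correlated random intercept and
slope, and the death hazard is a Weibull baseline multiplied by
``exp(assoc * m_i(t))`` where ``m_i(t)`` is the mouse's current longitudinal
linear predictor. On top of that longitudinal-survival core it emulates the
remaining phenotyping channels:

* a terminal body-weight decline starting on average 2.3 weeks before death
  with a mean total loss of 2.16 g;
* hanging-test trials (three per week, capped at 60 s) driven by a latent
  severity that combines an age ramp with the (negative, standardized)
  random slope;
* ordinal clinical signs (kyphosis, walking, ptosis, breathing) that switch
  0 -> 0.5 -> 1 as the same latent severity crosses per-mouse onset
  thresholds — functional signs first, ptosis/breathing late;
* dose arms in which treatment from a given week attenuates the weekly
  severity increments and the hazard multiplicatively (``dose_effect``);
* post-mortem muscle endpoints (masses, minimum Feret diameter, nuclei
  mispositioning) drawn conditional on terminal severity.

Randomness: one root seed; each mouse consumes its own counter-derived
substream, so enlarging a cohort never reshuffles earlier mice.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass, field, replace

import numpy as np
import pandas as pd

from .cohort import CohortDataset, HANG_MAX_SECONDS, ORDINAL_FACTORS

__all__ = [
    "HangParams",
    "CategoricalParams",
    "MuscleParams",
    "SimulationConfig",
    "ConfigurationError",
    "mutant_config",
    "wildtype_config",
    "simulate_cohort",
    "simulate_death_time",
    "simulate_muscle_endpoints",
    "simulate_dose_response",
    "DEFAULT_DOSE_EFFECTS",
]


class ConfigurationError(ValueError):
    """Invalid simulation configuration."""


def _pyify(obj):
    """Recursively convert numpy scalars/arrays to plain Python types."""
    if isinstance(obj, dict):
        return {k: _pyify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_pyify(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return _pyify(obj.tolist())
    if isinstance(obj, np.generic):
        return obj.item()
    return obj


@dataclass
class HangParams:
    """Hanging-test channel: mean start time at week 3 and severity-driven decay."""

    start_mean: float = 52.0  # s, mean of the three trials at week 3
    start_sd: float = 5.0  # s, between-mouse spread of the start level
    decay: float = 30.0  # s lost per unit latent severity
    trial_sd: float = 3.0  # s, within-week trial-to-trial noise


@dataclass
class CategoricalParams:
    """Ordinal-sign onsets on the latent-severity scale.

    Each factor maps to ``(onset_mean, onset_sd, width)``: the sign scores
    0.5 once severity crosses a per-mouse threshold drawn from
    Normal(onset_mean, onset_sd), and 1 once it exceeds threshold + width.
    Severity advances by ~1 per untreated week, so onset_mean ~ weeks after
    weaning. Ptosis and breathing onsets are late (after week 7).
    """

    onset: dict = field(
        default_factory=lambda: {
            "walking": (0.8, 0.4, 1.2),
            "kyphosis": (2.0, 0.5, 2.0),
            "ptosis": (4.5, 0.6, 1.0),
            "breathing": (5.0, 0.6, 1.0),
        }
    )


@dataclass
class MuscleParams:
    """Post-mortem endpoint panel, conditional on terminal severity.

    ``mass_ratio``/``feret_ratio`` scale the wild-type reference values
    (mutants sit 2-3-fold below wild type in mass); ``severity_effect``
    controls the log-linear link between terminal severity and mass/size,
    which makes the mass-severity correlation negative by construction.
    """

    ta_base: float = 45.0  # mg, wild-type tibialis anterior reference
    gas_base: float = 140.0  # mg, gastrocnemius
    quad_base: float = 180.0  # mg, quadriceps
    feret_base: float = 42.0  # µm, wild-type minimum Feret diameter
    mass_ratio: float = 1.0
    feret_ratio: float = 1.0
    severity_effect: float = 0.06  # log-mass decrease per unit terminal severity
    noise_cv: float = 0.12
    nuclei_mean: float = 1.0  # % mispositioned nuclei (wild type ~0-2%)
    nuclei_sd: float = 0.5
    nuclei_severity_slope: float = 0.0  # extra % per unit terminal severity


@dataclass
class SimulationConfig:
    """Full description of one simulated arm.

    The longitudinal core is ``log w = beta0 + b0 + (beta1 + b1) sqrt(week)
    + eps`` with ``(b0, b1) ~ N(0, re_cov)`` and ``eps ~ N(0, sigma_e^2)``;
    the hazard is ``(shape/scale)(t/scale)^(shape-1) exp(assoc * m(t))``
    (times dose_effect after treatment start for treated arms).
    """

    n_mice: int = 38
    genotype: str = "mutant"
    weeks: tuple[int, int] = (3, 12)  # inclusive age range, weekly assessments
    beta0: float = 1.95
    beta1: float = 0.20  # log g per sqrt(week)
    re_cov: tuple = ((0.08**2, 0.0), (0.0, 0.025**2))
    sigma_e: float = 0.045
    haz_scale: float = 1.55  # Weibull scale (weeks)
    haz_shape: float = 4.0
    assoc: float = -2.0  # log-hazard per unit of m(t); negative: heavier = safer
    decline_lead_mean: float = 2.3  # weeks before death at decline onset
    decline_lead_sd: float = 0.8
    decline_loss_mean: float = 2.16  # g total terminal loss
    decline_loss_sd: float = 1.07
    hang_params: HangParams = field(default_factory=HangParams)
    cat_params: CategoricalParams = field(default_factory=CategoricalParams)
    muscle_params: MuscleParams = field(default_factory=MuscleParams)
    sev_sd: float = 0.4  # SD of the slope-derived severity baseline
    sev_ramp: float = 1.0  # severity gained per untreated week
    arm: str = "untreated"
    treatment_start_week: int | None = None
    dose_effect: float = 1.0  # multiplicative attenuation after treatment start
    replace_pre_treatment_deaths: bool = True
    seed: int = 0

    # -- validation -----------------------------------------------------
    def validate(self) -> "SimulationConfig":
        if self.n_mice < 1:
            raise ConfigurationError("n_mice must be >= 1")
        if self.sigma_e <= 0:
            raise ConfigurationError("sigma_e must be > 0")
        if self.haz_scale <= 0 or self.haz_shape <= 0:
            raise ConfigurationError("Weibull parameters must be > 0")
        lo, hi = self.weeks
        if hi < lo:
            raise ConfigurationError("empty week range")
        if lo < 3:
            raise ConfigurationError("weeks must start at >= 3 (weaning)")
        cov = np.asarray(self.re_cov, dtype=float)
        if cov.shape != (2, 2) or not np.allclose(cov, cov.T):
            raise ConfigurationError("re_cov must be a symmetric 2x2 matrix")
        eigvals = np.linalg.eigvalsh(cov)
        if eigvals.min() < -1e-12:
            raise ConfigurationError("re_cov must be positive semi-definite")
        if not 0 < self.dose_effect <= 1:
            raise ConfigurationError("dose_effect must be in (0, 1]")
        return self

    @property
    def re_chol(self) -> np.ndarray:
        cov = np.asarray(self.re_cov, dtype=float)
        # tolerate PSD matrices with a zero eigenvalue
        jitter = 1e-12 * np.eye(2)
        return np.linalg.cholesky(cov + jitter)

    def week_grid(self) -> np.ndarray:
        return np.arange(self.weeks[0], self.weeks[1] + 1)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["re_cov"] = np.asarray(self.re_cov, dtype=float).tolist()
        return _pyify(d)


# -- calibrated factories ----------------------------------------------

#: Default per-arm severity attenuation for the dose-response design.
DEFAULT_DOSE_EFFECTS = {
    "control-ASO": 1.0,
    "low": 0.5,
    "mid": 0.3,
    "high": 0.15,
}

# Mean week-3 weight target for mutants (g); beta0 is solved from it below.
_MUTANT_WEEK3_MEAN_G = 10.31
# Average week-3 log-weight depression caused by terminal decline in mice
# already declining at weaning (measured once at large n under the defaults).
_WEEK3_DECLINE_OFFSET = 0.055


def mutant_config(**overrides) -> SimulationConfig:
    """Defaults calibrated to the mutant natural-history conditions.

    Week-3 mean weight 10.31 g, median survival ~5 weeks with deaths from
    week 3 and (almost) none past 12, weights never reaching 20 g, hanging
    ~50 s at week 3 collapsing by week 5, and 2-3-fold reduced muscle mass
    with ~20% mispositioned nuclei.
    """
    cfg = SimulationConfig(**overrides)
    if "beta0" not in overrides:
        cov = np.asarray(cfg.re_cov, dtype=float)
        v3 = cov[0, 0] + 3.0 * cov[1, 1] + 2.0 * math.sqrt(3.0) * cov[0, 1]
        total_var = v3 + cfg.sigma_e**2
        cfg = replace(
            cfg,
            beta0=math.log(_MUTANT_WEEK3_MEAN_G)
            - cfg.beta1 * math.sqrt(3.0)
            - 0.5 * total_var
            + _WEEK3_DECLINE_OFFSET,
        )
    if "muscle_params" not in overrides:
        cfg = replace(
            cfg,
            muscle_params=MuscleParams(
                mass_ratio=0.4,
                feret_ratio=0.62,
                nuclei_mean=20.0,
                nuclei_sd=4.0,
                nuclei_severity_slope=0.5,
            ),
        )
    return cfg.validate()


def wildtype_config(**overrides) -> SimulationConfig:
    """Healthy controls: steady growth, negligible hazard, full hanging times."""
    defaults = dict(
        genotype="wild-type",
        arm="wild-type",
        beta0=1.577,
        beta1=0.474,
        re_cov=((0.06**2, 0.0), (0.0, 0.02**2)),
        sigma_e=0.04,
        haz_scale=1e6,  # effectively immortal on the study horizon
        haz_shape=4.0,
        assoc=0.0,
        decline_loss_mean=0.0,
        decline_loss_sd=0.0,
        hang_params=HangParams(start_mean=60.0, start_sd=0.5, decay=0.0, trial_sd=0.5),
        sev_sd=0.1,
        sev_ramp=0.0,
        muscle_params=MuscleParams(),
    )
    defaults.update(overrides)
    return SimulationConfig(**defaults).validate()


# -- death-time sampling ----------------------------------------------

_DEATH_GRID_STEP = 0.01  # weeks; inversion grid for the cumulative hazard
_DEATH_HORIZON_PAD = 40.0  # weeks past study end before declaring "no death"


def _hazard_on_grid(b: np.ndarray, config: SimulationConfig, t: np.ndarray) -> np.ndarray:
    """h(t | b) on a time grid, including the treated-arm slowed disease clock.

    Treatment attenuates disease *progression*: after the treatment-start
    week the baseline-hazard clock advances at rate ``dose_effect`` (the
    effective disease age is ``t0 + dose_effect * (t - t0)``), matching the
    attenuation of the latent-severity increments. The time change carries
    the usual rate factor, so ``dose_effect = 1`` leaves the hazard
    untouched.
    """
    lam, k = config.haz_scale, config.haz_shape
    eff_t = t
    rate = np.ones_like(t)
    if config.treatment_start_week is not None and config.dose_effect != 1.0:
        t0 = float(config.treatment_start_week)
        eff_t = np.where(t > t0, t0 + config.dose_effect * (t - t0), t)
        rate = np.where(t > t0, config.dose_effect, 1.0)
    with np.errstate(divide="ignore"):
        base = rate * (k / lam) * (eff_t / lam) ** (k - 1.0)
    base = np.where(eff_t > 0, base, 0.0)
    m = config.beta0 + b[0] + (config.beta1 + b[1]) * np.sqrt(np.maximum(t, 0.0))
    return base * np.exp(np.clip(config.assoc * m, -700, 700))


def simulate_death_time(
    b,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
    u: float | None = None,
    truncate_at: float | None = None,
) -> float:
    """Draw a death time by numerically inverting the cumulative hazard.

    ``P(T > t) = exp(-∫_0^t h(u|b) du)`` with
    ``h(t|b) = Weibull(haz_scale, haz_shape) * exp(assoc * m(t))``; with
    ``assoc = 0`` the marginal is exactly Weibull. ``truncate_at`` draws
    conditional on survival past that age (left truncation at weaning);
    the default is the unconditional distribution. Returns ``inf`` when no
    death occurs within the numerical horizon (vanishing hazard).
    """
    config.validate()
    b = np.asarray(b, dtype=float)
    if rng is None and u is None:
        rng = np.random.default_rng()
    target = -math.log(u if u is not None else rng.uniform())
    horizon = config.weeks[1] + _DEATH_HORIZON_PAD
    t = np.arange(0.0, horizon + _DEATH_GRID_STEP, _DEATH_GRID_STEP)
    h = _hazard_on_grid(b, config, t)
    if not np.all(np.isfinite(h)):
        raise FloatingPointError("non-finite hazard on the inversion grid")
    H = np.concatenate([[0.0], np.cumsum((h[1:] + h[:-1]) * 0.5 * _DEATH_GRID_STEP)])
    if truncate_at is not None:
        target = target + float(np.interp(truncate_at, t, H))
    if H[-1] < target:
        return math.inf
    idx = int(np.searchsorted(H, target))
    lo, hi = idx - 1, idx
    dH = H[hi] - H[lo]
    frac = 0.0 if dH <= 0 else (target - H[lo]) / dH
    return float(t[lo] + frac * _DEATH_GRID_STEP)


# -- per-mouse simulation ----------------------------------------------


def _mouse_rng(seed: int, index: int, channel: int = 0) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((seed, index, channel)))


def _severity_path(
    base: float, weeks: np.ndarray, config: SimulationConfig
) -> np.ndarray:
    """Latent severity at each assessment week (increments attenuated by dose)."""
    increments = np.full(len(weeks), config.sev_ramp, dtype=float)
    increments[0] = 0.0  # baseline at the first assessment
    if config.treatment_start_week is not None:
        treated = weeks > config.treatment_start_week
        increments[treated] *= config.dose_effect
    return base + np.cumsum(increments)


def _draw_mouse(index: int, config: SimulationConfig) -> dict:
    """Simulate one mouse; redraws the animal if it dies before treatment start."""
    rng = _mouse_rng(config.seed, index)
    first_week, last_week = config.weeks
    L = config.re_chol
    needs_replacement = (
        config.treatment_start_week is not None
        and config.replace_pre_treatment_deaths
    )
    for _ in range(1000):
        b = L @ rng.standard_normal(2)
        death = simulate_death_time(b, config, rng=rng, truncate_at=first_week)
        if not needs_replacement or death > config.treatment_start_week:
            break
    else:  # pragma: no cover - would need a pathological configuration
        raise ConfigurationError(
            "could not draw a mouse surviving to treatment start"
        )
    if death > last_week:
        time, event = float(last_week), 0
    else:
        time, event = death, 1

    obs_end = last_week if death > last_week else math.floor(death)
    weeks = np.arange(first_week, obs_end + 1)
    weeks = weeks[weeks < death]  # a mouse dead at exactly w is not assessed at w
    if weeks.size == 0:  # death within the first assessment week
        weeks = np.array([first_week])
        time = max(time, float(first_week))

    sqrt_w = np.sqrt(weeks.astype(float))
    log_w = (
        config.beta0
        + b[0]
        + (config.beta1 + b[1]) * sqrt_w
        + rng.normal(0.0, config.sigma_e, size=weeks.size)
    )
    weight = np.exp(log_w)

    # terminal decline, linear over the lead window before death (gram scale)
    if event and config.decline_loss_mean > 0:
        lead = max(0.5, rng.normal(config.decline_lead_mean, config.decline_lead_sd))
        loss = max(0.0, rng.normal(config.decline_loss_mean, config.decline_loss_sd))
        onset = death - lead
        in_window = weeks > onset
        weight = weight - np.where(
            in_window, loss * (weeks - onset) / lead, 0.0
        )
        weight = np.maximum(weight, 0.5)

    # latent severity: age ramp + negative standardized slope
    sd_b1 = math.sqrt(max(np.asarray(config.re_cov, float)[1, 1], 1e-12))
    sev_base = -(b[1] / sd_b1) * config.sev_sd
    severity = _severity_path(sev_base, weeks, config)

    hp = config.hang_params
    start = rng.normal(hp.start_mean, hp.start_sd)
    hang_mean = np.clip(start - hp.decay * severity, 0.0, HANG_MAX_SECONDS)
    trials = np.clip(
        hang_mean[:, None] + rng.normal(0.0, hp.trial_sd, size=(weeks.size, 3)),
        0.0,
        HANG_MAX_SECONDS,
    )

    ordinals = {}
    for factor in ORDINAL_FACTORS:
        mean, sd, width = config.cat_params.onset[factor]
        threshold = max(0.05, rng.normal(mean, sd))
        ordinals[factor] = np.where(
            severity >= threshold + width,
            1.0,
            np.where(severity >= threshold, 0.5, 0.0),
        )

    return {
        "b": b,
        "weeks": weeks,
        "weight": weight,
        "trials": trials,
        "ordinals": ordinals,
        "time": time,
        "event": event,
        "terminal_severity": float(severity[-1]),
    }


def simulate_cohort(config: SimulationConfig, with_muscle: bool = True) -> CohortDataset:
    """Generate a full cohort; deterministic given (config, seed)."""
    config.validate()
    mice_rows, obs_rows, surv_rows = [], [], []
    terminal_severity = {}
    for i in range(config.n_mice):
        mid = f"{config.arm}-{i + 1:03d}"
        sim = _draw_mouse(i, config)
        terminal_severity[mid] = sim["terminal_severity"]
        mice_rows.append(
            {
                "mouse_id": mid,
                "genotype": config.genotype,
                "arm": config.arm,
                "treatment_start_week": (
                    np.nan
                    if config.treatment_start_week is None
                    else config.treatment_start_week
                ),
            }
        )
        for j, w in enumerate(sim["weeks"]):
            obs_rows.append(
                {
                    "mouse_id": mid,
                    "week": int(w),
                    "body_weight": float(sim["weight"][j]),
                    "hang1": float(sim["trials"][j, 0]),
                    "hang2": float(sim["trials"][j, 1]),
                    "hang3": float(sim["trials"][j, 2]),
                    **{f: float(sim["ordinals"][f][j]) for f in ORDINAL_FACTORS},
                }
            )
        surv_rows.append(
            {"mouse_id": mid, "time": float(sim["time"]), "event": int(sim["event"])}
        )

    dataset = CohortDataset(
        mice=pd.DataFrame(mice_rows),
        observations=pd.DataFrame(obs_rows),
        survival=pd.DataFrame(surv_rows),
        provenance={"config": config.to_dict(), "seed": config.seed},
    )
    dataset.provenance["terminal_severity"] = terminal_severity
    if with_muscle:
        dataset.muscle = simulate_muscle_endpoints(dataset, config)
        dataset.validate()
    return dataset


def simulate_muscle_endpoints(
    dataset: CohortDataset, config: SimulationConfig
) -> pd.DataFrame:
    """One post-mortem panel per dead/sacrificed mouse.

    Masses and fiber diameter decrease log-linearly with terminal latent
    severity (negative mass-severity correlation by construction); the
    percentage of mispositioned nuclei is clamped to [0, 100].
    """
    if dataset.survival.empty:
        raise ConfigurationError("dataset has no survival outcomes")
    mp = config.muscle_params
    sev = dataset.provenance.get("terminal_severity", {})
    rows = []
    order = {mid: i for i, mid in enumerate(dataset.mice["mouse_id"])}
    for _, rec in dataset.survival.iterrows():
        if not rec["event"]:
            continue
        mid = rec["mouse_id"]
        rng = _mouse_rng(config.seed, order.get(mid, 0), channel=1)
        s = float(sev.get(mid, 0.0))
        shrink = math.exp(-mp.severity_effect * s)
        noise = rng.normal(0.0, mp.noise_cv, size=4)
        pct = rng.normal(
            mp.nuclei_mean + mp.nuclei_severity_slope * max(s, 0.0), mp.nuclei_sd
        )
        rows.append(
            {
                "mouse_id": mid,
                "ta_mass": mp.ta_base * mp.mass_ratio * shrink * math.exp(noise[0]),
                "gas_mass": mp.gas_base * mp.mass_ratio * shrink * math.exp(noise[1]),
                "quad_mass": mp.quad_base * mp.mass_ratio * shrink * math.exp(noise[2]),
                "min_feret": mp.feret_base
                * mp.feret_ratio
                * math.exp(-0.5 * mp.severity_effect * s)
                * math.exp(noise[3]),
                "pct_mispositioned_nuclei": float(np.clip(pct, 0.0, 100.0)),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "mouse_id",
            "ta_mass",
            "gas_mass",
            "quad_mass",
            "min_feret",
            "pct_mispositioned_nuclei",
        ],
    )


def simulate_dose_response(
    n_per_arm: int = 7,
    treatment_start_week: int = 5,
    dose_effects: dict | None = None,
    seed: int = 0,
    base_config: SimulationConfig | None = None,
    include_untreated: bool = True,
    include_wildtype: bool = True,
) -> CohortDataset:
    """Simulate the dose-response design: WT + untreated + treated arms.

    Treated arms (control-ASO, low, mid, high by default) start weekly dosing
    at ``treatment_start_week``; animals dying before that week are replaced,
    mirroring the study's pre-established exclusion criterion.
    """
    if dose_effects is None:
        dose_effects = dict(DEFAULT_DOSE_EFFECTS)
    base = base_config if base_config is not None else mutant_config()
    parts = []
    arm_index = 0
    if include_wildtype:
        parts.append(
            simulate_cohort(
                wildtype_config(
                    n_mice=n_per_arm, seed=_derive_seed(seed, arm_index)
                )
            )
        )
        arm_index += 1
    if include_untreated:
        parts.append(
            simulate_cohort(
                replace(
                    base,
                    n_mice=n_per_arm,
                    arm="untreated",
                    treatment_start_week=None,
                    dose_effect=1.0,
                    seed=_derive_seed(seed, arm_index),
                )
            )
        )
        arm_index += 1
    for arm, effect in dose_effects.items():
        parts.append(
            simulate_cohort(
                replace(
                    base,
                    n_mice=n_per_arm,
                    arm=arm,
                    treatment_start_week=treatment_start_week,
                    dose_effect=effect,
                    seed=_derive_seed(seed, arm_index),
                )
            )
        )
        arm_index += 1
    return concat_cohorts(parts)


def _derive_seed(seed: int, index: int) -> int:
    return int(np.random.SeedSequence((seed, index)).generate_state(1)[0] % (2**31))


def concat_cohorts(parts: list[CohortDataset]) -> CohortDataset:
    """Stack independently simulated arms into one dataset."""
    muscle_parts = [
        p.muscle for p in parts if p.muscle is not None and len(p.muscle)
    ]
    severity = {}
    for p in parts:
        severity.update(p.provenance.get("terminal_severity", {}))
    return CohortDataset(
        mice=pd.concat([p.mice for p in parts], ignore_index=True),
        observations=pd.concat([p.observations for p in parts], ignore_index=True),
        survival=pd.concat([p.survival for p in parts], ignore_index=True),
        muscle=(
            pd.concat(muscle_parts, ignore_index=True) if muscle_parts else None
        ),
        provenance={
            "arms": [p.provenance.get("config", {}) for p in parts],
            "terminal_severity": severity,
        },
    )
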