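"""Synthetic EMSCI-like cohort generator.

Real ISNCSCI registries (EMSCI, Sygen, NISCI) are available only on request,
so this module generates cohorts with the statistical structure the rest of
the package assumes: the published marginal composition of the EMSCI
benchmark cohort (AIS mix, NLI region mix, age, sex, assessment-time
distributions, VAC/DAP prevalence) and a severity-dependent sigmoidal
segmental recovery process.

The mechanistic choices -- a logistic time course anchored at the injury
date, exponential attenuation of both baseline sparing and recovery with
segmental distance below the NLI, and correlated left/right Gaussian ordinal
noise that is rounded and clipped -- are this package's own parametric
emulation of qualitative clinical knowledge; all parameters live in
:class:`CohortConfig`.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy import stats

from .assessment import Assessment, Instance, PatientRecord, benchmark_inclusion
from .levels import KEY_MUSCLE_LEVELS, LEVEL_LABELS, SpinalLevel

__all__ = [
    "CohortConfig",
    "Cohort",
    "default_emsci_config",
    "expected_trajectory",
    "sample_patient",
    "generate_cohort",
]

GENERATOR_VERSION = "1.0"

_KEY_ANAT_IDX = np.array([LEVEL_LABELS.index(lev) for lev in KEY_MUSCLE_LEVELS])
_ALL_ANAT_IDX = np.arange(len(LEVEL_LABELS))

#: NLI index ranges per region (inclusive): cervical C2-C8, thoracic T1-T12,
#: lumbar L1-L5.  Sacral levels are never sampled (cohort exclusion rule).
_REGION_RANGES = {"cervical": (0, 6), "thoracic": (7, 18), "lumbar": (19, 23)}
_AIS = ("A", "B", "C", "D")


@dataclass
class RecoveryParams:
    """Per-AIS logistic recovery time course and its spatial extent.

    ``gain`` is the plateau motor-point gain at the level just below the NLI,
    ``midpoint`` (days) and ``rate`` (days) shape the logistic in time, and
    ``decay_segments`` is the e-folding distance (in segments below the NLI)
    over which recovery fades caudally.  Complete injuries recover locally
    around the lesion; motor-incomplete injuries recover diffusely, hence the
    much longer decay for AIS D.
    """

    gain: dict[str, float] = field(
        default_factory=lambda: {"A": 0.6, "B": 1.6, "C": 2.6, "D": 2.0}
    )
    midpoint: dict[str, float] = field(
        default_factory=lambda: {"A": 70.0, "B": 75.0, "C": 80.0, "D": 70.0}
    )
    rate: dict[str, float] = field(
        default_factory=lambda: {"A": 25.0, "B": 25.0, "C": 28.0, "D": 25.0}
    )
    decay_segments: dict[str, float] = field(
        default_factory=lambda: {"A": 4.0, "B": 6.0, "C": 10.0, "D": 30.0}
    )


@dataclass
class CohortConfig:
    """All knobs of the synthetic cohort generator.

    Defaults are set by :func:`default_emsci_config` to the published EMSCI
    benchmark cohort composition.
    """

    n_patients: int = 1000
    ais_mix: dict[str, float] = field(
        default_factory=lambda: {"A": 0.25, "B": 0.25, "C": 0.25, "D": 0.25}
    )
    nli_region_mix: dict[str, float] = field(
        default_factory=lambda: {"cervical": 0.5, "thoracic": 0.4, "lumbar": 0.1}
    )
    age_mean: float = 46.0
    age_sd: float = 18.0
    age_min: float = 16.0
    age_max: float = 95.0
    frac_female: float = 0.22
    #: first-assessment time (days after injury), truncated normal
    t_early_mean: float = 22.0
    t_early_sd: float = 20.0
    t_early_min: float = 0.0
    t_early_max: float = 98.0
    #: follow-up time, truncated normal with a floor at the inclusion window
    t_late_mean: float = 216.0
    t_late_sd: float = 91.0
    t_late_min: float = 150.0
    t_late_max: float = 700.0
    recovery: RecoveryParams = field(default_factory=RecoveryParams)
    #: fraction of full strength retained just below the NLI at baseline
    baseline_motor_frac: dict[str, float] = field(
        default_factory=lambda: {"A": 0.0, "B": 0.06, "C": 0.35, "D": 0.72}
    )
    baseline_sensory_frac: dict[str, float] = field(
        default_factory=lambda: {"A": 0.0, "B": 0.5, "C": 0.6, "D": 0.85}
    )
    #: e-folding distance (segments) of the baseline attenuation below the NLI
    decay_per_segment: float = 12.0
    #: probability of VAC / DAP presence given AIS, tuned so the implied
    #: marginals under the default AIS mix match the published 30.5% / 52.4%
    vac_prob: dict[str, float] = field(
        default_factory=lambda: {"A": 0.02, "B": 0.15, "C": 0.35, "D": 0.82}
    )
    dap_prob: dict[str, float] = field(
        default_factory=lambda: {"A": 0.08, "B": 0.80, "C": 0.82, "D": 0.92}
    )
    #: Gaussian ordinal noise scale (motor points) before round-and-clip
    noise_sd: float = 0.45
    #: left/right score correlation via a shared per-level latent
    lr_correlation: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        for name, probs, keys in (
            ("ais_mix", self.ais_mix, _AIS),
            ("nli_region_mix", self.nli_region_mix, tuple(_REGION_RANGES)),
        ):
            if set(probs) != set(keys):
                raise ValueError(f"{name} must have keys {keys}")
            total = sum(probs.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"{name} must sum to 1, got {total}")
        for scale in (self.age_sd, self.t_early_sd, self.t_late_sd):
            if scale <= 0:
                raise ValueError("distribution scales must be positive")

    # round-trippable plain-dict form (io serializes this as YAML)
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "CohortConfig":
        d = dict(d)
        if "recovery" in d and isinstance(d["recovery"], Mapping):
            d["recovery"] = RecoveryParams(**d["recovery"])
        return cls(**d)


@dataclass
class Cohort:
    """Generated records plus full provenance (config, seed, version)."""

    records: list[PatientRecord]
    config: CohortConfig
    provenance: dict

    def instances(self, early_max_dai: int = 98, late_min_dai: int = 150) -> list[Instance]:
        return benchmark_inclusion(self.records, early_max_dai, late_min_dai)


def default_emsci_config(n_patients: int = 1000, seed: int = 0) -> CohortConfig:
    """Configuration matching the published EMSCI benchmark cohort margins.

    AIS mix 43.1/12.5/18.1/26.0 (A/B/C/D), NLI regions 53.8/37.3/9.0
    (cervical/thoracic/lumbar), age 46 (SD 18) years, 22.1% female, first
    assessment at 22 (SD 20) days, follow-up at 216 (SD 91) days, VAC present
    in 30.5% and DAP in 52.4% -- each renormalized where the published
    percentages do not sum exactly to one.
    """
    ais_raw = {"A": 0.431, "B": 0.125, "C": 0.181, "D": 0.260}
    s = sum(ais_raw.values())
    region_raw = {"cervical": 0.538, "thoracic": 0.373, "lumbar": 0.090}
    r = sum(region_raw.values())
    return CohortConfig(
        n_patients=n_patients,
        ais_mix={k: v / s for k, v in ais_raw.items()},
        nli_region_mix={k: v / r for k, v in region_raw.items()},
        age_mean=46.0,
        age_sd=18.0,
        frac_female=0.221,
        t_early_mean=22.0,
        t_early_sd=20.0,
        t_late_mean=216.0,
        t_late_sd=91.0,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Recovery process
# ---------------------------------------------------------------------------

def _logistic_course(t: np.ndarray, midpoint: float, rate: float) -> np.ndarray:
    """Normalized sigmoid in time: exactly 0 at t = 0, saturating to 1."""
    s = 1.0 / (1.0 + np.exp(-(np.asarray(t, dtype=float) - midpoint) / rate))
    s0 = 1.0 / (1.0 + np.exp(midpoint / rate))
    return (s - s0) / (1.0 - s0)


def expected_trajectory(
    baseline_score: float,
    ais: str,
    distance: float,
    t: float,
    p: RecoveryParams | None = None,
) -> float:
    """Expected motor score at time ``t`` for a muscle ``distance`` segments
    below the NLI, under the severity-dependent sigmoidal recovery model.

    The deterministic backbone of the generator:
    ``baseline + gain(ais) * exp(-distance / decay(ais)) * s(t)`` with ``s``
    a logistic normalized to 0 at the injury date, the whole clipped to the
    ISNCSCI motor range [0, 5].  Monotone non-decreasing in ``t``.
    """
    p = p or RecoveryParams()
    d = max(float(distance), 0.0)
    rise = p.gain[ais] * np.exp(-d / p.decay_segments[ais])
    val = baseline_score + rise * _logistic_course(np.asarray(t), p.midpoint[ais], p.rate[ais])
    return float(np.clip(val, 0.0, 5.0))


# ---------------------------------------------------------------------------
# Sampling
# ---------------------------------------------------------------------------

def _truncnorm(rng, mean, sd, lo, hi, size):
    """Truncated normal whose realized mean equals ``mean``.

    Truncation shifts the mean of a plainly truncated normal (for age the
    floor at 16 adds almost two years), so the location parameter is solved
    such that the published cohort mean is reproduced after truncation.
    """
    def trunc_mean(loc):
        a, b = (lo - loc) / sd, (hi - loc) / sd
        return stats.truncnorm.mean(a, b, loc=loc, scale=sd)

    from scipy.optimize import brentq

    span = hi - lo
    loc = brentq(lambda m: trunc_mean(m) - mean, lo - 3 * span, hi + 3 * span, xtol=1e-10)
    a, b = (lo - loc) / sd, (hi - loc) / sd
    return stats.truncnorm.rvs(a, b, loc=loc, scale=sd, size=size, random_state=rng)


def _correlated_noise(rng, n, n_levels, rho, sd):
    """Left/right correlated Gaussian noise via a shared per-level latent."""
    shared = rng.standard_normal((n, n_levels, 1))
    indep = rng.standard_normal((n, n_levels, 2))
    return sd * (np.sqrt(rho) * shared + np.sqrt(1.0 - rho) * indep)


def _score_block(mean_rostral, frac, anat_idx, nli_idx, decay, scale, noise):
    """Continuous baseline scores: full rostral to the NLI, attenuated below."""
    d = anat_idx[None, :] - nli_idx[:, None]  # (n, n_levels), >0 strictly caudal
    d3 = d[:, :, None].astype(float)
    caudal_mean = scale * frac[:, None, None] * np.exp(-(d3 - 1.0) / decay)
    vals = np.where(d3 <= 0, float(mean_rostral), caudal_mean + noise)
    # complete loss stays exactly zero below the level (no noise resurrection)
    vals = np.where((d3 > 0) & (frac[:, None, None] == 0.0), 0.0, vals)
    return np.clip(np.rint(vals), 0, scale).astype(np.int16)


def _sample_arrays(config: CohortConfig, n: int, rng: np.random.Generator) -> dict:
    c = config
    ais_codes = rng.choice(4, size=n, p=[c.ais_mix[g] for g in _AIS])
    ais = np.array(_AIS)[ais_codes]
    regions = rng.choice(
        list(_REGION_RANGES), size=n, p=[c.nli_region_mix[k] for k in _REGION_RANGES]
    )
    lo = np.array([_REGION_RANGES[r][0] for r in regions])
    hi = np.array([_REGION_RANGES[r][1] for r in regions])
    nli_idx = rng.integers(lo, hi + 1)

    sex = np.where(rng.random(n) < c.frac_female, "female", "male")
    age = _truncnorm(rng, c.age_mean, c.age_sd, c.age_min, c.age_max, n)
    t_early = np.rint(
        _truncnorm(rng, c.t_early_mean, c.t_early_sd, c.t_early_min, c.t_early_max, n)
    ).astype(int)
    t_late = np.rint(
        _truncnorm(rng, c.t_late_mean, c.t_late_sd, c.t_late_min, c.t_late_max, n)
    ).astype(int)

    m_frac = np.array([c.baseline_motor_frac[g] for g in ais])
    s_frac = np.array([c.baseline_sensory_frac[g] for g in ais])

    motor0 = _score_block(
        5, m_frac, _KEY_ANAT_IDX, nli_idx, c.decay_per_segment, 5,
        _correlated_noise(rng, n, 10, c.lr_correlation, c.noise_sd),
    )
    lt0 = _score_block(
        2, s_frac, _ALL_ANAT_IDX, nli_idx, c.decay_per_segment, 2,
        _correlated_noise(rng, n, 28, c.lr_correlation, c.noise_sd * 0.5),
    )
    pp0 = _score_block(
        2, s_frac, _ALL_ANAT_IDX, nli_idx, c.decay_per_segment, 2,
        _correlated_noise(rng, n, 28, c.lr_correlation, c.noise_sd * 0.5),
    )

    vac = rng.random(n) < np.array([c.vac_prob[g] for g in ais])
    dap = rng.random(n) < np.array([c.dap_prob[g] for g in ais])

    # recovery-phase motor scores: sigmoidal gain below the NLI plus ordinal
    # noise, floored one point below baseline so no >=2-point deterioration
    # is ever generated (excluded cases are not modelled)
    p = c.recovery
    gain = np.array([p.gain[g] for g in ais])
    mid = np.array([p.midpoint[g] for g in ais])
    rate = np.array([p.rate[g] for g in ais])
    lam = np.array([p.decay_segments[g] for g in ais])
    d = np.maximum(_KEY_ANAT_IDX[None, :] - nli_idx[:, None], 0).astype(float)
    s = 1.0 / (1.0 + np.exp(-(t_late - mid) / rate))
    s0 = 1.0 / (1.0 + np.exp(mid / rate))
    course = (s - s0) / (1.0 - s0)
    rise = gain[:, None] * np.exp(-d / lam[:, None]) * course[:, None]
    noise = _correlated_noise(rng, n, 10, c.lr_correlation, c.noise_sd)
    motor1 = np.rint(motor0 + rise[:, :, None] + noise)
    motor1 = np.clip(motor1, np.maximum(motor0 - 1, 0), 5).astype(np.int16)

    # sensory recovery: same course at reduced amplitude on the 0-2 scale
    d_s = np.maximum(_ALL_ANAT_IDX[None, :] - nli_idx[:, None], 0).astype(float)
    rise_s = 0.3 * gain[:, None] * np.exp(-d_s / lam[:, None]) * course[:, None]
    lt1 = np.clip(
        np.rint(lt0 + rise_s[:, :, None] + _correlated_noise(rng, n, 28, c.lr_correlation, c.noise_sd * 0.5)),
        np.maximum(lt0 - 1, 0), 2,
    ).astype(np.int16)
    pp1 = np.clip(
        np.rint(pp0 + rise_s[:, :, None] + _correlated_noise(rng, n, 28, c.lr_correlation, c.noise_sd * 0.5)),
        np.maximum(pp0 - 1, 0), 2,
    ).astype(np.int16)

    return dict(
        ais=ais, nli_idx=nli_idx, sex=sex, age=age, t_early=t_early, t_late=t_late,
        motor0=motor0, motor1=motor1, lt0=lt0, lt1=lt1, pp0=pp0, pp1=pp1,
        vac=vac, dap=dap,
    )


def _build_records(arrays: dict, prefix: str = "SYN") -> list[PatientRecord]:
    records = []
    n = len(arrays["ais"])
    for i in range(n):
        pid = f"{prefix}-{i:06d}"
        nli = SpinalLevel(int(arrays["nli_idx"][i]))
        ais = str(arrays["ais"][i])
        common = dict(vac=bool(arrays["vac"][i]), dap=bool(arrays["dap"][i]), ais=ais, nli=nli)
        early = Assessment(
            patient_id=pid, dai=int(arrays["t_early"][i]),
            motor=arrays["motor0"][i], light_touch=arrays["lt0"][i],
            pinprick=arrays["pp0"][i], **common,
        )
        late = Assessment(
            patient_id=pid, dai=int(arrays["t_late"][i]),
            motor=arrays["motor1"][i], light_touch=arrays["lt1"][i],
            pinprick=arrays["pp1"][i], **common,
        )
        records.append(
            PatientRecord(
                patient_id=pid, age_at_injury=float(arrays["age"][i]),
                sex=str(arrays["sex"][i]), assessments=[early, late],
            )
        )
    return records


def sample_patient(config: CohortConfig, rng: np.random.Generator) -> PatientRecord:
    """Draw a single patient record from the generator."""
    return _build_records(_sample_arrays(config, 1, rng))[0]


def generate_cohort(config: CohortConfig) -> Cohort:
    """Generate ``config.n_patients`` independent records, reproducibly."""
    rng = np.random.default_rng(config.seed)
    arrays = _sample_arrays(config, config.n_patients, rng)
    # the seed in the id keeps independently generated cohorts disjoint
    records = _build_records(arrays, prefix=f"SYN{config.seed}")
    provenance = {"seed": config.seed, "generator_version": GENERATOR_VERSION}
    return Cohort(records=records, config=config, provenance=provenance)
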