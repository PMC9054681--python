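"""Seeded generators for cohorts, X-linked genotype counts, and Fura-2 traces.

These generators produce data with the statistical structure the analysis
stages assume, so the whole pipeline is testable end-to-end without any
external download:

* subject cohorts with log-normal (region-specific) miRNA levels, a Bernoulli
  APOE e4 covariate, and an ordered NCI/MCI/AD diagnosis drawn from the same
  latent proportional-odds model the fitter assumes,
  P(Y <= k | x) = logistic(alpha_k - eta) with
  eta = beta_mir*log(mir) + beta_e4*e4 + beta_interaction*log(mir)*e4;
* female genotype / male hemizygote counts for a biallelic X-linked SNP under
  Hardy-Weinberg equilibrium at allele frequency q;
* piecewise idealized calcium transients (flat pre-flow, linear rise to the
  peak, linear active discharge, exponential passive tail) plus additive
  Gaussian noise.

Every generator takes one integer seed and derives any per-subject or
per-trace streams deterministically from it, so identical seeds give
bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace

import numpy as np
import pandas as pd
from scipy.special import expit

from .exceptions import ConfigError, ValidationError
from .fura import FuraTrace
from .hwe import XGenotypeCounts
from .ordinal import DIAGNOSIS_LEVELS


def _from_dict(cls, mapping: dict):
    known = {f.name for f in fields(cls)}
    unknown = set(mapping) - known
    if unknown:
        raise ConfigError(f"{cls.__name__}: unknown config keys {sorted(unknown)}")
    return cls(**mapping)


@dataclass(frozen=True)
class OrdinalSimConfig:
    """Design of a simulated brain cohort.

    ``mir_log_mean``/``mir_log_sd`` parameterize the per-region log-normal
    miRNA level (pmol scale, analyzed on the log axis); a scalar broadcasts
    across regions.  ``cutpoints`` are the K-1 latent thresholds of the
    3-level diagnosis scale.
    """

    n_subjects: int = 200
    regions: tuple[str, ...] = ("TL", "CB", "PCC")
    mir_log_mean: dict[str, float] | float = field(
        default_factory=lambda: {"TL": 0.0, "CB": -0.5, "PCC": 0.5})
    mir_log_sd: dict[str, float] | float = 1.0
    p_e4: float = 0.30
    beta_mir: float = 1.0
    beta_e4: float = 0.8
    beta_interaction: float = 0.0
    cutpoints: tuple[float, ...] = (-0.5, 1.0)
    seed: int = 0

    def __post_init__(self):
        if self.n_subjects < 1:
            raise ConfigError("n_subjects must be positive")
        if not 0.0 <= self.p_e4 <= 1.0:
            raise ConfigError(f"p_e4={self.p_e4} outside [0, 1]")
        cut = np.asarray(self.cutpoints, dtype=float)
        if cut.ndim != 1 or len(cut) < 1 or np.any(np.diff(cut) <= 0):
            raise ConfigError(f"cutpoints {self.cutpoints} must be strictly increasing")
        for r in self.regions:
            if self._param(self.mir_log_sd, r) <= 0:
                raise ConfigError(f"mir_log_sd for region {r!r} must be > 0")
            self._param(self.mir_log_mean, r)

    @staticmethod
    def _param(value, region: str) -> float:
        if isinstance(value, dict):
            if region not in value:
                raise ConfigError(f"no parameter for region {region!r}")
            return float(value[region])
        return float(value)

    @classmethod
    def from_dict(cls, mapping: dict) -> "OrdinalSimConfig":
        mapping = dict(mapping)
        for key in ("regions", "cutpoints"):
            if key in mapping and isinstance(mapping[key], list):
                mapping[key] = tuple(mapping[key])
        return _from_dict(cls, mapping)


def category_probabilities(config: OrdinalSimConfig, eta) -> np.ndarray:
    """Closed-form level probabilities P(Y = k | eta) under the latent model."""
    eta = np.atleast_1d(np.asarray(eta, dtype=float))
    cut = np.asarray(config.cutpoints, dtype=float)
    cum = expit(cut[None, :] - eta[:, None])
    cum = np.hstack([np.zeros((len(eta), 1)), cum, np.ones((len(eta), 1))])
    return np.diff(cum, axis=1)


def simulate_ordinal_cohort(config: OrdinalSimConfig) -> pd.DataFrame:
    """Draw a cohort table (subject_id, region, mir20b, apoe_e4, age, sex, diagnosis).

    miRNA levels are log-normal per region; e4 ~ Bernoulli(p_e4); the ordered
    diagnosis is drawn from the latent cumulative-logit model.  Age and sex
    are filler demographics (not in the latent model) so the table matches
    the full cohort schema.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_subjects
    regions = rng.choice(np.asarray(config.regions, dtype=object), size=n)
    mu = np.array([config._param(config.mir_log_mean, r) for r in regions])
    sd = np.array([config._param(config.mir_log_sd, r) for r in regions])
    mir = np.exp(rng.normal(mu, sd))
    e4 = rng.random(n) < config.p_e4
    age = np.round(np.clip(rng.normal(84.0, 6.0, size=n), 60.0, 105.0), 1)
    sex = rng.choice(np.array(["F", "M"], dtype=object), size=n)
    eta = (config.beta_mir * np.log(mir)
           + config.beta_e4 * e4
           + config.beta_interaction * np.log(mir) * e4)
    cum = expit(np.asarray(config.cutpoints)[None, :] - eta[:, None])
    codes = (rng.random(n)[:, None] > cum).sum(axis=1)
    k = len(config.cutpoints) + 1
    levels = DIAGNOSIS_LEVELS[:k] if k <= len(DIAGNOSIS_LEVELS) else tuple(
        f"L{i}" for i in range(k))
    return pd.DataFrame({
        "subject_id": [f"S{i:05d}" for i in range(n)],
        "region": pd.Categorical(regions, categories=list(config.regions)),
        "mir20b": mir,
        "apoe_e4": e4.astype(int),
        "age": age,
        "sex": sex,
        "diagnosis": pd.Categorical.from_codes(codes, categories=list(levels),
                                               ordered=True),
    })


def simulate_x_genotypes(q: float, n_female: int, n_male: int,
                         seed: int = 0) -> XGenotypeCounts:
    """Sample X-linked genotype counts under HWE at G-allele frequency q.

    Female genotypes are multinomial((1-q)^2, 2q(1-q), q^2); male hemizygote
    G counts are binomial(n_male, q).  Totals are conserved by construction.
    """
    if not 0.0 <= q <= 1.0:
        raise ValidationError(f"allele frequency q={q} outside [0, 1]")
    if n_female < 0 or n_male < 0:
        raise ValidationError("sample sizes must be nonnegative")
    rng = np.random.default_rng(seed)
    p = 1.0 - q
    n_aa, n_ag, n_gg = rng.multinomial(n_female, [p * p, 2 * p * q, q * q])
    n_g = rng.binomial(n_male, q)
    return XGenotypeCounts(n_AA=int(n_aa), n_AG=int(n_ag), n_GG=int(n_gg),
                           n_A=int(n_male - n_g), n_G=int(n_g))


@dataclass(frozen=True)
class FuraSimConfig:
    """Shape of an idealized synthetic calcium transient.

    Defaults describe a 500-cycle recording with a 100-cycle pre-flow,
    40-cycle rise, 80-cycle active discharge, slow passive tail
    (``tail_rate`` per-cycle exponential decay toward baseline) and additive
    Gaussian noise at 1% of the peak amplitude.
    """

    n_cycles: int = 500
    idx_I: int = 100
    idx_P: int = 140
    idx_II: int = 220
    baseline_level: float = 1.0
    peak_amplitude: float = 1.2
    discharge_magnitude: float = 1.0
    tail_rate: float = 0.005
    noise_sd: float = 0.012
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.idx_I < self.idx_P < self.idx_II < self.n_cycles:
            raise ConfigError(
                f"phase indices must satisfy 0 < I={self.idx_I} < P={self.idx_P}"
                f" < II={self.idx_II} < n_cycles={self.n_cycles}")
        if self.baseline_level <= 0 or self.peak_amplitude <= 0:
            raise ConfigError("baseline_level and peak_amplitude must be positive")
        if not 0 < self.discharge_magnitude <= self.peak_amplitude:
            raise ConfigError("discharge_magnitude must be in (0, peak_amplitude]")
        if self.tail_rate < 0 or self.noise_sd < 0:
            raise ConfigError("tail_rate and noise_sd must be nonnegative")

    @classmethod
    def from_dict(cls, mapping: dict) -> "FuraSimConfig":
        return _from_dict(cls, mapping)


def ideal_fura_curve(config: FuraSimConfig) -> np.ndarray:
    """Noiseless piecewise transient: baseline, linear rise, linear discharge, tail.

    The rise is linear from one increment above baseline at cycle ``idx_I``
    (so influx is first detectable exactly at I) to
    ``baseline_level + peak_amplitude`` at ``idx_P``; the active discharge is
    linear down by ``discharge_magnitude`` at ``idx_II``; afterwards the
    residual elevation decays exponentially at ``tail_rate`` per cycle.
    """
    t = np.arange(config.n_cycles)
    b, a, ap = config.baseline_level, config.peak_amplitude, config.discharge_magnitude
    x = np.full(config.n_cycles, b, dtype=float)
    rise = (t >= config.idx_I) & (t <= config.idx_P)
    n_rise = config.idx_P - config.idx_I + 1
    x[rise] = b + a * (t[rise] - config.idx_I + 1) / n_rise
    disch = (t > config.idx_P) & (t <= config.idx_II)
    x[disch] = b + a - ap * (t[disch] - config.idx_P) / (config.idx_II - config.idx_P)
    tail = t > config.idx_II
    x[tail] = b + (a - ap) * np.exp(-config.tail_rate * (t[tail] - config.idx_II))
    return x


def simulate_fura_trace(config: FuraSimConfig, roi_id: str = "roi0") -> FuraTrace:
    """Idealized transient plus seeded additive Gaussian noise."""
    x = ideal_fura_curve(config)
    if config.noise_sd > 0:
        rng = np.random.default_rng(config.seed)
        x = x + rng.normal(0.0, config.noise_sd, size=config.n_cycles)
        # ratios are physically positive; noise at the stated scales never
        # approaches zero, but guard degenerate configurations
        x = np.maximum(x, 1e-9)
    return FuraTrace(cycle=np.arange(config.n_cycles), ratio=x, roi_id=roi_id)


def simulate_fura_batch(config: FuraSimConfig, n_responders: int,
                        n_flat: int = 0, seed: int | None = None) -> list[FuraTrace]:
    """A batch of responder traces plus flat (non-responder) traces.

    Per-trace noise streams are spawned deterministically from one seed
    (``config.seed`` unless overridden).  Flat traces are constant baseline
    plus noise — cells that did not respond to the stimulus.
    """
    if n_responders < 0 or n_flat < 0:
        raise ConfigError("trace counts must be nonnegative")
    root = np.random.SeedSequence(config.seed if seed is None else seed)
    children = root.spawn(n_responders + n_flat)
    traces: list[FuraTrace] = []
    for i in range(n_responders):
        sub = replace(config, seed=int(children[i].generate_state(1)[0] % (2**31)))
        traces.append(simulate_fura_trace(sub, roi_id=f"roi{i}"))
    for j in range(n_flat):
        rng = np.random.default_rng(children[n_responders + j])
        x = np.full(config.n_cycles, config.baseline_level)
        if config.noise_sd > 0:
            x = x + rng.normal(0.0, config.noise_sd, size=config.n_cycles)
        traces.append(FuraTrace(cycle=np.arange(config.n_cycles),
                                ratio=np.maximum(x, 1e-9),
                                roi_id=f"roi{n_responders + j}"))
    return traces
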