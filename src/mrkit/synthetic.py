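"""Synthetic two-sample GWAS summary statistics with known causal truth.

The generator emulates the summary-statistic abstraction every estimator
consumes: per SNP an allele frequency, a true exposure effect xi, sampling
noise on the observed exposure effect, and an outcome effect equal to
theta * xi plus optional horizontal pleiotropy (balanced, directional, or
planted per-SNP outliers) plus sampling noise.  Standard errors follow the
usual unit-variance GWAS approximation se = (2 * eaf * (1 - eaf) * n)^(-1/2),
so instrument strength is governed by allele frequency, effect size and
effective sample size exactly as in real data.  Outcome effects are drawn
directly on the log-odds scale — no individual-level case/control sampling —
and instruments are independent by construction, as post-clumping analysis
assumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats

from .exceptions import ConfigError
from .gwas_io import AssociationTable, VariantRecord
from .harmonize import InstrumentSet, harmonize

__all__ = [
    "EffectDistribution",
    "Pleiotropy",
    "SimulationConfig",
    "SimulatedStudy",
    "MethodRecovery",
    "simulate_study",
    "recovery_experiment",
]

# Non-palindromic allele pairs cycled across simulated SNPs.
_ALLELE_CYCLE = (("A", "G"), ("C", "T"), ("A", "C"), ("G", "T"))
_PALINDROMIC = (("A", "T"), ("C", "G"))

_MIN_P = 1e-300  # underflow guard for very strong instruments


@dataclass(frozen=True)
class EffectDistribution:
    """Distribution of true exposure-effect magnitudes.

    ``uniform`` draws from [low, high); ``normal`` uses (mean, sd) =
    (low, high) truncated to positive values; ``fixed`` repeats ``low``.
    Defaults give per-allele effects of 0.05-0.15 exposure SD, the typical
    range of genome-wide significant micronutrient loci.
    """

    kind: str = "uniform"
    low: float = 0.05
    high: float = 0.15

    def draw(self, k: int, rng: np.random.Generator) -> np.ndarray:
        if self.kind == "uniform":
            if not self.high > self.low >= 0:
                raise ConfigError("uniform effect distribution needs 0 <= low < high")
            return rng.uniform(self.low, self.high, size=k)
        if self.kind == "normal":
            if not self.high > 0:
                raise ConfigError("normal effect distribution needs sd > 0")
            return np.abs(rng.normal(self.low, self.high, size=k))
        if self.kind == "fixed":
            if self.low == 0:
                raise ConfigError("fixed effect distribution needs a nonzero effect")
            return np.full(k, self.low)
        raise ConfigError(f"unknown effect distribution kind {self.kind!r}")


@dataclass(frozen=True)
class Pleiotropy:
    """Direct SNP-to-outcome effects: none, balanced(sd) or directional(mean, sd)."""

    kind: str = "none"
    mean: float = 0.0
    sd: float = 0.0

    def draw(self, k: int, rng: np.random.Generator) -> np.ndarray:
        if self.kind == "none":
            return np.zeros(k)
        if self.sd < 0:
            raise ConfigError("pleiotropy sd must be >= 0")
        if self.kind == "balanced":
            return rng.normal(0.0, self.sd, size=k)
        if self.kind == "directional":
            return rng.normal(self.mean, self.sd, size=k)
        raise ConfigError(f"unknown pleiotropy kind {self.kind!r}")


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one simulated two-sample dataset.

    Defaults mirror the scale of the source studies: a few tens of thousands
    of exposure-GWAS samples and an outcome GWAS of ~15,700, with the causal
    effect theta in log-odds per exposure SD.
    """

    seed: int
    k: int = 20
    n_exp: float = 50_000
    n_out: float = 15_666
    theta: float = 0.0
    gamma_dist: EffectDistribution = field(default_factory=EffectDistribution)
    pleiotropy: Pleiotropy = field(default_factory=Pleiotropy)
    outliers: tuple[tuple[int, float], ...] = ()
    palindromic_fraction: float = 0.0

    def __post_init__(self):
        if self.k < 1:
            raise ConfigError(f"k must be >= 1, got {self.k}")
        if not (self.n_exp > 0 and self.n_out > 0):
            raise ConfigError("sample sizes must be > 0")
        if self.seed is None:
            raise ConfigError("a seed is mandatory")
        if not 0 <= self.palindromic_fraction <= 1:
            raise ConfigError("palindromic_fraction must lie in [0, 1]")
        for idx, _ in self.outliers:
            if not 0 <= idx < self.k:
                raise ConfigError(f"outlier index {idx} out of range for k = {self.k}")


@dataclass(frozen=True)
class Truth:
    """The generating parameters behind one simulated study."""

    theta: float
    xi: tuple[float, ...]
    alpha: tuple[float, ...]
    config: SimulationConfig


@dataclass(frozen=True)
class SimulatedStudy:
    """Exposure and outcome tables plus the truth that generated them."""

    exposure: AssociationTable
    outcome: AssociationTable
    truth: Truth

    def to_instruments(self) -> InstrumentSet:
        return harmonize(self.exposure, self.outcome)


def _pvals(beta: np.ndarray, se: np.ndarray) -> np.ndarray:
    z = np.abs(beta) / se
    return np.clip(2.0 * stats.norm.sf(z), _MIN_P, 1.0)


def simulate_study(config: SimulationConfig) -> SimulatedStudy:
    """Generate one two-sample summary-statistic study with known truth."""
    # Independent child streams per component so that e.g. a degenerate
    # pleiotropy draw (sd = 0) leaves the sampling-noise stream untouched.
    ss = np.random.SeedSequence(config.seed).spawn(4)
    rng_locus, rng_alpha, rng_exp, rng_out = map(np.random.default_rng, ss)
    k = config.k
    eaf = rng_locus.uniform(0.05, 0.95, size=k)
    xi = config.gamma_dist.draw(k, rng_locus)
    alpha = config.pleiotropy.draw(k, rng_alpha)

    se_exp = (2.0 * eaf * (1.0 - eaf) * config.n_exp) ** -0.5
    se_out = (2.0 * eaf * (1.0 - eaf) * config.n_out) ** -0.5
    beta_exp = rng_exp.normal(xi, se_exp)
    beta_out = rng_out.normal(config.theta * xi + alpha, se_out)
    # Planted outliers: displacement in first-order ratio-SE units, i.e.
    # a shift of disp * se_out on the outcome-beta scale.
    for idx, disp in config.outliers:
        beta_out[idx] += disp * se_out[idx]

    n_palindromic = int(round(config.palindromic_fraction * k))
    records_exp, records_out = [], []
    p_exp = _pvals(beta_exp, se_exp)
    p_out = _pvals(beta_out, se_out)
    for i in range(k):
        if i < n_palindromic:
            ea, oa = _PALINDROMIC[i % len(_PALINDROMIC)]
        else:
            ea, oa = _ALLELE_CYCLE[i % len(_ALLELE_CYCLE)]
        common = dict(
            snp_id=f"rs{i + 1:05d}",
            chrom=str(i % 22 + 1),
            pos=(i + 1) * 10_000,
            effect_allele=ea,
            other_allele=oa,
            eaf=float(eaf[i]),
        )
        records_exp.append(
            VariantRecord(beta=float(beta_exp[i]), se=float(se_exp[i]), pval=float(p_exp[i]), **common)
        )
        records_out.append(
            VariantRecord(beta=float(beta_out[i]), se=float(se_out[i]), pval=float(p_out[i]), **common)
        )

    return SimulatedStudy(
        exposure=AssociationTable("sim_exposure", "continuous", tuple(records_exp)),
        outcome=AssociationTable("sim_outcome", "binary", tuple(records_out)),
        truth=Truth(
            theta=config.theta,
            xi=tuple(float(x) for x in xi),
            alpha=tuple(float(a) for a in alpha),
            config=config,
        ),
    )


@dataclass(frozen=True)
class MethodRecovery:
    """Monte-Carlo operating characteristics of one estimator."""

    method: str
    n_reps: int
    n_failed: int
    mean_bias: float
    rmse: float
    coverage: float
    rejection_rate: float


def recovery_experiment(
    config: SimulationConfig,
    methods: tuple[str, ...] = ("ivw_mre",),
    n_reps: int = 200,
) -> dict[str, MethodRecovery]:
    """Estimate bias, RMSE, 95% CI coverage and alpha = 0.05 rejection rate
    for each method over ``n_reps`` independently seeded studies.

    Per-replicate estimator failures are counted, not fatal.  Methods are
    named as in :mod:`mrkit.mr_core` (``ivw_mre``, ``ivw_fe``,
    ``max_likelihood``, ``weighted_median``, ``egger_slope``).
    """
    from . import mr_core

    if n_reps < 100:
        raise ConfigError(f"n_reps must be >= 100, got {n_reps}")
    child_seeds = np.random.SeedSequence(config.seed).generate_state(n_reps) % (2**31)
    results: dict[str, list] = {m: [] for m in methods}
    failures = {m: 0 for m in methods}
    for rep in range(n_reps):
        study = simulate_study(replace(config, seed=int(child_seeds[rep])))
        instruments = study.to_instruments()
        for m in methods:
            try:
                if m == "ivw_mre":
                    est = mr_core.ivw(instruments, "multiplicative_random")
                elif m == "ivw_fe":
                    est = mr_core.ivw(instruments, "fixed")
                elif m == "max_likelihood":
                    est = mr_core.max_likelihood(instruments)
                elif m == "weighted_median":
                    est = mr_core.weighted_median(
                        instruments, seed=int(child_seeds[rep]) + 1
                    )
                elif m == "egger_slope":
                    est = mr_core.egger(instruments).slope
                elif m == "egger_intercept":
                    egg = mr_core.egger(instruments)
                    est = mr_core.MREstimate.from_beta_se(
                        "egger_slope",
                        instruments.k,
                        egg.intercept,
                        egg.intercept_se,
                        dist="t",
                        df=instruments.k - 2,
                    )
                else:
                    raise ConfigError(f"unknown method {m!r}")
            except ConfigError:
                raise
            except Exception:
                failures[m] += 1
                continue
            results[m].append(est)

    out: dict[str, MethodRecovery] = {}
    for m in methods:
        ests = results[m]
        target = config.pleiotropy.mean if m == "egger_intercept" else config.theta
        beta = np.array([e.beta for e in ests])
        lo = np.array([np.log(e.or_low) for e in ests])
        hi = np.array([np.log(e.or_high) for e in ests])
        pv = np.array([e.pval for e in ests])
        out[m] = MethodRecovery(
            method=m,
            n_reps=n_reps,
            n_failed=failures[m],
            mean_bias=float(np.mean(beta - target)),
            rmse=float(np.sqrt(np.mean((beta - target) ** 2))),
            coverage=float(np.mean((lo <= target) & (target <= hi))),
            rejection_rate=float(np.mean(pv < 0.05)),
        )
    return out
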