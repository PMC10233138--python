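"""MR-PRESSO: pleiotropy residual sum and outlier analysis.

Three seeded Monte-Carlo tests on a harmonized instrument set:

* the *global* test compares the observed leave-one-out weighted residual
  sum of squares against its null distribution under no pleiotropy,
* the *outlier* test compares each SNP's residual contribution against its
  own simulated null and flags SNPs at a Bonferroni-corrected threshold,
* the *distortion* test asks whether removing the flagged SNPs shifts the
  causal estimate more than removing equally many random SNPs would.

The raw estimate reported alongside is the IVW weighted-regression slope
with a multiplicative (unfloored) residual scale on its SE and t inference
on k-1 degrees of freedom.  All randomness flows from the config seed;
SNPs are canonicalized by rsID before simulation so results are exactly
invariant to input row order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import ConfigError, InsufficientInstrumentsError
from .harmonize import InstrumentSet
from .mr_core import MREstimate, ratio_statistics

__all__ = ["PressoConfig", "PressoResult", "presso_global", "presso_outlier", "presso_run"]

MIN_SNPS = 4  # leave-one-out slopes need k - 1 >= 3 stable instruments


@dataclass(frozen=True)
class PressoConfig:
    """Monte-Carlo settings: simulation count, seed, outlier alpha."""

    seed: int
    n_sim: int = 5000
    outlier_alpha: float = 0.05

    def __post_init__(self):
        if self.n_sim < 1000:
            raise ConfigError(f"n_sim must be >= 1000, got {self.n_sim}")
        if not 0 < self.outlier_alpha < 1:
            raise ConfigError(f"outlier_alpha must lie in (0, 1), got {self.outlier_alpha}")
        if self.seed is None:
            raise ConfigError("a seed is mandatory")


@dataclass(frozen=True)
class PressoResult:
    """Raw estimate, global/outlier/distortion tests, corrected estimate."""

    raw: MREstimate
    global_rss: float
    global_p: float
    outlier_p: dict[str, float]
    outliers: tuple[str, ...]
    corrected: MREstimate | None = None
    distortion_p: float | None = None

    def to_dict(self) -> dict:
        from dataclasses import asdict

        d = asdict(self)
        d["outliers"] = list(self.outliers)
        return d


def _canonical_arrays(instruments: InstrumentSet):
    """Arrays sorted by rsID so Monte-Carlo draws are order-invariant."""
    order = sorted(range(instruments.k), key=lambda i: instruments.pairs[i].snp_id)
    ids = [instruments.pairs[i].snp_id for i in order]
    bx, sx, by, sy = instruments.arrays()
    return ids, bx[order], sx[order], by[order], sy[order]


def _loo_slopes(bx, by, w):
    """Leave-one-out zero-intercept WLS slopes, vectorized over leading axes.

    slope_{-i} = (S1 - w_i bx_i by_i) / (S2 - w_i bx_i^2) with
    S1 = sum w bx by, S2 = sum w bx^2.
    """
    t1 = w * bx * by
    t2 = w * bx * bx
    s1 = np.sum(t1, axis=-1, keepdims=True)
    s2 = np.sum(t2, axis=-1, keepdims=True)
    return (s1 - t1) / (s2 - t2)


def _rss_terms(bx, by, sy):
    """Per-SNP weighted leave-one-out residual contributions."""
    w = sy**-2.0
    theta_loo = _loo_slopes(bx, by, w)
    return w * (by - theta_loo * bx) ** 2


def _require_k(instruments: InstrumentSet) -> None:
    if instruments.k < MIN_SNPS:
        raise InsufficientInstrumentsError(
            f"MR-PRESSO needs k >= {MIN_SNPS}, got k = {instruments.k}"
        )


def _simulate_terms(instruments: InstrumentSet, config: PressoConfig):
    """Observed per-SNP RSS terms plus their simulated null counterparts."""
    _require_k(instruments)
    ids, bx, sx, by, sy = _canonical_arrays(instruments)
    obs_terms = _rss_terms(bx, by, sy)
    w = sy**-2.0
    theta_loo = _loo_slopes(bx, by, w)

    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), 0x5E55]))
    shape = (config.n_sim, instruments.k)
    bx_sim = rng.normal(bx, sx, size=shape)
    by_sim = rng.normal(theta_loo * bx, sy, size=shape)
    sim_terms = _rss_terms(bx_sim, by_sim, sy)
    return ids, obs_terms, sim_terms


def presso_global(instruments: InstrumentSet, config: PressoConfig):
    """Global heterogeneity test: returns (observed RSS, empirical p)."""
    _, obs_terms, sim_terms = _simulate_terms(instruments, config)
    rss_obs = float(np.sum(obs_terms))
    rss_sim = np.sum(sim_terms, axis=1)
    global_p = float((1 + np.sum(rss_sim >= rss_obs)) / (config.n_sim + 1))
    return rss_obs, global_p


def presso_outlier(instruments: InstrumentSet, config: PressoConfig):
    """Per-SNP outlier test: empirical p per SNP, flags at Bonferroni
    ``outlier_alpha / k``.  Returns (p-values keyed by rsID, flagged ids)."""
    ids, obs_terms, sim_terms = _simulate_terms(instruments, config)
    counts = np.sum(sim_terms >= obs_terms, axis=0)
    pvals = (1 + counts) / (config.n_sim + 1)
    threshold = config.outlier_alpha / instruments.k
    outlier_p = {s: float(p) for s, p in zip(ids, pvals)}
    flagged = tuple(s for s, p in zip(ids, pvals) if p < threshold)
    return outlier_p, flagged


def _regression_estimate(instruments: InstrumentSet) -> MREstimate:
    """IVW regression point with multiplicative SE and t (k-1 df) inference."""
    _, _, _, beta, se_fixed, _, sigma = ratio_statistics(instruments)
    se = se_fixed if sigma is None else se_fixed * sigma
    return MREstimate.from_beta_se(
        "ivw_mre", instruments.k, beta, se, dist="t", df=instruments.k - 1, dispersion=sigma
    )


def presso_run(instruments: InstrumentSet, config: PressoConfig) -> PressoResult:
    """Full MR-PRESSO: raw estimate, global test, outlier flags, and — when
    outliers exist — the corrected estimate and distortion test."""
    _require_k(instruments)
    raw = _regression_estimate(instruments)
    ids, obs_terms, sim_terms = _simulate_terms(instruments, config)
    rss_obs = float(np.sum(obs_terms))
    global_p = float((1 + np.sum(np.sum(sim_terms, axis=1) >= rss_obs)) / (config.n_sim + 1))
    counts = np.sum(sim_terms >= obs_terms, axis=0)
    pvals = (1 + counts) / (config.n_sim + 1)
    outlier_p = {s: float(p) for s, p in zip(ids, pvals)}
    flagged = tuple(s for s, p in zip(ids, pvals) if p < config.outlier_alpha / instruments.k)

    corrected = None
    distortion_p = None
    if flagged:
        reduced = instruments.subset(set(instruments.snp_ids) - set(flagged))
        corrected = _regression_estimate(reduced)
        distortion_p = _distortion_test(instruments, config, len(flagged), raw, corrected)
    return PressoResult(
        raw=raw,
        global_rss=rss_obs,
        global_p=global_p,
        outlier_p=outlier_p,
        outliers=flagged,
        corrected=corrected,
        distortion_p=distortion_p,
    )


def _distortion_test(
    instruments: InstrumentSet,
    config: PressoConfig,
    n_removed: int,
    raw: MREstimate,
    corrected: MREstimate,
) -> float:
    """Compare the observed estimate shift after outlier removal with shifts
    under removal of ``n_removed`` SNPs chosen at random (two-sided)."""
    _, bx, _, by, sy = _canonical_arrays(instruments)
    w = sy**-2.0
    k = instruments.k
    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), 0xD157]))
    shift_obs = corrected.beta - raw.beta
    shifts = np.empty(config.n_sim)
    t1, t2 = w * bx * by, w * bx * bx
    s1, s2 = np.sum(t1), np.sum(t2)
    for b in range(config.n_sim):
        drop = rng.choice(k, size=n_removed, replace=False)
        slope = (s1 - np.sum(t1[drop])) / (s2 - np.sum(t2[drop]))
        shifts[b] = slope - raw.beta
    return float((1 + np.sum(np.abs(shifts) >= abs(shift_obs))) / (config.n_sim + 1))
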