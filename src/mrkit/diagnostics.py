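"""Heterogeneity diagnostics, sensitivity analyses, and study orchestration.

``cochran_q`` and ``leave_one_out`` are the per-exposure diagnostics;
``run_full_analysis`` drives the whole multi-exposure study: instrument
selection, every estimator the instrument count supports, MR-PRESSO,
heterogeneity, leave-one-out, Bonferroni significance labels, and TSV/JSON
export.  Exposures with too few SNPs for a sensitivity analysis carry an
explicit absence reason instead of aborting the run, and any per-exposure
failure is recorded without stopping the remaining exposures.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import ConfigError, InsufficientInstrumentsError, MRKitError
from .gwas_io import AssociationTable, load_fixture, read_association_table
from .harmonize import (
    DEFAULT_MAF_THRESHOLD,
    DEFAULT_R2_THRESHOLD,
    GWAS_SIGNIFICANCE,
    InstrumentSet,
    build_instrument_set,
    read_ld_matrix,
)
from .mr_core import EggerEstimate, MREstimate, egger, ivw, max_likelihood, ratio_statistics, weighted_median
from .presso import PressoConfig, PressoResult, presso_run

__all__ = [
    "HeterogeneityStats",
    "ExposureResult",
    "AnalysisReport",
    "RunConfig",
    "cochran_q",
    "leave_one_out",
    "significance_label",
    "run_full_analysis",
]

logger = logging.getLogger("mrkit")

#: Bonferroni-adjusted significance threshold: 0.05 over six exposures.
BONFERRONI_THRESHOLD = 0.008
NOMINAL_THRESHOLD = 0.05

ABSENT_FEWER_THAN_THREE = "fewer than three SNPs"
ABSENT_FEWER_THAN_FOUR = "fewer than four SNPs"


@dataclass(frozen=True)
class HeterogeneityStats:
    """Cochran's Q on the per-SNP Wald ratios, with its chi-square p-value
    and the multiplicative dispersion sigma = sqrt(Q/df)."""

    q: float
    df: int
    p_q: float
    sigma: float


def cochran_q(instruments: InstrumentSet) -> HeterogeneityStats:
    """Heterogeneity of the per-SNP ratios around the IVW pooled estimate.

    Q = sum of w_i (ratio_i - beta_IVW)^2 with inverse-variance weights from
    first-order Delta SEs; p from chi-square with k-1 df.  The sigma here is
    by construction the dispersion applied inside the multiplicative
    random-effects IVW (single source of truth).
    """
    if instruments.k < 2:
        raise InsufficientInstrumentsError(
            f"Cochran's Q needs k >= 2, got k = {instruments.k}"
        )
    _, _, _, _, _, q, sigma = ratio_statistics(instruments)
    df = instruments.k - 1
    return HeterogeneityStats(q=q, df=df, p_q=float(stats.chi2.sf(q, df)), sigma=sigma)


def leave_one_out(instruments: InstrumentSet) -> tuple[tuple[str, MREstimate], ...]:
    """Multiplicative random-effects IVW re-estimates, each omitting one SNP."""
    if instruments.k < 2:
        raise InsufficientInstrumentsError(
            f"leave-one-out needs k >= 2, got k = {instruments.k}"
        )
    return tuple(
        (snp, ivw(instruments.drop_snp(snp), "multiplicative_random"))
        for snp in instruments.snp_ids
    )


def significance_label(pval: float) -> str:
    """Bonferroni label: significant (< 0.008), suggestive (< 0.05), null."""
    if pval < BONFERRONI_THRESHOLD:
        return "significant"
    if pval < NOMINAL_THRESHOLD:
        return "suggestive"
    return "null"


@dataclass(frozen=True)
class ExposureResult:
    """Everything computed for one exposure, or the error that stopped it."""

    exposure: str
    outcome: str
    k: int = 0
    estimates: tuple[MREstimate, ...] = ()
    heterogeneity: HeterogeneityStats | None = None
    heterogeneity_absent: str | None = None
    egger_est: EggerEstimate | None = None
    egger_absent: str | None = None
    presso: PressoResult | None = None
    presso_absent: str | None = None
    loo: tuple[tuple[str, MREstimate], ...] = ()
    label: str | None = None
    dropped: tuple[tuple[str, str], ...] = ()
    error: str | None = None

    def estimate(self, method: str) -> MREstimate:
        for est in self.estimates:
            if est.method == method:
                return est
        raise KeyError(method)


@dataclass(frozen=True)
class AnalysisReport:
    """The full study: one :class:`ExposureResult` per exposure plus config echo."""

    results: tuple[ExposureResult, ...]
    seed: int
    config: dict = field(default_factory=dict)

    def for_exposure(self, name: str) -> ExposureResult:
        for res in self.results:
            if res.exposure == name:
                return res
        raise KeyError(name)

    # -- serialization ----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "config": self.config,
            "results": [_result_to_dict(r) for r in self.results],
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=1, sort_keys=True)

    @classmethod
    def from_dict(cls, data: dict) -> "AnalysisReport":
        return cls(
            results=tuple(_result_from_dict(d) for d in data["results"]),
            seed=data["seed"],
            config=data.get("config", {}),
        )

    @classmethod
    def from_json(cls, text: str) -> "AnalysisReport":
        return cls.from_dict(json.loads(text))


def _est_to_dict(est: MREstimate | None):
    return None if est is None else dataclasses.asdict(est)


def _est_from_dict(d):
    return None if d is None else MREstimate(**d)


def _result_to_dict(res: ExposureResult) -> dict:
    d = {
        "exposure": res.exposure,
        "outcome": res.outcome,
        "k": res.k,
        "estimates": [_est_to_dict(e) for e in res.estimates],
        "heterogeneity": None
        if res.heterogeneity is None
        else dataclasses.asdict(res.heterogeneity),
        "heterogeneity_absent": res.heterogeneity_absent,
        "egger": None
        if res.egger_est is None
        else {
            "slope": _est_to_dict(res.egger_est.slope),
            "intercept": res.egger_est.intercept,
            "intercept_se": res.egger_est.intercept_se,
            "intercept_p": res.egger_est.intercept_p,
        },
        "egger_absent": res.egger_absent,
        "presso": None
        if res.presso is None
        else {
            "raw": _est_to_dict(res.presso.raw),
            "global_rss": res.presso.global_rss,
            "global_p": res.presso.global_p,
            "outlier_p": res.presso.outlier_p,
            "outliers": list(res.presso.outliers),
            "corrected": _est_to_dict(res.presso.corrected),
            "distortion_p": res.presso.distortion_p,
        },
        "presso_absent": res.presso_absent,
        "loo": [[snp, _est_to_dict(e)] for snp, e in res.loo],
        "label": res.label,
        "dropped": [list(t) for t in res.dropped],
        "error": res.error,
    }
    return d


def _result_from_dict(d: dict) -> ExposureResult:
    egg = d.get("egger")
    presso = d.get("presso")
    return ExposureResult(
        exposure=d["exposure"],
        outcome=d["outcome"],
        k=d["k"],
        estimates=tuple(_est_from_dict(e) for e in d["estimates"]),
        heterogeneity=None
        if d["heterogeneity"] is None
        else HeterogeneityStats(**d["heterogeneity"]),
        heterogeneity_absent=d.get("heterogeneity_absent"),
        egger_est=None
        if egg is None
        else EggerEstimate(
            slope=_est_from_dict(egg["slope"]),
            intercept=egg["intercept"],
            intercept_se=egg["intercept_se"],
            intercept_p=egg["intercept_p"],
        ),
        egger_absent=d.get("egger_absent"),
        presso=None
        if presso is None
        else PressoResult(
            raw=_est_from_dict(presso["raw"]),
            global_rss=presso["global_rss"],
            global_p=presso["global_p"],
            outlier_p=presso["outlier_p"],
            outliers=tuple(presso["outliers"]),
            corrected=_est_from_dict(presso["corrected"]),
            distortion_p=presso["distortion_p"],
        ),
        presso_absent=d.get("presso_absent"),
        loo=tuple((snp, _est_from_dict(e)) for snp, e in d["loo"]),
        label=d.get("label"),
        dropped=tuple((s, r) for s, r in d.get("dropped", [])),
        error=d.get("error"),
    )


@dataclass(frozen=True)
class RunConfig:
    """Configuration of a full multi-exposure analysis.

    ``exposures`` maps labels to (exposure source, outcome source); a source
    is either ``"fixture:NAME"`` or a TSV path.  The seed drives the
    weighted-median bootstrap and MR-PRESSO; each exposure receives a stable
    sub-seed derived from (seed, label) so results do not depend on the
    order in which exposures are listed.
    """

    seed: int
    exposures: tuple[tuple[str, str, str], ...]  # (label, exposure_src, outcome_src)
    methods: tuple[str, ...] = ("ivw", "ml", "median", "egger", "presso")
    n_boot: int = 1000
    n_sim: int = 5000
    p_threshold: float = GWAS_SIGNIFICANCE
    r2_threshold: float = DEFAULT_R2_THRESHOLD
    maf_threshold: float = DEFAULT_MAF_THRESHOLD
    ld_path: str | None = None
    out_dir: str | None = None

    def __post_init__(self):
        if self.seed is None:
            raise ConfigError("a seed is mandatory")
        if not self.exposures:
            raise ConfigError("at least one exposure is required")
        unknown = set(self.methods) - {"ivw", "ml", "median", "egger", "presso"}
        if unknown:
            raise ConfigError(f"unknown methods: {sorted(unknown)}")


def _resolve_table(src: str, *, trait: str, trait_type: str, role: str) -> AssociationTable:
    if src.startswith("fixture:"):
        study = load_fixture(src.split(":", 1)[1])
        return study.exposure if role == "exposure" else study.outcome
    return read_association_table(src, trait=trait, trait_type=trait_type)


def _sub_seed(seed: int, label: str) -> int:
    return int(
        np.random.SeedSequence([int(seed), zlib.crc32(label.encode())]).generate_state(1)[0]
        % (2**31)
    )


def _analyse_exposure(
    label: str, instruments: InstrumentSet, config: RunConfig
) -> ExposureResult:
    sub = _sub_seed(config.seed, label)
    k = instruments.k
    estimates = []
    if "ivw" in config.methods:
        estimates.append(ivw(instruments, "multiplicative_random"))
        estimates.append(ivw(instruments, "fixed"))
    if "ml" in config.methods:
        estimates.append(max_likelihood(instruments))

    egger_est = egger_absent = None
    if "egger" in config.methods:
        if k >= 3:
            egger_est = egger(instruments)
            estimates.append(egger_est.slope)
        else:
            egger_absent = ABSENT_FEWER_THAN_THREE
    if "median" in config.methods:
        if k >= 3:
            estimates.append(weighted_median(instruments, n_boot=config.n_boot, seed=sub))
        else:
            pass  # recorded below alongside egger absence
    median_absent = ABSENT_FEWER_THAN_THREE if ("median" in config.methods and k < 3) else None

    presso_res = presso_absent = None
    if "presso" in config.methods:
        if k >= 4:
            presso_res = presso_run(
                instruments, PressoConfig(seed=sub, n_sim=config.n_sim)
            )
        else:
            presso_absent = (
                ABSENT_FEWER_THAN_THREE if k < 3 else ABSENT_FEWER_THAN_FOUR
            )

    het = het_absent = None
    if k >= 2:
        het = cochran_q(instruments)
        loo = leave_one_out(instruments)
    else:
        het_absent = "single SNP"
        loo = ()

    primary = next((e for e in estimates if e.method == "ivw_mre"), None)
    return ExposureResult(
        exposure=label,
        outcome=instruments.outcome,
        k=k,
        estimates=tuple(estimates),
        heterogeneity=het,
        heterogeneity_absent=het_absent,
        egger_est=egger_est,
        egger_absent=egger_absent or median_absent,
        presso=presso_res,
        presso_absent=presso_absent,
        loo=loo,
        label=None if primary is None else significance_label(primary.pval),
        dropped=instruments.dropped,
    )


def run_full_analysis(config: RunConfig) -> AnalysisReport:
    """Run the complete study over every configured exposure.

    Per-exposure failures are caught and recorded in that exposure's
    ``error`` field; remaining exposures still run.  When ``out_dir`` is
    set, writes results/heterogeneity/leave-one-out/scatter tables (TSV)
    and the full ``report.json``.
    """
    ld = read_ld_matrix(config.ld_path) if config.ld_path else None
    results = []
    instruments_map: dict[str, InstrumentSet] = {}
    for label, exp_src, out_src in config.exposures:
        t0 = time.perf_counter()
        try:
            exposure = _resolve_table(exp_src, trait=label, trait_type="continuous", role="exposure")
            outcome = _resolve_table(out_src, trait="outcome", trait_type="binary", role="outcome")
            instruments = build_instrument_set(
                exposure,
                outcome,
                ld=ld,
                p_threshold=config.p_threshold,
                r2_threshold=config.r2_threshold,
                maf_threshold=config.maf_threshold,
            )
            instruments_map[label] = instruments
            results.append(_analyse_exposure(label, instruments, config))
        except MRKitError as exc:
            logger.warning("exposure %s failed: %s", label, exc)
            results.append(
                ExposureResult(exposure=label, outcome=out_src, error=str(exc))
            )
        logger.info("exposure %s finished in %.2fs", label, time.perf_counter() - t0)

    report = AnalysisReport(
        results=tuple(results),
        seed=config.seed,
        config={
            "methods": list(config.methods),
            "n_boot": config.n_boot,
            "n_sim": config.n_sim,
            "p_threshold": config.p_threshold,
            "r2_threshold": config.r2_threshold,
            "maf_threshold": config.maf_threshold,
        },
    )
    if config.out_dir:
        write_report(report, config.out_dir, instruments_map)
    return report


# -- tabular export -------------------------------------------------------


def _results_frame(report: AnalysisReport) -> pd.DataFrame:
    rows = []
    for res in report.results:
        for est in res.estimates:
            rows.append(
                [
                    res.exposure,
                    res.outcome,
                    est.method,
                    est.k,
                    est.beta,
                    est.se,
                    est.pval,
                    est.or_point,
                    est.or_low,
                    est.or_high,
                    est.dispersion,
                ]
            )
    return pd.DataFrame(
        rows,
        columns=[
            "exposure",
            "outcome",
            "method",
            "k",
            "beta",
            "se",
            "pval",
            "or",
            "ci_low",
            "ci_high",
            "sigma",
        ],
    )


def _heterogeneity_frame(report: AnalysisReport) -> pd.DataFrame:
    rows = []
    for res in report.results:
        het = res.heterogeneity
        egg = res.egger_est
        rows.append(
            [
                res.exposure,
                None if het is None else het.q,
                None if het is None else het.df,
                None if het is None else het.p_q,
                None if het is None else het.sigma,
                None if egg is None else egg.intercept,
                None if egg is None else egg.intercept_p,
            ]
        )
    return pd.DataFrame(
        rows,
        columns=["exposure", "q", "df", "p_q", "sigma", "egger_intercept", "egger_intercept_p"],
    )


def _loo_frame(report: AnalysisReport) -> pd.DataFrame:
    rows = []
    for res in report.results:
        for snp, est in res.loo:
            rows.append(
                [res.exposure, snp, est.k, est.beta, est.se, est.pval, est.or_point, est.or_low, est.or_high]
            )
    return pd.DataFrame(
        rows,
        columns=["exposure", "omitted_snp", "k", "beta", "se", "pval", "or", "ci_low", "ci_high"],
    )


def _scatter_frames(report: AnalysisReport, config_by_label: dict) -> tuple[pd.DataFrame, pd.DataFrame]:
    points, fits = [], []
    for res in report.results:
        instruments = config_by_label.get(res.exposure)
        if instruments is not None:
            for p in instruments.pairs:
                points.append([res.exposure, p.snp_id, p.beta_exp, p.se_exp, p.beta_out, p.se_out])
        for est in res.estimates:
            intercept = 0.0
            if est.method == "egger_slope" and res.egger_est is not None:
                intercept = res.egger_est.intercept
            fits.append([res.exposure, est.method, est.beta, intercept])
    return (
        pd.DataFrame(points, columns=["exposure", "snp", "beta_exp", "se_exp", "beta_out", "se_out"]),
        pd.DataFrame(fits, columns=["exposure", "method", "slope", "intercept"]),
    )


def write_report(report: AnalysisReport, out_dir, instruments_by_label: dict | None = None) -> None:
    """Write the TSV tables and report.json into ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    _results_frame(report).to_csv(out / "results.tsv", sep="\t", index=False)
    _heterogeneity_frame(report).to_csv(out / "heterogeneity.tsv", sep="\t", index=False)
    _loo_frame(report).to_csv(out / "leave_one_out.tsv", sep="\t", index=False)
    points, fits = _scatter_frames(report, instruments_by_label or {})
    points.to_csv(out / "scatter_points.tsv", sep="\t", index=False)
    fits.to_csv(out / "scatter_fits.tsv", sep="\t", index=False)
    (out / "report.json").write_text(report.to_json(), encoding="utf-8")
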