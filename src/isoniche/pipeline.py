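"""End-to-end orchestration: standardize → fit → sample → compare.

A single call runs the whole analysis on a dataset (read from CSV or
generated from a StudySpec) and writes every artifact as delimited text:
standardized records, maximum-likelihood ellipse fits, posterior draws,
ellipse boundary coordinates for plotting, the per-group comparison
report with its pairwise-probability companion, and a machine-parseable
run log of key=value lines (seeds, configuration, R-hat values,
warnings).  Reruns with the same configuration and seed reproduce all
numeric artifacts exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .bayes import MCMCConfig, PosteriorSample, sample_posterior
from .compare import ComparisonReport, build_report
from .ellipse import EllipseFit, ellipse_boundary, fit_ml_ellipse
from .errors import ContractError
from .records import Dataset, FitUnit, IsotopeRecord, fit_units, read_dataset
from .simulate import StudySpec, derive_seed, generate_study
from .standardize import DEFAULT_TDF, standardize_dataset


@dataclass
class RunConfig:
    """Everything one run needs; exactly one of input_path / study_spec."""

    output_dir: str
    input_path: str | None = None
    study_spec: StudySpec | None = None
    tdf: float = DEFAULT_TDF
    reference_year: int | None = None  # default: first year in the data
    pooled_baseline: bool = False
    min_n: int = 3
    mcmc: MCMCConfig = field(default_factory=MCMCConfig)
    decimal_mark: str = "."
    interval_method: str = "hdi"

    def __post_init__(self) -> None:
        if (self.input_path is None) == (self.study_spec is None):
            raise ContractError("provide exactly one of input_path or study_spec")


@dataclass
class RunResult:
    dataset: Dataset
    standardized: pd.DataFrame
    fits: dict[tuple[str, int], EllipseFit]
    posteriors: dict[tuple[str, int], PosteriorSample]
    reports: dict[str, ComparisonReport]
    skipped_units: list[FitUnit]
    artifacts: dict[str, Path]
    log_lines: list[str]


def _guild_of(dataset: Dataset, group: str) -> str:
    for rec in dataset.records:
        if rec.group == group:
            return rec.guild
    return ""


def run_pipeline(config: RunConfig) -> RunResult:
    """Execute the full workflow and write all artifacts under output_dir."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    log: list[str] = [f"isoniche_version={__version__}"]

    # ---- load / generate -------------------------------------------------
    if config.study_spec is not None:
        dataset = generate_study(config.study_spec)
        log.append(f"input=synthetic study_seed={config.study_spec.seed}")
    else:
        dataset = read_dataset(config.input_path, decimal_mark=config.decimal_mark)
        log.append(f"input={config.input_path}")

    years = sorted({r.year for r in dataset.consumer_records()})
    ref_year = config.reference_year if config.reference_year is not None else years[0]
    if ref_year not in years:
        raise ContractError(
            f"stage=validate reference year {ref_year} not among data years {years}"
        )
    log += [
        f"tdf={config.tdf}",
        f"reference_year={ref_year}",
        f"mcmc_seed={config.mcmc.seed}",
        f"mcmc_chains={config.mcmc.n_chains}",
        f"mcmc_iters={config.mcmc.n_iter}",
        f"mcmc_thin={config.mcmc.thin}",
        f"mcmc_burnin={config.mcmc.burn_in}",
    ]

    # ---- standardize -----------------------------------------------------
    standardized = standardize_dataset(
        dataset, tdf=config.tdf, pooled_baseline=config.pooled_baseline
    )
    std_path = out / "standardized.csv"
    standardized.to_csv(std_path, index=False)

    std_records = [
        IsotopeRecord(r.record_id, r.group, r.guild, int(r.year), r.d13C_cor, r.d15N_cor)
        for r in standardized.itertuples(index=False)
    ]
    units = fit_units(Dataset(records=std_records), min_n=config.min_n)

    # ---- fit + sample ----------------------------------------------------
    fits: dict[tuple[str, int], EllipseFit] = {}
    posteriors: dict[tuple[str, int], PosteriorSample] = {}
    skipped: list[FitUnit] = []
    for unit in units:
        if unit.insufficient_n:
            skipped.append(unit)
            log.append(f"warning=insufficient_n group={unit.group} year={unit.year} n={unit.n}")
            continue
        try:
            fit = fit_ml_ellipse(unit.points, unit.group, unit.year)
            unit_seed = int(
                derive_seed(config.mcmc.seed, unit.group, unit.year).generate_state(1)[0]
            )
            unit_cfg = MCMCConfig(
                n_chains=config.mcmc.n_chains,
                n_iter=config.mcmc.n_iter,
                thin=config.mcmc.thin,
                burn_in=config.mcmc.burn_in,
                seed=unit_seed,
                mu0=config.mcmc.mu0,
                kappa0=config.mcmc.kappa0,
                nu0=config.mcmc.nu0,
                wishart_scale=config.mcmc.wishart_scale,
            )
            with warnings.catch_warnings(record=True) as caught:
                warnings.simplefilter("always")
                post = sample_posterior(unit.points, unit_cfg, unit.group, unit.year)
            for w in caught:
                msg = str(w.message).replace(" ", "_")
                log.append(f"warning=sampler group={unit.group} year={unit.year} message={msg}")
        except Exception as exc:
            raise type(exc)(
                f"stage=fit group={unit.group} year={unit.year}: {exc}"
            ) from exc
        fits[(unit.group, unit.year)] = fit
        posteriors[(unit.group, unit.year)] = post
        for name, value in post.rhat.items():
            log.append(
                f"event=rhat group={unit.group} year={unit.year} scalar={name} value={value:.5f}"
            )

    _write_fits(fits, out / "fits.csv")
    _write_draws(posteriors, out / "posterior_draws.csv")
    _write_boundaries(fits, out / "ellipse_boundaries.csv")

    # ---- compare ---------------------------------------------------------
    groups = sorted({g for g, _ in fits})
    reports: dict[str, ComparisonReport] = {}
    for group in groups:
        g_fits = {y: f for (g, y), f in fits.items() if g == group}
        g_posts = {y: p for (g, y), p in posteriors.items() if g == group}
        if len(g_fits) < 2 or ref_year not in g_fits:
            log.append(f"warning=comparison_skipped group={group} years={sorted(g_fits)}")
            continue
        reports[group] = build_report(
            g_posts,
            g_fits,
            ref_year,
            guild=_guild_of(dataset, group),
            expected_years=years,
            interval_method=config.interval_method,
        )
        if reports[group].missing_years:
            log.append(
                f"warning=missing_years group={group} years={reports[group].missing_years}"
            )
    _write_reports(reports, out / "comparison_report.csv", out / "pairwise_probabilities.csv")

    log_path = out / "run.log"
    log_path.write_text("\n".join(log) + "\n")
    artifacts = {
        "standardized": std_path,
        "fits": out / "fits.csv",
        "posterior_draws": out / "posterior_draws.csv",
        "ellipse_boundaries": out / "ellipse_boundaries.csv",
        "comparison_report": out / "comparison_report.csv",
        "pairwise_probabilities": out / "pairwise_probabilities.csv",
        "log": log_path,
    }
    return RunResult(
        dataset=dataset,
        standardized=standardized,
        fits=fits,
        posteriors=posteriors,
        reports=reports,
        skipped_units=skipped,
        artifacts=artifacts,
        log_lines=log,
    )


def _write_fits(fits, path: Path) -> None:
    rows = [
        {
            "group": f.group,
            "year": f.year,
            "n": f.n,
            "mu1": f.mean[0],
            "mu2": f.mean[1],
            "s11": f.cov[0, 0],
            "s12": f.cov[0, 1],
            "s22": f.cov[1, 1],
            "sea": f.sea,
            "seac": f.seac,
        }
        for f in fits.values()
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def _write_draws(posteriors, path: Path) -> None:
    frames = []
    for post in posteriors.values():
        chains, k = post.seab_draws.shape
        idx_chain = np.repeat(np.arange(chains), k)
        idx_draw = np.tile(np.arange(k), chains)
        frames.append(
            pd.DataFrame(
                {
                    "group": post.group,
                    "year": post.year,
                    "chain": idx_chain,
                    "draw_index": idx_draw,
                    "mu1": post.mu_draws[..., 0].reshape(-1),
                    "mu2": post.mu_draws[..., 1].reshape(-1),
                    "s11": post.cov_draws[..., 0, 0].reshape(-1),
                    "s12": post.cov_draws[..., 0, 1].reshape(-1),
                    "s22": post.cov_draws[..., 1, 1].reshape(-1),
                    "seab": post.seab_draws.reshape(-1),
                }
            )
        )
    df = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(
            columns=["group", "year", "chain", "draw_index", "mu1", "mu2", "s11", "s12", "s22", "seab"]
        )
    )
    df.to_csv(path, index=False)


def _write_boundaries(fits, path: Path, n_points: int = 100) -> None:
    frames = []
    for f in fits.values():
        b = ellipse_boundary(f.mean, f.cov, 1.0, n_points)
        frames.append(
            pd.DataFrame(
                {"group": f.group, "year": f.year, "x": b[:, 0], "y": b[:, 1]}
            )
        )
    df = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(columns=["group", "year", "x", "y"])
    )
    df.to_csv(path, index=False)


def _write_reports(reports, report_path: Path, pairwise_path: Path) -> None:
    per_year, pairwise = [], []
    for rep in reports.values():
        df = rep.per_year.copy()
        df.insert(0, "group", rep.group)
        df.insert(1, "guild", rep.guild)
        per_year.append(df)
        pw = rep.pairwise.copy()
        pw.insert(0, "group", rep.group)
        pairwise.append(pw)
    cols = [
        "group", "guild", "year", "n", "seac", "seac_ratio", "seab_mode",
        "hdi50_lo", "hdi50_hi", "hdi75_lo", "hdi75_hi", "hdi95_lo", "hdi95_hi",
    ]
    (pd.concat(per_year, ignore_index=True) if per_year else pd.DataFrame(columns=cols)).to_csv(
        report_path, index=False
    )
    pw_cols = ["group", "year_a", "year_b", "p_a_less_b"]
    (pd.concat(pairwise, ignore_index=True) if pairwise else pd.DataFrame(columns=pw_cols)).to_csv(
        pairwise_path, index=False
    )


def load_fits(path) -> dict[tuple[str, int], EllipseFit]:
    """Rebuild EllipseFit objects from a fits.csv artifact."""
    fits = {}
    for r in pd.read_csv(path).itertuples(index=False):
        cov = np.array([[r.s11, r.s12], [r.s12, r.s22]])
        fits[(r.group, int(r.year))] = EllipseFit(
            group=r.group,
            year=int(r.year),
            n=int(r.n),
            mean=np.array([r.mu1, r.mu2]),
            cov=cov,
            sea=float(r.sea),
            seac=float(r.seac),
        )
    return fits


def load_draws(path) -> dict[tuple[str, int], PosteriorSample]:
    """Rebuild PosteriorSample objects from a posterior_draws.csv artifact.

    R-hat values are not stored in the artifact and come back as NaN; the
    draws themselves round-trip exactly.
    """
    df = pd.read_csv(path)
    posteriors = {}
    for (group, year), g in df.groupby(["group", "year"], sort=True):
        chains = int(g["chain"].max()) + 1
        k = int(g["draw_index"].max()) + 1
        g = g.sort_values(["chain", "draw_index"])
        mu = np.stack([g["mu1"].to_numpy(), g["mu2"].to_numpy()], axis=-1).reshape(chains, k, 2)
        cov = np.empty((chains, k, 2, 2))
        cov[..., 0, 0] = g["s11"].to_numpy().reshape(chains, k)
        cov[..., 0, 1] = cov[..., 1, 0] = g["s12"].to_numpy().reshape(chains, k)
        cov[..., 1, 1] = g["s22"].to_numpy().reshape(chains, k)
        posteriors[(group, int(year))] = PosteriorSample(
            group=group,
            year=int(year),
            n=0,
            mu_draws=mu,
            cov_draws=cov,
            seab_draws=g["seab"].to_numpy().reshape(chains, k),
            rhat={name: float("nan") for name in ("log_seab", "mu1", "mu2")},
            config=MCMCConfig(),
        )
    return posteriors


def compare_artifacts(
    fits_path, draws_path, reference_year: int | None, out_dir, interval_method: str = "hdi"
) -> dict[str, ComparisonReport]:
    """Stand-alone comparison stage over previously written fit artifacts."""
    fits = load_fits(fits_path)
    posteriors = load_draws(draws_path)
    years = sorted({y for _, y in fits})
    ref_year = reference_year if reference_year is not None else years[0]
    reports = {}
    for group in sorted({g for g, _ in fits}):
        g_fits = {y: f for (g, y), f in fits.items() if g == group}
        g_posts = {y: p for (g, y), p in posteriors.items() if g == group}
        if len(g_fits) < 2 or ref_year not in g_fits:
            continue
        reports[group] = build_report(
            g_posts, g_fits, ref_year, expected_years=years, interval_method=interval_method
        )
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    _write_reports(reports, out / "comparison_report.csv", out / "pairwise_probabilities.csv")
    return reports


def summarize_sources(records: pd.DataFrame) -> pd.DataFrame:
    """Mean ± sd of basal-resource isotope values per source per year.

    Expects columns ``source, year, d13C, d15N``; with a single record the
    sd columns are NaN and ``sd_available`` is False.
    """
    required = {"source", "year", "d13C", "d15N"}
    missing = required - set(records.columns)
    if missing:
        raise ContractError(f"missing column(s) {sorted(missing)}")
    rows = []
    for (source, year), grp in records.groupby(["source", "year"], sort=True):
        rows.append(
            {
                "source": source,
                "year": year,
                "n": len(grp),
                "mean_d13C": grp["d13C"].mean(),
                "sd_d13C": grp["d13C"].std(ddof=1) if len(grp) > 1 else np.nan,
                "mean_d15N": grp["d15N"].mean(),
                "sd_d15N": grp["d15N"].std(ddof=1) if len(grp) > 1 else np.nan,
                "sd_available": len(grp) > 1,
            }
        )
    return pd.DataFrame(rows)
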