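"""Synthetic datasets with the group×year bivariate-normal structure the
ellipse analysis assumes.

Each consumer (group, year) is one bivariate normal cluster in raw δ-space
whose standard-ellipse area, shape (eigenvalue ratio), orientation and
sample size are set directly; the baseline guild is univariate normal in
δ¹⁵N with δ¹³C uniform over a stated range (baseline carbon never enters
the formulas).  The default template mirrors the study design: five
consumer groups over three years (totals 19, 23, 29, 20, 14 split as
evenly as possible), one baseline guild, and between-year area
trajectories matching the study's reported SEAc ratios.

Per-(group, year) seeds derive from the master seed by combining it with
a CRC-32 of ``"group|year"`` in a NumPy SeedSequence, so any single
cluster's records are reproducible and independent of every other spec.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, asdict

import numpy as np
import yaml

from .records import Dataset, IsotopeRecord


@dataclass(frozen=True)
class GroupYearSpec:
    """One consumer cluster: its location, ellipse geometry and sample size."""

    group: str
    guild: str
    year: int
    mean: tuple[float, float]  # raw (δ13C, δ15N)
    area: float  # target SEA in raw δ² units
    n: int
    eccentricity: float = 1.0  # ratio of covariance eigenvalues, >= 1
    angle: float = 0.0  # orientation of the major axis, radians
    # heavy-tailed contamination for robustness testing only (off by default):
    # each point is drawn with this probability from the same normal with
    # covariance inflated by contamination_scale
    contamination: float = 0.0
    contamination_scale: float = 9.0

    def __post_init__(self) -> None:
        if not self.area > 0:
            raise ValueError(f"area must be > 0, got {self.area}")
        if self.n < 3:
            raise ValueError(f"n must be >= 3, got {self.n}")
        if self.eccentricity < 1:
            raise ValueError(f"eccentricity must be >= 1, got {self.eccentricity}")
        if not 0 <= self.contamination < 1:
            raise ValueError(f"contamination must be in [0, 1), got {self.contamination}")


@dataclass(frozen=True)
class BaselineYearSpec:
    """Baseline guild for one year: δ¹⁵N normal, δ¹³C uniform."""

    year: int
    mean_d15N: float
    sd_d15N: float
    n: int
    d13C_range: tuple[float, float] = (-29.0, -25.0)


@dataclass
class StudySpec:
    """Full design: consumer cluster specs, baseline specs, master seed."""

    groups: list[GroupYearSpec] = field(default_factory=list)
    baselines: list[BaselineYearSpec] = field(default_factory=list)
    seed: int = 0

    def validate(self) -> None:
        consumer_years = {g.year for g in self.groups}
        baseline_years = {b.year for b in self.baselines}
        missing = consumer_years - baseline_years
        if missing:
            raise ValueError(f"no baseline spec for consumer year(s) {sorted(missing)}")


def make_sigma(area: float, eccentricity: float = 1.0, angle: float = 0.0) -> np.ndarray:
    """Covariance with standard-ellipse area π√det = ``area``, eigenvalue
    ratio ``eccentricity`` and major axis rotated by ``angle``."""
    if area <= 0:
        raise ValueError(f"area must be > 0, got {area}")
    if eccentricity < 1:
        raise ValueError(f"eccentricity must be >= 1, got {eccentricity}")
    geo = area / np.pi  # sqrt(det) = geometric mean of the eigenvalues
    lam1 = geo * np.sqrt(eccentricity)
    lam2 = geo / np.sqrt(eccentricity)
    c, s = np.cos(angle), np.sin(angle)
    R = np.array([[c, -s], [s, c]])
    return R @ np.diag([lam1, lam2]) @ R.T


def derive_seed(master_seed: int, group: str, year: int) -> np.random.SeedSequence:
    """Stable per-cluster seed: SeedSequence([master, crc32("group|year")])."""
    tag = zlib.crc32(f"{group}|{year}".encode("utf-8"))
    return np.random.SeedSequence([int(master_seed), tag])


def generate_group_year(spec: GroupYearSpec, seed) -> tuple[np.ndarray, list[IsotopeRecord]]:
    """Draw one cluster: points = mean + L·z with L the Cholesky root of the
    spec covariance and z standard normal.  Returns the points and records."""
    rng = np.random.default_rng(seed)
    L = np.linalg.cholesky(make_sigma(spec.area, spec.eccentricity, spec.angle))
    z = rng.standard_normal((spec.n, 2))
    pts = np.asarray(spec.mean, dtype=float) + z @ L.T
    if spec.contamination > 0:
        mask = rng.random(spec.n) < spec.contamination
        inflate = np.sqrt(spec.contamination_scale)
        pts[mask] = spec.mean + (pts[mask] - np.asarray(spec.mean)) * inflate
    records = [
        IsotopeRecord(
            record_id=f"{spec.group}-{spec.year}-{i:03d}",
            group=spec.group,
            guild=spec.guild,
            year=spec.year,
            d13C=float(p[0]),
            d15N=float(p[1]),
        )
        for i, p in enumerate(pts)
    ]
    return pts, records


def generate_baseline_year(spec: BaselineYearSpec, seed) -> list[IsotopeRecord]:
    rng = np.random.default_rng(seed)
    d15n = rng.normal(spec.mean_d15N, spec.sd_d15N, spec.n)
    d13c = rng.uniform(*spec.d13C_range, spec.n)
    return [
        IsotopeRecord(
            record_id=f"baseline-{spec.year}-{i:03d}",
            group="baseline",
            guild="baseline",
            year=spec.year,
            d13C=float(c),
            d15N=float(n),
        )
        for i, (c, n) in enumerate(zip(d13c, d15n))
    ]


def generate_study(spec: StudySpec) -> Dataset:
    """Generate the full dataset (consumers + baselines) for a StudySpec."""
    spec.validate()
    records: list[IsotopeRecord] = []
    for g in spec.groups:
        _, recs = generate_group_year(g, derive_seed(spec.seed, g.group, g.year))
        records.extend(recs)
    for b in spec.baselines:
        records.extend(
            generate_baseline_year(b, derive_seed(spec.seed, "baseline", b.year))
        )
    return Dataset(records=records, provenance=f"synthetic study (seed={spec.seed})")


def _split_total(total: int, k: int) -> list[int]:
    """Split a group total over k years as evenly as possible, remainder first."""
    base, rem = divmod(total, k)
    return [base + (1 if i < rem else 0) for i in range(k)]


# Study-mirroring defaults: (guild, total n over 3 years, raw δ mean,
# first-year SEA in ‰², SEAc-ratio trajectory across the years).
_TEMPLATE_GROUPS = {
    "perch": ("predator", 19, (-26.0, 8.5), 0.8, (1.0, 1.85, 4.46)),
    "roach": ("omnivore", 23, (-28.0, 5.6), 3.0, (1.0, 0.27, 0.25)),
    "crayfish": ("omnivore", 29, (-24.0, 4.8), 1.0, (1.0, 3.51, 1.55)),
    "predatory_zoobenthos": ("predator", 20, (-27.0, 5.3), 2.5, (1.0, 0.08, 0.20)),
    "detritivorous_zoobenthos": ("detritivore", 14, (-26.5, 3.6), 2.0, (1.0, 0.12, 0.02)),
}


def study_template(
    seed: int = 0,
    years=(2014, 2015, 2016),
    eccentricity: float = 2.0,
    angle: float = np.pi / 6,
) -> StudySpec:
    """StudySpec mirroring the study: 5 consumer groups × 3 years with the
    reported group totals and between-year area ratios, plus a baseline
    guild of 8 records per year."""
    groups = []
    for name, (guild, total, mean, area0, ratios) in _TEMPLATE_GROUPS.items():
        for year, n, ratio in zip(years, _split_total(total, len(years)), ratios):
            groups.append(
                GroupYearSpec(
                    group=name,
                    guild=guild,
                    year=year,
                    mean=mean,
                    area=area0 * ratio,
                    n=n,
                    eccentricity=eccentricity,
                    angle=angle,
                )
            )
    baselines = [
        BaselineYearSpec(year=y, mean_d15N=3.0, sd_d15N=0.8, n=8) for y in years
    ]
    return StudySpec(groups=groups, baselines=baselines, seed=seed)


def spec_to_yaml(spec: StudySpec, path) -> None:
    doc = {
        "seed": spec.seed,
        "groups": [asdict(g) for g in spec.groups],
        "baselines": [asdict(b) for b in spec.baselines],
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def spec_from_yaml(path) -> StudySpec:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    groups = [
        GroupYearSpec(
            group=g["group"],
            guild=g["guild"],
            year=int(g["year"]),
            mean=tuple(g["mean"]),
            area=float(g["area"]),
            n=int(g["n"]),
            eccentricity=float(g.get("eccentricity", 1.0)),
            angle=float(g.get("angle", 0.0)),
            contamination=float(g.get("contamination", 0.0)),
            contamination_scale=float(g.get("contamination_scale", 9.0)),
        )
        for g in doc.get("groups", [])
    ]
    baselines = [
        BaselineYearSpec(
            year=int(b["year"]),
            mean_d15N=float(b["mean_d15N"]),
            sd_d15N=float(b["sd_d15N"]),
            n=int(b["n"]),
            d13C_range=tuple(b.get("d13C_range", (-29.0, -25.0))),
        )
        for b in doc.get("baselines", [])
    ]
    spec = StudySpec(groups=groups, baselines=baselines, seed=int(doc.get("seed", 0)))
    spec.validate()
    return spec
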