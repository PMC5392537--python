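"""Synthetic whole-blood methylation cohorts with known age trends.

Emulates the statistical structure of pooled Illumina 27K/450K blood
profiles: per-CpG monotone age trends (linear to cubic, and saturating
logistic shapes, of both signs), additive measurement noise on the beta
scale, per-study batch offsets that are constant within a study, a null sex
effect, monozygotic twin pairs sharing age and a pair-level deviation, and
disease cohorts with per-sample perturbations of a subset of CpGs.

Every generator is deterministic given its seed and returns the ground
truth alongside the matrix, so downstream marker screening, model fitting
and evaluation can be validated against known answers.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import META_COLUMNS

__all__ = [
    "AgeTrendSpec",
    "CohortSpec",
    "TwinCohortSpec",
    "DiseasePerturbationSpec",
    "generate_cohort",
    "generate_twin_cohort",
    "generate_disease_cohort",
    "default_trend_specs",
    "default_cohort_spec",
    "INFORMATIVE_CPGS",
]

TREND_FORMS = ("linear", "quadratic", "cubic", "logistic-clamped")


class CohortConfigError(ValueError):
    """Raised for infeasible or inconsistent cohort specifications."""


@dataclass(frozen=True)
class AgeTrendSpec:
    """Mean methylation of one CpG as a function of age.

    ``coefficients`` are intercept-first on the methylation-fraction scale.
    Polynomial forms evaluate sum(c_k * age**k). The ``logistic-clamped``
    form takes (baseline, amplitude, rate_per_year, midpoint_age) and
    evaluates baseline + amplitude / (1 + exp(-rate*(age-midpoint))).
    ``noise_sd`` is the SD of additive Gaussian noise on the beta scale
    (0 allowed for noiseless validation cohorts).
    """

    cpg_id: str
    form: str
    coefficients: tuple[float, ...]
    noise_sd: float = 0.035
    direction: str = "none"

    def __post_init__(self):
        if self.form not in TREND_FORMS:
            raise CohortConfigError(f"{self.cpg_id}: unknown trend form {self.form!r}")
        if not (0 <= self.noise_sd <= 0.2):
            raise CohortConfigError(
                f"{self.cpg_id}: noise_sd must lie in [0, 0.2], got {self.noise_sd}"
            )
        if self.direction not in ("increasing", "decreasing", "none"):
            raise CohortConfigError(f"{self.cpg_id}: bad direction {self.direction!r}")
        if self.direction == "none" and any(c != 0 for c in self.coefficients[1:]):
            raise CohortConfigError(
                f"{self.cpg_id}: direction='none' requires zero non-intercept coefficients"
            )
        degree = {"linear": 1, "quadratic": 2, "cubic": 3}
        if self.form in degree and len(self.coefficients) > degree[self.form] + 1:
            raise CohortConfigError(
                f"{self.cpg_id}: {self.form} trend takes at most "
                f"{degree[self.form] + 1} coefficients"
            )
        if self.form == "logistic-clamped" and len(self.coefficients) != 4:
            raise CohortConfigError(
                f"{self.cpg_id}: logistic-clamped takes exactly 4 coefficients"
            )

    def mean_beta(self, ages) -> np.ndarray:
        """Noiseless trend value at the given ages (clamped to [0, 1])."""
        ages = np.asarray(ages, dtype=float)
        if self.form == "logistic-clamped":
            b0, amp, rate, mid = self.coefficients
            value = b0 + amp / (1.0 + np.exp(-rate * (ages - mid)))
        else:
            value = np.polynomial.polynomial.polyval(ages, np.asarray(self.coefficients))
        return np.clip(value, 0.0, 1.0)

    def is_feasible(self, age_range=(2, 90)) -> bool:
        """True when the noiseless trend needs no clamping on the age range."""
        grid = np.linspace(age_range[0], age_range[1], 353)
        if self.form == "logistic-clamped":
            b0, amp, rate, mid = self.coefficients
            raw = b0 + amp / (1.0 + np.exp(-rate * (grid - mid)))
        else:
            raw = np.polynomial.polynomial.polyval(grid, np.asarray(self.coefficients))
        return bool(np.all((raw >= 0.0) & (raw <= 1.0)))


@dataclass(frozen=True)
class CohortSpec:
    n_samples: int
    trend_specs: tuple[AgeTrendSpec, ...]
    age_range: tuple[int, int] = (2, 90)
    age_distribution: str = "uniform-per-decade"
    datasets: tuple[tuple[str, float, int], ...] = ()  # (label, batch offset, n)
    sex_ratio: float = 0.5
    noise_mode: str = "gaussian"  # or "logit-normal"
    seed: int = 0

    def __post_init__(self):
        if self.n_samples <= 0:
            raise CohortConfigError("n_samples must be positive")
        lo, hi = self.age_range
        if not (0 <= lo < hi):
            raise CohortConfigError(f"invalid age range {self.age_range}")
        if self.datasets:
            total = sum(n for _, _, n in self.datasets)
            if total != self.n_samples:
                raise CohortConfigError(
                    f"dataset shares sum to {total}, expected n_samples={self.n_samples}"
                )
        if self.age_distribution not in ("uniform-per-decade", "uniform"):
            raise CohortConfigError(f"unknown age distribution {self.age_distribution!r}")
        if self.noise_mode not in ("gaussian", "logit-normal"):
            raise CohortConfigError(f"unknown noise mode {self.noise_mode!r}")
        for spec in self.trend_specs:
            if not spec.is_feasible(self.age_range):
                raise CohortConfigError(
                    f"trend for {spec.cpg_id} leaves [0,1] on ages {self.age_range}"
                )


@dataclass(frozen=True)
class TwinCohortSpec:
    n_pairs: int
    shared_deviation_sd: float = 0.05
    individual_deviation_sd: float = 0.01
    age_range: tuple[int, int] = (33, 77)
    seed: int = 0

    def __post_init__(self):
        if self.n_pairs <= 0:
            raise CohortConfigError("n_pairs must be positive")
        if self.shared_deviation_sd < 0 or self.individual_deviation_sd < 0:
            raise CohortConfigError("deviation SDs must be non-negative")


@dataclass(frozen=True)
class DiseasePerturbationSpec:
    label: str
    affected_cpgs: tuple[str, ...]
    shift_sd: float
    blood_related: bool = False

    def __post_init__(self):
        if self.shift_sd < 0:
            raise CohortConfigError("shift_sd must be non-negative")


def _sample_ages(rng: np.random.Generator, spec: CohortSpec) -> np.ndarray:
    lo, hi = spec.age_range
    if spec.age_distribution == "uniform":
        return rng.integers(lo, hi + 1, size=spec.n_samples).astype(float)
    # Stratified-uniform decades: near-equal representation per decade,
    # mirroring pooled-cohort designs that aim for balanced age groups.
    edges = list(range(lo - lo % 10 if lo % 10 else lo, hi + 1, 10))
    bins = []
    for start in edges:
        b_lo, b_hi = max(lo, start), min(hi, start + 9)
        if b_lo <= b_hi:
            bins.append((b_lo, b_hi))
    base, extra = divmod(spec.n_samples, len(bins))
    counts = [base + (1 if i < extra else 0) for i in range(len(bins))]
    ages = np.concatenate(
        [rng.integers(b_lo, b_hi + 1, size=c) for (b_lo, b_hi), c in zip(bins, counts)]
    ).astype(float)
    return rng.permutation(ages)


def _add_noise(rng, mean: np.ndarray, noise_sd: np.ndarray, mode: str) -> np.ndarray:
    if mode == "gaussian":
        return np.clip(mean + rng.normal(0.0, 1.0, size=mean.shape) * noise_sd, 0.0, 1.0)
    # logit-normal: noise applied on the logit scale, scaled so small
    # noise_sd matches the beta-scale SD near beta=0.5
    eps = 1e-6
    m = np.clip(mean, eps, 1 - eps)
    logit = np.log(m / (1 - m))
    scale = noise_sd / np.maximum(m * (1 - m), eps)
    jittered = logit + rng.normal(0.0, 1.0, size=mean.shape) * scale
    return 1.0 / (1.0 + np.exp(-jittered))


def _assemble(spec: CohortSpec, ages, sex, dataset, betas, tissue="blood") -> pd.DataFrame:
    index = pd.Index([f"S{i:05d}" for i in range(len(ages))], name="sample_id")
    frame = pd.DataFrame(
        {"age": ages, "sex": sex, "dataset": dataset, "tissue": tissue}, index=index
    )
    for j, trend in enumerate(spec.trend_specs):
        frame[trend.cpg_id] = betas[:, j]
    return frame


def ground_truth_table(spec: CohortSpec) -> dict:
    """JSON-serialisable record of the generating trends."""
    return {
        "trends": [dataclasses.asdict(t) for t in spec.trend_specs],
        "informative": [t.cpg_id for t in spec.trend_specs if t.direction != "none"],
        "noise": [t.cpg_id for t in spec.trend_specs if t.direction == "none"],
        "age_range": list(spec.age_range),
        "seed": spec.seed,
        "noise_mode": spec.noise_mode,
    }


def generate_cohort(spec: CohortSpec) -> tuple[pd.DataFrame, dict]:
    """Draw a cohort beta matrix; returns (matrix, ground-truth table).

    Sex is a null covariate by construction: it never enters the mean.
    Batch offsets are additive constants per dataset, identical at every
    age, so per-CpG mean-shift normalization removes them exactly.
    """
    rng = np.random.default_rng(spec.seed)
    ages = _sample_ages(rng, spec)
    n = spec.n_samples
    sex = np.where(rng.random(n) < spec.sex_ratio, "F", "M")
    if spec.datasets:
        labels = np.concatenate([[lab] * cnt for lab, _, cnt in spec.datasets])
        offsets = np.concatenate([[off] * cnt for _, off, cnt in spec.datasets])
        order = rng.permutation(n)
        labels, offsets = labels[order], offsets[order]
    else:
        labels = np.array(["cohort"] * n)
        offsets = np.zeros(n)

    mean = np.column_stack([t.mean_beta(ages) for t in spec.trend_specs])
    noise_sd = np.array([t.noise_sd for t in spec.trend_specs])
    betas = _add_noise(rng, mean, noise_sd[None, :], spec.noise_mode)
    betas = np.clip(betas + offsets[:, None], 0.0, 1.0)

    return _assemble(spec, ages, sex, labels, betas), ground_truth_table(spec)


def generate_twin_cohort(
    spec: TwinCohortSpec, trends: tuple[AgeTrendSpec, ...]
) -> pd.DataFrame:
    """Monozygotic twin pairs: shared age, shared pair deviation, individual noise.

    Within-pair expected beta difference is driven only by
    ``individual_deviation_sd``; the trend's own ``noise_sd`` is not applied
    (the pair-level deviation plays that role).
    """
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.age_range
    pair_ages = rng.integers(lo, hi + 1, size=spec.n_pairs).astype(float)
    p = len(trends)
    mean = np.column_stack([t.mean_beta(pair_ages) for t in trends])  # n_pairs × p
    shared = rng.normal(0.0, spec.shared_deviation_sd, size=(spec.n_pairs, p))
    rows, ages, pair_ids = [], [], []
    for k in range(spec.n_pairs):
        for member in ("a", "b"):
            indiv = rng.normal(0.0, spec.individual_deviation_sd, size=p)
            rows.append(np.clip(mean[k] + shared[k] + indiv, 0.0, 1.0))
            ages.append(pair_ages[k])
            pair_ids.append(f"pair{k:03d}")
    index = pd.Index(
        [f"T{k:03d}{m}" for k in range(spec.n_pairs) for m in "ab"], name="sample_id"
    )
    frame = pd.DataFrame(
        {
            "age": ages,
            "sex": "F",
            "dataset": "twins",
            "tissue": "blood",
            "pair_id": pair_ids,
        },
        index=index,
    )
    for j, t in enumerate(trends):
        frame[t.cpg_id] = np.asarray(rows)[:, j]
    return frame


def generate_disease_cohort(
    spec: DiseasePerturbationSpec, base: CohortSpec
) -> pd.DataFrame:
    """Healthy cohort from ``base`` plus per-sample shifts at affected CpGs.

    With ``shift_sd == 0`` or no affected CpGs the output equals the healthy
    cohort drawn from ``base`` exactly.
    """
    matrix, _ = generate_cohort(base)
    affected = [c for c in spec.affected_cpgs if c in matrix.columns]
    unknown = set(spec.affected_cpgs) - set(affected)
    if unknown:
        raise CohortConfigError(f"affected CpGs not in cohort: {sorted(unknown)}")
    if affected and spec.shift_sd > 0:
        rng = np.random.default_rng(
            np.random.SeedSequence([base.seed, abs(hash(spec.label)) % (2**31)])
        )
        shifts = rng.normal(0.0, spec.shift_sd, size=(len(matrix), len(affected)))
        matrix[affected] = np.clip(matrix[affected].to_numpy() + shifts, 0.0, 1.0)
    matrix["dataset"] = spec.label
    return matrix


# ---------------------------------------------------------------------------
# Default candidate panel: 45 CpGs, 16 informative + 29 null.
#
# The informative ids and trend directions follow the 16-marker epigenetic
# aging signature (e.g. CSNK1D/SSRP1/FXN/P2RXL1 hypomethylate with age,
# FZD9/KLF14/VGF/NHLRC1 hypermethylate); coefficient values are synthetic
# fixtures chosen to span linear, quadratic, cubic and saturating shapes of
# both signs with realistic beta ranges. One null CpG carries a large
# variance but no trend (large methylation range without age association).
# ---------------------------------------------------------------------------

_U0, _USPAN = 2.0, 88.0  # age normalisation: u = (age - 2) / 88


def _poly_from_u(b0: float, r: float, u_coeffs: tuple[float, ...]) -> tuple[float, ...]:
    """Expand b0 + r * sum(k_i u^i), u=(a-_U0)/_USPAN, to coefficients in age."""
    u = np.polynomial.polynomial.Polynomial([-_U0 / _USPAN, 1.0 / _USPAN])
    poly = np.polynomial.polynomial.Polynomial([b0])
    for i, k in enumerate(u_coeffs):
        if k:
            poly = poly + (r * k) * u**i
    coefs = poly.coef.tolist()
    while len(coefs) > 1 and abs(coefs[-1]) < 1e-18:
        coefs.pop()
    return tuple(coefs)


_SMOOTH = (0.0, 0.0, 3.0, -2.0)  # 3u^2 - 2u^3, S-shaped saturating cubic

INFORMATIVE_CPGS = (
    "cg19761273", "cg27544190", "cg03286783", "cg01511567",
    "cg07158339", "cg05442902", "cg24450312", "cg17274064",
    "cg02085507", "cg20692569", "cg04528819", "cg08370996",
    "cg04084157", "cg22736354", "cg06493994", "cg02479575",
)


def default_trend_specs(noise_sd: float = 0.035) -> tuple[AgeTrendSpec, ...]:
    def T(cpg, form, coefs, direction, sd=noise_sd):
        return AgeTrendSpec(cpg, form, coefs, sd, direction)

    informative = (
        T("cg19761273", "cubic", _poly_from_u(0.74, -0.40, _SMOOTH), "decreasing"),
        T("cg27544190", "linear", _poly_from_u(0.25, 0.30, (0, 1)), "increasing"),
        T("cg03286783", "quadratic", _poly_from_u(0.30, 0.15, (0, 0, 1)), "increasing"),
        T("cg01511567", "quadratic", _poly_from_u(0.65, -0.35, (0, 0, 1)), "decreasing"),
        T("cg07158339", "linear", _poly_from_u(0.55, -0.28, (0, 1)), "decreasing"),
        T("cg05442902", "cubic", _poly_from_u(0.35, -0.25, _SMOOTH), "decreasing"),
        T("cg24450312", "cubic", _poly_from_u(0.20, 0.35, (0, 0, 0, 1)), "increasing"),
        T("cg17274064", "quadratic", _poly_from_u(0.70, -0.30, (0, 2, -1)), "decreasing"),
        T("cg02085507", "logistic-clamped", (0.25, 0.35, 8.0 / _USPAN, 46.0), "increasing"),
        T("cg20692569", "quadratic", _poly_from_u(0.15, 0.40, (0, 0, 1)), "increasing"),
        T("cg04528819", "linear", _poly_from_u(0.10, 0.35, (0, 1)), "increasing"),
        T("cg08370996", "cubic", _poly_from_u(0.60, -0.30, _SMOOTH), "decreasing"),
        T("cg04084157", "cubic", _poly_from_u(0.22, 0.45, _SMOOTH), "increasing"),
        T("cg22736354", "linear", _poly_from_u(0.15, 0.50, (0, 1)), "increasing"),
        T("cg06493994", "quadratic", _poly_from_u(0.12, 0.48, (0, 2, -1)), "increasing"),
        T("cg02479575", "linear", _poly_from_u(0.50, -0.22, (0, 1)), "decreasing"),
    )
    rng = np.random.default_rng(45)  # fixture ids/intercepts, frozen
    null_cpgs = ["cg07455279"] + [f"cg9{rng.integers(0, 10**7):07d}" for _ in range(28)]
    null_intercepts = rng.uniform(0.08, 0.85, size=29)
    null_sds = np.full(29, noise_sd)
    null_sds[0] = 0.15  # large-range, trend-free CpG
    noise = tuple(
        AgeTrendSpec(cpg, "linear", (float(b0),), float(sd), "none")
        for cpg, b0, sd in zip(null_cpgs, null_intercepts, null_sds)
    )
    return informative + noise


_DEFAULT_DATASETS = (
    ("gse_a", -0.05, 0.18),
    ("gse_b", -0.03, 0.16),
    ("gse_c", -0.01, 0.14),
    ("gse_d", 0.00, 0.14),
    ("gse_e", 0.02, 0.14),
    ("gse_f", 0.03, 0.12),
    ("gse_g", 0.05, 0.12),
)


def default_cohort_spec(n_samples: int = 1156, seed: int = 0, **overrides) -> CohortSpec:
    """Pooled-study default: 45 CpGs, ages 2-90 balanced per decade, 7 batches."""
    shares = []
    running = 0
    for i, (label, off, frac) in enumerate(_DEFAULT_DATASETS):
        cnt = n_samples - running if i == len(_DEFAULT_DATASETS) - 1 else int(round(frac * n_samples))
        shares.append((label, off, cnt))
        running += cnt
    params = dict(
        n_samples=n_samples,
        trend_specs=default_trend_specs(),
        datasets=tuple(shares),
        seed=seed,
    )
    params.update(overrides)
    return CohortSpec(**params)
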