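"""Statistics supporting individual-seed phenotyping.

Covers the pneumatic/hammer release kinematics, the old-balance noise
simulation and the minimal sample size needed to separate two trait
distributions, chi-square confidence intervals for a standard
deviation, Welch t-tests from summary statistics, the mass-density
plausibility check, the mass-from-projected-area power model, and the
trait correlation matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DomainError

__all__ = [
    "BatchSummary",
    "KinematicsResult",
    "release_kinematics",
    "simulate_old_balance",
    "minimal_n",
    "minimal_n_resampled",
    "sd_confidence_width",
    "welch_ttest",
    "density_check",
    "fit_mass_area_model",
    "correlation_matrix",
    "CONTROL_BATCH",
    "ELEVATED_TEMP_BATCH",
]

G_STANDARD = 9.81  # m/s²


@dataclass
class BatchSummary:
    """Per-trait mean/SD/n summary of one seed batch."""

    name: str
    means: dict[str, float]
    sds: dict[str, float]
    n: dict[str, int] = field(default_factory=dict)

    def __post_init__(self):
        if any(s < 0 for s in self.sds.values()):
            raise DomainError("SDs must be nonnegative")
        if any(v < 2 for v in self.n.values()):
            raise DomainError("n must be at least 2")

    def trait(self, name: str) -> tuple[float, float, int]:
        return self.means[name], self.sds[name], self.n.get(name, 0)


# Published trait summaries for Arabidopsis Col-0 seed batches matured
# under control conditions and under elevated temperature.  Used as
# generator defaults and as inputs to the sample-size calculations.
CONTROL_BATCH = BatchSummary(
    name="C",
    means={
        "mass_ug": 22.1, "volume_nl": 20.5, "length_mm": 0.49,
        "width_mm": 0.31, "height_mm": 0.27, "sphericity_pct": 94.5,
        "brightness_pct": 38.4, "germination_time_d": 3.77,
        "growth_rate_mm2_d": 1.02,
    },
    sds={
        "mass_ug": 2.92, "volume_nl": 2.69, "length_mm": 0.04,
        "width_mm": 0.02, "height_mm": 0.02, "sphericity_pct": 1.64,
        "brightness_pct": 3.01, "germination_time_d": 1.50,
        "growth_rate_mm2_d": 0.23,
    },
    n={
        "mass_ug": 98, "volume_nl": 99, "length_mm": 99, "width_mm": 99,
        "height_mm": 99, "sphericity_pct": 99, "brightness_pct": 94,
        "germination_time_d": 60, "growth_rate_mm2_d": 49,
    },
)

ELEVATED_TEMP_BATCH = BatchSummary(
    name="T",
    means={
        "mass_ug": 24.8, "volume_nl": 23.0, "length_mm": 0.51,
        "width_mm": 0.33, "height_mm": 0.27, "sphericity_pct": 92.9,
        "brightness_pct": 34.2, "germination_time_d": 4.62,
        "growth_rate_mm2_d": 1.09,
    },
    sds={
        "mass_ug": 3.95, "volume_nl": 3.46, "length_mm": 0.05,
        "width_mm": 0.02, "height_mm": 0.02, "sphericity_pct": 1.95,
        "brightness_pct": 3.66, "germination_time_d": 2.33,
        "growth_rate_mm2_d": 0.19,
    },
    n={
        "mass_ug": 98, "volume_nl": 96, "length_mm": 96, "width_mm": 96,
        "height_mm": 96, "sphericity_pct": 96, "brightness_pct": 97,
        "germination_time_d": 56, "growth_rate_mm2_d": 40,
    },
)


@dataclass
class KinematicsResult:
    """Seed speeds under pneumatic vs. hammer release."""

    acceleration: float  # m/s², pneumatic release
    release_speed: float  # m/s, pneumatic release after the given distance
    hammer_speed: float  # m/s, hammer at the end of its drop
    seed_speed_after_collision: float  # m/s, elastic collision, hammer ≫ seed


def release_kinematics(
    overpressure: float = 3000.0,  # Pa (30 mbar)
    nozzle_radius: float = 75e-6,  # m
    seed_mass: float = 20e-9,  # kg (20 µg)
    distance: float = 5e-3,  # m
    hammer_drop: float = 1e-3,  # m
    hammer_mass: float = 7.2e-6,  # kg; must greatly exceed seed_mass
    g: float = G_STANDARD,
) -> KinematicsResult:
    """Kinematics of seed release from the pick-up nozzle (SI units).

    Pneumatic release: the overpressure acting on the nozzle bore gives
    the seed an initial acceleration ``a = π r² p / m`` and a speed
    ``v = √(2 a d)`` after travelling distance d.  Hammer release: the
    hammer reaches ``√(2 g h)`` after its drop and, in a perfectly
    elastic collision with a much lighter seed, passes on at most twice
    its own speed.
    """
    vals = dict(overpressure=overpressure, nozzle_radius=nozzle_radius,
                seed_mass=seed_mass, distance=distance,
                hammer_drop=hammer_drop, hammer_mass=hammer_mass)
    for k, v in vals.items():
        if k == "overpressure":
            if v < 0:
                raise DomainError("overpressure must be >= 0")
        elif v <= 0:
            raise DomainError(f"{k} must be positive")
    a = np.pi * nozzle_radius**2 * overpressure / seed_mass
    v = np.sqrt(2 * a * distance)
    vh = np.sqrt(2 * g * hammer_drop)
    return KinematicsResult(
        acceleration=float(a),
        release_speed=float(v),
        hammer_speed=float(vh),
        seed_speed_after_collision=float(2 * vh),
    )


def simulate_old_balance(
    values,
    rel_sd: float = 0.15,
    draws_per_value: int = 100,
    rng_seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Inflate precise mass values with the old balance's 15% repeatability.

    Around each measured value a normal distribution with SD equal to
    ``rel_sd`` times the value is built, and ``draws_per_value`` values
    are drawn from each, emulating what the older, less precise balance
    would have recorded.  The inflated sample's SD converges to
    ``√(SD_batch² + (rel_sd·mean)²)``.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise DomainError("values must be non-empty")
    if rel_sd < 0:
        raise DomainError("rel_sd must be >= 0")
    rng = (rng_seed if isinstance(rng_seed, np.random.Generator)
           else np.random.default_rng(rng_seed))
    draws = rng.normal(
        loc=values[:, None],
        scale=np.abs(values[:, None]) * rel_sd,
        size=(values.size, draws_per_value),
    )
    return draws.ravel()


def _welch_from_stats(m1, s1, n1, m2, s2, n2):
    se2 = s1**2 / n1 + s2**2 / n2
    t = (m1 - m2) / np.sqrt(se2)
    df = se2**2 / ((s1**2 / n1) ** 2 / (n1 - 1) + (s2**2 / n2) ** 2 / (n2 - 1))
    return t, df


def minimal_n(
    batch_a,
    batch_b,
    alpha: float = 0.05,
    trait: str = "mass_ug",
    n_max: int = 100000,
) -> int | None:
    """Smallest per-batch sample size with a significant two-sided t-test.

    The batches are taken as fixed distributions (mean, SD — either a
    :class:`BatchSummary` plus trait name, a ``(mean, sd)`` pair, or a
    raw sample).  For each candidate n the two-sample t statistic at
    equal group sizes is compared with the critical value of the t
    distribution (Welch degrees of freedom) at level ``alpha``; the
    first n that exceeds it is returned.  Returns None when the means
    are equal (no finite n separates the batches).
    """

    def moments(b):
        if isinstance(b, BatchSummary):
            m, s, _ = b.trait(trait)
            return m, s
        b = np.asarray(b, dtype=float)
        if b.shape == (2,):
            return float(b[0]), float(b[1])
        return float(b.mean()), float(b.std(ddof=1))

    m1, s1 = moments(batch_a)
    m2, s2 = moments(batch_b)
    if m1 == m2:
        return None
    for n in range(2, n_max + 1):
        t, df = _welch_from_stats(m1, s1, n, m2, s2, n)
        if abs(t) > stats.t.ppf(1 - alpha / 2, df):
            return n
    return None


def minimal_n_resampled(
    batch_a,
    batch_b,
    alpha: float = 0.05,
    trait: str = "mass_ug",
    inflate_rel_sd: float | None = None,
    draws_per_value: int = 100,
    n_reps: int = 1000,
    rng_seed: int = 0,
) -> tuple[float, int]:
    """Minimal n by the resampling procedure; returns (mean, majority vote).

    Each repetition emulates the measured batches as normal samples of
    the recorded size, standardized so their empirical mean and SD
    equal the summary exactly (the batch data are a fixed observation;
    only the emulation of the noisier balance is stochastic), optionally
    inflates them with the old-balance noise model, computes the
    empirical means/SDs of the resulting distributions and finds the
    minimal significant n as in :func:`minimal_n`.  Reported are the
    mean over repetitions and the majority (modal) value.
    """
    rng = np.random.default_rng(rng_seed)
    results = []
    for _ in range(n_reps):
        samples = []
        for b in (batch_a, batch_b):
            m, s, n = b.trait(trait)
            z = rng.normal(size=max(n, 2))
            z = (z - z.mean()) / z.std(ddof=1)
            vals = m + s * z
            if inflate_rel_sd is not None:
                vals = simulate_old_balance(vals, inflate_rel_sd, draws_per_value, rng)
            samples.append(vals)
        res = minimal_n(samples[0], samples[1], alpha=alpha)
        if res is not None:
            results.append(res)
    if not results:
        raise DomainError("no repetition yielded a finite minimal n")
    arr = np.asarray(results)
    vals, counts = np.unique(arr, return_counts=True)
    return float(arr.mean()), int(vals[np.argmax(counts)])


def sd_confidence_width(n: int, conf: float = 0.95) -> tuple[float, float, int]:
    """Chi-square confidence interval for σ as a fraction of σ.

    For a normal sample of size n, ``(n−1)s²/σ²`` is chi-square with
    n−1 degrees of freedom, so the CI bounds for σ/s are
    ``√((n−1)/χ²)`` at the upper/lower quantiles.  Returns
    ``(lower, upper, width_pct)`` where width is ``(upper − lower)·100``
    rounded to an integer percent.
    """
    if n < 2:
        raise DomainError("n must be at least 2")
    df = n - 1
    alpha = 1 - conf
    lower = np.sqrt(df / stats.chi2.ppf(1 - alpha / 2, df))
    upper = np.sqrt(df / stats.chi2.ppf(alpha / 2, df))
    return float(lower), float(upper), int(round((upper - lower) * 100))


def welch_ttest(summary_a, summary_b, trait: str = "mass_ug") -> tuple[float, float, float]:
    """Two-sided Welch t-test from summaries or raw samples; returns (t, df, p)."""

    def moments(b):
        if isinstance(b, BatchSummary):
            m, s, n = b.trait(trait)
            if n < 2:
                raise DomainError("n must be at least 2")
            return m, s, n
        b = np.asarray(b, dtype=float)
        if b.size < 2:
            raise DomainError("n must be at least 2")
        return float(b.mean()), float(b.std(ddof=1)), b.size

    m1, s1, n1 = moments(summary_a)
    m2, s2, n2 = moments(summary_b)
    res = stats.ttest_ind_from_stats(m1, s1, n1, m2, s2, n2, equal_var=False)
    _, df = _welch_from_stats(m1, s1, n1, m2, s2, n2)
    return float(res.statistic), float(df), float(res.pvalue)


def density_check(
    mass_ug: float, volume_nl: float, bounds: tuple[float, float] = (0.8, 1.4)
) -> tuple[float, bool]:
    """Seed density in g/cm³ and a plausibility flag.

    µg/nl is numerically identical to g/cm³.  A density outside the
    plausible bounds indicates an invalid mass and/or volume (double
    pickup, broken seed, dust).
    """
    if volume_nl <= 0:
        raise DomainError("volume must be positive")
    density = mass_ug / volume_nl
    return float(density), bool(bounds[0] <= density <= bounds[1])


def fit_mass_area_model(areas_mm2, masses_ug) -> dict:
    """Least-squares fit of the power model mass = a·A^(3/2).

    Projected area scales like a length squared and mass like a length
    cubed, so mass ∝ A^(3/2) for geometrically similar seeds.  Returns
    the coefficient, per-seed relative deviations |ŷ−y|/y and their
    maximum.
    """
    A = np.asarray(areas_mm2, dtype=float)
    y = np.asarray(masses_ug, dtype=float)
    if A.size < 3 or A.size != y.size:
        raise DomainError("need at least 3 paired observations")
    if np.any(A <= 0) or np.any(y <= 0):
        raise DomainError("areas and masses must be positive")
    x = A**1.5
    a = float((x @ y) / (x @ x))
    pred = a * x
    rel_dev = np.abs(pred - y) / y
    return {
        "a": a,
        "rel_dev": rel_dev,
        "max_rel_dev": float(rel_dev.max()),
    }


def _stars(p: float) -> str:
    if np.isnan(p):
        return ""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def correlation_matrix(
    records: pd.DataFrame, traits: list[str] | None = None, min_pairs: int = 3
):
    """Pairwise-complete Pearson correlation matrix with significance stars.

    Returns ``(r, p, stars)`` DataFrames, symmetric with unit diagonal.
    Pairs with fewer than ``min_pairs`` complete observations or a
    constant trait give NaN.  Stars mark the conventional levels
    (* p<0.05, ** p<0.01, *** p<0.001); no multiplicity correction.
    """
    if traits is None:
        traits = [c for c in records.columns if records[c].dtype.kind == "f"]
    k = len(traits)
    r = np.full((k, k), np.nan)
    p = np.full((k, k), np.nan)
    for i in range(k):
        r[i, i] = 1.0
        p[i, i] = 0.0
        for j in range(i + 1, k):
            pair = records[[traits[i], traits[j]]].dropna()
            if len(pair) < min_pairs:
                continue
            x, y = pair.iloc[:, 0].to_numpy(), pair.iloc[:, 1].to_numpy()
            if np.std(x) == 0 or np.std(y) == 0:
                continue
            res = stats.pearsonr(x, y)
            r[i, j] = r[j, i] = res.statistic
            p[i, j] = p[j, i] = res.pvalue
    r_df = pd.DataFrame(r, index=traits, columns=traits)
    p_df = pd.DataFrame(p, index=traits, columns=traits)
    stars_df = p_df.map(_stars)
    return r_df, p_df, stars_df
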