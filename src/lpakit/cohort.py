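"""Synthetic cohort generation for latent-profile service-use analyses.

Real secondary-care service-receipt extracts are governed datasets that
cannot be redistributed, so every downstream stage of the pipeline is
exercised on synthetic cohorts that reproduce the statistical structure the
analysis assumes: a two-subgroup mixture of patients whose contact counts
are heavily overdispersed and right-skewed, with structural zeros (the
low-use subgroup records no psychology contacts and no internalizing
diagnoses), and an optional nursing-by-profile interaction on
non-attendance.

The default calibration encodes the published per-profile indicator
summaries of a South London personality-disorder cohort (n=3941; low-use
profile share 73.05%): count indicators are drawn from moment-matched
negative binomials, binary indicators from Bernoulli laws, age from a
truncated normal on the study's 20-101 year inclusion window, and
deprivation decile from a discretised truncated normal on 1..10.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats

#: Column order of the 12 LPA indicators.
INDICATORS = [
    "age",
    "female",
    "white",
    "imd_decile",
    "internalizing",
    "f2f",
    "dna",
    "medical",
    "nurse",
    "psychology",
    "therapy",
    "other",
]

#: Per-episode contact/count indicators (non-negative integers).
COUNT_INDICATORS = ["f2f", "dna", "medical", "nurse", "psychology", "therapy", "other"]

#: Clinical-team contact indicators, used e.g. for profile ordering.
TEAM_INDICATORS = ["medical", "nurse", "psychology", "therapy", "other"]

BINARY_INDICATORS = ["female", "white", "internalizing"]

AGE_RANGE = (20.0, 101.0)

COHORT_COLUMNS = ["patient_id"] + INDICATORS


@dataclass(frozen=True)
class DnaInteraction:
    """Optional non-attendance model: dna ~ Poisson(b0_k + b1_k * nurse).

    When enabled, the did-not-attend count is no longer drawn from its
    marginal cell but from a Poisson law whose rate is linear in the nursing
    contact count with a profile-specific intercept and slope (identity
    link; rates are clipped at zero). ``link="log"`` switches to a log-rate.
    """

    intercepts: tuple[float, ...]
    slopes: tuple[float, ...]
    link: str = "identity"

    def rate(self, profile: int, nurse: np.ndarray) -> np.ndarray:
        eta = self.intercepts[profile] + self.slopes[profile] * nurse
        if self.link == "log":
            return np.exp(eta)
        return np.clip(eta, 0.0, None)


@dataclass(frozen=True)
class ProfileConfig:
    """Indicator distribution for one latent profile.

    Count cells are (mean, sd) pairs; binary cells are probabilities; age
    and deprivation are (mean, sd) of truncated normals. A structural zero
    is encoded as mean 0 / sd 0 (counts) or probability 0 (binaries).
    """

    name: str
    age_mean: float
    age_sd: float
    female_p: float
    white_p: float
    imd_mean: float
    imd_sd: float
    internalizing_p: float
    f2f_mean: float
    f2f_sd: float
    dna_mean: float
    dna_sd: float
    medical_mean: float
    medical_sd: float
    nurse_mean: float
    nurse_sd: float
    psychology_mean: float
    psychology_sd: float
    therapy_mean: float
    therapy_sd: float
    other_mean: float
    other_sd: float
    structural_zeros: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        for ind in COUNT_INDICATORS:
            m, s = self.count_cell(ind)
            if m < 0 or s < 0:
                raise ValueError(f"{self.name}.{ind}: mean and sd must be >= 0")
        for p_name in ("female_p", "white_p", "internalizing_p"):
            p = getattr(self, p_name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{self.name}.{p_name} must be in [0, 1]")
        for ind in self.structural_zeros:
            if ind in COUNT_INDICATORS:
                m, s = self.count_cell(ind)
                if m != 0 or s != 0:
                    raise ValueError(
                        f"structural zero {self.name}.{ind} requires mean 0 and sd 0"
                    )
            elif ind in BINARY_INDICATORS:
                if getattr(self, f"{ind}_p") != 0:
                    raise ValueError(
                        f"structural zero {self.name}.{ind} requires probability 0"
                    )
            else:
                raise ValueError(f"unknown structural-zero indicator {ind!r}")

    def count_cell(self, indicator: str) -> tuple[float, float]:
        return (
            getattr(self, f"{indicator}_mean"),
            getattr(self, f"{indicator}_sd"),
        )


@dataclass(frozen=True)
class SyntheticConfig:
    """Full specification of a synthetic cohort.

    ``design`` is ``"T1"`` (one episode row per patient) or ``"repeated"``
    (two correlated episode rows per patient sharing the latent profile).
    ``count_copula_corr`` optionally correlates count indicators within a
    profile through a Gaussian copula (default 0 = independent);
    ``episode_corr`` is the episode-to-episode latent correlation used by
    the repeated design.
    """

    n_patients: int
    mixing_proportions: tuple[float, ...]
    profiles: tuple[ProfileConfig, ...]
    dna_interaction: DnaInteraction | None = None
    design: str = "T1"
    count_copula_corr: float = 0.0
    episode_corr: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients <= 0:
            raise ValueError("n_patients must be positive")
        w = np.asarray(self.mixing_proportions, dtype=float)
        if len(w) != len(self.profiles):
            raise ValueError("one mixing proportion per profile is required")
        if np.any(w <= 0) or np.any(w >= 1):
            raise ValueError("mixing proportions must each lie in (0, 1)")
        if abs(w.sum() - 1.0) > 1e-12:
            raise ValueError("mixing proportions must sum to 1 (tol 1e-12)")
        if self.design not in ("T1", "repeated"):
            raise ValueError("design must be 'T1' or 'repeated'")
        if not -1.0 < self.count_copula_corr < 1.0:
            raise ValueError("count_copula_corr must be in (-1, 1)")

    # convenience accessors matching the low-use / high-use naming
    @property
    def profile1(self) -> ProfileConfig:
        return self.profiles[0]

    @property
    def profile2(self) -> ProfileConfig:
        return self.profiles[1]

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["profiles"] = [dataclasses.asdict(p) for p in self.profiles]
        if self.dna_interaction is not None:
            d["dna_interaction"] = dataclasses.asdict(self.dna_interaction)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticConfig":
        d = dict(d)
        d["profiles"] = tuple(
            ProfileConfig(**{**p, "structural_zeros": tuple(p.get("structural_zeros", ()))})
            for p in d["profiles"]
        )
        d["mixing_proportions"] = tuple(float(x) for x in d["mixing_proportions"])
        if d.get("dna_interaction"):
            di = dict(d["dna_interaction"])
            di["intercepts"] = tuple(float(x) for x in di["intercepts"])
            di["slopes"] = tuple(float(x) for x in di["slopes"])
            d["dna_interaction"] = DnaInteraction(**di)
        else:
            d["dna_interaction"] = None
        return cls(**d)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def load(cls, path: str | Path) -> "SyntheticConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def default_config(
    n_patients: int = 3941,
    design: str = "T1",
    seed: int = 0,
    dna_interaction: DnaInteraction | None = None,
) -> SyntheticConfig:
    """Two-profile configuration calibrated to the published cohort summaries.

    Profile 1 is the low-use majority profile (share 73.05%) with structural
    zeros on psychology contacts and internalizing diagnoses; profile 2 is
    the high-use minority profile (26.95%). Count cells carry the published
    per-profile means and SDs; the gender and ethnicity probabilities use
    the published headline proportions (63% female, 32% White) for both
    profiles, because the per-profile table cells for these two rows print
    raw frequencies rather than proportions. The internalizing probability
    in the high-use profile is 120/1062.
    """
    low = ProfileConfig(
        name="low_use",
        age_mean=44.10,
        age_sd=14.1,
        female_p=0.63,
        white_p=0.32,
        imd_mean=3.66,
        imd_sd=1.75,
        internalizing_p=0.0,
        f2f_mean=4.43,
        f2f_sd=5.17,
        dna_mean=0.43,
        dna_sd=1.03,
        medical_mean=1.0,
        medical_sd=1.50,
        nurse_mean=2.15,
        nurse_sd=3.36,
        psychology_mean=0.0,
        psychology_sd=0.0,
        therapy_mean=0.05,
        therapy_sd=0.21,
        other_mean=0.25,
        other_sd=0.72,
        structural_zeros=("psychology", "internalizing"),
    )
    high = ProfileConfig(
        name="high_use",
        age_mean=44.95,
        age_sd=14.90,
        female_p=0.63,
        white_p=0.32,
        imd_mean=3.70,
        imd_sd=1.67,
        internalizing_p=120.0 / 1062.0,
        f2f_mean=35.78,
        f2f_sd=58.0,
        dna_mean=4.73,
        dna_sd=12.0,
        medical_mean=5.90,
        medical_sd=11.2,
        nurse_mean=9.43,
        nurse_sd=19.20,
        psychology_mean=5.70,
        psychology_sd=12.90,
        therapy_mean=3.25,
        therapy_sd=11.20,
        other_mean=5.10,
        other_sd=20.5,
    )
    return SyntheticConfig(
        n_patients=n_patients,
        mixing_proportions=(0.7305, 0.2695),
        profiles=(low, high),
        dna_interaction=dna_interaction,
        design=design,
        seed=seed,
    )


def _nb_params(mean: float, var: float) -> tuple[float, float]:
    """Moment-matched negative-binomial (size r, success prob p)."""
    r = mean * mean / (var - mean)
    p = r / (r + mean)
    return r, p


def sample_count(
    mean: float, sd: float, rng: np.random.Generator, size: int | None = None
) -> np.ndarray | int:
    """Draw overdispersion-aware counts with the given first two moments.

    A structural zero (mean 0) always yields 0. When sd^2 > mean the draw is
    negative binomial with size r = mean^2 / (sd^2 - mean), which matches
    both moments exactly; when 0 < sd^2 <= mean the draw is Poisson(mean)
    (the negative binomial cannot be underdispersed).
    """
    if mean < 0 or sd < 0:
        raise ValueError(f"mean and sd must be non-negative, got ({mean}, {sd})")
    if mean == 0:
        return 0 if size is None else np.zeros(size, dtype=np.int64)
    var = sd * sd
    if var > mean:
        r, p = _nb_params(mean, var)
        return rng.negative_binomial(r, p, size=size)
    return rng.poisson(mean, size=size)


def _count_ppf(u: np.ndarray, mean: float, sd: float) -> np.ndarray:
    """Quantile transform used by the copula paths of :func:`generate_cohort`."""
    if mean == 0:
        return np.zeros_like(u, dtype=np.int64)
    var = sd * sd
    if var > mean:
        r, p = _nb_params(mean, var)
        return stats.nbinom.ppf(u, r, p).astype(np.int64)
    return stats.poisson.ppf(u, mean).astype(np.int64)


def _truncnorm(mean: float, sd: float, lo: float, hi: float, size: int, rng) -> np.ndarray:
    if sd == 0:
        return np.full(size, mean)
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def _draw_counts_block(
    prof: ProfileConfig,
    n: int,
    rng: np.random.Generator,
    copula_corr: float,
    n_episodes: int,
    episode_corr: float,
) -> np.ndarray:
    """Count indicators for n patients of one profile.

    Returns an array of shape (n, n_episodes, len(COUNT_INDICATORS)). The
    single-episode independent case uses direct negative-binomial/Poisson
    draws; any correlation (across indicators or across episodes) goes
    through a Gaussian copula with the same marginals.
    """
    q = len(COUNT_INDICATORS)
    if n_episodes == 1 and copula_corr == 0.0:
        out = np.empty((n, 1, q), dtype=np.int64)
        for j, ind in enumerate(COUNT_INDICATORS):
            m, s = prof.count_cell(ind)
            out[:, 0, j] = sample_count(m, s, rng, size=n)
        return out

    # latent correlation: exchangeable across indicators within an episode,
    # episode_corr across the two episodes of one indicator
    dim = q * n_episodes
    corr = np.eye(dim)
    for a in range(dim):
        for b in range(a + 1, dim):
            ja, ea = a % q, a // q
            jb, eb = b % q, b // q
            if ea == eb and ja != jb:
                corr[a, b] = corr[b, a] = copula_corr
            elif ja == jb and ea != eb:
                corr[a, b] = corr[b, a] = episode_corr
            elif ja != jb and ea != eb:
                corr[a, b] = corr[b, a] = copula_corr * episode_corr
    z = rng.multivariate_normal(np.zeros(dim), corr, size=n, method="cholesky")
    u = stats.norm.cdf(z)
    out = np.empty((n, n_episodes, q), dtype=np.int64)
    for e in range(n_episodes):
        for j, ind in enumerate(COUNT_INDICATORS):
            m, s = prof.count_cell(ind)
            out[:, e, j] = _count_ppf(u[:, e * q + j], m, s)
    return out


def generate_cohort(config: SyntheticConfig, seed: int | None = None) -> pd.DataFrame:
    """Generate a cohort as a tidy DataFrame, one row per episode.

    Columns: patient_id, true_profile, the 12 indicators, and episode_index
    under the repeated design. ``true_profile`` is the generator's hidden
    label (0 = first profile); fitting code must never read it, and the CSV
    writer places it in a sidecar file for that reason. Identical
    (config, seed) pairs produce bit-identical cohorts.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n = config.n_patients
    n_episodes = 2 if config.design == "repeated" else 1

    labels = rng.choice(len(config.profiles), size=n, p=config.mixing_proportions)

    rows = np.empty((n, n_episodes, len(INDICATORS)))
    for k, prof in enumerate(config.profiles):
        idx = np.where(labels == k)[0]
        nk = idx.size
        if nk == 0:
            continue
        age = _truncnorm(prof.age_mean, prof.age_sd, *AGE_RANGE, size=nk, rng=rng)
        female = rng.binomial(1, prof.female_p, size=nk)
        white = rng.binomial(1, prof.white_p, size=nk)
        imd = np.clip(
            np.rint(_truncnorm(prof.imd_mean, prof.imd_sd, 0.5, 10.5, size=nk, rng=rng)),
            1,
            10,
        )
        internal = rng.binomial(1, prof.internalizing_p, size=nk)
        counts = _draw_counts_block(
            prof, nk, rng, config.count_copula_corr, n_episodes, config.episode_corr
        )
        if config.dna_interaction is not None:
            j_dna = COUNT_INDICATORS.index("dna")
            j_nurse = COUNT_INDICATORS.index("nurse")
            for e in range(n_episodes):
                rate = config.dna_interaction.rate(k, counts[:, e, j_nurse].astype(float))
                counts[:, e, j_dna] = rng.poisson(rate)
        for e in range(n_episodes):
            rows[idx, e, 0] = age
            rows[idx, e, 1] = female
            rows[idx, e, 2] = white
            rows[idx, e, 3] = imd
            rows[idx, e, 4] = internal
            rows[idx, e, 5:] = counts[:, e, :]

    frames = []
    for e in range(n_episodes):
        df = pd.DataFrame(rows[:, e, :], columns=INDICATORS)
        df.insert(0, "patient_id", np.arange(n))
        df.insert(1, "true_profile", labels)
        if n_episodes > 1:
            df["episode_index"] = e + 1
        frames.append(df)
    out = pd.concat(frames, ignore_index=True)
    if n_episodes > 1:
        out = out.sort_values(["patient_id", "episode_index"], ignore_index=True)
    for col in ["female", "white", "imd_decile", "internalizing"] + COUNT_INDICATORS:
        out[col] = out[col].astype(np.int64)
    out["patient_id"] = out["patient_id"].astype(np.int64)
    out["true_profile"] = out["true_profile"].astype(np.int64)
    return out


def write_cohort_csv(cohort: pd.DataFrame, path: str | Path) -> tuple[Path, Path]:
    """Write the indicator table and a true-profile sidecar.

    The main CSV carries only observable columns, so fitting code reading it
    cannot silently use the generator labels; the sidecar
    ``<stem>.labels.csv`` holds patient_id -> true_profile.
    """
    path = Path(path)
    obs_cols = [c for c in cohort.columns if c != "true_profile"]
    cohort[obs_cols].to_csv(path, index=False)
    sidecar = path.with_suffix(".labels.csv")
    label_cols = ["patient_id", "true_profile"]
    labels = cohort[label_cols].drop_duplicates("patient_id")
    labels.to_csv(sidecar, index=False)
    return path, sidecar
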