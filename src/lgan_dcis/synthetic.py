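"""Seeded synthetic TMA cores and clinicopathological cohort tables.

The image generator draws histology-like cores on a near-white background:
each duct is a disc of epithelium inside a stromal halo, carrying nuclei
whose density and radius dispersion (pleomorphism) differ between aggressive
and non-aggressive morphology; aggressive ducts may additionally contain a
central necrosis disc (comedo-type pattern).  The cohort generator samples
discretised clinical variables with a planted dependency structure
(Grade -> Size; Age and imaging risk -> breast-cancer event) plus four
tumour-infiltrating-lymphocyte (TILs) variables and a truncated-normal
follow-up time, and can alternatively reproduce a printed count table
exactly (marginal-exact mode).
"""

from __future__ import annotations

import zlib
from collections import namedtuple
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from skimage.draw import disk

from .types import (
    AGE_LEVELS, CIRCUMFERENTIAL_LEVELS, COHORT_COLUMNS, CoreImage,
    GAN_LEVELS, GRADE_LEVELS, HOTSPOT_LEVELS, LYMPHOCYTE_LEVELS,
    SIZE_LEVELS, TOUCHING_LEVELS, TissueMask,
)

__all__ = [
    "SyntheticCoreSpec", "CohortSpec", "CoreSample",
    "generate_core", "generate_patient_images",
    "generate_cohort", "generate_cohort_exact", "cohort_from_count_table",
    "OXFORD_COHORT", "SINGAPORE_COHORT",
    "truncated_normal_parent_params", "sample_followup",
]

# ---------------------------------------------------------------------------
# printed cohort characteristics (used as fixture inputs)
# ---------------------------------------------------------------------------

#: Oxford (training) cohort: categorical counts and follow-up moments.
OXFORD_COHORT = {
    "n": 67,
    "followup": {"mean": 7.74, "sd": 4.36, "range": (0.83, 17.08)},
    "counts": {
        "bce": {0: 40, 1: 27},
        "age_group": {"le50": 19, "gt50": 47, "NA": 1},
        "size_group": {"le20": 18, "gt20": 10, "NA": 39},
        "grade": {"low": 8, "intermediate": 17, "high": 34, "NA": 8},
        "lymphocyte": {"0-5": 27, "gt5": 40},
        "touching_tils": {"0": 52, "gt0": 15},
        "circumferential": {"no": 51, "yes": 16},
        "hotspot": {"no": 40, "dense": 27},
    },
}

#: Singapore (validation) cohort.
SINGAPORE_COHORT = {
    "n": 66,
    "followup": {"mean": 5.1, "sd": 2.17, "range": (0.96, 13.71)},
    "counts": {
        "bce": {0: 48, 1: 18},
        "age_group": {"le50": 23, "gt50": 43},
        "size_group": {"le20": 34, "gt20": 32},
        "grade": {"low": 8, "intermediate": 22, "high": 36},
        "lymphocyte": {"0-5": 22, "gt5": 44},
        "touching_tils": {"0": 52, "gt0": 14},
        "circumferential": {"no": 38, "yes": 28},
        "hotspot": {"no": 30, "dense": 36},
    },
}

# planted conditional P(size=gt20 | grade): only the high-grade entry (0.72)
# is an externally reported value; the low/intermediate rows are chosen so
# the implied overall size>20 marginal matches the validation cohort (~48.5%)
DEFAULT_SIZE_GIVEN_GRADE = {
    "low": {"le20": 0.80, "gt20": 0.20},
    "intermediate": {"le20": 0.79, "gt20": 0.21},
    "high": {"le20": 0.28, "gt20": 0.72},
}

# planted P(bce=1 | age, gan_risk): both parents informative, overall
# prevalence ~29%
DEFAULT_BCE_GIVEN_AGE_GAN = {
    ("le50", "high"): 0.70,
    ("le50", "low"): 0.30,
    ("gt50", "high"): 0.50,
    ("gt50", "low"): 0.10,
}


def _norm_counts(counts: dict, drop_na: bool = True) -> dict:
    total = sum(v for k, v in counts.items() if not (drop_na and k == "NA"))
    return {k: v / total for k, v in counts.items()
            if not (drop_na and k == "NA")}


# ---------------------------------------------------------------------------
# follow-up time model
# ---------------------------------------------------------------------------

def truncated_normal_parent_params(mean: float, sd: float, low: float,
                                   high: float) -> tuple[float, float]:
    """Parent (mu, sigma) whose [low, high]-truncated normal has the given
    mean and standard deviation.

    Cohort tables report the mean/SD of the *observed* (range-limited)
    follow-up, so the sampler matches the truncated distribution's first two
    moments to the printed values rather than using them as the parent
    parameters directly.
    """
    if not low < high:
        raise ValueError("need low < high")
    if not low < mean < high:
        raise ValueError("target mean outside the truncation range")

    def residual(theta):
        mu, log_s = theta
        s = np.exp(log_s)
        a, b = (low - mu) / s, (high - mu) / s
        d = stats.truncnorm(a, b, loc=mu, scale=s)
        return [d.mean() - mean, d.std() - sd]

    sol = optimize.root(residual, x0=[mean, np.log(sd)], method="hybr")
    if not sol.success:  # pragma: no cover - defensive
        return mean, sd
    return float(sol.x[0]), float(np.exp(sol.x[1]))


def sample_followup(n: int, mean: float, sd: float,
                    rng_range: tuple[float, float],
                    rng: np.random.Generator) -> np.ndarray:
    """Draw n follow-up years from the moment-matched truncated normal."""
    low, high = rng_range
    mu, s = truncated_normal_parent_params(mean, sd, low, high)
    a, b = (low - mu) / s, (high - mu) / s
    return stats.truncnorm.rvs(a, b, loc=mu, scale=s, size=n, random_state=rng)


# ---------------------------------------------------------------------------
# cohort tables
# ---------------------------------------------------------------------------

def _validate_row(name: str, row: dict) -> None:
    total = sum(row.values())
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"probability row {name!r} sums to {total}, not 1")
    if any(p < 0 for p in row.values()):
        raise ValueError(f"negative probability in row {name!r}")


@dataclass
class CohortSpec:
    """Sampling specification for a synthetic clinicopathological cohort."""

    n_patients: int = 66
    age_marginal: dict = field(
        default_factory=lambda: _norm_counts(
            SINGAPORE_COHORT["counts"]["age_group"]))
    grade_marginal: dict = field(
        default_factory=lambda: _norm_counts(
            SINGAPORE_COHORT["counts"]["grade"]))
    size_given_grade: dict = field(
        default_factory=lambda: {g: dict(r)
                                 for g, r in DEFAULT_SIZE_GIVEN_GRADE.items()})
    gan_risk_marginal: dict = field(
        default_factory=lambda: {"low": 0.7, "high": 0.3})
    bce_given_age_gan: dict = field(
        default_factory=lambda: dict(DEFAULT_BCE_GIVEN_AGE_GAN))
    tils_marginals: dict = field(default_factory=lambda: {
        "lymphocyte": _norm_counts(SINGAPORE_COHORT["counts"]["lymphocyte"]),
        "touching_tils": _norm_counts(
            SINGAPORE_COHORT["counts"]["touching_tils"]),
        "circumferential": _norm_counts(
            SINGAPORE_COHORT["counts"]["circumferential"]),
        "hotspot": _norm_counts(SINGAPORE_COHORT["counts"]["hotspot"]),
    })
    followup_mean: float = SINGAPORE_COHORT["followup"]["mean"]
    followup_sd: float = SINGAPORE_COHORT["followup"]["sd"]
    followup_range: tuple = SINGAPORE_COHORT["followup"]["range"]
    seed: int = 0

    def validate(self) -> None:
        if self.n_patients < 0:
            raise ValueError("n_patients must be >= 0")
        _validate_row("age_marginal", self.age_marginal)
        _validate_row("grade_marginal", self.grade_marginal)
        _validate_row("gan_risk_marginal", self.gan_risk_marginal)
        for g, row in self.size_given_grade.items():
            _validate_row(f"size | grade={g}", row)
        for key, p in self.bce_given_age_gan.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"P(bce=1 | {key}) = {p} outside [0, 1]")
        for var, row in self.tils_marginals.items():
            _validate_row(var, row)

    @classmethod
    def oxford_like(cls, n_patients: int | None = None, seed: int = 0):
        """Spec with Oxford marginals and follow-up moments."""
        t = OXFORD_COHORT
        return cls(
            n_patients=t["n"] if n_patients is None else n_patients,
            age_marginal=_norm_counts(t["counts"]["age_group"]),
            grade_marginal=_norm_counts(t["counts"]["grade"]),
            tils_marginals={
                "lymphocyte": _norm_counts(t["counts"]["lymphocyte"]),
                "touching_tils": _norm_counts(t["counts"]["touching_tils"]),
                "circumferential": _norm_counts(
                    t["counts"]["circumferential"]),
                "hotspot": _norm_counts(t["counts"]["hotspot"]),
            },
            followup_mean=t["followup"]["mean"],
            followup_sd=t["followup"]["sd"],
            followup_range=t["followup"]["range"],
            seed=seed,
        )

    @classmethod
    def singapore_like(cls, n_patients: int | None = None, seed: int = 0):
        n = SINGAPORE_COHORT["n"] if n_patients is None else n_patients
        return cls(n_patients=n, seed=seed)


def _sample_cat(rng, levels, probs, n):
    return rng.choice(np.asarray(levels, dtype=object), size=n,
                      p=np.asarray(probs, dtype=float))


def generate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Sample a cohort table from the planted generative structure.

    Age, Grade, imaging (GAN) risk and the TILs variables are sampled from
    their marginals; Size depends on Grade; the breast-cancer-event
    indicator depends on (Age, GAN risk).  GAN risk is sampled independently
    of Age by construction.
    """
    spec.validate()
    n = spec.n_patients
    rng = np.random.default_rng(spec.seed)
    cols: dict[str, np.ndarray] = {}
    cols["patient_id"] = np.array([f"P{i:05d}" for i in range(n)],
                                  dtype=object)
    age_levels = list(spec.age_marginal)
    cols["age_group"] = _sample_cat(
        rng, age_levels, [spec.age_marginal[k] for k in age_levels], n)
    grade_levels = list(spec.grade_marginal)
    cols["grade"] = _sample_cat(
        rng, grade_levels, [spec.grade_marginal[k] for k in grade_levels], n)
    # Size | Grade
    size = np.empty(n, dtype=object)
    u = rng.random(n)
    for g, row in spec.size_given_grade.items():
        sel = cols["grade"] == g
        size[sel] = np.where(u[sel] < row["gt20"], "gt20", "le20")
    cols["size_group"] = size
    gan_levels = list(spec.gan_risk_marginal)
    cols["gan_risk"] = _sample_cat(
        rng, gan_levels, [spec.gan_risk_marginal[k] for k in gan_levels], n)
    # BCE | (Age, GAN)
    p_bce = np.array([spec.bce_given_age_gan[(a, g)]
                      for a, g in zip(cols["age_group"], cols["gan_risk"])],
                     dtype=float) if n else np.empty(0)
    cols["bce"] = (rng.random(n) < p_bce).astype(int)
    for var, row in spec.tils_marginals.items():
        levels = list(row)
        cols[var] = _sample_cat(rng, levels, [row[k] for k in levels], n)
    cols["followup_years"] = sample_followup(
        n, spec.followup_mean, spec.followup_sd, spec.followup_range, rng)
    df = pd.DataFrame(cols)
    order = [c for c in COHORT_COLUMNS if c in df.columns] + ["gan_risk"]
    return df[order]


def generate_cohort_exact(counts_table: dict, followup: dict | None = None,
                          seed: int = 0) -> pd.DataFrame:
    """Build a cohort whose marginal counts equal ``counts_table`` exactly.

    ``counts_table`` maps column name -> {level: count}; a level named
    ``"NA"`` produces missing values.  Each column is an independently
    shuffled permutation of its level multiset, so the joint structure is
    randomised subject to the marginals.
    """
    if "bce" not in counts_table:
        raise ValueError("counts_table must include a 'bce' column")
    n = sum(counts_table["bce"].values())
    rng = np.random.default_rng(seed)
    cols = {"patient_id": np.array([f"P{i:05d}" for i in range(n)],
                                   dtype=object)}
    for col, counts in counts_table.items():
        total = sum(counts.values())
        if total > n:
            raise ValueError(f"counts for {col!r} exceed n={n}")
        if total < n:
            raise ValueError(f"counts for {col!r} sum to {total} < n={n}")
        values = []
        for level, c in counts.items():
            if c < 0:
                raise ValueError("negative count")
            values.extend([None if level == "NA" else level] * c)
        arr = np.array(values, dtype=object)
        rng.shuffle(arr)
        cols[col] = arr
    if followup is not None:
        cols["followup_years"] = sample_followup(
            n, followup["mean"], followup["sd"], followup["range"], rng)
    df = pd.DataFrame(cols)
    order = [c for c in COHORT_COLUMNS if c in df.columns]
    extra = [c for c in df.columns if c not in order]
    return df[order + extra]


def cohort_from_count_table(which: str, seed: int = 0) -> pd.DataFrame:
    """Marginal-exact cohort for ``which`` in {"oxford", "singapore"}."""
    table = {"oxford": OXFORD_COHORT, "singapore": SINGAPORE_COHORT}[which]
    return generate_cohort_exact(table["counts"], followup=table["followup"],
                                 seed=seed)


# ---------------------------------------------------------------------------
# core images
# ---------------------------------------------------------------------------

# morphology multipliers for aggressive ducts (denser, more pleomorphic)
AGGRESSIVE_DENSITY_FACTOR = 3.0
AGGRESSIVE_CV_FACTOR = 3.0

_BACKGROUND = np.array([246.0, 246.0, 246.0])
_STROMA = np.array([233.0, 186.0, 207.0])
_EPITHELIUM = np.array([204.0, 160.0, 196.0])
_NECROSIS = np.array([238.0, 216.0, 224.0])
_NUCLEUS = np.array([88.0, 58.0, 138.0])


@dataclass
class SyntheticCoreSpec:
    """Parameters of one synthetic TMA core."""

    width: int = 1024
    height: int = 1024
    n_ducts: int = 10
    aggressive_fraction: float = 0.0
    nuclear_density: float = 0.012   # nuclei per px^2 of duct area
    radius_cv: float = 0.12          # nucleus-radius coefficient of variation
    necrosis_prob: float = 0.85      # per aggressive duct
    stain_shift: tuple | None = None  # (add[3], mul[3]) colour perturbation
    seed: int = 0

    def validate(self) -> None:
        if not 0.0 <= self.aggressive_fraction <= 1.0:
            raise ValueError("aggressive_fraction outside [0, 1]")
        if self.n_ducts < 0:
            raise ValueError("n_ducts must be >= 0")
        if min(self.width, self.height) < 64:
            raise ValueError("canvas too small")


CoreSample = namedtuple("CoreSample", ["image", "mask", "duct_labels"])


def generate_core(spec: SyntheticCoreSpec, patient_id: str = "P00000",
                  core_id: str = "C0") -> CoreSample:
    """Render one core; returns (CoreImage, TissueMask, duct_labels).

    ``duct_labels`` is the render log: one dict per duct with its centre,
    radius, aggressiveness flag, necrosis-disc flag and nucleus count, in
    draw order.  Identical spec (including seed) gives bit-identical pixels.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    H, W = spec.height, spec.width
    S = min(H, W)
    img = _BACKGROUND + rng.normal(0.0, 2.2, size=(H, W, 3))
    mask = np.zeros((H, W), dtype=bool)

    # per-duct Bernoulli: aggressive_fraction is the per-duct probability
    flags = rng.random(spec.n_ducts) < spec.aggressive_fraction

    duct_labels = []
    for aggressive in flags:
        r_d = max(10.0, rng.uniform(0.045, 0.07) * S)
        halo = 1.9 * r_d
        cy = rng.uniform(halo, H - halo)
        cx = rng.uniform(halo, W - halo)

        rr, cc = disk((cy, cx), halo, shape=(H, W))
        tint = _STROMA + rng.normal(0.0, 5.0, size=3)
        img[rr, cc] = tint + rng.normal(0.0, 9.0, size=(len(rr), 3))
        mask[rr, cc] = True

        rr, cc = disk((cy, cx), r_d, shape=(H, W))
        tint = _EPITHELIUM + rng.normal(0.0, 5.0, size=3)
        img[rr, cc] = tint + rng.normal(0.0, 8.0, size=(len(rr), 3))

        has_necrosis = bool(aggressive and rng.random() < spec.necrosis_prob)
        if has_necrosis:
            rr, cc = disk((cy, cx), 0.45 * r_d, shape=(H, W))
            img[rr, cc] = _NECROSIS + rng.normal(0.0, 4.0,
                                                 size=(len(rr), 3))

        density = spec.nuclear_density * (
            AGGRESSIVE_DENSITY_FACTOR if aggressive else 1.0)
        cv = spec.radius_cv * (AGGRESSIVE_CV_FACTOR if aggressive else 1.0)
        cv = min(cv, 0.6)
        area = np.pi * r_d ** 2
        n_nuclei = int(rng.poisson(density * area))
        r_n0 = max(2.0, r_d / 18.0)
        inner = 0.5 * r_d if has_necrosis else 0.0  # comedo ring
        for _ in range(n_nuclei):
            rad = np.sqrt(rng.uniform((inner / r_d) ** 2, 1.0)) * r_d
            ang = rng.uniform(0.0, 2 * np.pi)
            ny, nx = cy + rad * np.sin(ang), cx + rad * np.cos(ang)
            r_n = max(1.2, rng.normal(r_n0, cv * r_n0))
            rr, cc = disk((ny, nx), r_n, shape=(H, W))
            img[rr, cc] = _NUCLEUS + rng.normal(0.0, 10.0, size=3)

        duct_labels.append({
            "center": (float(cy), float(cx)), "radius": float(r_d),
            "aggressive": bool(aggressive), "necrosis": has_necrosis,
            "n_nuclei": n_nuclei,
        })

    if spec.stain_shift is not None:
        add, mul = spec.stain_shift
        img = img * np.asarray(mul, dtype=float) + np.asarray(add, dtype=float)

    image = CoreImage(np.clip(img, 0, 255).astype(np.uint8),
                      patient_id=patient_id, core_id=core_id)
    return CoreSample(image, TissueMask(mask), duct_labels)


def _core_seed(base_seed: int, patient_id: str, core_index: int) -> int:
    h = zlib.crc32(f"{patient_id}/{core_index}".encode())
    return int((base_seed * 1_000_003 + h) % (2 ** 31))


def generate_patient_images(patient_id: str, n_cores: int, bce_status,
                            spec_base: SyntheticCoreSpec,
                            high: float = 0.7,
                            low: float = 0.1) -> list[CoreSample]:
    """Render a patient's 1-3 cores, aggressiveness tied to outcome.

    Cores of patients with a breast-cancer event are drawn with the high
    aggressive-duct fraction (default 0.7), others with the low fraction
    (default 0.1); all of a patient's cores share one level.
    """
    if n_cores not in (1, 2, 3):
        raise ValueError("n_cores must be 1, 2 or 3")
    positive = bce_status in (1, "1", "Y", "y", True)
    frac = high if positive else low
    samples = []
    for i in range(n_cores):
        spec = SyntheticCoreSpec(
            width=spec_base.width, height=spec_base.height,
            n_ducts=spec_base.n_ducts, aggressive_fraction=frac,
            nuclear_density=spec_base.nuclear_density,
            radius_cv=spec_base.radius_cv,
            necrosis_prob=spec_base.necrosis_prob,
            stain_shift=spec_base.stain_shift,
            seed=_core_seed(spec_base.seed, patient_id, i))
        samples.append(generate_core(spec, patient_id=patient_id,
                                     core_id=f"{patient_id}-C{i}"))
    return samples
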