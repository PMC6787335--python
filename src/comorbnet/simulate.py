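"""Synthetic cohort generation with a latent-Gaussian (Gaussian copula) model.

Correlated binary disease indicators are produced by thresholding a latent
multivariate normal vector: indicator k is 1 when the latent value exceeds the
standard-normal upper-tail quantile of its marginal prevalence, so the margin
equals the expected prevalence exactly. Pairwise dependence is controlled by
the latent correlation matrix, and the exact joint probability of any pair is
the bivariate-normal orthant probability at the two thresholds — which makes
every downstream estimator testable against known ground truth.

Survey weights are drawn from a unit-mean log-normal by default: strictly
positive and right-skewed, the generic shape of post-stratification weights.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml
from scipy import integrate
from scipy.special import ndtr
from scipy.stats import norm

from .cohort import CohortTable

_PSD_TOL = 1e-8


@dataclass(frozen=True)
class WeightModel:
    """Survey-weight distribution: ``lognormal`` (unit mean) or ``constant``."""

    family: str = "lognormal"
    dispersion: float = 0.3

    def __post_init__(self):
        if self.family not in ("lognormal", "constant"):
            raise ValueError(f"unknown weight family {self.family!r}")
        if self.family == "lognormal" and self.dispersion < 0:
            raise ValueError("dispersion must be non-negative")


@dataclass
class StratumSpec:
    """One stratum: label, size, per-condition margins and latent correlation."""

    label: str
    n: int
    margins: np.ndarray
    latent_correlation: np.ndarray | None = None

    def __post_init__(self):
        self.margins = np.asarray(self.margins, dtype=float)
        k = self.margins.size
        if self.latent_correlation is None:
            self.latent_correlation = np.eye(k)
        self.latent_correlation = np.asarray(self.latent_correlation, dtype=float)
        if self.n < 1:
            raise ValueError(f"stratum {self.label!r}: n must be >= 1")
        if np.any(self.margins <= 0) or np.any(self.margins >= 1):
            raise ValueError(f"stratum {self.label!r}: margins must lie strictly in (0, 1)")
        r = self.latent_correlation
        if r.shape != (k, k):
            raise ValueError(f"stratum {self.label!r}: correlation must be {k}x{k}")
        if not np.allclose(r, r.T, atol=1e-10):
            raise ValueError(f"stratum {self.label!r}: correlation is not symmetric")
        if not np.allclose(np.diag(r), 1.0, atol=1e-10):
            raise ValueError(f"stratum {self.label!r}: correlation diagonal must be 1")
        min_eig = float(np.linalg.eigvalsh(r).min())
        if min_eig < -_PSD_TOL:
            raise ValueError(
                f"stratum {self.label!r}: latent correlation is not positive "
                f"semidefinite (smallest eigenvalue {min_eig:.3e})")


@dataclass
class CohortSpec:
    """Generative description of a synthetic cohort."""

    condition_names: list[str]
    strata: list[StratumSpec]
    weight_model: WeightModel = field(default_factory=WeightModel)
    seed: int = 0

    def __post_init__(self):
        if len(set(self.condition_names)) != len(self.condition_names):
            raise ValueError("condition names must be unique")
        labels = [s.label for s in self.strata]
        if len(set(labels)) != len(labels):
            raise ValueError("stratum labels must be unique")
        k = len(self.condition_names)
        for s in self.strata:
            if s.margins.size != k:
                raise ValueError(
                    f"stratum {s.label!r}: expected {k} margins, got {s.margins.size}")

    # -- config-file round trip -----------------------------------------
    @classmethod
    def from_dict(cls, d: dict) -> "CohortSpec":
        wm = d.get("weight_model", {})
        strata = [StratumSpec(label=s["label"], n=int(s["n"]),
                              margins=s["margins"],
                              latent_correlation=s.get("correlation"))
                  for s in d["strata"]]
        return cls(condition_names=list(d["conditions"]), strata=strata,
                   weight_model=WeightModel(wm.get("family", "lognormal"),
                                            float(wm.get("dispersion", 0.3))),
                   seed=int(d.get("seed", 0)))

    @classmethod
    def from_yaml(cls, path) -> "CohortSpec":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_dict(self) -> dict:
        return {
            "conditions": list(self.condition_names),
            "strata": [{"label": s.label, "n": s.n,
                        "margins": s.margins.tolist(),
                        "correlation": s.latent_correlation.tolist()}
                       for s in self.strata],
            "weight_model": asdict(self.weight_model),
            "seed": self.seed,
        }

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


# ---------------------------------------------------------------------------
# bivariate-normal orthant probability and calibration
# ---------------------------------------------------------------------------

def orthant_probability(margin_a: float, margin_b: float, rho: float) -> float:
    """Exact P(A=1, B=1) for two thresholded latent-normal indicators.

    Equals P(X > a, Y > b) for standard bivariate normal (X, Y) with
    correlation ``rho``, where a, b are the upper-tail quantiles of the two
    margins. Evaluated by reducing to a one-dimensional integral
    ``∫_a^∞ φ(x) Φ̄((b − ρx)/√(1−ρ²)) dx`` and adaptive quadrature.
    """
    if not (0.0 < margin_a < 1.0 and 0.0 < margin_b < 1.0):
        raise ValueError("margins must lie strictly in (0, 1)")
    if not -1.0 - 1e-12 <= rho <= 1.0 + 1e-12:
        raise ValueError("correlation must lie in [-1, 1]")
    if rho >= 1.0 - 1e-12:
        return min(margin_a, margin_b)
    if rho <= -1.0 + 1e-12:
        return max(margin_a + margin_b - 1.0, 0.0)
    if abs(rho) < 1e-15:
        return margin_a * margin_b
    a = float(norm.isf(margin_a))
    b = float(norm.isf(margin_b))
    s = math.sqrt(1.0 - rho * rho)
    inv_sqrt2pi = 1.0 / math.sqrt(2.0 * math.pi)

    def integrand(x):
        # φ(x) · Φ((ρx − b)/√(1−ρ²)); scalar special functions for speed
        return inv_sqrt2pi * math.exp(-0.5 * x * x) * ndtr((rho * x - b) / s)

    val, _ = integrate.quad(integrand, a, np.inf,
                            epsabs=1e-13, epsrel=1e-12, limit=200)
    return float(min(max(val, 0.0), min(margin_a, margin_b)))


def calibrate_dependence(margin_a: float, margin_b: float,
                         target_joint: float) -> float:
    """Latent correlation whose orthant probability equals ``target_joint``.

    The target must lie strictly inside the Fréchet bounds
    (max(pA+pB−1, 0), min(pA, pB)); the orthant probability is strictly
    increasing in the correlation, so monotone bisection converges.
    """
    lower = max(margin_a + margin_b - 1.0, 0.0)
    upper = min(margin_a, margin_b)
    if target_joint <= lower:
        raise ValueError(
            f"target joint {target_joint} violates the Fréchet lower bound "
            f"max(pA+pB-1, 0) = {lower}")
    if target_joint >= upper:
        raise ValueError(
            f"target joint {target_joint} violates the Fréchet upper bound "
            f"min(pA, pB) = {upper}")
    lo, hi = -1.0 + 1e-9, 1.0 - 1e-9
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        f = orthant_probability(margin_a, margin_b, mid) - target_joint
        if abs(f) < 1e-10:
            return mid
        if f < 0:
            lo = mid
        else:
            hi = mid
        if hi - lo < 1e-13:
            break
    return 0.5 * (lo + hi)


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

def _correlation_factor(r: np.ndarray) -> np.ndarray:
    """Square factor L with L Lᵀ = r; eigenvalues in [−tol, 0) are clipped."""
    vals, vecs = np.linalg.eigh(r)
    min_eig = float(vals.min())
    if min_eig < -_PSD_TOL:
        raise ValueError(
            f"latent correlation is not positive semidefinite "
            f"(smallest eigenvalue {min_eig:.3e})")
    return vecs * np.sqrt(np.clip(vals, 0.0, None))


def _draw_weights(model: WeightModel, n: int, rng: np.random.Generator) -> np.ndarray:
    if model.family == "constant" or model.dispersion == 0:
        return np.ones(n)
    sigma = model.dispersion
    w = rng.lognormal(mean=-0.5 * sigma * sigma, sigma=sigma, size=n)
    return w / w.mean()  # stratum mean exactly 1


def generate_cohort(spec: CohortSpec) -> CohortTable:
    """Draw a cohort from ``spec``; deterministic given ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    frames = []
    counter = 0
    for st in spec.strata:
        factor = _correlation_factor(st.latent_correlation)
        z = rng.standard_normal((st.n, st.margins.size))
        latent = z @ factor.T
        thresholds = norm.isf(st.margins)
        ind = (latent > thresholds).astype(np.int8)
        w = _draw_weights(spec.weight_model, st.n, rng)
        df = pd.DataFrame(
            {"subject_id": [f"S{counter + i:06d}" for i in range(st.n)],
             "stratum": st.label, "weight": w})
        for j, name in enumerate(spec.condition_names):
            df[name] = ind[:, j]
        frames.append(df)
        counter += st.n
    return CohortTable(pd.concat(frames, ignore_index=True),
                       list(spec.condition_names))


def truth_table(spec: CohortSpec) -> pd.DataFrame:
    """Exact expected margins, pairwise joints and lifts for a spec.

    One row per ordered condition pair per stratum with columns
    ``stratum, condition_a, condition_b, p_a, p_b, joint, lift, planted``
    where ``planted`` flags pairs with nonzero latent correlation. Joints are
    bivariate-normal orthant probabilities, so P(A,B) respects the Fréchet
    bounds by construction and lift = P(A,B)/(P(A)P(B)).
    """
    rows = []
    names = spec.condition_names
    for st in spec.strata:
        k = st.margins.size
        for i in range(k):
            for j in range(k):
                if i == j:
                    continue
                rho = float(st.latent_correlation[i, j])
                joint = orthant_probability(st.margins[i], st.margins[j], rho)
                lift = joint / (st.margins[i] * st.margins[j])
                rows.append({"stratum": st.label,
                             "condition_a": names[i], "condition_b": names[j],
                             "p_a": st.margins[i], "p_b": st.margins[j],
                             "joint": joint, "lift": lift,
                             "planted": abs(rho) > 1e-12})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# ready-made study-like specification
# ---------------------------------------------------------------------------

#: 31 self-reported chronic conditions with per-sex prevalences (proportions)
#: typical of a population-representative survey of community-dwelling adults
#: aged 50+ (two sex strata of 2,754 men and 3,347 women).
STUDY_CONDITIONS: dict[str, tuple[float, float]] = {
    # name: (male margin, female margin)
    "hypertension": (0.4569, 0.4261),
    "angina": (0.0767, 0.0467),
    "heart_attack": (0.0813, 0.0245),
    "heart_failure": (0.0222, 0.0055),
    "diabetes": (0.1289, 0.0712),
    "stroke": (0.0235, 0.0175),
    "tia": (0.0311, 0.0348),
    "high_cholesterol": (0.4844, 0.5231),
    "heart_murmur": (0.0530, 0.0707),
    "heart_arrhythmia": (0.1251, 0.0949),
    "cataracts": (0.1184, 0.1602),
    "glaucoma": (0.0264, 0.0289),
    "armd": (0.0264, 0.0323),
    "lung_disease": (0.0444, 0.0598),
    "asthma": (0.0756, 0.1135),
    "arthritis": (0.2865, 0.4005),
    "osteoporosis": (0.0485, 0.2545),
    "cancer": (0.0523, 0.0430),
    "parkinsons": (0.0091, 0.0051),
    "alcohol_abuse": (0.0331, 0.0095),
    "ulcers": (0.0496, 0.0452),
    "varicose_ulcer": (0.0189, 0.0300),
    "liver_disease": (0.0075, 0.0064),
    "thyroid": (0.0275, 0.1316),
    "kidney_disease": (0.0085, 0.0032),
    "anaemia": (0.0015, 0.0080),
    "depression": (0.0868, 0.1284),
    "poor_hearing": (0.0298, 0.0140),
    "poor_vision": (0.0210, 0.0185),
    "obesity": (0.2540, 0.2165),
    "urinary_incontinence": (0.1044, 0.2693),
}

_FACTOR_LOADINGS = {
    # latent factors inducing realistic disease clustering: a general frailty
    # factor on everything, plus cardiovascular, cardiometabolic and
    # musculoskeletal/endocrine group factors
    "general": (0.35, None),
    "cardiovascular": (0.40, {"angina", "heart_attack", "heart_failure",
                              "stroke", "tia", "heart_murmur",
                              "heart_arrhythmia", "anaemia", "cataracts"}),
    "cardiometabolic": (0.35, {"hypertension", "high_cholesterol", "diabetes",
                               "obesity"}),
    "musculoskeletal": (0.35, {"arthritis", "osteoporosis", "thyroid",
                               "urinary_incontinence"}),
}


def _study_correlation(names: list[str]) -> np.ndarray:
    k = len(names)
    loadings = np.zeros((k, len(_FACTOR_LOADINGS)))
    for f, (load, members) in enumerate(_FACTOR_LOADINGS.values()):
        for i, name in enumerate(names):
            if members is None or name in members:
                loadings[i, f] = load
    r = loadings @ loadings.T
    np.fill_diagonal(r, 1.0)
    return r


def aging_cohort_spec(seed: int = 0, n_male: int = 2754,
                      n_female: int = 3347) -> CohortSpec:
    """Two-sex cohort spec emulating an ageing-population health survey.

    Margins follow the per-sex lifetime prevalences of 31 self-reported
    chronic conditions in a community-dwelling 50+ population; the latent
    factor structure plants cardiovascular, cardiometabolic and
    musculoskeletal dependence so that common disease pairs (hypertension /
    high cholesterol, arthritis / osteoporosis, ...) co-occur more often than
    chance, as observed in real multimorbidity data.
    """
    names = list(STUDY_CONDITIONS)
    corr = _study_correlation(names)
    male = np.array([STUDY_CONDITIONS[n][0] for n in names])
    female = np.array([STUDY_CONDITIONS[n][1] for n in names])
    return CohortSpec(
        condition_names=names,
        strata=[StratumSpec("male", n_male, male, corr.copy()),
                StratumSpec("female", n_female, female, corr.copy())],
        weight_model=WeightModel("lognormal", 0.3),
        seed=seed)
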