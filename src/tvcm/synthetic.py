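"""Synthetic behaviour-risk-factor surveillance data with known truth.

Emulates the sampling structure of an Italian-style BRFS system (PASSI):
independent monthly cross-sectional samples (no individual is followed
across waves), categorical covariates drawn from fixed marginals, and a
binary outcome whose log-odds combine constant category effects with
smooth, mean-zero time-varying category effects:

    logit P(Y=1) = b0 + a0(w) + sum_v [ b_{v,lev} + a_{v,lev}(w) ]

over waves w = 1..n_waves.  Because every varying effect is declared
mean-zero over the waves, the constant part carries the average effect and
generator truth is directly comparable with a fitted decomposition into a
constant coefficient plus a centred smooth.

The ``passi-like`` preset uses the published marginal distributions of the
2008–2012 PASSI sample (the category counts stored below) and average
odds ratios close to the published constant estimates.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .exceptions import ConfigError

__all__ = [
    "SmoothEffect",
    "Covariate",
    "SyntheticConfig",
    "generate",
    "true_or_curve",
    "true_log_odds_parts",
    "preset",
    "expected_prevalence",
    "calibrate_intercept",
    "PASSI_COMPOSITION_COUNTS",
    "PASSI_COMPOSITION_PERCENT",
]

#: Published sample composition, 2008-2012 (counts per category).
PASSI_COMPOSITION_COUNTS: dict[str, dict[str, int]] = {
    "smoking": {"Smoker": 51696, "Non-smoker": 133923},
    "age": {"18-29": 33450, "30-39": 38660, "40-49": 44193,
            "50-59": 35646, "60-69": 33670},
    "sex": {"Male": 91160, "Female": 94459},
    "marital": {"Married": 112853, "Single": 57959,
                "Widowed or divorced": 14807},
    "education": {"University or higher": 24700, "High school": 82324,
                  "Middle school": 58063, "Primary school or less": 20532},
    "income": {"High": 87989, "Medium": 74159, "Low": 23471},
    "work": {"Works": 107648, "Does not work": 77971},
    "region": {"North": 92741, "Central": 45142, "South": 47736},
    "physical": {"Active": 61357, "Partially active": 70800,
                 "Sedentary": 53462},
    "alcohol": {"High risk drinker": 18852, "Low risk drinker": 52838,
                "Non-drinker": 113929},
    "depression": {"Not depressed": 173416, "Depressed": 12203},
    "year": {"2008": 37205, "2009": 38690, "2010": 35896,
             "2011": 36825, "2012": 37003},
}

#: Published percentages (one decimal) for the same categories.
PASSI_COMPOSITION_PERCENT: dict[str, dict[str, float]] = {
    "smoking": {"Smoker": 27.9, "Non-smoker": 72.1},
    "age": {"18-29": 18.0, "30-39": 20.8, "40-49": 23.8,
            "50-59": 19.2, "60-69": 18.2},
    "sex": {"Male": 49.1, "Female": 50.9},
    "marital": {"Married": 60.8, "Single": 31.2, "Widowed or divorced": 8.0},
    "education": {"University or higher": 13.3, "High school": 44.4,
                  "Middle school": 31.3, "Primary school or less": 11.0},
    "income": {"High": 47.4, "Medium": 40.0, "Low": 12.6},
    "work": {"Works": 58.0, "Does not work": 42.0},
    "region": {"North": 50.0, "Central": 24.3, "South": 25.7},
    "physical": {"Active": 33.1, "Partially active": 38.1, "Sedentary": 28.8},
    "alcohol": {"High risk drinker": 10.2, "Low risk drinker": 28.4,
                "Non-drinker": 61.4},
    "depression": {"Not depressed": 93.4, "Depressed": 6.6},
    "year": {"2008": 20.0, "2009": 20.8, "2010": 19.2,
             "2011": 19.8, "2012": 20.0},
}

#: Published average odds ratios per non-reference category (reference first
#: level of each covariate below).
_PASSI_CONSTANT_OR = {
    ("age", "18-29"): 2.08, ("age", "30-39"): 1.79,
    ("age", "40-49"): 1.75, ("age", "50-59"): 1.46,
    ("sex", "Male"): 1.61,
    ("marital", "Single"): 1.47, ("marital", "Widowed or divorced"): 1.84,
    ("education", "High school"): 1.36, ("education", "Middle school"): 1.81,
    ("education", "Primary school or less"): 1.44,
    ("income", "Medium"): 1.30, ("income", "Low"): 1.78,
    ("work", "Does not work"): 0.74,
    ("region", "Central"): 1.21, ("region", "South"): 1.10,
    ("physical", "Partially active"): 0.95, ("physical", "Sedentary"): 1.15,
    ("alcohol", "Low risk drinker"): 0.69, ("alcohol", "Non-drinker"): 0.47,
    ("depression", "Depressed"): 1.43,
}

_PASSI_REFERENCES = {
    "age": "60-69", "sex": "Female", "marital": "Married",
    "education": "University or higher", "income": "High", "work": "Works",
    "region": "North", "physical": "Active",
    "alcohol": "High risk drinker", "depression": "Not depressed",
}


# ---------------------------------------------------------------------------
# truth components
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SmoothEffect:
    """A named mean-zero function of the wave index.

    shape ``flat``: identically zero.
    shape ``linear``: total change of ``magnitude`` log-odds from the first
    to the last wave (negative = decline), centred.
    shape ``sinusoid``: half-amplitude ``magnitude/2`` over ``periods``
    cycles with phase ``phase`` (radians), centred.
    shape ``piecewise``: flat, then from ``break_frac`` of the observation
    window a linear change totalling ``magnitude``, centred.
    """

    shape: str = "flat"
    magnitude: float = 0.0
    periods: float = 1.0
    phase: float = 0.0
    break_frac: float = 0.5

    def __post_init__(self):
        if self.shape not in {"flat", "linear", "sinusoid", "piecewise"}:
            raise ConfigError(f"unknown varying-effect shape {self.shape!r}")
        if not 0.0 <= self.break_frac <= 1.0:
            raise ConfigError("break_frac must lie in [0, 1]")

    def values(self, n_waves: int) -> np.ndarray:
        """Effect at waves 1..n_waves, exactly mean-zero over the waves."""
        u = np.linspace(0.0, 1.0, n_waves)
        if self.shape == "flat":
            return np.zeros(n_waves)
        if self.shape == "linear":
            v = self.magnitude * u
        elif self.shape == "sinusoid":
            v = 0.5 * self.magnitude * np.sin(
                2.0 * np.pi * self.periods * u + self.phase
            )
        else:  # piecewise
            v = np.where(
                u <= self.break_frac,
                0.0,
                self.magnitude * (u - self.break_frac)
                / max(1.0 - self.break_frac, 1e-12),
            )
        return v - v.mean()

    def __call__(self, n_waves: int, wave) -> np.ndarray:
        vals = self.values(n_waves)
        idx = np.asarray(wave, dtype=int) - 1
        if np.any((idx < 0) | (idx >= n_waves)):
            raise ConfigError(f"wave index outside 1..{n_waves}")
        return vals[idx]


@dataclass(frozen=True)
class Covariate:
    """A categorical covariate: levels, marginal probabilities, reference."""

    name: str
    levels: tuple[str, ...]
    probs: tuple[float, ...]
    reference: str

    def __post_init__(self):
        p = np.asarray(self.probs, dtype=float)
        if len(self.levels) != len(p) or len(self.levels) < 2:
            raise ConfigError(
                f"covariate {self.name!r}: levels and probabilities mismatch"
            )
        if (p < 0).any() or abs(p.sum() - 1.0) > 1e-8:
            raise ConfigError(
                f"covariate {self.name!r}: marginal probabilities must be "
                f"nonnegative and sum to 1 (got sum {p.sum():.6f})"
            )
        if self.reference not in self.levels:
            raise ConfigError(
                f"covariate {self.name!r}: reference {self.reference!r} "
                "is not a level"
            )


@dataclass
class SyntheticConfig:
    """Ground truth for one synthetic surveillance scenario."""

    covariates: list[Covariate]
    intercept_log_odds: float
    constant_log_or: dict[tuple[str, str], float] = field(default_factory=dict)
    varying_log_or: dict[tuple[str, str | None], SmoothEffect] = field(
        default_factory=dict
    )
    n_waves: int = 55
    monthly_n: int = 1000
    seed: int | None = None

    def __post_init__(self):
        names = [c.name for c in self.covariates]
        if len(set(names)) != len(names):
            raise ConfigError("duplicate covariate names")
        by_name = {c.name: c for c in self.covariates}
        for (var, lev) in self.constant_log_or:
            cov = by_name.get(var)
            if cov is None or lev not in cov.levels:
                raise ConfigError(f"constant effect for unknown {var!r}={lev!r}")
            if lev == cov.reference:
                raise ConfigError(
                    f"reference level {var!r}={lev!r} cannot carry a "
                    "constant effect"
                )
        for (var, lev) in self.varying_log_or:
            if var == "(intercept)":
                continue
            cov = by_name.get(var)
            if cov is None or lev not in cov.levels:
                raise ConfigError(f"varying effect for unknown {var!r}={lev!r}")
        if self.n_waves < 2 or self.monthly_n < 1:
            raise ConfigError("need n_waves >= 2 and monthly_n >= 1")

    @property
    def covariate(self) -> dict[str, Covariate]:
        return {c.name: c for c in self.covariates}

    def varying_variables(self) -> list[str]:
        """Variables with at least one non-flat varying effect."""
        out = []
        for (var, _), eff in self.varying_log_or.items():
            if var != "(intercept)" and eff.shape != "flat" and var not in out:
                out.append(var)
        return out

    def has_varying_intercept(self) -> bool:
        eff = self.varying_log_or.get(("(intercept)", None))
        return eff is not None and eff.shape != "flat"

    def to_json(self) -> str:
        d = asdict(self)
        d["constant_log_or"] = [
            {"variable": v, "level": l, "log_or": x}
            for (v, l), x in self.constant_log_or.items()
        ]
        d["varying_log_or"] = [
            {"variable": v, "level": l, **asdict(e)}
            for (v, l), e in self.varying_log_or.items()
        ]
        return json.dumps(d, indent=2)

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticConfig":
        covs = [Covariate(c["name"], tuple(c["levels"]), tuple(c["probs"]),
                          c["reference"]) for c in d["covariates"]]
        const = {(e["variable"], e["level"]): float(e["log_or"])
                 for e in d.get("constant_log_or", [])}
        varying = {}
        for e in d.get("varying_log_or", []):
            kw = {k: e[k] for k in ("shape", "magnitude", "periods", "phase",
                                    "break_frac") if k in e}
            varying[(e["variable"], e["level"])] = SmoothEffect(**kw)
        return cls(
            covariates=covs,
            intercept_log_odds=float(d["intercept_log_odds"]),
            constant_log_or=const, varying_log_or=varying,
            n_waves=int(d.get("n_waves", 55)),
            monthly_n=int(d.get("monthly_n", 1000)),
            seed=d.get("seed"),
        )

    @classmethod
    def from_json(cls, s: str) -> "SyntheticConfig":
        return cls.from_dict(json.loads(s))


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

def _linear_predictor(config: SyntheticConfig, frame: pd.DataFrame) -> np.ndarray:
    eta = np.full(len(frame), config.intercept_log_odds)
    wave = frame["wave"].to_numpy()
    eff = config.varying_log_or.get(("(intercept)", None))
    if eff is not None:
        eta += eff(config.n_waves, wave)
    for cov in config.covariates:
        vals = frame[cov.name].to_numpy()
        for lev in cov.levels:
            mask = vals == lev
            if not mask.any():
                continue
            add = config.constant_log_or.get((cov.name, lev), 0.0)
            veff = config.varying_log_or.get((cov.name, lev))
            if veff is not None:
                eta[mask] += add + veff(config.n_waves, wave[mask])
            elif add:
                eta[mask] += add
    return eta


def generate(config: SyntheticConfig, seed: int | None = None) -> pd.DataFrame:
    """Draw one long-format respondent table under ``config``.

    Each wave is an independent random sample of ``monthly_n`` respondents;
    covariates are drawn independently from their marginals and the binary
    outcome ``smoker`` is Bernoulli with the configured logit.  Fully
    reproducible given the seed (argument wins over ``config.seed``).
    """
    if seed is None:
        seed = config.seed
    rng = np.random.default_rng(seed)
    n = config.n_waves * config.monthly_n
    data = {"wave": np.repeat(np.arange(1, config.n_waves + 1), config.monthly_n)}
    for cov in config.covariates:
        codes = rng.choice(len(cov.levels), size=n, p=cov.probs)
        data[cov.name] = pd.Categorical.from_codes(
            codes, categories=list(cov.levels)
        )
    frame = pd.DataFrame(data)
    eta = _linear_predictor(config, frame)
    prob = 1.0 / (1.0 + np.exp(-eta))
    frame["smoker"] = (rng.random(n) < prob).astype(int)
    return frame


def true_log_odds_parts(config: SyntheticConfig, variable: str, level: str):
    """(constant log-OR, varying values over waves) for a non-reference level."""
    cov = config.covariate.get(variable)
    if cov is None or level not in cov.levels:
        raise ConfigError(f"unknown {variable!r}={level!r}")
    if level == cov.reference:
        raise ConfigError(
            f"{variable!r}={level!r} is the reference level; odds ratios "
            "are not defined for reference categories"
        )
    const = config.constant_log_or.get((variable, level), 0.0)
    eff = config.varying_log_or.get((variable, level), SmoothEffect("flat"))
    return const, eff.values(config.n_waves)


def true_or_curve(config: SyntheticConfig, variable: str, level: str, t) -> np.ndarray:
    """Ground-truth odds ratio exp(constant + varying(t)) at wave(s) t."""
    const, vals = true_log_odds_parts(config, variable, level)
    idx = np.asarray(t, dtype=int) - 1
    if np.any((idx < 0) | (idx >= config.n_waves)):
        raise ConfigError(f"wave index outside 1..{config.n_waves}")
    return np.exp(const + vals[idx])


# ---------------------------------------------------------------------------
# prevalence calibration
# ---------------------------------------------------------------------------

def expected_prevalence(config: SyntheticConfig) -> float:
    """Exact marginal outcome prevalence by enumerating covariate cells.

    Groups covariate combinations by the levels that carry varying effects,
    so the cost is (number of cells) x n_waves.
    """
    s = np.array([0.0])
    pr = np.array([1.0])
    group_vars = set(v for (v, _) in config.varying_log_or if v != "(intercept)")
    for cov in config.covariates:
        effs = np.array([
            config.constant_log_or.get((cov.name, lev), 0.0)
            for lev in cov.levels
        ])
        s = (s[:, None] + effs[None, :]).ravel()
        pr = (pr[:, None] * np.asarray(cov.probs)[None, :]).ravel()
    # group key: which levels of the varying-effect covariates each cell holds
    keys = np.zeros(1, dtype=int)
    for cov in config.covariates:
        reps = np.arange(len(cov.levels))
        if cov.name in group_vars:
            keys = (keys[:, None] * len(cov.levels) + reps[None, :]).ravel()
        else:
            keys = np.repeat(keys, len(cov.levels))
    a0 = config.varying_log_or.get(("(intercept)", None))
    base_t = a0.values(config.n_waves) if a0 is not None else np.zeros(config.n_waves)
    # varying contribution per group key per wave
    uniq, inv = np.unique(keys, return_inverse=True)
    vmat = np.zeros((len(uniq), config.n_waves))
    for gi, key in enumerate(uniq):
        rem = int(key)
        levels_for_key = {}
        for cov in reversed([c for c in config.covariates if c.name in group_vars]):
            rem, code = divmod(rem, len(cov.levels))
            levels_for_key[cov.name] = cov.levels[code]
        for (var, lev), eff in config.varying_log_or.items():
            if var == "(intercept)":
                continue
            if levels_for_key.get(var) == lev:
                vmat[gi] += eff.values(config.n_waves)
    eta = (config.intercept_log_odds + s[:, None]
           + base_t[None, :] + vmat[inv, :])
    p = 1.0 / (1.0 + np.exp(-eta))
    return float(np.sum(pr[:, None] * p) / config.n_waves)


def calibrate_intercept(config: SyntheticConfig, target: float,
                        tol: float = 1e-6) -> float:
    """Intercept log-odds giving marginal prevalence ``target`` (bisection)."""
    lo, hi = -20.0, 20.0
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        cfg = SyntheticConfig(
            covariates=config.covariates, intercept_log_odds=mid,
            constant_log_or=config.constant_log_or,
            varying_log_or=config.varying_log_or,
            n_waves=config.n_waves, monthly_n=config.monthly_n,
        )
        if expected_prevalence(cfg) < target:
            lo = mid
        else:
            hi = mid
        if hi - lo < tol:
            break
    return 0.5 * (lo + hi)


# ---------------------------------------------------------------------------
# presets
# ---------------------------------------------------------------------------

def _passi_covariates() -> list[Covariate]:
    out = []
    for name, counts in PASSI_COMPOSITION_COUNTS.items():
        if name in ("smoking", "year"):
            continue
        levels = tuple(counts)
        total = sum(counts.values())
        probs = tuple(c / total for c in counts.values())
        ref = _PASSI_REFERENCES[name]
        # reference level first for default dummy coding
        order = [ref] + [l for l in levels if l != ref]
        pmap = dict(zip(levels, probs))
        out.append(Covariate(name, tuple(order),
                             tuple(pmap[l] for l in order), ref))
    return out


#: Intercepts pre-calibrated with :func:`calibrate_intercept` so every
#: preset has marginal outcome prevalence 0.279 (the published smoking
#: prevalence).  See docs/methods.md.
_PRESET_INTERCEPTS = {
    "passi-like": -1.8445,
    "null": -1.8421,
    "dense": -1.8449,
    "bench-small": -1.3223,
    "bench-null": -1.3094,
}

_PASSI_VARYING = {
    # young-adult odds decline across the window; total log-range matches a
    # linear OR decline by a factor 2.1/1.7
    ("age", "18-29"): SmoothEffect("linear", -np.log(2.1 / 1.7)),
    ("age", "40-49"): SmoothEffect("linear", -0.12),
    # non-drinkers: non-linear, accelerating decline
    ("alcohol", "Non-drinker"): SmoothEffect("piecewise", -0.25, break_frac=0.4),
    ("alcohol", "Low risk drinker"): SmoothEffect("linear", -0.05),
    # slow background decline in overall smoking odds
    ("(intercept)", None): SmoothEffect("linear", -0.08),
}


def _bench_covariates() -> list[Covariate]:
    return [
        Covariate("age3", ("60-69", "18-39", "40-59"),
                  (0.182, 0.388, 0.430), "60-69"),
        Covariate("alcohol", ("High risk drinker", "Low risk drinker",
                              "Non-drinker"), (0.102, 0.284, 0.614),
                  "High risk drinker"),
        Covariate("sex", ("Female", "Male"), (0.509, 0.491), "Female"),
        Covariate("income", ("High", "Medium", "Low"),
                  (0.474, 0.400, 0.126), "High"),
    ]


_BENCH_CONSTANTS = {
    ("age3", "18-39"): np.log(2.0), ("age3", "40-59"): np.log(1.6),
    ("alcohol", "Low risk drinker"): np.log(0.69),
    ("alcohol", "Non-drinker"): np.log(0.47),
    ("sex", "Male"): np.log(1.61),
    ("income", "Medium"): np.log(1.30), ("income", "Low"): np.log(1.78),
}

_BENCH_VARYING = {
    ("age3", "18-39"): SmoothEffect("linear", -0.7),
    ("alcohol", "Non-drinker"): SmoothEffect("piecewise", -0.6, break_frac=0.3),
}


def preset(name: str, monthly_n: int | None = None,
           seed: int | None = None) -> SyntheticConfig:
    """Named scenarios.

    ``passi-like``
        Ten covariates with the published marginals, average effects equal
        to the published constant odds ratios, time-varying effects for the
        age and alcohol variables plus a slowly declining intercept.
    ``null``
        Same covariates and constant effects, nothing varies.
    ``dense``
        Like ``passi-like`` with additional varying effects (stress test).
    ``bench-small`` / ``bench-null``
        A four-covariate benchmark with pronounced effect evolution, sized
        for repeated-simulation studies of the selection procedure.
    """
    if name in {"passi-like", "null", "dense"}:
        covs = _passi_covariates()
        const = {k: float(np.log(v)) for k, v in _PASSI_CONSTANT_OR.items()}
        if name == "null":
            varying = {}
        elif name == "dense":
            varying = dict(_PASSI_VARYING)
            varying[("sex", "Male")] = SmoothEffect("sinusoid", 0.3, periods=1.5)
            varying[("income", "Low")] = SmoothEffect("linear", 0.3)
        else:
            varying = dict(_PASSI_VARYING)
        mn = 1000 if monthly_n is None else monthly_n
    elif name in {"bench-small", "bench-null"}:
        covs = _bench_covariates()
        const = dict(_BENCH_CONSTANTS)
        varying = dict(_BENCH_VARYING) if name == "bench-small" else {}
        mn = 150 if monthly_n is None else monthly_n
    else:
        raise ConfigError(f"unknown preset {name!r}")
    return SyntheticConfig(
        covariates=covs, intercept_log_odds=_PRESET_INTERCEPTS[name],
        constant_log_or=const, varying_log_or=varying,
        n_waves=55, monthly_n=mn, seed=seed,
    )
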