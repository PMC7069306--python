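"""Synthetic barnacle populations with known ground truth.

The generator emulates the field design the analysis assumes: suspended
scallop shells, each carrying a small cluster (2–7) of barnacles placed
uniformly on a disc, with penis lengths from a truncated normal
(mean 2.77, SD 0.53, bounds 1.67–4.46 cm) and operculum weights from a
log-normal calibrated so the 1st–99th percentiles span 244.98–1,807.32 mg.
True mating-group sizes are computed from the generated geometry by the
same reach-graph code the analysis uses — the geometry is never
re-implemented here.

Responses are generated from linear models in MGSm, MGSf and body weight
with a shared shell-level random intercept and an individual residual:

    response = b0 + b_m*MGSm + b_f*MGSf + b_body*body + u_shell + e

Two modes:

* ``organ_level``: testis+SV, penis and ovary dry weights are each drawn
  from their own coefficient set (floored at 0.01 mg; floor events are
  counted); sex allocation is then implied by the organ weights.
* ``allocation_level``: sex allocation itself is drawn from its
  coefficient set, clipped to [0, 1] (clip events counted); organ weights
  are back-filled for file-format completeness (ovary from its own model,
  testis+SV = allocation/(1-allocation) * ovary) so that recomputing the
  allocation from the written organ weights returns the drawn value.

Every random draw flows from one integer seed; identical configs and
seeds produce byte-identical populations.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field, asdict
from functools import lru_cache
from pathlib import Path
from typing import NamedTuple

import numpy as np
from scipy import stats

from mgsalloc.io import IndividualRecord, StudyConfig
from mgsalloc.graph import build_mating_graph, compute_mgs


class Coefficients(NamedTuple):
    """Fixed-effect coefficient set of one response model."""

    intercept: float
    mgs_m: float
    mgs_f: float
    body: float


#: Default generating coefficient sets: the published random-intercept LMM
#: estimates for each response (weights in mg; sex allocation a fraction).
DEFAULT_COEFFICIENTS: dict[str, Coefficients] = {
    "male_variable": Coefficients(17.980, 10.799, -10.501, 0.059),
    "male_fixed": Coefficients(0.275, 0.105, -0.097, 0.0007),
    "female_variable": Coefficients(0.761, 40.752, -39.898, 0.843),
    "sex_allocation": Coefficients(0.1084, 0.0089, -0.0083, -0.000020),
}

#: Default noise levels (shell-intercept SD, residual SD) per response,
#: chosen so simulated response ranges bracket the observed field ranges.
DEFAULT_NOISE: dict[str, tuple[float, float]] = {
    "male_variable": (10.0, 20.0),
    "male_fixed": (0.15, 0.3),
    "female_variable": (75.0, 150.0),
    "sex_allocation": (0.01, 0.02),
}

#: Truncated-normal penis-length distribution (cm): mean, SD, low, high.
PENIS_LENGTH_MEAN = 2.77
PENIS_LENGTH_SD = 0.53
PENIS_LENGTH_BOUNDS = (1.67, 4.46)

#: Operculum dry-weight calibration range (mg): 1st–99th percentile targets.
OPERCULUM_WEIGHT_RANGE = (244.98, 1807.32)

#: Dry weights are floored here in organ_level mode (mg).
ORGAN_WEIGHT_FLOOR = 0.01

MODES = ("organ_level", "allocation_level")


@dataclass
class GeneratorConfig:
    """Knobs of the synthetic-population generator (defaults = study design)."""

    n_shells: int = 42
    per_shell_range: tuple[int, int] = (2, 7)
    shell_radius: float = 7.5  # cm, disc substrate
    min_separation: float = 0.5  # cm, rejection-sampling floor between centres
    penis_length_mean: float = PENIS_LENGTH_MEAN
    penis_length_sd: float = PENIS_LENGTH_SD
    penis_length_bounds: tuple[float, float] = PENIS_LENGTH_BOUNDS
    operculum_weight_range: tuple[float, float] = OPERCULUM_WEIGHT_RANGE
    coefficient_sets: dict[str, Coefficients] = field(
        default_factory=lambda: dict(DEFAULT_COEFFICIENTS)
    )
    noise: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_NOISE)
    )
    mode: str = "organ_level"
    elongation_factor: float = 1.82
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.per_shell_range
        if not (1 <= lo <= hi <= 50):
            raise ValueError("per_shell_range must be ordered within [1, 50]")
        if self.n_shells < 1:
            raise ValueError("n_shells must be >= 1")
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}")
        if self.penis_length_sd < 0:
            raise ValueError("penis_length_sd must be >= 0")
        blo, bhi = self.penis_length_bounds
        if not blo <= bhi:
            raise ValueError("penis_length_bounds must be ordered")
        for resp, (shell_sd, resid_sd) in self.noise.items():
            if shell_sd < 0 or resid_sd < 0:
                raise ValueError(f"noise SDs for {resp!r} must be >= 0")
        self.coefficient_sets = {
            k: Coefficients(*v) for k, v in self.coefficient_sets.items()
        }


@dataclass
class GroundTruth:
    """Everything needed to recompute a generated population's responses."""

    seed: int
    mode: str
    coefficient_sets: dict[str, Coefficients]
    mgs_m: dict[str, int]
    mgs_f: dict[str, int]
    shell_effects: dict[str, dict[str, float]]  # response -> shell_id -> u
    n_floored: int = 0  # organ weights floored at ORGAN_WEIGHT_FLOOR
    n_clipped: int = 0  # allocations clipped into [0, 1]

    def to_json(self, path: str | Path) -> None:
        data = asdict(self)
        data["coefficient_sets"] = {
            k: list(v) for k, v in self.coefficient_sets.items()
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(data, fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        with open(path, "r", encoding="utf-8") as fh:
            data = json.load(fh)
        data["coefficient_sets"] = {
            k: Coefficients(*v) for k, v in data["coefficient_sets"].items()
        }
        return cls(**data)


@lru_cache(maxsize=32)
def _truncnorm_parent_params(
    mean: float, sd: float, lo: float, hi: float
) -> tuple[float, float]:
    """Parent (mu, sigma) such that the [lo, hi]-truncated normal has the
    requested mean and SD.

    Field summaries report the moments of the *observed* (bounded) sample,
    not of a hypothetical untruncated parent, so the generator calibrates
    the parent so the truncated distribution itself matches them.
    """
    from scipy.optimize import root

    def moments(params: np.ndarray) -> np.ndarray:
        mu, log_sigma = params
        sigma = math.exp(log_sigma)
        a, b = (lo - mu) / sigma, (hi - mu) / sigma
        m, v = stats.truncnorm.stats(a, b, loc=mu, scale=sigma, moments="mv")
        return np.array([m - mean, math.sqrt(v) - sd])

    sol = root(moments, x0=np.array([mean, math.log(sd)]), tol=1e-12)
    if not sol.success:  # pragma: no cover - well-posed for sane inputs
        raise RuntimeError(
            f"truncated-normal calibration failed for mean={mean}, sd={sd}, "
            f"bounds=({lo}, {hi}): {sol.message}"
        )
    mu, log_sigma = sol.x
    return float(mu), float(math.exp(log_sigma))


def sample_penis_length(
    config: GeneratorConfig, rng: np.random.Generator, size: int | None = None
):
    """Draw penis lengths (cm) from the calibrated truncated normal.

    The parent normal is solved so that the truncated distribution's mean
    and SD equal the configured values (which describe the observed,
    bounded sample). With SD = 0 the distribution degenerates to the mean.
    Every draw lies inside the configured bounds.
    """
    mean, sd = config.penis_length_mean, config.penis_length_sd
    lo, hi = config.penis_length_bounds
    if sd == 0:
        if size is None:
            return mean
        return np.full(size, mean)
    mu, sigma = _truncnorm_parent_params(mean, sd, lo, hi)
    a, b = (lo - mu) / sigma, (hi - mu) / sigma
    return stats.truncnorm.rvs(a, b, loc=mu, scale=sigma, size=size, random_state=rng)


def _lognormal_params(lo: float, hi: float) -> tuple[float, float]:
    """(mu, sigma) of a log-normal whose 1st/99th percentiles are lo/hi."""
    z99 = stats.norm.ppf(0.99)
    mu = 0.5 * (math.log(lo) + math.log(hi))
    sigma = (math.log(hi) - math.log(lo)) / (2 * z99)
    return mu, sigma


def _place_on_disc(
    n: int, radius: float, min_sep: float, rng: np.random.Generator
) -> np.ndarray:
    """Uniform positions on a disc with pairwise separation >= min_sep."""
    max_attempts = 10_000 * n
    pts: list[tuple[float, float]] = []
    attempts = 0
    while len(pts) < n:
        attempts += 1
        if attempts > max_attempts:
            raise ValueError(
                f"cannot place {n} individuals with min separation {min_sep} cm "
                f"on a disc of radius {radius} cm"
            )
        r = radius * math.sqrt(rng.uniform())
        theta = rng.uniform(0, 2 * math.pi)
        x, y = r * math.cos(theta), r * math.sin(theta)
        if all(math.hypot(x - px, y - py) >= min_sep for px, py in pts):
            pts.append((x, y))
    return np.asarray(pts)


def _linear_predictor(
    coefs: Coefficients, mgs_m: np.ndarray, mgs_f: np.ndarray, body: np.ndarray
) -> np.ndarray:
    return (
        coefs.intercept + coefs.mgs_m * mgs_m + coefs.mgs_f * mgs_f + coefs.body * body
    )


def generate_population(
    config: GeneratorConfig,
) -> tuple[list[IndividualRecord], GroundTruth]:
    """Generate one synthetic population and its ground truth.

    Deterministic in ``config.seed``: two calls with identical configs
    produce identical records and truth.
    """
    rng = np.random.default_rng(config.seed)
    lo_n, hi_n = config.per_shell_range
    op_mu, op_sigma = _lognormal_params(*config.operculum_weight_range)

    shell_ids: list[str] = []
    skeleton: list[dict] = []
    for s in range(config.n_shells):
        shell_id = f"S{s + 1:04d}"
        shell_ids.append(shell_id)
        n = int(rng.integers(lo_n, hi_n + 1))
        pts = _place_on_disc(n, config.shell_radius, config.min_separation, rng)
        penis = np.atleast_1d(sample_penis_length(config, rng, size=n))
        body = rng.lognormal(mean=op_mu, sigma=op_sigma, size=n)
        for k in range(n):
            skeleton.append(
                {
                    "id": f"{shell_id}-{k + 1:02d}",
                    "shell_id": shell_id,
                    "x": float(pts[k, 0]),
                    "y": float(pts[k, 1]),
                    "penis_length": float(penis[k]),
                    "body": float(body[k]),
                }
            )

    # true MGS from the generated geometry, via the analysis code itself
    geo_records = [
        IndividualRecord(
            id=d["id"],
            shell_id=d["shell_id"],
            x=d["x"],
            y=d["y"],
            penis_length=d["penis_length"],
            operculum_weight=d["body"],
        )
        for d in skeleton
    ]
    graph = build_mating_graph(
        geo_records, StudyConfig(elongation_factor=config.elongation_factor)
    )
    mgs = {m.id: m for m in compute_mgs(graph)}

    mgs_m = np.array([mgs[d["id"]].mgs_m for d in skeleton], dtype=float)
    mgs_f = np.array([mgs[d["id"]].mgs_f for d in skeleton], dtype=float)
    body = np.array([d["body"] for d in skeleton])
    shell_of = np.array([d["shell_id"] for d in skeleton])

    responses = (
        ["male_variable", "male_fixed", "female_variable"]
        if config.mode == "organ_level"
        else ["sex_allocation", "female_variable", "male_fixed"]
    )
    shell_effects: dict[str, dict[str, float]] = {}
    draws: dict[str, np.ndarray] = {}
    n_floored = 0
    n_clipped = 0
    for resp in responses:
        coefs = config.coefficient_sets[resp]
        shell_sd, resid_sd = config.noise[resp]
        u = {
            sid: (rng.normal(0.0, shell_sd) if shell_sd > 0 else 0.0)
            for sid in shell_ids
        }
        shell_effects[resp] = u
        eta = _linear_predictor(coefs, mgs_m, mgs_f, body)
        eta = eta + np.array([u[s] for s in shell_of])
        if resid_sd > 0:
            eta = eta + rng.normal(0.0, resid_sd, size=len(eta))
        if resp == "sex_allocation":
            clipped = np.clip(eta, 0.0, 1.0)
            n_clipped += int(np.sum(clipped != eta))
            draws[resp] = clipped
        else:
            floored = np.maximum(eta, ORGAN_WEIGHT_FLOOR)
            n_floored += int(np.sum(floored != eta))
            draws[resp] = floored

    if config.mode == "allocation_level":
        # back-fill testis+SV so the written organ weights reproduce the
        # drawn allocation: a = t/(t+o)  =>  t = a/(1-a) * o
        a = np.minimum(draws["sex_allocation"], 1.0 - 1e-12)
        draws["male_variable"] = a / (1.0 - a) * draws["female_variable"]

    total = n_floored + n_clipped
    if total > 0.01 * len(skeleton):
        warnings.warn(
            f"{total} of {len(skeleton)} generated responses were floored or "
            "clipped (>1%); coefficient recovery may be biased"
        )

    records = [
        IndividualRecord(
            id=d["id"],
            shell_id=d["shell_id"],
            x=d["x"],
            y=d["y"],
            penis_length=d["penis_length"],
            operculum_weight=d["body"],
            testis_sv_weight=float(draws["male_variable"][k]),
            penis_weight=float(draws["male_fixed"][k]),
            ovary_weight=float(draws["female_variable"][k]),
        )
        for k, d in enumerate(skeleton)
    ]
    truth = GroundTruth(
        seed=config.seed,
        mode=config.mode,
        coefficient_sets=dict(config.coefficient_sets),
        mgs_m={d["id"]: int(mgs_m[k]) for k, d in enumerate(skeleton)},
        mgs_f={d["id"]: int(mgs_f[k]) for k, d in enumerate(skeleton)},
        shell_effects=shell_effects,
        n_floored=n_floored,
        n_clipped=n_clipped,
    )
    return records, truth
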