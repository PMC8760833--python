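"""Synthetic data emulating the coculture optimization study.

The package ships no measured fermentation data; instead this module
generates it.  The default ground truth for ester production (``mbe``) is
the study's reduced cubic response surface in the three coded factors —
inoculation ratio (A), induction time (B) and IPTG concentration (C) —
with replicate noise matching the reported center-point scatter
(23.7 ± 2.3 A.U.).  The cell-density response (``od``) has no published
coefficients, so a clearly-labelled synthetic concave surrogate centered
near the reported predicted OD600 of 8.48 stands in for it.

A deliberately minimal two-strain growth simulator (lag phase, then
exponential growth, then a shared hard cap standing in for substrate
exhaustion) reproduces the qualitative fed-batch population dynamics: the
fast strain (µ = 0.71 1/h, no lag) overtakes a slow partner
(µ = 0.25 1/h, ~15 h lag) unless heavily outnumbered at inoculation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .doe import DesignTable, FactorSpec, generate_ccd, write_design
from .errors import DimensionError, InvalidParameterError
from .models import PolynomialModel, Term, _term_sort_key

__all__ = [
    "mbe_truth_model",
    "od_surrogate_model",
    "default_factors",
    "GroundTruth",
    "GrowthParams",
    "StrainRatioSeries",
    "simulate_responses",
    "simulate_coculture",
    "make_fixture_bundle",
]

# Reduced cubic ester-production surface (A.U.); terms as exponent triples.
_MBE_TERMS = {
    (0, 0, 0): 23.91,   # intercept: predicted production at the design center
    (1, 0, 0): -2.5,    # A
    (0, 1, 0): -1.32,   # B
    (0, 0, 1): 1.19,    # C
    (1, 1, 0): -2.33,   # AB
    (1, 0, 1): -0.078,  # AC
    (0, 1, 1): 0.68,    # BC
    (2, 0, 0): -5.62,   # A²
    (0, 2, 0): -4.42,   # B²
    (0, 0, 2): -5.48,   # C²
    (1, 1, 1): -3.3,    # ABC
    (2, 1, 0): -1.6,    # A²B
    (0, 0, 3): 1.45,    # C³
}


def mbe_truth_model() -> PolynomialModel:
    """The 13-term reduced cubic ester-production model used as ground truth.

    Terms are stored in the package's canonical order (degree, then
    first-factor-major), matching the ordering of fitted models.
    """
    items = sorted(_MBE_TERMS.items(), key=lambda kv: _term_sort_key(Term(kv[0])))
    return PolynomialModel(
        terms=[Term(e) for e, _ in items],
        coefficients=np.array([c for _, c in items]),
        response_name="mbe",
    )


def od_surrogate_model(intercept: float = 8.5, curvature: float = 2.0) -> PolynomialModel:
    """Synthetic concave cell-density surface ``intercept - c(A²+B²+C²)``.

    A surrogate: the study's fitted OD600 model is not published, so a
    paraboloid peaking at the design center (near the reported predicted
    OD600 of 8.48) emulates its qualitative shape.  Linear terms are
    included at zero so the model is hierarchical.
    """
    if curvature <= 0:
        raise InvalidParameterError("curvature must be > 0 (concave surface)")
    exps = [(0, 0, 0), (1, 0, 0), (0, 1, 0), (0, 0, 1), (2, 0, 0), (0, 2, 0), (0, 0, 2)]
    coefs = [intercept, 0.0, 0.0, 0.0, -curvature, -curvature, -curvature]
    return PolynomialModel(
        terms=[Term(e) for e in exps],
        coefficients=np.array(coefs),
        response_name="od",
    )


def default_factors() -> list[FactorSpec]:
    """Natural-unit factor mappings for the three coculture variables.

    Centers are the study's stated center point (50 %RQ5.1, 2.5 h,
    0.23 mM); the coded-unit steps are package configuration (the study's
    natural level table is not published) chosen to span realistic
    laboratory ranges at the axial points.
    """
    return [
        FactorSpec("A", center=50.0, step=15.0, units="%RQ5.1"),
        FactorSpec("B", center=2.5, step=1.0, units="h"),
        FactorSpec("C", center=0.23, step=0.10, units="mM IPTG"),
    ]


@dataclass
class GroundTruth:
    """True response surfaces plus the noise/block structure of replicates."""

    mbe_model: PolynomialModel = field(default_factory=mbe_truth_model)
    od_model: PolynomialModel = field(default_factory=od_surrogate_model)
    noise_sd: dict[str, float] = field(
        default_factory=lambda: {"mbe": 2.3, "od": 0.5}
    )
    block_offsets: dict[int, float] = field(default_factory=dict)

    @property
    def models(self) -> list[PolynomialModel]:
        return [self.mbe_model, self.od_model]

    def __post_init__(self) -> None:
        if any(sd < 0 for sd in self.noise_sd.values()):
            raise InvalidParameterError("noise_sd must be >= 0")


def simulate_responses(
    design: DesignTable,
    truth: GroundTruth | None = None,
    seed: int = 0,
    fmt: str = "wide",
) -> pd.DataFrame:
    """Draw a response table for a design from the ground-truth surfaces.

    Each run's value is the true surface at its coded point, plus the run's
    block offset, plus Gaussian replicate noise.  Each response uses an
    independent seeded substream, so adding a response never perturbs the
    draws of another.  ``fmt="long"`` melts to one row per run per response.
    """
    truth = truth or GroundTruth()
    coded = design.coded_matrix()
    k = coded.shape[1]
    for m in truth.models:
        if m.k != k:
            raise DimensionError(
                f"truth model {m.response_name!r} has {m.k} factors, design has {k}"
            )
    streams = np.random.SeedSequence(seed).spawn(len(truth.models))
    offsets = np.array(
        [truth.block_offsets.get(p.block, 0.0) for p in design.points]
    )
    out = design.to_frame()
    for m, ss in zip(truth.models, streams):
        rng = np.random.default_rng(ss)
        sd = truth.noise_sd.get(m.response_name, 0.0)
        y = m.predict(coded) + offsets
        if sd > 0:
            y = y + rng.normal(0.0, sd, size=len(coded))
        out[m.response_name] = y
    if fmt == "long":
        meta = [c for c in out.columns if c not in {m.response_name for m in truth.models}]
        out = out.melt(id_vars=meta, var_name="response", value_name="value")
    return out


@dataclass(frozen=True)
class GrowthParams:
    """Lag-exponential growth parameters for the fast/slow strain pair."""

    mu_fast: float = 0.71      # 1/h, ester-producer strain
    mu_slow: float = 0.25      # 1/h, alcohol-producer strain
    lag_fast: float = 0.0      # h
    lag_slow: float = 15.0     # h
    inoculum_fast: float = 0.001   # OD600
    inoculum_slow: float = 0.001   # OD600
    od_cap: float = 10.0       # shared carrying capacity (substrate proxy)

    def __post_init__(self) -> None:
        if self.mu_fast <= 0 or self.mu_slow <= 0:
            raise InvalidParameterError("growth rates must be > 0")
        if self.lag_fast < 0 or self.lag_slow < 0:
            raise InvalidParameterError("lag times must be >= 0")
        if self.inoculum_fast <= 0 or self.inoculum_slow <= 0:
            raise InvalidParameterError("inocula must be > 0")
        if self.od_cap <= self.inoculum_fast + self.inoculum_slow:
            raise InvalidParameterError("od_cap must exceed the total inoculum")


@dataclass
class StrainRatioSeries:
    """Per-strain OD600 trajectories and the fast-strain population fraction."""

    times: np.ndarray
    od_fast: np.ndarray
    od_slow: np.ndarray

    @property
    def percent_fast(self) -> np.ndarray:
        return 100.0 * self.od_fast / (self.od_fast + self.od_slow)

    @property
    def od_total(self) -> np.ndarray:
        return self.od_fast + self.od_slow

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_h": self.times,
                "od_fast": self.od_fast,
                "od_slow": self.od_slow,
                "percent_fast": self.percent_fast,
            }
        )


def simulate_coculture(
    params: GrowthParams = GrowthParams(), t_end: float = 24.0, dt: float = 0.1
) -> StrainRatioSeries:
    """Two-strain lag-then-exponential growth with a shared hard cap.

    Both strains grow exponentially after their lag; when the summed OD
    reaches ``od_cap`` (substrate exhaustion), both stop.  At the crossing
    step the final increments are shortened by a common sub-step so the
    total lands exactly on the cap.
    """
    if dt <= 0 or t_end <= 0:
        raise InvalidParameterError("t_end and dt must be > 0")
    times = np.arange(0.0, t_end + dt / 2, dt)
    n = len(times)
    od_f = np.empty(n)
    od_s = np.empty(n)
    od_f[0], od_s[0] = params.inoculum_fast, params.inoculum_slow
    capped = False
    for i in range(1, n):
        if capped:
            od_f[i], od_s[i] = od_f[i - 1], od_s[i - 1]
            continue
        t0 = times[i - 1]
        gf = np.exp(params.mu_fast * _active_dt(t0, dt, params.lag_fast))
        gs = np.exp(params.mu_slow * _active_dt(t0, dt, params.lag_slow))
        nf, ns = od_f[i - 1] * gf, od_s[i - 1] * gs
        if nf + ns >= params.od_cap:
            # shrink the step by lam in (0,1] so the total hits the cap
            from scipy.optimize import brentq

            def total(lam):
                return od_f[i - 1] * gf**lam + od_s[i - 1] * gs**lam - params.od_cap

            lam = 1.0 if total(1.0) <= 0 else brentq(total, 0.0, 1.0)
            nf, ns = od_f[i - 1] * gf**lam, od_s[i - 1] * gs**lam
            capped = True
        od_f[i], od_s[i] = nf, ns
    return StrainRatioSeries(times=times, od_fast=od_f, od_slow=od_s)


def _active_dt(t0: float, dt: float, lag: float) -> float:
    """Portion of the step [t0, t0+dt] past the lag phase."""
    return min(max(t0 + dt - lag, 0.0), dt)


def make_fixture_bundle(
    path, seed: int = 0, truth: GroundTruth | None = None
) -> dict[str, Path]:
    """Write a complete worked-example input set under ``path``.

    Produces the study-shaped 34-run design (3 factors, duplicated
    factorial and axial points, six centers, two blocks), simulated
    ester/OD responses, a cetyl-palmitate calibration table, colony counts
    from the growth simulator, and a pipeline config — everything the
    end-to-end pipeline consumes.  Deterministic per seed.
    """
    truth = truth or GroundTruth()
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    sub = np.random.SeedSequence(seed).spawn(3)

    design = generate_ccd(
        k=3,
        factorial_reps=2,
        axial_reps=2,
        center_reps=6,
        n_blocks=2,
        seed=seed,
        factors=default_factors(),
    )
    files = {"design": path / "design.csv"}
    write_design(files["design"], design)

    responses = simulate_responses(design, truth, seed=seed)
    files["responses"] = path / "responses.csv"
    responses.to_csv(files["responses"], index=False)

    # TLC external standard: 10-40 ug cetyl palmitate, near-linear signal
    rng = np.random.default_rng(sub[1])
    amounts = np.array([10.0, 20.0, 30.0, 40.0])
    signal = 1.0 * amounts + rng.normal(0, 0.2, size=amounts.size)
    files["calibration"] = path / "calibration.csv"
    pd.DataFrame({"amount_ug": amounts, "signal_au": signal}).to_csv(
        files["calibration"], index=False
    )

    # plate counts along the simulated takeover (100 colonies scored)
    series = simulate_coculture(GrowthParams(), t_end=24.0, dt=0.5)
    rng2 = np.random.default_rng(sub[2])
    sample_t = np.arange(0, 25, 4)
    rows = []
    for t in sample_t:
        i = int(np.argmin(np.abs(series.times - t)))
        frac = series.percent_fast[i] / 100.0
        total = 100
        rows.append(
            {
                "time_h": float(series.times[i]),
                "fluorescent": int(rng2.binomial(total, frac)),
                "total": total,
            }
        )
    files["colony_counts"] = path / "colony_counts.csv"
    pd.DataFrame(rows).to_csv(files["colony_counts"], index=False)

    config = {
        "seed": seed,
        "outdir": "results",
        "factors": [
            {
                "name": f.name,
                "center": f.center,
                "step": f.step,
                "alpha": f.alpha,
                "units": f.units,
            }
            for f in design.factors
        ],
        "design": {
            "factorial_reps": 2,
            "axial_reps": 2,
            "center_reps": 6,
            "n_blocks": 2,
        },
        "selection": {"method": "forward", "alpha_enter": 0.10, "max_degree": 3},
        "region": {"kind": "cube", "bound": 1.0},
        "responses": ["mbe", "od"],
        "simulate": False,
    }
    files["config"] = path / "config.json"
    files["config"].write_text(json.dumps(config, indent=2))
    return files
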