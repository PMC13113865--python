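"""Synthetic PSMC-style trajectories with known coverage-dependent distortion.

Every downstream stage (parsing, projection, distances, sweep, calibration)
is testable without external genomes: this module generates
piecewise-constant Ne histories under standard demographic archetypes
(constant size, bottleneck, expansion, zigzag), applies a coverage-
dependent multiplicative distortion with known ground-truth FNR, and can
render a trajectory back into a syntactically valid PSMC output file so
parser fixtures are self-generating.

The distortion emulates the first-order effect of missed heterozygotes at
low depth: a deflated theta0 shrinks both axes by the factor (1 - FNR), so
the distorted curve sits below and toward more recent times.  The default
ground-truth law is quadratic in coverage, f(c) = 0.6 * (15 - c)^2 / 15^2
for c < 15 and 0 at or above 15x, matching the anchor assumption that
false-negative losses vanish at high depth.  Real downsampling also
reshapes curves non-multiplicatively (depth filters bite hardest at 5x);
that second-order behaviour is deliberately out of scope here.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .psmc_io import SampleMeta, ScaledTrajectory, ScalingParams

__all__ = [
    "DemographyScenario",
    "DistortionModel",
    "SCENARIO_KINDS",
    "generate_trajectory",
    "distort_by_coverage",
    "render_psmc_file",
]

SCENARIO_KINDS = ("constant", "bottleneck", "expansion", "zigzag")


@dataclass(frozen=True)
class DemographyScenario:
    """A piecewise-constant demographic history archetype.

    ``kind`` selects the Ne profile; ``base_ne`` is the baseline size in
    individuals; events are placed between ``t_recent`` and ``t_oldest``
    (years).  ``n_segments`` controls how finely the history is cut; the
    segment boundaries receive a small seeded jitter so they never sit
    exactly on analysis-grid time points.
    """

    kind: str = "constant"
    base_ne: float = 10_000.0
    n_segments: int = 14
    t_recent: float = 5.0e3
    t_oldest: float = 2.0e6
    bottleneck_multiplier: float = 0.2
    expansion_multiplier: float = 5.0
    zigzag_multipliers: tuple[float, float] = (3.0, 0.4)
    event_window: tuple[float, float] = (5.0e4, 2.5e5)

    def __post_init__(self) -> None:
        if self.kind not in SCENARIO_KINDS:
            raise ValueError(f"kind must be one of {SCENARIO_KINDS}, got {self.kind!r}")
        if self.base_ne <= 0:
            raise ValueError("base_ne must be positive")
        if self.n_segments < 2:
            raise ValueError("need at least 2 segments")
        if not 0 < self.t_recent < self.t_oldest:
            raise ValueError("require 0 < t_recent < t_oldest")


@dataclass(frozen=True)
class DistortionModel:
    """Coverage-dependent multiplicative distortion with known true FNR.

    ``true_fnr(c)`` is 0 at or above ``anchor_coverage`` and rises
    quadratically as depth falls: amplitude * (anchor - c)^2 / anchor^2.
    ``noise_sd`` adds seeded multiplicative log-normal noise to segment Ne
    (never to times, preserving monotonicity), mimicking low-coverage
    instability.
    """

    amplitude: float = 0.6
    anchor_coverage: float = 15.0
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.amplitude < 1.0:
            raise ValueError("amplitude must lie in [0, 1)")
        if self.anchor_coverage <= 0:
            raise ValueError("anchor_coverage must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")

    def true_fnr(self, coverage: float) -> float:
        if coverage <= 0:
            raise ValueError("coverage must be positive")
        if coverage >= self.anchor_coverage:
            return 0.0
        frac = (self.anchor_coverage - coverage) / self.anchor_coverage
        return self.amplitude * frac * frac


def _segment_multipliers(scenario: DemographyScenario, starts: np.ndarray) -> np.ndarray:
    lo, hi = scenario.event_window
    mult = np.ones_like(starts)
    if scenario.kind == "constant":
        return mult
    if scenario.kind == "bottleneck":
        inside = (starts >= lo) & (starts < hi)
        mult[inside] = scenario.bottleneck_multiplier
        return mult
    if scenario.kind == "expansion":
        # Ancestral population small, expands toward the present at `lo`.
        mult[starts >= lo] = 1.0 / scenario.expansion_multiplier
        return mult
    # zigzag: alternate high/low blocks of two segments each.
    up, down = scenario.zigzag_multipliers
    for i in range(starts.size):
        phase = (i // 2) % 2
        mult[i] = up if phase == 0 else down
    mult[0] = 1.0
    return mult


def generate_trajectory(scenario: DemographyScenario, seed: int = 0) -> ScaledTrajectory:
    """Deterministically generate a trajectory for a scenario and seed."""
    rng = np.random.default_rng(seed)
    inner = np.logspace(
        np.log10(scenario.t_recent), np.log10(scenario.t_oldest), scenario.n_segments - 1
    )
    jitter = rng.uniform(0.97, 1.03, size=inner.size)
    starts = np.concatenate([[0.0], inner * jitter])
    starts = np.maximum.accumulate(starts + np.arange(starts.size) * 1e-9)
    ne = scenario.base_ne * _segment_multipliers(scenario, starts)
    meta = SampleMeta(sample_id=f"sim-{scenario.kind}", mean_coverage=30.0)
    return ScaledTrajectory(starts, ne, meta, fnr_applied=0.0)


def distort_by_coverage(
    traj: ScaledTrajectory, coverage: float, model: DistortionModel | None = None
) -> ScaledTrajectory:
    """Emulate the low-coverage bias on a trajectory.

    All coordinates shrink by (1 - f(coverage)); with ``noise_sd > 0``,
    segment Ne additionally picks up seeded multiplicative log-normal
    noise.  At or above the anchor coverage (noise off) this is the
    identity.
    """
    model = model or DistortionModel()
    f = model.true_fnr(coverage)
    factor = 1.0 - f
    ne = traj.ne * factor
    if model.noise_sd > 0:
        rng = np.random.default_rng(
            np.random.SeedSequence([model.seed, int(round(coverage * 1000))])
        )
        ne = ne * rng.lognormal(mean=0.0, sigma=model.noise_sd, size=ne.size)
    meta = SampleMeta(
        sample_id=f"{traj.meta.sample_id}-{coverage:g}x",
        mean_coverage=coverage,
        population=traj.meta.population,
    )
    return ScaledTrajectory(traj.times * factor, ne, meta, fnr_applied=0.0)


def render_psmc_file(
    traj: ScaledTrajectory,
    params: ScalingParams,
    path: str | Path,
    round_index: int = 25,
) -> None:
    """Write a trajectory as a syntactically valid PSMC output block.

    Inverse of the psmc_plot scaling: N0 is taken as the first segment's
    Ne, theta0 = 4 * mu * bin_size * N0, t_k = time / (2 * N0 * gen_time),
    lambda_k = Ne / N0.  Parsing the file and re-scaling reproduces the
    trajectory to floating-point accuracy.
    """
    n0 = float(traj.ne[0])
    theta0 = 4.0 * params.mu * params.bin_size * n0
    t_scaled = traj.times / (2.0 * n0 * params.gen_time)
    lambdas = traj.ne / n0
    with open(Path(path), "w") as fh:
        fh.write("CC\tsynthetic PSMC-style output rendered from a trajectory\n")
        fh.write(f"RD\t{round_index}\n")
        fh.write(f"TR\t{'%.17g' % theta0}\t0.00020\n")
        for k, (t, lam) in enumerate(zip(t_scaled, lambdas)):
            fh.write(f"RS\t{k}\t{'%.17g' % t}\t{'%.17g' % lam}\t0\t0\n")
        fh.write("PA\t-1 0\n")
        fh.write("//\n")
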