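"""Reading and writing PSMC results.

The PSMC program emits a plain-text log in which each EM iteration is a
block of record lines keyed by two-letter codes (``RD`` round index, ``TR``
scaled mutation/recombination rates, ``RS`` per-interval time and relative
size) terminated by ``//``.  This module parses those blocks, selects an EM
round, and converts the dimensionless estimate into a piecewise-constant
effective-population-size trajectory in real units (years, individuals)
using the standard psmc_plot scaling:

    N0 = theta0 / (4 * mu * bin_size)
    t_years[k] = 2 * N0 * t_k * gen_time
    Ne[k] = N0 * lambda_k

Trajectories round-trip losslessly through a simple TSV representation with
``#``-prefixed metadata headers.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = [
    "RawPSMCBlock",
    "ScalingParams",
    "SampleMeta",
    "ScaledTrajectory",
    "read_psmc_file",
    "select_block",
    "scale_trajectory",
    "write_curve_tsv",
    "read_curve_tsv",
]


@dataclass(frozen=True)
class RawPSMCBlock:
    """One EM-round block of a PSMC output file.

    Attributes
    ----------
    round_index : int
        EM iteration number (``RD`` record).
    theta0 : float
        Scaled mutation rate per consensus bin (first ``TR`` field).
    rho0 : float
        Scaled recombination rate (second ``TR`` field; carried, unused).
    times : ndarray
        Interval start times t_k in units of 2*N0 generations, t_0 = 0,
        strictly increasing.
    lambdas : ndarray
        Relative population-size multipliers lambda_k, all positive.
    """

    round_index: int
    theta0: float
    rho0: float
    times: np.ndarray
    lambdas: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        lam = np.asarray(self.lambdas, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "lambdas", lam)
        if t.size == 0:
            raise ValueError("PSMC block has no intervals")
        if t.size != lam.size:
            raise ValueError("times and lambdas length mismatch")
        if t[0] != 0.0:
            raise ValueError("first interval must start at t=0")
        if np.any(np.diff(t) <= 0):
            raise ValueError("interval times must be strictly increasing")
        if self.theta0 <= 0:
            raise ValueError("theta0 must be positive")
        if np.any(lam <= 0):
            raise ValueError("all lambda_k must be positive")


@dataclass(frozen=True)
class ScalingParams:
    """Real-unit scaling parameters.

    mu is the per-site per-generation mutation rate, gen_time the
    generation time in years, and bin_size the consensus bin size in bp
    (100 bp is the fq2psmcfa default).
    """

    mu: float
    gen_time: float
    bin_size: float = 100.0

    def __post_init__(self) -> None:
        if self.mu <= 0 or self.gen_time <= 0 or self.bin_size <= 0:
            raise ValueError("mu, gen_time and bin_size must be positive")


@dataclass(frozen=True)
class SampleMeta:
    """Per-sample metadata: identifier, mean depth (x) and population label."""

    sample_id: str = "sample"
    mean_coverage: float = 1.0
    population: str = ""

    def __post_init__(self) -> None:
        if self.mean_coverage <= 0:
            raise ValueError("mean_coverage must be positive")


@dataclass(frozen=True)
class ScaledTrajectory:
    """Piecewise-constant Ne-vs-time curve in real units.

    ``times`` holds segment start times in years (strictly increasing,
    first typically 0); each segment is right-open, [t_k, t_{k+1}), with
    the last extending to infinity.  ``ne`` holds the effective population
    size in individuals.  ``fnr_applied`` records the cumulative
    false-negative-rate correction already applied to the coordinates.
    """

    times: np.ndarray
    ne: np.ndarray
    meta: SampleMeta = field(default_factory=SampleMeta)
    fnr_applied: float = 0.0

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        n = np.asarray(self.ne, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "ne", n)
        if t.size == 0 or t.size != n.size:
            raise ValueError("times and ne must be equal-length, non-empty")
        if np.any(np.diff(t) <= 0):
            raise ValueError("segment start times must be strictly increasing")
        if np.any(n <= 0):
            raise ValueError("Ne must be positive everywhere")
        if not 0.0 <= self.fnr_applied < 1.0:
            raise ValueError("fnr_applied must lie in [0, 1)")

    @property
    def n_segments(self) -> int:
        return int(self.times.size)

    def with_meta(self, meta: SampleMeta) -> "ScaledTrajectory":
        return replace(self, meta=meta)


def read_psmc_file(path: str | Path) -> list[RawPSMCBlock]:
    """Parse a PSMC output file into its EM-round blocks, in file order.

    Only ``RD``, ``TR`` and ``RS`` records are consumed; any other record
    code (``LK``, ``QD``, ``RI``, ``MM``, ``MT``, ``PA``, ``DC``, ...) is
    skipped.  Blocks are separated by ``//``; a missing final ``//`` and
    trailing blank lines are tolerated.  A block is reported only if it
    carries both a ``TR`` and at least one ``RS`` record.
    """
    path = Path(path)
    blocks: list[RawPSMCBlock] = []
    round_index: int | None = None
    theta0 = rho0 = None
    times: list[float] = []
    lambdas: list[float] = []

    def flush() -> None:
        nonlocal round_index, theta0, rho0, times, lambdas
        if round_index is not None and theta0 is not None and times:
            blocks.append(
                RawPSMCBlock(round_index, theta0, rho0, np.array(times), np.array(lambdas))
            )
        round_index = theta0 = rho0 = None
        times, lambdas = [], []

    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("//"):
                flush()
                continue
            fields = line.split()
            code = fields[0]
            try:
                if code == "RD":
                    flush()
                    round_index = int(fields[1])
                elif code == "TR":
                    theta0 = float(fields[1])
                    rho0 = float(fields[2])
                elif code == "RS":
                    times.append(float(fields[2]))
                    lambdas.append(float(fields[3]))
            except (IndexError, ValueError) as exc:
                raise ValueError(
                    f"{path}: malformed {code} record at line {lineno}: {line!r}"
                ) from exc
    flush()

    if not blocks:
        raise ValueError(f"empty PSMC file: {path} contains no parseable block")
    return blocks


def select_block(
    blocks: Sequence[RawPSMCBlock], round_index: int | None = None
) -> RawPSMCBlock:
    """Pick one EM round; by default the largest round index (final estimate)."""
    if not blocks:
        raise ValueError("no PSMC blocks to select from")
    if round_index is None:
        return max(blocks, key=lambda b: b.round_index)
    for block in blocks:
        if block.round_index == round_index:
            return block
    available = sorted(b.round_index for b in blocks)
    raise ValueError(f"EM round {round_index} not present; available rounds: {available}")


def scale_trajectory(
    block: RawPSMCBlock, params: ScalingParams, meta: SampleMeta | None = None
) -> ScaledTrajectory:
    """Convert a dimensionless PSMC block to real time/Ne units."""
    n0 = block.theta0 / (4.0 * params.mu * params.bin_size)
    times = 2.0 * n0 * block.times * params.gen_time
    ne = n0 * block.lambdas
    return ScaledTrajectory(times, ne, meta or SampleMeta(), fnr_applied=0.0)


_FLOAT_FMT = "%.17g"


def write_curve_tsv(traj: ScaledTrajectory, path: str | Path) -> None:
    """Write a trajectory as TSV with ``#`` metadata headers (lossless)."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# sample={traj.meta.sample_id}\n")
        fh.write(f"# coverage={_FLOAT_FMT % traj.meta.mean_coverage}\n")
        fh.write(f"# population={traj.meta.population}\n")
        fh.write(f"# fnr_applied={_FLOAT_FMT % traj.fnr_applied}\n")
        fh.write("time_years\tNe\n")
        for t, n in zip(traj.times, traj.ne):
            fh.write(f"{_FLOAT_FMT % t}\t{_FLOAT_FMT % n}\n")


def read_curve_tsv(path: str | Path) -> ScaledTrajectory:
    """Read back a trajectory written by :func:`write_curve_tsv`."""
    path = Path(path)
    meta_kv: dict[str, str] = {}
    header: list[str] | None = None
    times: list[float] = []
    ne: list[float] = []
    with open(path) as fh:
        for raw in fh:
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("#"):
                body = line.lstrip("# ").strip()
                if "=" in body:
                    key, _, val = body.partition("=")
                    meta_kv[key.strip()] = val.strip()
                continue
            fields = line.split("\t")
            if header is None:
                header = fields
                if "time_years" not in header or "Ne" not in header:
                    raise ValueError(
                        f"{path}: expected columns 'time_years' and 'Ne', got {header}"
                    )
                continue
            row = dict(zip(header, fields))
            times.append(float(row["time_years"]))
            ne.append(float(row["Ne"]))
    if header is None or not times:
        raise ValueError(f"{path}: no trajectory rows found")
    meta = SampleMeta(
        sample_id=meta_kv.get("sample", "sample"),
        mean_coverage=float(meta_kv.get("coverage", 1.0)),
        population=meta_kv.get("population", ""),
    )
    return ScaledTrajectory(
        np.array(times), np.array(ne), meta, fnr_applied=float(meta_kv.get("fnr_applied", 0.0))
    )
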