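"""Pseudo-data generation for the integrated abundance model.

The simulator mirrors the data-generating process the model is built for:
a landscape of ``n_sites`` sites, each occupied with probability ``occupancy``
(Omega); a fixed total population allocated multinomially across occupied
sites; replicated citizen-science counts subject to imperfect detection
(``detection``, p) and a constant per-site, per-replicate expectation of
false positives (``misidentification``, m); and expert counts at a subset
of sites observed with Poisson or variance-scaled Normal error.

Everything downstream (inference, the simulation experiments) is testable
against datasets produced here, with no external data required.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ScenarioConfig",
    "TrueState",
    "SimulatedDataset",
    "simulate_truth",
    "simulate_cs_counts",
    "simulate_expert_counts",
    "generate_dataset",
    "read_scenario_file",
    "write_dataset",
    "read_dataset",
]


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


@dataclass(frozen=True)
class ScenarioConfig:
    """One point in the simulation design space.

    Defaults are the baseline scenario of the simulation study: 20 sites,
    10 citizen-science replicates, total abundance 2000, occupancy 0.8,
    detection 0.8, misidentification 10 per site per replicate, Poisson-level
    expert variance (k = 1) and full expert coverage.
    """

    n_sites: int = 20
    n_replicates: int = 10
    total_abundance: int = 2000
    occupancy: float = 0.8
    detection: float = 0.8
    misidentification: float = 10.0
    expert_variance_scale: float = 1.0
    expert_coverage: float = 1.0
    n_simulations: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_sites < 2:
            raise ValueError("n_sites must be at least 2")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be positive")
        if self.total_abundance < 0:
            raise ValueError("total_abundance must be non-negative")
        for name in ("occupancy", "detection"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.misidentification < 0:
            raise ValueError("misidentification must be non-negative")
        if self.expert_variance_scale < 0:
            raise ValueError("expert_variance_scale must be non-negative")
        if not 0.0 < self.expert_coverage <= 1.0:
            raise ValueError(
                "expert_coverage must lie in (0, 1]; at least one expert "
                "site is required for the joint likelihood"
            )
        if self.n_simulations < 1:
            raise ValueError("n_simulations must be positive")

    @property
    def n_expert_sites(self) -> int:
        return max(1, _round_half_up(self.expert_coverage * self.n_sites))


@dataclass(frozen=True)
class TrueState:
    """Latent state that generated a dataset: occupancy z, abundances N."""

    z: np.ndarray
    N: np.ndarray
    omega: float
    total: int

    def __post_init__(self) -> None:
        if np.any((self.z == 0) & (self.N > 0)):
            raise ValueError("unoccupied sites must have N = 0")


@dataclass(frozen=True)
class SimulatedDataset:
    """Citizen-science matrix y, expert vector w with mask, and the truth."""

    y: np.ndarray  # (n_sites, n_replicates) int
    w: np.ndarray  # (n_sites,) float; meaningful only where expert_mask
    expert_mask: np.ndarray  # (n_sites,) bool
    truth: TrueState
    config: ScenarioConfig
    w_raw: np.ndarray | None = field(default=None, repr=False)  # pre-rounding


def simulate_truth(config: ScenarioConfig, rng: np.random.Generator) -> TrueState:
    """Draw per-site occupancy and allocate the total abundance.

    Occupancy indicators are independent Bernoulli(Omega); the configured
    total is then split among occupied sites by a multinomial draw with
    equal cell probabilities.  If the Bernoulli draw leaves no site occupied
    while a positive total is configured, the occupancy vector is redrawn so
    the returned state is always internally consistent.
    """
    n = config.n_sites
    if config.occupancy == 0.0 and config.total_abundance > 0:
        raise ValueError("cannot place positive abundance with occupancy 0")
    for _ in range(100_000):
        z = (rng.random(n) < config.occupancy).astype(np.int64)
        if z.any() or config.total_abundance == 0:
            break
    else:  # pragma: no cover - occupancy > 0 makes this astronomically rare
        raise RuntimeError("failed to draw an occupied site")
    N = np.zeros(n, dtype=np.int64)
    occ = np.flatnonzero(z)
    if occ.size and config.total_abundance > 0:
        probs = np.full(occ.size, 1.0 / occ.size)
        N[occ] = rng.multinomial(config.total_abundance, probs)
    return TrueState(z=z, N=N, omega=config.occupancy, total=int(N.sum()))


def simulate_cs_counts(
    truth: TrueState,
    p: float,
    m: float,
    n_replicates: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Replicated citizen-science counts, y[i, j] ~ Poisson(N_i * p + m)."""
    if not 0.0 <= p <= 1.0:
        raise ValueError("detection probability must lie in [0, 1]")
    if m < 0:
        raise ValueError("misidentification rate must be non-negative")
    mu = truth.N * p + m
    return rng.poisson(mu[:, None], size=(truth.N.size, n_replicates))


def simulate_expert_counts(
    truth: TrueState,
    k: float,
    coverage: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Expert counts with variance k*N_i at a random subset of sites.

    k = 1 draws Poisson(N_i); k = 0 returns the exact abundances; any other
    k draws Normal(N_i, k*N_i), truncated below at zero and rounded to the
    nearest integer so that simulated expert data are valid counts.

    Returns ``(w, mask, w_raw)`` where ``mask`` flags the
    round(coverage * n_sites) sites with expert data and ``w_raw`` holds the
    untruncated continuous draws (for variance checking).
    """
    if not 0.0 < coverage <= 1.0:
        raise ValueError("coverage must lie in (0, 1]")
    n = truth.N.size
    Nf = truth.N.astype(float)
    if k == 1.0:
        w_raw = rng.poisson(truth.N).astype(float)
        w = w_raw.copy()
    elif k == 0.0:
        w_raw = Nf.copy()
        w = Nf.copy()
    else:
        sd = np.sqrt(k * Nf)
        w_raw = rng.normal(Nf, sd)
        w_raw[truth.N == 0] = 0.0  # zero variance at empty sites
        w = np.floor(np.clip(w_raw, 0.0, None) + 0.5)
    n_in = max(1, _round_half_up(coverage * n))
    mask = np.zeros(n, dtype=bool)
    mask[rng.choice(n, size=n_in, replace=False)] = True
    return w, mask, w_raw


def generate_dataset(
    config: ScenarioConfig, rng: np.random.Generator | None = None
) -> SimulatedDataset:
    """Compose truth, citizen-science and expert simulation into one dataset.

    With ``rng=None`` a fresh generator is seeded from ``config.seed`` so the
    same (config, seed) pair always reproduces the same dataset bit for bit.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    truth = simulate_truth(config, rng)
    y = simulate_cs_counts(
        truth, config.detection, config.misidentification, config.n_replicates, rng
    )
    w, mask, w_raw = simulate_expert_counts(
        truth, config.expert_variance_scale, config.expert_coverage, rng
    )
    return SimulatedDataset(
        y=y, w=w, expert_mask=mask, truth=truth, config=config, w_raw=w_raw
    )


# ---------------------------------------------------------------------------
# plain-text interfaces

_FIELD_ALIASES = {
    "k": "expert_variance_scale",
    "coverage": "expert_coverage",
    "m": "misidentification",
    "p": "detection",
    "omega": "occupancy",
    "total": "total_abundance",
}
_INT_FIELDS = {"n_sites", "n_replicates", "total_abundance", "n_simulations", "seed"}


def read_scenario_file(path: str | Path) -> list[ScenarioConfig]:
    """Read a scenario grid from a ``key: value`` plain-text file.

    Comma-separated values denote a swept parameter; the cartesian product
    of all sweeps is returned.  Short aliases (k, coverage, m, p, omega,
    total) are accepted alongside the full field names.
    """
    entries: dict[str, list] = {}
    for raw in Path(path).read_text().splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if ":" not in line:
            raise ValueError(f"expected 'key: value', got {raw!r}")
        key, val = (s.strip() for s in line.split(":", 1))
        key = _FIELD_ALIASES.get(key, key)
        if key not in ScenarioConfig.__dataclass_fields__:
            raise ValueError(f"unknown scenario parameter {key!r}")
        cast = int if key in _INT_FIELDS else float
        entries[key] = [cast(float(v)) for v in val.split(",")]
    configs = [ScenarioConfig()]
    for key, values in entries.items():
        configs = [replace(c, **{key: v}) for c in configs for v in values]
    return configs


def write_dataset(dataset: SimulatedDataset, outdir: str | Path) -> None:
    """Archive a dataset as three delimited-text tables (y, w+mask, truth)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        dataset.y, columns=[f"rep{j}" for j in range(dataset.y.shape[1])]
    ).rename_axis("site").to_csv(outdir / "y.csv")
    pd.DataFrame(
        {"w": dataset.w, "expert_mask": dataset.expert_mask.astype(int)}
    ).rename_axis("site").to_csv(outdir / "w.csv")
    pd.DataFrame(
        {"z": dataset.truth.z, "N": dataset.truth.N}
    ).rename_axis("site").to_csv(outdir / "truth.csv")
    cfg = dataset.config
    lines = [
        f"{name}: {getattr(cfg, name)}" for name in cfg.__dataclass_fields__
    ]
    (outdir / "config.txt").write_text("\n".join(lines) + "\n")


def read_dataset(indir: str | Path) -> SimulatedDataset:
    """Inverse of :func:`write_dataset`."""
    indir = Path(indir)
    y = pd.read_csv(indir / "y.csv", index_col="site").to_numpy(dtype=np.int64)
    wtab = pd.read_csv(indir / "w.csv", index_col="site")
    truth_tab = pd.read_csv(indir / "truth.csv", index_col="site")
    cfgs = read_scenario_file(indir / "config.txt")
    config = cfgs[0]
    truth = TrueState(
        z=truth_tab["z"].to_numpy(np.int64),
        N=truth_tab["N"].to_numpy(np.int64),
        omega=config.occupancy,
        total=int(truth_tab["N"].sum()),
    )
    return SimulatedDataset(
        y=y,
        w=wtab["w"].to_numpy(float),
        expert_mask=wtab["expert_mask"].to_numpy(bool),
        truth=truth,
        config=config,
    )
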