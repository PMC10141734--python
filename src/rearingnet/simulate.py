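"""Generative model for synthetic rearing surveys.

The generator emulates the statistical structure a market rearing
survey produces, so every pipeline stage can be tested, calibrated and
power-checked without field data:

* a fly pool whose relative abundances are iid draws from a log-series
  distribution (the classic dominance-skewed abundance model: a few
  dominant species against many rare ones), with the log-series
  parameter derived from a Fisher alpha and the species count via
  N = alpha (e^{S/alpha} - 1), x = N / (N + alpha);
* geographic origins assigned by independent Bernoulli draws, for flies
  and hosts separately;
* a binary fly x host *compatibility* matrix drawn per origin-class
  pair with probabilities (p_NN, p_NE, p_EN, p_EE) -- the quantity the
  occupancy analysis estimates;
* sample units with lognormal masses assigned uniformly to hosts, and
  per-sample emergence counts for compatible pairs drawn from a
  negative binomial with mean mass x density_per_g x relative
  abundance and dispersion (size) ``nb_dispersion``; incompatible pairs
  never produce flies.

Emergence and detection are deliberately collapsed into ``density_per_g``:
the survey design only ever observes emergences.  Note the practical
consequence: observed occupancy estimates compatibility only once
sampling is deep enough that every compatible pair has near-certain
detection; calibration experiments should therefore use a generous
density (see :mod:`docs/methods`).

All randomness flows from one integer seed through fixed named
substreams, so identical (config, seed) pairs give byte-identical
datasets.
"""
from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats as sps

from .errors import ConfigError
from .network import build_matrix
from .niche import CELL_ORDER, OccupancyTable, occupancy_gof, occupancy_table
from .records import (EmergenceRecord, FlySpecies, Origin, PlantTaxon,
                      RearingDataset, ResourceType, SampleUnit)

_SUBSTREAMS = {"community": 0, "compat": 1, "samples": 2, "counts": 3}


@dataclass(frozen=True)
class CompatProbs:
    """Per-origin-class probabilities that a fly-host pair is compatible."""

    p_nn: float = 0.15
    p_ne: float = 0.10
    p_en: float = 0.20
    p_ee: float = 0.25

    def for_pair(self, fly_origin: str, host_origin: str) -> float:
        return {("N", "N"): self.p_nn, ("N", "E"): self.p_ne,
                ("E", "N"): self.p_en, ("E", "E"): self.p_ee}[(fly_origin, host_origin)]

    def as_tuple(self) -> tuple[float, float, float, float]:
        return (self.p_nn, self.p_ne, self.p_en, self.p_ee)


@dataclass
class SimulationConfig:
    """Generative settings, defaulting to the scale of the study system:

    16 fly species (10 exotic) x 49 origin-classed host taxa (28
    exotic), two collection periods of 300 sample units each, strongly
    dominance-skewed abundances (Fisher alpha 2), lognormal sample
    masses around 200 g, and overdispersed per-sample emergence counts.
    """

    n_fly_species: int = 16
    n_host_taxa: int = 49
    exotic_fraction_flies: float = 10 / 16
    exotic_fraction_hosts: float = 28 / 49
    fisher_alpha: float = 2.0
    compat: CompatProbs = field(default_factory=CompatProbs)
    mass_log_mean: float = 4.8   # lognormal mu, grams scale
    mass_log_sd: float = 1.0
    density_per_g: float = 2.0   # expected emergences / g for a compatible pair
    nb_dispersion: float = 0.5   # negative-binomial size; smaller = more dispersed
    samples_per_period: int = 300
    periods: tuple[str, ...] = ("2007-2008", "2018-2019")
    fleshy_fruit_fraction: float = 39 / 50

    def validate(self) -> None:
        if self.n_fly_species < 1 or self.n_host_taxa < 1:
            raise ConfigError("need at least one fly species and one host taxon")
        for name in ("exotic_fraction_flies", "exotic_fraction_hosts",
                     "fleshy_fruit_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1], got {v}")
        for p in self.compat.as_tuple():
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"compatibility probabilities must be in [0, 1], got {p}")
        for name in ("fisher_alpha", "mass_log_sd", "density_per_g", "nb_dispersion"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        if self.samples_per_period < 1 or len(self.periods) < 1:
            raise ConfigError("need at least one period with at least one sample")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "compat" in raw:
            raw["compat"] = CompatProbs(**raw["compat"])
        if "periods" in raw:
            raw["periods"] = tuple(raw["periods"])
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        d["periods"] = list(self.periods)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)


@dataclass
class TrueParams:
    """Realized generative state backing one synthetic dataset."""

    compat: pd.DataFrame            # binary fly x host compatibility
    rel_abundance: pd.Series        # per fly species, sums to 1
    fly_origins: pd.Series
    host_origins: pd.Series
    expected_rate_per_g: pd.DataFrame  # density x rel_abundance x compat

    def class_compat_proportions(self) -> dict[tuple[str, str], float]:
        """Realized compatible fraction per origin class (NaN if empty)."""
        out = {}
        for fo, ho in CELL_ORDER:
            rows = self.fly_origins[self.fly_origins == fo].index
            cols = self.host_origins[self.host_origins == ho].index
            block = self.compat.loc[rows, cols]
            out[(fo, ho)] = float(block.to_numpy().mean()) if block.size else float("nan")
        return out


def _rngs(seed: int) -> dict[str, np.random.Generator]:
    children = np.random.SeedSequence(seed).spawn(len(_SUBSTREAMS))
    return {name: np.random.default_rng(children[i])
            for name, i in _SUBSTREAMS.items()}


def _logseries_x(alpha: float, s: int) -> float:
    """Log-series parameter from Fisher alpha and species count."""
    ratio = s / alpha
    if ratio > 500:  # expm1 overflows; x is 1 to machine precision anyway
        return 1.0 - 1e-12
    n = alpha * np.expm1(ratio)
    return min(n / (n + alpha), 1.0 - 1e-12)


def sample_community(cfg: SimulationConfig, seed: int
                     ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw the fly pool (with relative abundances) and the host pool."""
    cfg.validate()
    rng = _rngs(seed)["community"]
    s = cfg.n_fly_species
    x = _logseries_x(cfg.fisher_alpha, s)
    counts = sps.logser.rvs(x, size=s, random_state=rng).astype(float)
    rel = counts / counts.sum()
    fly_origin = np.where(rng.random(s) < cfg.exotic_fraction_flies, "E", "N")
    flies = pd.DataFrame({
        "code": [f"F{i + 1:02d}" for i in range(s)],
        "origin": fly_origin,
        "relative_abundance": rel,
    }).set_index("code")

    h = cfg.n_host_taxa
    host_origin = np.where(rng.random(h) < cfg.exotic_fraction_hosts, "E", "N")
    other_types = [rt.value for rt in ResourceType if rt is not ResourceType.FLESHY_FRUIT]
    rtypes = np.where(rng.random(h) < cfg.fleshy_fruit_fraction, "FF",
                      rng.choice(other_types, size=h))
    hosts = pd.DataFrame({
        "code": [f"H{j + 1:02d}" for j in range(h)],
        "origin": host_origin,
        "resource_type": rtypes,
    }).set_index("code")
    return flies, hosts


def generate_dataset(cfg: SimulationConfig, seed: int
                     ) -> tuple[RearingDataset, TrueParams]:
    """Generate one synthetic survey plus its true generative state."""
    cfg.validate()
    rng = _rngs(seed)
    flies, hosts = sample_community(cfg, seed)
    s, h = len(flies), len(hosts)

    p_pair = np.array([[cfg.compat.for_pair(fo, ho) for ho in hosts["origin"]]
                       for fo in flies["origin"]])
    compat = (rng["compat"].random((s, h)) < p_pair).astype(int)

    n_samples = cfg.samples_per_period * len(cfg.periods)
    host_idx = rng["samples"].integers(0, h, size=n_samples)
    mass = rng["samples"].lognormal(cfg.mass_log_mean, cfg.mass_log_sd, size=n_samples)

    rel = flies["relative_abundance"].to_numpy()
    mu = mass[:, None] * cfg.density_per_g * rel[None, :] * compat.T[host_idx, :]
    k = cfg.nb_dispersion
    counts = np.zeros_like(mu, dtype=int)
    nz = mu > 0
    counts[nz] = rng["counts"].negative_binomial(k, k / (k + mu[nz]))

    n_fam = max(1, h // 2)  # paired taxa per synthetic family
    taxa = [PlantTaxon(code=c, scientific_name=f"Hostplant sp. {j + 1}",
                       family=f"Hostfam{(j % n_fam) + 1:02d}",
                       origin=Origin(hosts["origin"].iloc[j]),
                       resource_type=ResourceType(hosts["resource_type"].iloc[j]))
            for j, c in enumerate(hosts.index)]
    species = [FlySpecies(code=c, name=f"Drosophilid sp. {i + 1}",
                          origin=Origin(flies["origin"].iloc[i]))
               for i, c in enumerate(flies.index)]
    samples = [SampleUnit(sample_id=f"S{j + 1:05d}",
                          period=cfg.periods[j // cfg.samples_per_period],
                          taxon_code=hosts.index[host_idx[j]],
                          mass_g=float(mass[j]))
               for j in range(n_samples)]
    emerg = [EmergenceRecord(sample_id=f"S{j + 1:05d}",
                             fly_code=flies.index[i], count=int(counts[j, i]))
             for j, i in zip(*np.nonzero(counts))]

    ds = RearingDataset(taxa, species, samples, emerg)
    tp = TrueParams(
        compat=pd.DataFrame(compat, index=flies.index, columns=hosts.index),
        rel_abundance=flies["relative_abundance"],
        fly_origins=flies["origin"],
        host_origins=hosts["origin"],
        expected_rate_per_g=pd.DataFrame(
            cfg.density_per_g * rel[:, None] * compat,
            index=flies.index, columns=hosts.index),
    )
    return ds, tp


@dataclass
class RecoveryResult:
    """Replicated end-to-end occupancy estimation and GOF testing."""

    replicates: pd.DataFrame  # per rep: chi2, p_value, reject, occ_* columns
    true_p: dict[tuple[str, str], float]
    alpha: float

    @property
    def rejection_rate(self) -> float:
        r = self.replicates["reject"].dropna()
        return float(r.mean()) if len(r) else float("nan")

    def summary(self) -> pd.DataFrame:
        rows = []
        for fo, ho in CELL_ORDER:
            rows.append(((fo, ho), self.true_p[(fo, ho)],
                         float(self.replicates[f"occ_{fo}{ho}".lower()].mean()),
                         self.rejection_rate))
        return pd.DataFrame(rows, columns=[
            "cell", "true_p", "mean_estimated_occupancy", "rejection_rate"])


def recovery_experiment(cfg: SimulationConfig, n_reps: int, seed: int,
                        alpha: float = 0.05) -> RecoveryResult:
    """Generate -> tabulate -> test, ``n_reps`` times.

    Each replicate runs the full pipeline (dataset generation,
    interaction-matrix construction, occupancy table, count-scale GOF)
    on an independent substream of ``seed``.  Replicates whose random
    origin assignment empties one origin class are recorded with NaN
    results and excluded from the rejection rate.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    cfg.validate()
    rep_seeds = np.random.default_rng(seed).integers(0, 2**31 - 1, size=n_reps)
    rows = []
    for r in range(n_reps):
        ds, _ = generate_dataset(cfg, int(rep_seeds[r]))
        m = build_matrix(ds)
        t = occupancy_table(m, ds.taxa, ds.species)
        occ = {f"occ_{fo}{ho}".lower(): (row.observed / row.possible
                                         if row.possible > 0 else np.nan)
               for (fo, ho), row in zip(CELL_ORDER, t.cells.itertuples(index=False))}
        if (t.cells["possible"] > 0).all() and t.cells["observed"].sum() > 0:
            g = occupancy_gof(t, scale="count")
            chi2, p, reject = g.chi2, g.p_value, float(g.p_value < alpha)
        else:
            chi2 = p = reject = np.nan
        rows.append({"rep": r, "seed": int(rep_seeds[r]), "chi2": chi2,
                     "p_value": p, "reject": reject, **occ})
    true_p = {pair: cfg.compat.for_pair(*pair) for pair in CELL_ORDER}
    return RecoveryResult(pd.DataFrame(rows), true_p, alpha)
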