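"""Synthetic genotype landscapes with known ground truth.

The generator emulates the study system the pipeline targets: a
fragmented montane tree with three divergent lineages (West, East,
South) and two admixed groups (Wmix = West x South, Emix = East x
South), sampled at a handful of sites scattered over a regular climate
grid.  Pure-lineage allele frequencies follow a Balding-Nichols-style
hierarchical drift model tuned to a target F_ST; a minority of loci
carry logistic allele-frequency clines in one climate variable each;
declared chromosome windows are introgressed wholesale from a donor
lineage into the admixed groups.  Every planted feature is recorded in
a :class:`GroundTruth` object so downstream methods can be scored
against it.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .climate import ClimateStack
from .genotypes import MISSING, GenotypeMatrix

__all__ = ["SimConfig", "GroundTruth", "make_landscape", "simulate_genotypes"]

PURE_GROUPS = ("West", "East", "South")
ADMIXED_PARENTS = {"Wmix": ("West", "South"), "Emix": ("East", "South")}

# fractional (row, col) group centres: west/east flanks, south centre,
# admixed groups between their parents
_GROUP_CENTRES = {
    "West": (0.35, 0.15),
    "East": (0.35, 0.85),
    "South": (0.80, 0.50),
    "Wmix": (0.55, 0.30),
    "Emix": (0.55, 0.68),
}
# deterministic within-group site offsets (fractions of the grid);
# sites of one group scatter over a sizeable climate span, as sampled
# populations of one lineage do across a mountain range
_SITE_OFFSETS = [(0.0, 0.0), (0.13, 0.10), (-0.13, -0.10), (0.10, -0.14),
                 (-0.10, 0.14), (0.17, 0.0)]

_CLIMATE_SCALES = {
    # name: (baseline, east-west span, north-south span, wiggle amplitude)
    "bio1": (14.0, 6.0, -4.0, 1.0),
    "bio2": (8.0, -1.5, 1.0, 0.5),
    "bio7": (28.0, 5.0, -3.0, 1.5),
    "bio12": (1100.0, -450.0, 220.0, 80.0),
    "bio18": (560.0, -260.0, 120.0, 50.0),
}
_DEFAULT_SHIFT = {"bio1": 3.2, "bio2": 0.3, "bio7": 1.5,
                  "bio12": -60.0, "bio18": -40.0}


@dataclass
class SimConfig:
    """Study-design parameters for one synthetic dataset.

    ``intro_windows`` entries are ``(chrom, start, end, donor)`` or
    ``(chrom, start, end, donor, recipient_group)`` with 0-based
    *within-chromosome* locus indices, both endpoints inclusive.  A
    4-tuple window applies to every admixed group whose donor parent
    matches.
    """

    seed: int = 0
    n_per_group: int = 10
    n_neutral: int = 900
    n_adaptive: int = 100
    admix_alpha: float = 0.3
    fst_target: float = 0.3
    intro_windows: list[tuple] = field(default_factory=list)
    missing_rate: float = 0.1
    grid_shape: tuple[int, int] = (24, 36)
    climate_shift: dict[str, float] | float = field(
        default_factory=lambda: dict(_DEFAULT_SHIFT))
    climate_vars: list[str] = field(
        default_factory=lambda: list(_CLIMATE_SCALES))
    pops_per_group: dict[str, int] = field(default_factory=lambda: {
        "West": 4, "East": 5, "South": 3, "Wmix": 2, "Emix": 4})
    n_chrom: int = 5
    cline_slope: float = 3.0
    window_contrast: float | None = None
    lon_range: tuple[float, float] = (100.0, 112.0)
    lat_range: tuple[float, float] = (26.0, 34.0)

    def validate(self) -> None:
        if not 0.0 <= self.admix_alpha <= 1.0:
            raise ValueError("admix_alpha must be in [0, 1]")
        if not 0.0 < self.fst_target < 1.0:
            raise ValueError("fst_target must be in the open interval (0, 1)")
        if not 0.0 <= self.missing_rate <= 0.4:
            raise ValueError("missing_rate must be in [0, 0.4]")
        if self.grid_shape[0] <= 0 or self.grid_shape[1] <= 0:
            raise ValueError("grid_shape dimensions must be positive")
        if len(self.climate_vars) < 2:
            raise ValueError("at least 2 climate variables are required")
        if self.n_neutral + self.n_adaptive < 50:
            raise ValueError("need at least 50 loci in total")
        sizes = self._chrom_sizes()
        for w in self.intro_windows:
            chrom, start, end, donor = w[0], w[1], w[2], w[3]
            if chrom not in sizes:
                raise ValueError(f"unknown chromosome in window: {chrom}")
            if not (0 <= start <= end < sizes[chrom]):
                raise ValueError(f"window indices out of range: {w}")
            if donor not in PURE_GROUPS:
                raise ValueError(f"unknown donor lineage: {donor}")

    def _chrom_sizes(self) -> dict[str, int]:
        n_loci = self.n_neutral + self.n_adaptive
        base, extra = divmod(n_loci, self.n_chrom)
        return {f"chr{i + 1}": base + (1 if i < extra else 0)
                for i in range(self.n_chrom)}

    @property
    def groups(self) -> list[str]:
        return list(self.pops_per_group)


@dataclass
class GroundTruth:
    """Planted structure recorded by :func:`simulate_genotypes`."""

    adaptive_locus_ids: list[int]
    driver_variable: dict[int, str]
    cline_slope: dict[int, float]
    introgressed_locus_ids: dict[str, list[int]]
    group_assignments: dict[str, str]
    ancestral_frequencies: list[float]
    population_sites: dict[str, tuple[float, float]]
    expected_group_freqs: dict[str, list[float]]

    def to_json(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        Path(path).write_text(json.dumps(d))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        d = json.loads(Path(path).read_text())
        d["driver_variable"] = {int(k): v for k, v in d["driver_variable"].items()}
        d["cline_slope"] = {int(k): v for k, v in d["cline_slope"].items()}
        d["population_sites"] = {k: tuple(v) for k, v in
                                 d["population_sites"].items()}
        return cls(**d)


# ---------------------------------------------------------------------------
# landscape


def make_landscape(config: SimConfig) -> tuple[ClimateStack, ClimateStack]:
    """Build paired current/future climate stacks with smooth gradients.

    Each layer is a linear east-west + north-south trend plus a seeded
    sinusoidal wiggle, scaled to plausible bioclim units.  The future
    stack is the current stack plus the per-variable additive
    ``climate_shift``; grid, mask and coordinates are shared.
    """
    config.validate()
    rows, cols = config.grid_shape
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 101]))
    lon = np.linspace(*config.lon_range, cols)
    lat = np.linspace(config.lat_range[1], config.lat_range[0], rows)
    X, Y = np.meshgrid(np.linspace(0, 1, cols), np.linspace(0, 1, rows))

    data = np.empty((len(config.climate_vars), rows, cols))
    for i, name in enumerate(config.climate_vars):
        base, ew, ns, amp = _CLIMATE_SCALES.get(name, (0.0, 1.0, 0.5, 0.2))
        fx, fy = rng.uniform(0.8, 2.2, size=2)
        phase = rng.uniform(0, 2 * np.pi)
        data[i] = (base + ew * (X - 0.5) + ns * (Y - 0.5)
                   + amp * np.sin(2 * np.pi * (fx * X + fy * Y) + phase))
    mask = np.ones((rows, cols), dtype=bool)
    current = ClimateStack(list(config.climate_vars), data, lon, lat, mask)

    shift = config.climate_shift
    future = current.copy()
    for i, name in enumerate(config.climate_vars):
        s = shift if np.isscalar(shift) else shift.get(name, 0.0)
        future.data[i] = future.data[i] + s
    return current, future


# ---------------------------------------------------------------------------
# genotypes


def _logistic(x):
    return 1.0 / (1.0 + np.exp(-x))


def _population_sites(config: SimConfig, stack: ClimateStack):
    """Deterministic site placement: group centre plus fixed offsets."""
    rows, cols = config.grid_shape
    sites, pop_group = {}, {}
    for group, n_pops in config.pops_per_group.items():
        cr, cc = _GROUP_CENTRES[group]
        for p in range(n_pops):
            orow, ocol = _SITE_OFFSETS[p % len(_SITE_OFFSETS)]
            r = int(np.clip(round((cr + orow) * (rows - 1)), 0, rows - 1))
            c = int(np.clip(round((cc + ocol) * (cols - 1)), 0, cols - 1))
            name = f"{group}{p + 1}"
            sites[name] = (float(stack.lon[c]), float(stack.lat[r]))
            pop_group[name] = group
    return sites, pop_group


def _window_locus_ids(config: SimConfig) -> dict[str, dict[int, str]]:
    """Per admixed group: {global locus id: donor} for declared windows."""
    sizes = config._chrom_sizes()
    offsets, off = {}, 0
    for chrom, size in sizes.items():
        offsets[chrom] = off
        off += size
    out: dict[str, dict[int, str]] = {g: {} for g in ADMIXED_PARENTS
                                      if g in config.pops_per_group}
    for w in config.intro_windows:
        chrom, start, end, donor = w[0], w[1], w[2], w[3]
        recipients = ([w[4]] if len(w) > 4 else
                      [g for g, (_, d) in ADMIXED_PARENTS.items() if d == donor])
        ids = range(offsets[chrom] + start, offsets[chrom] + end + 1)
        for g in recipients:
            if g in out:
                out[g].update({i: donor for i in ids})
    return out


def simulate_genotypes(config: SimConfig,
                       current: ClimateStack) -> tuple[GenotypeMatrix, GroundTruth]:
    """Draw genotypes for all groups on the supplied current climate.

    Pure-lineage frequencies: ancestral Beta(0.8, 0.8) draws perturbed
    per lineage by Normal noise of variance p(1-p)*fst_target, truncated
    to (0, 1).  Adaptive loci instead follow logistic clines in their
    driver variable at each sampling site.  Admixed-group frequencies
    are (1-alpha)*recipient + alpha*donor, except inside declared
    introgression windows where they equal the donor lineage's.
    Genotypes are Binomial(2, freq) with uniform missingness.
    """
    config.validate()
    ss = np.random.SeedSequence([config.seed, 202])
    r_freq, r_adapt, r_geno, r_miss = (np.random.default_rng(s)
                                       for s in ss.spawn(4))
    n_loci = config.n_neutral + config.n_adaptive
    sites, pop_group = _population_sites(config, current)
    pop_names = list(sites)

    # environment at sites, z-standardised per variable across sites
    lonlat = np.array([sites[p] for p in pop_names])
    env = current.values_at(lonlat[:, 0], lonlat[:, 1])
    env_z = (env - env.mean(axis=0)) / env.std(axis=0)

    # ancestral frequencies and per-lineage Balding-Nichols drift:
    # p_L ~ Beta(p(1-F)/F, (1-p)(1-F)/F) has mean p and variance
    # F*p*(1-p) exactly, so realised W-C F_ST tracks fst_target
    p_anc = np.clip(r_freq.beta(0.8, 0.8, size=n_loci), 0.02, 0.98)
    F = config.fst_target
    sa, sb = p_anc * (1 - F) / F, (1 - p_anc) * (1 - F) / F
    L_base = {}
    for g in PURE_GROUPS:
        L_base[g] = np.clip(r_freq.beta(sa, sb), 1e-3, 1 - 1e-3)
    L = {g: L_base[g].copy() for g in PURE_GROUPS}

    # adaptive loci: logistic clines in the driver variable, acting on
    # the lineage's drift background (logit-additive), so a zero slope
    # degenerates exactly to a neutral locus; drivers round-robin
    adaptive_ids = np.sort(r_adapt.choice(n_loci, size=config.n_adaptive,
                                          replace=False)) \
        if config.n_adaptive else np.array([], dtype=int)
    drivers = {int(l): config.climate_vars[i % len(config.climate_vars)]
               for i, l in enumerate(adaptive_ids)}
    slopes = {int(l): float(config.cline_slope * r_adapt.choice([-1.0, 1.0]))
              for l in adaptive_ids}
    var_col = {v: i for i, v in enumerate(config.climate_vars)}

    def _logit(p):
        return np.log(p / (1.0 - p))

    # lineage-centre frequencies of adaptive loci (used for admixed-
    # group introgression windows and as the lineage-level reference)
    centre_env = {}
    for g in config.groups:
        cr, cc = _GROUP_CENTRES[g]
        rows, cols = config.grid_shape
        r = int(round(cr * (rows - 1)))
        c = int(round(cc * (cols - 1)))
        e = current.data[:, r, c]
        centre_env[g] = (e - env.mean(axis=0)) / env.std(axis=0)
    for l in adaptive_ids:
        li = int(l)
        col = var_col[drivers[li]]
        for g in PURE_GROUPS:
            L[g][li] = _logistic(_logit(L_base[g][li])
                                 + slopes[li] * centre_env[g][col])

    # introgression windows and optional planted allele-frequency contrast
    window_map = _window_locus_ids(config)
    if config.window_contrast is not None:
        c = config.window_contrast
        for g, loci_map in window_map.items():
            rec, _ = ADMIXED_PARENTS[g]
            for li, donor in loci_map.items():
                L[donor][li] = 0.5 + c / 2.0
                L[rec][li] = 0.5 - c / 2.0

    # per-population expected frequencies
    is_adaptive = np.zeros(n_loci, dtype=bool)
    is_adaptive[adaptive_ids] = True
    F = np.empty((len(pop_names), n_loci))
    for pi, pop in enumerate(pop_names):
        g = pop_group[pop]
        if g in PURE_GROUPS:
            f = L[g].copy()
            base = L_base[g]
        else:
            rec, don = ADMIXED_PARENTS[g]
            a = config.admix_alpha
            f = (1 - a) * L[rec] + a * L[don]
            base = (1 - a) * L_base[rec] + a * L_base[don]
            for li, donor in window_map[g].items():
                f[li] = L[donor][li]
        # adaptive loci track the climate at the sampling site, the
        # cline acting on the group's drift background
        for l in adaptive_ids:
            li = int(l)
            if g not in PURE_GROUPS and li in window_map[g]:
                continue
            col = var_col[drivers[li]]
            f[li] = _logistic(_logit(base[li]) + slopes[li] * env_z[pi, col])
        F[pi] = f

    # individuals: round-robin over the group's populations
    sample_rows, dosage_rows = [], []
    for g in config.groups:
        gpops = [p for p in pop_names if pop_group[p] == g]
        for i in range(config.n_per_group):
            pop = gpops[i % len(gpops)]
            pi = pop_names.index(pop)
            dosage_rows.append(r_geno.binomial(2, F[pi]).astype(np.int8))
            sample_rows.append((f"{g}_{i + 1:03d}", pop, g, *sites[pop]))
    dosages = np.stack(dosage_rows)
    if config.missing_rate > 0:
        miss = r_miss.random(dosages.shape) < config.missing_rate
        dosages[miss] = MISSING

    sizes = config._chrom_sizes()
    chroms = np.concatenate([[c] * s for c, s in sizes.items()])
    pos = np.concatenate([1000 * (np.arange(s) + 1) for s in sizes.values()])
    loci = pd.DataFrame({"chrom": chroms, "pos": pos, "ref": "A", "alt": "T"})
    samples = pd.DataFrame(sample_rows, columns=["sample_id", "population",
                                                 "group", "lon", "lat"])
    G = GenotypeMatrix(dosages, loci, samples)

    # expected *group-level* frequencies (population-size weighted)
    exp_group = {}
    for g in config.groups:
        gi = [i for i, p in enumerate(pop_names) if pop_group[p] == g]
        counts = np.bincount([i % len(gi) for i in range(config.n_per_group)],
                             minlength=len(gi)).astype(float)
        w = counts / counts.sum()
        exp_group[g] = (w @ F[gi]).tolist()

    truth = GroundTruth(
        adaptive_locus_ids=[int(i) for i in adaptive_ids],
        driver_variable=drivers,
        cline_slope=slopes,
        introgressed_locus_ids={g: sorted(m) for g, m in window_map.items()},
        group_assignments=dict(zip(samples["sample_id"], samples["group"])),
        ancestral_frequencies=p_anc.tolist(),
        population_sites=sites,
        expected_group_freqs=exp_group,
    )
    return G, truth
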