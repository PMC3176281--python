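"""Seeded generator of synthetic forests and coring campaigns.

The generator emulates the statistical structure the inverse model assumes
about a censused tropical-forest hectare: a log-series species-abundance
distribution (the standard model for tropical tree communities, with a
long tail of rare species), homogeneous-Poisson stem positions, a
right-skewed diameter distribution (shifted exponential above the census
minimum with a small heavy-tail admixture of large canopy trees), and a
coring campaign whose fragments are multinomial draws from the forward
model's expected composition at each core location.  Because the true
parameters are known, every pipeline stage is testable end to end without
any external data.

All generation is a pure function of the configuration (including its
seed): the stem map and the core dataset use independent child streams of
the seed, so the same forest can be re-cored reproducibly.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import brentq
from scipy.stats import logser

from .datamodel import (CoreDataset, RootFragment, SoilCore, Species, Stem,
                        StemMap)
from .errors import ConfigurationError, DegeneratePointError
from .forward import RootModelParams, contribution_matrix
from .kernels import KernelFamily, KernelParams

log = logging.getLogger(__name__)

#: Background taxon code used for fragments from unmapped sources
#: (emulates e.g. liana roots absent from the stem census).
BACKGROUND_TAXON = "liana-bg1"


def _default_true_params() -> RootModelParams:
    return RootModelParams(beta=1.79, family=KernelFamily.EXPONENTIAL,
                           kernel=KernelParams(alpha=5.0, theta=0.0))


@dataclass
class SyntheticConfig:
    """Generative description of a forest plus a coring campaign.

    Attributes
    ----------
    window
        Plot rectangle ``(x_min, y_min, x_max, y_max)`` in m.
    n_species, expected_stems
        Community size; log-series abundances are calibrated so the
        expected total stem count matches ``expected_stems``.
    abundances
        Explicit per-species abundance vector overriding the log-series.
    dbh_min, dbh_mean, dbh_tail_fraction, dbh_tail_max
        Diameter model: ``dbh_min + Exponential`` with the given mean (cm),
        plus a ``dbh_tail_fraction`` admixture drawn log-uniformly up to
        ``dbh_tail_max`` (large canopy trees).
    true_params
        Forward-model parameters the cores are sampled under.
    core_layout
        ``"grid_offset"`` (cores offset NE from centers of alternate
        square subplots), ``"random"`` (uniform in the window) or
        ``"explicit"`` (use ``core_points``).
    core_spacing, core_offset
        Subplot size (m) and NE offset vector for the grid layout; the
        default offset (2, 2) is 2.83 m toward the north-east.
    n_cores
        Core count for the random layout.
    fragments_per_core
        ``(lo, hi)`` for a uniform integer draw, or a single int for a
        fixed count.
    mass_log_mu, mass_log_sigma
        Lognormal per-fragment dry-mass model (g); defaults give a median
        of 0.02 g with most mass in 0.001-0.1 g, the range typically
        subsampled for DNA extraction.
    background_fraction
        Fraction of fragments assigned to an out-of-map taxon
        (:data:`BACKGROUND_TAXON`), exercising the background pathway.
    seed
        Master seed; child streams derive from it.
    """

    window: tuple[float, float, float, float] = (0.0, 0.0, 100.0, 100.0)
    n_species: int = 160
    expected_stems: float = 4023.0
    abundances: Sequence[int] | None = None
    dbh_min: float = 1.0
    dbh_mean: float = 5.0
    dbh_tail_fraction: float = 0.02
    dbh_tail_max: float = 200.0
    true_params: RootModelParams = field(default_factory=_default_true_params)
    core_layout: str = "grid_offset"
    core_points: Sequence[tuple[float, float]] | None = None
    core_spacing: float = 20.0
    core_offset: tuple[float, float] = (2.0, 2.0)
    n_cores: int = 13
    fragments_per_core: tuple[int, int] | int = (3, 22)
    mass_log_mu: float = math.log(0.02)
    mass_log_sigma: float = 1.0
    background_fraction: float = 0.1
    seed: int = 0

    def __post_init__(self):
        x0, y0, x1, y1 = self.window
        if not (x1 > x0 and y1 > y0):
            raise ConfigurationError("degenerate window")
        if self.n_species < 1:
            raise ConfigurationError("n_species must be >= 1")
        if not 0 <= self.background_fraction < 1:
            raise ConfigurationError("background_fraction must be in [0, 1)")
        if self.core_layout not in ("grid_offset", "random", "explicit"):
            raise ConfigurationError(
                f"unknown core_layout {self.core_layout!r}")


def logseries_parameter(mean_abundance: float) -> float:
    """Log-series parameter p giving the requested mean per-species
    abundance (mean = -p / ((1-p) log(1-p)))."""
    if mean_abundance <= 1:
        raise ConfigurationError("mean abundance must exceed 1")

    def gap(p):
        return -p / ((1 - p) * math.log1p(-p)) - mean_abundance

    return brentq(gap, 1e-9, 1 - 1e-12, xtol=1e-14)


def species_code(i: int) -> str:
    return f"sp{i + 1:03d}"


def _species_registry(config: SyntheticConfig) -> dict[str, Species]:
    out = {}
    for i in range(config.n_species):
        code = species_code(i)
        out[code] = Species(code=code, name=f"Synthetic species {i + 1}",
                            genus="", family=f"Family{(i % 25) + 1:02d}",
                            guild="tree")
    out[BACKGROUND_TAXON] = Species(
        code=BACKGROUND_TAXON, name="Unmapped liana-like taxon",
        genus="", family="FamilyBG", guild="liana")
    return out


def gen_stem_map(config: SyntheticConfig) -> StemMap:
    """Generate the mapped stand: abundances, positions, diameters.

    Abundances come from the (calibrated) log-series unless given
    explicitly; positions are homogeneous Poisson in the window; diameters
    are i.i.d. from the mixture model.  Reproducible from the seed.
    """
    rng = np.random.default_rng([config.seed, 0])
    if config.abundances is not None:
        counts = np.asarray(config.abundances, dtype=int)
        if len(counts) != config.n_species:
            raise ConfigurationError("abundance vector length != n_species")
    else:
        p = logseries_parameter(config.expected_stems / config.n_species)
        counts = logser.rvs(p, size=config.n_species, random_state=rng)
    x0, y0, x1, y1 = config.window
    stems = []
    k = 0
    for i, n in enumerate(counts):
        code = species_code(i)
        xs = rng.uniform(x0, x1, size=n)
        ys = rng.uniform(y0, y1, size=n)
        tail = rng.random(n) < config.dbh_tail_fraction
        dbh = config.dbh_min + rng.exponential(
            config.dbh_mean - config.dbh_min, size=n)
        if tail.any():
            lo, hi = math.log(10.0), math.log(config.dbh_tail_max)
            dbh[tail] = np.exp(rng.uniform(lo, hi, size=int(tail.sum())))
        for j in range(n):
            k += 1
            stems.append(Stem(f"s{k:05d}", code, float(xs[j]), float(ys[j]),
                              float(dbh[j])))
    return StemMap(stems, config.window, buffer_available=False,
                   species=_species_registry(config))


def core_positions(config: SyntheticConfig) -> np.ndarray:
    """Core locations for the configured layout."""
    x0, y0, x1, y1 = config.window
    if config.core_layout == "explicit":
        if not config.core_points:
            raise ConfigurationError("explicit layout needs core_points")
        return np.asarray(config.core_points, dtype=float)
    if config.core_layout == "grid_offset":
        s = config.core_spacing
        ox, oy = config.core_offset
        pts = []
        nx = int((x1 - x0) // s)
        ny = int((y1 - y0) // s)
        for i in range(nx):
            for j in range(ny):
                if (i + j) % 2 == 0:
                    pts.append((x0 + (i + 0.5) * s + ox,
                                y0 + (j + 0.5) * s + oy))
        return np.asarray(pts)
    rng = np.random.default_rng([config.seed, 2])
    return np.column_stack([rng.uniform(x0, x1, config.n_cores),
                            rng.uniform(y0, y1, config.n_cores)])


def gen_core_dataset(stem_map: StemMap, config: SyntheticConfig,
                     ) -> CoreDataset:
    """Forward-sample a coring campaign from the stand.

    Each core draws its fragment count, then each fragment's taxon from
    the forward model's expected composition at the core location (with
    ``background_fraction`` routed to the unmapped background taxon) and
    its dry mass from the lognormal model.  Depth intervals alternate
    0-10 / 10-20 cm.  A core at a degenerate point (zero expected mass,
    possible under truncated kernels) is relocated within 1 m, with a log
    note; if that fails its fragments are all background when the
    background is enabled, else an error is raised.
    """
    rng = np.random.default_rng([config.seed, 1])
    pts = core_positions(config)
    taxa = stem_map.species_codes()
    params = config.true_params

    def proportions(points):
        C = contribution_matrix(stem_map, points, params)
        codes = stem_map.arrays["species"]
        S = np.column_stack([C[:, codes == t].sum(axis=1) for t in taxa])
        return S

    S = proportions(pts)
    totals = S.sum(axis=1)
    for i in np.nonzero(totals <= 0)[0]:
        for _ in range(20):
            cand = pts[i] + rng.uniform(-1, 1, size=2)
            s = proportions(cand[None, :])
            if s.sum() > 0:
                log.info("core %d relocated %.2f m off a degenerate point",
                         i, float(np.hypot(*(cand - pts[i]))))
                pts[i], S[i] = cand, s[0]
                break
        else:
            if config.background_fraction <= 0:
                raise DegeneratePointError(
                    f"core at {tuple(pts[i])} has zero expected root mass",
                    point=tuple(pts[i]))
    totals = S.sum(axis=1)

    cores, fragments = [], []
    fpc = config.fragments_per_core
    for i, (px, py) in enumerate(pts):
        cid = f"C{i + 1:03d}"
        n_frag = (int(fpc) if np.isscalar(fpc)
                  else int(rng.integers(fpc[0], fpc[1] + 1)))
        n_bg = (rng.binomial(n_frag, config.background_fraction)
                if config.background_fraction > 0 else 0)
        if totals[i] <= 0:
            n_bg = n_frag  # fully outside every kernel's support
        n_map = n_frag - n_bg
        draws = []
        if n_map > 0:
            p = S[i] / totals[i]
            counts = rng.multinomial(n_map, p)
            for t, c in zip(taxa, counts):
                draws.extend([t] * int(c))
        draws.extend([BACKGROUND_TAXON] * n_bg)
        rng.shuffle(draws)
        masses = np.exp(rng.normal(config.mass_log_mu, config.mass_log_sigma,
                                   size=n_frag))
        seq_fraction = rng.uniform(0.03, 0.25)
        cores.append(SoilCore(cid, float(px), float(py), 0.0625, 20.0,
                              float(masses.sum() / seq_fraction)))
        for j, t in enumerate(draws):
            top, bottom = (0.0, 10.0) if j % 2 == 0 else (10.0, 20.0)
            fragments.append(RootFragment(
                f"{cid}-f{j + 1:02d}", cid, top, bottom, t,
                "species" if t != BACKGROUND_TAXON else "family",
                float(masses[j])))
    return CoreDataset(cores, fragments, depth_filter=20.0,
                       species=stem_map.species)


def make_bci_like_config(seed: int = 0) -> SyntheticConfig:
    """Preset emulating the censused focal hectare: 100 x 100 m window,
    160 species, ~4023 expected stems, 13 cores on the alternate-subplot
    grid offset 2.83 m NE, 3-22 fragments per core."""
    return SyntheticConfig(seed=seed)


def make_recovery_config(seed: int = 0, n_cores: int = 200,
                         fragments_per_core: int = 20) -> SyntheticConfig:
    """Parameter-recovery conditions: the BCI-like stand sampled much more
    intensively (randomly placed cores, fixed fragment count) under a pure
    exponential-kernel truth (alpha = 5 m, theta = 0, beta = 1.79) with no
    unmapped background source."""
    return SyntheticConfig(seed=seed, core_layout="random", n_cores=n_cores,
                           fragments_per_core=fragments_per_core,
                           background_fraction=0.0)
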