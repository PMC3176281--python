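"""Descriptive below-ground statistics.

Per-core taxon richness, species accumulation over cores, distances from
sampling points to the nearest stem at several taxonomic ranks, and the
"equivalent sampling area": the above-ground quadrat area whose expected
species richness matches a below-ground sample's observed richness.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
import numpy as np
import pandas as pd

from .datamodel import CoreDataset, StemMap, filter_by_depth
from .errors import ResolutionError

#: Census minimum stem size (cm dbh) applied in all distance analyses.
MIN_DBH = 1.0


@dataclass(frozen=True)
class RichnessSummary:
    """Per-core distinct-taxon counts and their summary statistics.

    ``sd`` is the n-1 sample standard deviation, and is ``None`` for a
    single core (undefined for n = 1).
    """

    per_core: dict[str, int]
    mean: float
    sd: float | None
    min: int
    max: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"richness": pd.Series(self.per_core)}).rename_axis("core_id")


@dataclass(frozen=True)
class DistanceRecord:
    """Distance from a sampling point to the nearest qualifying stem.

    ``distance`` and ``target_stem_id`` are ``None`` when no stem
    qualifies; ``reason`` then says why.
    """

    core_id: str
    taxon_code: str
    rank_used: str
    distance: float | None
    target_stem_id: str | None
    reason: str = ""

    @property
    def found(self) -> bool:
        return self.distance is not None


def richness_summary(dataset: CoreDataset,
                     depth_cutoff: float | None = None) -> RichnessSummary:
    """Distinct taxa per core (set semantics), optionally after a depth cut.

    Cores emptied by the cut count as richness 0.
    """
    if depth_cutoff is not None:
        dataset = filter_by_depth(dataset, depth_cutoff)
    per_core = {c.core_id: len({f.taxon_code
                                for f in dataset.fragments_for(c.core_id)})
                for c in dataset.cores}
    vals = np.array(list(per_core.values()), dtype=float)
    sd = float(vals.std(ddof=1)) if len(vals) > 1 else None
    return RichnessSummary(per_core=per_core, mean=float(vals.mean()),
                           sd=sd, min=int(vals.min()), max=int(vals.max()))


def _nearest(stem_map: StemMap, point, mask, core_id="", taxon_code="",
             rank_used="species", reason_if_empty="no qualifying stem",
             ) -> DistanceRecord:
    """Nearest stem among ``mask``; ties break to the smallest stem_id."""
    a = stem_map.arrays
    idx = np.nonzero(mask)[0]
    if idx.size == 0:
        return DistanceRecord(core_id, taxon_code, rank_used, None, None,
                              reason=reason_if_empty)
    d = np.hypot(a["x"][idx] - point[0], a["y"][idx] - point[1])
    ids = a["stem_id"][idx]
    order = np.lexsort((ids, d))
    best = order[0]
    return DistanceRecord(core_id, taxon_code, rank_used,
                          float(d[best]), str(ids[best]))


def nearest_conspecific(stem_map: StemMap, point, species_code: str,
                        min_dbh: float = MIN_DBH,
                        core_id: str = "") -> DistanceRecord:
    """Euclidean distance to the nearest stem of ``species_code`` with
    dbh >= ``min_dbh``."""
    a = stem_map.arrays
    mask = (a["species"] == species_code) & (a["dbh"] >= min_dbh)
    return _nearest(stem_map, point, mask, core_id, species_code, "species",
                    f"no {species_code!r} stem with dbh >= {min_dbh}")


def nearest_any_stem(stem_map: StemMap, point, min_dbh: float = MIN_DBH,
                     core_id: str = "") -> DistanceRecord:
    """Distance to the nearest stem of any species (het- or conspecific)."""
    a = stem_map.arrays
    mask = a["dbh"] >= min_dbh
    return _nearest(stem_map, point, mask, core_id, "", "species",
                    f"no stem with dbh >= {min_dbh}")


def nearest_confamilial(stem_map: StemMap, point, family_name: str,
                        min_dbh: float = MIN_DBH,
                        guild_filter: str | None = None,
                        core_id: str = "") -> DistanceRecord:
    """Distance to the nearest stem whose species belongs to
    ``family_name``, optionally restricted to one guild (tree/liana).

    Requires the stem map to carry a species registry; an unknown family
    raises :class:`~rootkern.errors.ResolutionError`.
    """
    if not stem_map.species:
        raise ResolutionError("stem map has no species registry for "
                              "family lookups")
    fam_codes = {c for c, sp in stem_map.species.items()
                 if sp.family == family_name
                 and (guild_filter is None or sp.guild == guild_filter)}
    known_families = {sp.family for sp in stem_map.species.values()
                      if sp.family}
    if family_name not in known_families:
        raise ResolutionError(f"unknown family {family_name!r}")
    a = stem_map.arrays
    mask = np.isin(a["species"], list(fam_codes)) & (a["dbh"] >= min_dbh)
    reason = (f"no {family_name} stem"
              + (f" of guild {guild_filter!r}" if guild_filter else "")
              + f" with dbh >= {min_dbh}")
    return _nearest(stem_map, point, mask, core_id, family_name, "family",
                    reason)


def core_distance_records(dataset: CoreDataset, stem_map: StemMap,
                          min_dbh: float = MIN_DBH,
                          depth_cutoff: float | None = None,
                          ) -> list[DistanceRecord]:
    """Nearest-conspecific distance for every distinct (core, taxon) pair.

    Multiple fragments of the same taxon within a core yield one record
    (the core location stands for every fragment in it).
    """
    if depth_cutoff is not None:
        dataset = filter_by_depth(dataset, depth_cutoff)
    out = []
    for core in dataset.cores:
        taxa = sorted({f.taxon_code for f in dataset.fragments_for(core.core_id)})
        for t in taxa:
            out.append(nearest_conspecific(stem_map, (core.x, core.y), t,
                                           min_dbh, core_id=core.core_id))
    return out


def species_accumulation(dataset: CoreDataset, n_permutations: int = 100,
                         seed: int = 0) -> pd.DataFrame:
    """Mean cumulative richness over seeded random orderings of cores.

    Returns a two-column frame (``n_cores``, ``mean_richness``); the curve
    is nondecreasing and its endpoint equals the total distinct-taxon count
    regardless of permutation.
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    rng = np.random.default_rng(seed)
    core_taxa = [frozenset(f.taxon_code
                           for f in dataset.fragments_for(c.core_id))
                 for c in dataset.cores]
    n = len(core_taxa)
    acc = np.zeros(n)
    for _ in range(n_permutations):
        order = rng.permutation(n)
        seen: set = set()
        for k, i in enumerate(order):
            seen |= core_taxa[i]
            acc[k] += len(seen)
    return pd.DataFrame({"n_cores": np.arange(1, n + 1),
                         "mean_richness": acc / n_permutations})


def total_cross_sectional_area(dataset: CoreDataset) -> float:
    """Summed core cross-sectional area in m^2."""
    return sum(c.cross_section_area for c in dataset.cores)


# ---------------------------------------------------------------------------
# equivalent sampling area


@dataclass(frozen=True)
class EquivalentAreaResult:
    """Outcome of the equivalent-sampling-area search.

    ``area`` is the quadrat area (m^2) whose Monte-Carlo mean richness
    matches the target, or ``None`` when the target is unreachable within
    the area bounds (``status`` then reports which boundary was hit and the
    mean richness there).
    """

    area: float | None
    status: str
    mean_richness: float
    target: float


def mean_quadrat_richness(points: np.ndarray, species: np.ndarray,
                          area: float, window, n_mc: int,
                          rng: np.random.Generator,
                          shape: str = "square") -> float:
    """Monte-Carlo mean species richness of randomly placed quadrats.

    Quadrats are axis-aligned squares (or circles) of the given area placed
    uniformly so that they lie fully inside the window.
    """
    x0, y0, x1, y1 = window
    if shape == "square":
        side = math.sqrt(area)
        if side > min(x1 - x0, y1 - y0):
            raise ValueError("quadrat larger than window")
        ox = rng.uniform(x0, x1 - side, size=n_mc)
        oy = rng.uniform(y0, y1 - side, size=n_mc)
        rich = 0
        for k in range(n_mc):
            inside = ((points[:, 0] >= ox[k]) & (points[:, 0] <= ox[k] + side)
                      & (points[:, 1] >= oy[k]) & (points[:, 1] <= oy[k] + side))
            rich += len(set(species[inside]))
        return rich / n_mc
    if shape == "circle":
        rad = math.sqrt(area / math.pi)
        if 2 * rad > min(x1 - x0, y1 - y0):
            raise ValueError("quadrat larger than window")
        ox = rng.uniform(x0 + rad, x1 - rad, size=n_mc)
        oy = rng.uniform(y0 + rad, y1 - rad, size=n_mc)
        rich = 0
        for k in range(n_mc):
            inside = np.hypot(points[:, 0] - ox[k],
                              points[:, 1] - oy[k]) <= rad
            rich += len(set(species[inside]))
        return rich / n_mc
    raise ValueError(f"unknown quadrat shape {shape!r}")


def equivalent_sampling_area(points_with_species, target_richness: float,
                             window, n_mc: int = 400, seed: int = 0,
                             area_bounds: tuple[float, float] = (0.01, 1e4),
                             rtol: float = 1e-2,
                             shape: str = "square") -> EquivalentAreaResult:
    """Quadrat area whose mean richness equals ``target_richness``.

    Mean quadrat richness is nondecreasing in area (a larger quadrat
    contains a smaller one in expectation), so monotone bisection on
    ``log(area)`` within ``area_bounds`` converges; the mean at each
    candidate area is a fresh Monte-Carlo estimate with ``n_mc`` seeded
    placements.  When the target lies outside the richness range attained
    at the area bounds, a boundary report is returned instead of a number.
    """
    if target_richness < 1:
        raise ValueError("target_richness must be >= 1")
    pts = np.asarray([(p[0], p[1]) for p in points_with_species], dtype=float)
    species = np.asarray([p[2] for p in points_with_species], dtype=object)
    x0, y0, x1, y1 = window
    max_area = min(x1 - x0, y1 - y0) ** 2
    lo, hi = area_bounds
    hi = min(hi, max_area)
    rng = np.random.default_rng(seed)

    def f(area):
        return mean_quadrat_richness(pts, species, area, window, n_mc,
                                     np.random.default_rng(rng.integers(2**31)),
                                     shape)

    f_lo, f_hi = f(lo), f(hi)
    if target_richness <= f_lo:
        return EquivalentAreaResult(None, "lower-bound", f_lo,
                                    target_richness)
    if target_richness >= f_hi:
        return EquivalentAreaResult(None, "upper-bound", f_hi,
                                    target_richness)
    a_lo, a_hi = lo, hi
    mean_mid = f_lo
    while a_hi / a_lo > 1 + rtol:
        mid = math.sqrt(a_lo * a_hi)
        mean_mid = f(mid)
        if mean_mid < target_richness:
            a_lo = mid
        else:
            a_hi = mid
    area = math.sqrt(a_lo * a_hi)
    return EquivalentAreaResult(area, "converged", mean_mid,
                                target_richness)
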