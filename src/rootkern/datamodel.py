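"""Domain types and delimited-text IO for stem maps and soil-core data.

The observational units are (1) a fully mapped stand — every woody stem with
coordinates, species and diameter at breast height (dbh) — and (2) soil
cores whose root fragments have been assigned to taxa (by DNA barcoding or
otherwise), each with an optional dry mass and a depth interval.

Coordinates are plot-local meters, origin at the south-west corner, x east,
y north; all distances are Euclidean.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, ResolutionError, ValidationError

GUILDS = ("tree", "liana", "seedling-only", "unknown")
ASSIGNMENT_RANKS = ("species", "genus", "family", "unassigned")

#: Default column names for the stem table.
STEM_COLUMNS = {
    "stem_id": "stem_id",
    "species": "species",
    "x": "x_m",
    "y": "y_m",
    "dbh": "dbh_cm",
}

CORE_COLUMNS = ("core_id", "x_m", "y_m", "diameter_m", "max_depth_cm",
                "total_root_mass_g")
FRAGMENT_COLUMNS = ("fragment_id", "core_id", "depth_top_cm",
                    "depth_bottom_cm", "taxon", "rank", "mass_g")


@dataclass(frozen=True)
class Species:
    """A taxon that root fragments can be assigned to.

    Higher-rank assignments (e.g. a family-level morphotaxon such as
    "Bignoniaceae sp. 1") are first-class species entries; they carry an
    empty ``genus`` and the family name in ``family``.
    """

    code: str
    name: str
    genus: str = ""
    family: str = ""
    guild: str = "unknown"

    def __post_init__(self):
        if self.guild not in GUILDS:
            raise ValidationError(
                f"species {self.code!r}: unknown guild {self.guild!r}")
        if self.genus and not self.family:
            raise ValidationError(
                f"species {self.code!r}: family required when genus given")


@dataclass(frozen=True)
class Stem:
    """One mapped stem: position in meters, dbh in cm (symbol z)."""

    stem_id: str
    species_code: str
    x: float
    y: float
    dbh: float

    def __post_init__(self):
        if not (math.isfinite(self.x) and math.isfinite(self.y)):
            raise ValidationError(f"stem {self.stem_id!r}: non-finite position")
        if not (self.dbh > 0 and math.isfinite(self.dbh)):
            raise ValidationError(f"stem {self.stem_id!r}: dbh must be > 0")


class StemMap:
    """A collection of mapped stems with rectangular plot bounds.

    Parameters
    ----------
    stems
        Iterable of :class:`Stem`.
    bounds
        ``(x_min, y_min, x_max, y_max)`` in meters; must be non-degenerate
        and contain every stem.
    buffer_available
        True when stems outside the focal analysis window are included, so
        edge corrections are unnecessary.
    species
        Optional mapping ``code -> Species`` used for family/guild lookups.
    """

    def __init__(self, stems: Iterable[Stem],
                 bounds: tuple[float, float, float, float],
                 buffer_available: bool = False,
                 species: Mapping[str, Species] | None = None):
        self.stems: tuple[Stem, ...] = tuple(stems)
        x0, y0, x1, y1 = (float(v) for v in bounds)
        if not (x1 > x0 and y1 > y0):
            raise ValidationError(f"degenerate bounds {bounds!r}")
        self.bounds = (x0, y0, x1, y1)
        self.buffer_available = bool(buffer_available)
        self.species = dict(species) if species else {}
        ids = [s.stem_id for s in self.stems]
        if len(set(ids)) != len(ids):
            raise ValidationError("duplicate stem_id in stem map")
        bad = [s.stem_id for s in self.stems
               if not (x0 <= s.x <= x1 and y0 <= s.y <= y1)]
        if bad:
            raise ValidationError(
                f"{len(bad)} stems outside bounds (first: {bad[0]!r})")
        self._arrays: dict | None = None

    def __len__(self):
        return len(self.stems)

    def __eq__(self, other):
        return (isinstance(other, StemMap)
                and self.stems == other.stems
                and self.bounds == other.bounds
                and self.buffer_available == other.buffer_available)

    @property
    def arrays(self) -> dict:
        """Cached column arrays: ``x``, ``y``, ``dbh`` (float64) and
        ``species`` (object)."""
        if self._arrays is None:
            self._arrays = {
                "x": np.array([s.x for s in self.stems], dtype=float),
                "y": np.array([s.y for s in self.stems], dtype=float),
                "dbh": np.array([s.dbh for s in self.stems], dtype=float),
                "species": np.array([s.species_code for s in self.stems],
                                    dtype=object),
                "stem_id": np.array([s.stem_id for s in self.stems],
                                    dtype=object),
            }
        return self._arrays

    def to_frame(self) -> pd.DataFrame:
        a = self.arrays
        return pd.DataFrame({
            "stem_id": a["stem_id"], "species": a["species"],
            "x_m": a["x"], "y_m": a["y"], "dbh_cm": a["dbh"],
        })

    def species_codes(self) -> list[str]:
        """Sorted distinct species codes present in the map."""
        return sorted(set(s.species_code for s in self.stems))

    def subset(self, keep) -> "StemMap":
        """New StemMap with stems for which ``keep(stem)`` is true."""
        return StemMap([s for s in self.stems if keep(s)], self.bounds,
                       self.buffer_available, self.species)


@dataclass(frozen=True)
class RootFragment:
    """One sequenced root fragment from a soil core.

    ``mass`` is dry mass in g and may be ``None`` (count-based proportions
    are then used downstream).  ``flags`` carries provenance notes such as
    ``"depth-unresolved"`` for fixture fragments whose depth interval is a
    convention rather than a measurement.
    """

    fragment_id: str
    core_id: str
    depth_top: float
    depth_bottom: float
    taxon_code: str
    assignment_rank: str = "species"
    mass: float | None = None
    flags: str = ""

    def __post_init__(self):
        if not (0 <= self.depth_top < self.depth_bottom):
            raise ValidationError(
                f"fragment {self.fragment_id!r}: bad depth interval "
                f"[{self.depth_top}, {self.depth_bottom}]")
        if self.assignment_rank not in ASSIGNMENT_RANKS:
            raise ValidationError(
                f"fragment {self.fragment_id!r}: unknown rank "
                f"{self.assignment_rank!r}")
        if self.mass is not None and not self.mass > 0:
            raise ValidationError(
                f"fragment {self.fragment_id!r}: mass must be > 0 if present")


@dataclass(frozen=True)
class SoilCore:
    """One soil core: position, auger diameter (m), sampled depth (cm) and
    the total dry root mass recovered (g)."""

    core_id: str
    x: float
    y: float
    diameter: float = 0.0625
    max_depth: float = 20.0
    total_root_mass: float = float("nan")

    def __post_init__(self):
        if not self.diameter > 0:
            raise ValidationError(f"core {self.core_id!r}: diameter must be > 0")
        if not self.max_depth > 0:
            raise ValidationError(f"core {self.core_id!r}: max_depth must be > 0")

    @property
    def cross_section_area(self) -> float:
        """Cross-sectional area of the core in m^2."""
        return math.pi * (self.diameter / 2.0) ** 2


class CoreDataset:
    """Soil cores plus their root fragments (the observation side of the
    inverse model)."""

    def __init__(self, cores: Iterable[SoilCore],
                 fragments: Iterable[RootFragment],
                 depth_filter: float = 20.0,
                 species: Mapping[str, Species] | None = None):
        self.cores: tuple[SoilCore, ...] = tuple(cores)
        self.fragments: tuple[RootFragment, ...] = tuple(fragments)
        if not depth_filter > 0:
            raise ValidationError("depth_filter must be > 0")
        self.depth_filter = float(depth_filter)
        self.species = dict(species) if species else {}
        core_ids = [c.core_id for c in self.cores]
        if len(set(core_ids)) != len(core_ids):
            raise ValidationError("duplicate core_id")
        known = set(core_ids)
        for f in self.fragments:
            if f.core_id not in known:
                raise ResolutionError(
                    f"fragment {f.fragment_id!r} references unknown core "
                    f"{f.core_id!r}")

    def __eq__(self, other):
        return (isinstance(other, CoreDataset)
                and self.cores == other.cores
                and self.fragments == other.fragments
                and self.depth_filter == other.depth_filter)

    @property
    def n_cores(self) -> int:
        return len(self.cores)

    @property
    def n_fragments(self) -> int:
        return len(self.fragments)

    def core(self, core_id: str) -> SoilCore:
        for c in self.cores:
            if c.core_id == core_id:
                return c
        raise ResolutionError(f"no core {core_id!r}")

    def fragments_for(self, core_id: str) -> list[RootFragment]:
        return [f for f in self.fragments if f.core_id == core_id]

    def taxa(self) -> list[str]:
        """Sorted distinct taxon codes with at least one fragment."""
        return sorted(set(f.taxon_code for f in self.fragments))

    def counts(self) -> pd.DataFrame:
        """Core x taxon fragment-count matrix (cores as rows)."""
        idx = [c.core_id for c in self.cores]
        cols = self.taxa()
        m = pd.DataFrame(0, index=idx, columns=cols, dtype=int)
        for f in self.fragments:
            m.loc[f.core_id, f.taxon_code] += 1
        return m


def filter_by_depth(dataset: CoreDataset, cutoff: float) -> CoreDataset:
    """Retain only fragments whose ``depth_bottom`` <= ``cutoff`` (cm).

    Cores are kept even when emptied, so core-level metadata (position,
    total mass) survives the filter.  Idempotent and monotone in ``cutoff``.
    """
    if not cutoff > 0:
        raise ConfigurationError("depth cutoff must be > 0")
    kept = [f for f in dataset.fragments if f.depth_bottom <= cutoff]
    return CoreDataset(dataset.cores, kept, depth_filter=dataset.depth_filter,
                       species=dataset.species)


# ---------------------------------------------------------------------------
# Delimited-text readers / writers


def _require_columns(frame: pd.DataFrame, names: Sequence[str], path) -> None:
    missing = [n for n in names if n not in frame.columns]
    if missing:
        raise ConfigurationError(
            f"{path}: missing required column(s) {missing}")


def read_stem_table(path, dialect: Mapping[str, str] | None = None,
                    bounds: tuple[float, float, float, float] | None = None,
                    sep: str = ",") -> StemMap:
    """Read a stem inventory table into a :class:`StemMap`.

    ``dialect`` maps logical names (``stem_id``, ``species``, ``x``, ``y``,
    ``dbh``) to the file's column names; defaults to :data:`STEM_COLUMNS`.
    When ``bounds`` is omitted, the tight bounding box of the stems
    (expanded by 1 mm to stay non-degenerate) is used.

    Rows that fail validation are reported together with their 1-based data
    row numbers.
    """
    cols = dict(STEM_COLUMNS)
    if dialect:
        cols.update(dialect)
    frame = pd.read_csv(path, sep=sep, float_precision="round_trip")
    _require_columns(frame, list(cols.values()), path)
    stems, bad = [], []
    for i, row in enumerate(frame.itertuples(index=False), start=1):
        rec = dict(zip(frame.columns, row))
        try:
            x = float(rec[cols["x"]])
            y = float(rec[cols["y"]])
            dbh = float(rec[cols["dbh"]])
            stems.append(Stem(str(rec[cols["stem_id"]]),
                              str(rec[cols["species"]]), x, y, dbh))
        except (ValueError, TypeError, ValidationError) as exc:
            bad.append((i, str(exc)))
    if bad:
        rows = [r for r, _ in bad]
        raise ValidationError(
            f"{path}: {len(bad)} invalid stem row(s) at data row(s) "
            f"{rows[:10]}{'...' if len(rows) > 10 else ''}; "
            f"first error: {bad[0][1]}", rows=rows)
    if bounds is None:
        xs = [s.x for s in stems]
        ys = [s.y for s in stems]
        bounds = (min(xs) - 1e-3, min(ys) - 1e-3,
                  max(xs) + 1e-3, max(ys) + 1e-3)
    return StemMap(stems, bounds)


def write_stem_table(stem_map: StemMap, path, sep: str = ",") -> None:
    # %.17g guarantees bit-exact float round-trips through the text form
    stem_map.to_frame().to_csv(path, sep=sep, index=False,
                               float_format="%.17g")


def read_core_tables(core_path, fragment_path, sep: str = ",",
                     depth_filter: float = 20.0) -> CoreDataset:
    """Read core and fragment tables into a validated :class:`CoreDataset`.

    An orphan fragment (core_id not present in the core table) raises
    :class:`~rootkern.errors.ResolutionError` naming both ids.
    """
    cores_df = pd.read_csv(core_path, sep=sep,
                           float_precision="round_trip")
    _require_columns(cores_df, CORE_COLUMNS, core_path)
    frags_df = pd.read_csv(fragment_path, sep=sep,
                           float_precision="round_trip")
    _require_columns(frags_df, FRAGMENT_COLUMNS, fragment_path)
    cores = [SoilCore(str(r.core_id), float(r.x_m), float(r.y_m),
                      float(r.diameter_m), float(r.max_depth_cm),
                      float(r.total_root_mass_g))
             for r in cores_df.itertuples(index=False)]
    fragments = []
    for r in frags_df.itertuples(index=False):
        mass = None if pd.isna(r.mass_g) else float(r.mass_g)
        flags = getattr(r, "flags", "")
        fragments.append(RootFragment(
            str(r.fragment_id), str(r.core_id), float(r.depth_top_cm),
            float(r.depth_bottom_cm), str(r.taxon), str(r.rank), mass,
            "" if pd.isna(flags) else str(flags)))
    return CoreDataset(cores, fragments, depth_filter=depth_filter)


def write_core_tables(dataset: CoreDataset, core_path, fragment_path,
                      sep: str = ",") -> None:
    pd.DataFrame(
        [{"core_id": c.core_id, "x_m": c.x, "y_m": c.y,
          "diameter_m": c.diameter, "max_depth_cm": c.max_depth,
          "total_root_mass_g": c.total_root_mass} for c in dataset.cores]
    ).to_csv(core_path, sep=sep, index=False, float_format="%.17g")
    pd.DataFrame(
        [{"fragment_id": f.fragment_id, "core_id": f.core_id,
          "depth_top_cm": f.depth_top, "depth_bottom_cm": f.depth_bottom,
          "taxon": f.taxon_code, "rank": f.assignment_rank,
          "mass_g": f.mass, "flags": f.flags} for f in dataset.fragments]
    ).to_csv(fragment_path, sep=sep, index=False, float_format="%.17g")


def read_species_table(path, sep: str = ",") -> dict[str, Species]:
    frame = pd.read_csv(path, sep=sep).fillna("")
    _require_columns(frame, ("code", "name"), path)
    out = {}
    for r in frame.itertuples(index=False):
        sp = Species(str(r.code), str(r.name), str(getattr(r, "genus", "")),
                     str(getattr(r, "family", "")),
                     str(getattr(r, "guild", "unknown") or "unknown"))
        if sp.code in out:
            raise ValidationError(f"duplicate species code {sp.code!r}")
        out[sp.code] = sp
    return out


def write_species_table(species: Mapping[str, Species], path,
                        sep: str = ",") -> None:
    pd.DataFrame(
        [{"code": s.code, "name": s.name, "genus": s.genus,
          "family": s.family, "guild": s.guild}
         for s in species.values()]
    ).to_csv(path, sep=sep, index=False)
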