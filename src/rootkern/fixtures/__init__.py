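"""Packaged reference dataset: species composition of roots in 12 soil
cores from one fully censused tropical-forest hectare.

The tables mirror a published per-core composition matrix: 32 taxa, 120
sequenced root fragments across cores A-L, with per-core sampled depth,
total dry root mass, and the fraction of that mass that was successfully
sequenced.  Fragment masses were published only as plot-wide per-species
sums, so individual fragments carry no mass and count-based proportions
apply downstream.

Two caveats travel with the fixture:

* Per-fragment depths were not published.  Every fixture fragment is
  assigned the 0-20 cm band and flagged ``depth-unresolved``; depths below
  20 cm exist in four cores (max depth 100-300 cm) but cannot be attributed
  to individual fragments.
* Core coordinates were not published.  The positions shipped in
  ``table1_core_positions_synthetic.csv`` are synthetic stand-ins derived
  from the stated sampling design (centers of alternate 20 x 20 m subplots
  of a 100 x 100 m hectare, offset 2.83 m to the north-east; the 13th
  design location is the core that yielded no sequences).  Use them for
  demonstrations, not for inference about the real stand.
"""

from dataclasses import dataclass
from importlib import resources

import pandas as pd

from ..datamodel import CoreDataset, RootFragment, SoilCore, read_species_table


@dataclass(frozen=True)
class FocalHectareCensus:
    """Published above-ground census summary of the focal hectare.

    These are inputs for ratio statistics (below/above richness, seedling
    density), not outputs of this package.
    """

    n_stems: int = 4023            # trees > 1 cm dbh, focal hectare
    n_tree_species: int = 160      # species among those stems
    n_lianas: int = 1022
    n_liana_species: int = 63
    n_seedlings: int = 1596        # individuals > 20 cm height in plots
    n_seedling_plots: int = 400    # 1 m^2 plots in the hectare
    n_woody_species: int = 235     # unique woody species, all censuses
    n_root_taxa: int = 33          # taxa assigned below ground (the
    #                                printed composition table resolves 32)


FOCAL_HECTARE = FocalHectareCensus()


def _read(name: str) -> pd.DataFrame:
    with resources.files(__package__).joinpath(name).open() as fh:
        return pd.read_csv(fh)


def load_table1_species():
    """Species registry for the fixture taxa (code -> Species)."""
    with resources.files(__package__).joinpath("table1_species.csv").open() as fh:
        return read_species_table(fh)


def load_table1_fixture(with_positions: bool = True) -> CoreDataset:
    """Load the 12-core fixture as a :class:`~rootkern.datamodel.CoreDataset`.

    Each (taxon, core) cell of the composition matrix is expanded into that
    many unit fragments with missing mass, depth band 0-20 cm and flag
    ``depth-unresolved``.  Row and column totals reproduce the printed
    marginals exactly (120 fragments; per-core counts 4,5,10,3,10,12,12,22,
    16,10,9,7; per-core richness 4,4,6,3,1,7,4,9,4,4,6,4).

    When ``with_positions`` is true the synthetic design-derived coordinates
    are attached (see module docstring); otherwise cores sit at (0, 0).
    """
    cores_df = _read("table1_cores.csv")
    counts = _read("table1_counts.csv")
    species = load_table1_species()
    pos = {r.core_id: (float(r.x_m), float(r.y_m))
           for r in _read("table1_core_positions_synthetic.csv").itertuples()}
    cores = []
    for r in cores_df.itertuples(index=False):
        x, y = pos[r.core_id] if with_positions else (0.0, 0.0)
        cores.append(SoilCore(str(r.core_id), x, y, 0.0625,
                              float(r.max_depth_cm),
                              float(r.total_root_mass_g)))
    fragments = []
    for r in counts.itertuples(index=False):
        rank = _SPECIES_RANK[r.taxon_code]
        for k in range(int(r.n_fragments)):
            fragments.append(RootFragment(
                fragment_id=f"{r.core_id}-{r.taxon_code}-{k + 1:02d}",
                core_id=str(r.core_id), depth_top=0.0, depth_bottom=20.0,
                taxon_code=str(r.taxon_code), assignment_rank=rank,
                mass=None, flags="depth-unresolved"))
    ds = CoreDataset(cores, fragments, depth_filter=20.0, species=species)
    _check_marginals(ds, cores_df)  # expansion must reproduce stored marginals
    return ds


def _check_marginals(ds: CoreDataset, cores_df: pd.DataFrame) -> None:
    m = ds.counts()
    for r in cores_df.itertuples(index=False):
        n = int(m.loc[r.core_id].sum())
        rich = int((m.loc[r.core_id] > 0).sum())
        if n != int(r.n_fragments) or rich != int(r.richness):
            raise AssertionError(
                f"fixture marginal mismatch for core {r.core_id}: "
                f"got {n} fragments / {rich} taxa, stored "
                f"{r.n_fragments} / {r.richness}")


def core_marginals() -> pd.DataFrame:
    """The stored per-core marginals (fragments, richness, depth, mass,
    sequenced mass fraction), indexed by core id."""
    return _read("table1_cores.csv").set_index("core_id")


with resources.files(__package__).joinpath("table1_species.csv").open() as _fh:
    _SPECIES_RANK = {r.code: r.rank
                     for r in pd.read_csv(_fh).itertuples(index=False)}
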