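"""Packaged study fixtures: published per-collection statistics.

Three small tables ship with the package, transcribed from the published
survey of *Spea multiplicata* tadpole collections:

* ``load_selection_table`` — per-collection standardized linear (beta) and
  quadratic (gamma) selection differentials with SEs, t and P (the quadratic
  entries already carry the doubling convention).  P-values printed as upper
  bounds ("<.0001") are stored at the bound with ``*_is_bound = True``.
* ``load_ecology_table`` — per-collection sample size, ordinal tadpole and
  fairy-shrimp densities, and fractional vegetative cover.
* ``load_mos_table`` — constrained-regression (Mitchell-Olds & Shaw) F tests
  for an interior fitness extremum, for collections with significant gamma.
* ``load_pond_map`` — best-effort mapping of the 22 collections onto the 15
  unique physical ponds, inferred from the pond naming convention (state
  prefix + trailing two-digit pond number, e.g. AZ0602/AZ0802/AZ0902 are the
  same pond sampled in 2006/2008/2009).  The inferred map reproduces the
  published counts (15 unique ponds, 6 sampled in multiple years) but the
  original assignment is not published, so treat it as unverified.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = [
    "load_selection_table",
    "load_ecology_table",
    "load_mos_table",
    "load_pond_map",
]


def _read(name: str) -> pd.DataFrame:
    with resources.files("selsurf.data").joinpath(name).open("r") as fh:
        return pd.read_csv(fh)


def load_selection_table() -> pd.DataFrame:
    return _read("table1_selection.csv")


def load_ecology_table() -> pd.DataFrame:
    return _read("table2_ecology.csv")


def load_mos_table() -> pd.DataFrame:
    return _read("table4_mos.csv")


def load_pond_map() -> pd.DataFrame:
    return _read("pond_map_inferred.csv")
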