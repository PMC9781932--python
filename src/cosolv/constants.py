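"""Physical constants, fusion properties and bundled fixture accessors."""

from __future__ import annotations

from importlib import resources

R_GAS = 8.31446  # J/(mol K)

#: melting temperature [K] and fusion enthalpy [J/mol] of the two solutes
FUSION_CONSTANTS = {
    "acetaminophen": {"t_m": 442.2, "h_fus": 26900.0},
    "phenacetin": {"t_m": 408.1, "h_fus": 30700.0},
}


def fixture_path(name: str):
    """Path to a bundled data file (``table1.csv``, ``solvents.csv``)."""
    return resources.files("cosolv.data").joinpath(name)


def load_table1():
    """The measured binary-solvent solubility table shipped with the package.

    84 records: acetaminophen in aqueous DMSO, DMF and 4-formylmorpholine
    and phenacetin in aqueous 4-formylmorpholine, each over a solute-free
    composition grid at 25-40 °C.
    """
    from .datasets import read_solubility_table
    return read_solubility_table(fixture_path("table1.csv"))


def load_solvent_meta(ei_threshold: float = 0.5):
    from .datasets import read_solvent_meta
    return read_solvent_meta(fixture_path("solvents.csv"),
                             ei_threshold=ei_threshold)
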