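"""Fallback force-field parameter templates.

The primary source of the four electrostatic channels (AMBER/CHARMM charge
and radius) is a PQR file produced externally (pdb2pqr).  When no PQR is
supplied, the tables below provide per-(residue, atom-name) templates for
protein backbone atoms of the twenty standard amino acids plus the ALA and
GLY side chains.  Atoms not covered resolve to zero with a logged count.

AMBER values follow the ff94/ff14SB backbone convention; CHARMM values
follow the CHARMM36 protein backbone convention.  Radii are vdW radii in Å
as emitted by pdb2pqr for the respective force field.
"""

from __future__ import annotations

_STANDARD_AA = (
    "ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE "
    "LEU LYS MET PHE PRO SER THR TRP TYR VAL"
).split()

# Generic backbone parameters: (amber_charge, amber_radius,
# charmm_charge, charmm_radius).
_BACKBONE = {
    "N": (-0.4157, 1.8240, -0.47, 1.8500),
    "CA": (0.0337, 1.9080, 0.07, 2.2750),
    "C": (0.5973, 1.9080, 0.51, 2.0000),
    "O": (-0.5679, 1.6612, -0.51, 1.7000),
    "OXT": (-0.8055, 1.6612, -0.67, 1.7000),
    "H": (0.2719, 0.6000, 0.31, 0.2245),
    "HA": (0.0823, 1.3870, 0.09, 1.3200),
}

_SIDECHAIN = {
    ("ALA", "CB"): (-0.1825, 1.9080, -0.27, 2.0600),
    ("GLY", "CA"): (-0.0252, 1.9080, -0.02, 2.2750),
}


def _build() -> dict[tuple[str, str], tuple[float, float, float, float]]:
    table: dict[tuple[str, str], tuple[float, float, float, float]] = {}
    for res in _STANDARD_AA:
        for name, vals in _BACKBONE.items():
            table[(res, name)] = vals
    table.update(_SIDECHAIN)
    return table


#: (resname, atom name) -> (amber_charge, amber_radius, charmm_charge, charmm_radius)
FF_TEMPLATE = _build()
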