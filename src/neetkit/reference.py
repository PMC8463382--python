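"""Packaged reference bond tables for the human mNT [2Fe-2S] cluster.

The shipped table holds the published equilibrium bond lengths (R_min,
nm) and bond force constants (K_r, kJ/mol/nm^2, E = K_r (r - R_min)^2
convention) of truncated cluster model 1 built on the mNT structure
2QH7, B3LYP level with the Fe-bound histidine protonated, for both the
oxidized and the reduced state.  It serves as a regression fixture for
the redox comparison report: reduction lengthens and softens the four
iron-ligand-donor bonds (most dramatically Fe_Y-N^His, whose force
constant drops by more than half) and the Fe_Y-bridging-sulfur bonds,
while the Fe_X-bridging-sulfur bonds stiffen.
"""

from importlib.resources import files

import pandas as pd

from .sites import GeometryTable

__all__ = ["load_mnt_b3lyp_protonated", "LIGAND_BONDS", "FEY_BRIDGE_BONDS",
           "FEX_BRIDGE_BONDS"]

LIGAND_BONDS = ["FeX-SCys1", "FeX-SCys2", "FeY-SCys3", "FeY-NHis"]
FEY_BRIDGE_BONDS = ["FeY-S1", "FeY-S2"]
FEX_BRIDGE_BONDS = ["FeX-S1", "FeX-S2"]


def load_mnt_b3lyp_protonated() -> tuple[GeometryTable, GeometryTable]:
    """The (oxidized, reduced) reference bond tables for mNT (2QH7)."""
    path = files("neetkit") / "data" / "fe2s2_mnt_b3lyp_protonated.csv"
    df = pd.read_csv(path)
    ox = df[df.state == "oxidized"].drop(columns="state").reset_index(drop=True)
    red = df[df.state == "reduced"].drop(columns="state").reset_index(drop=True)
    return (GeometryTable(ox, state="oxidized", source="mNT 2QH7 B3LYP protonated"),
            GeometryTable(red, state="reduced", source="mNT 2QH7 B3LYP protonated"))
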