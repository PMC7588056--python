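"""Small packaged reference tables.

``load_assembly_lengths`` returns the published per-species plastid
assembly summary for the 17-taxon *Iris* panel (genome, LSC, IRb, SSC and
IRa lengths in bp for the 15 newly reported assemblies); it is the input
for reproducing the summary-table mean row without re-running an assembly.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = ["load_assembly_lengths"]


def load_assembly_lengths() -> pd.DataFrame:
    with resources.files("plastomarkers.data").joinpath(
        "iris_plastome_assembly_summary.tsv"
    ).open() as fh:
        return pd.read_csv(fh, sep="\t")
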