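"""Reference differential-expression panels and mature sequences.

The bundled TSVs hold the reported significant-miRNA tables for the two EV
compartments of the TDP-43*Q331K vs TDP-43*WT mouse comparison — brain-
derived EVs (BDEV, 24 miRNAs) and serum EVs (7 miRNAs) — in the standard
column layout used throughout this package.  They serve as worked-example
inputs for checking the fold-change convention, the panel filters and the
cross-compartment intersection against reported results.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

COMPARTMENTS = ("bdev", "serum")

#: Mature sequences (miRBase) of the two cross-compartment biomarkers.
MATURE_SEQUENCES = {
    "mmu-miR-122-5p": "UGGAGUGUGACAAUGGUGUUUG",
    "mmu-miR-486a-5p": "UCCUGUACUGAGCUGCCCCGAG",
}


def load_panel_table(compartment: str) -> pd.DataFrame:
    """Load the reported DE table for ``'bdev'`` or ``'serum'``.

    Returns a DataFrame indexed by feature with the standard DE columns
    (total/maximum counts, geometric/arithmetic mean, p-value, FDR step-up,
    ratio, log2 ratio, signed fold change).
    """
    compartment = compartment.lower()
    if compartment not in COMPARTMENTS:
        raise ValueError(f"compartment must be one of {COMPARTMENTS}")
    ref = resources.files("evmir.data") / f"{compartment}_panel.tsv"
    with resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t", index_col="feature")
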