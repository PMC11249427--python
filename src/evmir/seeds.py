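"""miRNA seed-region utilities and exact seed-site scanning of 3'UTRs.

The seed of a mature miRNA is nucleotides 2-8 (1-based, 5'->3').  A
canonical 7mer seed site on a 3'UTR is the exact reverse complement of the
seed read on the UTR plus strand.  Note that papers often print the paired
miRNA "region" in 3'->5' orientation — i.e. the reverse of the seed — so a
printed region pairs with its printed site by straight base-wise
complementation; all functions here operate on 5'->3' strings.

Coordinates are 1-based inclusive on the UTR plus strand.
"""

from __future__ import annotations

from collections.abc import Mapping

import pandas as pd

_DNA_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}
_RNA_COMPLEMENT = {"A": "U", "C": "G", "G": "C", "U": "A", "N": "N"}

SEED_START = 2  # 1-based, inclusive
SEED_END = 8


def _table_for(sequence: str, alphabet: str | None) -> dict[str, str]:
    if alphabet is not None:
        if alphabet not in ("rna", "dna"):
            raise ValueError("alphabet must be 'rna', 'dna' or None")
        return _RNA_COMPLEMENT if alphabet == "rna" else _DNA_COMPLEMENT
    # infer: RNA if it contains U (and no T); default to DNA otherwise
    has_u = "U" in sequence.upper()
    has_t = "T" in sequence.upper()
    if has_u and has_t:
        raise ValueError("sequence mixes U and T")
    return _RNA_COMPLEMENT if has_u else _DNA_COMPLEMENT


def complement(sequence: str, alphabet: str | None = None) -> str:
    """Base-wise Watson-Crick complement (no reversal).

    Accepts RNA or DNA; the output alphabet matches the input, inferred
    from the sequence unless ``alphabet`` ('rna' or 'dna') is given (a
    string with neither U nor T is treated as DNA).  Raises on any
    non-nucleotide character, naming its 1-based position.
    """
    table = _table_for(sequence, alphabet)
    out = []
    for i, base in enumerate(sequence.upper(), start=1):
        try:
            out.append(table[base])
        except KeyError:
            raise ValueError(
                f"non-nucleotide character {base!r} at position {i}"
            ) from None
    return "".join(out)


def reverse_complement(sequence: str, alphabet: str | None = None) -> str:
    """Reverse complement (5'->3' of the opposite strand)."""
    return complement(sequence, alphabet)[::-1]


def extract_seed(mature: str, start: int = SEED_START, end: int = SEED_END) -> str:
    """Seed region of a mature miRNA: positions ``start``-``end`` (1-based,
    inclusive, 5'->3'); the default 2-8 yields the canonical 7-nt seed."""
    if len(mature) < end:
        raise ValueError(
            f"mature sequence of length {len(mature)} is shorter than seed end {end}"
        )
    return mature[start - 1: end]


def find_seed_sites(
    mirnas: Mapping[str, str], utrs: Mapping[str, str]
) -> pd.DataFrame:
    """All exact 7mer seed sites of each miRNA in each UTR.

    A site is an exact occurrence of the reverse complement of the miRNA
    seed (positions 2-8) in the UTR; overlapping occurrences are all
    reported.  Returns a DataFrame with columns (mirna, utr, start,
    site_sequence, site_type), 1-based inclusive start, sorted by
    (mirna, utr, start).
    """
    rows = []
    for mirna_name in sorted(mirnas):
        seed = extract_seed(mirnas[mirna_name])
        site = reverse_complement(seed)
        for utr_name in sorted(utrs):
            utr = utrs[utr_name].upper()
            # normalize both to the UTR's alphabet for matching
            probe = site.upper()
            if "U" in utr and "T" not in utr:
                probe = probe.replace("T", "U")
            else:
                probe = probe.replace("U", "T")
                utr = utr.replace("U", "T")
            start = utr.find(probe)
            while start != -1:
                rows.append(
                    {
                        "mirna": mirna_name,
                        "utr": utr_name,
                        "start": start + 1,
                        "site_sequence": site,
                        "site_type": "7mer",
                    }
                )
                start = utr.find(probe, start + 1)  # allow overlaps
    return pd.DataFrame(
        rows, columns=["mirna", "utr", "start", "site_sequence", "site_type"]
    )


def shared_targets(sites: pd.DataFrame, min_mirnas: int) -> list[str]:
    """UTRs targeted by strictly more than ``min_mirnas`` distinct miRNAs."""
    if sites.empty:
        return []
    counts = sites.groupby("utr")["mirna"].nunique()
    return sorted(counts.index[counts > min_mirnas])
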