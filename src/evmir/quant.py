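"""Adapter trimming and isomiR-tolerant alignment of small-RNA reads.

Reads are assigned to mature miRNAs by an end-variant-aware exact matcher:
a read maps to a mature sequence if, after allowing up to 2 additional
non-templated bases and up to 2 missing bases at each end, the remaining
core matches the reference with at most 2 substitutions.  Additional
terminal bases are unconstrained and never counted as mismatches (without
a genome there is nothing to template them against).  Among candidate
placements the one with the fewest mismatches wins, then the fewest total
end modifications, then the smallest 5' addition; reads tying across
different references are ambiguous and, by default, discarded.
"""

from __future__ import annotations

import logging
from collections.abc import Iterable, Mapping
from dataclasses import dataclass

import pandas as pd

logger = logging.getLogger(__name__)

_STATUSES = ("assigned", "unaligned", "too_short", "ambiguous")


@dataclass(frozen=True)
class AlignmentPolicy:
    """Mapping tolerances (defaults follow standard isomiR criteria)."""

    max_mismatches: int = 2
    max_additional_upstream: int = 2
    max_additional_downstream: int = 2
    max_missing_upstream: int = 2
    max_missing_downstream: int = 2
    min_trimmed_length: int = 15
    ambiguous_policy: str = "discard"  # or "first_by_name"

    def __post_init__(self) -> None:
        for name in (
            "max_mismatches",
            "max_additional_upstream",
            "max_additional_downstream",
            "max_missing_upstream",
            "max_missing_downstream",
            "min_trimmed_length",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.ambiguous_policy not in ("discard", "first_by_name"):
            raise ValueError(f"unknown ambiguous_policy {self.ambiguous_policy!r}")


@dataclass
class ReadAssignment:
    """Outcome of aligning one read."""

    read_id: str
    feature: str | None
    n_mismatches: int | None
    end_variant: tuple[int, int, int, int] | None  # (add5, add3, miss5, miss3)
    status: str

    def __post_init__(self) -> None:
        if self.status not in _STATUSES:
            raise ValueError(f"unknown status {self.status!r}")


def _normalize(seq: str) -> str:
    return seq.upper().replace("U", "T")


# ---------------------------------------------------------------------------
# adapter trimming
# ---------------------------------------------------------------------------

def trim_adapter(
    read: str,
    adapter: str,
    min_overlap: int = 8,
    max_error_rate: float = 0.125,
) -> str:
    """Remove a 3' adapter from a read.

    Scans for the leftmost position where the adapter (or, at the read's
    end, a prefix of it at least ``min_overlap`` long) matches with a
    mismatch fraction of at most ``max_error_rate``; returns the read
    prefix before that position, or the read unchanged if no occurrence
    is found.
    """
    if not adapter:
        raise ValueError("adapter must be non-empty")
    read_n = _normalize(read)
    adapter_n = _normalize(adapter)
    n, m = len(read_n), len(adapter_n)
    for i in range(n):
        overlap = min(m, n - i)
        if overlap < m and overlap < min_overlap:
            break  # remaining suffix too short for a partial match
        mismatches = sum(
            1 for a, b in zip(read_n[i: i + overlap], adapter_n[:overlap]) if a != b
        )
        if mismatches <= max_error_rate * overlap:
            return read[:i]
    return read


# ---------------------------------------------------------------------------
# alignment
# ---------------------------------------------------------------------------

def _best_candidate(read: str, mature: str, policy: AlignmentPolicy):
    """Best (n_mismatches, total_ends, add5, add3, miss5, miss3) for one reference.

    A candidate writes the read as add5-bases + core + add3-bases where the
    core pairs against the mature sequence minus miss5/miss3 terminal bases;
    only core positions count toward the mismatch budget.
    """
    best = None
    lr, lm = len(read), len(mature)
    for add5 in range(min(policy.max_additional_upstream, lr - 1) + 1):
        for add3 in range(min(policy.max_additional_downstream, lr - 1 - add5) + 1):
            core_len = lr - add5 - add3
            for miss5 in range(policy.max_missing_upstream + 1):
                miss3 = lm - miss5 - core_len
                if miss3 < 0 or miss3 > policy.max_missing_downstream:
                    continue
                core = read[add5: lr - add3]
                ref_core = mature[miss5: lm - miss3 if miss3 else lm]
                mm = sum(1 for a, b in zip(core, ref_core) if a != b)
                if mm > policy.max_mismatches:
                    continue
                key = (mm, add5 + add3 + miss5 + miss3, add5, add3, miss5, miss3)
                if best is None or key < best:
                    best = key
    return best


def align_read(
    read_id: str,
    read: str,
    reference: Mapping[str, str],
    policy: AlignmentPolicy = AlignmentPolicy(),
) -> ReadAssignment:
    """Assign one (already trimmed) read to a mature miRNA, or a status.

    The read and reference may use RNA or DNA alphabets interchangeably.
    """
    if not reference:
        raise ValueError("reference must be non-empty")
    seq = _normalize(read)
    if len(seq) < policy.min_trimmed_length:
        return ReadAssignment(read_id, None, None, None, "too_short")

    best_key = None
    best_names: list[str] = []
    for name in sorted(reference):
        cand = _best_candidate(seq, _normalize(reference[name]), policy)
        if cand is None:
            continue
        score = cand[:2]  # (mismatches, total end modifications)
        if best_key is None or score < best_key[:2]:
            best_key = cand
            best_names = [name]
        elif score == best_key[:2]:
            best_names.append(name)

    if best_key is None:
        return ReadAssignment(read_id, None, None, None, "unaligned")
    if len(best_names) > 1 and policy.ambiguous_policy == "discard":
        return ReadAssignment(read_id, None, None, None, "ambiguous")
    name = best_names[0]  # sorted iteration => lexicographically first
    mm, _total, add5, add3, miss5, miss3 = best_key
    return ReadAssignment(read_id, name, mm, (add5, add3, miss5, miss3), "assigned")


# ---------------------------------------------------------------------------
# per-sample quantification
# ---------------------------------------------------------------------------

def quantify(
    samples: Mapping[str, Iterable[tuple[str, str]]],
    reference: Mapping[str, str],
    policy: AlignmentPolicy = AlignmentPolicy(),
    adapter: str | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Count assigned reads per feature for each sample.

    Parameters
    ----------
    samples
        Mapping ``sample id -> iterable of (read id, sequence)``.
    reference
        Mature miRNA sequences.
    policy
        Alignment tolerances.
    adapter
        If given, each read is adapter-trimmed before alignment.

    Returns
    -------
    counts, summary
        ``counts`` is a features x samples integer DataFrame
        (``attrs['units'] == 'raw'``); ``summary`` tabulates reads per
        status for each sample.
    """
    features = list(reference)
    counts = pd.DataFrame(0, index=features, columns=list(samples), dtype=int)
    summary_rows = []
    for sample, reads in samples.items():
        tally = dict.fromkeys(_STATUSES, 0)
        for read_id, seq in reads:
            if adapter is not None:
                seq = trim_adapter(seq, adapter)
            assignment = align_read(read_id, seq, reference, policy)
            tally[assignment.status] += 1
            if assignment.status == "assigned":
                counts.loc[assignment.feature, sample] += 1
        if tally["assigned"] == 0:
            logger.warning("sample %s has zero assigned reads; kept for QC", sample)
        summary_rows.append({"sample": sample, **tally})
    counts.attrs["units"] = "raw"
    summary = pd.DataFrame(summary_rows).set_index("sample")
    return counts, summary


def read_fastq(path) -> list[tuple[str, str]]:
    """Read (id, sequence) pairs from a FASTQ file (Phred+33, quality ignored)."""
    from Bio import SeqIO

    return [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fastq")]
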