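"""Synthetic small-RNA-seq data with known ground truth.

This module generates the three layers of input the pipeline consumes —
mature-miRNA references, negative-binomial count matrices with a planted
genotype effect, and raw reads carrying isomiR end-variants — together with
a :class:`GroundTruth` record so that recovery can be tested quantitatively.

The default experimental design mirrors a two-genotype mouse EV study:
2 genotypes (Q331K transgenic vs WT transgenic) x 2 timepoints (3m, 6m) x
2 sexes x ``n_per_cell`` replicates, i.e. 24 samples per compartment at the
default of 3 replicates per cell.  Only genotype modulates expression; the
timepoint and sex factors are pure grouping labels, so they serve as
negative controls for the attribute-weighting confounder scan.

Counts are drawn from a negative binomial with per-feature dispersion
(var = mu + dispersion * mu^2).  A planted log2 fold change ``lfc`` is split
symmetrically: case means are scaled by 2**(+lfc/2) and control means by
2**(-lfc/2), keeping the grand mean composition effect-free.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

RNA_BASES = "ACGU"
DNA_BASES = "ACGT"

GENOTYPES = ("Q331K", "WT")
TIMEPOINTS = ("3m", "6m")
SEXES = ("F", "M")


def _rng(seed: int | np.random.Generator) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# reference generation
# ---------------------------------------------------------------------------

def generate_reference(
    n_features: int,
    length_range: tuple[int, int] = (18, 25),
    seed: int = 0,
) -> dict[str, str]:
    """Generate a mature-miRNA reference set.

    Returns an ordered mapping ``name -> RNA sequence`` with names
    ``syn-miR-<k>-5p`` and unique sequences of length 18–25 nt.

    Raises
    ------
    ValueError
        If ``n_features`` exceeds the available sequence space or the
        length range is outside 18–25 nt.
    """
    if n_features < 1:
        raise ValueError("n_features must be >= 1")
    lo, hi = length_range
    if not (18 <= lo <= hi <= 25):
        raise ValueError(f"length_range must lie within 18-25 nt, got {length_range}")
    space = sum(4 ** L for L in range(lo, hi + 1))
    if n_features > space:
        raise ValueError(
            f"cannot draw {n_features} unique sequences from a space of {space}"
        )
    rng = _rng(seed)
    seqs: dict[str, str] = {}
    seen: set[str] = set()
    attempts = 0
    while len(seqs) < n_features:
        L = int(rng.integers(lo, hi + 1))
        s = "".join(rng.choice(list(RNA_BASES), size=L))
        attempts += 1
        if attempts > 1000 * n_features + 1000:
            raise ValueError("exhausted attempts to draw unique sequences")
        if s in seen:
            continue
        seen.add(s)
        seqs[f"syn-miR-{len(seqs) + 1}-5p"] = s
    return seqs


# ---------------------------------------------------------------------------
# count-level simulation
# ---------------------------------------------------------------------------

@dataclass
class SyntheticDesign:
    """Parameters of a simulated two-genotype EV miRNA experiment.

    Parameters
    ----------
    n_features
        Number of miRNA features.
    n_per_cell
        Replicates per genotype x timepoint x sex cell (3 gives the
        canonical 24-sample compartment).
    planted
        Mapping ``feature name -> signed log2 fold change`` (Q331K vs WT).
        Features absent from the mapping have a true log2 FC of exactly 0.
    dispersion
        Negative-binomial dispersion (var = mu + dispersion * mu^2).
        0 degenerates to Poisson.
    baseline_log_mean_range
        Natural-log range of the raw per-feature abundance weights; the
        width controls how skewed the library composition is (the default
        span of ~7 log-units reproduces per-miRNA totals spanning several
        orders of magnitude).
    library_size_range
        Uniform range of per-sample sequencing depth.
    seed
        RNG seed; everything downstream is deterministic given it.
    """

    n_features: int = 300
    n_per_cell: int = 3
    planted: dict[str, float] = field(default_factory=dict)
    dispersion: float = 0.1
    baseline_log_mean_range: tuple[float, float] = (0.0, 7.0)
    library_size_range: tuple[int, int] = (500_000, 2_000_000)
    seed: int = 0
    feature_names: list[str] | None = None

    def __post_init__(self) -> None:
        if self.n_per_cell < 1:
            raise ValueError("n_per_cell must be >= 1")
        if self.n_features < 1:
            raise ValueError("n_features must be >= 1")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        for name, rng_ in (
            ("baseline_log_mean_range", self.baseline_log_mean_range),
            ("library_size_range", self.library_size_range),
        ):
            if rng_[0] > rng_[1]:
                raise ValueError(f"{name} must be ordered low <= high")
        if self.feature_names is None:
            self.feature_names = [f"syn-miR-{k + 1}-5p" for k in range(self.n_features)]
        if len(self.feature_names) != self.n_features:
            raise ValueError("feature_names length must equal n_features")
        unknown = set(self.planted) - set(self.feature_names)
        if unknown:
            raise ValueError(f"planted features not in feature set: {sorted(unknown)}")

    @property
    def n_samples(self) -> int:
        return 8 * self.n_per_cell


@dataclass
class ReadTruth:
    """Edit provenance of one simulated read."""

    read_id: str
    source: str
    add5: str  # extra 5' bases (templated-free), '' if none
    add3: str
    miss5: int  # reference bases missing at the 5' end
    miss3: int
    substitutions: tuple[tuple[int, str], ...]  # (0-based core position, new base) in RNA


@dataclass
class GroundTruth:
    """What the generator actually planted, for recovery tests."""

    log2_fold_change: pd.Series  # per feature, 0 for non-planted
    library_size: pd.Series  # per sample
    reads: list[ReadTruth] = field(default_factory=list)


def sample_table(design: SyntheticDesign, compartment: str = "BDEV") -> pd.DataFrame:
    """Enumerate the sample sheet for a design (one compartment)."""
    rows = []
    for genotype in GENOTYPES:
        for timepoint in TIMEPOINTS:
            for sex in SEXES:
                for rep in range(1, design.n_per_cell + 1):
                    sid = f"{compartment}_{genotype}_{timepoint}_{sex}_{rep}"
                    rows.append(
                        {
                            "sample": sid,
                            "genotype": genotype,
                            "timepoint": timepoint,
                            "sex": sex,
                            "compartment": compartment,
                        }
                    )
    return pd.DataFrame(rows).set_index("sample")


def generate_counts(
    design: SyntheticDesign, compartment: str = "BDEV"
) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Simulate a raw count matrix for one compartment.

    Returns ``(counts, samples, truth)`` where ``counts`` is a
    features x samples integer DataFrame (``counts.attrs['units'] == 'raw'``),
    ``samples`` the metadata table with realised library sizes, and
    ``truth`` the planted effects.
    """
    rng = _rng(design.seed)
    meta = sample_table(design, compartment)
    features = list(design.feature_names or [])

    log_w = rng.uniform(*design.baseline_log_mean_range, size=design.n_features)
    rel = np.exp(log_w)
    rel /= rel.sum()

    lib = rng.integers(
        design.library_size_range[0], design.library_size_range[1] + 1, size=len(meta)
    ).astype(float)

    lfc = pd.Series(0.0, index=features)
    for name, value in design.planted.items():
        lfc[name] = float(value)

    # symmetric effect split keeps the grand mean composition unchanged
    shift = np.where(meta["genotype"].to_numpy() == "Q331K", 0.5, -0.5)
    mu = rel[:, None] * lib[None, :] * np.exp2(lfc.to_numpy()[:, None] * shift[None, :])

    if design.dispersion < 1e-12:
        counts = rng.poisson(mu)
    else:
        size = 1.0 / design.dispersion
        p = size / (size + mu)
        counts = rng.negative_binomial(size, p)

    counts_df = pd.DataFrame(counts, index=features, columns=meta.index)
    counts_df.attrs["units"] = "raw"
    meta = meta.assign(library_size=counts_df.sum(axis=0))
    truth = GroundTruth(
        log2_fold_change=lfc, library_size=pd.Series(lib, index=meta.index)
    )
    return counts_df, meta, truth


# ---------------------------------------------------------------------------
# read-level simulation
# ---------------------------------------------------------------------------

@dataclass
class IsomirProfile:
    """Bounds and rates of isomiR-style read edits.

    Each end may carry up to 2 additional (non-templated) or missing bases,
    and the core may carry up to 2 substitutions — the same tolerance the
    quantifier accepts.  ``end_edit_prob``/``sub_prob`` are the per-read
    probabilities of applying an edit of each kind.
    """

    max_add5: int = 2
    max_add3: int = 2
    max_miss5: int = 2
    max_miss3: int = 2
    max_substitutions: int = 2
    end_edit_prob: float = 0.3
    sub_prob: float = 0.2

    def __post_init__(self) -> None:
        for name in ("max_add5", "max_add3", "max_miss5", "max_miss3", "max_substitutions"):
            v = getattr(self, name)
            if not 0 <= v <= 2:
                raise ValueError(f"{name} must be within 0-2, got {v}")
        for name in ("end_edit_prob", "sub_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be a probability, got {v}")


def _pick_end_edit(rng: np.random.Generator, prob: float, max_add: int, max_miss: int):
    """Return (n_added, n_missing) for one read end; at most one is non-zero."""
    if rng.random() >= prob:
        return 0, 0
    choices = []
    if max_add > 0:
        choices.append("add")
    if max_miss > 0:
        choices.append("miss")
    if not choices:
        return 0, 0
    kind = choices[int(rng.integers(len(choices)))]
    if kind == "add":
        return int(rng.integers(1, max_add + 1)), 0
    return 0, int(rng.integers(1, max_miss + 1))


def generate_reads(
    reference: dict[str, str],
    abundances: dict[str, float],
    isomir_profile: IsomirProfile,
    n_reads: int,
    adapter: str = "TGGAATTCTCGGGTGCCAAGG",
    seed: int = 0,
) -> tuple[list[tuple[str, str]], GroundTruth]:
    """Simulate adapter-carrying small-RNA reads.

    Each read is a (possibly end-modified, possibly substituted) reference
    sequence followed by the 3' adapter, emitted in the DNA alphabet.
    Returns ``(reads, truth)`` where ``reads`` is a list of
    ``(read_id, sequence)`` and ``truth.reads`` records every edit.
    """
    if not adapter or set(adapter) - set(DNA_BASES):
        raise ValueError("adapter must be a non-empty DNA sequence")
    rng = _rng(seed)
    names = list(reference)
    missing = set(abundances) - set(names)
    if missing:
        raise ValueError(f"abundances reference unknown miRNAs: {sorted(missing)}")
    w = np.array([abundances.get(n, 0.0) for n in names], dtype=float)
    if w.sum() <= 0:
        raise ValueError("abundances must have positive total mass")
    w /= w.sum()

    reads: list[tuple[str, str]] = []
    truths: list[ReadTruth] = []
    for i in range(n_reads):
        src = names[int(rng.choice(len(names), p=w))]
        seq = reference[src].upper().replace("T", "U")
        add5, miss5 = _pick_end_edit(
            rng, isomir_profile.end_edit_prob, isomir_profile.max_add5, isomir_profile.max_miss5
        )
        add3, miss3 = _pick_end_edit(
            rng, isomir_profile.end_edit_prob, isomir_profile.max_add3, isomir_profile.max_miss3
        )
        core = seq[miss5: len(seq) - miss3 if miss3 else len(seq)]
        subs: list[tuple[int, str]] = []
        if isomir_profile.max_substitutions > 0 and rng.random() < isomir_profile.sub_prob:
            k = int(rng.integers(1, isomir_profile.max_substitutions + 1))
            k = min(k, len(core))
            positions = rng.choice(len(core), size=k, replace=False)
            core_list = list(core)
            for pos in sorted(int(p) for p in positions):
                alternatives = [b for b in RNA_BASES if b != core_list[pos]]
                new = alternatives[int(rng.integers(3))]
                core_list[pos] = new
                subs.append((pos, new))
            core = "".join(core_list)
        add5_bases = "".join(rng.choice(list(RNA_BASES), size=add5)) if add5 else ""
        add3_bases = "".join(rng.choice(list(RNA_BASES), size=add3)) if add3 else ""
        insert = add5_bases + core + add3_bases
        read_id = f"read_{i + 1}"
        reads.append((read_id, insert.replace("U", "T") + adapter))
        truths.append(
            ReadTruth(
                read_id=read_id,
                source=src,
                add5=add5_bases,
                add3=add3_bases,
                miss5=miss5,
                miss3=miss3,
                substitutions=tuple(subs),
            )
        )
    truth = GroundTruth(
        log2_fold_change=pd.Series(0.0, index=names),
        library_size=pd.Series({"sample": float(n_reads)}),
        reads=truths,
    )
    return reads, truth


def apply_truth(truth: ReadTruth, reference: dict[str, str]) -> str:
    """Reconstruct a read's insert (RNA alphabet, no adapter) from its recorded edits."""
    seq = reference[truth.source].upper().replace("T", "U")
    core = list(seq[truth.miss5: len(seq) - truth.miss3 if truth.miss3 else len(seq)])
    for pos, base in truth.substitutions:
        core[pos] = base
    return truth.add5 + "".join(core) + truth.add3


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

def write_fasta(sequences: dict[str, str], path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i: i + width] + "\n")


def write_fastq(reads: list[tuple[str, str]], path, quality_char: str = "I") -> None:
    with open(path, "w") as fh:
        for read_id, seq in reads:
            fh.write(f"@{read_id}\n{seq}\n+\n{quality_char * len(seq)}\n")


def fastq_string(reads: list[tuple[str, str]], quality_char: str = "I") -> str:
    buf = io.StringIO()
    for read_id, seq in reads:
        buf.write(f"@{read_id}\n{seq}\n+\n{quality_char * len(seq)}\n")
    return buf.getvalue()
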