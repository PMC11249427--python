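"""End-to-end orchestration: simulate -> normalize -> weigh -> test -> compare.

``run_pipeline`` executes the full analysis on synthetic data for the two
EV compartments (brain-derived and serum), writing every intermediate and
final table to a run directory together with a resolved-config snapshot,
so a run is reproducible byte-for-byte from its own output.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .de import FilterSpec, de_table, select_panel
from .io import write_tsv
from .normalize import pca_qc, tmm_factors
from .panels import intersect_panels, venn_counts
from .seeds import find_seed_sites
from .synthetic import SyntheticDesign, generate_counts, generate_reference
from .weighting import Discretization, confounder_scan

logger = logging.getLogger(__name__)

COMPARTMENTS = ("BDEV", "serum")


@dataclass
class RunConfig:
    """All pipeline parameters with their default analysis values.

    Tolerances that have a conventional value in this analysis (2 mismatches,
    isomiR end bounds of 2, mean >= 5 RPM expression filter, alpha 0.05,
    |FC| >= 1.5) default to those values; everything else defaults to the
    documented package choice.
    """

    out_dir: str = "evmir_run"
    seed: int = 0
    # simulation
    n_features: int = 300
    n_per_cell: int = 3
    dispersion: float = 0.1
    n_planted_bdev: int = 12
    n_planted_serum: int = 6
    n_planted_common: int = 2
    planted_lfc_range: tuple[float, float] = (1.0, 2.63)
    # normalization / QC
    trim_m: float = 0.30
    trim_a: float = 0.05
    pca_k: int = 2
    flag_sd: float = 3.0
    drop_flagged: bool = True
    # weighting
    n_bins: int = 4
    relief_k: int = 10
    top_k: int = 30
    # differential expression
    case: str = "Q331K"
    control: str = "WT"
    min_mean_rpm: float = 5.0
    alpha: float = 0.05
    fc_threshold: float = 1.5
    inclusive: bool = True
    pseudocount: float = 0.5

    def filter_spec(self) -> FilterSpec:
        return FilterSpec(
            min_mean_rpm=self.min_mean_rpm,
            alpha=self.alpha,
            fc_threshold=self.fc_threshold,
            inclusive=self.inclusive,
        )

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        data.pop("evmir_version", None)  # provenance tag from a resolved snapshot
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "planted_lfc_range" in data:
            data["planted_lfc_range"] = tuple(data["planted_lfc_range"])
        return cls(**data)

    def to_yaml(self, path) -> None:
        data = dataclasses.asdict(self)
        data["planted_lfc_range"] = list(self.planted_lfc_range)
        data["evmir_version"] = __version__
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)


def planted_effects(config: RunConfig) -> dict[str, dict[str, float]]:
    """Per-compartment planted log2 fold changes.

    The two compartments receive partially overlapping planted feature
    sets (``n_planted_common`` shared), emulating panels that intersect in
    a small biomarker core.  Magnitudes are drawn uniformly from
    ``planted_lfc_range`` with random sign, deterministically in the seed.
    """
    rng = np.random.default_rng(config.seed)
    names = [f"syn-miR-{k + 1}-5p" for k in range(config.n_features)]
    n_bdev, n_serum, n_common = (
        config.n_planted_bdev,
        config.n_planted_serum,
        config.n_planted_common,
    )
    if n_common > min(n_bdev, n_serum):
        raise ValueError("n_planted_common exceeds a compartment's planted count")
    total = n_bdev + n_serum - n_common
    if total > config.n_features:
        raise ValueError("not enough features for the requested planted sets")
    chosen = list(rng.choice(names, size=total, replace=False))
    common = chosen[:n_common]
    bdev_only = chosen[n_common:n_bdev]
    serum_only = chosen[n_bdev:]

    def draw(feature_names: list[str]) -> dict[str, float]:
        lo, hi = config.planted_lfc_range
        return {
            name: float(rng.uniform(lo, hi) * rng.choice([-1.0, 1.0]))
            for name in feature_names
        }

    shared = draw(common)
    return {
        "BDEV": {**shared, **draw(bdev_only)},
        "serum": {**shared, **draw(serum_only)},
    }


def run_pipeline(config: RunConfig) -> Path:
    """Run every stage and return the run directory."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config_resolved.yaml")

    planted = planted_effects(config)
    reference = generate_reference(config.n_features, seed=config.seed)
    panels = {}
    truths = {}
    for i, compartment in enumerate(COMPARTMENTS):
        logger.info("stage simulate[%s]", compartment)
        design = SyntheticDesign(
            n_features=config.n_features,
            n_per_cell=config.n_per_cell,
            planted=planted[compartment],
            dispersion=config.dispersion,
            seed=config.seed * 7919 + i + 1,
        )
        counts, meta, truth = generate_counts(design, compartment=compartment)
        truths[compartment] = truth
        write_tsv(counts, out / f"counts_{compartment}.tsv", "units: raw counts")
        write_tsv(meta, out / f"samples_{compartment}.tsv", "sample metadata")
        write_tsv(
            truth.log2_fold_change.to_frame("true_log2_fc"),
            out / f"truth_{compartment}.tsv",
            "planted log2 fold changes (Q331K vs WT)",
        )

        logger.info("stage normalize[%s] (%d features x %d samples)", compartment, *counts.shape)
        norm = tmm_factors(counts, config.trim_m, config.trim_a)
        qc = pca_qc(norm.cpm, k=config.pca_k, flag_sd=config.flag_sd)
        qc_table = qc.scores.copy()
        qc_table["distance"] = qc.distances
        qc_table["flagged"] = [s in qc.flags for s in qc_table.index]
        write_tsv(
            qc_table,
            out / f"qc_{compartment}.tsv",
            f"PCA QC on log2(TMM-CPM+0.5); flag threshold {config.flag_sd} robust SD",
        )
        cpm_matrix = norm.cpm
        meta_used = meta
        if config.drop_flagged and qc.flags:
            logger.info("dropping %d flagged sample(s): %s", len(qc.flags), qc.flags)
            keep = [s for s in cpm_matrix.columns if s not in qc.flags]
            cpm_matrix = cpm_matrix[keep]
            meta_used = meta.loc[keep]
        write_tsv(
            cpm_matrix,
            out / f"tmm_cpm_{compartment}.tsv",
            "units: TMM-CPM (counts per million on TMM effective library sizes)",
        )

        logger.info("stage weigh[%s]", compartment)
        reports, overlap = confounder_scan(
            cpm_matrix,
            meta_used,
            discretization=Discretization(n_bins=config.n_bins),
            relief_k=config.relief_k,
            seed=config.seed,
            top_m=config.top_k,
        )
        for label, report in reports.items():
            write_tsv(
                report,
                out / f"weights_{compartment}_{label}.tsv",
                f"7-model attribute weights vs {label}; per-model min-max "
                "normalized, ensemble = row sum",
            )
        write_tsv(overlap, out / f"weights_{compartment}_overlap.tsv",
                  "top-k overlap between label weightings", index=False)

        logger.info("stage de[%s]", compartment)
        table = de_table(
            cpm_matrix,
            meta_used,
            case=config.case,
            control=config.control,
            min_mean_rpm=config.min_mean_rpm,
            pseudocount=config.pseudocount,
        )
        table.attrs["compartment"] = compartment
        write_tsv(
            table,
            out / f"de_{compartment}.tsv",
            f"ANOVA on log2(TMM-CPM+{config.pseudocount}); ratio of geometric "
            "means (case/control); signed fold change",
        )
        panel = select_panel(table, config.filter_spec())
        write_tsv(
            panel.records,
            out / f"panel_{compartment}.tsv",
            f"p < {config.alpha}, |FC| {'>=' if config.inclusive else '>'} "
            f"{config.fc_threshold}",
        )
        panels[compartment] = panel

    logger.info("stage compare")
    venn = venn_counts(panels["BDEV"], panels["serum"])
    with open(out / "venn.json", "w") as fh:
        json.dump(venn._asdict(), fh, indent=2)
    common = intersect_panels(panels["BDEV"], panels["serum"])
    write_tsv(common, out / "common_panel.tsv",
              "features significant in both compartments")

    logger.info("stage seeds")
    common_names = [f for f in panels["BDEV"].features
                    if f in set(panels["serum"].features)]
    mirnas = {name: reference[name] for name in common_names}
    utrs = _demo_utrs(mirnas, seed=config.seed)
    sites = find_seed_sites(mirnas, utrs)
    write_tsv(sites, out / "seed_sites.tsv",
              "exact 7mer seed sites; 1-based inclusive UTR coordinates",
              index=False)
    logger.info("pipeline complete: %s", out)
    return out


def _demo_utrs(mirnas: dict[str, str], seed: int, flank: int = 20) -> dict[str, str]:
    """Synthetic 3'UTRs each embedding every common miRNA's seed site."""
    from .seeds import extract_seed, reverse_complement

    rng = np.random.default_rng(seed + 104729)
    utrs = {}
    sites = [reverse_complement(extract_seed(seq)) for seq in mirnas.values()]
    for i in range(max(len(mirnas), 1)):
        parts = ["".join(rng.choice(list("ACGU"), size=flank))]
        for site in sites:
            parts.append(site)
            parts.append("".join(rng.choice(list("ACGU"), size=flank)))
        utrs[f"syn-UTR-{i + 1}"] = "".join(parts)
    return utrs
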