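"""End-to-end orchestration: simulate/load -> rarefy -> diversity ->
multivariate tests -> per-condition neutral fits and core selection.

Every run writes TSV outputs plus one JSON manifest recording the config,
input checksums, seed, stage timings, and output list; identical inputs and
manifest reproduce identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import pandas as pd

from . import __version__
from .core import build_core_selection, compare_core_sets, aggregate_class_abundance
from .datamodel import (
    AnalysisConfig,
    FeatureTable,
    SampleMetadata,
    drop_low_depth_samples,
    validate_alignment,
    write_distance_matrix,
)
from .diversity import alpha_diversity_table, bray_curtis, rarefy, weighted_unifrac
from .multivariate import nested_permanova, nmds, permdisp
from .neutral import (
    classify_neutral_partition,
    fit_migration_rate,
    occupancy_abundance,
    partition_counts,
)

__all__ = ["RunManifest", "run_pipeline"]


@dataclass
class RunManifest:
    config: dict
    seed: int
    version: str
    input_checksums: dict = dc_field(default_factory=dict)
    stage_seconds: dict = dc_field(default_factory=dict)
    outputs: list = dc_field(default_factory=list)

    def write(self, path: Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.__dict__, fh, indent=2, default=str)


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run_pipeline(
    table: FeatureTable,
    metadata: SampleMetadata,
    tree=None,
    config: AnalysisConfig | None = None,
    out_dir: str | Path = "results",
    input_paths: dict | None = None,
) -> RunManifest:
    """Run every analysis stage in dependency order and write result TSVs.

    Stages: depth filtering and rarefaction; alpha diversity (+ Faith PD if
    a tree is given); weighted UniFrac (if a tree is given) and Bray-Curtis;
    nested blocked PERMANOVA, PERMDISP, NMDS on the primary distance matrix;
    then per-condition neutral-model fits, partitions, and core selection,
    summarized in a Table-2-shaped overview. A stage failure aborts with the
    stage name; outputs written so far are preserved.
    """
    config = config or AnalysisConfig()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config=dict(config.__dict__), seed=config.rng_seed,
                           version=__version__)
    if input_paths:
        manifest.input_checksums = {
            k: _checksum(Path(v)) for k, v in input_paths.items()
        }

    def emit(frame: pd.DataFrame, name: str, **kwargs) -> None:
        path = out / name
        with open(path, "w") as fh:
            fh.write(f"# neutralcore={__version__} config={config.config_hash()} "
                     f"seed={config.rng_seed}\n")
            frame.to_csv(fh, sep="\t", **kwargs)
        manifest.outputs.append(str(path))

    stage = "validate"
    t0 = time.time()
    try:
        validate_alignment(table, tree, metadata, strict=False)
        table, dropped = drop_low_depth_samples(table, config.rarefaction_depth)
        metadata = metadata.subset(table.sample_ids)
        manifest.stage_seconds[stage] = round(time.time() - t0, 3)

        stage = "rarefy"
        t0 = time.time()
        rare = rarefy(table, config.rarefaction_depth, config.rng_seed)
        manifest.stage_seconds[stage] = round(time.time() - t0, 3)

        stage = "alpha_diversity"
        t0 = time.time()
        alpha = alpha_diversity_table(rare, tree, base=config.shannon_log_base)
        emit(alpha, "alpha_diversity.tsv")
        manifest.stage_seconds[stage] = round(time.time() - t0, 3)

        stage = "beta_diversity"
        t0 = time.time()
        bc = bray_curtis(rare)
        write_distance_matrix(bc, out / "bray_curtis.tsv")
        manifest.outputs.append(str(out / "bray_curtis.tsv"))
        if tree is not None:
            primary = weighted_unifrac(rare, tree, normalized=config.unifrac_normalized)
            write_distance_matrix(primary, out / "weighted_unifrac.tsv")
            manifest.outputs.append(str(out / "weighted_unifrac.tsv"))
        else:
            primary = bc
        manifest.stage_seconds[stage] = round(time.time() - t0, 3)

        stage = "permanova"
        t0 = time.time()
        perm = nested_permanova(
            primary, metadata, n_perm=config.n_permutations, seed=config.rng_seed
        )
        emit(perm.to_frame(), "permanova.tsv")
        manifest.stage_seconds[stage] = round(time.time() - t0, 3)

        stage = "permdisp"
        t0 = time.time()
        cond = metadata.frame["condition"]
        disp = permdisp(
            primary, cond, n_perm=config.n_permutations, seed=config.rng_seed
        )
        disp_frame = disp.group_means.rename("mean_distance").to_frame()
        emit(disp_frame, "dispersion_group_means.tsv", index_label="condition")
        manifest.stage_seconds[stage] = round(time.time() - t0, 3)

        stage = "nmds"
        t0 = time.time()
        ord_res = nmds(primary, k=config.nmds_dimensions, seed=config.rng_seed)
        emit(ord_res.coordinates, "nmds_coordinates.tsv", index_label="sample-id")
        manifest.stage_seconds[stage] = round(time.time() - t0, 3)

        stage = "neutral_core"
        t0 = time.time()
        summary_rows = []
        core_sets: dict[str, set[str]] = {}
        for condition in sorted(cond.unique()):
            samples = cond.index[cond == condition].tolist()
            sub = rare.filter_samples(samples).drop_empty_taxa()
            oa = occupancy_abundance(sub, config.abundance_mode)
            fit = fit_migration_rate(oa)
            part = classify_neutral_partition(fit, config.ci_method)
            sel = build_core_selection(sub, oa, config.core_threshold, part)
            emit(sel.frame, f"neutral_core_{condition}.tsv")
            counts = partition_counts(part)
            n_tot = len(part)
            core_sets[condition] = set(sel.core_taxa)
            summary_rows.append(
                {
                    "condition": condition,
                    "migration_rate": fit.m,
                    "r_squared": fit.r_squared,
                    "n_variants": n_tot,
                    "above": counts["above"],
                    "above_pct": 100 * counts["above"] / n_tot,
                    "below": counts["below"],
                    "below_pct": 100 * counts["below"] / n_tot,
                    "core": sel.core_size,
                    "core_pct": 100 * sel.core_size / n_tot,
                    "over_occupant_core": int(
                        sel.frame.get("over_occupant_core", pd.Series(dtype=bool)).sum()
                    ),
                }
            )
            if table.taxonomy:
                agg = aggregate_class_abundance(sub, core_sets[condition])
                emit(agg.rename("relative_abundance").to_frame(),
                     f"core_class_abundance_{condition}.tsv", index_label="class")
        emit(pd.DataFrame(summary_rows).set_index("condition"), "neutral_summary.tsv")
        if {"uninvaded", "invaded"} <= core_sets.keys():
            comp = compare_core_sets(core_sets["uninvaded"], core_sets["invaded"])
            comp_frame = pd.DataFrame(
                {
                    "category": ["shared", "unique_uninvaded", "unique_invaded"],
                    "n": [len(comp["shared"]), len(comp["unique_a"]), len(comp["unique_b"])],
                    "taxa": [
                        ";".join(sorted(comp["shared"])),
                        ";".join(sorted(comp["unique_a"])),
                        ";".join(sorted(comp["unique_b"])),
                    ],
                }
            ).set_index("category")
            emit(comp_frame, "core_comparison.tsv")
        manifest.stage_seconds[stage] = round(time.time() - t0, 3)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    manifest.write(out / "manifest.json")
    manifest.outputs.append(str(out / "manifest.json"))
    return manifest
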