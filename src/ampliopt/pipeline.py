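"""End-to-end benchmark pipeline: simulate -> optimize -> assign -> grade.

``run_pipeline`` reproduces the full benchmarking loop for one mock
community: for every requested primer it simulates replicate paired-end
runs, finds the survival-maximizing trim cell on the grid, builds the
ASV table at that cell, and then for every reference database assigns
taxonomy, collapses to the requested rank, and scores the profile
against the theoretical composition (CLR grades, Spearman similarity,
PCA coordinates, Shannon diversity).  All randomness flows from the
single configured seed.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .compo import (
    GradingThresholds,
    clr_transform,
    filter_low_abundance,
    grade_table,
    pca_clr,
    shannon,
    spearman_vs_theory,
)
from .denoise import MergeParams
from .grid import GridSpec, GridResult, _Prepared, _evaluate_cell, optimize_trim, table1_report
from .mock import MockMember, TheoreticalComposition, theoretical_composition
from .refs import (
    amplicon_lengths,
    default_primer_pairs,
    extract_amplicon,
    mock1_members,
    mock2_members,
    synthetic_reference_set,
)
from .simulate import (
    DEFAULT_FORWARD_QUALITY,
    DEFAULT_REVERSE_QUALITY,
    QualityModel,
    SimConfig,
    simulate_pairs,
)
from .taxdb import assign_all, build_fixture_db, collapse_to_level, registered_count

__all__ = ["RunConfig", "PrimerOutcome", "ConditionOutcome", "run_pipeline", "load_config"]


@dataclass
class RunConfig:
    """Configuration of one benchmark run (one mock community)."""

    seed: int = 0
    mock: str | Sequence[MockMember] = "mock1"
    primers: Sequence[str] = ("V3-V4", "V4")
    databases: Mapping[str, Sequence[str]] = field(
        default_factory=lambda: {"universal": ()}
    )  # db name -> dropped taxa
    read_len: int = 300
    n_pairs: int = 20000
    replicates: int = 3
    chimera_rate: float = 0.05
    rank: str = "genus"
    grid: GridSpec | None = None  # None -> preset for read_len
    max_expected_errors: float = 2.0
    merge_params: MergeParams = field(default_factory=MergeParams)
    thresholds: GradingThresholds = field(default_factory=GradingThresholds)
    fwd_quality: QualityModel = DEFAULT_FORWARD_QUALITY
    rev_quality: QualityModel = DEFAULT_REVERSE_QUALITY
    grid_max_pairs: int | None = 2000  # subsample used to rank grid cells
    ref_seed: int = 0  # fixes the synthetic reference sequences
    outdir: str | Path | None = None

    def members(self) -> list[MockMember]:
        if isinstance(self.mock, str):
            if self.mock == "mock1":
                return mock1_members()
            if self.mock == "mock2":
                return mock2_members()
            from .mock import read_mock_table

            return read_mock_table(self.mock)
        return list(self.mock)


@dataclass
class PrimerOutcome:
    """Per-primer results independent of any database."""

    primer: str
    grid: GridResult
    asv_table: pd.DataFrame  # ASV x replicate counts at the best cell


@dataclass
class ConditionOutcome:
    """Results of one (primer, database) condition."""

    primer: str
    database: str
    registered: tuple[int, int]
    taxon_table: pd.DataFrame  # mock taxa x (replicates + ideal), counts
    grades: pd.Series
    spearman_r: float
    spearman_p: float
    shannon_by_sample: pd.Series
    pca_coords: pd.DataFrame
    pca_variances: np.ndarray


def _sub_seed(seed: int, primer_idx: int, replicate: int) -> int:
    return (seed * 100003 + primer_idx * 1009 + replicate) % (2**31)


def _observed_taxon_counts(
    collapsed: pd.DataFrame, taxa: Sequence[str], rank: str
) -> pd.DataFrame:
    """Counts per mock taxon (0 where unobserved), replicate columns kept.

    The collapsed table is indexed by rank labels (genus names at genus
    rank); rows are pulled back onto the mock taxon ids.
    """
    labels = [t.split()[0] if rank == "genus" else t for t in taxa]
    out = collapsed.reindex(labels).fillna(0.0)
    out.index = pd.Index(taxa, name="taxon")
    return out


def run_pipeline(config: RunConfig) -> dict:
    """Run the full benchmark; returns a result bundle.

    The bundle maps:

    * ``"composition"`` — the theoretical composition,
    * ``"primer_outcomes"`` — per-primer grid results and ASV tables,
    * ``"conditions"`` — per (primer, database) ConditionOutcome,
    * ``"table1"`` — the survival summary across primers,
    * ``"manifest"`` — config echo with versions and the defaults in force.

    When ``config.outdir`` is set, tables and the manifest are also
    written there as TSV/JSON.
    """
    members = config.members()
    comp = theoretical_composition(members)
    taxa = list(comp.abundances)
    pairs_by_name = default_primer_pairs()
    unknown = [p for p in config.primers if p not in pairs_by_name]
    if unknown:
        raise KeyError(f"unknown primer label(s): {unknown}")
    amp_lens = amplicon_lengths()
    spec = config.grid or GridSpec.preset(config.read_len)
    references = synthetic_reference_set(taxa, seed=config.ref_seed)

    dbs = {
        name: build_fixture_db(name, taxa, dropout=dropout, seed=config.ref_seed)
        for name, dropout in config.databases.items()
    }

    theo_clr = pd.Series(
        clr_transform(np.array([comp.abundances[t] for t in taxa])), index=taxa
    )

    primer_outcomes: list[PrimerOutcome] = []
    conditions: list[ConditionOutcome] = []

    for p_idx, primer_name in enumerate(config.primers):
        primer = pairs_by_name[primer_name]
        amplicons = {t: extract_amplicon(references[t], primer) for t in taxa}

        replicate_pairs = []
        for r in range(config.replicates):
            sim = SimConfig(
                seed=_sub_seed(config.seed, p_idx, r),
                n_pairs=config.n_pairs,
                read_len=config.read_len,
                pair=primer,
                composition=comp,
                chimera_rate=config.chimera_rate,
                fwd_quality=config.fwd_quality,
                rev_quality=config.rev_quality,
            )
            replicate_pairs.append(simulate_pairs(sim, amplicons))

        grid_res = optimize_trim(
            replicate_pairs[0],
            spec,
            max_expected_errors=config.max_expected_errors,
            merge_params=config.merge_params,
            primer=primer_name,
            max_pairs=config.grid_max_pairs,
            subsample_seed=_sub_seed(config.seed, p_idx, 999),
        )

        # ASV table at the winning cell, one column per replicate
        rep_tables = []
        for r, rp in enumerate(replicate_pairs):
            prep = _Prepared(rp)
            _, tbl = _evaluate_cell(
                prep,
                grid_res.best,
                config.max_expected_errors,
                config.merge_params,
                collapse=True,
                collapse_fold=8.0,
                parent_fold=2.0,
            )
            rep_tables.append(tbl.rename(columns={"sample1": f"rep{r + 1}"}))
        asv_table = pd.concat(rep_tables, axis=1).fillna(0).astype(int)
        asv_table = filter_low_abundance(asv_table)
        primer_outcomes.append(
            PrimerOutcome(primer=primer_name, grid=grid_res, asv_table=asv_table)
        )

        depth = float(asv_table.sum(axis=0).mean()) if not asv_table.empty else 0.0
        ideal = pd.Series(
            {t: depth * comp.abundances[t] for t in taxa}, name="ideal"
        )

        for db_name, db in dbs.items():
            assignments = assign_all(
                asv_table.index, db, rank=config.rank, region=primer
            )
            collapsed = collapse_to_level(asv_table, assignments)
            observed = _observed_taxon_counts(collapsed, taxa, config.rank)
            table = pd.concat([observed, ideal], axis=1)

            clr_cols = {}
            for c in table.columns:
                if table[c].sum() > 0:
                    clr_cols[c] = clr_transform(table[c])
                else:
                    warnings.warn(
                        f"column {c!r} of {primer_name}/{db_name} has no assigned "
                        "reads; CLR undefined",
                        stacklevel=2,
                    )
                    clr_cols[c] = pd.Series(np.nan, index=table.index)
            clr_df = pd.DataFrame(clr_cols, index=table.index)
            obs_mean_clr = clr_df.drop(columns="ideal").mean(axis=1)

            db_labels = db.labels_at(config.rank)
            registered_taxa = {
                t
                for t in taxa
                if (t.split()[0] if config.rank == "genus" else t) in db_labels
            }
            grades = grade_table(
                obs_mean_clr, theo_clr, registered=registered_taxa,
                thresholds=config.thresholds,
            )
            reg_list = sorted(registered_taxa)
            if len(reg_list) >= 3:
                r_val, p_val = spearman_vs_theory(
                    obs_mean_clr[reg_list], theo_clr[reg_list]
                )
            else:
                r_val, p_val = float("nan"), float("nan")

            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                shannon_by_sample = pd.Series(
                    {
                        c: shannon(table[c][table[c] > 0]) if (table[c] > 0).any() else np.nan
                        for c in table.columns
                    },
                    name="shannon",
                )
            coords, variances = pca_clr(clr_df.T)
            conditions.append(
                ConditionOutcome(
                    primer=primer_name,
                    database=db_name,
                    registered=registered_count(taxa, db, rank=config.rank),
                    taxon_table=table,
                    grades=grades,
                    spearman_r=r_val,
                    spearman_p=p_val,
                    shannon_by_sample=shannon_by_sample,
                    pca_coords=coords,
                    pca_variances=variances,
                )
            )

    table1 = table1_report((po.grid for po in primer_outcomes), amp_lens)
    manifest = {
        "ampliopt_version": __version__,
        "seed": config.seed,
        "mock": config.mock if isinstance(config.mock, str) else "custom",
        "primers": list(config.primers),
        "databases": {k: list(v) for k, v in config.databases.items()},
        "read_len": config.read_len,
        "n_pairs": config.n_pairs,
        "replicates": config.replicates,
        "chimera_rate": config.chimera_rate,
        "rank": config.rank,
        "grid": [spec.start, spec.stop, spec.step],
        "max_expected_errors": config.max_expected_errors,
        "min_overlap": config.merge_params.min_overlap,
        "grading_thresholds": [config.thresholds.inner, config.thresholds.outer],
        "conventions": {
            "lengths": "all trim/amplicon lengths measured after primer removal",
            "survival_denominator": "primer-removed input pairs",
            "clr": "natural log; zeros replaced with 0.5 x smallest nonzero proportion",
            "shannon": "log base 2",
        },
        "bimeras_removed_total": int(
            sum(
                po.grid.best_stats.merged - po.grid.best_stats.nonchimeric
                for po in primer_outcomes
            )
        ),
    }

    bundle = {
        "composition": comp,
        "primer_outcomes": primer_outcomes,
        "conditions": conditions,
        "table1": table1,
        "manifest": manifest,
    }
    if config.outdir is not None:
        _write_bundle(bundle, Path(config.outdir))
    return bundle


def _write_bundle(bundle: dict, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    bundle["table1"].to_csv(outdir / "table1.tsv", sep="\t", index=False)
    for po in bundle["primer_outcomes"]:
        po.asv_table.to_csv(outdir / f"asv_{po.primer}.tsv", sep="\t")
    grade_frames = {}
    for c in bundle["conditions"]:
        c.taxon_table.to_csv(outdir / f"taxa_{c.primer}_{c.database}.tsv", sep="\t")
        grade_frames[(c.primer, c.database)] = c.grades
    if grade_frames:
        pd.DataFrame(grade_frames).to_csv(outdir / "grades.tsv", sep="\t")
        pd.DataFrame(
            [
                {
                    "primer": c.primer,
                    "database": c.database,
                    "registered": f"{c.registered[0]}/{c.registered[1]}",
                    "spearman_r": c.spearman_r,
                    "spearman_p": c.spearman_p,
                }
                for c in bundle["conditions"]
            ]
        ).to_csv(outdir / "similarity.tsv", sep="\t", index=False)
    (outdir / "manifest.json").write_text(json.dumps(bundle["manifest"], indent=2))


def load_config(path: str | Path) -> RunConfig:
    """Build a RunConfig from a YAML file (unknown keys rejected)."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    known = set(RunConfig.__dataclass_fields__)
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    if "grid" in raw and raw["grid"] is not None:
        raw["grid"] = GridSpec(*raw["grid"])
    if "merge_params" in raw:
        raw["merge_params"] = MergeParams(**raw["merge_params"])
    if "thresholds" in raw:
        raw["thresholds"] = GradingThresholds(**raw["thresholds"])
    for key in ("fwd_quality", "rev_quality"):
        if key in raw:
            raw[key] = QualityModel(**raw[key])
    return RunConfig(**raw)
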