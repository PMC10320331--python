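"""End-to-end orchestration: records -> traits -> ordinations -> report.

Three stages mirror the analysis levels:

* interspecific -- aggregate individual traits to species means, run one
  phylogenetic PCA per input tree plus one on the average tree, and
  evaluate the slow-fast verdict on the average-tree axes;
* within -- a separate plain PCA on the individuals of each species,
  with zero-variance traits dropped (reducing k) and the verdict left
  undefined where one of the four traits does not vary;
* cross-level -- project each species' standardized individuals onto the
  interspecific axes, compare rotated pPC1 variance shares with the
  interspecific pPC1 share, and fit the generation-time regressions.

Failures in one species' within-population analysis are isolated and
logged; they never abort the interspecific stage.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .ordination import (
    OrdinationResult,
    TransformedMatrix,
    broken_stick,
    canonicalize_signs,
    pca,
    phylo_pca,
    retain_components,
    transform,
)
from .phylo import average_tree, read_newick_file, vcv_matrix, write_newick
from .records import (
    TRAITS,
    aggregate_species,
    coefficient_of_variation,
    read_records_csv,
    traits_table,
    write_table_csv,
)
from .slowfast import (
    ProjectionResult,
    SlowFastVerdict,
    VerdictUndefined,
    cross_level_report,
    data_ellipse,
    ols,
    project_individuals,
    slow_fast_verdict,
)

log = logging.getLogger("pacelife")


@dataclass
class RunConfig:
    """Validated options for a pipeline run."""

    records: Path
    trees: Path | None = None
    outdir: Path = Path("pacelife_out")
    aggregation: str = "mean"
    fecundity_plus_one: bool = True
    coverage: float = 0.95
    min_individuals: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        self.records = Path(self.records)
        if self.trees is not None:
            self.trees = Path(self.trees)
        self.outdir = Path(self.outdir)
        if not 0 < self.coverage < 1:
            raise ValueError("coverage must be in (0, 1)")


@dataclass
class InterspecificOutcome:
    average: OrdinationResult
    verdict: SlowFastVerdict
    bs: np.ndarray
    per_tree_p1: list[float]
    species_table: pd.DataFrame
    Z: TransformedMatrix
    ridge_events: list = field(default_factory=list)
    average_tree_newick: str = ""


def run_interspecific(
    individual_traits: pd.DataFrame,
    trees,
    aggregation: str = "mean",
    fecundity_plus_one: bool = True,
) -> InterspecificOutcome:
    """One pPCA per tree plus one on the average tree, with the verdict."""
    species_table = aggregate_species(individual_traits, aggregation)
    if len(species_table) < 2:
        raise ValueError("interspecific analysis needs at least 2 species")
    Z = transform(
        species_table[list(TRAITS)], fecundity_plus_one=fecundity_plus_one
    )
    order = Z.row_labels
    ridge_events: list = []
    per_tree_p1 = []
    for tree in trees:
        C = vcv_matrix(tree, order)
        res = phylo_pca(Z, C, ridge_log=ridge_events)
        per_tree_p1.append(float(res.proportions[0]))
    avg = average_tree(list(trees))
    C = vcv_matrix(avg, order)
    result = phylo_pca(Z, C, ridge_log=ridge_events)
    canonicalize_signs(result)
    bs = broken_stick(result.k)
    retain_components(result, bs)
    verdict = slow_fast_verdict(result, bs)
    return InterspecificOutcome(
        average=result,
        verdict=verdict,
        bs=bs,
        per_tree_p1=per_tree_p1,
        species_table=species_table,
        Z=Z,
        ridge_events=ridge_events,
        average_tree_newick=write_newick(avg),
    )


@dataclass
class WithinOutcome:
    results: dict[str, OrdinationResult]
    verdicts: dict[str, SlowFastVerdict | None]
    skipped: dict[str, str]
    dropped: dict[str, list[str]]


def run_within(
    individual_traits: pd.DataFrame,
    fecundity_plus_one: bool = True,
    min_individuals: int = 3,
) -> WithinOutcome:
    """Species-specific PCAs on individual data, one species at a time."""
    results: dict[str, OrdinationResult] = {}
    verdicts: dict[str, SlowFastVerdict | None] = {}
    skipped: dict[str, str] = {}
    dropped: dict[str, list[str]] = {}
    for sp, sub in individual_traits.groupby("species"):
        if len(sub) < min_individuals:
            skipped[sp] = f"only {len(sub)} individuals (< {min_individuals})"
            log.info("skipping %s: %s", sp, skipped[sp])
            continue
        try:
            Z = transform(
                sub[list(TRAITS)],
                fecundity_plus_one=fecundity_plus_one,
                on_constant="drop",
            )
            dropped[sp] = list(Z.dropped)
            result = pca(Z)
            anchor = (
                "adult_lifespan"
                if "adult_lifespan" in result.columns
                else result.columns[0]
            )
            canonicalize_signs(result, anchor_trait=anchor)
            bs = broken_stick(result.k)
            retain_components(result, bs)
            results[sp] = result
            try:
                verdicts[sp] = slow_fast_verdict(result, bs)
            except VerdictUndefined as exc:
                verdicts[sp] = None
                log.info("verdict undefined for %s: %s", sp, exc)
        except Exception as exc:  # isolate per-species failures
            skipped[sp] = str(exc)
            log.warning("within-population analysis failed for %s: %s", sp, exc)
    return WithinOutcome(
        results=results, verdicts=verdicts, skipped=skipped, dropped=dropped
    )


def run_projection(
    individual_traits: pd.DataFrame,
    interspecific: OrdinationResult,
    fecundity_plus_one: bool = True,
    min_individuals: int = 2,
) -> ProjectionResult:
    """Standardize individuals within species, rotate by the pPCA axes.

    Traits that do not vary within a species are standardized to an
    all-zero column so the column set stays aligned with the loadings; a
    constant trait simply contributes nothing to that species' cloud.
    """
    Z_by_species: dict[str, TransformedMatrix] = {}
    cols = list(interspecific.columns)
    for sp, sub in individual_traits.groupby("species"):
        if len(sub) < min_individuals:
            continue
        Z = transform(
            sub[cols], fecundity_plus_one=fecundity_plus_one, on_constant="zero"
        )
        Z_by_species[sp] = Z
    if not Z_by_species:
        raise ValueError("no species with enough individuals to project")
    return project_individuals(Z_by_species, interspecific)


# ---------------------------------------------------------------------------
# consolidated report


def _safe_ols(x, y) -> dict:
    try:
        fit = ols(x, y)
        return dataclasses.asdict(fit)
    except ValueError as exc:
        return {"error": str(exc)}


def cv_comparison(
    individual_traits: pd.DataFrame, species_table: pd.DataFrame
) -> pd.DataFrame:
    """Across-species CV of each trait vs its mean within-species CV."""
    rows = []
    for trait in TRAITS:
        across = coefficient_of_variation(species_table[trait].dropna())
        within = []
        for _, sub in individual_traits.groupby("species"):
            v = sub[trait].dropna()
            if len(v) >= 2 and v.mean() != 0:
                within.append(coefficient_of_variation(v))
        mean_within = float(np.mean(within)) if within else math.nan
        rows.append(
            {
                "trait": trait,
                "cv_across_species": across,
                "mean_cv_within_species": mean_within,
                "ratio": across / mean_within if within else math.nan,
            }
        )
    return pd.DataFrame(rows).set_index("trait")


def run_report(config: RunConfig) -> dict:
    """Full pipeline from files on disk to a consolidated output directory."""
    records = read_records_csv(config.records)
    individual_traits = traits_table(records)
    if config.trees is None:
        raise ValueError("interspecific stage needs a tree file")
    trees = read_newick_file(config.trees)

    inter = run_interspecific(
        individual_traits, trees, config.aggregation, config.fecundity_plus_one
    )
    within = run_within(
        individual_traits, config.fecundity_plus_one, config.min_individuals
    )
    projections = run_projection(
        individual_traits, inter.average, config.fecundity_plus_one
    )
    table, within_spectrum = cross_level_report(
        inter.average, projections, within.results, within.verdicts, inter.bs
    )

    # generation-time regressions
    species_scores = inter.average.scores_frame()["PC1"]
    gt = inter.species_table.loc[species_scores.index, "generation_time"]
    ok = gt > 0
    regressions = {
        "species_pc1_vs_log_generation_time": _safe_ols(
            np.log(gt[ok]), species_scores[ok]
        ),
        "within_p1_vs_log_generation_time": _safe_ols(
            np.log(gt[ok & gt.index.isin(table.index)]),
            table.loc[gt[ok & gt.index.isin(table.index)].index, "own_p1"],
        ),
    }
    per_species_gt: dict[str, dict] = {}
    for sp, res in within.results.items():
        sub = individual_traits[individual_traits["species"] == sp]
        g = sub["generation_time"]
        scores = res.scores_frame()["PC1"]
        mask = g.notna() & (g > 0)
        if mask.sum() >= 3:
            per_species_gt[sp] = _safe_ols(
                np.log(g[mask]), scores.to_numpy()[mask.to_numpy()]
            )
    regressions["individual_pc1_vs_log_generation_time"] = per_species_gt

    # 95% data ellipses of rotated individual clouds (PC1 x PC2)
    ellipse_rows = []
    for sp, U in projections.scores.items():
        if U.shape[0] >= 3 and U.shape[1] >= 2:
            e = data_ellipse(U[:, :2], config.coverage)
            ellipse_rows.append(
                {
                    "species": sp,
                    "center_x": e.center[0],
                    "center_y": e.center[1],
                    "semi_major": e.semi_axes[0],
                    "semi_minor": e.semi_axes[1],
                    "angle_rad": e.angle,
                    "degenerate": e.degenerate,
                }
            )
    ellipses = pd.DataFrame(ellipse_rows).set_index("species") if ellipse_rows else None

    cv_table = cv_comparison(individual_traits, inter.species_table)

    manifest = {
        "package_version": __version__,
        "seed": config.seed,
        "aggregation": config.aggregation,
        "fecundity_plus_one": config.fecundity_plus_one,
        "n_species": int(len(inter.species_table)),
        "n_individuals": int(len(individual_traits)),
        "n_trees": len(trees),
        "average_tree_method": "mean-patristic+NJ",
        "interspecific": {
            "p1_average_tree": inter.verdict.p1,
            "p1_across_trees": {
                "min": float(np.min(inter.per_tree_p1)),
                "median": float(np.median(inter.per_tree_p1)),
                "max": float(np.max(inter.per_tree_p1)),
            },
            "verdict_present": inter.verdict.present,
            "sign_flips": inter.average.sign_flips,
            "dropped_traits": inter.Z.dropped,
            "ridge_regularizations": len(inter.ridge_events),
        },
        "within": {
            "dropped_traits": within.dropped,
            "skipped": within.skipped,
            "sign_flips": {
                sp: res.sign_flips for sp, res in within.results.items()
            },
        },
    }

    outputs = {
        "interspecific": inter,
        "within": within,
        "projections": projections,
        "cross_level": table,
        "within_spectrum": within_spectrum,
        "regressions": regressions,
        "cv_table": cv_table,
        "ellipses": ellipses,
        "manifest": manifest,
        "individual_traits": individual_traits,
    }
    _write_outputs(config, outputs)
    return outputs


def _write_outputs(config: RunConfig, outputs: dict) -> None:
    out = config.outdir
    out.mkdir(parents=True, exist_ok=True)
    inter: InterspecificOutcome = outputs["interspecific"]
    meta = {"aggregation_statistic": config.aggregation}
    write_table_csv(inter.species_table, out / "species_traits.csv", meta)
    write_table_csv(
        outputs["individual_traits"], out / "individual_traits.csv", meta
    )
    inter.average.loadings_frame().to_csv(out / "interspecific_loadings.csv")
    inter.average.scores_frame().to_csv(out / "interspecific_scores.csv")
    pd.DataFrame(
        {
            "eigenvalue": inter.average.eigenvalues,
            "proportion": inter.average.proportions,
            "broken_stick": inter.bs,
            "retained": inter.average.retained,
        },
        index=[f"PC{i + 1}" for i in range(inter.average.k)],
    ).to_csv(out / "interspecific_eigen.csv")
    outputs["cross_level"].to_csv(out / "cross_level_report.csv")
    outputs["within_spectrum"].to_csv(out / "within_spectrum.csv")
    outputs["cv_table"].to_csv(out / "cv_comparison.csv")
    if outputs["ellipses"] is not None:
        outputs["ellipses"].to_csv(out / "ellipses.csv")
    (out / "regressions.json").write_text(
        json.dumps(outputs["regressions"], indent=1, sort_keys=True) + "\n"
    )
    (out / "manifest.json").write_text(
        json.dumps(outputs["manifest"], indent=1, sort_keys=True) + "\n"
    )
    (out / "average_tree.nwk").write_text(inter.average_tree_newick + "\n")
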