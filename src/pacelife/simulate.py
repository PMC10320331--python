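"""Synthetic phylogenies, species means and individual life histories.

The generator mirrors the structure of a comparative life-history study:

* a pure-birth (Yule) phylogeny for ``n_species`` tips;
* a latent "pace" value g per species evolving by Brownian motion on the
  tree (variance ``sigma2_pace`` accrued over one tree depth), mapped to
  the four traits on the log scale as ``log trait = alpha_t + beta_t * g``
  with negative slopes for the duration traits and positive slopes for
  the frequency traits -- so the species means carry a genuine slow-fast
  axis;
* individual life histories under four competing within-species regimes:

  - ``A`` shared pace axis: each individual shifts all four traits
    coherently along the same slopes (a real within-population
    continuum);
  - ``B`` idiosyncratic noise: independent log-normal noise per trait
    (variation with no axis);
  - ``C`` event-level demographic stochasticity: whole life courses are
    drawn year by year -- survive, attempt, produce offspring -- from the
    species-level rates, so between-individual variation is chance alone;
  - ``D`` acquisition heterogeneity: a per-individual resource-acquisition
    multiplier raises survival and fecundity together, masking the
    survival-reproduction trade-off with positive trait correlations.

Regimes A/B synthesize records that reproduce target trait values;
regimes C/D emit genuine year-by-year histories so the whole
record-to-trait pipeline is exercised, not bypassed.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd
import yaml

from .records import TRAITS, BreedingEvent, IndividualRecord
from .phylo import write_newick

__all__ = [
    "GeneratorConfig",
    "GroundTruth",
    "simulate_tree",
    "simulate_species_means",
    "simulate_individuals",
    "make_fixture",
]

REGIMES = ("A", "B", "C", "D")


@dataclass
class GeneratorConfig:
    """All knobs of the generator; defaults define the study conditions."""

    n_species: int = 17
    birth_rate: float = 1.0
    #: Brownian variance of the latent pace axis accrued over one tree depth
    sigma2_pace: float = 1.0
    #: per-trait intercept on the log scale (afr, adult_lifespan,
    #: breeding_frequency, fecundity); units log-years / log-per-year
    alpha: tuple[float, float, float, float] = (1.0, 1.6, -0.3, -0.5)
    #: per-trait slope on the latent pace axis; duration traits negative,
    #: frequency traits positive so fast species mature early, die young,
    #: breed often
    beta: tuple[float, float, float, float] = (-0.4, -0.8, 0.3, 0.5)
    #: log-scale residual sd of species means around the pace line
    species_residual_sd: float = 0.05
    regime: str = "C"
    n_individuals: int = 100
    # regime A: sd of the individual pace shift and of trait-level noise
    pace_sd: float = 0.3
    pace_noise_sd: float = 0.02
    # regime B: independent per-trait log-scale noise
    trait_noise_sd: float = 0.3
    # regime C: geometric jitter parameter for individual maturity age
    afr_jitter_p: float = 0.5
    # regime D: log-scale sd of the acquisition multiplier
    acquisition_sd: float = 0.5
    # fixture: number of trees written (true tree + jittered replicates)
    n_trees: int = 1
    tree_jitter_sd: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.regime not in REGIMES:
            raise ValueError(f"regime must be one of {REGIMES}")
        if self.n_species < 2:
            raise ValueError("need at least 2 species")
        for name in (
            "sigma2_pace", "species_residual_sd", "pace_sd", "pace_noise_sd",
            "trait_noise_sd", "acquisition_sd", "tree_jitter_sd",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0 < self.afr_jitter_p <= 1:
            raise ValueError("afr_jitter_p must be in (0, 1]")


@dataclass
class GroundTruth:
    """Latent values behind a simulated data set, keyed by emitted ids."""

    regime: str
    species_pace: dict[str, float] = field(default_factory=dict)
    individual_latent: dict[str, float] = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=1, sort_keys=True)


def simulate_tree(
    n_species: int, birth_rate: float, rng: np.random.Generator
) -> dendropy.Tree:
    """Pure-birth tree with exponential waiting times; ultrametric.

    Starts from a root split into two lineages; while fewer than
    ``n_species`` lineages exist the next speciation waits
    Exp(k * birth_rate) and hits a uniformly chosen lineage; a final
    Exp(n * birth_rate) wait sets the present.
    """
    if n_species < 2:
        raise ValueError("need at least 2 tips")
    tns = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=tns)
    root = tree.seed_node
    t = 0.0
    active: list[tuple[dendropy.Node, float]] = []
    for _ in range(2):
        child = dendropy.Node()
        root.add_child(child)
        active.append((child, 0.0))
    while len(active) < n_species:
        t += rng.exponential(1.0 / (birth_rate * len(active)))
        i = int(rng.integers(len(active)))
        node, born = active.pop(i)
        node.edge.length = t - born
        for _ in range(2):
            child = dendropy.Node()
            node.add_child(child)
            active.append((child, t))
    t += rng.exponential(1.0 / (birth_rate * len(active)))
    for node, born in active:
        node.edge.length = t - born
    width = len(str(n_species))
    for i, leaf in enumerate(tree.leaf_node_iter(), start=1):
        taxon = tns.new_taxon(f"sp{i:0{width}d}")
        leaf.taxon = taxon
    tree.is_rooted = True
    return tree


def _tree_depth(tree: dendropy.Tree) -> float:
    def root_dist(leaf):
        d, node = 0.0, leaf
        while node.parent_node is not None:
            d += node.edge.length or 0.0
            node = node.parent_node
        return d

    return max(root_dist(leaf) for leaf in tree.leaf_node_iter())


def _brownian_tips(
    tree: dendropy.Tree, sigma2: float, rng: np.random.Generator
) -> dict[str, float]:
    """Brownian motion from the root; variance sigma2 over one tree depth."""
    depth = _tree_depth(tree)
    scale = sigma2 / depth if depth > 0 else 0.0
    values: dict[int, float] = {id(tree.seed_node): 0.0}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        parent = values[id(node.parent_node)]
        var = scale * (node.edge.length or 0.0)
        values[id(node)] = parent + (
            rng.normal(0.0, np.sqrt(var)) if var > 0 else 0.0
        )
    return {
        leaf.taxon.label: values[id(leaf)] for leaf in tree.leaf_node_iter()
    }


def simulate_species_means(
    tree: dendropy.Tree,
    config: GeneratorConfig,
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Species mean traits structured by a latent pace axis on the tree.

    Returns the natural-scale species table (rows sorted by tip label,
    columns in canonical trait order) and the latent pace values.
    """
    pace = _brownian_tips(tree, config.sigma2_pace, rng)
    species = sorted(pace)
    alpha = np.asarray(config.alpha, dtype=float)
    beta = np.asarray(config.beta, dtype=float)
    rows = []
    for sp in species:
        resid = rng.normal(0.0, config.species_residual_sd, size=len(TRAITS))
        log_traits = alpha + beta * pace[sp] + resid
        rows.append(np.exp(log_traits))
    table = pd.DataFrame(rows, index=pd.Index(species, name="species"),
                         columns=list(TRAITS))
    truth = GroundTruth(regime=config.regime, species_pace=dict(pace))
    return table, truth


# ---------------------------------------------------------------------------
# individual life histories


def _record_from_traits(
    iid: str, species: str, afr: float, lifespan: float,
    breeding_frequency: float, fecundity: float,
) -> IndividualRecord:
    """Synthesize a breeding record whose computed traits match the targets.

    Attempts are spread evenly over the adult lifespan and the (rounded)
    total offspring distributed as evenly as possible across attempts;
    the count round-off is the only deviation from the targets.
    """
    denom = max(lifespan, 1.0)
    n_attempts = max(1, round(breeding_frequency * denom))
    total_offspring = max(0, round(fecundity * denom))
    if n_attempts == 1:
        ages = [afr]
    else:
        ages = list(np.linspace(afr, afr + lifespan, n_attempts))
    base, extra = divmod(total_offspring, n_attempts)
    events = [
        BreedingEvent(age=a, attempted=True,
                      offspring=base + (1 if i < extra else 0))
        for i, a in enumerate(ages)
    ]
    return IndividualRecord(
        individual_id=iid, species=species, events=events,
        death_age=afr + lifespan,
    )


def _stochastic_history(
    iid: str, species: str, afr_i: int, p_survive: float, p_attempt: float,
    mean_offspring: float, rng: np.random.Generator,
) -> IndividualRecord:
    """One year-by-year life course; the first adult year always attempts.

    Death is recorded at the end of the final breeding season (last event
    age + 1): the individual lived through that season, so adult lifespan
    is at least one year and stays on the log scale downstream.
    """
    events = []
    age = afr_i
    first = True
    while True:
        attempted = first or (rng.random() < p_attempt)
        offspring = int(rng.poisson(mean_offspring)) if attempted else 0
        events.append(BreedingEvent(age=float(age), attempted=attempted,
                                    offspring=offspring))
        first = False
        if rng.random() >= p_survive:
            break
        age += 1
    return IndividualRecord(
        individual_id=iid, species=species, events=events,
        death_age=float(age) + 1.0,
    )


def simulate_individuals(
    species_means: pd.DataFrame,
    config: GeneratorConfig,
    rng: np.random.Generator,
    truth: GroundTruth | None = None,
) -> tuple[list[IndividualRecord], GroundTruth]:
    """Individual records for every species under the configured regime."""
    truth = truth or GroundTruth(regime=config.regime)
    truth.regime = config.regime
    records: list[IndividualRecord] = []
    beta = np.asarray(config.beta, dtype=float)
    for sp, row in species_means.iterrows():
        afr_s, al_s, bf_s, f_s = (float(row[t]) for t in TRAITS)
        if min(afr_s, al_s, bf_s) <= 0 or f_s < 0:
            raise ValueError(
                f"species {sp!r}: non-viable rates "
                f"(afr={afr_s}, lifespan={al_s}, frequency={bf_s})"
            )
        log_means = np.log([afr_s, al_s, bf_s, f_s + 1e-12])
        for j in range(config.n_individuals):
            iid = f"{sp}_i{j + 1:04d}"
            if config.regime == "A":
                delta = rng.normal(0.0, config.pace_sd)
                noise = rng.normal(0.0, config.pace_noise_sd, size=4)
                vals = np.exp(log_means + beta * delta + noise)
                records.append(_record_from_traits(iid, sp, *vals))
                truth.individual_latent[iid] = float(delta)
            elif config.regime == "B":
                noise = rng.normal(0.0, config.trait_noise_sd, size=4)
                vals = np.exp(log_means + noise)
                records.append(_record_from_traits(iid, sp, *vals))
                truth.individual_latent[iid] = 0.0
            elif config.regime == "C":
                afr_i = max(1, round(afr_s)) + int(
                    rng.geometric(config.afr_jitter_p) - 1
                )
                rec = _stochastic_history(
                    iid, sp, afr_i,
                    p_survive=float(np.exp(-1.0 / al_s)),
                    p_attempt=min(1.0, bf_s),
                    mean_offspring=f_s / bf_s,
                    rng=rng,
                )
                records.append(rec)
                truth.individual_latent[iid] = 0.0
            else:  # regime D
                q = float(np.exp(rng.normal(0.0, config.acquisition_sd)))
                afr_i = max(1, round(afr_s)) + int(
                    rng.geometric(config.afr_jitter_p) - 1
                )
                rec = _stochastic_history(
                    iid, sp, afr_i,
                    p_survive=float(np.exp(-1.0 / (al_s * q))),
                    p_attempt=min(1.0, bf_s),
                    mean_offspring=q * f_s / bf_s,
                    rng=rng,
                )
                records.append(rec)
                truth.individual_latent[iid] = q
    return records, truth


# ---------------------------------------------------------------------------
# fixture on disk


def _jittered_tree(
    tree: dendropy.Tree, sd: float, rng: np.random.Generator
) -> dendropy.Tree:
    clone = tree.clone(depth=1)
    for edge in clone.preorder_edge_iter():
        if edge.length is not None:
            edge.length = edge.length * float(np.exp(rng.normal(0.0, sd)))
    return clone


def records_to_frame(records: list[IndividualRecord]) -> pd.DataFrame:
    rows = []
    for rec in records:
        for e in rec.events:
            rows.append(
                {
                    "individual_id": rec.individual_id,
                    "species": rec.species,
                    "age": e.age,
                    "attempted": int(e.attempted),
                    "offspring": e.offspring,
                    "death_age": rec.death_age,
                }
            )
    return pd.DataFrame(rows)


def make_fixture(config: GeneratorConfig, outdir) -> dict[str, Path]:
    """Write a complete runnable input set: records, trees, truth, config."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    tree = simulate_tree(config.n_species, config.birth_rate, rng)
    means, truth = simulate_species_means(tree, config, rng)
    records, truth = simulate_individuals(means, config, rng, truth)

    paths = {
        "records": outdir / "records.csv",
        "trees": outdir / "trees.nwk",
        "ground_truth": outdir / "ground_truth.json",
        "config": outdir / "config.yaml",
    }
    records_to_frame(records).to_csv(
        paths["records"], index=False, float_format="%.10g"
    )
    with open(paths["trees"], "w") as fh:
        fh.write(write_newick(tree) + "\n")
        for _ in range(max(0, config.n_trees - 1)):
            fh.write(
                write_newick(_jittered_tree(tree, config.tree_jitter_sd, rng))
                + "\n"
            )
    paths["ground_truth"].write_text(truth.to_json() + "\n")
    paths["config"].write_text(
        yaml.safe_dump(dataclasses.asdict(config), sort_keys=True)
    )
    return paths
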