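"""Synthetic trees and allometrically structured traits with known truth.

The generator emulates the statistical structure the comparative analyses
assume: a time-calibrated pure-birth phylogeny, a latent log body size
(ln toL) evolving by Brownian motion, the remaining traits scaling
log-linearly with size with phylogenetically correlated (Brownian) residuals,
additive log-scale sexual dimorphism, a couple of measured individuals per
species and sex, and missing predictor values injected completely at random.

Defaults mirror the buthid study conditions: 195 species, two individuals per
sex, 13% maximum missingness, total length spanning roughly 12-120 mm with a
tree depth of ~50 My.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping

import numpy as np
import pandas as pd

from .tree import PhyloTree
from .traits import PREDICTOR_ONLY_TRAITS, SEXES, TRAITS, TraitMatrix, species_means


@dataclass(frozen=True)
class TraitLaw:
    """Allometric law ln(trait) = a + b * ln(toL) + Brownian residual."""

    a: float
    b: float
    sigma2_resid: float = 3e-4   # residual BM rate per My on log scale


#: per-trait allometric laws giving realistically sized body parts for a
#: 50 mm scorpion (e.g. carapace ~5.5 mm, metasomal segment V ~7 mm)
DEFAULT_TRAIT_LAWS: dict[str, TraitLaw] = {
    "carL": TraitLaw(a=-2.20, b=1.00),
    "cheL": TraitLaw(a=-2.00, b=1.00),
    "cheW": TraitLaw(a=-3.30, b=1.00),
    "met5L": TraitLaw(a=-2.05, b=1.05),
    "met5W": TraitLaw(a=-3.40, b=0.90),
    "teL": TraitLaw(a=-2.10, b=0.95),
    "teW": TraitLaw(a=-3.40, b=0.95),
}


@dataclass
class AllometryScenario:
    """Ground-truth configuration for one simulated data set."""

    n_species: int = 195
    birth_rate: float = 0.1            # speciations per lineage per My
    sigma2_size: float = 3e-3          # BM rate of latent ln(toL), per My
    root_log_size: float = np.log(50.0)
    trait_laws: Mapping[str, TraitLaw] = field(
        default_factory=lambda: dict(DEFAULT_TRAIT_LAWS)
    )
    sex_offset: float | Mapping[str, float] = 0.06  # female minus male, log scale
    individual_sd: float = 0.05        # within-species log-scale noise
    n_individuals: int = 2             # per species per sex
    missing_fraction: float = 0.13     # MCAR rate on predictor-only traits
    seed: int | None = None

    def __post_init__(self):
        if self.n_species < 2:
            raise ValueError("n_species must be >= 2")
        if self.birth_rate <= 0 or self.sigma2_size < 0:
            raise ValueError("rates must be positive")
        if not 0 <= self.missing_fraction < 1:
            raise ValueError("missing_fraction must be in [0, 1)")
        unknown = set(self.trait_laws) - set(TRAITS)
        if unknown:
            raise ValueError(f"unknown traits in trait_laws: {sorted(unknown)}")

    def offset_for(self, trait: str) -> float:
        if isinstance(self.sex_offset, Mapping):
            return float(self.sex_offset.get(trait, 0.0))
        return float(self.sex_offset)


@dataclass
class SimulatedDataset:
    """Generator output: data plus the truth channel downstream tests use."""

    tree: PhyloTree
    records: pd.DataFrame          # individual rows: species, sex, trait, value_mm
    truth_log: TraitMatrix         # complete species x sex log means (no noise)
    observed: TraitMatrix          # species means from records, mask injected (mm)
    scenario: AllometryScenario

    def truth_sidecar(self) -> dict:
        """JSON-serializable ground-truth summary."""
        sc = asdict(self.scenario)
        sc["trait_laws"] = {t: asdict(v) for t, v in self.scenario.trait_laws.items()}
        sc["root_log_size"] = float(sc["root_log_size"])
        return sc


# ------------------------------------------------------------------ trees


class _Lineage:
    __slots__ = ("birth", "children", "split")

    def __init__(self, birth: float):
        self.birth = birth
        self.children: list["_Lineage"] = []
        self.split: float | None = None


def simulate_tree(
    n_tips: int,
    birth_rate: float = 0.1,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> PhyloTree:
    """Pure-birth (Yule) ultrametric tree with ``n_tips`` labelled tips.

    The process starts at the crown (two lineages); with k extant lineages
    the waiting time to the next speciation is Exponential(birth_rate * k)
    and the splitting lineage is uniform.  A final Exponential(birth_rate *
    n_tips) stretch is appended so the last-born tips have positive branch
    lengths.  Deterministic under a fixed seed.
    """
    if n_tips < 2:
        raise ValueError("n_tips must be >= 2")
    if rng is None:
        rng = np.random.default_rng(seed)
    root = _Lineage(0.0)
    root.split = 0.0
    active = [_Lineage(0.0), _Lineage(0.0)]
    root.children = list(active)
    t = 0.0
    k = 2
    while k < n_tips:
        t += rng.exponential(1.0 / (birth_rate * k))
        i = int(rng.integers(k))
        parent = active[i]
        parent.split = t
        parent.children = [_Lineage(t), _Lineage(t)]
        active[i] = parent.children[0]
        active.append(parent.children[1])
        k += 1
    t_end = t + rng.exponential(1.0 / (birth_rate * n_tips))

    width = len(str(n_tips))
    counter = iter(range(1, n_tips + 1))

    def newick(node: _Lineage) -> str:
        if not node.children:
            label = f"s{next(counter):0{width}d}"
            return f"{label}:{t_end - node.birth:.10g}"
        inner = ",".join(newick(c) for c in node.children)
        length = (node.children[0].birth) - node.birth
        return f"({inner}):{length:.10g}"

    text = "(" + ",".join(newick(c) for c in root.children) + ");"
    return PhyloTree.from_newick(text)


# ---------------------------------------------------------------- traits


def simulate_bm(
    tree: PhyloTree,
    sigma2: float,
    root_value: float = 0.0,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> pd.Series:
    """Brownian-motion tip values: MVN(root_value, sigma2 * C)."""
    if sigma2 < 0:
        raise ValueError("sigma2 must be >= 0")
    if rng is None:
        rng = np.random.default_rng(seed)
    labels = tree.tip_labels
    if sigma2 == 0:
        return pd.Series(root_value, index=labels)
    C = tree.covariance().to_numpy()
    L = np.linalg.cholesky(sigma2 * C + 1e-12 * np.eye(len(labels)))
    vals = root_value + L @ rng.standard_normal(len(labels))
    return pd.Series(vals, index=labels)


def simulate_traits(
    scenario: AllometryScenario,
    tree: PhyloTree | None = None,
) -> SimulatedDataset:
    """Simulate individual records and their species-level ground truth.

    The latent size axis is ln(toL) itself.  Every other trait obeys its
    :class:`TraitLaw` with a Brownian residual; sexes differ by an additive
    log-scale offset (female = +offset/2, male = -offset/2); individuals add
    i.i.d. Normal(0, individual_sd) log-scale noise; predictor-only traits are
    masked completely at random at ``missing_fraction``.
    """
    rng = np.random.default_rng(scenario.seed)
    if tree is None:
        tree = simulate_tree(scenario.n_species, scenario.birth_rate, rng=rng)
    species = tree.tip_labels

    latent = simulate_bm(
        tree, scenario.sigma2_size, scenario.root_log_size, rng=rng
    )
    log_means: dict[str, pd.Series] = {"toL": latent}
    for trait, law in scenario.trait_laws.items():
        resid = simulate_bm(tree, law.sigma2_resid, 0.0, rng=rng)
        log_means[trait] = law.a + law.b * latent + resid

    sign = {"female": 0.5, "male": -0.5}
    truth_rows = {}
    for sex in SEXES:
        frame = pd.DataFrame(
            {
                t: log_means[t] + sign[sex] * scenario.offset_for(t)
                for t in log_means
            }
        )
        truth_rows[sex] = frame
    truth = pd.concat(truth_rows, names=["sex", "species"]).swaplevel().sort_index()
    cols = [t for t in TRAITS if t in truth.columns]
    truth_log = TraitMatrix(truth[cols], scale="log")

    recs = []
    for sex in SEXES:
        tab = truth_rows[sex]
        for trait in cols:
            mu = tab[trait].to_numpy()
            noise = rng.normal(
                0.0, scenario.individual_sd, size=(len(species), scenario.n_individuals)
            )
            vals = np.exp(mu[:, None] + noise)
            for j, sp in enumerate(species):
                for m in range(scenario.n_individuals):
                    recs.append((sp, sex, trait, vals[j, m]))
    records = pd.DataFrame(recs, columns=["species", "sex", "trait", "value_mm"])

    observed = species_means(records)
    if scenario.missing_fraction > 0:
        data = observed.data.copy()
        for sex in SEXES:
            sub = data.xs(sex, level="sex", drop_level=False)
            n = len(sub)
            n_mask = int(round(scenario.missing_fraction * n))
            for trait in PREDICTOR_ONLY_TRAITS:
                if trait not in data.columns or n_mask == 0:
                    continue
                rows = rng.choice(n, size=n_mask, replace=False)
                data.loc[sub.index[rows], trait] = np.nan
        observed = TraitMatrix(data, scale="mm")

    return SimulatedDataset(
        tree=tree,
        records=records,
        truth_log=truth_log,
        observed=observed,
        scenario=scenario,
    )


def simulate_pmm_dataset(
    tree: PhyloTree,
    a: float = 2.13,
    b: float = 0.95,
    response: str = "toL",
    predictor: str = "met5L",
    sigma2_x: float = 3e-3,
    sigma2_phylo: float = 3e-4,
    sigma2_species: float = 5e-4,
    sigma2_resid: float = 1e-3,
    root_log_x: float = 1.9,
    sex_offset: float = 0.0,
    sex_slope_offset: float = 0.0,
    seed: int | None = None,
) -> TraitMatrix:
    """Simulate records exactly under the phylogenetic mixed model.

    The log predictor evolves by Brownian motion; each species contributes
    one record per sex with

        y = a + (b + s * sex_slope_offset) x + s * sex_offset
            + u_phylo + u_species + e,

    where s is -1/2 for females and +1/2 for males, u_phylo is Brownian with
    rate ``sigma2_phylo``, u_species ~ N(0, sigma2_species) and
    e ~ N(0, sigma2_resid) per record.  Because the predictor enters without
    error, the regression slope equals ``b`` exactly — the right testbed for
    parameter-recovery and sampler-vs-oracle checks.  Returns a complete
    log-scale :class:`TraitMatrix` with the two columns.
    """
    rng = np.random.default_rng(seed)
    x = simulate_bm(tree, sigma2_x, root_log_x, rng=rng)
    u_phylo = simulate_bm(tree, sigma2_phylo, 0.0, rng=rng)
    species = tree.tip_labels
    n = len(species)
    u_species = rng.normal(0.0, np.sqrt(sigma2_species), size=n)
    sign = {"female": -0.5, "male": 0.5}
    rows = {}
    for sex in SEXES:
        e = rng.normal(0.0, np.sqrt(sigma2_resid), size=n)
        y = (
            a
            + (b + sign[sex] * sex_slope_offset) * x.to_numpy()
            + sign[sex] * sex_offset
            + u_phylo.to_numpy()
            + u_species
            + e
        )
        rows[sex] = pd.DataFrame(
            {response: y, predictor: x.to_numpy()}, index=species
        )
    frame = pd.concat(rows, names=["sex", "species"]).swaplevel().sort_index()
    return TraitMatrix(frame, scale="log")
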