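"""Synthetic meal-level dietary cohort with planted network structure.

The generator emulates the data structure the pipeline assumes: participants
complete up to three recall days (one per trimester), each day holds breakfast,
lunch, dinner and a small number of snacks, and intake over 40 food groups is
episodic (zero-inflated) with participant-level clustering.

The statistical mechanism is a latent-Gaussian single hurdle. Per meal type and
diet-quality stratum a sparse precision matrix Theta* is planted; its implied
correlation Sigma* drives a latent vector

    Z = sqrt(rho_b) * U_participant + sqrt(1 - rho_b) * eps,   eps ~ N(0, Sigma*)

and food group g is consumed iff Z_g exceeds the threshold tau_g matched to the
target prevalence pi_g, with gram amount exp(mu_g + sigma_g * Z_g) when
consumed. A single latent correlation therefore governs both occurrence and
amount, which is exactly the structure the rank-based copula network estimator
is designed to partially observe; the equicorrelated participant term makes
the between-participant ICC of the latent scale equal rho_b by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from .core_data import MEAL_TYPES, FoodGroupTaxonomy, RecallRecord, default_food_groups
from .core_data import HEIStandards, example_hei_standards


@dataclass(frozen=True)
class PlantedEntry:
    """Planted truth for one (meal type, stratum) cell."""

    theta: np.ndarray        # sparse precision, unit diagonal
    sigma: np.ndarray        # implied latent correlation (unit diagonal)
    edges: frozenset         # {(i, j): theta_ij != 0, i < j}
    tau: np.ndarray          # consumption thresholds
    prevalence: np.ndarray   # target prevalence pi_g

    @property
    def partial_correlations(self) -> np.ndarray:
        d = np.sqrt(np.diag(self.theta))
        p = -self.theta / np.outer(d, d)
        np.fill_diagonal(p, 1.0)
        return p


@dataclass
class PlantedModel:
    """All planted (meal type x stratum) truth entries plus shared parameters."""

    entries: dict[tuple[str, str], PlantedEntry]
    rho_b: float
    groups: tuple[str, ...]


@dataclass
class GeneratorConfig:
    """Study-design and distributional knobs of the synthetic cohort.

    Defaults emulate the target cohort scale: ~120 participants per
    diet-quality stratum, up to three recall days each (one per trimester,
    most completing all three), three main meals plus 0-2 snacks per day,
    40 food groups with episodic consumption (target prevalence decaying
    geometrically from 0.6 to 0.03 so a realistic share of groups sits near
    the 5% analysis threshold), modest participant-level clustering
    (rho_b = 0.2, matching the mostly-low ICCs such cohorts show), and planted
    partial correlations of magnitude 0.25-0.45 on ~6% of pairs.
    """

    n_participants: int = 120
    strata: tuple[str, ...] = ("low", "mid", "high")
    network_strata: tuple[str, ...] = ("low", "high")
    recall_count_probs: tuple[float, ...] = (0.1, 0.2, 0.7)   # P(1), P(2), P(3) recalls
    snack_count_probs: tuple[float, ...] = (0.3, 0.5, 0.2)    # P(0), P(1), P(2) snacks
    n_groups: int = 40
    sparsity: float = 0.06
    strength_range: tuple[float, float] = (0.25, 0.45)
    prevalence_max: float = 0.6
    prevalence_min: float = 0.03
    rho_b: float = 0.2
    mu_log_g: float = 3.9       # log-gram location (~50 g typical portions)
    sigma_log_g: float = 0.6    # log-gram scale
    energy_density_kcal_g: float = 0.85  # calibrated so daily totals centre near 2600 kcal
    p_supper_label: float = 0.3     # dinners reported as "supper"
    p_drink_label: float = 0.05     # snacks reported as "just_a_drink"
    p_low_energy_recall: float = 0.02  # recalls rescaled to implausibly low energy
    codes_per_group: int = 2
    score_ranges: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: {"low": (30.0, 50.0), "mid": (51.0, 64.0), "high": (65.0, 90.0)})
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_groups < 2:
            raise ValueError("n_groups must be >= 2")
        if not 0 <= self.rho_b < 1:
            raise ValueError("rho_b must be in [0, 1)")
        if not (0 < self.prevalence_min <= self.prevalence_max <= 1):
            raise ValueError("prevalence bounds must satisfy 0 < min <= max <= 1")
        for probs, name in ((self.recall_count_probs, "recall_count_probs"),
                            (self.snack_count_probs, "snack_count_probs")):
            if abs(sum(probs) - 1.0) > 1e-9 or any(p < 0 for p in probs):
                raise ValueError(f"{name} must be nonnegative and sum to 1")
        if set(self.network_strata) - set(self.strata):
            raise ValueError("network_strata must be a subset of strata")
        if not 0 < self.sparsity < 1:
            raise ValueError("sparsity must be in (0, 1)")


def generate_sparse_precision(
    p: int,
    sparsity: float,
    strength_range: tuple[float, float],
    rng: np.random.Generator,
    *,
    min_eig: float = 0.05,
    max_tries: int = 50,
) -> tuple[np.ndarray, np.ndarray, frozenset]:
    """Sample a sparse SPD precision matrix with unit diagonal.

    Each off-diagonal pair enters the support independently with probability
    ``sparsity``; nonzero entries get magnitude uniform in ``strength_range``
    with random sign. With unit diagonal the planted partial correlation is
    simply -theta_ij. If the raw draw is not positive definite its diagonal is
    inflated by (|lambda_min| + min_eig) and rescaled back to unit diagonal,
    which shrinks partials but preserves the support; this repair is bounded by
    ``max_tries`` resamples if degeneracy persists.

    Returns ``(theta, sigma, edges)`` where ``sigma`` is the implied latent
    correlation matrix (unit diagonal) and ``edges`` the planted support.
    """
    if p < 2:
        raise ValueError("p must be >= 2")
    if not 0 <= sparsity < 1:
        raise ValueError("sparsity must be in [0, 1)")
    lo, hi = strength_range
    for _ in range(max_tries):
        theta = np.eye(p)
        iu = np.triu_indices(p, k=1)
        support = rng.random(len(iu[0])) < sparsity
        mags = rng.uniform(lo, hi, size=len(iu[0]))
        signs = rng.choice([-1.0, 1.0], size=len(iu[0]))
        vals = np.where(support, mags * signs, 0.0)
        theta[iu] = vals
        theta.T[iu] = vals
        lam = np.linalg.eigvalsh(theta)[0]
        if lam < min_eig:
            theta = theta + (abs(lam) + min_eig) * np.eye(p)
            d = np.sqrt(np.diag(theta))
            theta = theta / np.outer(d, d)
        if np.linalg.eigvalsh(theta)[0] > 0:
            break
    else:  # pragma: no cover - repair always succeeds after inflation
        raise RuntimeError("could not construct an SPD precision matrix")
    cov = np.linalg.inv(theta)
    d = np.sqrt(np.diag(cov))
    sigma = cov / np.outer(d, d)
    np.fill_diagonal(sigma, 1.0)
    edges = frozenset((int(i), int(j)) for i, j in zip(*iu) if theta[i, j] != 0.0)
    return theta, sigma, edges


def thresholds_from_prevalence(pi: np.ndarray) -> np.ndarray:
    """Latent thresholds tau_g with P(Z > tau_g) = pi_g for standard normal Z.

    pi = 1 gives tau = -inf (always consumed); pi must be strictly positive.
    """
    pi = np.asarray(pi, dtype=float)
    if np.any(pi <= 0) or np.any(pi > 1):
        raise ValueError("prevalence targets must lie in (0, 1]")
    return stats.norm.isf(pi)


def default_prevalence(config: GeneratorConfig) -> np.ndarray:
    """Geometric decay from prevalence_max to prevalence_min over the groups."""
    p = config.n_groups
    return config.prevalence_max * (config.prevalence_min / config.prevalence_max) ** (
        np.arange(p) / (p - 1))


def plant_models(config: GeneratorConfig, rng: np.random.Generator) -> PlantedModel:
    """Draw one planted precision/threshold entry per (meal type x stratum)."""
    groups = default_food_groups()[: config.n_groups]
    if len(groups) < config.n_groups:
        groups = tuple(list(groups) + [f"group_{k:02d}" for k in range(len(groups), config.n_groups)])
    pi = default_prevalence(config)
    entries: dict[tuple[str, str], PlantedEntry] = {}
    for stratum in config.strata:
        for meal_type in MEAL_TYPES:
            theta, sigma, edges = generate_sparse_precision(
                config.n_groups, config.sparsity, config.strength_range, rng)
            entries[(meal_type, stratum)] = PlantedEntry(
                theta=theta, sigma=sigma, edges=edges,
                tau=thresholds_from_prevalence(pi), prevalence=pi.copy())
    return PlantedModel(entries=entries, rho_b=config.rho_b, groups=groups)


def synthetic_taxonomy(config: GeneratorConfig, groups: Sequence[str]) -> FoodGroupTaxonomy:
    """Synthetic food codes, ``codes_per_group`` per group, mapped onto the groups."""
    mapping: dict[str, str] = {}
    code = 1
    for g in groups:
        for _ in range(config.codes_per_group):
            mapping[f"F{code:03d}"] = g
            code += 1
    return FoodGroupTaxonomy(mapping=mapping, groups=tuple(groups))


@dataclass
class SyntheticCohort:
    """Everything :func:`generate_cohort` produces.

    ``records`` is a drop-in recall-record table; ``component_amounts`` feeds
    the diet-quality scorer so the full scoring-to-tertile path is exercisable;
    ``truth`` carries the planted networks and parameters for recovery checks.
    """

    records: list[RecallRecord]
    component_amounts: pd.DataFrame
    scores: pd.DataFrame                 # participant_id, stratum, planted total
    taxonomy: FoodGroupTaxonomy
    truth: PlantedModel
    config: GeneratorConfig

    def records_frame(self) -> pd.DataFrame:
        from .core_data import records_to_frame
        return records_to_frame(self.records)

    def save(self, out_dir: str | Path) -> None:
        """Write all tables (TSV) and the truth bundle to a directory."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.records_frame().to_csv(out / "recalls.tsv", sep="\t", index=False)
        self.component_amounts.to_csv(out / "component_amounts.tsv", sep="\t", index=False)
        self.scores.to_csv(out / "scores.tsv", sep="\t", index=False)
        tax = pd.DataFrame({"food_code": list(self.taxonomy.mapping),
                            "group": [self.taxonomy.mapping[c] for c in self.taxonomy.mapping]})
        tax.to_csv(out / "taxonomy.tsv", sep="\t", index=False)
        truth_dir = out / "truth"
        truth_dir.mkdir(exist_ok=True)
        for (meal_type, stratum), entry in self.truth.entries.items():
            tag = f"{meal_type}_{stratum}"
            pd.DataFrame(entry.theta, columns=self.truth.groups).to_csv(
                truth_dir / f"theta_{tag}.tsv", sep="\t", index=False)
            pd.DataFrame({"group": self.truth.groups, "tau": entry.tau,
                          "prevalence": entry.prevalence}).to_csv(
                truth_dir / f"thresholds_{tag}.tsv", sep="\t", index=False)
        cfg = asdict(self.config)
        cfg["score_ranges"] = {k: list(v) for k, v in dict(cfg["score_ranges"]).items()}
        with open(out / "generator_config.yaml", "w") as fh:
            yaml.safe_dump({"rho_b": self.truth.rho_b, "config": cfg}, fh)


def _component_amounts_for(
    pid: str, total: float, recall_energy: Mapping[str, float], standards: HEIStandards
) -> list[dict]:
    """Per-recall component amounts whose pooled score equals ``total`` exactly.

    Every component is set to the same fraction of its maximum, and amounts are
    spread over recalls in proportion to recall energy so the pooled density is
    constant regardless of which recalls survive plausibility filtering.
    """
    frac = total / 100.0
    rows = []
    for rid, energy in recall_energy.items():
        row = {"participant_id": pid, "recall_id": rid, "energy_kcal": energy}
        for comp in standards.components:
            density = comp.standard_for_zero + frac * (comp.standard_for_max - comp.standard_for_zero)
            if comp.unit == "per_1000_kcal":
                row[comp.name] = density * energy / 1000.0
            elif comp.unit == "percent_energy":
                row[comp.name] = density / 100.0 * energy
            else:
                row[comp.name] = density
        rows.append(row)
    return rows


def generate_cohort(
    config: GeneratorConfig | None = None,
    planted: PlantedModel | None = None,
    *,
    standards: HEIStandards | None = None,
) -> SyntheticCohort:
    """Generate the full synthetic cohort: recall records, scores, taxonomy, truth.

    Fully deterministic given ``config.seed``: the same seed and config produce
    byte-identical tables via :meth:`SyntheticCohort.save`.
    """
    config = config or GeneratorConfig()
    rng = np.random.default_rng(config.seed)
    if planted is None:
        planted = plant_models(config, rng)
    if standards is None:
        standards = example_hei_standards()
    groups = planted.groups
    taxonomy = synthetic_taxonomy(config, groups)
    codes_by_group = {g: [c for c, gg in taxonomy.mapping.items() if gg == g] for g in groups}
    chol = {key: np.linalg.cholesky(e.sigma) for key, e in planted.entries.items()}
    p = config.n_groups
    sb = np.sqrt(planted.rho_b)
    sw = np.sqrt(1.0 - planted.rho_b)

    records: list[RecallRecord] = []
    comp_rows: list[dict] = []
    score_rows: list[dict] = []

    for stratum in config.strata:
        lo_s, hi_s = config.score_ranges[stratum]
        for i in range(config.n_participants):
            pid = f"{stratum[0].upper()}{i:03d}"
            u = rng.standard_normal(p)  # participant effect, shared across meals
            n_recalls = 1 + rng.choice(len(config.recall_count_probs), p=config.recall_count_probs)
            trimesters = sorted(rng.choice([1, 2, 3], size=n_recalls, replace=False).tolist())
            total_score = float(rng.uniform(lo_s, hi_s))
            recall_energy: dict[str, float] = {}
            for tri in trimesters:
                rid = f"{pid}-T{tri}"
                n_snacks = rng.choice(len(config.snack_count_probs), p=config.snack_count_probs)
                occasions = [("breakfast", 1), ("lunch", 2), ("dinner", 3)]
                occasions += [("snack", 4 + k) for k in range(n_snacks)]
                recall_items: list[RecallRecord] = []
                for meal_type, occ_idx in occasions:
                    entry = planted.entries[(meal_type, stratum)]
                    eps = chol[(meal_type, stratum)] @ rng.standard_normal(p)
                    z = sb * u + sw * eps
                    consumed = z > entry.tau
                    if meal_type == "dinner" and rng.random() < config.p_supper_label:
                        label = "supper"
                    elif meal_type == "snack" and rng.random() < config.p_drink_label:
                        label = "just_a_drink"
                    else:
                        label = meal_type
                    for g_idx in np.flatnonzero(consumed):
                        amount = float(np.exp(config.mu_log_g + config.sigma_log_g * z[g_idx]))
                        code = codes_by_group[groups[g_idx]][
                            rng.integers(len(codes_by_group[groups[g_idx]]))]
                        recall_items.append(RecallRecord(
                            participant_id=pid, recall_id=rid, trimester=int(tri),
                            occasion_index=occ_idx, occasion_label=label,
                            food_code=code, amount_g=round(amount, 2),
                            energy_kcal=round(amount * config.energy_density_kcal_g, 2)))
                if recall_items and rng.random() < config.p_low_energy_recall:
                    # Rescale the whole day to an implausibly low total so the
                    # energy-plausibility screen has something to exclude.
                    tot = sum(it.energy_kcal for it in recall_items)
                    factor = float(rng.uniform(300.0, 500.0)) / tot
                    recall_items = [RecallRecord(
                        participant_id=it.participant_id, recall_id=it.recall_id,
                        trimester=it.trimester, occasion_index=it.occasion_index,
                        occasion_label=it.occasion_label, food_code=it.food_code,
                        amount_g=round(it.amount_g * factor, 2),
                        energy_kcal=round(it.energy_kcal * factor, 2)) for it in recall_items]
                records.extend(recall_items)
                recall_energy[rid] = sum(it.energy_kcal for it in recall_items)
            comp_rows.extend(_component_amounts_for(pid, total_score, recall_energy, standards))
            score_rows.append({"participant_id": pid, "stratum": stratum, "total": total_score})

    return SyntheticCohort(
        records=records,
        component_amounts=pd.DataFrame(comp_rows),
        scores=pd.DataFrame(score_rows),
        taxonomy=taxonomy,
        truth=planted,
        config=config,
    )
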