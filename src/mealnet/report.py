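"""Cross-stratum comparison, file export, and full-pipeline orchestration.

Node prevalence (the percentage of meals at which a food group is consumed)
is compared between diet-quality strata with a per-group Pearson chi-square
test on the 2x2 consumed-by-stratum table. Fitted networks are exported as
GraphML with node attributes (prevalence, community, matched community, role)
and edge attributes (weight, sign, partial correlation) so they load directly
into standard graph viewers. ``run_pipeline`` chains every stage — ingestion,
scoring, stratification, per-meal network fits, communities and roles, ICC
decomposition, prevalence comparison — and writes a manifest that conserves
meal counts through every filter.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
import yaml
from scipy import stats

from . import __version__
from .core_data import (
    DEFAULT_OCCASION_POLICY,
    MEAL_TYPES,
    FoodGroupTaxonomy,
    HEIStandards,
    MealMatrix,
    assign_tertiles,
    build_meal_matrix,
    example_hei_standards,
    filter_energy_plausibility,
    hei_total_pooled,
    load_recalls,
    normalize_meal_type,
    records_to_frame,
    scores_to_frame,
)
from .communities import (
    Partition,
    build_graph,
    louvain_partition,
    match_communities,
    node_role_table,
)
from .icc import icc_table
from .networks import DEFAULT_LAMBDA_GRID, NetworkModel, fit_meal_network, fit_trimester_networks

logger = logging.getLogger(__name__)


def node_prevalence(matrix: MealMatrix, meal_type: str | None = None) -> pd.Series:
    """Fraction of meals (of the given type, if any) at which each group appears."""
    if meal_type is not None:
        matrix = matrix.restrict(meal_type=meal_type)
    return matrix.prevalence()


def chi_square_prevalence_test(n1: int, k1: int, n2: int, k2: int,
                               *, correction: bool = False) -> dict:
    """Pearson chi-square on the 2x2 consumed/not x stratum table.

    No continuity correction by default (``correction=True`` enables Yates).
    Returns statistic, p-value and the two proportions; when a margin of the
    table is empty (e.g. the food is consumed in neither stratum) the test is
    undefined and statistic/p are NaN.
    """
    if n1 <= 0 or n2 <= 0:
        raise ValueError("sample sizes must be positive")
    if not (0 <= k1 <= n1 and 0 <= k2 <= n2):
        raise ValueError("consumption counts must lie in [0, n]")
    table = np.array([[k1, n1 - k1], [k2, n2 - k2]], dtype=float)
    out = {"n1": n1, "k1": k1, "n2": n2, "k2": k2,
           "prop1": k1 / n1, "prop2": k2 / n2}
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        out.update(statistic=np.nan, p_value=np.nan, significant=False)
        return out
    res = stats.chi2_contingency(table, correction=correction)
    out.update(statistic=float(res.statistic), p_value=float(res.pvalue),
               significant=bool(res.pvalue < 0.05))
    return out


def prevalence_comparison(
    matrix: MealMatrix,
    strata: Mapping[str, str],
    strata_pair: tuple[str, str] = ("low", "high"),
    *,
    correction: bool = False,
    adjust: str | None = None,
) -> pd.DataFrame:
    """Per (food group x meal type) chi-square comparison of node prevalence.

    ``adjust="bh"`` applies Benjamini-Hochberg across the tests per meal type;
    by default raw p-values are compared to 0.05, matching single-test usage.
    """
    if adjust not in (None, "bh"):
        raise ValueError("adjust must be None or 'bh'")
    s1, s2 = strata_pair
    rows = []
    for mt in MEAL_TYPES:
        subs = {}
        for s in strata_pair:
            pids = [p for p, lab in strata.items() if lab == s]
            subs[s] = matrix.restrict(meal_type=mt, participants=pids)
        if subs[s1].n_meals == 0 or subs[s2].n_meals == 0:
            continue
        counts = {s: (subs[s].values > 0).sum(axis=0) for s in strata_pair}
        for group in matrix.groups:
            k1, k2 = int(counts[s1][group]), int(counts[s2][group])
            if k1 == 0 and k2 == 0:
                continue
            res = chi_square_prevalence_test(subs[s1].n_meals, k1, subs[s2].n_meals, k2,
                                             correction=correction)
            rows.append({"food_group": group, "meal_type": mt, **res})
    df = pd.DataFrame(rows)
    if adjust == "bh" and len(df):
        for mt in df["meal_type"].unique():
            mask = (df["meal_type"] == mt) & df["p_value"].notna()
            p = df.loc[mask, "p_value"].to_numpy()
            order = np.argsort(p)
            m = len(p)
            adj = np.empty(m)
            running = 1.0
            for rank_i in range(m - 1, -1, -1):
                running = min(running, p[order[rank_i]] * m / (rank_i + 1))
                adj[order[rank_i]] = running
            df.loc[mask, "p_adjusted"] = adj
            df.loc[mask, "significant"] = adj < 0.05
    return df


def export_network(
    model: NetworkModel,
    partition: Partition | None,
    roles: pd.DataFrame | None,
    path: str | Path,
    *,
    matched: Mapping | None = None,
) -> nx.Graph:
    """Write the network as GraphML with full node/edge annotation.

    Node attributes: label, prevalence_pct, community, matched_community,
    role; edge attributes: weight (=|partial correlation|), sign,
    partial_correlation. Round-trips losslessly through a GraphML reader.
    """
    g = build_graph(model)
    role_by_node = {} if roles is None else dict(zip(roles["group"], roles["role"]))
    for node in g.nodes:
        g.nodes[node]["label"] = str(node)
        if partition is not None:
            c = partition.membership.get(node, -1)
            g.nodes[node]["community"] = int(c)
            g.nodes[node]["matched_community"] = int(matched.get(c, -1)) if matched else int(c)
        if role_by_node:
            g.nodes[node]["role"] = role_by_node.get(node, "isolated")
    nx.write_graphml(g, path)
    return g


# ---------------------------------------------------------------------------
# Pipeline orchestration
# ---------------------------------------------------------------------------


@dataclass
class PipelineConfig:
    """Everything ``run_pipeline`` needs; loadable from YAML.

    Either ``simulate`` (generator overrides, possibly empty for defaults) or
    the three input paths (recalls, taxonomy, component amounts) must be set.
    """

    out_dir: str | Path = "mealnet_out"
    seed: int = 0
    simulate: dict | None = None
    recalls_path: str | None = None
    taxonomy_path: str | None = None
    component_amounts_path: str | None = None
    hei_standards_path: str | None = None
    occasion_policy: dict = field(default_factory=dict)
    prevalence_threshold: float = 0.05
    lambda_grid: Sequence[float] = DEFAULT_LAMBDA_GRID
    cv_folds: int = 5
    method: str = "spearman"
    analysis_strata: tuple[str, str] = ("low", "high")
    meal_types: Sequence[str] = MEAL_TYPES
    chi_square_correction: bool = False
    icc_transform: str | None = None
    icc_structure: str = "crossed"
    trimester_networks: bool = False
    community_seed: int = 0
    jaccard_threshold: float = 0.25

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config fields: {sorted(unknown)}")
        return cls(**raw)

    def validate(self) -> None:
        if self.simulate is None:
            for name in ("recalls_path", "taxonomy_path", "component_amounts_path"):
                if getattr(self, name) is None:
                    raise ValueError(f"config field {name!r} is required when not simulating")


@dataclass
class PipelineResult:
    matrix: MealMatrix
    scores: pd.DataFrame
    networks: dict
    partitions: dict
    roles: dict
    matched: dict
    icc: pd.DataFrame
    comparison: pd.DataFrame
    manifest: dict


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, Path):
        return str(o)
    if isinstance(o, (set, frozenset, tuple)):
        return sorted(o) if isinstance(o, (set, frozenset)) else list(o)
    raise TypeError(f"not JSON serializable: {type(o)}")


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute the full analysis and write all outputs under ``config.out_dir``.

    Stages: load or simulate recall records -> energy-plausibility screen ->
    meal matrix -> pooled diet-quality scores and tertiles -> per
    (meal type x stratum) network fit with cross-validated penalty -> Louvain
    communities, node roles, cross-stratum community matching -> ICC
    decomposition -> prevalence comparison. Deterministic given the seed:
    reruns produce byte-identical tables.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"version": __version__, "seed": config.seed,
                      "config": {k: (list(v) if isinstance(v, tuple) else v)
                                 for k, v in config.__dict__.items() if k != "out_dir"}}

    # --- stage: inputs -----------------------------------------------------
    if config.simulate is not None:
        from .synthetic import GeneratorConfig, generate_cohort
        gen_cfg = GeneratorConfig(**{**config.simulate, "seed": config.seed})
        cohort = generate_cohort(gen_cfg)
        records = cohort.records
        taxonomy = cohort.taxonomy
        component_amounts = cohort.component_amounts
        records_to_frame(records).to_csv(out / "recalls.tsv", sep="\t", index=False)
        manifest["simulated"] = True
    else:
        records = load_recalls(config.recalls_path)
        taxonomy = FoodGroupTaxonomy.from_table(config.taxonomy_path)
        component_amounts = pd.read_csv(
            config.component_amounts_path, sep="\t", dtype={"participant_id": str, "recall_id": str})
        manifest["simulated"] = False
    standards = (HEIStandards.from_yaml(config.hei_standards_path)
                 if config.hei_standards_path else example_hei_standards())

    # --- stage: plausibility filter ---------------------------------------
    energy = filter_energy_plausibility(records)
    manifest["recalls"] = {
        "total": len(energy.recall_energy),
        "excluded_low_energy": len(energy.excluded_recalls),
        "flagged_high_energy": len(energy.flagged_recalls),
        "retained": len(energy.recall_energy) - len(energy.excluded_recalls),
    }
    retained_recall_ids = {(r.participant_id, r.recall_id) for r in energy.retained}

    # --- stage: meal matrix ------------------------------------------------
    policy = {**DEFAULT_OCCASION_POLICY, **config.occasion_policy}
    occasions = {(r.participant_id, r.recall_id, r.occasion_index): r.occasion_label
                 for r in energy.retained}
    n_dropped_occ = sum(1 for lab in occasions.values()
                        if normalize_meal_type(lab, policy) is None)
    matrix = build_meal_matrix(energy.retained, taxonomy, occasion_policy=policy)
    matrix.to_tsv(out / "meal_matrix.tsv")
    manifest["meals"] = {"occasions_in_retained_recalls": len(occasions),
                        "dropped_by_occasion_policy": n_dropped_occ,
                        "in_matrix": matrix.n_meals}
    assert manifest["meals"]["occasions_in_retained_recalls"] == \
        manifest["meals"]["dropped_by_occasion_policy"] + manifest["meals"]["in_matrix"]

    # --- stage: diet-quality scores and tertiles ---------------------------
    keep = component_amounts.apply(
        lambda r: (str(r["participant_id"]), str(r["recall_id"])) in retained_recall_ids, axis=1)
    scores = hei_total_pooled(component_amounts.loc[keep], standards)
    scores = assign_tertiles(scores)
    scores_df = scores_to_frame(scores)
    scores_df.to_csv(out / "scores.tsv", sep="\t", index=False)
    strata = dict(zip(scores_df["participant_id"], scores_df["tertile"]))
    manifest["participants"] = {"scored": len(scores_df),
                                **scores_df["tertile"].value_counts().to_dict()}

    # --- stage: networks, communities, roles -------------------------------
    networks: dict = {}
    partitions: dict = {}
    roles: dict = {}
    matched: dict = {}
    manifest["networks"] = {}
    for mt in config.meal_types:
        for stratum in config.analysis_strata:
            pids = [p for p, s in strata.items() if s == stratum]
            sub = matrix.restrict(meal_type=mt, participants=pids)
            model = fit_meal_network(
                sub, meal_type=mt, stratum=stratum, method=config.method,
                grid=config.lambda_grid, k=config.cv_folds, seed=config.seed,
                prevalence_threshold=config.prevalence_threshold)
            networks[(mt, stratum)] = model
            graph = build_graph(model)
            part = louvain_partition(graph, seed=config.community_seed)
            partitions[(mt, stratum)] = part
            roles[(mt, stratum)] = node_role_table(graph, part)
            tag = f"{mt}_{stratum}"
            model.edge_table().to_csv(out / f"edges_{tag}.tsv", sep="\t", index=False)
            model.node_table().to_csv(out / f"nodes_{tag}.tsv", sep="\t", index=False)
            manifest["networks"][tag] = {
                "n_meals": model.n_meals, "lambda": model.lam,
                "retained_groups": len(model.groups),
                "excluded_groups": len(model.excluded_groups),
                "n_edges": len(model.edges),
                "modularity": part.modularity,
                "n_communities": len(part.communities),
            }
            if config.trimester_networks:
                tri_models = fit_trimester_networks(
                    sub, model, method=config.method,
                    prevalence_threshold=config.prevalence_threshold)
                for tm in tri_models:
                    tm.edge_table().to_csv(out / f"edges_{tag}_t{tm.trimester}.tsv",
                                           sep="\t", index=False)
        s1, s2 = config.analysis_strata
        map_a, map_b = match_communities(partitions[(mt, s1)], partitions[(mt, s2)],
                                         config.jaccard_threshold)
        matched[mt] = {s1: map_a, s2: map_b}
        for stratum, mapping in ((s1, map_a), (s2, map_b)):
            tag = f"{mt}_{stratum}"
            part = partitions[(mt, stratum)]
            role_df = roles[(mt, stratum)].copy()
            role_df["matched_community"] = [
                mapping.get(c, -1) for c in role_df["community"]]
            role_df.to_csv(out / f"roles_{tag}.tsv", sep="\t", index=False)
            export_network(networks[(mt, stratum)], part, roles[(mt, stratum)],
                           out / f"network_{tag}.graphml", matched=mapping)

    # --- stage: ICC decomposition ------------------------------------------
    icc_df = icc_table(matrix, strata, analysis_strata=config.analysis_strata,
                       prevalence_threshold=config.prevalence_threshold,
                       transform=config.icc_transform, structure=config.icc_structure)
    icc_df.to_csv(out / "icc_table.tsv", sep="\t", index=False)

    # --- stage: prevalence comparison --------------------------------------
    comparison = prevalence_comparison(matrix, strata, config.analysis_strata,
                                       correction=config.chi_square_correction)
    comparison.to_csv(out / "prevalence_comparison.tsv", sep="\t", index=False)

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=_json_default)
    logger.info("pipeline complete: %d networks under %s", len(networks), out)
    return PipelineResult(matrix=matrix, scores=scores_df, networks=networks,
                          partitions=partitions, roles=roles, matched=matched,
                          icc=icc_df, comparison=comparison, manifest=manifest)
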