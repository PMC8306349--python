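"""Recall-record ingestion, plausibility filtering, meal matrices, and diet-quality scoring.

The unit of observation downstream is the *meal* (eating occasion): each row of a
:class:`MealMatrix` is one occasion reported by one participant on one recall day,
with columns holding gram intake per food group. Diet quality is a pooled
HEI-style score (0-100) per participant, computed from config-supplied component
standards, and used to stratify participants into tertiles.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

#: Occasion labels a recall instrument may emit.
OCCASION_LABELS = (
    "breakfast",
    "brunch",
    "lunch",
    "dinner",
    "supper",
    "snack",
    "just_a_drink",
    "just_a_supplement",
)

#: The four meal types networks are fitted for.
MEAL_TYPES = ("breakfast", "lunch", "dinner", "snack")

#: Default mapping from occasion label to network meal type (None = occasion dropped).
#: Supper is folded into dinner; brunch into lunch; drink-only occasions into snack;
#: supplement-only occasions are dropped. All overridable via config.
DEFAULT_OCCASION_POLICY: dict[str, str | None] = {
    "breakfast": "breakfast",
    "brunch": "lunch",
    "lunch": "lunch",
    "dinner": "dinner",
    "supper": "dinner",
    "snack": "snack",
    "just_a_drink": "snack",
    "just_a_supplement": None,
}

ENERGY_EXCLUDE_BELOW_KCAL = 600.0
ENERGY_FLAG_ABOVE_KCAL = 4500.0

REQUIRED_COLUMNS = (
    "participant_id",
    "recall_id",
    "trimester",
    "occasion_index",
    "occasion_label",
    "food_code",
    "amount_g",
    "energy_kcal",
)

MEAL_KEY_COLUMNS = ("participant_id", "recall_id", "trimester", "meal_type", "occasion_index")


@dataclass(frozen=True)
class RecallRecord:
    """One food item reported at one eating occasion."""

    participant_id: str
    recall_id: str
    trimester: int
    occasion_index: int
    occasion_label: str
    food_code: str
    amount_g: float
    energy_kcal: float

    def __post_init__(self) -> None:
        if self.amount_g < 0:
            raise ValueError(f"amount_g must be >= 0, got {self.amount_g}")
        if self.energy_kcal < 0:
            raise ValueError(f"energy_kcal must be >= 0, got {self.energy_kcal}")
        if self.trimester not in (1, 2, 3):
            raise ValueError(f"trimester must be 1, 2 or 3, got {self.trimester}")
        if self.occasion_label not in OCCASION_LABELS:
            raise ValueError(f"unknown occasion_label {self.occasion_label!r}")


class RowValidationError(ValueError):
    """Raised when rows of an input table violate record invariants.

    ``rows`` holds the 0-based positional indices of the offending rows.
    """

    def __init__(self, message: str, rows: Sequence[int]):
        super().__init__(message)
        self.rows = list(rows)


def _detect_sep(path: str | Path) -> str:
    return "\t" if str(path).endswith((".tsv", ".tab", ".txt")) else ","


def load_recalls(path: str | Path, *, on_invalid: str = "raise") -> list[RecallRecord]:
    """Load recall records from a delimited file (CSV or TSV by extension).

    A missing required column is a hard error naming the column. Rows violating
    record invariants (negative amounts, bad trimester, unknown occasion label)
    are reported with their row indices; with ``on_invalid="raise"`` (default)
    that report is an exception, with ``"drop"`` the rows are dropped and logged.
    """
    if on_invalid not in ("raise", "drop"):
        raise ValueError("on_invalid must be 'raise' or 'drop'")
    df = pd.read_csv(path, sep=_detect_sep(path), dtype={"participant_id": str, "recall_id": str, "food_code": str})
    for col in REQUIRED_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"input file {path} is missing required column {col!r}")
    bad: list[tuple[int, str]] = []
    records: list[RecallRecord] = []
    for i, row in enumerate(df.itertuples(index=False)):
        try:
            records.append(
                RecallRecord(
                    participant_id=str(row.participant_id),
                    recall_id=str(row.recall_id),
                    trimester=int(row.trimester),
                    occasion_index=int(row.occasion_index),
                    occasion_label=str(row.occasion_label),
                    food_code=str(row.food_code),
                    amount_g=float(row.amount_g),
                    energy_kcal=float(row.energy_kcal),
                )
            )
        except (ValueError, TypeError) as exc:
            bad.append((i, str(exc)))
    if bad:
        msg = "; ".join(f"row {i}: {m}" for i, m in bad[:10])
        if on_invalid == "raise":
            raise RowValidationError(f"{len(bad)} invalid row(s): {msg}", [i for i, _ in bad])
        logger.warning("dropped %d invalid row(s): %s", len(bad), msg)
    return records


def records_to_frame(records: Iterable[RecallRecord]) -> pd.DataFrame:
    """Tabulate records as a DataFrame with the canonical columns."""
    return pd.DataFrame([r.__dict__ for r in records], columns=list(REQUIRED_COLUMNS))


@dataclass
class EnergyFilterResult:
    """Outcome of the per-recall energy-plausibility screen."""

    retained: list[RecallRecord]
    excluded: list[RecallRecord]
    flagged_recalls: list[tuple[str, str]]    # (participant_id, recall_id) retained but > upper bound
    excluded_recalls: list[tuple[str, str]]   # recall keys below the lower bound
    recall_energy: dict[tuple[str, str], float] = field(default_factory=dict)


def filter_energy_plausibility(
    records: Iterable[RecallRecord],
    *,
    exclude_below: float = ENERGY_EXCLUDE_BELOW_KCAL,
    flag_above: float = ENERGY_FLAG_ABOVE_KCAL,
) -> EnergyFilterResult:
    """Screen whole recall days on total energy.

    Recalls totalling less than ``exclude_below`` kcal are implausibly low and
    excluded; recalls above ``flag_above`` kcal are retained (pregnancy raises
    energy needs) but flagged for review; everything else passes unflagged.
    """
    records = list(records)
    totals: dict[tuple[str, str], float] = {}
    for r in records:
        key = (r.participant_id, r.recall_id)
        totals[key] = totals.get(key, 0.0) + r.energy_kcal
    excluded_keys = {k for k, v in totals.items() if v < exclude_below}
    flagged_keys = sorted(k for k, v in totals.items() if v > flag_above)
    retained = [r for r in records if (r.participant_id, r.recall_id) not in excluded_keys]
    excluded = [r for r in records if (r.participant_id, r.recall_id) in excluded_keys]
    for key in flagged_keys:
        logger.info("recall %s/%s totals %.0f kcal: retained but flagged for review", key[0], key[1], totals[key])
    return EnergyFilterResult(
        retained=retained,
        excluded=excluded,
        flagged_recalls=flagged_keys,
        excluded_recalls=sorted(excluded_keys),
        recall_energy=totals,
    )


def normalize_meal_type(
    occasion_label: str, policy: Mapping[str, str | None] | None = None
) -> str | None:
    """Map an occasion label to a network meal type, or ``None`` if dropped.

    Supper occasions are folded into dinner. The treatment of brunch,
    drink-only, and supplement-only occasions is policy-driven (see
    :data:`DEFAULT_OCCASION_POLICY`).
    """
    pol = DEFAULT_OCCASION_POLICY if policy is None else {**DEFAULT_OCCASION_POLICY, **policy}
    if occasion_label not in pol:
        raise ValueError(f"unknown occasion label {occasion_label!r}")
    target = pol[occasion_label]
    if target is not None and target not in MEAL_TYPES:
        raise ValueError(f"policy maps {occasion_label!r} to unknown meal type {target!r}")
    logger.debug("occasion %r -> %s", occasion_label, target if target else "dropped")
    return target


@dataclass(frozen=True)
class FoodGroupTaxonomy:
    """Mapping from food code to food group, plus the ordered group list.

    Every food code maps to exactly one group; mixed-dish disaggregation policy
    is expressed entirely through this mapping (a code for a composite dish may
    point at a component group or at a dish-level group).
    """

    mapping: Mapping[str, str]
    groups: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(set(self.groups)) != len(self.groups):
            raise ValueError("group list contains duplicates")
        unknown = sorted({g for g in self.mapping.values()} - set(self.groups))
        if unknown:
            raise ValueError(f"mapping targets groups not in the group list: {unknown}")

    @classmethod
    def from_table(cls, path: str | Path, groups: Sequence[str] | None = None) -> "FoodGroupTaxonomy":
        """Read a two-column (food_code, group) delimited table.

        If ``groups`` is omitted the group order is first-appearance order.
        """
        df = pd.read_csv(path, sep=_detect_sep(path), dtype=str)
        for col in ("food_code", "group"):
            if col not in df.columns:
                raise ValueError(f"taxonomy file {path} is missing required column {col!r}")
        if df["food_code"].duplicated().any():
            dupes = df.loc[df["food_code"].duplicated(), "food_code"].tolist()
            raise ValueError(f"food codes mapped more than once: {dupes[:5]}")
        mapping = dict(zip(df["food_code"], df["group"]))
        if groups is None:
            groups = list(dict.fromkeys(df["group"]))
        return cls(mapping=mapping, groups=tuple(groups))


def default_food_groups() -> tuple[str, ...]:
    """The 40 default food-group names shipped with the package."""
    path = Path(__file__).parent / "data" / "default_food_groups.txt"
    names = [ln.strip() for ln in path.read_text().splitlines() if ln.strip() and not ln.startswith("#")]
    return tuple(names)


@dataclass
class MealMatrix:
    """Meals-by-food-groups gram intake.

    ``keys`` carries one row per meal (participant_id, recall_id, trimester,
    meal_type, occasion_index); ``values`` is the aligned numeric frame with one
    column per food group, including all-zero columns for never-consumed groups.
    """

    keys: pd.DataFrame
    values: pd.DataFrame

    def __post_init__(self) -> None:
        if len(self.keys) != len(self.values):
            raise ValueError("keys and values row counts differ")
        if (self.values.to_numpy() < 0).any():
            raise ValueError("meal matrix cells must be >= 0")
        if self.keys.duplicated(subset=list(MEAL_KEY_COLUMNS)).any():
            raise ValueError("duplicate meal keys")

    @property
    def n_meals(self) -> int:
        return len(self.values)

    @property
    def groups(self) -> list[str]:
        return list(self.values.columns)

    def restrict(self, meal_type: str | None = None, trimester: int | None = None,
                 participants: Iterable[str] | None = None) -> "MealMatrix":
        """Subset meals by meal type, trimester, and/or participant set."""
        mask = pd.Series(True, index=self.keys.index)
        if meal_type is not None:
            mask &= self.keys["meal_type"] == meal_type
        if trimester is not None:
            mask &= self.keys["trimester"] == trimester
        if participants is not None:
            mask &= self.keys["participant_id"].isin(set(participants))
        return MealMatrix(self.keys.loc[mask].reset_index(drop=True),
                          self.values.loc[mask].reset_index(drop=True))

    def prevalence(self) -> pd.Series:
        """Fraction of meals in which each group was consumed (> 0 g)."""
        if self.n_meals == 0:
            raise ValueError("empty meal matrix")
        return (self.values > 0).mean(axis=0)

    def to_frame(self) -> pd.DataFrame:
        return pd.concat([self.keys.reset_index(drop=True), self.values.reset_index(drop=True)], axis=1)

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "MealMatrix":
        keys = df[list(MEAL_KEY_COLUMNS)].copy()
        values = df.drop(columns=list(MEAL_KEY_COLUMNS))
        return cls(keys=keys, values=values.astype(float))

    @classmethod
    def from_tsv(cls, path: str | Path) -> "MealMatrix":
        return cls.from_frame(pd.read_csv(path, sep="\t", dtype={"participant_id": str, "recall_id": str}))


def build_meal_matrix(
    records: Iterable[RecallRecord],
    taxonomy: FoodGroupTaxonomy,
    *,
    occasion_policy: Mapping[str, str | None] | None = None,
    unmapped: str = "error",
) -> MealMatrix:
    """Aggregate item-level records into a meals x food-groups gram matrix.

    Each eating occasion becomes one row (multiple snack occasions on one recall
    stay separate rows); cell (m, g) sums the grams of all items at meal m whose
    food code maps to group g. Groups never consumed remain as zero columns so
    every matrix shares the taxonomy's column order.

    ``unmapped`` controls food codes absent from the taxonomy: ``"error"``
    (default) or ``"drop"`` (dropped with a log line).
    """
    if unmapped not in ("error", "drop"):
        raise ValueError("unmapped must be 'error' or 'drop'")
    rows: dict[tuple, np.ndarray] = {}
    gidx = {g: j for j, g in enumerate(taxonomy.groups)}
    n_dropped_items = 0
    for r in records:
        meal_type = normalize_meal_type(r.occasion_label, occasion_policy)
        if meal_type is None:
            continue
        group = taxonomy.mapping.get(r.food_code)
        if group is None:
            if unmapped == "error":
                raise KeyError(f"food code {r.food_code!r} not in taxonomy")
            n_dropped_items += 1
            continue
        key = (r.participant_id, r.recall_id, r.trimester, meal_type, r.occasion_index)
        if key not in rows:
            rows[key] = np.zeros(len(taxonomy.groups))
        rows[key][gidx[group]] += r.amount_g
    if n_dropped_items:
        logger.warning("dropped %d item(s) with unmapped food codes", n_dropped_items)
    keys = pd.DataFrame(list(rows.keys()), columns=list(MEAL_KEY_COLUMNS))
    values = pd.DataFrame(np.array(list(rows.values())) if rows else np.empty((0, len(taxonomy.groups))),
                          columns=list(taxonomy.groups))
    return MealMatrix(keys=keys, values=values)


def prevalence_filter(matrix: MealMatrix, threshold: float = 0.05) -> tuple[MealMatrix, list[str]]:
    """Drop food groups consumed in fewer than ``threshold`` of meals.

    Strict "fewer than" semantics: a group consumed in exactly 5% of meals is
    retained. Returns the filtered matrix and the excluded group names.
    """
    prev = matrix.prevalence()
    keep = prev[prev >= threshold].index.tolist()
    excluded = [g for g in matrix.groups if g not in keep]
    return MealMatrix(matrix.keys.copy(), matrix.values[keep].copy()), excluded


# ---------------------------------------------------------------------------
# Diet-quality (HEI-style) scoring
# ---------------------------------------------------------------------------

VALID_DENSITY_UNITS = ("per_1000_kcal", "percent_energy", "ratio")


@dataclass(frozen=True)
class HEIComponentStandard:
    """Scoring standard for one diet-quality component.

    ``standard_for_zero`` is the density earning 0 points, ``standard_for_max``
    the density earning full points; scores are linear between and clipped.
    For adequacy components zero < max; for moderation components max < zero
    (lower density is better).
    """

    name: str
    kind: str            # "adequacy" | "moderation"
    unit: str            # per_1000_kcal | percent_energy | ratio
    standard_for_zero: float
    standard_for_max: float
    max_points: float

    def __post_init__(self) -> None:
        if self.kind not in ("adequacy", "moderation"):
            raise ValueError(f"component kind must be adequacy or moderation, got {self.kind!r}")
        if self.unit not in VALID_DENSITY_UNITS:
            raise ValueError(f"unknown density unit {self.unit!r}")
        if self.kind == "adequacy" and self.standard_for_zero >= self.standard_for_max:
            raise ValueError(f"adequacy component {self.name}: standard_for_zero must be < standard_for_max")
        if self.kind == "moderation" and self.standard_for_max >= self.standard_for_zero:
            raise ValueError(f"moderation component {self.name}: standard_for_max must be < standard_for_zero")
        if self.max_points <= 0:
            raise ValueError("max_points must be positive")


@dataclass(frozen=True)
class HEIStandards:
    """The full component set: 9 adequacy + 4 moderation, max points summing to 100."""

    components: tuple[HEIComponentStandard, ...]

    def __post_init__(self) -> None:
        n_adeq = sum(1 for c in self.components if c.kind == "adequacy")
        n_mod = sum(1 for c in self.components if c.kind == "moderation")
        if len(self.components) != 13 or n_adeq != 9 or n_mod != 4:
            raise ValueError(
                f"expected 13 components (9 adequacy, 4 moderation), got {len(self.components)} "
                f"({n_adeq} adequacy, {n_mod} moderation)")
        total = sum(c.max_points for c in self.components)
        if abs(total - 100.0) > 1e-9:
            raise ValueError(f"max points must sum to 100, got {total}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "HEIStandards":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        comps = tuple(HEIComponentStandard(**c) for c in raw["components"])
        return cls(components=comps)

    def names(self) -> list[str]:
        return [c.name for c in self.components]


def example_hei_standards() -> HEIStandards:
    """The example standards table shipped with the package (see its header note)."""
    return HEIStandards.from_yaml(Path(__file__).parent / "data" / "hei2015_standards_example.yaml")


def hei_component_score(density: float, standard: HEIComponentStandard) -> float:
    """Score one component from its energy-adjusted density, linear between standards.

    Adequacy: 0 points at/below ``standard_for_zero``, full points at/above
    ``standard_for_max``. Moderation runs the other way (full points at/below
    the better standard). Always clipped to [0, max_points].
    """
    if density < 0:
        raise ValueError(f"density must be >= 0, got {density}")
    lo, hi = standard.standard_for_zero, standard.standard_for_max
    frac = (density - lo) / (hi - lo)   # moderation: hi < lo flips the direction
    return float(np.clip(frac, 0.0, 1.0) * standard.max_points)


@dataclass
class DietQualityScore:
    """Pooled diet-quality score for one participant."""

    participant_id: str
    component_scores: dict[str, float]
    total: float
    tertile: str | None = None  # "low" | "mid" | "high"

    def __post_init__(self) -> None:
        if not np.isclose(self.total, sum(self.component_scores.values())):
            raise ValueError("total must equal the sum of component scores")
        if self.total > 100 + 1e-9:
            raise ValueError("total exceeds 100")


def hei_total_pooled(
    component_amounts: pd.DataFrame,
    standards: HEIStandards,
) -> list[DietQualityScore]:
    """Pooled-recall diet-quality scoring, one score per participant.

    ``component_amounts`` has one row per recall: ``participant_id``,
    ``energy_kcal``, and one column per component holding the recall's raw
    component amount (cup/oz equivalents for per-1000-kcal components, component
    kcal for percent-energy components, the ratio numerator/denominator pair is
    pre-divided for ratio components — ratio columns are averaged weighted by
    energy rather than re-derived).

    Densities are computed on *pooled* sums — total component amount over all of
    a participant's recalls divided by pooled energy — then scored; this is the
    per-person simple scoring algorithm, not a mean of per-recall scores.
    """
    need = {"participant_id", "energy_kcal"}
    missing = need - set(component_amounts.columns)
    if missing:
        raise ValueError(f"component_amounts missing columns: {sorted(missing)}")
    comp_names = standards.names()
    missing_comps = [c for c in comp_names if c not in component_amounts.columns]
    if missing_comps:
        raise ValueError(f"component_amounts missing component columns: {missing_comps}")
    out: list[DietQualityScore] = []
    for pid, sub in component_amounts.groupby("participant_id", sort=True):
        pooled_energy = float(sub["energy_kcal"].sum())
        if pooled_energy <= 0:
            raise ValueError(f"participant {pid}: pooled energy is zero")
        scores: dict[str, float] = {}
        for comp in standards.components:
            pooled_amount = float(sub[comp.name].sum())
            if comp.unit == "per_1000_kcal":
                density = pooled_amount / (pooled_energy / 1000.0)
            elif comp.unit == "percent_energy":
                density = 100.0 * pooled_amount / pooled_energy
            else:  # ratio: energy-weighted mean of per-recall ratios
                w = sub["energy_kcal"].to_numpy()
                density = float(np.average(sub[comp.name].to_numpy(), weights=w))
            scores[comp.name] = hei_component_score(density, comp)
        total = sum(scores.values())
        out.append(DietQualityScore(participant_id=str(pid), component_scores=scores, total=total))
    return out


def assign_tertiles(scores: list[DietQualityScore]) -> list[DietQualityScore]:
    """Rank participants by total score and split into low/mid/high tertiles.

    Sizes differ by at most one; when n is not divisible by 3 the extra members
    go to the low, then the mid tertile. Ties are broken by participant ID so
    the split is deterministic.
    """
    n = len(scores)
    if n < 3:
        raise ValueError("need at least 3 participants to form tertiles")
    if len({s.total for s in scores}) == 1:
        warnings.warn("all diet-quality scores identical; tertiles assigned by participant-ID order")
    order = sorted(scores, key=lambda s: (s.total, s.participant_id))
    sizes = [n // 3 + (1 if i < n % 3 else 0) for i in range(3)]
    labels = ["low"] * sizes[0] + ["mid"] * sizes[1] + ["high"] * sizes[2]
    for s, lab in zip(order, labels):
        s.tertile = lab
    return scores


def scores_to_frame(scores: list[DietQualityScore]) -> pd.DataFrame:
    rows = [{"participant_id": s.participant_id, "total": s.total, "tertile": s.tertile,
             **s.component_scores} for s in scores]
    return pd.DataFrame(rows)
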