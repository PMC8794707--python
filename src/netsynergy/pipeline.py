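"""Decision layer and orchestration: additivity calls, reversal
statistics and the end-to-end synergy pipeline.

Additivity rules
----------------
*Drug level*: a combination is called additive for a motive when its
score strictly exceeds both component scores and reaches the HIGH band
(>= 78 by default).  *Target level*: a target is selected for a motive
when its solo score already shows a positive predicted relationship
(>= 47, MEDIUM band), the combination score strictly exceeds the solo
score, and the combination score is itself >= 47.  Ties are never
additive.

Reversal statistics
-------------------
A disease effector counts as *reversed* by a treatment when the
treatment's predicted activity carries the opposite sign to the
effector's disease state with magnitude >= tau (0.1 by default).  For two
treatments the motive's effectors partition into both / A-only / B-only /
neither; the four percentages sum to 100 per motive.
"""

from __future__ import annotations

import json
import math
import shutil
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence, Union

import numpy as np
import pandas as pd
import yaml

from .errors import (
    ConfigurationError,
    MissingEntityError,
    PipelineStageError,
    ShapeMismatchError,
)
from .expression import derive_restrictions, read_de_table
from .knowledge_base import (
    DiseaseCharacterisation,
    DrugTargetProfile,
    ProteinNetwork,
    combine_profiles,
    read_characterisation,
    read_drug_profile,
    read_network,
    summarize_characterisation,
)
from .sampling import (
    ActivityMap,
    aggregate_activities,
    extract_moa_subnetwork,
    sample_solutions,
)
from .scoring import (
    categorize_score,
    score_relationship,
    train_relationship_scorer,
)

__all__ = [
    "ScoreMatrix",
    "AdditivityCall",
    "ReversalReport",
    "detect_drug_level_additivity",
    "select_additive_targets",
    "compute_reversed_proteins",
    "reversal_coverage",
    "round_half_up",
    "PipelineConfig",
    "run_synergy_pipeline",
]

DEFAULT_HIGH_THRESHOLD = 78.0
DEFAULT_MEDIUM_THRESHOLD = 47.0
DEFAULT_TAU = 0.1


@dataclass
class ScoreMatrix:
    """Entity x motive relationship scores on the 0-100 scale."""

    values: pd.DataFrame

    def __post_init__(self):
        self.values = self.values.astype(float)
        arr = self.values.to_numpy()
        if arr.size and (np.nanmin(arr) < 0 or np.nanmax(arr) > 100):
            raise ValueError("score matrix cells must lie in [0, 100]")

    @property
    def entities(self) -> list[str]:
        return list(self.values.index)

    @property
    def motives(self) -> list[str]:
        return list(self.values.columns)

    def score(self, entity: str, motive: str) -> float:
        try:
            return float(self.values.at[entity, motive])
        except KeyError as exc:
            raise MissingEntityError(str(exc)) from exc

    @classmethod
    def from_tidy(
        cls,
        frame: pd.DataFrame,
        entity_col: str = "entity",
        motive_col: str = "motive",
        score_col: str = "score",
    ) -> "ScoreMatrix":
        wide = frame.pivot(index=entity_col, columns=motive_col,
                           values=score_col)
        # preserve first-appearance order of rows and columns
        wide = wide.loc[
            frame[entity_col].drop_duplicates(),
            frame[motive_col].drop_duplicates(),
        ]
        return cls(wide)

    @classmethod
    def from_tsv(cls, path: Union[str, Path]) -> "ScoreMatrix":
        return cls(pd.read_csv(path, sep="\t", index_col=0))

    def to_tsv(self, path: Union[str, Path]) -> None:
        self.values.to_csv(path, sep="\t")


@dataclass(frozen=True)
class AdditivityCall:
    """One positive additivity decision."""

    motive: str
    level: str  # "drug" or "target"
    entity: str
    combo_score: float
    solo_score: float

    def __post_init__(self):
        if self.combo_score <= self.solo_score:
            raise ValueError(
                "an additive call requires combo_score > solo_score"
            )


def detect_drug_level_additivity(
    scores: ScoreMatrix,
    drug_a: str,
    drug_b: str,
    combination: str | None = None,
    high_threshold: float = DEFAULT_HIGH_THRESHOLD,
) -> list[str]:
    """Motives where the combination row beats both drug rows and
    reaches the HIGH band.

    The comparison against each single drug is strict (a tie is not
    additive); the band condition is ``combination >= high_threshold``.
    Returns motive names in column order.
    """
    combination = combination if combination is not None else f"{drug_a}+{drug_b}"
    for row in (drug_a, drug_b, combination):
        if row not in scores.values.index:
            raise MissingEntityError(f"score matrix lacks entity row {row!r}")
    out = []
    for motive in scores.motives:
        combo = scores.score(combination, motive)
        if (
            combo > scores.score(drug_a, motive)
            and combo > scores.score(drug_b, motive)
            and combo >= high_threshold
        ):
            out.append(motive)
    return out


def select_additive_targets(
    solo: ScoreMatrix,
    combination: ScoreMatrix,
    medium_threshold: float = DEFAULT_MEDIUM_THRESHOLD,
) -> dict[str, set[str]]:
    """Per-motive targets with a positive solo relationship that the
    combination strictly improves.

    A target is selected for a motive iff its solo score >= the MEDIUM
    threshold (the positive predicted relationship), the combination
    score strictly exceeds the solo score, and the combination score is
    itself >= the MEDIUM threshold.
    """
    if list(solo.values.index) != list(combination.values.index) or list(
        solo.values.columns
    ) != list(combination.values.columns):
        raise ShapeMismatchError(
            "solo and combination matrices must share rows and columns"
        )
    out: dict[str, set[str]] = {}
    for motive in solo.motives:
        selected = set()
        for target in solo.entities:
            s = solo.score(target, motive)
            c = combination.score(target, motive)
            if s >= medium_threshold and c > s and c >= medium_threshold:
                selected.add(target)
        out[motive] = selected
    return out


# ---------------------------------------------------------------------------
# Reversal statistics
# ---------------------------------------------------------------------------

def compute_reversed_proteins(
    disease: DiseaseCharacterisation,
    activity: ActivityMap | Mapping[str, float],
    tau: float = DEFAULT_TAU,
) -> dict[str, set[str]]:
    """Per-motive effectors driven opposite to their disease state.

    An effector is reversed iff sign(activity) == -disease_sign and
    |activity| >= tau; effectors absent from the activity map are never
    reversed.
    """
    if tau <= 0:
        raise ValueError("tau must be > 0")
    get = activity.get if hasattr(activity, "get") else dict(activity).get
    out: dict[str, set[str]] = {}
    for motive in disease.motives:
        reversed_set = set()
        for st in motive.effectors:
            val = get(st.protein.accession)
            if val is None or abs(val) < tau:
                continue
            if math.copysign(1, val) == -st.disease_sign:
                reversed_set.add(st.protein.accession)
        out[motive.name] = reversed_set
    return out


@dataclass
class ReversalReport:
    """Per-motive partition of effectors by which treatment reverses them.

    Percentages are stored at full precision; rounding to integers
    happens only at presentation (:meth:`to_frame`).
    """

    treatment_a: str
    treatment_b: str
    counts: dict[str, dict[str, int]]          # motive -> partition counts
    percentages: dict[str, dict[str, float]]   # motive -> partition %
    reversed_by_a: dict[str, set[str]]
    reversed_by_b: dict[str, set[str]]

    PARTS = ("both", "a_only", "b_only", "neither")

    def to_frame(self, rounded: bool = True) -> pd.DataFrame:
        rows = []
        for motive, pct in self.percentages.items():
            row = {"motive": motive}
            row.update(
                {
                    part: (round_half_up(pct[part]) if rounded else pct[part])
                    for part in self.PARTS
                }
            )
            row["n_effectors"] = sum(self.counts[motive].values())
            rows.append(row)
        return pd.DataFrame(rows)


def round_half_up(x: float) -> int:
    """Round to the nearest integer with halves going up."""
    return int(math.floor(x + 0.5))


def reversal_coverage(
    disease: DiseaseCharacterisation,
    activity_a: ActivityMap | Mapping[str, float],
    activity_b: ActivityMap | Mapping[str, float],
    tau: float = DEFAULT_TAU,
    treatment_a: str = "A",
    treatment_b: str = "B",
) -> ReversalReport:
    """Partition each motive's effectors into both / A-only / B-only /
    neither according to which treatment reverses them."""
    rev_a = compute_reversed_proteins(disease, activity_a, tau)
    rev_b = compute_reversed_proteins(disease, activity_b, tau)
    counts: dict[str, dict[str, int]] = {}
    pct: dict[str, dict[str, float]] = {}
    for motive in disease.motives:
        a, b = rev_a[motive.name], rev_b[motive.name]
        n = len(motive)
        c = {
            "both": len(a & b),
            "a_only": len(a - b),
            "b_only": len(b - a),
            "neither": n - len(a | b),
        }
        counts[motive.name] = c
        pct[motive.name] = {k: 100.0 * v / n for k, v in c.items()}
    return ReversalReport(
        treatment_a, treatment_b, counts, pct, rev_a, rev_b
    )


# ---------------------------------------------------------------------------
# End-to-end orchestration
# ---------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    """Configuration of one synergy-pipeline run.

    Either provide precomputed score matrices (``drug_scores_path`` plus
    optionally ``target_solo_scores_path``/``target_combo_scores_path``)
    or training pairs for the scorer; sampling stages run only when a
    training set is given.
    """

    network_path: str | Path | None = None
    disease_path: str | Path | None = None
    drug_a_path: str | Path | None = None
    drug_b_path: str | Path | None = None
    drug_scores_path: str | Path | None = None
    target_solo_scores_path: str | Path | None = None
    target_combo_scores_path: str | Path | None = None
    de_table_path: str | Path | None = None
    training_set_path: str | Path | None = None
    training_set: Sequence | None = None
    scorer_pairs: tuple[Sequence, Sequence] | None = None
    seed: int = 0
    high_threshold: float = DEFAULT_HIGH_THRESHOLD
    medium_threshold: float = DEFAULT_MEDIUM_THRESHOLD
    tau: float = DEFAULT_TAU
    n_accept: int = 20
    cv_folds: int = 3
    accuracy_threshold: float = 0.90
    out_dir: str | Path = "netsynergy-out"

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


def _require(condition: bool, message: str) -> None:
    if not condition:
        raise ConfigurationError(message)


def run_synergy_pipeline(config: PipelineConfig) -> dict:
    """Run scoring -> additivity calls -> ensemble sampling -> reversal
    coverage and write a report bundle under ``config.out_dir``.

    Stages run in a fixed order; any failure is re-raised as
    :class:`PipelineStageError` naming the stage, and partially written
    outputs are removed.  Identical config + seed give identical outputs.
    """
    out_dir = Path(config.out_dir)
    report: dict = {"seed": config.seed, "stages": []}
    written = False
    try:
        # --- stage: load inputs ------------------------------------------
        stage = "load-inputs"
        _require(config.network_path is not None, "network_path is required")
        _require(
            Path(config.network_path).exists(),
            f"network file not found: {config.network_path}",
        )
        _require(config.disease_path is not None, "disease_path is required")
        network = read_network(config.network_path)
        disease = read_characterisation(config.disease_path)
        drug_a = (
            read_drug_profile(config.drug_a_path)
            if config.drug_a_path
            else None
        )
        drug_b = (
            read_drug_profile(config.drug_b_path)
            if config.drug_b_path
            else None
        )
        report["stages"].append(stage)
        report["network"] = {"nodes": network.n_nodes, "edges": network.n_edges}
        summary = summarize_characterisation(disease)
        report["disease"] = {
            "name": disease.name,
            "per_motive": summary.per_motive,
            "unique_proteins": summary.unique_proteins,
        }

        # --- stage: expression restrictions ------------------------------
        restrictions = []
        if config.de_table_path:
            stage = "expression-restrictions"
            records, n_unmapped = read_de_table(config.de_table_path)
            restrictions = derive_restrictions(records)
            report["stages"].append(stage)
            report["restrictions"] = {
                "count": len(restrictions),
                "unmapped_dropped": n_unmapped,
            }

        # --- stage: scoring ----------------------------------------------
        stage = "scoring"
        scorer = None
        if config.drug_scores_path:
            drug_scores = ScoreMatrix.from_tsv(config.drug_scores_path)
        else:
            _require(
                config.scorer_pairs is not None and drug_a and drug_b,
                "either drug_scores_path or scorer_pairs + both drug "
                "profiles are required",
            )
            positives, negatives = config.scorer_pairs
            scorer = train_relationship_scorer(
                positives, negatives, network, seed=config.seed
            )
            combo = combine_profiles(drug_a, drug_b)
            rows = {}
            for profile in (drug_a, drug_b, combo):
                rows[profile.drug_name] = {
                    m.name: score_relationship(
                        scorer, network, profile.accessions, m.accessions
                    ).value
                    for m in disease.motives
                }
            drug_scores = ScoreMatrix(pd.DataFrame(rows).T)
        report["stages"].append(stage)
        a_name = drug_a.drug_name if drug_a else drug_scores.entities[0]
        b_name = drug_b.drug_name if drug_b else drug_scores.entities[1]
        combo_name = (
            f"{a_name}+{b_name}"
            if f"{a_name}+{b_name}" in drug_scores.entities
            else drug_scores.entities[-1]
        )
        report["drug_scores"] = {
            entity: {
                m: {
                    "score": drug_scores.score(entity, m),
                    "category": categorize_score(drug_scores.score(entity, m)),
                }
                for m in drug_scores.motives
            }
            for entity in drug_scores.entities
        }

        # --- stage: drug-level additivity --------------------------------
        stage = "drug-additivity"
        additive_motives = detect_drug_level_additivity(
            drug_scores, a_name, b_name, combo_name,
            high_threshold=config.high_threshold,
        )
        report["stages"].append(stage)
        report["additive_motives"] = additive_motives
        # per-motive modelling plan: combination models where the
        # combination is additive; otherwise solo models for drugs whose
        # own relationship reaches the HIGH band; nothing else
        plan = {}
        for motive in drug_scores.motives:
            if motive in additive_motives:
                plan[motive] = {"type": "combination", "drugs": [a_name, b_name]}
            else:
                solo = [
                    d
                    for d in (a_name, b_name)
                    if drug_scores.score(d, motive) >= config.high_threshold
                ]
                plan[motive] = (
                    {"type": "solo", "drugs": solo}
                    if solo
                    else {"type": "none", "drugs": []}
                )
        report["model_plan"] = plan

        # --- stage: target-level selection -------------------------------
        target_selection = None
        if config.target_solo_scores_path and config.target_combo_scores_path:
            stage = "target-selection"
            solo = ScoreMatrix.from_tsv(config.target_solo_scores_path)
            combo_m = ScoreMatrix.from_tsv(config.target_combo_scores_path)
            target_selection = select_additive_targets(
                solo, combo_m, medium_threshold=config.medium_threshold
            )
            report["stages"].append(stage)
            report["target_selection"] = {
                m: sorted(ts) for m, ts in target_selection.items()
            }

        # --- stage: MoA sampling + reversal coverage ----------------------
        coverage = None
        moa_nets = {}
        training_set = config.training_set
        if training_set is None and config.training_set_path:
            from .serialize import read_training_set

            training_set = read_training_set(config.training_set_path)
        if training_set is not None and drug_a and drug_b:
            stage = "moa-sampling"
            maps = {}
            for profile in (drug_a, drug_b):
                ensemble = sample_solutions(
                    network,
                    training_set,
                    n_accept=config.n_accept,
                    seed=config.seed,
                    cv_folds=config.cv_folds,
                    accuracy_threshold=config.accuracy_threshold,
                    stimulus=profile,
                )
                amap = aggregate_activities(ensemble, network)
                maps[profile.drug_name] = amap
                moa_nets[profile.drug_name] = extract_moa_subnetwork(
                    network, amap
                )
            report["stages"].append(stage)
            stage = "reversal-coverage"
            coverage = reversal_coverage(
                disease,
                maps[drug_a.drug_name],
                maps[drug_b.drug_name],
                tau=config.tau,
                treatment_a=drug_a.drug_name,
                treatment_b=drug_b.drug_name,
            )
            report["stages"].append(stage)
            report["reversal_coverage"] = {
                m: coverage.percentages[m] for m in coverage.percentages
            }

        # --- stage: write reports -----------------------------------------
        stage = "write-reports"
        out_dir.mkdir(parents=True, exist_ok=True)
        written = True
        (out_dir / "report.json").write_text(
            json.dumps(report, indent=2, sort_keys=True) + "\n"
        )
        drug_scores.to_tsv(out_dir / "drug_scores.tsv")
        pd.DataFrame(
            {"motive": additive_motives}
        ).to_csv(out_dir / "additive_motives.tsv", sep="\t", index=False)
        if target_selection is not None:
            pd.DataFrame(
                [
                    {"motive": m, "targets": ",".join(sorted(ts))}
                    for m, ts in target_selection.items()
                ]
            ).to_csv(out_dir / "target_selection.tsv", sep="\t", index=False)
        if coverage is not None:
            coverage.to_frame().to_csv(
                out_dir / "reversal_coverage.tsv", sep="\t", index=False
            )
        for name, moa in moa_nets.items():
            safe = name.replace("/", "_").replace(" ", "_")
            moa.to_graphml(out_dir / f"moa_{safe}.graphml")
            moa.to_tsv(out_dir / f"moa_{safe}.tsv")
        return report
    except Exception as exc:
        if written and out_dir.exists():
            shutil.rmtree(out_dir, ignore_errors=True)
        if isinstance(exc, PipelineStageError):
            raise
        raise PipelineStageError(stage, exc) from exc
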