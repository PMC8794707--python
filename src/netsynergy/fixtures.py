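"""Packaged mRCC fixtures: published drug target profiles and score
tables for metastatic renal cell carcinoma.

These small reference tables ship with the package so the decision layer
(score banding, drug-level additivity, target selection) can be exercised
and validated against published values without any external files:

* the 13-receptor cabozantinib target profile and the single-target
  anti-PD1 profile (PDCD1, UniProtKB Q15116);
* the drug-level relationship score matrix (cabozantinib, PD1 inhibitor,
  and their combination against the five mRCC motives);
* the per-target score matrix (each cabozantinib target alone and
  combined with a PD1 inhibitor, against the five motives);
* the expected per-motive additive target selection.
"""

from __future__ import annotations

import json
from importlib import resources

import pandas as pd

from .knowledge_base import DrugTargetProfile, read_drug_profile

__all__ = [
    "MRCC_MOTIVES",
    "load_cabozantinib_profile",
    "load_anti_pd1_profile",
    "load_drug_score_table",
    "load_target_score_table",
    "load_expected_additive_targets",
]

#: The five mRCC pathophysiological motives, in published order.
MRCC_MOTIVES: tuple[str, ...] = (
    "Apoptosis evasion",
    "Immune evasion",
    "Angiogenesis",
    "Metastasis and Invasion",
    "Cell growth and Proliferation",
)


def _data(name: str):
    return resources.files("netsynergy.data").joinpath(name)


def load_cabozantinib_profile() -> DrugTargetProfile:
    """Cabozantinib's 13 inhibited receptor tyrosine kinase targets."""
    with resources.as_file(_data("cabozantinib_targets.json")) as p:
        return read_drug_profile(p)


def load_anti_pd1_profile() -> DrugTargetProfile:
    """Anti-PD1: a single inhibited target, PDCD1 (Q15116)."""
    with resources.as_file(_data("anti_pd1_targets.json")) as p:
        return read_drug_profile(p)


def load_drug_score_table() -> pd.DataFrame:
    """Tidy drug-level scores: entity, motive, score, category."""
    with resources.as_file(_data("mrcc_drug_scores.tsv")) as p:
        return pd.read_csv(p, sep="\t", dtype={"category": str})


def load_target_score_table() -> pd.DataFrame:
    """Tidy per-target scores: target, motive, condition, score, category.

    ``condition`` is ``solo`` (target alone) or ``combination`` (target
    plus PD1 inhibition).
    """
    with resources.as_file(_data("mrcc_target_scores.tsv")) as p:
        return pd.read_csv(p, sep="\t", dtype={"category": str})


def load_expected_additive_targets() -> dict[str, set[str]]:
    """Published per-motive additive cabozantinib targets."""
    with resources.as_file(_data("mrcc_additive_targets.json")) as p:
        raw = json.loads(p.read_text())
    return {motive: set(targets) for motive, targets in raw.items()}
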