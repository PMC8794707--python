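"""JSON serialisation of training sets.

Layout: a list of pairs, each with an inline drug profile, the output
effector states, and the pair polarity::

    [{"input": {"drug_name": "...", "targets": [...]},
      "output": [{"accession": "...", "disease_sign": 1}, ...],
      "polarity": "causal" | "therapeutic"}, ...]
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence, Union

from .knowledge_base import EffectorState, ProteinRef, read_drug_profile
from .sampling import TrainingPair

__all__ = ["read_training_set", "write_training_set"]


def read_training_set(path: Union[str, Path]) -> list[TrainingPair]:
    raw = json.loads(Path(path).read_text(encoding="utf-8"))
    pairs = []
    for entry in raw:
        profile = read_drug_profile(entry["input"])
        outputs = [
            EffectorState(
                ProteinRef(e["accession"], e.get("symbol")),
                int(e["disease_sign"]),
            )
            for e in entry["output"]
        ]
        pairs.append(
            TrainingPair(profile, outputs, entry.get("polarity", "causal"))
        )
    return pairs


def write_training_set(
    pairs: Sequence[TrainingPair], path: Union[str, Path]
) -> None:
    doc = [
        {
            "input": {
                "drug_name": p.input.drug_name,
                "targets": [
                    {"accession": ref.accession, "symbol": ref.symbol,
                     "action": action}
                    for ref, action in p.input.targets
                ],
            },
            "output": [
                {
                    "accession": st.protein.accession,
                    "symbol": st.protein.symbol,
                    "disease_sign": st.disease_sign,
                }
                for st in p.output
            ],
            "polarity": p.polarity,
        }
        for p in pairs
    ]
    Path(path).write_text(json.dumps(doc, indent=2) + "\n", encoding="utf-8")
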