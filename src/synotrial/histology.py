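"""Semi-quantitative synovial histology classification.

Immunohistochemistry sections are scored 0-4 for CD20 (B cells), CD3
(T cells), CD138 (plasma cells) and CD68 lining/sublining macrophages.
The CD20 score drives the pathotype call used for randomization strata:

* not gradable (no definite synovial tissue)  -> ``unknown``
* CD20 score < 2                              -> ``bcell_poor``
* CD20 score 2-4                              -> ``bcell_rich``
* B-cell rich with CD21+ follicular dendritic
  cell networks                               -> ``gc_positive``

The published rule couples the rich call to the presence of CD20 B-cell
aggregates ("score of two to four and aggregates"); a score >= 2 without
aggregates is left undefined by that wording. Here the score alone is
operative (the poor rule is purely "< 2") and the aggregates flag is
retained for audit. Only B-cell poor and B-cell rich patients enter the
primary analysis population.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, List, Literal, Optional

import pandas as pd

__all__ = [
    "HistologyScore",
    "PathotypeLabel",
    "classify_histology",
    "primary_population_filter",
    "classify_histology_table",
    "adjudicate",
]

_ORDINALS = {0, 1, 2, 3, 4}


@dataclass(frozen=True)
class HistologyScore:
    """One biopsy's ordinal IHC scores and gradability flags."""

    cd20: int
    cd3: int = 0
    cd68_lining: int = 0
    cd68_sublining: int = 0
    cd138: int = 0
    cd20_aggregates: bool = False
    cd21_fdc_networks: bool = False
    tissue_gradable: bool = True

    def __post_init__(self) -> None:
        for name in ("cd20", "cd3", "cd68_lining", "cd68_sublining", "cd138"):
            if getattr(self, name) not in _ORDINALS:
                raise ValueError(f"{name}={getattr(self, name)} not in 0..4")
        if self.cd21_fdc_networks and not self.tissue_gradable:
            raise ValueError("cd21_fdc_networks requires gradable tissue")


@dataclass(frozen=True)
class PathotypeLabel:
    """Pathotype call plus the basis (histology or molecular) it came from."""

    label: Literal["bcell_poor", "bcell_rich", "gc_positive", "unknown"]
    basis: Literal["histology", "molecular"]

    def __post_init__(self) -> None:
        if self.label == "gc_positive" and self.basis != "histology":
            raise ValueError("gc_positive is only assigned on histology")


def classify_histology(score: HistologyScore) -> PathotypeLabel:
    """Pathotype from the CD20 semi-quantitative score (total function)."""
    if not score.tissue_gradable:
        return PathotypeLabel("unknown", "histology")
    if score.cd20 < 2:
        return PathotypeLabel("bcell_poor", "histology")
    if score.cd21_fdc_networks:
        return PathotypeLabel("gc_positive", "histology")
    return PathotypeLabel("bcell_rich", "histology")


def primary_population_filter(labels: Iterable[PathotypeLabel]) -> List[bool]:
    """Mask selecting B-cell poor and B-cell rich patients only."""
    return [lab.label in ("bcell_poor", "bcell_rich") for lab in labels]


def classify_histology_table(histology: pd.DataFrame) -> pd.DataFrame:
    """Classify a histology table (one row per patient); appends ``label``.

    Expects columns ``cd20``, ``cd20_aggregates``, ``cd21_fdc_networks``
    and ``tissue_gradable``; remaining ordinal columns default to 0.
    """
    out = histology.copy()
    labels = []
    for _, row in out.iterrows():
        score = HistologyScore(
            cd20=int(row["cd20"]),
            cd3=int(row.get("cd3", 0)),
            cd68_lining=int(row.get("cd68_lining", 0)),
            cd68_sublining=int(row.get("cd68_sublining", 0)),
            cd138=int(row.get("cd138", 0)),
            cd20_aggregates=bool(row.get("cd20_aggregates", False)),
            cd21_fdc_networks=bool(row.get("cd21_fdc_networks", False))
            and bool(row.get("tissue_gradable", True)),
            tissue_gradable=bool(row.get("tissue_gradable", True)),
        )
        labels.append(classify_histology(score).label)
    out["label"] = labels
    return out


def adjudicate(
    primary: Iterable[HistologyScore],
    second: Optional[Iterable[HistologyScore]] = None,
) -> pd.DataFrame:
    """Dual-observer adjudication report.

    The trial's independent second evaluation is modelled as an optional
    second score column; disagreements are reported, not auto-resolved.
    """
    rows = []
    second_list = list(second) if second is not None else None
    for i, s1 in enumerate(primary):
        lab1 = classify_histology(s1).label
        row = {"index": i, "label_primary": lab1}
        if second_list is not None:
            lab2 = classify_histology(second_list[i]).label
            row["label_second"] = lab2
            row["agree"] = lab1 == lab2
        rows.append(row)
    return pd.DataFrame(rows)
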