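"""Usability-study instruments and placement-accuracy metrics.

Scores the two standard questionnaires used to evaluate planning software —
the 10-item System Usability Scale (SUS, 0-100, 68 is the usability
benchmark) and the raw 6-dimension NASA Task Load Index normalised to 0-100
per dimension — and converts endpoint-placement errors between enlarged
(world) model space and patient millimetres.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from seegplan.errors import ValidationError

TLX_DIMENSIONS = ("mental", "physical", "temporal", "performance", "effort", "frustration")


@dataclass
class SUSResponse:
    """Ten 1-5 Likert ratings, item order as administered (1-indexed odd/even)."""

    items: Sequence[int]

    def __post_init__(self) -> None:
        items = list(self.items)
        if len(items) != 10:
            raise ValidationError(f"SUS needs exactly 10 items, got {len(items)}")
        for i, x in enumerate(items, start=1):
            if not (isinstance(x, (int, np.integer)) and 1 <= x <= 5):
                raise ValidationError(f"SUS item {i} must be an integer in [1, 5], got {x!r}")
        self.items = items


@dataclass
class TLXResponse:
    """Six 1-21 workload ratings: mental, physical, temporal, performance,
    effort, frustration."""

    items: Sequence[int]

    def __post_init__(self) -> None:
        items = list(self.items)
        if len(items) != 6:
            raise ValidationError(f"NASA-TLX needs exactly 6 items, got {len(items)}")
        for name, x in zip(TLX_DIMENSIONS, items):
            if not (isinstance(x, (int, np.integer)) and 1 <= x <= 21):
                raise ValidationError(f"TLX item '{name}' must be an integer in [1, 21], got {x!r}")
        self.items = items


@dataclass
class EndpointPair:
    """Placed vs intended (guide) endpoint centroids, both in world mm."""

    placed_centroid: np.ndarray
    guide_centroid: np.ndarray
    scale_factor: float = 6.0

    def __post_init__(self) -> None:
        self.placed_centroid = np.asarray(self.placed_centroid, dtype=float).reshape(3)
        self.guide_centroid = np.asarray(self.guide_centroid, dtype=float).reshape(3)
        if not self.scale_factor > 0:
            raise ValidationError(f"scale_factor must be positive, got {self.scale_factor}")


def score_sus(r: SUSResponse | Sequence[int]) -> float:
    """SUS total: odd items contribute x-1, even items 5-x, sum times 2.5."""
    if not isinstance(r, SUSResponse):
        r = SUSResponse(r)
    total = 0
    for i, x in enumerate(r.items, start=1):
        total += (x - 1) if i % 2 == 1 else (5 - x)
    return 2.5 * total


def score_tlx(r: TLXResponse | Sequence[int]) -> tuple[dict[str, float], float]:
    """Normalised NASA-TLX sub-scores ((x-1)*5, each in [0, 100]) and their mean."""
    if not isinstance(r, TLXResponse):
        r = TLXResponse(r)
    subs = {name: (x - 1) * 5.0 for name, x in zip(TLX_DIMENSIONS, r.items)}
    return subs, float(np.mean(list(subs.values())))


def endpoint_error(pair: EndpointPair) -> tuple[float, float]:
    """(world mm, patient mm) Euclidean error between placed and guide centroids."""
    world = float(np.linalg.norm(pair.placed_centroid - pair.guide_centroid))
    return world, world / pair.scale_factor


# ---------------------------------------------------------------------------
# CSV batch scoring
# ---------------------------------------------------------------------------


def score_sus_csv(path_in: str | Path, path_out: str | Path | None = None) -> pd.DataFrame:
    """Score one SUS response per row (10 columns, header required).

    Appends ``sus_score`` per row plus summary rows (mean, sd).
    """
    df = pd.read_csv(path_in)
    if df.shape[1] != 10:
        raise ValidationError(f"SUS CSV needs 10 columns, got {df.shape[1]}")
    scores = [score_sus(list(row)) for row in df.itertuples(index=False)]
    out = df.copy()
    out["sus_score"] = scores
    if path_out is not None:
        summary = pd.DataFrame(
            {out.columns[0]: ["mean", "sd"], "sus_score": [np.mean(scores), np.std(scores, ddof=1) if len(scores) > 1 else 0.0]}
        )
        pd.concat([out.astype(object), summary], ignore_index=True).to_csv(path_out, index=False)
    return out


def score_tlx_csv(path_in: str | Path, path_out: str | Path | None = None) -> pd.DataFrame:
    """Score one NASA-TLX response per row (6 columns, header required)."""
    df = pd.read_csv(path_in)
    if df.shape[1] != 6:
        raise ValidationError(f"TLX CSV needs 6 columns, got {df.shape[1]}")
    rows = []
    for row in df.itertuples(index=False):
        subs, overall = score_tlx(list(row))
        rows.append({**{f"{k}_norm": v for k, v in subs.items()}, "tlx_overall": overall})
    out = pd.concat([df.reset_index(drop=True), pd.DataFrame(rows)], axis=1)
    if path_out is not None:
        overall = out["tlx_overall"]
        summary = pd.DataFrame(
            {
                df.columns[0]: ["mean", "sd"],
                "tlx_overall": [overall.mean(), overall.std(ddof=1) if len(overall) > 1 else 0.0],
            }
        )
        pd.concat([out.astype(object), summary], ignore_index=True).to_csv(path_out, index=False)
    return out
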