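"""Phenotypic-screening layer: rescue indices, efficacy scores, hit calling.

Each compound group of larvae is compared against an untreated control group
and a disease-model group. For every cardiac parameter X,

    rescue index = (X_drug - X_model) / (X_ctrl - X_model)

so 0 means no recovery beyond the model group and 1 means full restoration to
control level. The efficacy score is the mean rescue index over the usable
parameters — the six continuous readouts (EDA, ESA, FAC, FS, SV, HR) plus the
pericardial-edema Boolean (coded normal = 1 / edema = 0 and averaged to a
fraction-normal per group), seven parameters in all. Compounds scoring
strictly above the threshold (default 0.7) are called hits.

Rescue indices are computed on group means and are not clamped by default:
a compound worse than the model can score negative and over-rescue can exceed
1. Parameters whose control and model means coincide are dropped from the
score (with a logged warning) rather than zero-filled.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .cardiometrics import CardiacParams

logger = logging.getLogger(__name__)

PARAMETERS = ("EDA", "ESA", "FAC", "FS", "SV", "HR", "edema")


@dataclass(frozen=True)
class ScreenGroup:
    """One experimental group (control / model / compound) of larvae."""

    label: str
    larvae: tuple

    def __post_init__(self):
        if len(self.larvae) < 1:
            raise ValueError("a group needs at least one larva")

    @property
    def means(self) -> dict[str, float]:
        return group_means(self.larvae)


@dataclass
class ScreenResult:
    """Per-compound rescue indices and efficacy score."""

    compound: str
    rescue_indices: dict[str, float]
    efficacy_score: float
    n_parameters: int
    is_hit: bool = False
    rank: int | None = None


def group_means(larvae) -> dict[str, float]:
    """Per-parameter means over larvae, skipping missing (NaN) values.

    The edema Boolean (normal = 1, edema = 0) averages to the fraction of
    normal larvae. A parameter missing in every larva is returned as NaN and
    excluded downstream with a warning.
    """
    larvae = list(larvae)
    if not larvae:
        raise ValueError("empty group")
    rows = [l.as_dict() if isinstance(l, CardiacParams) else dict(l)
            for l in larvae]
    means: dict[str, float] = {}
    for p in PARAMETERS:
        vals = np.array([float(r[p]) for r in rows if p in r
                         and np.isfinite(float(r[p]))])
        if len(vals) == 0:
            logger.warning("parameter %s missing in every larva", p)
            means[p] = math.nan
        else:
            means[p] = float(vals.mean())
    return means


def rescue_index(x_drug: float, x_model: float, x_ctrl: float,
                 clamp: bool = False) -> float:
    """(x_drug - x_model) / (x_ctrl - x_model); optionally clamped to [0, 1].

    Raises on x_ctrl == x_model (the parameter carries no model-vs-control
    signal); callers scoring whole parameter sets drop such parameters
    instead.
    """
    denom = x_ctrl - x_model
    if denom == 0:
        raise ZeroDivisionError("control and model means coincide")
    ri = (x_drug - x_model) / denom
    if clamp:
        ri = min(1.0, max(0.0, ri))
    return ri


def efficacy_score(rescue_indices) -> float:
    """Mean of the usable rescue indices (sum / number of parameters)."""
    vals = [float(v) for v in (rescue_indices.values()
                               if isinstance(rescue_indices, dict)
                               else rescue_indices)]
    if not vals:
        raise ValueError("no usable rescue indices")
    return float(sum(vals)) / len(vals)


def score_compound(compound: str, drug_means: dict, model_means: dict,
                   ctrl_means: dict, clamp: bool = False) -> ScreenResult:
    """Rescue indices and efficacy score for one compound group.

    Parameters that are NaN in any of the three groups, or whose control and
    model means coincide, are excluded from the score with a warning.
    """
    indices: dict[str, float] = {}
    for p in PARAMETERS:
        xd, xm, xc = drug_means.get(p), model_means.get(p), ctrl_means.get(p)
        if any(v is None or not np.isfinite(v) for v in (xd, xm, xc)):
            logger.warning("%s: parameter %s unavailable, excluded",
                           compound, p)
            continue
        try:
            indices[p] = rescue_index(xd, xm, xc, clamp=clamp)
        except ZeroDivisionError:
            logger.warning("%s: parameter %s degenerate (ctrl == model), "
                           "excluded", compound, p)
    return ScreenResult(compound=compound, rescue_indices=indices,
                        efficacy_score=efficacy_score(indices),
                        n_parameters=len(indices))


def call_hits(results: list[ScreenResult],
              threshold: float = 0.7) -> list[ScreenResult]:
    """Set is_hit on each result: efficacy score strictly above threshold."""
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    for r in results:
        r.is_hit = bool(r.efficacy_score > threshold)
    return results


def rank_compounds(results: list[ScreenResult]) -> list[ScreenResult]:
    """Descending by efficacy score; ties broken lexicographically by
    compound id. Sets the 1-based rank on each result."""
    if not results:
        raise ValueError("no results to rank")
    ordered = sorted(results, key=lambda r: (-r.efficacy_score, r.compound))
    for i, r in enumerate(ordered):
        r.rank = i + 1
    return ordered


def run_screen(groups: dict[str, list], control: str = "control",
               model: str = "model", threshold: float = 0.7,
               clamp: bool = False) -> list[ScreenResult]:
    """Score every compound group against the control and model groups,
    call hits at `threshold`, and return the ranked results.

    `groups` maps a group label to its larvae (CardiacParams or dicts); every
    label other than `control` and `model` is treated as a compound.
    """
    if control not in groups or model not in groups:
        raise ValueError(f"groups must include {control!r} and {model!r}")
    ctrl_means = group_means(groups[control])
    model_means = group_means(groups[model])
    results = [score_compound(label, group_means(larvae), model_means,
                              ctrl_means, clamp=clamp)
               for label, larvae in groups.items()
               if label not in (control, model)]
    return rank_compounds(call_hits(results, threshold=threshold))
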