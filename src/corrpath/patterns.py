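"""Rule-based temporal pattern classification.

Time-course profiles from batch culture fall into a handful of qualitative
shapes — continuous increase, continuous decrease, a transient ("variable")
excursion, and flat — which practitioners traditionally assign by eye.
This module replaces the visual call with a deterministic, scale-invariant
rule chain so the grouping is reproducible and auditable.

All thresholds are relative (normalised by the profile's maximum absolute
value), so classify_pattern(c * v) == classify_pattern(v) for any c > 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd

from .errors import InputError
from .io import Dataset, mean_profile


class PatternClass(str, Enum):
    INCREASE = "increase"
    DECREASE = "decrease"
    VARIABLE = "variable"
    CONSTANT = "constant"
    UNCLASSIFIED = "unclassified"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


@dataclass(frozen=True)
class ClassifierParams:
    """Thresholds of the rule chain (all relative, dimensionless).

    const_cv:
        Coefficient-of-variation ceiling below which a series is "constant".
    net_change:
        Minimum |net change| / max|v| for a monotone call, and minimum
        range / max|v| for a "variable" call.
    step_tol:
        Tolerated counter-directional step (relative to max|v|) within an
        otherwise monotone series — absorbs replicate jitter.
    """

    const_cv: float = 0.10
    net_change: float = 0.20
    step_tol: float = 0.05

    def __post_init__(self) -> None:
        if min(self.const_cv, self.net_change, self.step_tol) <= 0:
            raise InputError("classifier thresholds must be positive")


def classify_pattern(means: np.ndarray,
                     params: ClassifierParams | None = None) -> PatternClass:
    """Classify one mean time course into a :class:`PatternClass`.

    Rule chain (first match wins), with m = max|v|, relative steps
    s_t = (v_{t+1} - v_t)/m, net = (v_T - v_0)/m and CV = SD/|mean|:

    1. all-zero series, or CV < const_cv               -> constant
    2. net >= net_change and every s_t >= -step_tol    -> increase
    3. net <= -net_change and every s_t <= step_tol    -> decrease
    4. range >= net_change * m and |net| < net_change  -> variable
    5. otherwise                                       -> unclassified
    """
    params = params or ClassifierParams()
    v = np.asarray(means, dtype=float)
    if v.ndim != 1 or v.size < 3:
        raise InputError("classify_pattern needs >= 3 time points")
    if not np.all(np.isfinite(v)):
        raise InputError("classify_pattern requires finite values")

    m = float(np.max(np.abs(v)))
    if m == 0.0:
        return PatternClass.CONSTANT
    steps = np.diff(v) / m
    net = float((v[-1] - v[0]) / m)
    mean = float(np.mean(v))
    cv = float(np.std(v) / abs(mean)) if mean != 0.0 else np.inf

    if cv < params.const_cv:
        return PatternClass.CONSTANT
    if net >= params.net_change and np.all(steps >= -params.step_tol):
        return PatternClass.INCREASE
    if net <= -params.net_change and np.all(steps <= params.step_tol):
        return PatternClass.DECREASE
    if (np.max(v) - np.min(v)) >= params.net_change * m and abs(net) < params.net_change:
        return PatternClass.VARIABLE
    return PatternClass.UNCLASSIFIED


def classify_dataset(d: Dataset,
                     params: ClassifierParams | None = None) -> pd.DataFrame:
    """Classify every profile in ``d``.

    Returns a DataFrame with one row per (entity, condition):
    ``entity_id, condition, pattern, net_change_value, cv_value``.
    """
    params = params or ClassifierParams()
    rows = []
    for p in sorted(d, key=lambda p: p.key):
        means, _ = mean_profile(p)
        label = classify_pattern(means, params)
        m = float(np.max(np.abs(means)))
        net = float((means[-1] - means[0]) / m) if m else 0.0
        mean = float(np.mean(means))
        cv = float(np.std(means) / abs(mean)) if mean else np.inf
        rows.append({
            "entity_id": p.entity_id,
            "condition": p.condition,
            "pattern": label.value,
            "net_change_value": net,
            "cv_value": cv,
        })
    return pd.DataFrame(
        rows, columns=["entity_id", "condition", "pattern",
                       "net_change_value", "cv_value"],
    )
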