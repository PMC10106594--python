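"""Composite performance-quality score from the four assessment parameters.

A principal component analysis of the correlation matrix of the (pooled
baseline + acquisition) assessment parameters yields a single component;
indicators whose absolute loading falls below a salience threshold
(default 0.4) are dropped and the component refitted once.  The score is
the loading-weighted sum of standardized retained indicators, oriented so
that every error-type loading is positive — hence an inverted scale:
low scores mean good playing.

Indicators at a measurement ceiling (a large majority of observations at
the minimum value) carry little variance and typically fail retention;
they are flagged explicitly.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

DEFAULT_INDICATORS = ("wrong", "missed", "sd_ioi_s", "sd_vel")
RETENTION_THRESHOLD = 0.4
CEILING_FRACTION = 0.8


@dataclass(frozen=True)
class QualityModel:
    retained_indicators: tuple[str, ...]
    loadings: dict[str, float]
    eigenvalue_1: float
    scaling: dict[str, tuple[float, float]]  # indicator -> (mean, SD)
    dropped_indicators: tuple[str, ...] = ()
    ceiling_flags: tuple[str, ...] = ()
    initial_loadings: dict[str, float] = field(default_factory=dict)

    @property
    def max_refit_shift(self) -> float:
        """Largest absolute loading change between initial fit and refit."""
        if not self.initial_loadings:
            return 0.0
        return max(
            abs(self.loadings[k] - self.initial_loadings.get(k, self.loadings[k]))
            for k in self.retained_indicators
        )

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({
            "retained_indicators": list(self.retained_indicators),
            "loadings": self.loadings,
            "eigenvalue_1": self.eigenvalue_1,
            "scaling": {k: list(v) for k, v in self.scaling.items()},
            "dropped_indicators": list(self.dropped_indicators),
            "ceiling_flags": list(self.ceiling_flags),
        }, indent=1))


@dataclass(frozen=True)
class QualityScore:
    participant_id: str
    phase: str
    score: float


def _first_component(z: np.ndarray) -> tuple[float, np.ndarray]:
    """First eigenpair of the correlation matrix of standardized columns."""
    corr = np.corrcoef(z, rowvar=False)
    vals, vecs = np.linalg.eigh(corr)
    ev1 = float(vals[-1])
    vec = vecs[:, -1]
    loadings = vec * np.sqrt(ev1)
    if loadings.sum() < 0:  # orient so error loadings are positive
        loadings = -loadings
    return ev1, loadings


def fit_quality_component(
    assessments: pd.DataFrame,
    indicators: Sequence[str] = DEFAULT_INDICATORS,
    retention_threshold: float = RETENTION_THRESHOLD,
) -> QualityModel:
    """Fit the single-component quality model.

    Columns are standardized (sample SD); the first principal component of
    their correlation matrix is extracted and oriented positive.  Indicators
    with |loading| below the threshold are dropped and the component
    refitted once on the surviving set.
    """
    if len(assessments) < 5:
        raise ValueError("need at least 5 assessments to fit the composite")
    cols = list(indicators)
    X = assessments[cols].to_numpy(float)
    if not np.all(np.isfinite(X)):
        raise ValueError("assessment indicators contain non-finite values")

    means = X.mean(axis=0)
    sds = X.std(axis=0, ddof=1)
    ceiling = tuple(
        c for c, col in zip(cols, X.T)
        if np.mean(col == col.min()) > CEILING_FRACTION
    )
    keep = sds > 0
    for c, ok in zip(cols, keep):
        if not ok:
            warnings.warn(f"indicator {c!r} has zero variance; dropped", stacklevel=2)
    cols = [c for c, ok in zip(cols, keep) if ok]
    X, means, sds = X[:, keep], means[keep], sds[keep]
    if len(cols) < 2:
        raise ValueError("fewer than 2 usable indicators")

    z = (X - means) / sds
    ev1, load = _first_component(z)
    initial = dict(zip(cols, map(float, load)))

    retained = [c for c, l in zip(cols, load) if abs(l) >= retention_threshold]
    dropped = tuple(c for c in cols if c not in retained)
    if dropped and len(retained) >= 2:
        sel = [cols.index(c) for c in retained]
        ev1, load = _first_component(z[:, sel])
        cols, means, sds = retained, means[sel], sds[sel]
    elif len(retained) < 2:
        warnings.warn("retention would leave < 2 indicators; keeping all", stacklevel=2)
        dropped = ()

    return QualityModel(
        retained_indicators=tuple(cols),
        loadings=dict(zip(cols, map(float, load))),
        eigenvalue_1=ev1,
        scaling={c: (float(m), float(s)) for c, m, s in zip(cols, means, sds)},
        dropped_indicators=dropped,
        ceiling_flags=ceiling,
        initial_loadings=initial,
    )


def quality_scores(
    model: QualityModel, assessments: pd.DataFrame, unit_variance: bool = False
) -> pd.DataFrame:
    """Score assessments on the fitted composite.

    score = sum over retained indicators of loading * standardized value.
    With ``unit_variance`` the sum is divided by its analytic SD under the
    fitted component (the first eigenvalue), so scores are in SD units and
    regression coefficients on them are comparable across studies.
    Returns a DataFrame (`id, phase, score`); scores computed on the
    fitting sample have mean zero by construction.
    """
    missing = [c for c in model.retained_indicators if c not in assessments.columns]
    if missing:
        raise KeyError(f"missing indicator column(s): {missing}")
    score = np.zeros(len(assessments))
    for c in model.retained_indicators:
        mean, sd = model.scaling[c]
        score += model.loadings[c] * (assessments[c].to_numpy(float) - mean) / sd
    if unit_variance:
        score = score / model.eigenvalue_1
    out = assessments[["id", "phase"]].copy() if "id" in assessments.columns else pd.DataFrame(index=assessments.index)
    out["score"] = score
    return out
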