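"""Per-feature two-group differential tests for the +QTL vs -QTL contrasts.

Expression DEG calls use a per-gene two-sample Welch t test on log
intensities at raw p < 0.001; genomic-hybridization polymorphism calls use
the same machinery at raw p < 0.05.  No multiplicity adjustment is applied:
the downstream window-aggregation and enrichment statistics consume the raw
threshold decisions, which is the decision rule this pipeline's threshold
semantics are built around.

Both stress severities are pooled as replicates of the line contrast by
default (the contrast of interest is line, not drought treatment); pass a
single stress level to obtain per-severity calls.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .genome_model import SampleMeta

__all__ = [
    "DiffCall",
    "welch_t_test",
    "call_degs",
    "call_hybridization_polymorphisms",
    "diffcalls_to_frame",
    "significant_ids",
]

Contrast = Literal["expression_p001", "hybridization_p005"]

_TINY = np.finfo(float).tiny


@dataclass(frozen=True)
class DiffCall:
    """One feature's two-group test result (effect = +QTL minus -QTL mean)."""

    feature_id: str
    effect: float
    p_value: float
    significant: bool
    contrast: Contrast


def welch_t_test(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise Welch t test.

    Parameters
    ----------
    x, y : arrays of shape (features, n1) and (features, n2)

    Returns
    -------
    effect, p_value : arrays of shape (features,)
        ``effect`` is ``mean(x) - mean(y)``; the two-sided p-value comes from
        the t distribution with Welch-Satterthwaite degrees of freedom.
        Features with zero pooled variance get p = 1 when the means are equal
        and the smallest positive float otherwise (so p stays in (0, 1]).
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    y = np.atleast_2d(np.asarray(y, dtype=float))
    n1, n2 = x.shape[1], y.shape[1]
    if n1 < 2 or n2 < 2:
        raise ValueError("Welch t test needs >= 2 observations per group")
    m1, m2 = x.mean(axis=1), y.mean(axis=1)
    v1, v2 = x.var(axis=1, ddof=1), y.var(axis=1, ddof=1)
    effect = m1 - m2
    se2 = v1 / n1 + v2 / n2
    with np.errstate(divide="ignore", invalid="ignore"):
        t = effect / np.sqrt(se2)
        df = se2**2 / (v1**2 / (n1**2 * (n1 - 1)) + v2**2 / (n2**2 * (n2 - 1)))
        p = 2.0 * stats.t.sf(np.abs(t), df)
    degenerate = se2 == 0
    p = np.where(degenerate & (effect == 0), 1.0, p)
    p = np.where(degenerate & (effect != 0), _TINY, p)
    return effect, np.clip(p, _TINY, 1.0)


def _group_columns(
    samples: Sequence[SampleMeta],
    line: str,
    tissue: str | None,
    stress_levels: Sequence[str] | None,
) -> list[str]:
    cols = []
    for s in samples:
        if s.line_id != line:
            continue
        if tissue is not None and s.tissue != tissue:
            continue
        if stress_levels is not None and s.stress not in stress_levels:
            continue
        cols.append(s.sample_id)
    return cols


def _call_two_group(
    matrix: pd.DataFrame,
    plus_cols: list[str],
    minus_cols: list[str],
    alpha: float,
    contrast: Contrast,
) -> list[DiffCall]:
    if matrix.empty:
        return []
    effect, p = welch_t_test(matrix[plus_cols].to_numpy(), matrix[minus_cols].to_numpy())
    return [
        DiffCall(fid, float(e), float(pv), bool(pv < alpha), contrast)
        for fid, e, pv in zip(matrix.index, effect, p)
    ]


def call_degs(
    matrix: pd.DataFrame,
    samples: Sequence[SampleMeta],
    pair: tuple[str, str],
    tissue: str,
    stress_levels: Sequence[str] = ("FTSW_0.5", "FTSW_0.2"),
    alpha: float = 0.001,
) -> list[DiffCall]:
    """Per-gene DEG calls for one BIL pair and tissue.

    ``pair`` is (+QTL line, -QTL line); samples of the listed stress levels
    are pooled as replicates of the line contrast.  Raises ``ValueError``
    naming the offending group if it retains fewer than two replicates.
    """
    plus_line, minus_line = pair
    plus_cols = _group_columns(samples, plus_line, tissue, stress_levels)
    minus_cols = _group_columns(samples, minus_line, tissue, stress_levels)
    for line, cols in ((plus_line, plus_cols), (minus_line, minus_cols)):
        if len(cols) < 2:
            raise ValueError(
                f"group {line!r} (tissue {tissue!r}, stress {tuple(stress_levels)}) "
                f"has {len(cols)} replicate(s); need >= 2"
            )
    return _call_two_group(matrix, plus_cols, minus_cols, alpha, "expression_p001")


def call_hybridization_polymorphisms(
    matrix: pd.DataFrame,
    samples: Sequence[SampleMeta],
    pair: tuple[str, str],
    alpha: float = 0.05,
) -> list[DiffCall]:
    """Per-probe differential-hybridization (single-feature polymorphism) calls."""
    if matrix.empty:
        return []
    plus_line, minus_line = pair
    plus_cols = _group_columns(samples, plus_line, None, None)
    minus_cols = _group_columns(samples, minus_line, None, None)
    for line, cols in ((plus_line, plus_cols), (minus_line, minus_cols)):
        if len(cols) < 2:
            raise ValueError(f"group {line!r} has {len(cols)} replicate(s); need >= 2")
    return _call_two_group(matrix, plus_cols, minus_cols, alpha, "hybridization_p005")


def diffcalls_to_frame(calls: Sequence[DiffCall]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "feature_id": [c.feature_id for c in calls],
            "effect": [c.effect for c in calls],
            "p_value": [c.p_value for c in calls],
            "significant": [c.significant for c in calls],
            "contrast": [c.contrast for c in calls],
        }
    )


def significant_ids(calls: Sequence[DiffCall]) -> set[str]:
    return {c.feature_id for c in calls if c.significant}
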