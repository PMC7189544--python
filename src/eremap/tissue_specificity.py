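"""Tissue-specificity calling for repeat families and genes.

The tau index summarizes how restricted a feature's expression is
across an N-tissue panel:

    tau = sum_i (1 - x_i) / (N - 1),   x_i = value_i / max_j value_j

tau is 0 for perfectly uniform expression, 1 for single-tissue
expression, and is scale-free.  Features with tau >= 0.8 are called
tissue-restricted; housekeeping-like profiles sit at tau <= 0.4.  The
tissues actually overexpressing a restricted feature are found by the
max-gap binarization: sort tissues by expression, find the largest
drop between neighbors, and mark everything above it.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .expression import chi_squared
from .io_formats import ERE_GROUPS, RepeatRecord

__all__ = [
    "tau_index",
    "binary_pattern",
    "SpecificityResult",
    "call_restricted",
    "group_enrichment",
    "TAU_RESTRICTED",
    "TAU_HOUSEKEEPING",
]

TAU_RESTRICTED = 0.8
TAU_HOUSEKEEPING = 0.4


def tau_index(profile: Sequence[float]) -> float:
    """Tissue-specificity tau of a per-tissue expression profile.

    Raises on an all-zero profile (tau undefined there, not 0) and on
    negative expression.
    """
    x = np.asarray(list(profile), dtype=float)
    if len(x) < 2:
        raise ValueError("tau needs at least 2 tissues")
    if (x < 0).any():
        raise ValueError("expression values must be non-negative")
    top = x.max()
    if top == 0:
        raise ValueError("tau undefined for an all-zero profile")
    return float((1 - x / top).sum() / (len(x) - 1))


def binary_pattern(
    profile: pd.Series | Sequence[float],
    tissue_ids: Sequence[str] | None = None,
) -> tuple[dict[str, int], float]:
    """Max-gap binarization of a per-tissue profile.

    Tissues are sorted by expression (descending); the largest
    difference between neighbors is the threshold and every tissue
    strictly above it gets 1.  When two gaps tie for maximal, the gap
    closer to the top of the ranking wins (fewer overexpressing
    tissues).  Returns (tissue -> 0/1, gap size).
    """
    if isinstance(profile, pd.Series):
        values = profile.to_numpy(dtype=float)
        ids = list(profile.index)
    else:
        values = np.asarray(list(profile), dtype=float)
        ids = list(tissue_ids) if tissue_ids is not None else [str(i) for i in range(len(values))]
    if len(values) < 2:
        raise ValueError("binary pattern needs at least 2 tissues")
    if np.ptp(values) == 0:
        raise ValueError("all tissues equal: no gap to threshold on")
    # sort descending; tie in values broken by tissue id for determinism
    order = sorted(range(len(ids)), key=lambda i: (-values[i], ids[i]))
    sorted_vals = values[order]
    gaps = sorted_vals[:-1] - sorted_vals[1:]
    cut = int(np.argmax(gaps))  # first (topmost) maximal gap
    pattern = {ids[i]: (1 if rank <= cut else 0) for rank, i in enumerate(order)}
    return pattern, float(gaps[cut])


@dataclass
class SpecificityResult:
    feature_id: str
    tau: float
    binary_pattern: dict[str, int]
    overexpressing_tissues: frozenset[str]
    n_overexpressing: int
    tissue_specific: bool  # exactly one overexpressing tissue

    def __post_init__(self) -> None:
        if not (0 <= self.tau <= 1 + 1e-12):
            raise ValueError(f"tau out of [0,1]: {self.tau}")
        if self.n_overexpressing != sum(self.binary_pattern.values()):
            raise ValueError("n_overexpressing inconsistent with pattern")


def call_restricted(
    profile_table: pd.DataFrame,
    tau_threshold: float = TAU_RESTRICTED,
    expression_floor: float = 1.0,
) -> list[SpecificityResult]:
    """Call tissue-restricted features from a feature x tissue table.

    Features whose maximal expression falls below ``expression_floor``
    are skipped: tau is scale-free and becomes noise-dominated at trace
    expression.  Set the floor to 0 to disable.  All-zero and constant
    profiles are skipped (tau or gap undefined).
    """
    if profile_table.shape[1] < 2:
        raise ValueError("need at least 2 tissues")
    out = []
    for fid, row in profile_table.iterrows():
        values = row.to_numpy(dtype=float)
        if values.max() <= 0 or values.max() < expression_floor:
            continue
        if np.ptp(values) == 0:
            continue
        tau = tau_index(values)
        if tau < tau_threshold:
            continue
        pattern, _ = binary_pattern(row)
        over = frozenset(t for t, v in pattern.items() if v == 1)
        out.append(
            SpecificityResult(
                feature_id=str(fid),
                tau=tau,
                binary_pattern=pattern,
                overexpressing_tissues=over,
                n_overexpressing=len(over),
                tissue_specific=len(over) == 1,
            )
        )
    return out


def group_enrichment(
    restricted: Sequence[SpecificityResult],
    all_families: Sequence[RepeatRecord] | dict[str, str],
) -> dict:
    """Compare LINE/LTR/SINE shares among restricted families vs all.

    ``all_families`` is either repeat records or a family -> group map.
    Families outside the three main groups are excluded from the test
    (the proportion analysis is defined over LINE/LTR/SINE).
    """
    if not restricted:
        raise ValueError("empty restricted set")
    if isinstance(all_families, dict):
        fam_group = dict(all_families)
    else:
        fam_group = {r.family: r.group for r in all_families}
    background = pd.Series(
        [g for g in fam_group.values() if g in ERE_GROUPS], dtype=object
    ).value_counts()
    if len(background[background > 0]) < 2:
        raise ValueError("degenerate single-group background")
    observed = pd.Series(
        [
            fam_group.get(r.feature_id)
            for r in restricted
            if fam_group.get(r.feature_id) in ERE_GROUPS
        ],
        dtype=object,
    ).value_counts()
    groups = [g for g in ERE_GROUPS if background.get(g, 0) > 0]
    obs = [int(observed.get(g, 0)) for g in groups]
    props = [background[g] / background[groups].sum() for g in groups]
    statistic, df, p = chi_squared(obs, props)
    n_restricted = sum(obs)
    return {
        "groups": groups,
        "observed_counts": dict(zip(groups, obs)),
        "observed_proportions": {
            g: (c / n_restricted if n_restricted else float("nan"))
            for g, c in zip(groups, obs)
        },
        "background_proportions": dict(zip(groups, map(float, props))),
        "statistic": statistic,
        "df": df,
        "p_value": p,
    }
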