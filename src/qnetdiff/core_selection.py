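"""Core-taxon selection by one-sided Mann-Whitney U test.

A representative taxon becomes a *core* taxon when its relative abundance is
significantly increased in the focus group (strictly ``p < p_threshold``,
default 0.005).  The test compares per-sample relative abundances, not raw
counts, since sequencing depth differs between samples.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import stats

from .contraction import ContractionMap
from .tables_io import AbundanceTable

__all__ = [
    "CoreSet",
    "mann_whitney_one_sided",
    "select_core",
    "write_core_tsv",
    "DEFAULT_P_THRESHOLD",
]

DEFAULT_P_THRESHOLD = 0.005

#: Exact null distribution is used when the smaller sample is at most this
#: size and there are no ties; otherwise the tie-corrected normal
#: approximation (with continuity correction) is used.
EXACT_MAX_N = 8


@dataclass
class CoreSet:
    """Representatives significantly increased in the focus group.

    ``p_values`` retains the test result for *every* representative (needed
    for the output feature table); ``core`` lists only those passing the
    strict threshold.
    """

    focus: str
    core: list[str]
    p_values: dict[str, float]
    p_threshold: float = DEFAULT_P_THRESHOLD

    def __contains__(self, taxon: str) -> bool:
        return taxon in self.core

    def __len__(self) -> int:
        return len(self.core)


def mann_whitney_one_sided(
    x: Sequence[float], y: Sequence[float], method: str = "auto"
) -> float:
    """One-sided Mann-Whitney U p-value for "y stochastically greater than x".

    ``method="auto"`` uses the exact permutation null when the smaller sample
    has at most 8 observations and the pooled data are tie-free, and the
    tie-corrected normal approximation otherwise.  ``"exact"`` and
    ``"asymptotic"`` force the choice.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both sample vectors must be nonempty")
    if method == "auto":
        pooled = np.concatenate([x, y])
        tie_free = np.unique(pooled).size == pooled.size
        method = "exact" if (min(x.size, y.size) <= EXACT_MAX_N and tie_free) else "asymptotic"
    elif method not in ("exact", "asymptotic"):
        raise ValueError(f"unknown method {method!r}")
    res = stats.mannwhitneyu(y, x, alternative="greater", method=method)
    return float(res.pvalue)


def select_core(
    cmap: ContractionMap,
    at_x: AbundanceTable,
    at_y: AbundanceTable,
    focus: str = "Y",
    p_threshold: float = DEFAULT_P_THRESHOLD,
) -> CoreSet:
    """Test every representative for increase in the focus group.

    Keeps representatives with ``p < p_threshold`` (strict).  All p-values
    are retained for reporting.  An empty core set is a valid outcome and
    propagates to empty downstream networks.
    """
    if focus not in ("X", "Y"):
        raise ValueError(f"focus must be 'X' or 'Y', got {focus!r}")
    if not (0.0 < p_threshold <= 1.0):
        raise ValueError(f"p_threshold must lie in (0, 1], got {p_threshold}")
    p_values: dict[str, float] = {}
    core: list[str] = []
    for rep in cmap.representatives:
        vx, vy = at_x.row(rep), at_y.row(rep)
        if focus == "Y":
            p = mann_whitney_one_sided(vx, vy)  # increased in Y
        else:
            p = mann_whitney_one_sided(vy, vx)  # increased in X
        p_values[rep] = p
        if p < p_threshold:
            core.append(rep)
    return CoreSet(focus=focus, core=core, p_values=p_values, p_threshold=p_threshold)


def write_core_tsv(core: CoreSet, path: str | Path) -> None:
    """Write all representatives with p-values and an ``is_core`` flag."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("taxon\tp_value\tis_core\n")
        for taxon, p in sorted(core.p_values.items(), key=lambda kv: kv[1]):
            fh.write(f"{taxon}\t{p:.6g}\t{taxon in core.core}\n")
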