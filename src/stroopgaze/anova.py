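"""Per-feature one-way ANOVA screening of the condition contrasts.

Each of the 29 variables is compared between two groups of conditions with
a standard one-way ANOVA (for two groups, F = t**2 and the p-value equals
the two-sided equal-variance t-test).  Raw per-feature p-values are
reported; a Benjamini-Hochberg adjustment is available but off by default.
The ANOVA runs on the uncentered, unscaled feature table.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .features import FEATURE_NAMES, FIXATION_FEATURES
from .records import ValidationError

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class ContrastSpec:
    """A named two-group comparison over condition labels."""

    name: str
    group_a: frozenset[str]
    group_b: frozenset[str]

    def __post_init__(self) -> None:
        if not self.group_a or not self.group_b:
            raise ValidationError(f"contrast {self.name}: both groups must be nonempty")
        if self.group_a & self.group_b:
            raise ValidationError(f"contrast {self.name}: groups overlap")


def _spec(name: str, a: set[str], b: set[str]) -> ContrastSpec:
    return ContrastSpec(name, frozenset(a), frozenset(b))


#: The three pairwise task contrasts plus the pooled Naming-vs-Reading one.
CONTRASTS: dict[str, ContrastSpec] = {
    "NWoIvRWoI": _spec("NWoIvRWoI", {"NWoI"}, {"RWoI"}),
    "NWIvNWoI": _spec("NWIvNWoI", {"NWI"}, {"NWoI"}),
    "RWIvRWoI": _spec("RWIvRWoI", {"RWI"}, {"RWoI"}),
    "NamingvReading": _spec("NamingvReading", {"NWoI", "NWI"}, {"RWoI", "RWI"}),
}

#: The three binary contrasts used by the classification experiments.
CLASSIFICATION_CONTRASTS: tuple[str, ...] = ("NWoIvRWoI", "NWIvNWoI", "RWIvRWoI")


def run_anova(
    table: pd.DataFrame,
    contrast: ContrastSpec,
    features: list[str] | None = None,
) -> pd.DataFrame:
    """One-way ANOVA per feature for one contrast.

    Returns a frame indexed by feature with columns F, p, mean_a, mean_b,
    n_a, n_b.  NaN feature values are excluded; a feature with fewer than
    two valid values in either group gets NaN with a warning.
    """
    features = list(features or FEATURE_NAMES)
    in_a = table["condition"].isin(contrast.group_a)
    in_b = table["condition"].isin(contrast.group_b)
    rows = []
    for f in features:
        a = table.loc[in_a, f].dropna().to_numpy(dtype=float)
        b = table.loc[in_b, f].dropna().to_numpy(dtype=float)
        if len(a) < 2 or len(b) < 2:
            log.warning("contrast %s, feature %s: a group has < 2 values; p = NaN",
                        contrast.name, f)
            F, p = float("nan"), float("nan")
        else:
            F, p = stats.f_oneway(a, b)
        rows.append({
            "feature": f, "F": float(F), "p": float(p),
            "mean_a": float(np.mean(a)) if len(a) else float("nan"),
            "mean_b": float(np.mean(b)) if len(b) else float("nan"),
            "n_a": len(a), "n_b": len(b),
        })
    return pd.DataFrame(rows).set_index("feature")


def run_all_contrasts(
    table: pd.DataFrame,
    contrasts: dict[str, ContrastSpec] | None = None,
) -> dict[str, pd.DataFrame]:
    contrasts = contrasts or CONTRASTS
    return {name: run_anova(table, spec) for name, spec in contrasts.items()}


@dataclass
class ReportConfig:
    star_thresholds: tuple[float, ...] = (0.05, 0.01, 0.005)
    bh_adjust: bool = False


def _stars(p: float, thresholds: tuple[float, ...]) -> str:
    if np.isnan(p):
        return ""
    return "*" * sum(p < t for t in sorted(thresholds, reverse=True))


def anova_report(
    results: dict[str, pd.DataFrame],
    config: ReportConfig | None = None,
) -> pd.DataFrame:
    """Features x contrasts grid of p-values.

    The fixation block precedes the saccade block (column ``block`` marks
    which).  Optional Benjamini-Hochberg adjustment is applied per contrast
    across the 29 features.
    """
    if not results:
        raise ValidationError("anova_report requires at least one contrast result")
    config = config or ReportConfig()
    grid = pd.DataFrame(index=list(next(iter(results.values())).index))
    grid.index.name = "feature"
    for name, res in results.items():
        p = res["p"].copy()
        if config.bh_adjust:
            valid = p.dropna()
            p.loc[valid.index] = stats.false_discovery_control(valid.to_numpy(), method="bh")
        grid[name] = p
    grid.insert(0, "block", ["fixation" if f in FIXATION_FEATURES else "saccade"
                             for f in grid.index])
    return grid


def format_report(grid: pd.DataFrame, config: ReportConfig | None = None) -> str:
    """Aligned plain-text rendering with significance stars."""
    config = config or ReportConfig()
    contrasts = [c for c in grid.columns if c != "block"]
    width = max(len(f) for f in grid.index) + 2
    lines = [("feature".ljust(width) + "".join(c.rjust(16) for c in contrasts))]
    last_block = None
    for f, row in grid.iterrows():
        if row["block"] != last_block:
            lines.append(f"-- {row['block']} variables --")
            last_block = row["block"]
        cells = []
        for c in contrasts:
            p = row[c]
            cells.append((f"{p:.4g}{_stars(p, config.star_thresholds)}").rjust(16)
                         if not np.isnan(p) else "NaN".rjust(16))
        lines.append(f.ljust(width) + "".join(cells))
    return "\n".join(lines)
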