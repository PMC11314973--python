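"""Label-based views of the feature table.

The baseline condition is recorded once, as limb position P1, and doubles
as electrode shift S0.  These helpers materialize the per-factor views so
every analysis sees the level labels it expects.
"""

from __future__ import annotations

import pandas as pd

BASELINE_POSITION = "P1"
BASELINE_SHIFT = "S0"


def factor_view(features: pd.DataFrame, factor_kind: str) -> pd.DataFrame:
    """All rows of one factor, with the shared baseline relabeled.

    position: P1..P4 as stored.  shift: S1..S4 plus the P1 rows relabeled
    (factor_kind="shift", factor_level="S0").
    """
    if factor_kind == "position":
        return features[features["factor_kind"] == "position"].copy()
    if factor_kind == "shift":
        shift = features[features["factor_kind"] == "shift"]
        base = features[(features["factor_kind"] == "position")
                        & (features["factor_level"] == BASELINE_POSITION)]
        base = base.copy()
        base["factor_kind"] = "shift"
        base["factor_level"] = BASELINE_SHIFT
        return pd.concat([base, shift], ignore_index=True)
    raise ValueError(f"unknown factor kind {factor_kind!r}")


def combined_view(features: pd.DataFrame) -> pd.DataFrame:
    """Both factors with their 8 distinct levels (P1..P4, S1..S4)."""
    return features.copy()


def kind_levels(view: pd.DataFrame, factor_kind: str) -> list:
    """Sorted level labels present in a factor view."""
    levels = sorted(view["factor_level"].unique())
    expected_prefix = "P" if factor_kind == "position" else "S"
    bad = [l for l in levels if not str(l).startswith(expected_prefix)]
    if bad:
        raise ValueError(f"levels {bad} do not belong to {factor_kind}")
    return levels


def baseline_level(factor_kind: str) -> str:
    if factor_kind == "position":
        return BASELINE_POSITION
    if factor_kind == "shift":
        return BASELINE_SHIFT
    raise ValueError(f"unknown factor kind {factor_kind!r}")
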